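import numpy as np
import pytest

from multisrm.data import UNOBSERVED, LayerSpec, MultiplexNetwork, Roster
from multisrm.simulate import SimulationConfig, simulate


@pytest.fixture
def tiny_net() -> MultiplexNetwork:
    """Three people, all egos, one layer, a couple of ties."""
    J = 3
    G = np.full((J, J, 1), UNOBSERVED, dtype=np.int8)
    obs = ~np.eye(J, dtype=bool)
    G[obs, 0] = 0
    G[0, 1, 0] = 1
    G[1, 0, 0] = 1
    G[2, 0, 0] = 1
    roster = Roster(ids=("ana", "bob", "cyn"), is_ego=np.ones(J, bool))
    return MultiplexNetwork(roster=roster, layers=[LayerSpec("give")], G=G)


@pytest.fixture
def mixed_net() -> MultiplexNetwork:
    """Five people (two egos), two layers, used for masking tests."""
    J = 5
    is_ego = np.array([True, True, False, False, False])
    G = np.full((J, J, 2), UNOBSERVED, dtype=np.int8)
    obs = is_ego[:, None] & ~np.eye(J, dtype=bool)
    G[obs, :] = 0
    G[0, 1, 0] = G[0, 2, 0] = G[1, 0, 1] = G[1, 4, 1] = 1
    roster = Roster(ids=tuple("abcde"), is_ego=is_ego)
    return MultiplexNetwork(
        roster=roster,
        layers=[LayerSpec("give"), LayerSpec("rate", role="rating")],
        G=G,
    )


@pytest.fixture
def sim_small():
    """Simulated 12-person two-layer network with known truth."""
    config = SimulationConfig(
        J=12,
        M=2,
        eta=[-1.0, 0.0],
        sigma=0.8 * np.ones(4),
        rho_gen=np.eye(4),
        varsigma=[1.0, 0.7],
        C=np.eye(2),
        B=np.array([[0.5, 0.0], [0.0, 0.4]]),
        ego_fraction=0.75,
        layer_names=["give", "rate"],
        seed=42,
    )
    net, state = simulate(config)
    return config, net, state
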