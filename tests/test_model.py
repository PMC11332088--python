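"""Likelihood, effect transforms, priors, and the symmetry penalty."""

import numpy as np
import pytest
from scipy.stats import norm

from multisrm.data import DyadIndex, UNOBSERVED
from multisrm.model import (
    DyadicEffects,
    FixedEffects,
    GeneralizedEffects,
    HyperPriors,
    ParameterState,
    corr_from_cholesky,
    linear_predictor,
    linear_predictor_matrix,
    log_likelihood,
    log_posterior,
    log_prior,
    lkj_cholesky_logpdf,
    symmetry_penalty,
    transform_dyadic,
    transform_generalized,
)


def _random_cholesky(K: int, rng) -> np.ndarray:
    A = rng.standard_normal((K, K))
    S = A @ A.T + K * np.eye(K)
    d = np.sqrt(np.diag(S))
    L = np.linalg.cholesky(S / np.outer(d, d))
    return L / np.sqrt((L**2).sum(axis=1, keepdims=True))


def _random_state(J, M, rng, sigma=None, varsigma=None) -> ParameterState:
    K = 2 * M
    D = J * (J - 1) // 2
    return ParameterState(
        fixed=FixedEffects(eta=rng.standard_normal(M)),
        gen=GeneralizedEffects(
            raw=rng.standard_normal((J, K)),
            sigma=np.abs(rng.standard_normal(K)) + 0.2 if sigma is None else sigma,
            L=_random_cholesky(K, rng),
        ),
        dyad=DyadicEffects(
            raw=rng.standard_normal((D, K)),
            varsigma_free=np.abs(rng.standard_normal(M)) + 0.2
            if varsigma is None
            else varsigma,
            Gamma=_random_cholesky(K, rng),
        ),
    )


class TestTransformGeneralized:
    def test_identity_map(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((5, 4))
        gen = GeneralizedEffects(raw=raw, sigma=np.ones(4), L=np.eye(4))
        alpha, beta = transform_generalized(gen)
        assert np.allclose(np.hstack([alpha, beta]), raw)

    def test_zero_raws_give_zero_effects(self):
        rng = np.random.default_rng(1)
        gen = GeneralizedEffects(
            raw=np.zeros((6, 4)), sigma=np.array([1.0, 2.0, 0.5, 3.0]),
            L=_random_cholesky(4, rng),
        )
        alpha, beta = transform_generalized(gen)
        assert np.all(alpha == 0) and np.all(beta == 0)

    def test_empirical_covariance_matches_target(self):
        """Monte-Carlo check: transformed unit normals have cov diag(s)LL'diag(s)."""
        rng = np.random.default_rng(2)
        K = 4
        L = _random_cholesky(K, rng)
        sigma = np.array([0.5, 1.0, 1.5, 0.8])
        raw = rng.standard_normal((100_000, K))
        gen = GeneralizedEffects(raw=raw, sigma=sigma, L=L)
        alpha, beta = transform_generalized(gen)
        draws = np.hstack([alpha, beta])
        target = np.diag(sigma) @ L @ L.T @ np.diag(sigma)
        err = np.linalg.norm(np.cov(draws.T) - target)
        assert err < 0.05


class TestTransformDyadic:
    def test_identity_map(self):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((10, 2))
        dyad = DyadicEffects(raw=raw, varsigma_free=np.ones(1), Gamma=np.eye(2))
        assert np.allclose(transform_dyadic(dyad), raw)

    def test_zero_raws(self):
        dyad = DyadicEffects(
            raw=np.zeros((4, 2)), varsigma_free=np.array([2.0]), Gamma=np.eye(2)
        )
        assert np.all(transform_dyadic(dyad) == 0)

    def test_direction_tie_equalizes_marginal_scales(self):
        """The two directions of a dyad share a marginal sd exactly (and empirically)."""
        rng = np.random.default_rng(4)
        M, K = 2, 4
        Gamma = _random_cholesky(K, rng)
        vs = np.array([1.3, 0.6])
        dyad = DyadicEffects(
            raw=rng.standard_normal((100_000, K)), varsigma_free=vs, Gamma=Gamma
        )
        assert np.allclose(dyad.varsigma[:M], dyad.varsigma[M:])
        delta = transform_dyadic(dyad)
        sd = delta.std(axis=0)
        assert np.allclose(sd[:M], sd[M:], atol=0.02)


class TestLinearPredictor:
    def test_all_zero_gives_even_odds(self):
        state = _random_state(5, 2, np.random.default_rng(5))
        state.fixed.eta[:] = 0
        state.gen.raw[:] = 0
        state.dyad.raw[:] = 0
        theta = linear_predictor(state, 0, 1, 0)
        assert theta == 0.0
        assert 1 / (1 + np.exp(-theta)) == 0.5

    def test_intercept_only(self):
        state = _random_state(4, 1, np.random.default_rng(6))
        state.fixed.eta[:] = -2.0
        state.gen.raw[:] = 0
        state.dyad.raw[:] = 0
        assert linear_predictor(state, 2, 0, 0) == pytest.approx(-2.0)

    def test_matches_term_by_term_sum(self):
        rng = np.random.default_rng(7)
        J, M = 6, 2
        state = _random_state(J, M, rng)
        alpha, beta = transform_generalized(state.gen)
        delta = transform_dyadic(state.dyad)
        idx = DyadIndex(J)
        for j, k, m in [(0, 1, 0), (3, 2, 1), (5, 4, 0)]:
            d, direction = idx.dyad_of(j, k)
            expected = (
                state.fixed.eta[m]
                + alpha[j, m]
                + beta[k, m]
                + delta[d, m + direction * M]
            )
            assert linear_predictor(state, j, k, m) == pytest.approx(expected)

    def test_self_pair_rejected(self):
        state = _random_state(4, 1, np.random.default_rng(8))
        with pytest.raises(ValueError):
            linear_predictor(state, 1, 1, 0)


class TestLogLikelihood:
    def test_single_cell_even_odds(self, tiny_net):
        net = tiny_net
        state = _random_state(3, 1, np.random.default_rng(9))
        state.fixed.eta[:] = 0
        state.gen.raw[:] = 0
        state.dyad.raw[:] = 0
        # all 6 observed cells at p = 0.5 regardless of outcome
        assert log_likelihood(net, state) == pytest.approx(6 * np.log(0.5))

    def test_all_zero_network_limit(self, tiny_net):
        net = tiny_net
        net.G[net.observed_mask, 0] = 0
        state = _random_state(3, 1, np.random.default_rng(10))
        state.gen.raw[:] = 0
        state.dyad.raw[:] = 0
        state.fixed.eta[:] = -40.0
        assert log_likelihood(net, state) == pytest.approx(0.0, abs=1e-12)

    def test_matches_cellwise_oracle(self, sim_small):
        _, net, state = sim_small
        theta = linear_predictor_matrix(state)
        total = 0.0
        J, M = net.roster.size, net.n_layers
        for j in range(J):
            for k in range(J):
                for m in range(M):
                    g = net.G[j, k, m]
                    if g == UNOBSERVED:
                        continue
                    p = 1 / (1 + np.exp(-theta[j, k, m]))
                    total += np.log(p if g == 1 else 1 - p)
        assert log_likelihood(net, state) == pytest.approx(total, rel=1e-9)

    def test_masked_cells_do_not_contribute(self, mixed_net):
        state = _random_state(5, 2, np.random.default_rng(11))
        base = log_likelihood(mixed_net, state)
        tampered = mixed_net
        # flip hidden cells: non-ego rows stay unobserved so value is moot
        assert (tampered.G[2:, :, :] == UNOBSERVED).all()
        assert log_likelihood(tampered, state) == base


class TestCorrFromCholesky:
    def test_identity(self):
        assert np.allclose(corr_from_cholesky(np.eye(4)), np.eye(4))

    def test_two_by_two_angle(self):
        r = 0.6
        Gamma = np.array([[1.0, 0.0], [r, np.sqrt(1 - r**2)]])
        rho = corr_from_cholesky(Gamma)
        assert rho[0, 1] == pytest.approx(r)
        assert rho[1, 0] == pytest.approx(r)

    def test_unit_diagonal_and_psd(self):
        rng = np.random.default_rng(12)
        Gamma = _random_cholesky(6, rng)
        rho = corr_from_cholesky(Gamma)
        assert np.allclose(np.diag(rho), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(rho).min() >= -1e-8

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            corr_from_cholesky(np.ones((3, 3)))


class TestSymmetryPenalty:
    def test_maximum_on_block_symmetric_rho(self):
        M = 3
        rng = np.random.default_rng(13)
        C = np.eye(M) + 0.0
        B = 0.3 * np.eye(M)
        rho = np.block([[C, B], [B, C]])
        eps = 0.1
        expected = M * (M - 1) * norm.logpdf(0.0, 0.0, eps)
        assert symmetry_penalty(rho, eps) == pytest.approx(expected)
        # perturbing any constrained entry strictly decreases the penalty
        bad = rho.copy()
        bad[0, 1] += 0.05
        assert symmetry_penalty(bad, eps) < symmetry_penalty(rho, eps)

    def test_single_layer_penalty_is_zero(self):
        assert symmetry_penalty(np.eye(2), 0.1) == 0.0

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(14)
        K, M, eps = 6, 3, 0.1
        A = rng.standard_normal((K, K))
        S = A @ A.T + K * np.eye(K)
        d = np.sqrt(np.diag(S))
        rho = S / np.outer(d, d)
        expected = 0.0
        for m in range(M - 1):
            for n in range(m + 1, M):
                expected += norm.logpdf(
                    abs(rho[m + M, n + M] - rho[m, n]), 0.0, eps
                )
                expected += norm.logpdf(
                    abs(rho[m, n + M] - rho[n, m + M]), 0.0, eps
                )
        assert symmetry_penalty(rho, eps) == pytest.approx(expected)

    def test_strictly_decreasing_in_each_difference(self):
        M = 2
        rho0 = np.eye(4)
        vals = []
        for d in [0.0, 0.05, 0.1, 0.2]:
            rho = rho0.copy()
            rho[0, 1] = rho[1, 0] = 0.3
            rho[2, 3] = rho[3, 2] = 0.3 + d
            vals.append(symmetry_penalty(rho, 0.1))
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestLogPrior:
    def test_closed_form_at_reference_point(self):
        """Assemble the expected value term by term with scipy densities."""
        rng = np.random.default_rng(15)
        J, M = 4, 2
        K, D = 2 * M, J * (J - 1) // 2
        state = ParameterState(
            fixed=FixedEffects(eta=np.zeros(M)),
            gen=GeneralizedEffects(
                raw=np.zeros((J, K)), sigma=np.ones(K), L=np.eye(K)
            ),
            dyad=DyadicEffects(
                raw=np.zeros((D, K)), varsigma_free=np.ones(M), Gamma=np.eye(K)
            ),
        )
        hyper = HyperPriors()
        expected = (
            norm.logpdf(0.0).sum() * (J * K + D * K)  # unit-normal raws at 0
            + (np.log(2.5) - 2.5) * K  # Exponential(2.5) at sigma = 1
            + (np.log(2.5) - 2.5) * M  # Exponential(2.5) at free varsigma = 1
            + 0.0  # LKJ kernel at identity factors
            + M * (M - 1) * norm.logpdf(0.0, 0.0, hyper.epsilon)
            + norm.logpdf(0.0, 0.0, hyper.eta_scale) * M
        )
        assert log_prior(state, hyper) == pytest.approx(expected)

    def test_quadratic_response_to_raw_perturbation(self):
        rng = np.random.default_rng(16)
        state = _random_state(5, 2, rng)
        hyper = HyperPriors()
        base = log_prior(state, hyper)
        z = state.gen.raw[0, 0]
        state.gen.raw[0, 0] = 2 * z
        # normal kernel: delta log p = -(1/2)(4z^2 - z^2)
        assert log_prior(state, hyper) - base == pytest.approx(-1.5 * z**2)

    def test_penalty_scales_with_epsilon_like_symmetry_penalty(self):
        rng = np.random.default_rng(17)
        state = _random_state(4, 2, rng)
        rho = state.dyad.Gamma @ state.dyad.Gamma.T
        h1 = HyperPriors(epsilon=0.1)
        h2 = HyperPriors(epsilon=0.3)
        diff = log_prior(state, h1) - log_prior(state, h2)
        assert diff == pytest.approx(
            symmetry_penalty(rho, 0.1) - symmetry_penalty(rho, 0.3)
        )

    def test_nonpositive_scales_rejected(self):
        state = _random_state(4, 1, np.random.default_rng(18))
        state.gen.sigma = np.zeros(2)
        with pytest.raises(ValueError):
            log_prior(state, HyperPriors())


class TestLogPosterior:
    def test_equals_sum_of_components(self, sim_small):
        _, net, state = sim_small
        hyper = HyperPriors()
        assert log_posterior(net, state, hyper) == pytest.approx(
            log_likelihood(net, state) + log_prior(state, hyper)
        )

    def test_invariant_under_node_relabeling(self, sim_small):
        """Permuting people (and their effects) leaves the posterior unchanged.

        Relabeling flips the direction orientation of some dyads, which
        permutes the two direction blocks of their raw effect vectors.
        That raw-space swap mirrors the delta-space swap when the dyadic
        rotation is direction-exchangeable, so the check pins Gamma at
        the identity (an exactly block-symmetric correlation).
        """
        _, net, state = sim_small
        state.dyad.Gamma = np.eye(2 * net.n_layers)
        hyper = HyperPriors()
        base = log_posterior(net, state, hyper)

        J, M = net.roster.size, net.n_layers
        rng = np.random.default_rng(19)
        # keep egos first so the network stays valid, permute within groups
        egos = list(np.flatnonzero(net.roster.is_ego))
        alters = list(np.flatnonzero(~net.roster.is_ego))
        perm = np.array(
            list(rng.permutation(egos)) + list(rng.permutation(alters))
        )
        from multisrm.data import LayerSpec, MultiplexNetwork, Roster

        net2 = MultiplexNetwork(
            roster=Roster(
                ids=tuple(net.roster.ids[p] for p in perm),
                is_ego=net.roster.is_ego[perm],
            ),
            layers=net.layers,
            G=net.G[np.ix_(perm, perm)],
        )
        idx, idx2 = DyadIndex(J), DyadIndex(J)
        inv = np.empty(J, dtype=int)
        inv[perm] = np.arange(J)
        # permute dyadic raws to follow the relabeling
        raw2 = np.empty_like(state.dyad.raw)
        for d in range(idx.n_dyads):
            j2, k2 = idx2.endpoints(d, 0)  # pair in the new labelling
            j, k = perm[j2], perm[k2]
            d_old, direction = idx.dyad_of(j, k)
            if direction == 0:
                raw2[d, :M] = state.dyad.raw[d_old, :M]
                raw2[d, M:] = state.dyad.raw[d_old, M:]
            else:
                raw2[d, :M] = state.dyad.raw[d_old, M:]
                raw2[d, M:] = state.dyad.raw[d_old, :M]
        state2 = ParameterState(
            fixed=state.fixed,
            gen=GeneralizedEffects(
                raw=state.gen.raw[perm], sigma=state.gen.sigma, L=state.gen.L
            ),
            dyad=DyadicEffects(
                raw=raw2,
                varsigma_free=state.dyad.varsigma_free,
                Gamma=state.dyad.Gamma,
            ),
        )
        assert log_posterior(net2, state2, hyper) == pytest.approx(base)

    def test_monotone_in_agreement_with_observed_cell(self, tiny_net):
        """Raising the dyadic effect behind an observed 1 raises the posterior."""
        net = tiny_net
        assert net.G[0, 1, 0] == 1
        state = _random_state(3, 1, np.random.default_rng(20))
        state.dyad.Gamma = np.eye(2)
        state.dyad.varsigma_free = np.array([2.0])
        state.fixed.eta[:] = 0.0
        state.gen.raw[:] = 0.0
        idx = DyadIndex(3)
        d, direction = idx.dyad_of(0, 1)
        hyper = HyperPriors()
        state.dyad.raw[d, direction] = 0.0
        lp0 = log_posterior(net, state, hyper)
        state.dyad.raw[d, direction] = 0.5
        lp1 = log_posterior(net, state, hyper)
        assert lp1 > lp0


class TestDyadicRawPermutation:
    def test_raw_permutation_mapping_is_consistent(self):
        """Swapping the two direction blocks mirrors swapping j and k labels."""
        rng = np.random.default_rng(21)
        M = 2
        dyad = DyadicEffects(
            raw=rng.standard_normal((3, 4)),
            varsigma_free=np.array([1.0, 2.0]),
            Gamma=np.eye(4),
        )
        delta = transform_dyadic(dyad)
        swapped = DyadicEffects(
            raw=np.hstack([dyad.raw[:, M:], dyad.raw[:, :M]]),
            varsigma_free=dyad.varsigma_free,
            Gamma=np.eye(4),
        )
        delta_swapped = transform_dyadic(swapped)
        assert np.allclose(delta_swapped[:, :M], delta[:, M:])
        assert np.allclose(delta_swapped[:, M:], delta[:, :M])


def test_lkj_kernel_at_identity_is_zero():
    assert lkj_cholesky_logpdf(np.eye(5), 2.5) == 0.0
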