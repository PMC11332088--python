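"""Posterior sampling, diagnostics, and correlation summaries.

:func:`fit` samples the multiplex SRM posterior with the package's NUTS
engine and records the interpretable quantities per draw: layer
intercepts, random-effect standard deviations, and the two 2M x 2M
correlation matrices (generalized sender/receiver correlations and
dyadic correlations). :func:`summarize` reports posterior means with
89% equal-tailed credible intervals by default, plus split-Rhat and
effective sample size; :func:`correlation_report` emits the long-format
tables from which reciprocity-matrix figures are drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

from .data import MultiplexNetwork
from .hmc import NutsConfig, nuts_chain
from .model import HyperPriors
from .posterior import SRMPosterior

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "PosteriorSamples",
    "CorrelationReport",
    "fit",
    "diagnose",
    "summarize",
    "correlation_report",
]


@dataclass(frozen=True)
class FitConfig:
    """Sampler configuration.

    Defaults (4 chains, 500 warmup + 500 sampling iterations) suit
    desk-scale data; community-scale networks warrant longer runs.
    ``fix_scales`` pins every random-effect standard deviation to a
    constant (0 gives an intercept-only logistic model), which is used
    for oracle checks.
    """

    chains: int = 4
    warmup_iterations: int = 500
    sampling_iterations: int = 500
    seed: int = 0
    epsilon: float = 0.1
    hyper: HyperPriors = field(default_factory=HyperPriors)
    max_depth: int = 10
    target_accept: float = 0.9
    fix_scales: float | None = None
    jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.warmup_iterations < 0 or self.sampling_iterations <= 0:
            raise ValueError("iteration counts must be positive")


@dataclass
class PosteriorSamples:
    """Per-chain draws of the interpretable model quantities.

    ``params`` maps a parameter-block name to an array of shape
    (chains, draws, *block_shape). Blocks produced by :func:`fit`:
    ``eta`` (M,), ``sigma`` (2M,), ``varsigma`` (M,), ``rho_gen`` and
    ``rho_dyad`` (2M, 2M), and the scalar ``lp``.
    """

    params: dict[str, np.ndarray]
    layer_names: list[str]
    stats: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    @property
    def gen_labels(self) -> list[str]:
        return [f"{l}:sender" for l in self.layer_names] + [
            f"{l}:receiver" for l in self.layer_names
        ]

    @property
    def dyad_labels(self) -> list[str]:
        return [f"{l}:ij" for l in self.layer_names] + [
            f"{l}:ji" for l in self.layer_names
        ]


def _axis_labels(samples: PosteriorSamples, name: str, shape: tuple) -> list[list[str]]:
    layers = samples.layer_names
    if name == "eta" or name == "varsigma":
        return [layers]
    if name == "sigma":
        return [samples.gen_labels]
    if name == "rho_gen":
        return [samples.gen_labels, samples.gen_labels]
    if name == "rho_dyad":
        return [samples.dyad_labels, samples.dyad_labels]
    return [[str(i) for i in range(n)] for n in shape]


def iter_scalars(samples: PosteriorSamples):
    """Yield (label, draws (chains, n)) for every reportable scalar.

    Correlation matrices contribute their strict upper triangle only;
    the diagonal is identically one and the matrices are symmetric.
    """
    for name, arr in samples.params.items():
        shape = arr.shape[2:]
        if shape == ():
            yield name, arr
        elif len(shape) == 1:
            labels = _axis_labels(samples, name, shape)[0]
            for i in range(shape[0]):
                yield f"{name}[{labels[i]}]", arr[:, :, i]
        elif len(shape) == 2 and name.startswith("rho"):
            labels = _axis_labels(samples, name, shape)[0]
            for i in range(shape[0]):
                for j in range(i + 1, shape[1]):
                    yield f"{name}[{labels[i]},{labels[j]}]", arr[:, :, i, j]
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for i in range(flat.shape[2]):
                yield f"{name}[{i}]", flat[:, :, i]


def fit(net: MultiplexNetwork, config: FitConfig) -> PosteriorSamples:
    """Sample the multiplex SRM posterior by NUTS.

    Chains run sequentially with independent RNG streams spawned from
    ``config.seed``; two fits with identical configuration produce
    identical draws on one platform.
    """
    hyper = replace(config.hyper, epsilon=config.epsilon)
    post = SRMPosterior(net, hyper, fix_scales=config.fix_scales)
    if post.P == 0:
        raise ValueError("network has no observed cells")
    nuts = NutsConfig(
        n_warmup=config.warmup_iterations,
        n_samples=config.sampling_iterations,
        max_depth=config.max_depth,
        target_accept=config.target_accept,
    )
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    blocks = ("eta", "sigma", "varsigma", "rho_gen", "rho_dyad")
    collected: dict[str, list] = {b: [] for b in blocks}
    collected["lp"] = []
    chain_stats = []
    for c, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        phi0 = post.init_position(rng, jitter=config.jitter)
        records: dict[str, list] = {b: [] for b in blocks}
        lps: list[float] = []

        def store(q: np.ndarray, logp: float) -> None:
            u = post.unpack(q)
            for b in blocks:
                records[b].append(u[b])
            lps.append(logp)

        logger.info("chain %d/%d: warmup %d + sampling %d iterations",
                    c + 1, config.chains, nuts.n_warmup, nuts.n_samples)
        try:
            result = nuts_chain(
                post.logp_and_grad, phi0, rng, nuts, store=store,
                label=f"chain {c + 1}",
            )
        except FloatingPointError as exc:
            raise RuntimeError(
                f"chain {c + 1} failed at initialization "
                f"(J={post.J}, M={post.M}, {post.n_params} parameters): {exc}"
            ) from exc
        for b in blocks:
            collected[b].append(np.asarray(records[b]))
        collected["lp"].append(np.asarray(lps))
        chain_stats.append(
            {k: result[k] for k in
             ("divergences", "divergences_warmup", "step_size")}
        )
        logger.info("chain %d done: step size %.3g, %d divergences",
                    c + 1, result["step_size"], result["divergences"])
    params = {k: np.stack(v) for k, v in collected.items()}
    return PosteriorSamples(
        params=params,
        layer_names=net.layer_names,
        stats={"chains": chain_stats, "seed": config.seed, "config": config},
    )


def diagnose(samples: PosteriorSamples) -> pd.DataFrame:
    """Split-Rhat and bulk effective sample size per reportable scalar."""
    if samples.n_chains < 2:
        raise ValueError("Rhat requires at least two chains")
    rows = []
    for label, draws in iter_scalars(samples):
        if np.ptp(draws) == 0:  # constant across all chains: diagnostics undefined
            rhat, ess = np.nan, np.nan
        else:
            rhat = float(az.rhat(np.asarray(draws)))
            ess = float(az.ess(np.asarray(draws)))
        rows.append({"parameter": label, "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows).set_index("parameter")


def summarize(samples: PosteriorSamples, level: float = 0.89) -> pd.DataFrame:
    """Posterior means and equal-tailed credible intervals per scalar.

    The default level of 0.89 reports the (5.5%, 94.5%) quantiles.
    Rhat and ESS columns are included when at least two chains exist.
    """
    if not 0 < level < 1:
        raise ValueError("credible level must be in (0, 1)")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    diag = None
    if samples.n_chains >= 2:
        diag = diagnose(samples)
    rows = []
    for label, draws in iter_scalars(samples):
        flat = np.asarray(draws).reshape(-1)
        row = {
            "parameter": label,
            "mean": float(flat.mean()),
            "ci_low": float(np.quantile(flat, lo_q)),
            "ci_high": float(np.quantile(flat, hi_q)),
        }
        if diag is not None:
            row["rhat"] = diag.loc[label, "rhat"]
            row["ess"] = diag.loc[label, "ess"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class CorrelationReport:
    """Posterior summaries of the two 2M x 2M correlation matrices.

    ``dyadic`` and ``generalized`` are long-format tables with one row
    per unordered matrix entry (row_label, col_label, mean, ci_low,
    ci_high, reliable); an entry is flagged reliable when its credible
    interval excludes zero — a display convention, not a test.
    ``dyadic_mean`` / ``generalized_mean`` are the posterior-mean
    matrices themselves.
    """

    dyadic: pd.DataFrame
    generalized: pd.DataFrame
    dyadic_mean: np.ndarray
    generalized_mean: np.ndarray
    dyad_labels: list[str]
    gen_labels: list[str]


def _matrix_table(arr: np.ndarray, labels: list[str], lo_q: float, hi_q: float) -> pd.DataFrame:
    K = arr.shape[-1]
    flat = arr.reshape(-1, K, K)
    rows = []
    for i in range(K):
        for j in range(i + 1, K):
            draws = flat[:, i, j]
            lo = float(np.quantile(draws, lo_q))
            hi = float(np.quantile(draws, hi_q))
            rows.append(
                {
                    "row_label": labels[i],
                    "col_label": labels[j],
                    "mean": float(draws.mean()),
                    "ci_low": lo,
                    "ci_high": hi,
                    "reliable": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)


def correlation_report(samples: PosteriorSamples, level: float = 0.89) -> CorrelationReport:
    """Summarize the dyadic and generalized correlation matrices.

    The dyadic matrix rho carries within-layer dyadic reciprocity on the
    (m, m+M) entries, within-person between-layer correlations on the
    leading C block, and between-person between-layer correlations on
    the B block; the generalized matrix carries sender/receiver
    correlations within and across layers.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rho_d = samples.params["rho_dyad"]
    rho_g = samples.params["rho_gen"]
    return CorrelationReport(
        dyadic=_matrix_table(rho_d, samples.dyad_labels, lo_q, hi_q),
        generalized=_matrix_table(rho_g, samples.gen_labels, lo_q, hi_q),
        dyadic_mean=rho_d.reshape(-1, *rho_d.shape[2:]).mean(axis=0),
        generalized_mean=rho_g.reshape(-1, *rho_g.shape[2:]).mean(axis=0),
        dyad_labels=samples.dyad_labels,
        gen_labels=samples.gen_labels,
    )
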