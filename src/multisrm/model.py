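"""Multiplex social relations model: likelihood, transforms, and priors.

The model decomposes the log-odds of a directed tie from sender j to
receiver k in layer m as

    theta[j,k,m] = eta[m] + alpha[j,m] + beta[k,m] + delta[j,k,m] + covariates

with ``G[j,k,m] ~ Bernoulli(logistic(theta))``. The per-person sender and
receiver effects (alpha, beta) are jointly multivariate normal across the
2M (layer, role) axes, and the paired dyad effects (delta[j,k,·],
delta[k,j,·]) are jointly multivariate normal across the 2M
(layer, direction) axes. Both are expressed in non-centered form: unit
normal raw vectors scaled by standard deviations and rotated by the
Cholesky factor of a correlation matrix.

Exchangeability of the two direction labels within a dyad imposes two
constraints on the dyadic block: the scale of delta[j,k,m] must equal that
of delta[k,j,m] (the 2M-vector of scales has only M free values), and the
2M x 2M dyadic correlation matrix rho must have the block form
``[[C, B], [B, C]]`` with B symmetric. No Cholesky-based construction
guarantees that structure, so it is imposed softly: Gaussian penalties
with scale epsilon shrink the block-asymmetry norms of rho toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import DyadIndex, MultiplexNetwork

__all__ = [
    "HyperPriors",
    "Covariates",
    "FixedEffects",
    "GeneralizedEffects",
    "DyadicEffects",
    "ParameterState",
    "transform_generalized",
    "transform_dyadic",
    "linear_predictor",
    "linear_predictor_matrix",
    "log_likelihood",
    "corr_from_cholesky",
    "symmetry_penalty",
    "log_prior",
    "log_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def bernoulli_logit_logpmf(y: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Log-mass of Bernoulli(logistic(theta)) at y, computed stably."""
    return np.asarray(y, dtype=float) * theta - softplus(theta)


@dataclass(frozen=True)
class HyperPriors:
    """Hyperparameters of the weakly informative priors.

    scale_rate
        Rate of the exponential prior on all random-effect standard
        deviations (default 2.5, prior mean 0.4 on the log-odds scale).
    lkj_eta
        Concentration of the LKJ prior on both correlation Cholesky
        factors (default 2.5, mildly favouring weak correlations).
    epsilon
        Scale of the Gaussian block-symmetry penalties on the dyadic
        correlation matrix; smaller values enforce the block structure
        more strictly (default 0.1).
    eta_scale
        Standard deviation of the Normal(0, eta_scale) prior on layer
        intercepts and covariate coefficients (default 5).
    """

    scale_rate: float = 2.5
    lkj_eta: float = 2.5
    epsilon: float = 0.1
    eta_scale: float = 5.0

    def __post_init__(self) -> None:
        for name in ("scale_rate", "lkj_eta", "epsilon", "eta_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Covariates:
    """Optional sender / receiver / dyadic predictor arrays.

    sender : array (Cs, J) — one row per sender-level covariate (e.g. wealth)
    receiver : array (Cr, J) — receiver-level covariates
    dyadic : array (Cd, J, J) — pair-level covariates (e.g. relatedness)
    """

    sender: Optional[np.ndarray] = None
    receiver: Optional[np.ndarray] = None
    dyadic: Optional[np.ndarray] = None


@dataclass
class FixedEffects:
    """Per-layer intercepts and optional covariate coefficients.

    ``eta[m]`` is the intercept of layer m on the log-odds scale. When
    covariates are supplied, ``lam_*[c, m]`` is the coefficient of
    covariate c in layer m.
    """

    eta: np.ndarray
    covariates: Optional[Covariates] = None
    lam_sender: Optional[np.ndarray] = None
    lam_receiver: Optional[np.ndarray] = None
    lam_dyad: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.ndim != 1 or not np.isfinite(self.eta).all():
            raise ValueError("eta must be a finite 1-D array of length M")


def _check_corr_cholesky(L: np.ndarray, name: str) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(L, np.tril(L)):
        raise ValueError(f"{name} must be lower triangular")
    if (np.diag(L) <= 0).any():
        raise ValueError(f"{name} must have a positive diagonal")
    if not np.allclose((L**2).sum(axis=1), 1.0, atol=1e-8):
        raise ValueError(f"{name} rows must have unit norm")
    return L


@dataclass
class GeneralizedEffects:
    """Non-centered sender/receiver (generalized) random effects.

    raw : (J, 2M) unit-normal raw effects, columns ordered
        (alpha layer 1..M, beta layer 1..M).
    sigma : (2M,) positive standard deviations.
    L : (2M, 2M) Cholesky factor of the sender/receiver correlation
        matrix; the implied covariance is diag(sigma) L L' diag(sigma).
    """

    raw: np.ndarray
    sigma: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.L = _check_corr_cholesky(self.L, "L")
        K = self.L.shape[0]
        if K % 2 != 0:
            raise ValueError("generalized axis must have even length 2M")
        if self.sigma.shape != (K,) or (self.sigma < 0).any():
            raise ValueError("sigma must be a nonnegative vector of length 2M")
        if self.raw.ndim != 2 or self.raw.shape[1] != K:
            raise ValueError("raw must have shape (J, 2M)")

    @property
    def n_layers(self) -> int:
        return self.L.shape[0] // 2


@dataclass
class DyadicEffects:
    """Non-centered dyad-level random effects with the direction-tie.

    raw : (D, 2M) unit-normal raws over unordered dyads; columns 0..M-1
        are the low-to-high direction, M..2M-1 the reverse.
    varsigma_free : (M,) free standard deviations; the full 2M scale
        vector repeats them so the two directions of a dyad share a
        marginal scale exactly.
    Gamma : (2M, 2M) Cholesky factor of the dyadic correlation matrix.
    """

    raw: np.ndarray
    varsigma_free: np.ndarray
    Gamma: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.varsigma_free = np.asarray(self.varsigma_free, dtype=float)
        self.Gamma = _check_corr_cholesky(self.Gamma, "Gamma")
        K = self.Gamma.shape[0]
        if K % 2 != 0 or self.varsigma_free.shape != (K // 2,):
            raise ValueError("varsigma_free must have length M = K/2")
        if (self.varsigma_free < 0).any():
            raise ValueError("varsigma_free must be nonnegative")
        if self.raw.ndim != 2 or self.raw.shape[1] != K:
            raise ValueError("raw must have shape (D, 2M)")

    @property
    def varsigma(self) -> np.ndarray:
        """Full 2M scale vector with the direction-tie applied."""
        return np.concatenate([self.varsigma_free, self.varsigma_free])

    @property
    def n_layers(self) -> int:
        return self.Gamma.shape[0] // 2


@dataclass
class ParameterState:
    """Complete parameter state of the multiplex SRM."""

    fixed: FixedEffects
    gen: GeneralizedEffects
    dyad: DyadicEffects

    def __post_init__(self) -> None:
        M = len(self.fixed.eta)
        if self.gen.n_layers != M or self.dyad.n_layers != M:
            raise ValueError("layer counts of fixed, gen, dyad must agree")

    @property
    def n_layers(self) -> int:
        return len(self.fixed.eta)

    @property
    def n_persons(self) -> int:
        return self.gen.raw.shape[0]


def transform_generalized(gen: GeneralizedEffects) -> tuple[np.ndarray, np.ndarray]:
    """Scale-and-rotate the raw generalized effects.

    Returns (alpha, beta), each of shape (J, M). With unit-normal raws the
    rows are draws from MVN(0, diag(sigma) L L' diag(sigma)).
    """
    effects = (gen.raw @ gen.L.T) * gen.sigma
    M = gen.n_layers
    return effects[:, :M], effects[:, M:]


def transform_dyadic(dyad: DyadicEffects) -> np.ndarray:
    """Scale-and-rotate the raw dyadic effects.

    Returns an array of shape (D, 2M): columns 0..M-1 hold
    delta[lo->hi, m], columns M..2M-1 hold delta[hi->lo, m]. The
    direction-tie makes the two marginal scales of a dyad equal exactly.
    """
    return (dyad.raw @ dyad.Gamma.T) * dyad.varsigma


def _covariate_term(fixed: FixedEffects, J: int, M: int) -> np.ndarray:
    """Covariate contribution to theta, shape (J, J, M); zeros if none."""
    out = np.zeros((J, J, M))
    cov = fixed.covariates
    if cov is None:
        return out
    if cov.sender is not None and fixed.lam_sender is not None:
        # sum_c lam[c,m] * X[c,j]  -> (J, M), broadcast over receivers
        out += np.einsum("cm,cj->jm", fixed.lam_sender, cov.sender)[:, None, :]
    if cov.receiver is not None and fixed.lam_receiver is not None:
        out += np.einsum("cm,ck->km", fixed.lam_receiver, cov.receiver)[None, :, :]
    if cov.dyadic is not None and fixed.lam_dyad is not None:
        out += np.einsum("cm,cjk->jkm", fixed.lam_dyad, cov.dyadic)
    return out


def linear_predictor_matrix(state: ParameterState) -> np.ndarray:
    """Log-odds theta for every ordered pair and layer, shape (J, J, M).

    Diagonal entries are set to NaN; they correspond to no modelled cell.
    """
    J, M = state.n_persons, state.n_layers
    alpha, beta = transform_generalized(state.gen)
    delta = transform_dyadic(state.dyad)
    idx = DyadIndex(J)
    theta = state.fixed.eta[None, None, :] + alpha[:, None, :] + beta[None, :, :]
    theta = theta + _covariate_term(state.fixed, J, M)
    dmat = np.zeros((J, J, M))
    dmat[idx.lo, idx.hi, :] = delta[:, :M]
    dmat[idx.hi, idx.lo, :] = delta[:, M:]
    theta = theta + dmat
    theta[np.arange(J), np.arange(J), :] = np.nan
    return theta


def linear_predictor(state: ParameterState, j: int, k: int, m: int) -> float:
    """Log-odds of a tie from person j to person k in layer m."""
    if j == k:
        raise ValueError("self-pairs have no linear predictor")
    J, M = state.n_persons, state.n_layers
    alpha, beta = transform_generalized(state.gen)
    delta = transform_dyadic(state.dyad)
    idx = DyadIndex(J)
    d, direction = idx.dyad_of(j, k)
    theta = (
        state.fixed.eta[m]
        + alpha[j, m]
        + beta[k, m]
        + delta[d, m + direction * M]
    )
    cov = _covariate_term(state.fixed, J, M)
    return float(theta + cov[j, k, m])


def log_likelihood(net: MultiplexNetwork, state: ParameterState) -> float:
    """Bernoulli-logit log-likelihood summed over observed cells only.

    Unobserved cells (the diagonal and all non-ego-sender rows)
    contribute exactly zero.
    """
    if state.n_persons != net.roster.size or state.n_layers != net.n_layers:
        raise ValueError("state dimensions do not match network")
    theta = linear_predictor_matrix(state)
    mask = net.observed_mask
    y = net.G[mask, :].astype(float)
    return float(bernoulli_logit_logpmf(y, theta[mask, :]).sum())


def corr_from_cholesky(Gamma: np.ndarray) -> np.ndarray:
    """Correlation matrix from its Cholesky factor: rho = Gamma Gamma'."""
    Gamma = _check_corr_cholesky(np.asarray(Gamma, dtype=float), "Gamma")
    rho = Gamma @ Gamma.T
    np.fill_diagonal(rho, 1.0)
    return rho


def symmetry_penalty(rho: np.ndarray, epsilon: float) -> float:
    """Gaussian log-penalty shrinking rho toward dyadic block symmetry.

    For every layer pair m < n the penalty evaluates a Normal(0, epsilon)
    log-density at the two block-asymmetry norms
    ``|rho[m+M, n+M] - rho[m, n]|`` (the two within-person C blocks must
    agree) and ``|rho[m, n+M] - rho[n, m+M]|`` (the between-person B block
    must be symmetric). It is maximal exactly on block-symmetric
    matrices; for M = 1 the index set is empty and the penalty is zero.
    """
    rho = np.asarray(rho, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    K = rho.shape[0]
    if rho.ndim != 2 or rho.shape != (K, K) or K % 2 != 0:
        raise ValueError("rho must be a square 2M x 2M matrix")
    M = K // 2
    const = -0.5 * _LOG_2PI - np.log(epsilon)
    total = 0.0
    for m in range(M - 1):
        for n in range(m + 1, M):
            d_c = rho[m + M, n + M] - rho[m, n]
            d_b = rho[m, n + M] - rho[n, m + M]
            total += 2 * const - 0.5 * (d_c**2 + d_b**2) / epsilon**2
    return float(total)


def lkj_cholesky_logpdf(L: np.ndarray, eta: float) -> float:
    """LKJ log-density kernel of a correlation Cholesky factor.

    Computed up to an additive constant that depends only on the
    dimension and eta (the constant cancels in posterior computation).
    """
    L = np.asarray(L, dtype=float)
    K = L.shape[0]
    k = np.arange(2, K + 1)
    return float(((K - k + 2.0 * eta - 2.0) * np.log(np.diag(L)[1:])).sum())


def _exponential_logpdf(x: np.ndarray, rate: float) -> float:
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("scale parameters must be positive")
    return float((np.log(rate) - rate * x).sum())


def _std_normal_logpdf_sum(z: np.ndarray) -> float:
    z = np.asarray(z, dtype=float)
    return float(-0.5 * (z**2).sum() - 0.5 * _LOG_2PI * z.size)


def log_prior(state: ParameterState, hyper: HyperPriors) -> float:
    """Joint log-prior of a parameter state.

    Unit normals on all raw effects; Exponential(scale_rate) on the 2M
    generalized scales and the M free dyadic scales; LKJ(lkj_eta) kernels
    on both Cholesky factors; the block-symmetry penalty on the dyadic
    correlation matrix; Normal(0, eta_scale) on intercepts and any
    covariate coefficients.
    """
    lp = _std_normal_logpdf_sum(state.gen.raw)
    lp += _std_normal_logpdf_sum(state.dyad.raw)
    lp += _exponential_logpdf(state.gen.sigma, hyper.scale_rate)
    lp += _exponential_logpdf(state.dyad.varsigma_free, hyper.scale_rate)
    lp += lkj_cholesky_logpdf(state.gen.L, hyper.lkj_eta)
    lp += lkj_cholesky_logpdf(state.dyad.Gamma, hyper.lkj_eta)
    rho = state.dyad.Gamma @ state.dyad.Gamma.T
    lp += symmetry_penalty(rho, hyper.epsilon)
    s = hyper.eta_scale
    norm_const = -0.5 * _LOG_2PI - np.log(s)
    eta = state.fixed.eta
    lp += float((norm_const - 0.5 * eta**2 / s**2).sum())
    for lam in (state.fixed.lam_sender, state.fixed.lam_receiver, state.fixed.lam_dyad):
        if lam is not None:
            lam = np.asarray(lam, dtype=float)
            lp += float((norm_const - 0.5 * lam**2 / s**2).sum())
    return lp


def log_posterior(net: MultiplexNetwork, state: ParameterState, hyper: HyperPriors) -> float:
    """Unnormalized joint log-density: log-likelihood plus log-prior."""
    return log_likelihood(net, state) + log_prior(state, hyper)
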