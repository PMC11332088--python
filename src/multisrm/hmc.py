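"""No-U-Turn sampler with dual-averaging step size and diagonal mass
matrix adaptation.

A self-contained gradient-based MCMC engine operating on a flat
unconstrained parameter vector. The implementation follows the standard
recipe: multinomial trajectory sampling over a doubling binary tree, the
original U-turn termination criterion, Nesterov dual averaging toward a
target acceptance statistic during warmup, and windowed estimation of a
diagonal mass matrix from warmup draws (expanding windows, variance
regularized toward unity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["NutsConfig", "nuts_chain"]

_MAX_DELTA_H = 1000.0  # divergence threshold on energy error


@dataclass
class NutsConfig:
    n_warmup: int = 500
    n_samples: int = 500
    max_depth: int = 10
    target_accept: float = 0.8
    init_step_size: float = 0.1


@dataclass
class _Tree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    q_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    q_prop: np.ndarray
    g_prop: np.ndarray
    logp_prop: float
    log_w: float
    sum_alpha: float
    n_alpha: int
    turning: bool
    diverging: bool


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target accept."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w2 = self.count ** (-self.kappa)
        self.log_eps_bar = w2 * self.log_eps + (1 - w2) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # shrink toward unit metric, as is conventional for short windows
        return var * self.n / (self.n + 5.0) + 1e-3 * 5.0 / (self.n + 5.0)


def _find_initial_step_size(
    logp_grad: Callable, q: np.ndarray, rng: np.random.Generator,
    inv_mass: np.ndarray, eps: float,
) -> float:
    logp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * float(p**2 @ inv_mass)

    def energy_after_step(e: float) -> float:
        p1 = p + 0.5 * e * grad
        q1 = q + e * inv_mass * p1
        lp1, g1 = logp_grad(q1)
        p1 = p1 + 0.5 * e * g1
        return -lp1 + 0.5 * float(p1**2 @ inv_mass)

    h1 = energy_after_step(eps)
    if not np.isfinite(h1):
        h1 = np.inf
    direction = 1.0 if (h0 - h1) > np.log(0.5) else -1.0
    for _ in range(50):
        eps_new = eps * 2.0**direction
        h1 = energy_after_step(eps_new)
        if not np.isfinite(h1):
            h1 = np.inf
        if direction > 0 and (h0 - h1) <= np.log(0.5):
            break
        if direction < 0 and (h0 - h1) > np.log(0.5):
            eps = eps_new
            break
        eps = eps_new
    return eps


def _build_tree(
    logp_grad, q, p, g, direction, depth, eps, h0, inv_mass, rng,
) -> _Tree:
    if depth == 0:
        p1 = p + 0.5 * direction * eps * g
        q1 = q + direction * eps * inv_mass * p1
        logp1, g1 = logp_grad(q1)
        p1 = p1 + 0.5 * direction * eps * g1
        h1 = -logp1 + 0.5 * float(p1**2 @ inv_mass)
        if not np.isfinite(h1):
            h1 = np.inf
        delta = h0 - h1
        diverging = bool(-delta > _MAX_DELTA_H)
        alpha = float(min(1.0, np.exp(min(delta, 0.0))))
        return _Tree(
            q1, p1, g1, q1, p1, g1, q1, g1, logp1,
            log_w=float(delta) if np.isfinite(delta) else -np.inf,
            sum_alpha=alpha, n_alpha=1,
            turning=False, diverging=diverging,
        )
    first = _build_tree(
        logp_grad, q, p, g, direction, depth - 1, eps, h0, inv_mass, rng
    )
    if first.diverging or first.turning:
        return first
    if direction > 0:
        second = _build_tree(
            logp_grad, first.q_plus, first.p_plus, first.g_plus,
            direction, depth - 1, eps, h0, inv_mass, rng,
        )
        q_minus, p_minus, g_minus = first.q_minus, first.p_minus, first.g_minus
        q_plus, p_plus, g_plus = second.q_plus, second.p_plus, second.g_plus
    else:
        second = _build_tree(
            logp_grad, first.q_minus, first.p_minus, first.g_minus,
            direction, depth - 1, eps, h0, inv_mass, rng,
        )
        q_minus, p_minus, g_minus = second.q_minus, second.p_minus, second.g_minus
        q_plus, p_plus, g_plus = first.q_plus, first.p_plus, first.g_plus

    log_w = float(np.logaddexp(first.log_w, second.log_w))
    if second.diverging or second.turning:
        turning, diverging = second.turning, second.diverging
        q_prop, g_prop, logp_prop = first.q_prop, first.g_prop, first.logp_prop
    else:
        # multinomial sampling within the doubled tree
        if np.log(rng.uniform()) < second.log_w - log_w:
            q_prop, g_prop, logp_prop = second.q_prop, second.g_prop, second.logp_prop
        else:
            q_prop, g_prop, logp_prop = first.q_prop, first.g_prop, first.logp_prop
        dq = q_plus - q_minus
        turning = (
            float(dq @ (inv_mass * p_minus)) < 0
            or float(dq @ (inv_mass * p_plus)) < 0
        )
        diverging = False
    return _Tree(
        q_minus, p_minus, g_minus, q_plus, p_plus, g_plus,
        q_prop, g_prop, logp_prop, log_w,
        first.sum_alpha + second.sum_alpha, first.n_alpha + second.n_alpha,
        turning, diverging,
    )


def _nuts_transition(logp_grad, q, logp, grad, eps, max_depth, inv_mass, rng):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * float(p0**2 @ inv_mass)
    q_minus = q_plus = q
    p_minus = p_plus = p0
    g_minus = g_plus = grad
    q_cur, g_cur, logp_cur = q, grad, logp
    log_w = 0.0
    sum_alpha, n_alpha = 0.0, 0
    divergent = False
    depth = 0
    for depth in range(max_depth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction > 0:
            tree = _build_tree(
                logp_grad, q_plus, p_plus, g_plus, 1, depth, eps, h0, inv_mass, rng
            )
            q_plus, p_plus, g_plus = tree.q_plus, tree.p_plus, tree.g_plus
        else:
            tree = _build_tree(
                logp_grad, q_minus, p_minus, g_minus, -1, depth, eps, h0, inv_mass, rng
            )
            q_minus, p_minus, g_minus = tree.q_minus, tree.p_minus, tree.g_minus
        sum_alpha += tree.sum_alpha
        n_alpha += tree.n_alpha
        if tree.diverging:
            divergent = True
            break
        if tree.turning:
            break
        # biased progressive sampling favouring the new subtree
        if np.log(rng.uniform()) < tree.log_w - log_w:
            q_cur, g_cur, logp_cur = tree.q_prop, tree.g_prop, tree.logp_prop
        log_w = float(np.logaddexp(log_w, tree.log_w))
        dq = q_plus - q_minus
        if (
            float(dq @ (inv_mass * p_minus)) < 0
            or float(dq @ (inv_mass * p_plus)) < 0
        ):
            break
    accept_stat = sum_alpha / max(n_alpha, 1)
    return q_cur, logp_cur, g_cur, accept_stat, divergent, depth + 1


def _warmup_schedule(n_warmup: int) -> list[tuple[int, int, bool]]:
    """(start, end, collect_mass) windows mirroring the usual 3-stage plan."""
    if n_warmup < 40:
        return [(0, n_warmup, False)]
    init = max(15, int(0.15 * n_warmup))
    term = max(10, int(0.10 * n_warmup))
    windows: list[tuple[int, int, bool]] = [(0, init, False)]
    start, size = init, 25
    end_of_middle = n_warmup - term
    while start < end_of_middle:
        end = min(start + size, end_of_middle)
        if end_of_middle - end < size:
            end = end_of_middle
        windows.append((start, end, True))
        start, size = end, size * 2
    windows.append((end_of_middle, n_warmup, False))
    return windows


def nuts_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    rng: np.random.Generator,
    config: NutsConfig,
    store: Callable[[np.ndarray, float], None] | None = None,
    label: str = "chain",
) -> dict:
    """Run one NUTS chain; returns draws and sampler statistics.

    ``store(q, logp)``, if given, is called for every post-warmup draw
    (used to record derived quantities without keeping the full flat
    trajectory in memory). Raw draws are always returned.
    """
    q = np.asarray(q0, dtype=float).copy()
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise FloatingPointError(
            f"non-finite log-density at initialization (logp={logp})"
        )
    dim = q.size
    inv_mass = np.ones(dim)
    eps = _find_initial_step_size(logp_grad, q, rng, inv_mass, config.init_step_size)
    da = _DualAveraging(eps, config.target_accept)
    windows = _warmup_schedule(config.n_warmup)
    welford = _Welford(dim)
    divergences_warmup = 0

    it = 0
    for (start, end, collect) in windows:
        for it in range(start, end):
            q, logp, grad, alpha, div, _ = _nuts_transition(
                logp_grad, q, logp, grad, eps, config.max_depth, inv_mass, rng
            )
            divergences_warmup += int(div)
            eps = da.update(alpha)
            if collect:
                welford.add(q)
        if collect and welford.n >= 5:
            inv_mass = welford.variance()
            welford = _Welford(dim)
            eps = _find_initial_step_size(logp_grad, q, rng, inv_mass, da.adapted)
            da = _DualAveraging(eps, config.target_accept)
    eps = da.adapted if config.n_warmup > 0 else eps

    draws = np.empty((config.n_samples, dim))
    logps = np.empty(config.n_samples)
    accept = np.empty(config.n_samples)
    depths = np.empty(config.n_samples, dtype=int)
    divergences = 0
    for i in range(config.n_samples):
        q, logp, grad, alpha, div, depth = _nuts_transition(
            logp_grad, q, logp, grad, eps, config.max_depth, inv_mass, rng
        )
        divergences += int(div)
        draws[i] = q
        logps[i] = logp
        accept[i] = alpha
        depths[i] = depth
        if store is not None:
            store(q, logp)
        if (i + 1) % 200 == 0:
            logger.info(
                "%s: %d/%d draws (step %.3g, mean accept %.2f)",
                label, i + 1, config.n_samples, eps, accept[: i + 1].mean(),
            )
    return {
        "draws": draws,
        "logp": logps,
        "accept_stat": accept,
        "tree_depth": depths,
        "divergences": divergences,
        "divergences_warmup": divergences_warmup,
        "step_size": eps,
        "inv_mass": inv_mass,
    }
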