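"""Unconstrained reparameterization of the multiplex SRM posterior.

MCMC runs on a single flat vector of unconstrained parameters:

* layer intercepts ``eta`` (identity transform);
* raw generalized effects ``zG`` (J x 2M) and raw dyadic effects
  ``zD`` (D x 2M), already unconstrained;
* log standard deviations (2M generalized, M free dyadic);
* correlation Cholesky factors expressed through row normalization:
  row i of the factor is ``(w_i, 1) / ||(w_i, 1)||`` for a free vector
  ``w_i`` of length i, which maps R^{K(K-1)/2} bijectively onto the set
  of lower-triangular matrices with positive diagonal and unit row
  norms. The log-Jacobian of row i is ``(i + 2) * log L[i, i]``
  (0-based row index).

:meth:`SRMPosterior.logp_and_grad` returns the log-density (likelihood +
priors + change-of-variable Jacobians) together with its exact analytic
gradient; correctness is checked against finite differences and against
the constrained-space functions in :mod:`multisrm.model` in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .data import DyadIndex, MultiplexNetwork
from .model import HyperPriors, softplus

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = ["SRMPosterior", "cholesky_from_flat", "flat_from_cholesky"]


def cholesky_from_flat(w: np.ndarray, K: int) -> np.ndarray:
    """Build a unit-row-norm lower-triangular factor from free parameters."""
    L = np.zeros((K, K))
    L[0, 0] = 1.0
    off = 0
    for i in range(1, K):
        z = w[off : off + i]
        s = np.sqrt(1.0 + (z**2).sum())
        L[i, :i] = z / s
        L[i, i] = 1.0 / s
        off += i
    return L


def flat_from_cholesky(L: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cholesky_from_flat` (rows divided by diagonal)."""
    K = L.shape[0]
    parts = [L[i, :i] / L[i, i] for i in range(1, K)]
    return np.concatenate(parts) if parts else np.zeros(0)


def _cholesky_backward(L: np.ndarray, grad_L: np.ndarray) -> np.ndarray:
    """Pull a gradient w.r.t. the factor back to the free row parameters."""
    K = L.shape[0]
    out = []
    for i in range(1, K):
        s = 1.0 / L[i, i]
        u = np.append(L[i, :i] * s, 1.0)  # the raw row (w_i, 1)
        g = grad_L[i, : i + 1]
        gu = float(g @ u)
        out.append(g[:i] / s - gu * u[:i] / s**3)
    return np.concatenate(out) if out else np.zeros(0)


@dataclass
class _Blocks:
    """Slice layout of the flat unconstrained vector."""

    eta: slice
    zG: slice
    tG: Optional[slice]
    wL: slice
    zD: slice
    tD: Optional[slice]
    wG: slice
    size: int


class SRMPosterior:
    """Flat-vector view of the multiplex SRM joint log-density.

    Parameters
    ----------
    net
        Observed multiplex network; only ego-sender off-diagonal cells
        enter the likelihood.
    hyper
        Prior hyperparameters (scale rate, LKJ concentration, symmetry
        penalty scale, intercept prior scale).
    fix_scales
        If given, all random-effect standard deviations are held at this
        constant (0 reduces the model to intercept-only logistic
        regression) and the corresponding log-scale blocks are dropped
        from the sampled vector.
    """

    def __init__(
        self,
        net: MultiplexNetwork,
        hyper: HyperPriors | None = None,
        fix_scales: float | None = None,
    ):
        self.net = net
        self.hyper = hyper or HyperPriors()
        self.fix_scales = fix_scales
        J = net.roster.size
        M = net.n_layers
        K = 2 * M
        self.J, self.M, self.K = J, M, K
        self.dyads = DyadIndex(J)
        self.D = self.dyads.n_dyads
        self.T = K * (K - 1) // 2

        # observed (sender, receiver) pairs: every ego to every other person
        egos = net.roster.ego_indices
        S = np.repeat(egos, J - 1)
        R = np.concatenate([np.delete(np.arange(J), j) for j in egos])
        self.S, self.R = S, R
        self.P = S.size
        self.Y = net.G[S, R, :].astype(float)  # (P, M), all observed
        dy = self.dyads._lookup[S, R]
        direction = (S > R).astype(np.int64)
        ar = np.arange(M)
        # flat gather/scatter indices into (J,K) effects and (D,K) deltas
        self._ia = S[:, None] * K + ar[None, :]
        self._ib = R[:, None] * K + (M + ar)[None, :]
        self._id = dy[:, None] * K + (direction[:, None] * M + ar[None, :])

        free_scales = fix_scales is None
        off = 0

        def take(n: int) -> slice:
            nonlocal off
            s = slice(off, off + n)
            off += n
            return s

        self.blocks = _Blocks(
            eta=take(M),
            zG=take(J * K),
            tG=take(K) if free_scales else None,
            wL=take(self.T),
            zD=take(self.D * K),
            tD=take(M) if free_scales else None,
            wG=take(self.T),
            size=0,
        )
        self.blocks.size = off

    @property
    def n_params(self) -> int:
        return self.blocks.size

    # ------------------------------------------------------------------
    def init_position(self, rng: np.random.Generator | None = None, jitter: float = 0.0) -> np.ndarray:
        """High-density start: zero raws, prior-mean scales, identity factors.

        Intercepts start at the empirical logit of each layer's observed
        density (clipped away from the boundary). Optional uniform jitter
        diversifies chains.
        """
        phi = np.zeros(self.n_params)
        dens = self.Y.mean(axis=0)
        dens = np.clip(dens, 1e-3, 1 - 1e-3)
        phi[self.blocks.eta] = np.log(dens / (1 - dens))
        if self.blocks.tG is not None:
            phi[self.blocks.tG] = np.log(1.0 / self.hyper.scale_rate)
            phi[self.blocks.tD] = np.log(1.0 / self.hyper.scale_rate)
        if jitter > 0 and rng is not None:
            phi = phi + rng.uniform(-jitter, jitter, size=phi.shape)
        return phi

    def unpack(self, phi: np.ndarray) -> dict:
        """Constrained quantities implied by a flat vector."""
        b = self.blocks
        M, K = self.M, self.K
        eta = phi[b.eta]
        if b.tG is not None:
            sigma = np.exp(phi[b.tG])
            vs_free = np.exp(phi[b.tD])
        else:
            sigma = np.full(K, float(self.fix_scales))
            vs_free = np.full(M, float(self.fix_scales))
        L = cholesky_from_flat(phi[b.wL], K)
        Gamma = cholesky_from_flat(phi[b.wG], K)
        return {
            "eta": eta.copy(),
            "sigma": sigma,
            "varsigma": vs_free,
            "L": L,
            "Gamma": Gamma,
            "rho_gen": L @ L.T,
            "rho_dyad": Gamma @ Gamma.T,
            "zG": phi[b.zG].reshape(self.J, K),
            "zD": phi[b.zD].reshape(self.D, K),
        }

    # ------------------------------------------------------------------
    def logp_and_grad(self, phi: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-density (with Jacobians) and its gradient at ``phi``."""
        b = self.blocks
        J, M, K, D = self.J, self.M, self.K, self.D
        hyp = self.hyper
        grad = np.zeros_like(phi)

        eta = phi[b.eta]
        zG = phi[b.zG].reshape(J, K)
        zD = phi[b.zD].reshape(D, K)
        if b.tG is not None:
            tG = phi[b.tG]
            tD = phi[b.tD]
            sigma = np.exp(tG)
            vs_free = np.exp(tD)
        else:
            sigma = np.full(K, float(self.fix_scales))
            vs_free = np.full(M, float(self.fix_scales))
        vs_full = np.concatenate([vs_free, vs_free])
        L = cholesky_from_flat(phi[b.wL], K)
        Gamma = cholesky_from_flat(phi[b.wG], K)

        TG = sigma[:, None] * L          # scale-then-rotate operator
        TD = vs_full[:, None] * Gamma
        Aeff = zG @ TG.T                 # (J, K): alpha cols 0..M-1, beta M..2M-1
        Delta = zD @ TD.T                # (D, K)

        theta = (
            eta[None, :]
            + Aeff.ravel()[self._ia]
            + Aeff.ravel()[self._ib]
            + Delta.ravel()[self._id]
        )
        logp = float((self.Y * theta - softplus(theta)).sum())
        resid = self.Y - expit(theta)  # d loglik / d theta

        grad[b.eta] = resid.sum(axis=0)
        gA = np.zeros(J * K)
        np.add.at(gA, self._ia, resid)
        np.add.at(gA, self._ib, resid)
        gA = gA.reshape(J, K)
        gD = np.zeros(D * K)
        np.add.at(gD, self._id, resid)
        gD = gD.reshape(D, K)

        # --- generalized block backward
        grad[b.zG] = (gA @ TG - zG).ravel()
        gTG = gA.T @ zG
        grad_sigma = (gTG * L).sum(axis=1)
        gL = gTG * sigma[:, None]

        # --- dyadic block backward
        grad[b.zD] = (gD @ TD - zD).ravel()
        gTD = gD.T @ zD
        grad_vs_full = (gTD * Gamma).sum(axis=1)
        gGam = gTD * vs_full[:, None]

        # --- raw-effect priors
        logp += -0.5 * float((zG**2).sum() + (zD**2).sum())
        logp += -0.5 * _LOG_2PI * (zG.size + zD.size)

        # --- intercept prior
        s0 = hyp.eta_scale
        logp += float((-0.5 * eta**2 / s0**2 - 0.5 * _LOG_2PI - np.log(s0)).sum())
        grad[b.eta] -= eta / s0**2

        # --- scale priors (+ exp-transform Jacobian) when scales are free
        if b.tG is not None:
            rate = hyp.scale_rate
            logp += float((np.log(rate) - rate * sigma + tG).sum())
            logp += float((np.log(rate) - rate * vs_free + tD).sum())
            grad[b.tG] = grad_sigma * sigma - rate * sigma + 1.0
            grad[b.tD] = (
                (grad_vs_full[:M] + grad_vs_full[M:]) * vs_free
                - rate * vs_free
                + 1.0
            )

        # --- block-symmetry penalty on rho = Gamma Gamma'
        rho = Gamma @ Gamma.T
        eps = hyp.epsilon
        Spen = np.zeros((K, K))
        pen_const = -0.5 * _LOG_2PI - np.log(eps)
        for m in range(M - 1):
            for n in range(m + 1, M):
                d_c = rho[m + M, n + M] - rho[m, n]
                d_b = rho[m, n + M] - rho[n, m + M]
                logp += 2 * pen_const - 0.5 * (d_c**2 + d_b**2) / eps**2
                Spen[m + M, n + M] += -d_c / eps**2
                Spen[m, n] += d_c / eps**2
                Spen[m, n + M] += -d_b / eps**2
                Spen[n, m + M] += d_b / eps**2
        gGam += (Spen + Spen.T) @ Gamma

        # --- LKJ kernels plus row-normalization Jacobians
        # per-row coefficient on log L[i,i] works out constant: K + 2*eta - 1
        a = K + 2.0 * hyp.lkj_eta - 1.0
        for F, gF in ((L, gL), (Gamma, gGam)):
            diag = np.diag(F)[1:]
            logp += float(a * np.log(diag).sum())
        gL = np.tril(gL)
        gGam = np.tril(gGam)
        i = np.arange(1, K)
        gL[i, i] += a / np.diag(L)[1:]
        gGam[i, i] += a / np.diag(Gamma)[1:]

        grad[b.wL] = _cholesky_backward(L, gL)
        grad[b.wG] = _cholesky_backward(Gamma, gGam)
        return logp, grad

    def logp(self, phi: np.ndarray) -> float:
        return self.logp_and_grad(phi)[0]
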