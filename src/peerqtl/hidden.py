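"""Variational Bayesian factor analysis with automatic relevance determination.

Models the residual expression matrix R (genes x individuals) as
``R_gn = sum_k w_gk x_nk + noise`` with standard-normal factor
activations x, Gaussian loadings w with per-factor precision alpha_k,
and gamma ARD priors on the alphas.  Surplus factors are switched off
by the ARD mechanism: their relevance precision grows and the loadings
collapse to zero, so the effective number of factors is inferred rather
than fixed.

The variational posterior factorises over loadings (per-gene full K x K
covariance), activations (per-individual covariance) and ARD precisions.
Within one update we refresh loadings, then activations, then the ARD
precisions; each step is an exact conjugate coordinate-ascent update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import digamma

__all__ = ["HiddenFactorState", "update_hidden", "active_factors"]


def _tau_of(noise) -> np.ndarray:
    """Accept a NoiseState or a plain array of expected precisions."""
    if hasattr(noise, "expected_precision"):
        return np.asarray(noise.expected_precision, dtype=float)
    return np.asarray(noise, dtype=float)


@dataclass
class HiddenFactorState:
    """Variational posterior for the hidden factor component."""

    loadings_mean: np.ndarray      # (G, K)
    loadings_cov: np.ndarray       # (G, K, K)
    activations_mean: np.ndarray   # (N, K)
    activations_cov: np.ndarray    # (N, K, K)
    ard_shape: np.ndarray          # (K,)
    ard_rate: np.ndarray           # (K,)
    prior_shape: float = 1e-3
    prior_rate: float = 1e-3
    # cached contribution summaries, refreshed by update_hidden
    contrib_mean: np.ndarray = None        # (G, N)
    contrib_var_gene: np.ndarray = None    # (G,) sum over observed n of Var[c_gn]

    @property
    def n_factors(self) -> int:
        return self.loadings_mean.shape[1]

    @property
    def ard_mean(self) -> np.ndarray:
        return self.ard_shape / self.ard_rate

    @property
    def ard_log_mean(self) -> np.ndarray:
        return digamma(self.ard_shape) - np.log(self.ard_rate)

    def loadings_second_moment(self) -> np.ndarray:
        """E[w_g w_g^T] per gene, shape (G, K, K)."""
        mu = self.loadings_mean
        return self.loadings_cov + mu[:, :, None] * mu[:, None, :]

    def activations_second_moment(self) -> np.ndarray:
        m = self.activations_mean
        return self.activations_cov + m[:, :, None] * m[:, None, :]

    def contribution_mean(self) -> np.ndarray:
        return self.loadings_mean @ self.activations_mean.T

    def contribution_second_moment(self) -> np.ndarray:
        """Elementwise E[c_gn^2], shape (G, N)."""
        EWW = self.loadings_second_moment()
        EXX = self.activations_second_moment()
        return np.einsum("gkl,nkl->gn", EWW, EXX, optimize=True)

    @classmethod
    def initialize(cls, R: np.ndarray, mask: np.ndarray, K: int,
                   prior_shape: float, prior_rate: float,
                   method: str = "pca", rng=None) -> "HiddenFactorState":
        """Initialise activations from the top-K principal components of R
        (maximum-likelihood style start), or from the prior if requested."""
        G, N = R.shape
        R0 = np.where(mask, R, 0.0)
        if method == "random":
            rng = np.random.default_rng(rng)
            M = rng.standard_normal((N, K))
        else:
            # right singular vectors of the (masked) residual, unit variance
            _, s, Vt = np.linalg.svd(R0, full_matrices=False)
            k_avail = min(K, Vt.shape[0])
            M = np.zeros((N, K))
            V = Vt[:k_avail].T
            sd = V.std(axis=0)
            sd[sd == 0] = 1.0
            M[:, :k_avail] = V / sd
        state = cls(
            loadings_mean=np.zeros((G, K)),
            loadings_cov=np.broadcast_to(np.eye(K) * 1e-6, (G, K, K)).copy(),
            activations_mean=M,
            activations_cov=np.broadcast_to(np.eye(K) * 1e-6, (N, K, K)).copy(),
            ard_shape=np.full(K, prior_shape),
            ard_rate=np.full(K, prior_rate),
            prior_shape=prior_shape,
            prior_rate=prior_rate,
        )
        state.contrib_mean = np.zeros((G, N))
        state.contrib_var_gene = np.zeros(G)
        return state


def _refresh_contribution(state: HiddenFactorState, mask) -> None:
    """Cache contribution mean and per-gene posterior-variance sums."""
    W, M = state.loadings_mean, state.activations_mean
    Sig, S = state.loadings_cov, state.activations_cov
    mean = W @ M.T
    if mask is None:
        # per-gene sum over n of Var[c_gn] = tr(Sig_g Sxx) + mu^T Sx mu
        #   + tr((mu mu^T) Sum_n S_n), with Sxx = sum_n m m^T, Sx = sum_n S_n
        Sxx = M.T @ M
        Ssum = S.sum(axis=0)
        var_g = (
            np.einsum("gkl,lk->g", Sig, Sxx + Ssum, optimize=True)
            + np.einsum("gk,kl,gl->g", W, Ssum, W, optimize=True)
        )
    else:
        B = state.activations_second_moment()          # (N, K, K)
        EWW = state.loadings_second_moment()           # (G, K, K)
        Bg = np.einsum("gn,nkl->gkl", mask.astype(float), B, optimize=True)
        e2 = np.einsum("gkl,glk->g", EWW, Bg, optimize=True)
        var_g = e2 - ((mean ** 2) * mask).sum(axis=1)
        mean = np.where(mask, mean, 0.0)
    state.contrib_mean = mean
    state.contrib_var_gene = var_g


def update_hidden(state: HiddenFactorState, R: np.ndarray, noise,
                  mask: np.ndarray | None = None) -> HiddenFactorState:
    """One conjugate update of loadings, activations and ARD precisions.

    ``R`` is the residual for the hidden component with missing entries
    arbitrary; ``mask`` marks observed entries (None = fully observed).
    Returns a new state with refreshed contribution moments.
    """
    tau = _tau_of(noise)
    G, N = R.shape
    K = state.n_factors
    if K == 0:
        return state
    complete = mask is None or bool(mask.all())
    msk = None if complete else mask
    R0 = R if complete else np.where(mask, R, 0.0)

    st = replace(state)

    # --- loadings given activations -------------------------------------
    M, S = st.activations_mean, st.activations_cov
    EXX = st.activations_second_moment()               # (N, K, K)
    if complete:
        EXX_sum = EXX.sum(axis=0)                      # shared across genes
        A = st.ard_mean[None, :] * np.eye(K)[None] + tau[:, None, None] * EXX_sum
    else:
        EXXg = np.einsum("gn,nkl->gkl", msk.astype(float), EXX, optimize=True)
        A = st.ard_mean[None, :] * np.eye(K)[None] + tau[:, None, None] * EXXg
    Sig = np.linalg.inv(A)
    Sig = 0.5 * (Sig + np.swapaxes(Sig, 1, 2))
    rhs = tau[:, None] * (R0 @ M)                      # (G, K)
    W = np.einsum("gkl,gl->gk", Sig, rhs, optimize=True)
    st.loadings_mean, st.loadings_cov = W, Sig

    # --- activations given loadings -------------------------------------
    EWW = st.loadings_second_moment()                  # (G, K, K)
    if complete:
        C = np.einsum("g,gkl->kl", tau, EWW, optimize=True)
        Sx = np.linalg.inv(np.eye(K) + C)
        Sx = 0.5 * (Sx + Sx.T)
        Mx = ((tau[:, None] * R0).T @ W) @ Sx
        st.activations_cov = np.broadcast_to(Sx, (N, K, K)).copy()
    else:
        Cn = np.einsum("gn,g,gkl->nkl", msk.astype(float), tau, EWW, optimize=True)
        Sxn = np.linalg.inv(np.eye(K)[None] + Cn)
        Sxn = 0.5 * (Sxn + np.swapaxes(Sxn, 1, 2))
        rhs_x = (tau[:, None] * R0).T @ W              # (N, K)
        Mx = np.einsum("nkl,nl->nk", Sxn, rhs_x, optimize=True)
        st.activations_cov = Sxn
    st.activations_mean = Mx

    # --- ARD precisions ---------------------------------------------------
    Ew2 = st.loadings_mean ** 2 + np.einsum("gkk->gk", st.loadings_cov)
    st.ard_shape = np.full(K, st.prior_shape + 0.5 * G)
    st.ard_rate = st.prior_rate + 0.5 * Ew2.sum(axis=0)

    _refresh_contribution(st, msk)
    return st


def active_factors(state: HiddenFactorState, variance_floor: float = 1e-3,
                   total_variance: float | None = None) -> list[int]:
    """Indices of factors with non-negligible contribution variance.

    A factor is active when the mean per-entry variance of its
    contribution exceeds ``variance_floor`` times ``total_variance``
    (mean squared entry of the residual the model was fitted to).
    Sorted by explained variance, descending.
    """
    W, M = state.loadings_mean, state.activations_mean
    G, N = W.shape[0], M.shape[0]
    ev = (W ** 2).sum(axis=0) * (M ** 2).sum(axis=0) / (G * N)
    if total_variance is None:
        total_variance = float(ev.sum()) if ev.sum() > 0 else 1.0
    idx = [k for k in range(state.n_factors) if ev[k] > variance_floor * total_variance]
    return sorted(idx, key=lambda k: -ev[k])
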