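"""Bayesian linear regression on observed covariates with per-covariate ARD.

Each gene's residual profile is regressed on the F known covariates
(gender, batch, environment, ...) with a Gaussian posterior over the
per-gene weight vector and a shared gamma ARD precision per covariate.
Irrelevant covariates acquire a large relevance precision, which shrinks
their weights to zero across all genes; in the flat-prior limit the
posterior mean reduces to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import digamma

__all__ = ["KnownFactorState", "update_known"]


def _tau_of(noise) -> np.ndarray:
    if hasattr(noise, "expected_precision"):
        return np.asarray(noise.expected_precision, dtype=float)
    return np.asarray(noise, dtype=float)


@dataclass
class KnownFactorState:
    """Variational posterior for the known covariate component."""

    weights_mean: np.ndarray   # (G, F)
    weights_cov: np.ndarray    # (G, F, F)
    ard_shape: np.ndarray      # (F,)
    ard_rate: np.ndarray       # (F,)
    covariates: np.ndarray     # (F, N) design, fixed over the fit
    prior_shape: float = 1e-3
    prior_rate: float = 1e-3
    contrib_mean: np.ndarray = None
    contrib_var_gene: np.ndarray = None

    @property
    def n_covariates(self) -> int:
        return self.weights_mean.shape[1]

    @property
    def ard_mean(self) -> np.ndarray:
        return self.ard_shape / self.ard_rate

    @property
    def ard_log_mean(self) -> np.ndarray:
        return digamma(self.ard_shape) - np.log(self.ard_rate)

    def weights_second_moment(self) -> np.ndarray:
        mu = self.weights_mean
        return self.weights_cov + mu[:, :, None] * mu[:, None, :]

    def contribution_mean(self) -> np.ndarray:
        return self.weights_mean @ self.covariates

    def contribution_second_moment(self) -> np.ndarray:
        H = self.covariates
        mean = self.contribution_mean()
        # Var[c_gn] = h_n^T Sigma_g h_n
        var = np.einsum("fn,gfe,en->gn", H, self.weights_cov, H, optimize=True)
        return mean ** 2 + var

    @classmethod
    def initialize(cls, H: np.ndarray, G: int,
                   prior_shape: float, prior_rate: float) -> "KnownFactorState":
        F = H.shape[0]
        st = cls(
            weights_mean=np.zeros((G, F)),
            weights_cov=np.broadcast_to(np.eye(F) * 1e-6, (G, F, F)).copy(),
            ard_shape=np.full(F, prior_shape),
            ard_rate=np.full(F, prior_rate),
            covariates=np.asarray(H, dtype=float),
            prior_shape=prior_shape,
            prior_rate=prior_rate,
        )
        st.contrib_mean = np.zeros((G, H.shape[1]))
        st.contrib_var_gene = np.zeros(G)
        return st


def _refresh_contribution(state: KnownFactorState, mask) -> None:
    H = state.covariates
    mean = state.weights_mean @ H
    if mask is None:
        HH = H @ H.T
        var_g = np.einsum("gfe,ef->g", state.weights_cov, HH, optimize=True)
    else:
        var = np.einsum("fn,gfe,en->gn", H, state.weights_cov, H, optimize=True)
        var_g = (var * mask).sum(axis=1)
        mean = np.where(mask, mean, 0.0)
    state.contrib_mean = mean
    state.contrib_var_gene = var_g


def update_known(state: KnownFactorState, R: np.ndarray, noise,
                 mask: np.ndarray | None = None) -> KnownFactorState:
    """One conjugate update of the covariate weights and their ARD precisions.

    Posterior precision per gene is ``diag(E[ard]) + E[tau_g] H H^T`` and
    the mean the matching ridge-style solution; the ARD gamma posterior
    per covariate accumulates E[v_gf^2] over genes.
    """
    tau = _tau_of(noise)
    G, N = R.shape
    F = state.n_covariates
    if F == 0:
        return state
    complete = mask is None or bool(mask.all())
    msk = None if complete else mask
    R0 = R if complete else np.where(mask, R, 0.0)
    H = state.covariates

    st = replace(state)
    if complete:
        HH = H @ H.T
        A = st.ard_mean[None, :] * np.eye(F)[None] + tau[:, None, None] * HH[None]
    else:
        HHg = np.einsum("gn,fn,en->gfe", msk.astype(float), H, H, optimize=True)
        A = st.ard_mean[None, :] * np.eye(F)[None] + tau[:, None, None] * HHg
    Sig = np.linalg.inv(A)
    Sig = 0.5 * (Sig + np.swapaxes(Sig, 1, 2))
    rhs = tau[:, None] * (R0 @ H.T)
    Mu = np.einsum("gfe,ge->gf", Sig, rhs, optimize=True)
    st.weights_mean, st.weights_cov = Mu, Sig

    Ev2 = Mu ** 2 + np.einsum("gff->gf", Sig)
    st.ard_shape = np.full(F, st.prior_shape + 0.5 * G)
    st.ard_rate = st.prior_rate + 0.5 * Ev2.sum(axis=0)

    _refresh_contribution(st, msk)
    return st
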