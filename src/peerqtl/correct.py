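"""Non-Bayesian confounder-correction baselines.

All methods first remove known-covariate effects by per-gene ordinary
least squares, then estimate hidden-factor effects on the residuals:

* ``standard`` - no hidden factor model at all;
* ``pca`` - subtract the rank-K truncated SVD reconstruction, with K a
  user parameter;
* ``pcasig`` - PCA with K chosen by permutation significance testing of
  eigenvalue variance fractions (gene-wise permutations);
* ``sva`` - surrogate variable analysis: significant eigengenes are
  rebuilt from only the genes associated with them, allowing sparse,
  non-orthogonal surrogates, and removed by joint regression.

Each corrector returns the corrected residuals that downstream eQTL
tests operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import CovariateMatrix, ExpressionMatrix

__all__ = [
    "CorrectionResult", "correct_standard", "correct_pca",
    "pcasig_num_components", "correct_sva",
]


@dataclass
class CorrectionResult:
    method: str
    n_components: int
    components: np.ndarray          # (N, n_components)
    residuals: ExpressionMatrix
    settings: dict = field(default_factory=dict)


def _values_and_ids(Y):
    if isinstance(Y, ExpressionMatrix):
        vals = Y.values.copy()
        mask = Y.missing_mask
        # impute missing with gene means so SVD-based methods can run
        means = np.nansum(np.where(mask, vals, 0.0), axis=1) / np.maximum(mask.sum(axis=1), 1)
        vals = np.where(mask, vals, means[:, None])
        return vals, mask, Y.gene_ids, Y.individual_ids
    vals = np.asarray(Y, dtype=float)
    mask = np.ones(vals.shape, dtype=bool)
    return vals.copy(), mask, [f"g{i}" for i in range(vals.shape[0])], \
        [f"i{j}" for j in range(vals.shape[1])]


def _design(covs, N) -> np.ndarray:
    """Covariate design (N x P) with an intercept column prepended."""
    X = np.ones((N, 1))
    if covs is not None:
        vals = covs.values if isinstance(covs, CovariateMatrix) else np.asarray(covs, float)
        X = np.hstack([X, vals.T])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient covariates; dependent columns are "
                      "effectively dropped in the least-squares fit")
    return X


def _ols_residual(vals: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-gene least-squares residual of vals (G x N) on design X (N x P)."""
    beta, *_ = np.linalg.lstsq(X, vals.T, rcond=None)
    return vals - (X @ beta).T


def _result(method, vals_resid, mask, gene_ids, ind_ids, components, settings):
    resid = np.where(mask, vals_resid, np.nan)
    expr = ExpressionMatrix(resid, gene_ids, ind_ids, mask)
    ncomp = components.shape[1]
    return CorrectionResult(method, ncomp, components, expr, settings)


def correct_standard(Y, covs=None) -> CorrectionResult:
    """Known covariates only: per-gene OLS residual (centred if none)."""
    vals, mask, gids, iids = _values_and_ids(Y)
    X = _design(covs, vals.shape[1])
    resid = _ols_residual(vals, X)
    return _result("standard", resid, mask, gids, iids,
                   np.empty((vals.shape[1], 0)), {})


def correct_pca(Y, covs=None, K: int = 10) -> CorrectionResult:
    """Remove the rank-K principal subspace of the covariate residual."""
    vals, mask, gids, iids = _values_and_ids(Y)
    G, N = vals.shape
    if not (1 <= K <= min(G, N)):
        raise ValueError(f"K={K} outside 1..min(G,N)={min(G, N)}")
    resid0 = _ols_residual(vals, _design(covs, N))
    U, s, Vt = np.linalg.svd(resid0, full_matrices=False)
    recon = (U[:, :K] * s[:K]) @ Vt[:K]
    components = Vt[:K].T * s[:K]
    return _result("pca", resid0 - recon, mask, gids, iids, components, {"K": K})


def _eigen_fractions(mat: np.ndarray, k: int) -> np.ndarray:
    s = np.linalg.svd(mat, compute_uv=False)
    frac = s ** 2 / np.sum(s ** 2)
    return frac[:k]


def pcasig_num_components(Y, alpha: float = 0.01, n_perm: int = 100,
                          seed: int = 0, covs=None) -> int:
    """Number of eigencomponents more variable than a permutation null.

    Each permuted dataset shuffles every gene's values independently
    across individuals, destroying inter-gene correlation while keeping
    gene-level distributions.  Eigenvalue variance fractions are tested
    sequentially; the count stops at the first non-significant one.
    P-values are the plain null exceedance fraction, so components that
    beat every permutation are significant at any cutoff.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    vals, mask, *_ = _values_and_ids(Y)
    G, N = vals.shape
    resid0 = _ols_residual(vals, _design(covs, N))
    kmax = min(G, N)
    obs = _eigen_fractions(resid0, kmax)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(kmax)
    for _ in range(n_perm):
        perm = resid0.copy()
        # independent permutation within each gene row
        idx = np.argsort(rng.random(perm.shape), axis=1)
        perm = np.take_along_axis(perm, idx, axis=1)
        exceed += _eigen_fractions(perm, kmax) >= obs
    pvals = exceed / n_perm
    count = 0
    for p in pvals:
        if p > alpha:
            break
        count += 1
    return count


def correct_sva(Y, covs=None, alpha: float = 0.01, n_perm: int = 100,
                seed: int = 0) -> CorrectionResult:
    """Surrogate variable correction built on sparse eigengene subsets.

    Significant eigengenes (permutation test as in PCAsig) are each
    rebuilt from the eigen-decomposition of only the genes significantly
    associated with them, then all surrogates are regressed out jointly
    with the covariates.
    """
    vals, mask, gids, iids = _values_and_ids(Y)
    G, N = vals.shape
    X = _design(covs, N)
    resid0 = _ols_residual(vals, X)
    n_sig = pcasig_num_components(resid0, alpha=alpha, n_perm=n_perm, seed=seed)
    if n_sig == 0:
        res = correct_standard(Y, covs)
        res.method = "sva"
        res.settings = {"alpha": alpha, "n_perm": n_perm}
        return res

    U, s, Vt = np.linalg.svd(resid0, full_matrices=False)
    surrogates = np.empty((N, n_sig))
    sds = resid0.std(axis=1)
    sds[sds == 0] = 1.0
    Z = resid0 / sds[:, None]
    for i in range(n_sig):
        eig = Vt[i]
        # genes significantly associated with this eigengene
        r = (Z @ (eig - eig.mean())) / (N * np.std(eig - eig.mean()))
        r = np.clip(r, -0.9999999, 0.9999999)
        t = r * np.sqrt(N - 2) / np.sqrt(1 - r ** 2)
        p = 2 * stats.t.sf(np.abs(t), N - 2)
        subset = np.nonzero(p < alpha)[0]
        if subset.size < 2:
            surrogates[:, i] = eig
            continue
        _, _, Vsub = np.linalg.svd(resid0[subset], full_matrices=False)
        v = Vsub[0]
        if v @ eig < 0:  # align orientation with the dense eigengene
            v = -v
        surrogates[:, i] = v
    design = np.hstack([X, surrogates])
    resid = _ols_residual(vals, design)
    return _result("sva", resid, mask, gids, iids, surrogates,
                   {"alpha": alpha, "n_perm": n_perm, "n_sig": n_sig})
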