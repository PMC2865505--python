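"""Spike-and-slab genetic association component with a best-SNP bottleneck.

Each gene carries a Bernoulli inclusion indicator and, conditional on
inclusion, a Gaussian effect of one SNP on its residual expression.  To
keep the joint model tractable only the single most relevant SNP per
gene is considered at each update ("bottleneck"): the SNP maximising the
slab marginal likelihood, which for equal effective genotype scales is
the SNP with the largest absolute correlation to the gene's residual.

Genotypes enter the variational updates mean-imputed, centred and scaled
to unit variance, so the effect slab prior N(0, slab_var) is expressed
per genotype standard deviation and the Bayes factor is invariant to
allele-frequency scale.  Association *tests* elsewhere in the package
instead drop missing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = ["GeneticState", "standardize_genotypes", "select_best_snp", "update_genetic"]


def _tau_of(noise) -> np.ndarray:
    if hasattr(noise, "expected_precision"):
        return np.asarray(noise.expected_precision, dtype=float)
    return np.asarray(noise, dtype=float)


@dataclass
class GeneticState:
    """Variational posterior of the per-gene single-SNP effect."""

    selected_snp: np.ndarray     # (G,) int, -1 = none
    inclusion_prob: np.ndarray   # (G,)
    weight_mean: np.ndarray      # (G,) effect per genotype sd
    weight_var: np.ndarray       # (G,)
    prior_inclusion: float = 0.01
    slab_var: float = 1.0
    # selected standardized genotype rows, cached for contribution algebra
    z_selected: np.ndarray = None      # (G, N)
    contrib_mean: np.ndarray = None    # (G, N)
    contrib_var_gene: np.ndarray = None

    @classmethod
    def initialize(cls, G: int, N: int, prior_inclusion: float,
                   slab_var: float) -> "GeneticState":
        st = cls(
            selected_snp=np.full(G, -1, dtype=int),
            inclusion_prob=np.zeros(G),
            weight_mean=np.zeros(G),
            weight_var=np.full(G, slab_var),
            prior_inclusion=prior_inclusion,
            slab_var=slab_var,
        )
        st.z_selected = np.zeros((G, N))
        st.contrib_mean = np.zeros((G, N))
        st.contrib_var_gene = np.zeros(G)
        return st

    def contribution_mean(self) -> np.ndarray:
        return (self.inclusion_prob * self.weight_mean)[:, None] * self.z_selected

    def contribution_second_moment(self) -> np.ndarray:
        p, mu, v = self.inclusion_prob, self.weight_mean, self.weight_var
        return (p * (mu ** 2 + v))[:, None] * self.z_selected ** 2


def standardize_genotypes(values: np.ndarray) -> np.ndarray:
    """Mean-impute missing codes (< 0) per SNP, centre and scale to unit sd.

    Monomorphic SNPs come out as all-zero rows (and are never selected).
    """
    X = np.asarray(values, dtype=float)
    X = np.where(X < 0, np.nan, X)
    mean = np.nanmean(X, axis=1, keepdims=True)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    X = np.where(np.isnan(X), mean, X)
    X = X - mean
    sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, X / np.where(sd > 0, sd, 1.0), 0.0)
    return Z


def select_best_snp(r_g: np.ndarray, geno, candidate_snps=None):
    """Best single SNP for one gene by squared correlation with its residual.

    Missing values (NaN residual entries or negative genotype codes) are
    dropped pairwise.  Ties are broken by the lowest SNP index; returns
    None when every candidate is monomorphic on the complete pairs.
    """
    values = geno.values if hasattr(geno, "values") else np.asarray(geno)
    S = values.shape[0]
    cands = np.arange(S) if candidate_snps is None else np.asarray(sorted(candidate_snps))
    if cands.size == 0:
        raise ValueError("candidate SNP set is empty")
    r_g = np.asarray(r_g, dtype=float)
    best, best_r2 = None, -1.0
    for s in cands:
        x = values[s].astype(float)
        ok = np.isfinite(r_g) & (x >= 0)
        if ok.sum() < 3:
            continue
        xs, ys = x[ok], r_g[ok]
        if xs.std() == 0 or ys.std() == 0:
            continue
        r2 = np.corrcoef(xs, ys)[0, 1] ** 2
        if r2 > best_r2 + 1e-15:
            best, best_r2 = int(s), r2
    return best


def update_genetic(state: GeneticState, R: np.ndarray, Z: np.ndarray, noise,
                   mask: np.ndarray | None = None,
                   candidate_mask: np.ndarray | None = None,
                   reselect: bool = True) -> GeneticState:
    """Re-select the best SNP per gene and update the spike-and-slab posterior.

    Given the residual R and expected noise precisions, the slab posterior
    for gene g and SNP s is N(mu, v) with v = 1/(1/slab + tau_g * z'z) and
    mu = v * tau_g * z'r; the log Bayes factor slab-vs-spike is
    0.5*log(v/slab) + 0.5*mu^2/v, and the posterior inclusion probability
    combines it with the prior log-odds.  ``candidate_mask`` (G, S) can
    restrict the SNPs considered per gene (e.g. a cis window).
    """
    tau = _tau_of(noise)
    G, N = R.shape
    S = Z.shape[0]
    complete = mask is None or bool(mask.all())
    R0 = R if complete else np.where(mask, R, 0.0)

    st = replace(state)
    zr = R0 @ Z.T                                   # (G, S)
    if complete:
        zz = np.broadcast_to((Z ** 2).sum(axis=1), (G, S))
    else:
        zz = mask.astype(float) @ (Z ** 2).T        # (G, S)

    slab = st.slab_var
    v = 1.0 / (1.0 / slab + tau[:, None] * zz)
    mu = v * tau[:, None] * zr
    with np.errstate(divide="ignore"):
        log_bf = 0.5 * np.log(v / slab) + 0.5 * mu ** 2 / v
    log_bf = np.where(zz > 0, log_bf, -np.inf)      # monomorphic: never selected
    if candidate_mask is not None:
        log_bf = np.where(candidate_mask, log_bf, -np.inf)

    if reselect or np.all(st.selected_snp < 0):
        best = np.argmax(log_bf, axis=1)            # ties -> lowest index
    else:
        best = np.where(st.selected_snp >= 0, st.selected_snp, 0)
    rows = np.arange(G)
    bf_best = log_bf[rows, best]
    usable = np.isfinite(bf_best)

    logit_prior = np.log(st.prior_inclusion) - np.log1p(-st.prior_inclusion)
    p = np.where(usable, expit(bf_best + logit_prior), 0.0)
    mu_b = np.where(usable, mu[rows, best], 0.0)
    v_b = np.where(usable, v[rows, best], slab)

    st.selected_snp = np.where(usable, best, -1)
    st.inclusion_prob = p
    st.weight_mean = mu_b
    st.weight_var = v_b
    st.z_selected = np.where(usable[:, None], Z[best], 0.0)
    if not complete:
        st.z_selected = np.where(mask, st.z_selected, 0.0)

    mean = (p * mu_b)[:, None] * st.z_selected
    zz_b = (st.z_selected ** 2).sum(axis=1)
    st.contrib_mean = mean
    st.contrib_var_gene = zz_b * (p * (mu_b ** 2 + v_b) - (p * mu_b) ** 2)
    return st
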