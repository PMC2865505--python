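"""eQTL association testing on (corrected) expression residuals.

Per gene, the best SNP is the one with the largest absolute Pearson
correlation; its significance can be assessed with a two-sided t test on
the correlation (``ttest``), the same test on expression midranks
(``rank``), a chi-squared likelihood-ratio test of the nested linear
model (``lrt``), or a permutation test of the per-gene maximum |r| over
SNPs (``perm``).  Analytic per-SNP p-values receive a per-gene
Bonferroni correction for the number of SNPs tested; the permutation
p-value is already family-wise.  Associations are classified cis when
the SNP lies within 1 Mb of the probe midpoint (outbred designs) or on
the same chromosome (crosses).

Missing data are dropped pairwise and the per-test sample size recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, GenotypeMatrix, ProbeAnnotation

__all__ = [
    "AssociationResult", "corr_t_test", "rank_test", "lrt_test",
    "permutation_test", "bonferroni_per_gene", "classify_location",
    "map_eqtls", "empirical_fdr",
]

CIS_WINDOW_BP = 1_000_000  # |snp - probe midpoint| <= 1 Mb, inclusive


@dataclass
class AssociationResult:
    gene_id: str
    snp_id: str
    r: float
    stat: float
    p_nominal: float
    p_adjusted: float
    significant: bool
    location_class: str
    n_used: int


def _complete_pairs(y, x):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    # genotype missing conventions: NaN or the -1 code
    ok = np.isfinite(y) & np.isfinite(x) & (x != -1)
    return y[ok], x[ok]


def corr_t_test(y, x):
    """Pearson correlation t test on complete pairs.

    Returns (r, t, two-sided p) with t = r*sqrt(n-2)/sqrt(1-r^2) on n-2
    degrees of freedom.  A constant genotype is untestable: r = 0, p = 1.
    """
    ys, xs = _complete_pairs(y, x)
    n = len(ys)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(xs) == 0:
        return 0.0, 0.0, 1.0
    if np.std(ys) == 0:
        return 0.0, 0.0, 1.0
    r = float(np.corrcoef(ys, xs)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        return float(np.sign(r)), np.inf * np.sign(r), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(t), float(p)


def rank_test(y, x):
    """Correlation t test on midranks of the expression values."""
    y = np.asarray(y, dtype=float)
    ranks = np.where(np.isfinite(y), stats.rankdata(y, nan_policy="omit"), np.nan)
    return corr_t_test(ranks, x)


def lrt_test(y, x):
    """Nested-model likelihood ratio: chi-squared with 1 df on n*log(1/(1-r^2))."""
    r, _, _ = corr_t_test(y, x)
    ys, xs = _complete_pairs(y, x)
    n = len(ys)
    if abs(r) >= 1.0 - 1e-15:
        return r, np.inf, 0.0
    stat = n * np.log1p(-(r * r)) * -1.0
    p = float(stats.chi2.sf(stat, 1))
    return r, float(stat), p


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    return np.where(sd > 0, M / np.where(sd > 0, sd, 1.0), 0.0)


def permutation_test(y, X_snps: np.ndarray, n_perm: int = 1000, seed: int = 0):
    """Per-gene family-wise empirical p for the best SNP.

    The null statistic is the maximum |r| over SNPs after permuting the
    expression labels; p = (1 + #{null >= observed}) / (1 + n_perm).
    Missing genotypes are mean-imputed for the permutation scan.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 observed expression values")
    X = np.asarray(X_snps, dtype=float)[:, ok]
    X = np.where(X < 0, np.nan, X)
    means = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), np.where(np.isfinite(means), means, 0.0), X)
    Z = _standardize_rows(X)
    if not np.any(Z.std(axis=1) > 0):
        return 1.0
    n = ok.sum()
    ys = y[ok]
    ys = (ys - ys.mean())
    sd = ys.std()
    if sd == 0:
        return 1.0
    ys = ys / sd
    obs = np.max(np.abs(Z @ ys)) / n
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)  # (P, n)
    null = np.max(np.abs(Z @ perms.T), axis=0) / n
    return float((1 + np.sum(null >= obs)) / (1 + n_perm))


def bonferroni_per_gene(p_nominal, n_snps_tested: int):
    """min(1, p * n): per-gene correction for the SNPs scanned."""
    if n_snps_tested < 1:
        raise ValueError("n_snps_tested must be >= 1")
    return np.minimum(1.0, np.asarray(p_nominal, dtype=float) * n_snps_tested)


def classify_location(gene_chrom: str, gene_mid_bp: int, snp_chrom: str,
                      snp_pos_bp: int, mode: str = "window") -> str:
    """'cis' or 'trans' under the window (outbred) or chromosome (cross) rule."""
    if mode == "window":
        same = str(gene_chrom) == str(snp_chrom)
        return "cis" if same and abs(int(snp_pos_bp) - int(gene_mid_bp)) <= CIS_WINDOW_BP \
            else "trans"
    if mode == "chromosome":
        return "cis" if str(gene_chrom) == str(snp_chrom) else "trans"
    raise ValueError(f"unknown mode {mode!r}")


def _pairwise_corr(Y: np.ndarray, X: np.ndarray):
    """Pairwise-complete Pearson correlations and sample sizes.

    Y: (G, N) with NaN missing; X: (S, N) with negative codes missing.
    Returns (r, n) of shape (G, S).
    """
    My = np.isfinite(Y)
    Y0 = np.where(My, Y, 0.0)
    Xf = np.asarray(X, dtype=float)
    Mx = Xf >= 0
    X0 = np.where(Mx, Xf, 0.0)
    Myf, Mxf = My.astype(float), Mx.astype(float)
    n = Myf @ Mxf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        Sy = Y0 @ Mxf.T
        Sx = Myf @ X0.T
        Sxy = Y0 @ X0.T
        Syy = (Y0 ** 2) @ Mxf.T
        Sxx = Myf @ (X0 ** 2).T
        cov = Sxy - Sy * Sx / n
        vy = Syy - Sy ** 2 / n
        vx = Sxx - Sx ** 2 / n
        denom = np.sqrt(np.maximum(vy, 0.0) * np.maximum(vx, 0.0))
        r = np.where(denom > 0, cov / np.maximum(denom, 1e-300), 0.0)
    return np.clip(r, -1.0, 1.0), n


def map_eqtls(R, geno: GenotypeMatrix, annotations: ProbeAnnotation | None = None,
              test: str = "ttest", fpr: float = 1e-3, mode: str = "window",
              n_perm: int = 1000, seed: int = 0):
    """Genome-wide per-gene best-SNP association scan.

    Returns (DataFrame of per-gene results, summary dict).  The best SNP
    is chosen by |r|; significance uses the selected test at the per-gene
    Bonferroni-corrected false positive rate ``fpr``.
    """
    if test not in ("ttest", "rank", "lrt", "perm"):
        raise ValueError(f"unknown test {test!r}")
    if isinstance(R, ExpressionMatrix):
        Y = R.values
        gene_ids = R.gene_ids
    else:
        Y = np.asarray(R, dtype=float)
        gene_ids = [f"g{i}" for i in range(Y.shape[0])]
    if Y.shape[1] != geno.n_individuals:
        raise ValueError("expression and genotype individuals are not aligned")
    Yt = Y
    if test == "rank":
        Yt = np.empty_like(Y)
        for g in range(Y.shape[0]):
            row = Y[g]
            Yt[g] = np.where(np.isfinite(row),
                             stats.rankdata(row, nan_policy="omit"), np.nan)

    r, n = _pairwise_corr(Yt, geno.values)
    G, S = r.shape
    best = np.argmax(np.abs(r), axis=1)
    rows = np.arange(G)
    r_b = r[rows, best]
    n_b = n[rows, best]

    df_ = np.maximum(n_b - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_b = r_b * np.sqrt(df_) / np.sqrt(np.maximum(1.0 - r_b ** 2, 1e-300))
    if test in ("ttest", "rank"):
        p_nom = 2.0 * stats.t.sf(np.abs(t_b), df_)
        stat = t_b
        p_adj = bonferroni_per_gene(p_nom, S)
    elif test == "lrt":
        stat = -n_b * np.log1p(-np.minimum(r_b ** 2, 1 - 1e-300))
        p_nom = stats.chi2.sf(stat, 1)
        p_adj = bonferroni_per_gene(p_nom, S)
    else:  # permutation: already family-wise over SNPs
        rng = np.random.default_rng(seed)
        p_nom = np.empty(G)
        for g in range(G):
            p_nom[g] = permutation_test(Yt[g], geno.values, n_perm=n_perm,
                                        seed=int(rng.integers(2 ** 31)))
        stat = t_b
        p_adj = p_nom.copy()
    significant = p_adj <= fpr

    loc = ["NA"] * G
    if annotations is not None:
        for g in range(G):
            chrom, mid = annotations.lookup(gene_ids[g])
            s = best[g]
            loc[g] = classify_location(chrom, mid, geno.chrom[s],
                                       geno.pos_bp[s], mode)
    df = pd.DataFrame({
        "gene_id": gene_ids,
        "snp_id": [geno.snp_ids[s] for s in best],
        "snp_index": best,
        "r": r_b,
        "stat": stat,
        "p_nominal": p_nom,
        "p_adjusted": p_adj,
        "significant": significant,
        "location_class": loc,
        "n_used": n_b.astype(int),
    })
    summary = {
        "n_genes_tested": int(G),
        "n_significant": int(significant.sum()),
        "n_cis": int(((df["location_class"] == "cis") & significant).sum()),
        "n_trans": int(((df["location_class"] == "trans") & significant).sum()),
        "fpr": fpr,
        "test": test,
        "mode": mode,
    }
    return df, summary


def empirical_fdr(results: pd.DataFrame, R, geno: GenotypeMatrix,
                  n_perm: int = 10, seed: int = 0, test: str = "ttest",
                  fpr: float = 1e-3):
    """Permutation estimate of the false discovery rate at the threshold.

    Individual labels of the genotype matrix are permuted (preserving LD
    among SNPs) and the scan re-run; the FDR estimate is the mean null
    significant count divided by the observed count, capped at 1.
    Returns NaN when there are no observed positives.
    """
    observed = int(results["significant"].sum())
    if observed == 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    null_counts = []
    for _ in range(n_perm):
        perm = rng.permutation(geno.n_individuals)
        geno_p = GenotypeMatrix(geno.values[:, perm], geno.snp_ids, geno.chrom,
                                geno.pos_bp, geno.individual_ids, geno.ploidy)
        _, summ = map_eqtls(R, geno_p, annotations=None, test=test, fpr=fpr)
        null_counts.append(summ["n_significant"])
    return float(min(1.0, np.mean(null_counts) / observed))
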