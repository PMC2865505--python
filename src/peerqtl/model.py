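"""Joint additive model of expression variability and its variational fit.

The observed expression matrix Y (genes x individuals) is modelled as a
sum of independent component contributions plus gene-specific Gaussian
noise::

    y_gn = c_gn(genetic) + c_gn(known) + c_gn(hidden) + eps_gn,
    eps_gn ~ N(0, 1/tau_g),   tau_g ~ Gamma(noise_shape, noise_rate)

with the component models defined in :mod:`peerqtl.genetic`,
:mod:`peerqtl.known` and :mod:`peerqtl.hidden`.  Inference is variational
Bayes with a posterior that factorises over components; each update is an
exact conjugate coordinate-ascent step, so the evidence lower bound is
non-decreasing over sweeps (up to floating-point tolerance) and is used
as the convergence monitor.

Two schedules are provided.  The iterative schedule (``iVBQTL``) sweeps
genetic -> known -> hidden -> noise until the bound stabilises, so the
genetic component competes with the hidden factors for shared signal
(e.g. trans hotspots).  The fast schedule (``fVBQTL``) first fits known
and hidden factors to convergence without any genetic component, then
performs a single genetic pass on the factor residuals; it is cheaper
and equivalent whenever genetic effects are roughly orthogonal to the
confounders.

The user-facing entry points follow the statsmodels convention: build a
:class:`VBQTL` model from data, call :meth:`VBQTL.fit`, and work with the
returned :class:`VBQTLResults`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, xlogy

from .data import (CovariateMatrix, ExpressionMatrix, GenotypeMatrix,
                   Hyperparameters)
from .genetic import GeneticState, standardize_genotypes, update_genetic
from .hidden import HiddenFactorState, active_factors, update_hidden
from .known import KnownFactorState, update_known

__all__ = [
    "NoiseState", "ComponentContribution", "ModelState",
    "residual_for", "update_noise", "variational_bound",
    "corrected_expression", "VBQTL", "VBQTLResults", "fit_vbqtl",
    "load_fit",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class NoiseState:
    """Gamma posterior over the per-gene noise precisions tau_g."""

    shape_g: np.ndarray
    rate_g: np.ndarray

    def __post_init__(self):
        self.shape_g = np.asarray(self.shape_g, dtype=float)
        self.rate_g = np.asarray(self.rate_g, dtype=float)
        if np.any(self.shape_g <= 0) or np.any(self.rate_g <= 0):
            raise ValueError("gamma posterior parameters must be positive")

    @property
    def expected_precision(self) -> np.ndarray:
        return self.shape_g / self.rate_g

    @property
    def expected_log_precision(self) -> np.ndarray:
        return digamma(self.shape_g) - np.log(self.rate_g)


@dataclass
class ComponentContribution:
    """First and second posterior moments of one component, per entry."""

    mean: np.ndarray
    second_moment: np.ndarray


@dataclass
class ModelState:
    """Full variational state of a fitted (or partially fitted) model."""

    hidden: HiddenFactorState | None
    known: KnownFactorState | None
    genetic: GeneticState | None
    noise: NoiseState
    hyper: Hyperparameters
    gene_means: np.ndarray            # per-gene observed means absorbed by centring
    bound_trace: list = field(default_factory=list)
    converged: bool = False

    def components(self) -> dict:
        out = {}
        if self.genetic is not None:
            out["genetic"] = self.genetic
        if self.known is not None:
            out["known"] = self.known
        if self.hidden is not None:
            out["hidden"] = self.hidden
        return out


# ---------------------------------------------------------------------------
# Engine primitives
# ---------------------------------------------------------------------------

def _centered(Y, state: ModelState):
    """Centred values and observed mask from an ExpressionMatrix or array."""
    if isinstance(Y, ExpressionMatrix):
        vals, mask = Y.values, Y.missing_mask
    else:
        vals = np.asarray(Y, dtype=float)
        mask = np.isfinite(vals)
    Yc = vals - (state.gene_means[:, None] if state.hyper.center_genes else 0.0)
    return Yc, mask


def residual_for(model: str, state: ModelState, Y) -> np.ndarray:
    """Residual dataset for the named active component.

    Returns the (centred) expression minus the posterior-mean
    contributions of every *other* fitted component; missing entries are
    NaN.
    """
    comps = state.components()
    if model not in ("genetic", "known", "hidden"):
        raise ValueError(f"unknown component label {model!r}")
    Yc, mask = _centered(Y, state)
    R = Yc.copy()
    for name, comp in comps.items():
        if name != model and comp.contrib_mean is not None:
            R = R - comp.contrib_mean
    R[~mask] = np.nan
    return R


def _expected_rss(state: ModelState, Yc: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene E[sum_n (y - sum_m c_m)^2] over observed entries."""
    total = np.zeros_like(Yc)
    var_g = np.zeros(Yc.shape[0])
    for comp in state.components().values():
        total = total + comp.contrib_mean
        var_g = var_g + comp.contrib_var_gene
    diff = np.where(mask, Yc - total, 0.0)
    return (diff ** 2).sum(axis=1) + var_g


def update_noise(state: ModelState, Y) -> NoiseState:
    """Gamma update of the per-gene noise precisions.

    shape = noise_shape + n_obs/2 and rate = noise_rate + E[RSS]/2 with
    the residual expectation taken under all component posteriors.
    """
    Yc, mask = _centered(Y, state)
    n_obs = mask.sum(axis=1)
    esq = _expected_rss(state, Yc, mask)
    shape = state.hyper.noise_shape + 0.5 * n_obs
    rate = state.hyper.noise_rate + 0.5 * esq
    return NoiseState(shape, np.maximum(rate, 1e-300))


def _gamma_bound_term(shape, rate, prior_shape, prior_rate) -> float:
    """E_q[log p(tau)] - E_q[log q(tau)] for gamma q and prior, summed."""
    shape = np.asarray(shape, dtype=float)
    rate = np.asarray(rate, dtype=float)
    elog = digamma(shape) - np.log(rate)
    etau = shape / rate
    term = (prior_shape * np.log(prior_rate) - gammaln(prior_shape)
            + (prior_shape - shape) * elog - prior_rate * etau
            - shape * np.log(rate) + gammaln(shape) + shape)
    return float(np.sum(term))


def _batched_logdet(cov: np.ndarray) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(cov)
    return logdet


def variational_bound(state: ModelState, Y) -> float:
    """Evidence lower bound of the current variational state.

    Constant terms are kept consistently, so only differences between
    states of the same model are meaningful.
    """
    Yc, mask = _centered(Y, state)
    n_obs = mask.sum(axis=1)
    noise = state.noise
    etau = noise.expected_precision
    elog = noise.expected_log_precision
    esq = _expected_rss(state, Yc, mask)

    bound = float(np.sum(0.5 * n_obs * (elog - LOG2PI) - 0.5 * etau * esq))
    bound += _gamma_bound_term(noise.shape_g, noise.rate_g,
                               state.hyper.noise_shape, state.hyper.noise_rate)

    hid = state.hidden
    if hid is not None and hid.n_factors > 0:
        G, K = hid.loadings_mean.shape
        N = hid.activations_mean.shape[0]
        Ew2 = hid.loadings_mean ** 2 + np.einsum("gkk->gk", hid.loadings_cov)
        bound += float(0.5 * G * np.sum(hid.ard_log_mean - LOG2PI)
                       - 0.5 * np.sum(hid.ard_mean * Ew2.sum(axis=0)))
        bound += float(0.5 * np.sum(_batched_logdet(hid.loadings_cov))
                       + 0.5 * G * K * (1.0 + LOG2PI))
        Ex2 = hid.activations_mean ** 2 + np.einsum("nkk->nk", hid.activations_cov)
        bound += float(-0.5 * N * K * LOG2PI - 0.5 * np.sum(Ex2))
        bound += float(0.5 * np.sum(_batched_logdet(hid.activations_cov))
                       + 0.5 * N * K * (1.0 + LOG2PI))
        bound += _gamma_bound_term(hid.ard_shape, hid.ard_rate,
                                   hid.prior_shape, hid.prior_rate)

    kn = state.known
    if kn is not None and kn.n_covariates > 0:
        G, F = kn.weights_mean.shape
        Ev2 = kn.weights_mean ** 2 + np.einsum("gff->gf", kn.weights_cov)
        bound += float(0.5 * G * np.sum(kn.ard_log_mean - LOG2PI)
                       - 0.5 * np.sum(kn.ard_mean * Ev2.sum(axis=0)))
        bound += float(0.5 * np.sum(_batched_logdet(kn.weights_cov))
                       + 0.5 * G * F * (1.0 + LOG2PI))
        bound += _gamma_bound_term(kn.ard_shape, kn.ard_rate,
                                   kn.prior_shape, kn.prior_rate)

    gen = state.genetic
    if gen is not None:
        p = np.clip(gen.inclusion_prob, 0.0, 1.0)
        rho = gen.prior_inclusion
        s = gen.slab_var
        bern = (xlogy(p, rho) - xlogy(p, p)
                + xlogy(1.0 - p, 1.0 - rho) - xlogy(1.0 - p, 1.0 - p))
        kl_w = 0.5 * (np.log(s / gen.weight_var)
                      + (gen.weight_var + gen.weight_mean ** 2) / s - 1.0)
        bound += float(np.sum(bern - p * kl_w))

    if not np.isfinite(bound):
        raise FloatingPointError("variational bound is not finite")
    return bound


def corrected_expression(state: ModelState, Y, remove=("known", "hidden")):
    """Expression with the listed components' posterior means subtracted.

    The genetic component is never removed by default, so residuals keep
    the association signal for downstream eQTL testing.
    """
    remove = set(remove)
    comps = state.components()
    unknown = remove - {"genetic", "known", "hidden"}
    if unknown:
        raise ValueError(f"unknown component labels: {sorted(unknown)}")
    missing = remove - set(comps)
    if missing:
        raise ValueError(f"components not fitted: {sorted(missing)}")
    if isinstance(Y, ExpressionMatrix):
        vals = Y.values.copy()
        out_ids = (Y.gene_ids, Y.individual_ids)
        mask = Y.missing_mask
    else:
        vals = np.asarray(Y, dtype=float).copy()
        mask = np.isfinite(vals)
        out_ids = ([f"g{i}" for i in range(vals.shape[0])],
                   [f"i{j}" for j in range(vals.shape[1])])
    for name in remove:
        vals = vals - comps[name].contrib_mean
    vals[~mask] = np.nan
    return ExpressionMatrix(vals, out_ids[0], out_ids[1], mask)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class VBQTL:
    """Joint Bayesian model of expression with genetic, known and hidden
    components.

    Parameters
    ----------
    expr : ExpressionMatrix, DataFrame (genes x individuals) or ndarray
    genotypes : GenotypeMatrix, optional
    covariates : CovariateMatrix, optional
    hyper : Hyperparameters, optional (keyword overrides also accepted)

    Individual identifiers of genotypes/covariates must already match the
    expression columns; use :func:`peerqtl.data.align_individuals` first
    if they do not.
    """

    def __init__(self, expr, genotypes: GenotypeMatrix | None = None,
                 covariates: CovariateMatrix | None = None,
                 hyper: Hyperparameters | None = None, **overrides):
        if isinstance(expr, pd.DataFrame):
            expr = ExpressionMatrix(expr.to_numpy(dtype=float),
                                    list(expr.index), list(expr.columns))
        elif not isinstance(expr, ExpressionMatrix):
            arr = np.asarray(expr, dtype=float)
            expr = ExpressionMatrix(arr, [f"g{i}" for i in range(arr.shape[0])],
                                    [f"i{j}" for j in range(arr.shape[1])])
        self.expr = expr
        for other, what in ((genotypes, "genotype"), (covariates, "covariate")):
            if other is not None and list(other.individual_ids) != list(expr.individual_ids):
                raise ValueError(
                    f"{what} individuals do not match expression columns; "
                    "run align_individuals first")
        self.genotypes = genotypes
        self.covariates = covariates
        hyper = hyper if hyper is not None else Hyperparameters()
        if overrides:
            hyper = hyper.replace(**overrides)
        self.hyper = hyper

    @classmethod
    def from_dataframes(cls, expr_df: pd.DataFrame,
                        geno_df: pd.DataFrame | None = None,
                        covs_df: pd.DataFrame | None = None, **kw) -> "VBQTL":
        """Build from pandas frames; genotype frame needs chrom/pos columns."""
        geno = covs = None
        if geno_df is not None:
            meta = [c for c in ("chrom", "pos") if c in geno_df.columns]
            if len(meta) != 2:
                raise ValueError("genotype frame needs 'chrom' and 'pos' columns")
            inds = [c for c in geno_df.columns if c not in ("chrom", "pos")]
            geno = GenotypeMatrix(geno_df[inds].to_numpy(), list(geno_df.index),
                                  list(geno_df["chrom"]), geno_df["pos"].to_numpy(),
                                  inds, kw.pop("ploidy", 2))
        if covs_df is not None:
            covs = CovariateMatrix(covs_df.to_numpy(dtype=float),
                                   list(covs_df.index), list(covs_df.columns))
        return cls(expr_df, geno, covs, **kw)

    # -- fitting ----------------------------------------------------------

    def fit(self, schedule: str | None = None, init: str = "pca",
            reselect_snp: bool = True, **overrides) -> "VBQTLResults":
        """Run variational inference and return a results object.

        ``schedule`` is ``"iVBQTL"`` (joint iterative) or ``"fVBQTL"``
        (factors first, single genetic pass); keyword overrides update
        any :class:`Hyperparameters` field for this fit only.
        """
        hyper = self.hyper.replace(**overrides) if overrides else self.hyper
        if schedule is not None:
            hyper = hyper.replace(schedule=schedule)

        Yv = self.expr.values
        mask = self.expr.missing_mask
        G, N = Yv.shape
        complete = bool(mask.all())
        n_obs = mask.sum(axis=1)
        if np.any(n_obs == 0):
            raise ValueError("every gene needs at least one observed value")

        gene_means = (np.nansum(np.where(mask, Yv, 0.0), axis=1) / n_obs
                      if hyper.center_genes else np.zeros(G))
        Yc = np.where(mask, Yv - gene_means[:, None], 0.0)

        K = hyper.K_hidden
        if K > N:
            warnings.warn(f"K_hidden={K} exceeds N={N}; clamping to N")
            K = N

        H = None
        if self.covariates is not None:
            H = self.covariates.values.copy()
        if not hyper.center_genes:
            ones = np.ones((1, N))
            H = ones if H is None else np.vstack([H, ones])

        Z = standardize_genotypes(self.genotypes.values) if self.genotypes is not None else None

        # initial noise from per-gene residual variance (ML-style start)
        var0 = np.maximum((Yc ** 2 * mask).sum(axis=1) / np.maximum(n_obs, 1), 1e-8)
        shape0 = hyper.noise_shape + 0.5 * n_obs
        noise = NoiseState(shape0, shape0 * var0)

        state = ModelState(
            hidden=None,
            known=(KnownFactorState.initialize(H, G, hyper.ard_shape, hyper.ard_rate)
                   if H is not None else None),
            genetic=(GeneticState.initialize(G, N, hyper.prior_inclusion, hyper.slab_var)
                     if Z is not None else None),
            noise=noise,
            hyper=hyper,
            gene_means=gene_means,
        )
        msk = None if complete else mask

        def resid(active: str) -> np.ndarray:
            R = Yc.copy()
            for name, comp in state.components().items():
                if name != active:
                    R -= comp.contrib_mean
            return R

        def do_hidden():
            if K == 0:
                return
            R = resid("hidden")
            if state.hidden is None:
                state.hidden = HiddenFactorState.initialize(
                    R, mask, K, hyper.ard_shape, hyper.ard_rate,
                    method=init, rng=hyper.seed)
            state.hidden = update_hidden(state.hidden, R, state.noise, msk)

        def do_known():
            if state.known is not None:
                state.known = update_known(state.known, resid("known"), state.noise, msk)

        def do_genetic():
            if state.genetic is not None:
                state.genetic = update_genetic(
                    state.genetic, resid("genetic"), Z, state.noise, msk,
                    reselect=reselect_snp)

        def do_noise():
            state.noise = update_noise(state, self.expr)

        def converged() -> bool:
            tr = state.bound_trace
            if len(tr) < 2:
                return False
            return abs(tr[-1] - tr[-2]) < hyper.tol * max(1.0, abs(tr[-1]))

        if hyper.schedule == "iVBQTL":
            for _ in range(hyper.max_iter):
                do_genetic(); do_known(); do_hidden(); do_noise()
                state.bound_trace.append(variational_bound(state, self.expr))
                if converged():
                    state.converged = True
                    break
        else:  # fVBQTL: confounders to convergence, one genetic pass
            for _ in range(hyper.max_iter):
                do_known(); do_hidden(); do_noise()
                state.bound_trace.append(variational_bound(state, self.expr))
                if converged():
                    state.converged = True
                    break
            if state.genetic is not None:
                do_genetic(); do_noise()
                state.bound_trace.append(variational_bound(state, self.expr))

        return VBQTLResults(self, state)


class VBQTLResults:
    """Fitted-model view: posterior summaries, residuals, diagnostics."""

    def __init__(self, model: VBQTL, state: ModelState):
        self.model = model
        self.state = state

    # -- basic accessors ---------------------------------------------------

    @property
    def bound_trace(self) -> np.ndarray:
        return np.asarray(self.state.bound_trace)

    @property
    def n_sweeps(self) -> int:
        return len(self.state.bound_trace)

    @property
    def converged(self) -> bool:
        return self.state.converged

    @property
    def noise_precision(self) -> np.ndarray:
        return self.state.noise.expected_precision

    def component_contribution(self, label: str) -> ComponentContribution:
        comp = self.state.components().get(label)
        if comp is None:
            raise ValueError(f"component {label!r} not fitted")
        return ComponentContribution(comp.contribution_mean(),
                                     comp.contribution_second_moment())

    # -- residuals ---------------------------------------------------------

    def residuals(self, remove=("known", "hidden")) -> ExpressionMatrix:
        """Expression minus the selected components (default: confounders)."""
        remove = set(remove) & set(self.state.components()) if remove == ("known", "hidden") \
            else set(remove)
        return corrected_expression(self.state, self.model.expr, remove)

    def residual_for(self, label: str) -> np.ndarray:
        return residual_for(label, self.state, self.model.expr)

    # -- factors and genetics ----------------------------------------------

    @property
    def factors(self) -> pd.DataFrame:
        """Hidden factor activations, individuals x factors."""
        hid = self.state.hidden
        if hid is None:
            return pd.DataFrame(index=self.model.expr.individual_ids)
        cols = [f"factor_{k+1}" for k in range(hid.n_factors)]
        return pd.DataFrame(hid.activations_mean,
                            index=self.model.expr.individual_ids, columns=cols)

    def active_factors(self, variance_floor: float = 1e-3) -> list[int]:
        hid = self.state.hidden
        if hid is None:
            return []
        R = self.residual_for("hidden")
        total_var = float(np.nanmean(R ** 2))
        return active_factors(hid, variance_floor, total_var)

    def factor_alignment(self, v: np.ndarray, variance_floor: float = 1e-3) -> float:
        """Multiple correlation of a vector with the active factor activations.

        Measures how much of an external signal (e.g. a hotspot genotype)
        lives in the span of the inferred hidden factors; rotation of the
        factor basis does not affect it.  Returns 0 when no factor is
        active.
        """
        hid = self.state.hidden
        if hid is None:
            return 0.0
        act = self.active_factors(variance_floor)
        if not act:
            return 0.0
        A = hid.activations_mean[:, act]
        v = np.asarray(v, dtype=float)
        v = v - v.mean()
        if v.std() == 0:
            return 0.0
        X = np.column_stack([np.ones(len(v)), A - A.mean(axis=0)])
        coef, *_ = np.linalg.lstsq(X, v, rcond=None)
        fitted = X @ coef
        return float(np.sqrt(max(0.0, 1.0 - np.sum((v - fitted) ** 2) / np.sum(v ** 2))))

    def genetic_effects(self) -> pd.DataFrame:
        """Per-gene best SNP, inclusion probability and effect size."""
        gen = self.state.genetic
        if gen is None:
            raise ValueError("model was fitted without genotypes")
        geno = self.model.genotypes
        snp_ids = [geno.snp_ids[s] if s >= 0 else "" for s in gen.selected_snp]
        return pd.DataFrame({
            "gene_id": self.model.expr.gene_ids,
            "snp_id": snp_ids,
            "inclusion_prob": gen.inclusion_prob,
            "weight_mean": gen.weight_mean,
            "weight_var": gen.weight_var,
        })

    # -- reporting -----------------------------------------------------------

    def summary(self, variance_floor: float = 1e-3) -> str:
        st = self.state
        G, N = self.model.expr.shape
        lines = [
            "VBQTL fit summary",
            "=" * 40,
            f"genes: {G}   individuals: {N}",
            f"schedule: {st.hyper.schedule}   sweeps: {self.n_sweeps}"
            f"   converged: {self.converged}",
            f"final bound: {st.bound_trace[-1]:.4f}" if st.bound_trace else "final bound: n/a",
        ]
        if st.hidden is not None:
            act = self.active_factors(variance_floor)
            lines.append(f"hidden factors: {st.hidden.n_factors} allowed, "
                         f"{len(act)} active (floor {variance_floor:g})")
        if st.known is not None:
            ard = ", ".join(f"{a:.3g}" for a in st.known.ard_mean)
            lines.append(f"known covariates: {st.known.n_covariates} "
                         f"(ARD precisions: {ard})")
        if st.genetic is not None:
            n_assoc = int((st.genetic.inclusion_prob > 0.5).sum())
            lines.append(f"genes with P(association) > 0.5: {n_assoc} "
                         f"(prior inclusion {st.genetic.prior_inclusion:g})")
        med_sd = float(np.median(1.0 / np.sqrt(self.noise_precision)))
        lines.append(f"median residual noise sd: {med_sd:.4f}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Archive posterior arrays plus a JSON metadata block (npz)."""
        st = self.state
        arrays = {
            "gene_means": st.gene_means,
            "noise_shape": st.noise.shape_g,
            "noise_rate": st.noise.rate_g,
            "bound_trace": np.asarray(st.bound_trace),
        }
        for name, comp in st.components().items():
            arrays[f"{name}_contrib_mean"] = comp.contrib_mean
        if st.hidden is not None:
            arrays.update(hidden_loadings=st.hidden.loadings_mean,
                          hidden_activations=st.hidden.activations_mean,
                          hidden_ard_shape=st.hidden.ard_shape,
                          hidden_ard_rate=st.hidden.ard_rate)
        if st.known is not None:
            arrays.update(known_weights=st.known.weights_mean,
                          known_ard_shape=st.known.ard_shape,
                          known_ard_rate=st.known.ard_rate)
        if st.genetic is not None:
            arrays.update(genetic_selected=st.genetic.selected_snp,
                          genetic_inclusion=st.genetic.inclusion_prob,
                          genetic_weight_mean=st.genetic.weight_mean,
                          genetic_weight_var=st.genetic.weight_var)
        meta = {
            "hyper": dataclasses.asdict(st.hyper),
            "gene_ids": self.model.expr.gene_ids,
            "individual_ids": self.model.expr.individual_ids,
            "components": sorted(st.components()),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_fit(path):
    """Load a saved fit archive into a dict of arrays plus metadata."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
    return arrays, meta


def fit_vbqtl(expr, genotypes=None, covariates=None,
              hyper: Hyperparameters | None = None, **kw) -> VBQTLResults:
    """Convenience wrapper: build a :class:`VBQTL` model and fit it."""
    return VBQTL(expr, genotypes, covariates, hyper=hyper, **kw).fit()
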