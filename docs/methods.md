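# Methods

## The model

Gene expression measurements mix the signal of interest — genetic effects
on transcript levels — with known covariates (gender, batch, environment)
and unobserved global influences (cell state, culture conditions, array
artefacts).  `peerqtl` models the observed expression matrix
Y (G genes × N individuals) as a sum of independent additive components
plus gene-specific Gaussian noise:

    y_gn = c_gn^genetic + c_gn^known + c_gn^hidden + ε_gn,
    ε_gn ~ N(0, τ_g⁻¹),   τ_g ~ Gamma(a_τ, b_τ)

**Genetic component.**  Per gene, a Bernoulli inclusion indicator b_g with
prior probability ρ and, conditional on inclusion, a Gaussian effect
w_g ~ N(0, σ²_slab) of a single SNP on the gene ("spike and slab").  To
keep the joint model tractable only the most relevant SNP per gene
carries the slab at any time (the bottleneck approximation); the SNP is
re-selected at every sweep by the slab marginal likelihood, which equals
the absolute-correlation rule when genotype scales are equal.  Genotypes
enter this component mean-imputed, centred and scaled to unit variance,
so effects are per genotype standard deviation and the Bayes factor
0.5·log(v/σ²_slab) + m²/(2v), with v = (1/σ²_slab + τ_g·zᵀz)⁻¹ and
m = v·τ_g·zᵀr, is allele-frequency invariant.  The posterior inclusion
probability is the Bayes factor combined with the prior log-odds; ρ plays
the role a significance threshold plays in a classical scan.

**Known component.**  Bayesian linear regression of each gene on the F
observed covariates, with a gamma ARD (automatic relevance determination)
precision per covariate shared across genes.  Irrelevant covariates
acquire a large relevance precision and their weights collapse to zero;
in the flat-prior limit the update reduces to ordinary least squares.

**Hidden component.**  Probabilistic factor analysis with K latent
factors: standard-normal activations per individual, Gaussian loadings
per gene with a gamma ARD precision per factor.  The ARD prior switches
surplus factors off, so K is an upper bound rather than a choice that
must be exactly right.  Factors are not constrained to be orthogonal;
recovery is therefore evaluated with subspace (canonical-correlation)
metrics, and hotspot absorption with a projection statistic
(`hotspot_absorption`) that is insensitive to factor rotation.

## Inference

The posterior is approximated by a distribution that factorises over
components (and within components over loadings, activations and
precisions).  Every update is an exact conjugate coordinate-ascent step
on the evidence lower bound: the active component's residual
(observations minus the other components' posterior means) is computed,
the component's posterior is refreshed using the other components' first
and second moments and the expected noise precisions, and the per-gene
noise precisions are updated from the full first/second moments
(shape a_τ + n_g/2, rate b_τ + E[RSS_g]/2).  The bound is evaluated after
every sweep and is non-decreasing up to floating-point tolerance
(asserted at 1e-6·|bound| in the tests); convergence is declared when the
relative bound change falls below `tol`.

Two schedules are provided:

* **iVBQTL** — sweeps genetic → known → hidden → noise jointly until
  convergence.  Because the genetic component competes with the hidden
  factors for shared variance, signal that is genuinely genetic (e.g. a
  trans hotspot driven by a variant in a regulator) stays genetic.
* **fVBQTL** — fits known + hidden + noise to convergence with the
  genetic component switched off, then performs a single genetic pass on
  the factor residuals.  Cheaper, and equivalent when genetic effects are
  sparse, modest and orthogonal to the confounders; under those
  conditions (5% of genes with effects 1–2 noise sd, prior inclusion
  matched to that sparsity) the two schedules' residuals agree to <1%
  Frobenius in our tests.  With strong dense genetic effects they differ
  by a few percent through noise-precision feedback.

Initialisation is maximum-likelihood flavoured: noise precisions from
per-gene residual variance, hidden activations from the top-K principal
components of the residual available at the first hidden update (so
under iVBQTL the genetic model has had first claim on the data), known
weights and genetic effects from their first conjugate update.  A
random-from-prior initialisation exists behind `fit(init="random")` but
is not used by any reported result.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `K_hidden` | 10 | upper bound on hidden factors; ARD prunes the surplus |
| `ard_shape`, `ard_rate` | 1e-3, 1e-3 | broad gamma prior on relevance precisions |
| `noise_shape`, `noise_rate` | 1e-3, 1e-3 | broad gamma prior on noise precisions |
| `prior_inclusion` | 0.01 | prior probability of a per-gene association |
| `slab_var` | 1.0 | effect-size prior variance per genotype sd |
| `tol`, `max_iter` | 1e-5, 1000 | convergence controls on the bound |
| `center_genes` | on | subtract gene means; otherwise an intercept covariate is added |

Two behaviours deserve note.  First, each *pruned* factor's ARD posterior
diverges towards its prior-dominated fixed point and pays a fixed KL
bookkeeping cost (~0.3% of the bound per factor here), so the converged
bound decreases slightly — not monotonically increases — as surplus K
grows; what does not degrade is the fit quality, which is the property
the benchmark asserts.  Second, the degenerate zero-residual gene is
safe: the noise rate falls back to its prior and the precision stays
finite.

## Residual-based eQTL mapping

Corrected expression is the observation minus the posterior means of the
removed components — by default known + hidden, never the genetic
component.  Per gene the best SNP by |Pearson r| (pairwise-complete
observations) is tested with a two-sided t test on the correlation
(t = r·√(n−2)/√(1−r²), n−2 df), a midrank variant, a 1-df chi-squared
likelihood-ratio test of the nested linear model, or a permutation test
of the per-gene maximum |r| over SNPs (p = (1+#{null ≥ obs})/(1+P)).
Analytic p-values get a per-gene Bonferroni correction for the number of
SNPs scanned; the permutation p is already family-wise.  The default
per-gene false-positive rate is 0.001.  Associations are cis when the
SNP lies within 1 Mb (inclusive) of the probe midpoint, or on the same
chromosome for inbred-cross designs.  An optional empirical FDR permutes
the genotype columns as a block (preserving LD) and compares null and
observed significant counts; it is a documented estimator of our own
design, not a reconstruction of any published procedure.

## Baseline correctors

All baselines first remove known-covariate effects by per-gene OLS, then:
**Standard** stops there; **PCA** subtracts the rank-K truncated SVD
reconstruction; **PCAsig** chooses K by sequentially testing eigenvalue
variance fractions against a gene-wise permutation null (p-values are
plain exceedance fractions, so components that beat every permutation
are significant at any cutoff — this is what makes the selected count
invariant across cutoffs from 1e-5 to 1e-2); **SVA** rebuilds each
significant eigengene from the eigen-decomposition of only the genes
associated with it (same cutoff) and regresses all surrogates out
jointly, which recovers sparse, non-orthogonal confounders.

## The simulation and what it does (and does not) show

The generator emulates a bulk eQTL study: independent SNPs with allele
frequencies in [0.1, 0.9] (haploid by default, diploid dosages behind a
flag); 20% of genes with a cis eQTL (effects 3–6 per allele, random
sign); three of the cis genes designated hotspot regulators whose
noise-free cis signal drives 15% of genes each (weights 1.5–2.5),
mimicking a variant in a transcription factor; three known covariates
and seven dense hidden factors with per-factor scales 0.5–2 ("influence
varies significantly"); gene noise sd 2–4.  These scales put the global
(known + hidden + hotspot) components at roughly two thirds of the total
variance — the regime where confounder correction decides the outcome —
and make every global component detectable above the Marchenko–Pastur
noise edge, so the PCA complexity optimum lands at the true count of ten
global components.  All contribution matrices, the gene→SNP map and the
hotspot target sets are recorded and sum exactly to the generated
expression.

Benchmark fits use `max_iter=60, tol=1e-4` (the bound plateaus within a
few dozen sweeps at the default G=1000, N=100, S=500 scale); evaluation
re-runs over ten seeds and asserts orderings and coarse optima, not
absolute values.

What the simulation does not contain: linkage disequilibrium, population
structure or kinship, non-Gaussian expression noise, probe-level
artefacts, or nonlinear/epistatic effects.  Passing benchmarks therefore
demonstrate correct complexity control and attribution under the
linear-additive assumptions shared by all the compared methods, not
robustness to real-data pathologies.

One measured deviation from the idealised expectation is documented here
deliberately: on null genes, mapping on iVBQTL residuals is mildly
anti-conservative (~0.5–1.4% per-gene family-wise rate at a nominal
0.1%).  The joint model shields each gene's best chance correlation from
being absorbed while the factor removal shrinks residual variance, and a
few-percent inflation of |r| multiplies the extreme-tail false-positive
rate by an order of magnitude.  The flagged genes carry posterior
inclusion probabilities near 1 — at N=100 they are indistinguishable
from genuine weak eQTLs.  The other methods (Standard, Ideal, PCA, SVA,
fVBQTL) stay within three binomial standard deviations of the nominal
rate.

## Numerical choices

Ties in best-SNP selection break to the lowest SNP index.  Monomorphic
SNPs are never selected and are untestable (p = 1).  Missing expression
entries are excluded from all sufficient statistics (never imputed);
missing genotypes are mean-imputed inside the VB update only and dropped
pairwise in association tests.  Covariances are symmetrised after each
batched inverse; the bound keeps all constant terms so only differences
are meaningful.  The cis window is inclusive at exactly 1 Mb.  Gene
centring absorbs means by default; disabling it adds an intercept
covariate instead, so exactly one mechanism absorbs the mean.
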