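# Methods

## The analysis

`pnstrat` stratifies a tumour cohort by the expression of a curated
proteostasis-network (PN) gene set and characterises the resulting
subtypes.  The pipeline's statistical content, stage by stage:

**Purity residualisation.** Bulk expression of sample *j* is a mixture of
tumour and stromal/immune signal in proportion to tumour purity
*p<sub>j</sub>* ∈ [0, 1].  For each gene the model is

    log2(x_gj + c) = a_g + b_g p_j + e_gj

fit by ordinary least squares per gene; downstream clustering uses the
residuals *e<sub>gj</sub>*.  The pseudocount *c* defaults to 1 (the
source does not pin it down; it is configurable).  Residuals are exactly
orthogonal to the purity vector and mean-zero per gene, the operation is
idempotent, and it is equivariant to per-gene affine changes — these are
tested properties, not aspirations.  Samples without a purity estimate
are dropped, not imputed: clustering is sensitive to imputation
artefacts and no principled imputation rule exists here.  If all
purities coincide the fit degenerates gracefully to mean-centring.

**Clustering and labelling.** Samples are clustered on the z-scored
(per gene) purity residuals of the PN genes only, genes on the same
block, both with Ward's minimum-variance criterion on Euclidean
distances (the Ward.D2 variant — the standard modern definition; the
agglomeration is deterministic given input order via the
nearest-neighbour-chain ordering of `scipy.cluster.hierarchy.linkage`).
The dendrogram is cut by cluster count *k* (defaults: 2 for samples, 2
for genes), not by height, since subtype counts are the quantity of
interest.  The anchor "cluster 1" of genes is the larger gene cluster
(ties to the cluster containing the lexicographically smallest gene id;
overridable).  Sample clusters are ranked by mean residual expression
over cluster-1 genes: the lower half is labelled A (A1, A2, …, in
ascending mean), the upper half B; exact ties (within 1e−12) break by
smallest member sample id and are logged.  Sub-labels merge additively
(A1, A2 → A).

**Composite DE call.** Between groups A and B, per gene:

* pooled-variance two-sided Student *t* on log-scale expression (the
  purity residuals in the pipeline — the same matrix that defined the
  groups; configurable),
* a count-based NB Wald test on the raw counts (below),
* linear fold change fc = mean_A / mean_B on unadjusted FPKM-like
  values (residuals can be negative, which makes ratios meaningless).

A gene is `lower` iff *p* < 0.05 and BH-adjusted *q* < 0.1 in **both**
tests, fc < 0.8, and both test statistics are negative; `higher`
symmetrically with fc > 1.25; otherwise `unchanged`.  All thresholds are
strict inequalities; fc = 0.8 exactly is `unchanged`.  The
direction-consistency requirement is a safeguard that can only reduce
calls.  BH adjustment is applied within whatever gene universe is being
analysed (the PN set for PN calls, each random set separately, the
transcriptome for genome-wide rates) so that proportions are compared
like for like.

**The NB Wald test.** A deliberately transparent approximation of the
count-model Wald tests used by dedicated DE packages:

* size factors by median-of-ratios: reference = per-gene geometric mean
  over samples; genes containing any zero are excluded from the median;
* per-gene dispersion α by method of moments on normalised counts
  y = K/s: pooled within-group variance minus the Poisson part
  μ·mean(1/s), divided by μ², floored at 1e−8;
* Wald statistic z = log(μ̂_A/μ̂_B) / SE with the delta-method
  SE² = Σ_K Var(μ̂_K)/μ̂_K², Var(μ̂_K) = (μ̂_K·mean(1/s) + α μ̂_K²)/n_K,
  referred to the standard normal.

All-zero genes report p = 1 and a missing fold change; a group mean of
exactly zero (for a gene that is not all-zero) receives a half-count
continuity correction.  Because the variance estimate is floored from
below by the Poisson part, the test is mildly conservative near the
Poisson limit (measured type-I error ≈ 0.04 at nominal 0.05 with 20
samples per group); there is no dispersion-trend shrinkage, independent
filtering, or fold-change shrinkage by design.

**Resampling nulls.** Two procedures, both with count-convention
empirical p-values p = #{draw ≥ observed}/n (every p an exact multiple
of 1/n; a (count+1)/(n+1) variant sits behind a flag):

* *Random-gene-set null*: draw sets of the PN set's size uniformly
  without replacement from all genes in the matrix, re-run the composite
  caller within each set (raw per-gene statistics are set-independent
  and computed once; BH is re-applied per set), record the called
  fraction; the PN set's fraction is the observed statistic.
* *Overlap permutation*: for two DE lists of sizes a and b in a
  universe of size N with observed intersection k, simulate pairs of
  independent uniform subsets and count intersections.  The exact tail
  P(X ≥ k) of the hypergeometric distribution, summed in log space, is
  implemented alongside as the analytic oracle; the tests require the
  permutation p to match it within Monte-Carlo tolerance.

A subtlety worth recording: when group labels are *inferred* by
clustering on the PN genes themselves, the PN set's called fraction is
slightly optimistic even without planted enrichment (the labels fit the
PN genes' noise).  Calibration tests therefore use an observed set that
is itself a uniform random draw, for which the empirical p-value is
exchangeable with the draws and verifiably uniform.

**Survival.** Kaplan–Meier per subtype and the log-rank test across
subtypes; events beyond an analysis horizon (e.g. 3 years) are recoded
as censored at the horizon before estimation; the metastatic-style
analysis uses no truncation by default.  Cox proportional hazards with
Efron tie handling; the subtype enters as a dummy against the
alphabetically first label; stage is collapsed to the major Roman
numeral and enters as ordinal 1–4 (sub-stages are sparse; the encoding
is configurable); gender and other categoricals are dummy-coded;
zero-variance covariates are dropped with a warning.  Whether the time
column is disease-specific or overall survival is a property of the
input table, not a code branch.  Clinical attributes associate with the
subtype via an exact conditional 2×k Fisher test (full enumeration of
tables with the observed margins, two-sided by summing tables no more
probable than the observed; for 2×2 this reproduces the classical
test) or a two-sample *t*-test; the 0–3 pigmentation score is recoded
0,1 → low and 2,3 → high.

## The synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, so
that every stage can be tested against known truth:

    log2 E[K_gj] = b_g + Δ_g·I[group_j = B] + c_g·(1 − p_j)

* baselines b_g ~ N(6, 1.5²) (log2 scale, i.e. typical counts of ~64
  with a realistic dynamic range);
* planted effects Δ_g = ±log2(fold) for a chosen number of genes inside
  and outside the PN-like set (defaults 136 inside / 164 outside of
  2000 genes, fold 1.5 — the PN set is enriched for DE, as in the real
  cohorts);
* purity p_j ~ Beta(6, 2) (mean 0.75); stromal effects
  c_g ~ N(0, 1.5²) enter scaled by the stromal fraction, giving all
  genes a shared purity-driven axis of variation that confounds
  unadjusted clustering;
* counts are gamma–Poisson (negative binomial) with dispersion 0.2, so
  Var = μ + 0.2 μ²; the "FPKM" surrogate rescales each sample to a
  fixed total of 10⁶;
* survival is exponential with baseline hazard 0.15/year, hazard ratio
  2.5 for group B, censoring at a 10-year horizon; age, gender, stage,
  pigmentation and subsequent metastasis are drawn independently of the
  group, so covariate-adjusted models run under a clean null for the
  covariates.

Default cohort size is 50 samples per group.  All randomness derives
from a single root seed through `numpy.random.SeedSequence.spawn` into
four named streams (structure, counts, purity, survival), so identical
configs give byte-identical cohorts and stages can be re-run
independently.

What the generator does **not** emulate: empirical TCGA gene-level
distributions (GC/length effects, expression-dependent dispersion
trends), correlated gene modules beyond the single purity axis,
batch effects, mutational or copy-number structure, competing risks or
non-proportional hazards.  Passing tests therefore demonstrate that the
implementation recovers the model it assumes — not that the model
captures every property of real cohorts.

## Problem sizes and numerical choices

Test and acceptance computations run at deliberately chosen sizes:
purity orthogonality on 1000 genes × 100 samples; overlap agreement on a
~40-point grid at 5000 simulations per point; exhaustive-enumeration
check on the C(10,5) = 252 subsets of a 10-gene universe against 5000
sampled draws (χ² after pooling expected counts below 5); null
calibration over 200 replicate cohorts of 2000 genes × 50 samples with
200-draw nulls (set size 200 keeps the called-count lattice fine enough
that ties between observed and draws stay rare relative to the KS
critical distance); parameter recovery over 20 seeds of the default
cohort; count-test calibration over five 2000-gene null datasets;
survival recovery over 50 (power) and 200 (null uniformity) replicates.

Other numerical conventions: Ward heights are validated non-decreasing;
labelling ties break by smallest sample id; BH is the step-up procedure
clipped at 1; the exact Fisher enumeration refuses tables whose
enumeration space exceeds 5×10⁶; survival times are floored at 1e−6
years so horizon-zero censoring keeps times positive.

## Known limitations

* The NB Wald test approximates, but does not reproduce, the shrinkage
  estimators of dedicated count-model packages; concordance is
  property-based (calibration, power, direction), not numerical.
* The exact 2×k Fisher test is enumeration-based and intended for the
  small contingency tables of clinical attributes.
* Clustering inference and DE calling share the PN genes, so PN-set
  DE proportions under inferred labels carry a mild selection optimism
  (quantified and discussed above).
* Identifiers are opaque case-sensitive strings; no gene-symbol
  aliasing or conversion is attempted.
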