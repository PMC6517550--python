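# Methods

This note documents the models, the numerical choices and the synthetic-data
conditions behind `growthmodulon`, and what the shipped tests do and do not
establish about real data.

## Growth kinetics

A culture inoculated from a long stationary pre-culture contains dead
biomass that gravimetric cell-dry-weight (CDW) measurement cannot separate
from viable biomass.  With percent viability υ₀ measured at inoculation
(colony-forming units relative to a mid-exponential reference; values above
100% are flagged, not clipped), the dead-biomass offset is
`d = c₀ (1 − υ₀/100)` and the viability-adjusted differential growth rate of
the interval (t₁, t₂] is

    μ_diff = ln[(c₂ − d) / (c₁ − d)] / (t₂ − t₁)   [h⁻¹].

Two deliberate readings are implemented.  The default subtracts the *dead*
fraction, so that at υ₀ = 100 the formula reduces exactly to the ordinary
log-ratio specific growth rate; a `strict_as_printed` flag instead subtracts
the *viable* inoculum `c₀ υ₀/100`, which is kept only for comparison because
at full viability it removes the entire inoculum.  The rate carries a Δt
denominator so its unit is h⁻¹ throughout.  Rates may be negative during a
lag (biomass decline) and are not clipped.

Each interval's μ_diff is attributed to the interval midpoint and μ(t) is
interpolated linearly between midpoints (constant beyond the outer midpoints
but inside the observed range; extrapolation is an error).  Transcriptome
samples are selected per target rate as the candidate minimizing
|μ(t) − target|, ties broken by earliest time, with reuse of one sample for
several targets flagged.

`substrate_depletion_time(c, q, X) = c/(qX)` gives the zero-order bound on
how long a medium component lasts; with 0.2 mmol L⁻¹ substrate, an uptake of
2.04 mmol gCDW⁻¹ h⁻¹ and 1.2 g L⁻¹ biomass it evaluates to ≈ 0.08 h.

## Normalization and sample dissimilarity

Size factors are relative log expression (median-of-ratios): the reference
set is the genes positive in every sample; the factor of sample j is the
median over that set of `count_gj / geomean_g`.  Genes that are zero in all
samples are dropped beforehand (they carry no information and break
geometric means).  Factors are defined only up to the per-gene geometric
mean normalization, so statements about scaling behaviour hold for factor
*ratios*.

The dissimilarity of samples i, j is the deviance of the Poisson null that
both columns share one relative-abundance profile scaled by their size
factors: with `m_gi = s_i (x_gi + x_gj)/(s_i + s_j)`,

    d(i,j) = Σ_g [ x_gi log(x_gi/m_gi) − (x_gi − m_gi)
                 + x_gj log(x_gj/m_gj) − (x_gj − m_gj) ],   0·log 0 := 0.

d is symmetric, non-negative, zero exactly when the columns are proportional
with ratio s_i/s_j.  A square-root variance-stabilizing option exists but is
off by default.  Samples are clustered agglomeratively (complete linkage by
default) on this matrix; the leaf order and flat cuts are deterministic in
the input order.

Whether size factors belong inside the dissimilarity at all is a design
choice; we apply them inside the Poisson model (the statistically coherent
composition of normalization with the model) rather than pre-dividing
counts.

## Rate-course differential expression

Per condition, every gene's counts are modelled by a log-link GLM with the
differential growth rate as covariate,

    log E[y_j] = log s_j + β₀ + β₁ μ_j + β₂ μ_j² + β₃ μ_j³,

family negative binomial (variance m + φm²).  Cubic degree is used because
the rate course spans 4–5 grid points and the modulon comparison is based on
cubic profiles.  The carbon condition has only four rate points; the cubic
is then saturated in rate levels but remains identifiable with replicates.

**Dispersion.** φ is estimated by matching the Pearson chi-square of the
full-model fit to its residual degrees of freedom (a df-corrected method of
moments), solved by bisection.  By default one φ is pooled across all genes
of a condition (all genes share the design matrix; at 11–15 samples
per-gene estimates carry ~40% relative error and are unusable as plug-ins);
a `per-gene` mode is available.  Genes not overdispersed at the Poisson fit
get φ = 0.

**Test.** Significance of the rate dependence is a quasi-likelihood F-test:
`F = [(dev₀ − dev₁)/3] / scale` referred to F(3, df₂).  With pooled
dispersion the scale is 1 and df₂ is the pooled residual df (the reference
is then essentially χ²₃/3); in per-gene mode df₂ = n − 4, which prices in
the dispersion-estimation uncertainty — a plug-in χ² LRT at these sample
sizes is badly anti-conservative (in our null simulations 90% of repeats
produced a spurious BH discovery; the F-form brings that to the nominal
level).  The fitted-vs-null deviance ratio is reported as R² (not used as a
filter by default).  All-zero genes are flagged with p = 1 and a flat
profile.

**Calling.** Log₂ fold changes are the fitted polynomial evaluated on the
condition's rate grid, re-anchored to 0 at the reference rate (the highest
rate, 0.4 h⁻¹).  A DEG satisfies BH-adjusted p < 0.05 *and*
max|log₂FC| ≥ cutoff over the grid, with shipped cutoffs 0.73 (phosphate),
0.73 (nitrogen), 0.6 (carbon; compensates the missing lowest-rate point).
The cutoff is applied to the profile maximum of the *fitted* (smoothed)
curve; whether a single contrast or the profile maximum is the right object
is genuinely open, and the profile maximum is our choice for rate-course
data.

Numerics: one batched IRLS solves all genes at once (shared n×4 design,
per-gene 4×4 normal equations with a 1e-10 ridge, linear predictor clipped
to ±30); the polynomial is fitted on μ/μ_max ∈ [0, 1] for conditioning and
coefficients are mapped back exactly.

## Modulon identification and profile clustering

The modulon is the intersection of the per-condition DEG sets, filtered by
cross-condition profile similarity: each gene's fitted log₂FC profile is
evaluated per condition on the common rate grid (the intersection of the
condition grids, [0.1, 0.4] when carbon is present) and the score is the
*minimum* pairwise Pearson correlation between condition profiles.  Genes
with score ≥ 0.7 (configurable; −1 disables the filter) enter the modulon.
Profiles with a range below 0.1 log₂ in any condition are excluded as flat —
the correlation of near-constant vectors is noise — and logged.  The
threshold 0.7 and the min-pairwise-correlation statistic are this package's
reconstruction of "similar profiles in all conditions"; they are prominent
configuration items, and the resulting modulon size depends on them.

Clustering: genes are represented by their condition-averaged fitted profile
(the similarity filter has already enforced a shared shape across
conditions, so averaging suppresses per-condition estimation noise without
discarding signal; a concatenated per-condition mode exists), distance
1 − Pearson, Ward linkage, tree cut at k = 4.  Ward rather than complete
linkage is deliberate: the two rising canonical shapes (steady rise vs late
rise) correlate at r ≈ 0.88, and complete/average linkage provably merge
them while splitting another cluster — on planted data this cost ~0.25 of
adjusted Rand index.  k = 4 because further splits do not yield materially
different shapes.  Cluster labels are not dendrogram-order artifacts: for
k = 4 the cluster means are matched one-to-one (Hungarian assignment on
correlations) to the four canonical templates, so label 1 is always the
steady riser and label 4 the steady faller; for other k, labels order by
mean profile slope.

## Regulon and gene-set enrichment

For a universe of N genes (all genes retained in the count matrix after the
all-zero filter — the universe is a reported choice, since p-values depend
on it), a set with K members in the universe and a modulon of n genes, an
observed overlap k is scored by the upper-tail hypergeometric probability
P(X ≥ k), BH-adjusted across all tested sets.  Regulators need ≥ 2 targets
in the universe to be tested (configurable).  Only over-representation is
tested.  Each significant regulon's overlap is split by profile cluster
(the four-way breakdown that summarizes which expression shape a regulator
drives), and the significant regulator → modulon-target subnetwork is
written as a SIF edge list plus node attributes.  Generic gene-set
collections (GMT) run through the same machinery, conventionally at
α = 0.025.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study layout: conditions phosphate, nitrogen,
carbon; rate grid {0, 0.1, 0.2, 0.3, 0.4} h⁻¹; three biological replicates;
no μ = 0 sample for carbon (no observable lag after carbon limitation); and
two rejected replicates (C2-0.1, N3-0.2) — 15 + 14 + 11 = 40 samples.
Counts are gamma-Poisson (negative binomial): per-gene baseline abundances
are heavy-tailed log-normal (σ = 1.3), sample library sizes log-uniform, and
a planted modulon multiplies the baseline by 2^Δ where Δ follows one of four
canonical shape templates (anchored at 0 at the reference rate).
Condition-private DEGs carry a random shape, in a random one or two
conditions, flat elsewhere — they must survive per-condition DE but fail the
intersection.  Planted enriched regulons draw ≥ 60% of their targets from
the modulon; all other regulons sample targets uniformly.

Default conditions (all in `SimulationConfig`): 3,000 genes, modulon 400
split evenly over the four shapes, amplitude 1.5 log₂ (within the 1–2 log₂
span characteristic of the steadily rising cluster), 150 condition-private
DEGs, NB dispersion φ = 0.02, library sizes 5×10⁶–2×10⁷, 50 regulons of
10–40 targets with 5 planted.  The depth and dispersion defaults were set
by a power analysis of the weakest arm of the design: the carbon condition
sees only an effective 1.125 log₂ span for the monotone shapes on four rate
points, giving a noncentrality of ≈ 0.93/φ; recovery of ≥ 90% of planted
genes in *all three* conditions simultaneously requires φ ≲ 0.03 and enough
depth that shot noise does not dominate (≳ 10⁶ counts/sample).  φ = 0.02
(replicate CV ≈ 14%) is typical of triplicate bioreactor cultivations of an
isogenic strain, and the library range matches rRNA-depleted bacterial
RNA-Seq on a modern instrument.

What the generator does **not** model: operon structure and co-regulation
(genes are independent given their template), batch effects, gene-specific
dispersion variation, GC/length bias, compositional effects beyond the
planted fold changes, and read-level artifacts.  Passing recovery tests
therefore shows the pipeline is correct and well calibrated under its own
assumptions — not that real libraries of arbitrary depth or replicate
quality would yield the same sensitivity.  On real data the per-gene
dispersion mode and the R² filter are the knobs to reach for when the
pooled-dispersion assumption is doubtful.

Growth curves are simulated as dead biomass (constant) plus viable biomass
growing under a piecewise-linear μ(t): zero through the lag, linear ramp to
μ_max over ~6 h, then constant.  The sampling grid includes the ramp knots,
making the trapezoid integral of μ(t) exact between samples, so noiseless
curves round-trip through the kinetics module to machine precision (the
interval log-ratio equals the midpoint rate when μ(t) is linear on the
interval).

## Tested guarantees

The suite pins, among others: the hypergeometric tail against full draw
enumeration (exact rational arithmetic) for every valid configuration with
N ≤ 12; BH step-up against hand-computed vectors plus its order-statistic
monotonicity (BH is *not* idempotent — re-adjustment can only inflate — and
is tested accordingly); the RLE median-of-ratios fixed point; the Poisson
deviance term-by-term on toys; GLM coefficients and deviances against an
independent reference implementation on fixed datasets; planted-modulon
recovery (sensitivity, precision, cluster agreement, planted-regulator
flags) at the default design; the rate-dominated sample-clustering
structure; and empirical false-discovery proportions ≤ 0.075 under null
generators for both the DEG and the regulon tests (200 Monte-Carlo repeats
each).  Monte-Carlo problem sizes (300–1,200 genes per null repeat, one
full-design recovery run) were chosen to keep the whole suite under a
minute while leaving the estimates' standard errors well inside the margins
being asserted.

## Known limitations

- The similarity threshold (0.7) and the profile statistic are
  reconstructions; modulon size is sensitive to them.
- The pooled dispersion assumes exchangeable gene-level noise; strongly
  heteroskedastic data should use `dispersion="per-gene"` and accept the
  power cost.
- The enrichment universe (count-matrix genes) is one of several defensible
  choices and changes p-values; it is recorded in the output metadata.
- Cubic profiles cannot represent more than one interior extremum; faster
  transients between grid rates are invisible by design.
- No batch correction: the pipeline assumes replicates are exchangeable
  within (condition, rate).
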