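# Methods

`atrasens` implements a quantitative pipeline for studying sensitivity of
breast cancer models to all-trans retinoic acid (ATRA), a cytostatic —
rather than cytotoxic — retinoid. This note documents the models and
procedures each stage implements, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the design was genuinely open.

## The ATRA sensitivity score

ATRA slows growth; it rarely kills. Classical IC50 summaries of
dose–response are therefore ill-suited: with little cell death the
viability curve may never cross 50%, and its midpoint confounds potency
with assay duration. The score used here is instead built from growth
*rates*.

For one cell line assayed at concentrations c (μM; 0 = vehicle/DMSO) and
days t, with replicate-mean optical densities OD_c(t):

1. **Growth-rate inhibition per dose.** Between two assay days
   t₁ < t₂ (default 3 and 6, matching the slow kinetics of the retinoid
   response),

       I_c = clip( 1 − log₂(OD_c(t₂)/OD_c(t₁)) / log₂(OD₀(t₂)/OD₀(t₁)), 0, 1 ).

   I_c = 0 is growth indistinguishable from vehicle; I_c = 1 is complete
   cytostasis. Clipping below 0 discards apparent growth stimulation;
   clipping above 1 treats net regression as complete inhibition — both
   keep the index in a bounded, comparable range for a drug that is
   predominantly growth-inhibitory. Replicates are averaged *before*
   ratios are formed, mirroring how mean ± SD growth curves are plotted.

2. **Dose integration.** The scalar score is the trapezoidal mean of I_c
   over log₁₀ concentration across the tested nonzero doses:

       score = (∫ I d log₁₀c) / (log₁₀ c_max − log₁₀ c_min) ∈ [0, 1].

   Higher = more sensitive. The score is invariant to rescaling all ODs
   (absorbance units cancel), invariant to replicate count at equal
   means, and monotone nondecreasing in any pointwise increase of the
   inhibition profile. With a single nonzero dose the score degrades to
   that dose's I_c with a logged warning.

**Doubling time** is estimated as 1/slope of the least-squares fit of
log₂(mean OD) against day at the chosen concentration; a slope ≤ 0 (within
1e-12, the round-off floor of the fit) raises a non-growth error rather
than returning a negative or infinite doubling time.

**Stratification.** Cell lines are split into four sensitivity groups
A–D (A = most sensitive) by the *optimal one-dimensional contiguous
partition* of the sorted scores minimising within-group sum of squares,
computed by dynamic programming and verified against exhaustive
enumeration in the tests. This is deterministic, unlike seeded k-means,
so repeated runs agree exactly. Tertiles T1–T3 (T1 = most sensitive) are
rank-based equal thirds; when the cohort size is not divisible by 3 the
extra members go to the extreme tertiles first (T1, then T3), and ties
keep stable input order. A 42-line screen yields 14/14/14.

## Association statistics

Two-group comparisons default to Student's pooled-variance t-test
(two-sided); Welch's form is available by flag. A summary-only variant
computes the Welch statistic from published (n, mean, SE) rows —
t = (m₁−m₂)/√(se₁²+se₂²) with Satterthwaite degrees of freedom — so
significance calls can be reproduced from printed tables when raw values
are unavailable. Co-regulation and protein–mRNA analyses use Pearson
correlation with the t-transform p-value; zero-variance members are
flagged `undefined` rather than propagating NaN. Stratified analyses
(e.g. T1 vs T3 within Luminal lines) are annotation filters composed with
the same comparison, and filter-then-test equals test-on-prefiltered by
construction. Raw p-values are reported by default, as is conventional
for these small-panel comparisons; Benjamini–Hochberg adjustment is
available (`atrasens.stats.bh_adjust`).

## Signature discovery

Genes are ranked by a Random Forest *regression* of the continuous score
on basal expression — not a sensitive/resistant classification — so all
lines inform the ranking. Defaults: 1,000 trees, mtry = ⌈p/3⌉ (the
regression-forest convention), minimum leaf 5, recorded in `model_meta`
together with the seed and out-of-bag R². In the p ≫ n regime of
expression panels (thousands of genes, tens of lines) impurity-based
importance is biased toward high-cardinality features, so importance is
**out-of-bag permutation importance**: for each tree, the increase in
mean squared error on that tree's out-of-bag samples when each feature
the tree actually uses is permuted, averaged over trees. The forest is
built as explicit bootstrap-aggregated decision trees so the out-of-bag
bookkeeping is exact and the whole ranking is a pure function of the
seed; samples are canonicalised by id so column order is irrelevant.

The top-k genes (default k = 100) are split by the **sign of their
Pearson correlation with the score** into "up in sensitive" and "down in
sensitive" sets — using the continuous score rather than a T1-vs-T3 mean
difference keeps every sample informative. Cross-platform
reproducibility of two top-k lists is quantified by the upper-tail
hypergeometric probability of the observed overlap. Separation of
sensitive (T1) from resistant (T3) lines by a gene set is measured by
z-scoring each gene across samples, average-linkage agglomerative
clustering under 1 − Pearson correlation distance, cutting at two
clusters, and reporting the best cluster-to-label matching accuracy
(purity) over the labelled samples.

## Single-sample enrichment (ssGSEA)

For one profile of N genes with m set genes present, genes are sorted by
value descending (ties broken lexicographically by gene id, making the
score platform-independent) and given the rank statistic
r_i = N − position + 1. Walking the sorted list, in-set genes increment a
cumulative sum by r_i^α / Σ_set r^α and out-of-set genes increment a
second sum by 1/(N − m); the enrichment score is Σ over positions of
(cum_in − cum_out). α defaults to 0.25, the canonical ssGSEA exponent;
α = 0 reduces to the unweighted Kolmogorov–Smirnov-style running sum.
The score is rank-based, hence exactly invariant under monotone
transforms of the values. A set covering the entire profile makes the
out-of-set increment degenerate; it is defined as 0 with a warning. No
cross-set normalisation is applied: scores are compared across samples
of one cohort against one set, as in the Luminal-vs-TN tumor validation.

## Tissue-slice analysis

**Ki67.** Per-field percentages 100·positive/total are summarised as
mean ± SE per condition (≥ 5 fields required). The sensitivity call uses
a one-sided Welch two-sample t-test for a *decrease* under ATRA at
p < 0.05, gated on the ATRA mean actually being lower. Welch rather than
pooled: field-to-field variance need not match between conditions, and at
five fields per arm the pooled test is slightly anticonservative (its
empirical size exceeds the nominal 5%, while the Welch form's is ~4.6%
under the binomial field model). Fields are treated as unpaired — slide
fields have no natural pairing across conditions.

**Paired differential expression.** Per gene, a paired t-test on
log₂(ATRA) − log₂(vehicle) across patients (≥ 3 required); genes with
zero paired-difference variance are skipped with a logged count. Genes
below the threshold (default raw p < 0.005) are partitioned by the sign
of the mean log₂ ratio. The Venn partition between Luminal/ER⁺ and TN
subtypes is exact set algebra with one safeguard: a gene up in one
subtype and down in the other goes to a *discordant* bucket and never to
a common bucket, keeping all buckets pairwise disjoint.

**Curated target subset.** Stage 1 restricts the paired test to a
curated target list at a stringent threshold (default p < 0.001) per
subtype. Stage 2 asks which stage-1 genes respond *differently* between
subtypes: a Welch two-sample test on the per-patient log₂ ratios,
flagged at p < 0.05. The between-subtype rule is a declared design
choice — ratio distributions are compared directly, which uses each
patient once and inherits no within-subtype significance assumptions.

## Synthetic data: what it emulates and what it does not

The generators produce inputs with exactly the statistical structure the
stages assume, so every pipeline property is testable without external
data. All generators are pure functions of their seed.

* **Growth assays.** OD(c,t) = od0 · 2^{t(1−I(c))/td} with Hill
  inhibition I(c) = imax·c^h/(ec50^h + c^h) and multiplicative
  lognormal noise exp(N(0, cv)) per reading — absorbance noise scales
  with signal and stays positive. The default grid is vehicle plus five
  log-spaced doses 0.001–10 μM read at days 3/6/9 with three replicates,
  a standard sulforhodamine screen layout. In the noiseless limit the
  inhibition profile recovers I(c) to 1e-12, which anchors the
  closed-form score checks (Hill imax 0.8, ec50 0.1 μM, h 1 on the
  default grid gives score 0.400 exactly, by a coincidence of the
  trapezoid on that symmetric grid).
* **Expression cohorts.** Scores ~ Uniform(0,1); each of
  `n_informative` genes is beta·score + N(0, σ), the rest pure
  N(0, σ) noise. Defaults 40 lines × 2,000 genes with 20 informative
  genes at beta = 1, σ = 0.385, giving gene–score correlation ≈ 0.6 — a
  moderate effect a ranking method should recover without being
  trivial. Lineage labels follow a score threshold (0.5), mimicking the
  enrichment of Basal lines among resistant lines. `remeasure_cohort`
  adds fresh measurement noise to the same cohort, emulating a second
  platform.
* **Slice cohorts.** Default 11 Luminal/ER⁺ + 5 TN patients. ATRA
  expression = vehicle + planted subtype-specific log₂ shift + N(0, σ);
  Ki67 counts ~ Binomial(cells_per_field, p) with p reduced by a
  per-subtype fractional drop under ATRA (defaults: 5 fields × 200
  cells, vehicle positivity 0.5).

Not emulated: platform-specific array artifacts, batch effects,
sequencing count noise, gene–gene correlation structure, stromal
contamination of slices, and non-linear score–expression links. Passing
tests therefore demonstrate that each algorithm behaves correctly under
its stated model — calibrated error rates, recovery of planted signal,
agreement with closed forms — not that real cohorts satisfy that model.

## Numerical choices and degenerate inputs

* Exact-identity checks (noiseless limits, ssGSEA oracle equality) are
  asserted at 1e-12; analytic calibration at 1e-9.
* Text round-trips write floats with `%.17g` and parse with round-trip
  precision, so write∘parse is the identity on matrices.
* All ranking ties (importance, ssGSEA ordering) break lexicographically
  by gene id; tertile ties keep input order — every output is
  deterministic and platform-independent.
* Zero-variance inputs are handled explicitly everywhere: dropped with a
  warning (forest), flagged undefined (correlation), skipped with a
  count (paired DE), or given the analytic limit (t = 0, p = 1 for
  identical groups; a zero-SE unequal-mean summary comparison reports
  p = 0 with a `zero-variance-limit` flag).
* Problem sizes used by the verification script: 100-seed doubling-time
  recovery, 200 partition instances, 1,000 ssGSEA trials, 10-seed
  forest recovery at the default cohort size, a 10,000-gene null slice
  cohort, 100-seed paired-DE power, 500/5,000-seed Ki67 power/null
  rates — sizes at which every Monte-Carlo estimate has comfortably
  sub-point precision while the full run stays in the minutes range.

## Known limitations

* The score formula is one member of a family (choice of day window,
  clipping, dose weighting); the package exposes the interval as a
  parameter but commits to trapezoidal log-dose averaging.
* Forest importance at n = 40 has high seed-to-seed variance for genes
  near the decision boundary of the top-k cut; `model_meta` records the
  seed, and cross-platform overlap statistics are the recommended
  stability check.
* Raw-p thresholds (0.05/0.005/0.001) control per-test error, not FDR;
  the BH helper exists but is off by default to match the reporting
  convention of small-cohort slice studies.
* Annotation matching is exact and case-sensitive; no gene-symbol
  aliasing or identifier conversion is attempted.
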