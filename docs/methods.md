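# Methods

`lumisig` re-implements, as a reusable and tested pipeline, the
computational chain used to link a transcription factor's expression to
the luminal breast-cancer phenotype: two-channel array normalization and
filtering, a two-class SAM differential-expression engine that yields
weighted gene signatures, inner-product projection of those signatures
onto tumor and mammary-lineage expression profiles, node-correlation
gene-module extraction from a correlation dendrogram, signature-overlap
decomposition, and expression-stratified survival association. This note
records the models, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Two-channel preprocessing

Expression matrices are genes x samples on the log2 scale; missing
values are `NaN` and the presence mask is derived from them. Matrices are
written at full float precision and read back with round-trip float
parsing, so write→read is bit-exact — derived report tables use 6
significant digits instead.

**Lowess normalization.** For each spot, M = log2(Cy5/Cy3) and
A = ½·log2(Cy5·Cy3). A locally weighted linear regression of M on A
(tricube weights) is fit with `statsmodels`' lowess and subtracted:
M′ = M − fit(A). Defaults: span 0.4, 3 robustness iterations — a common
two-channel default; both are configurable. The fit is local-*linear*,
so a strongly curved bias (e.g. a sinusoid) is attenuated near its
extrema at wide spans; the tests that plant a 0.5·sin(A) bias therefore
use a small span (0.08) over many spots (20,000), which keeps the binned
residual bias under 0.05 while still averaging out the biological spread
of M. Normalization is invariant to multiplying both channels by the
same constant (A shifts; M and the fitted trend are unchanged).

**Gene filtering.** A gene is kept when at least 70% of its samples are
"good". By default a sample is good when the value is present *and* both
raw channels reach 10 intensity units — the presence and intensity
clauses are combined conjunctively per sample, which is the stricter and
(we judge) more natural reading; a flag evaluates the two clauses
independently. Filtering is idempotent and preserves row order. Duplicate
gene identifiers are collapsed to their per-sample median before
analysis, the deterministic standard for multi-probe 4×44K designs.
Missing values are never imputed; every downstream statistic uses the
available values. Filtering defaults to running on the normalized data;
the order can be swapped by the caller since both operations are exposed
separately.

## Two-class unpaired SAM

For gene *i* with class means x̄₁ᵢ, x̄₂ᵢ, the relative difference is

    dᵢ = (x̄₂ᵢ − x̄₁ᵢ) / (sᵢ + s₀)

with gene scatter

    sᵢ = sqrt[ (1/n₁ + 1/n₂) · (Σ₁(x−x̄₁)² + Σ₂(x−x̄₂)²) / (n₁+n₂−2) ],

i.e. the pooled-SD scale of the classical t statistic; with s₀ = 0, dᵢ
*is* the pooled t statistic, which the tests assert to 1e-10. Classes
are ordered lexicographically by label so that exchanging the label
names negates every d.

**Fudge factor s₀.** Candidates are the percentiles {0, 5, …, 100} of
the sᵢ distribution. For each candidate, d is recomputed and its scale
(normal-consistent MAD) is measured within 100 s-quantile windows; the
candidate minimizing the coefficient of variation of these window scales
is chosen, ties breaking to the lowest percentile. When all sᵢ are equal
any candidate is equivalent and that common value is returned.

**Permutation null.** When the number of distinct two-class label
assignments C(n, n₁) is at most 10,000 they are all enumerated exactly
once, making the null seed-independent (the emulated 5-vs-6 design has
C(11,5) = 462, so it always enumerates); otherwise the requested number
of assignments is drawn with replacement from a seeded generator — this
deliberately permits more draws than there are distinct assignments,
since the draws are independent samples of the null rather than a
without-replacement sweep. The expected order statistics d̄ᵢ are the
means of the i-th ascending order statistic across permutations.
Convergence of the sampled d̄ to the enumerated d̄ is checked with the
statistic regularized at s₀ = median(s): that is how a SAM run actually
operates, and an unregularized d on a small two-class design is so
heavy-tailed that its extreme order statistics dominate the Monte-Carlo
error of the comparison.

**Calling and FDR.** At band half-width delta, the upper cutpoint is the
smallest observed d (genes sorted by d, ties broken by gene index) whose
displacement d − d̄ is at least delta; all genes at or above it are
called up, and symmetrically for down. For each delta the median count
across permutations of permuted statistics beyond the cutpoints, divided
by the number called, is the FDR (clipped to [0,1] for reporting). No
π₀ correction is applied by default — the plain median-false-positive
definition — but a `pi0` multiplier is available. The delta grid is the
set of observed displacements (quantile-thinned to ≤ 200 values), so
`n_called` steps exactly where the data step and is non-increasing in
delta.

**Signatures.** At a requested FDR threshold (1% for discovery, 5% for
the projection signatures), the smallest delta whose estimated FDR falls
below the threshold defines the called set; the signature maps each
called gene to its observed d as weight, partitioned into positive and
negative sets by sign. Genes with fewer than two present values in
either class are excluded before analysis (the 70% presence filter does
not guarantee per-class coverage) and recorded.

## Signature-activity projection

The activity of signature w in sample x is the inner product
Σᵢ wᵢ·xᵢ over the signature genes found in the profiled matrix
(exact identifier match after upper-casing; unmatched genes are dropped
and reported — no fuzzy symbol mapping). By default each projected
dataset is gene-median-centered first, which makes the score a contrast
and keeps two-channel log-ratio datasets comparable; the raw inner
product is available with `center=False`. Scores are *relative*: they
are comparable within one projected dataset only, and no per-gene-count
normalization is applied by default (a mean mode exists for
unequal-coverage comparisons). Missing values contribute 0 after
centering. Group comparisons use one-way ANOVA; for two groups F equals
the squared pooled t exactly.

## Node-correlation gene modules

Genes (rows, median-centered) are clustered by average-linkage
agglomeration on centered Pearson similarity (distance 1 − r). The
"node correlation" of an internal dendrogram node is the similarity at
which its branches merge. Average linkage guarantees merge similarities
are non-increasing toward the root, which makes a threshold cut
well-defined; centroid linkage is available behind a flag, with the
ascent truncated at the first inversion. A module around a seed gene is
obtained by ascending from the seed leaf while node correlations stay at
or above the threshold (0.65 by convention for the ESR1/luminal
cluster) and returning the leaves of the highest accepted ancestor — the
seed alone if even its first merge falls short. Raising the threshold
can only shrink the module, and the module always contains the seed.
Constant genes (undefined correlation) are excluded with a warning.
Trees serialize to Newick with node correlations as internal labels.

The overlap decomposition assigns each module gene to exactly one
exclusive category — the single signature containing it, "multiple" when
two or more do, or "none" — so counts partition the module exactly and
percentages sum to 100.

## Survival and group statistics

Expression values are rank-ordered high-to-low and split into halves;
the high group takes the extra member when n is odd, and ties break by
stable input order. Kaplan–Meier curves come from `lifelines`. The
association between the halves and overall survival uses the standard
two-group log-rank test (observed-minus-expected events with
hypergeometric variance; the statistic is chi-square with 1 df). The
log-rank statistic is computed in-house with a vectorized routine so
that 10,000-replicate calibrations run in seconds, and is verified
against `lifelines.statistics.logrank_test` in the test suite; a naive
2×2 death-count chi-square is provided as a sensitivity check. Subtype
association uses a two-sided t-test (2 groups, Welch optional) or
one-way ANOVA; response tables use the Pearson chi-square without
continuity correction (1 df). Doubling time is 1/slope of the OLS
regression of log2(count) on time, with a non-positive slope flagged as
non-growing.

## Synthetic data: what it emulates, and what it does not

All generators take an explicit seed and are reproducible; each emits
its ground truth (planted DE genes with signed shifts, planted activity
ordering, pre-bias log-ratios) so recovery is testable.

- **Knockdown experiment** — 1,000 genes, 5 vs 6 arrays, 10% planted DE
  at a log2 effect of 2.0 with per-gene noise SD 0.5 by default,
  mirroring the emulated 11-array knockdown design. Planted shifts
  alternate in sign so signatures exercise both the positive and
  negative sets; a flag makes them all positive. Heteroscedastic noise
  (per-gene variance from a scaled inverse-chi-square draw clipped to a
  stated range) is available because s₀ only matters under unequal
  variances; the homoscedastic default keeps the t-limit tests exact.
  Missing values are injected completely at random.
- **Tumor cohort** — five subtypes (LumA, LumB, HER2, Basal,
  Claudin-low), subtype-shifted signature genes, and a marker gene whose
  centered expression enters an exponential survival model:
  hazard = λ₀·exp(β·x). With `dichotomize_hazard` the covariate is the
  above/below-median indicator so exp(β) is exactly the hazard ratio
  between the split halves, which is the natural parameterization for
  power studies. Censoring is an independent exponential clock
  calibrated so a baseline-hazard subject is censored with the requested
  probability.
- **Lineage panel** — four sorted populations (MaSC, LP, ML, St), six
  samples each, expressing a supplied signature at planted levels
  (default ordering ML > LP > MaSC > St, i.e. a mature-luminal-like
  signature) by shifting each signature gene by level·sign(weight).
- **Two-channel spots** — A uniform on (6, 14), true M normal with SD
  0.5, an arbitrary intensity-dependent bias function of A, and
  technical noise; channel intensities are reconstructed from (A, M).

None of the generators model probe-level noise structure, batch
effects, correlated gene-gene backgrounds beyond the planted blocks, or
copy-number structure. Passing the recovery tests therefore shows the
*algorithms* behave as specified under controlled truth — not that real
arrays meet these assumptions.

## Problem sizes and numerical choices

The calibration studies use 20 replicate simulations for FDR/recall,
module and activity recovery, 10,000 null cohorts (n = 200) for log-rank
size and 1,000 for power — sizes at which the Monte-Carlo error is well
inside the asserted bands. FDR calibration on the 5-vs-6 design always
enumerates its 462 label assignments, so those results are
seed-independent given the data. Ties everywhere break by stable order
(gene index, sample order); degenerate inputs (constant genes, all-tied
splits, zero-variance classes) are either handled by a documented
convention or rejected with a specific error, as listed per function.

## Known limitations

- The exact published probe counts for the original knockdown series
  (2,088 called genes; 892 positive / 1,196 negative; 2.5-fold marker
  decrease) depend on probe-collapsing order and s₀ details that the
  original description leaves open; `reproduce_gse21371` therefore
  reports its counts side by side with those reference values rather
  than asserting equality, and requires the user to supply the GEO
  series files (no network access is assumed anywhere else).
- The 79-gene ESR1 module and the 24%/10%/4%/6% overlap shares were
  derived on external tumor cohorts not bundled here; the module and
  overlap machinery is instead validated on planted-block synthetic
  data.
- Only the two-class unpaired SAM variant is implemented (no paired,
  multi-class or survival modes, no KNN imputation), and survival
  analysis is limited to the two-group log-rank setting (no Cox
  regression or competing risks).
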