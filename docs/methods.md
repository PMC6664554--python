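# Methods

## Data model

NPX (normalized protein expression) values are log2-scale relative
abundances: a difference of 1 NPX is a two-fold concentration difference,
and values are comparable across samples within a panel but carry no
absolute unit. Each protein has a limit of detection (LOD) on the same
scale. Measurements below LOD are **retained as reported and flagged**,
never imputed or dropped; every downstream statistic uses the reported
value. This matches how such panels are analyzed in practice (LOD is a QC
annotation, not a censoring rule) and keeps ranks — the basis of every test
here — well defined. Callers who want to exclude flagged values can do so
via the `below_lod` mask before analysis.

QC percentages (proteins fully detected, samples fully above LOD) are
rounded to the nearest integer with halves away from zero, the convention
of clinical tables (87/92 = 94.6% reports as 95%).

## Differential abundance

Groups are independent patients, so "Wilcoxon test" is implemented as the
two-sample rank-sum (Mann–Whitney) test, two-sided. The implementation
delegates to `scipy.stats.mannwhitneyu`: exact enumeration of the null when
the pooled sample is ≤ 12 and tie-free (only relevant for test oracles),
otherwise the midrank normal approximation with tie-corrected variance and
continuity correction. Multiple testing is controlled per pairwise
comparison across its 92 proteins with Benjamini–Hochberg step-up
(`statsmodels`), significance at adjusted *p* < 0.05. BH is applied per
comparison, not jointly across comparisons, mirroring per-comparison
p-value columns in panel reports. Covariates (age, sex, smoking) are
recorded but never modeled; the emulated analysis does not adjust for them.

## Single-marker classifiers

The cut-off for a "high vs low" single-protein rule is the median of the
pooled values of the two groups being compared (not of the whole cohort):
the per-comparison framing of the benchmark tables implies a two-group
pool. Samples exactly at the cut-off are classed "low" (strict `>`); the
rule direction defaults to the side on which the positive class has the
higher median and can be forced. Ratios with empty denominators are
reported as NaN, never 0. Reported metrics are rounded to 2 decimals,
halves away from zero.

ROC curves sweep all distinct thresholds; AUC is the trapezoid area, which
equals the concordant-pair (Mann–Whitney) probability with half credit for
ties. The multi-marker combination is a Fisher linear discriminant
`w ∝ S_w⁻¹(μ₊ − μ₋)` — the simplest standard linear combiner, consistent
with the linear-discriminant analysis mentioned alongside the emulated
study's learner comparison; a singular pooled covariance falls back to its
diagonal with a warning.

## Weighted bagged-tree classifier

Trees are plain CART: greedy binary splits maximizing the Gini decrease,
with `⌊√p⌋` candidate proteins drawn without replacement per node
(random-forest style) and all midpoints between sorted distinct values
evaluated. Growth stops at pure nodes, nodes below `2·min_leaf` samples, or
zero-gain splits. `min_leaf = 3` by default so no cut-off rests on a single
patient in ~343-sample cohorts. The recorded `impurity_decrease` of a split
is weighted by the fraction of the tree's training samples reaching the
node, so root-level splits outrank deep ones of equal local gain.

Each of `n_trees` (default 5000) trees is grown on an n-sample bootstrap
resample and scored on its own out-of-bag samples. The source procedure
states that trees were "weighted" to minimize OOB error without giving the
formula; this package adopts the simplest OOB-consistent choice,
`w_t = max(0, 1 − OOB error_t)`, documented as the key interpretive
decision (uniform weighting is available by flag). The `k` highest-weighted
trees (default 2500 — half) are selected, ties broken by lower OOB error
then lower index. Prediction is the weight-normalized fraction of selected
trees voting positive; a sample is called positive iff that score strictly
exceeds 0.5, so exact ties resolve to the negative (benign) class — a
deliberate, configurable convention. Train/validation splits are seeded
random 80/20, stratified by class to ±1 sample.

Tests and the bundled pipeline use 300–500 trees; experiments showed no
qualitative difference from larger forests, and the defaults remain
available for full runs.

## Three-protein signatures

From each selected tree the internal nodes are ranked by impurity decrease
(ties: larger node, then shallower), and the top three *distinct* proteins
are extracted with their thresholds; a protein splitting twice contributes
its higher-ranked threshold. Across the forest, proteins are ranked by
extraction frequency (ties by mean impurity decrease); the top three form
the signature. The consensus cut-off is the **median** of a protein's
extracted thresholds — robust to outlier splits — and the rule direction is
"above" where the positive class's median NPX exceeds the other class's,
per protein (real analyses of this design use both above- and below-rules).
The three rules combine conjunctively with strict inequalities. An optional
refinement grid-searches each cut-off over observed-value midpoints to
maximize training accuracy subject to perfect specificity, mirroring
published cut-offs "chosen to best separate" benign from cancer. The
training count of a tree's largest pure positive leaf is kept as provenance
("size of the best predicted group") but drives no decision.

## Hierarchical clustering

Sample clustering uses correlation distance with average linkage after
per-protein z-scoring — common expression-heatmap defaults, since the
emulated analysis names none — all configurable (Euclidean/complete).
Zero-variance proteins are dropped with a warning (the correlation distance
is undefined on them). Agreement with clinical labels is summarized as the
adjusted Rand index of the 2-cluster cut; it is reported, not asserted
high: on realistically weak effects, unsupervised clustering does *not*
separate LAC from benign, which is part of the motivation for the
supervised classifier.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not assay
chemistry: independent Gaussian noise per protein on the log2 NPX scale
(symmetric on that scale; inter-protein correlation is out of scope),
additive group effects, 144/68/83/48 group sizes, LAC stages drawn
multinomially from the emulated cohort's stage distribution, a 37/68
inflammatory fraction among benign samples, and per-protein LODs placed at
the 0.005 quantile of five censored proteins' simulated values (guaranteeing
each has ≥1 flagged sample, hence 87/92 = 95% fully detected). All draws
come from one seeded `numpy` Generator in a fixed order, so identical
configs are bit-identical.

Default marker effects are ±0.9 NPX at unit SD for the four LAC markers
(CXCL17 ↑, CEACAM5 ↑, VEGFR2 ↓, ERBB3 ↓) and +0.9 for WFDC2/MSLN in CRC
metastases. The 0.9 figure was calibrated analytically: the pooled-median
cut-off classifier of a 144-vs-68 normal mixture then lands near the
benchmark single-marker sensitivity/specificity (≈0.61/0.73 vs 0.60/0.66),
while the per-marker power of the FDR-adjusted rank-sum test stays near 1,
matching both published anchors at once. Because the generator draws
independent Gaussians, passing recovery tests demonstrate correctness of
the machinery under the assumed model — they do not certify performance on
real plasma data, where effects are skewed, correlated and
batch-structured.

## Numerical conventions and edge cases

- Rounding: halves away from zero everywhere a table value is printed.
- Undefined diagnostic ratios: NaN with a warning, never silently 0.
- Degenerate single-marker input (all values equal): error, since the
  median cut-off cannot dichotomize.
- Tree weight sums of zero (every selected tree at weight 0): votes fall
  back to uniform weights rather than dividing by zero.
- Splits: samples equal to a threshold go left ("low"); thresholds are
  midpoints of adjacent distinct values.
- Reproducibility: every CLI entry point and `run_pipeline` derive all
  randomness from one top-level seed via `SeedSequence` substreams;
  re-running an identical config reproduces outputs byte-exactly.

## Known limitations

- Binary classification only; all emulated analyses compare one (possibly
  pooled) tumor group against benign controls.
- The OOB weighting formula and the 0.5 vote threshold are interpretive
  choices where the source procedure is underspecified; both are flagged
  and configurable.
- The generator's independence assumption understates the difficulty of
  real cohorts; validated performance numbers on synthetic data are
  analogues, not predictions, of clinical performance.
- No batch/plate correction and no Cq→NPX normalization: inputs are assumed
  already normalized NPX.
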