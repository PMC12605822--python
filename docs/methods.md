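# Methods

This note documents the models behind `abnormap`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not establish.

## Harmonization (ComBat)

Scanner/protocol effects are removed with the classic *parametric*
empirical-Bayes location/scale model.  Features are standardized per
region against a least-squares fit of batch indicators plus covariates
(age, sex), using the batch-size-weighted intercept as the grand mean and
the pooled residual variance (ML, divisor n).  Within each batch,
per-region location (`γ̂`) and scale (`δ̂²`, ML variance) estimates are
shrunk toward method-of-moments hyperpriors estimated across regions
(normal for locations, inverse-gamma for scales), by iterated conditional
estimation to a max-change tolerance of 1e-6 (cap 100 iterations).

Choices worth knowing:

* **ML (divisor n) batch variances** rather than n−1: this makes a
  single-batch fit an exact identity (γ̂ ≡ 0, δ̂² ≡ 1), which is the
  correct degenerate behaviour when there is nothing to harmonize.
* **Degenerate hyperpriors**: when the per-region estimates have no
  spread across regions (single region, or exact ties), EB shrinkage is
  undefined and the unshrunk estimates are used.
* **Zero-variance regions** are flagged (QC warning) and passed through
  unadjusted instead of failing the run.
* **Fit population**: by default the batch model is fitted on controls
  only and applied to patients, so patient pathology cannot be absorbed
  as a site effect; a pooled mode exists.
* **Covariate handling**: the transform either restores covariate
  contributions (standard ComBat, default) or returns covariate-adjusted
  values (intercept + harmonized residual).  The pipeline uses the
  adjusted form for both controls and patients, folding the age/sex
  adjustment into this stage, so normative maps are covariate-adjusted.
  When validating batch-effect removal, residual between-site differences
  must be measured on the adjusted form — a chance age imbalance between
  sites re-enters legitimately through the restored covariate term.

What EB harmonization does *not* do: per-region batch differences are
only removed up to shrinkage bias plus sampling noise; at n = 200/site
the per-region residual standardized mean difference has ~0.07 SD spread
even when the method works perfectly.  Aggregate (across-region) residual
effects are the meaningful quantity and are what the tests bound.

## Normative maps and z-scores

Per-region control mean and unbiased (n−1) SD on harmonized,
covariate-adjusted values; patients are z-scored against them.  Regions
with zero control SD are flagged and excluded downstream (NaN z).
Volumes are used raw (no intracranial-volume normalization).  Left/right
labels can be relabelled ipsi/contra to the seizure focus per patient;
the mapping is an involution, values are untouched, and midline regions
pass through.  Abnormality detection itself runs in anatomical space.

## Change-point thresholding of ranked z-scores

Per patient and modality, regional z-scores are ranked with the
expected-abnormal tail first: most negative first for GM volume (volume
loss is abnormal), most positive first for SWM MD (diffusivity increase
is abnormal).  Ties break by region ID, so the ranking is deterministic.
The abnormal set is the prefix of this ranking before a detected mean
shift.  Detection is exact model comparison — conjugate marginal
likelihoods, no sampling — between a no-change model and a two-segment
model at every admissible split k (`min_segment` = 3 ≤ k ≤ n −
`min_segment`), with prior mass 1/2 on no-change and the rest uniform
over splits.  Two evidence models are provided:

* **`mean_shift`** — the textbook two-segment Gaussian mean-shift with a
  shared unknown variance: segment means have N(0, σ²/τ) priors
  (τ = 0.01), σ² ~ InvGamma(0.01, 0.01).  Appropriate when the null is
  "no shift anywhere" (e.g. genuinely exchangeable sequences).  Its
  selected split is scale-invariant in practice (the weak b₀ prior is
  the only scale-bearing constant) and matches brute-force enumeration
  of the same marginal likelihood computed independently through the
  multivariate-t predictive density.
* **`ranked_null`** (pipeline default) — accounts for the input being a
  *sorted* sample.  A sorted null z-vector is not flat: it follows the
  order-statistic profile of a standard normal sample.  A pure mean-shift
  model applied to sorted values therefore always prefers a near-median
  split (two means fit an S-curve far better than one), which would call
  half the brain abnormal in a healthy subject.  Instead, the suffix
  under split k is pinned to the expected order-statistic profile of a
  null sample of size n−k (Blom scores with marginal-variance weights,
  independence approximation), while the prefix is a free Gaussian
  segment with the same NIG marginal likelihood as above.  The no-change
  model is the full-length null profile.  This mode is deliberately
  *not* scale-invariant: z-scores carry a fixed scale (control-SD units)
  and the model compares them against the unit-normal null.

A selected split must additionally pass a direction guard: the prefix
mean (in oriented units) must be negative and more extreme than the
suffix mean; otherwise k = 0.  Sequences shorter than 2·`min_segment`
return k = 0 with a flag.

**Operating characteristics** (measured in simulation, 128 regions):
with 5–6 regions injected at 2.5–3 SD, `ranked_null` recovers the
injected set with sensitivity ≈ 0.5 (2.5 SD) to 0.7 (3 SD) at per-region
false-positive rates of 0.015–0.03; sensitivity is monotone in effect
size; on pure-noise patients the mean false-call count is ≈ 1 region.
This sits near the Bayes-optimal 0–1-loss point for the implied
prevalence: with ~5 abnormal regions in 128 at 2.5 SD, the posterior
odds cross 1 near z ≈ −2.5, so a calibrated detector *should* be
conservative relative to a fixed z < −1.64 cut.  Detectors targeting
higher recall at matched false-positive rate would need an explicit
asymmetric loss and a wider model family (e.g. latent mixtures); the
change-point posterior over k is too concentrated for a selection-rule
change alone (posterior-median selection measures identical to MAP).

"Multiple" change points reduce to the first boundary here: the
threshold only needs the boundary between the extreme prefix and the
remainder, so a single split against a no-change alternative is the
whole decision problem.

## Volumetric utilities

SWM features: Euclidean distance (anisotropy-aware, physical spacing)
from each WM voxel to the nearest GM voxel; WM voxels within
`depth_mm` (default 5 mm, inclusive) are assigned to the label of that
nearest GM voxel, with exact ties going to the lower label ID.
Per-region SWM MD is the mean over assigned voxels; regions with no
assigned voxels are missing.  Resection overlap is exact voxel counting;
a region is called resected when its resected fraction is *strictly*
greater than the 10% threshold (a fraction of exactly 0.10 is not
resected).  Synthetic parcellations are axis-aligned GM blocks wrapped
in WM shells — overlap and depth logic are shape-agnostic, so nothing
downstream depends on anatomical realism.

## Multimodal combination and scoring

Union, concordant (intersection) and discordant (symmetric difference)
region sets per patient; per category, the score is the count-based
proportion of abnormal regions resected (regions are not weighted by
volume or abnormality magnitude).  A patient with an empty set in a
category has an *undefined* proportion there — excluded from that
category's group statistics, not treated as zero.  "Complete concordant
resection" means every concordant region passed the resection call;
undefined when no concordant regions exist.

## Outcome statistics

* AUC is computed through the Mann–Whitney statistic (AUC = U/n₁n₂,
  ties counted half), oriented so that more-resected-abnormality →
  good outcome gives AUC > 0.5.
* The one-sided two-group comparison is the rank-sum test (a
  Kruskal–Wallis statistic on two groups has no tail direction; the
  rank-sum form does): exact null for tie-free samples with
  n₁·n₂ ≤ 400, otherwise tie-corrected normal approximation with
  continuity correction.
* Logistic fits are Newton/IRLS maximum likelihood (tolerance 1e-8,
  cap 50 iterations), intercept always included; perfect separation is
  flagged rather than silently diverging.
* Likelihood-ratio comparisons report 2·Δll with chi-square reference on
  the parameter-count difference; comparisons of non-nested models (the
  single-predictor GM vs union case) are computed but flagged, and with
  zero parameter difference the p-value is NaN (or exactly 1 when the
  statistic is 0, i.e. a model compared with itself).
* Bootstrap CIs are percentile intervals under stratified resampling
  (within outcome groups, sizes preserved), deterministic given a seed.
* Contingency tables use Pearson chi-square with Yates continuity
  correction for 2×2.

## Synthetic cohort generator

The generator emulates a two-protocol TLE study: region means and noise
SDs drawn per region (GM volume ~5000–9000 mm³, SD 200–500 mm³; SWM MD
~7–9×10⁻⁴ mm²/s, SD 2–5×10⁻⁵), linear age effects (GM −8 mm³/yr, MD
+1×10⁻⁶/yr), a sex offset, additive per-site shifts with multiplicative
noise scaling (site 0 is reference), ages uniform 18–65, sex and site
Bernoulli(½).  Patients carry 6 injected regions per modality (half
shared between modalities), drawn with 70% probability from an
ipsilateral temporal-lobe-like block of 15 regions (the resection
candidate zone plus margin); injections shift GM down and SWM MD up by
3 noise-SDs.  The resected set is the ipsilateral 10-region temporal
block.  Outcome is Bernoulli(sigmoid(−1.2 + 6.0·p)) where p is the
proportion of injected (union) regions resected; these two constants
were set so the cohort matches the base rate (~73–77% good outcome) and
truth-level discrimination (union AUC ≈ 0.72–0.73) of the study design
the generator emulates.  Everything is deterministic given the seed.

What the generator does **not** emulate: anatomical geometry, spatial
correlation between neighbouring regions, heavy-tailed or skewed feature
distributions, site-by-region interactions beyond location/scale,
disease heterogeneity (HS vs non-HS), or measurement artifacts.  Passing
tests therefore demonstrate internal statistical correctness of the
pipeline under its own assumptions — not clinical performance on real
imaging data.

## Problem sizes and numerics

Tests and the acceptance script run at 128 regions (the coarse
114+14-style parcellation), 97 controls and 143–150 patients — the
study-scale cohort — with 100 cohort replicates for the end-to-end
discrimination check; these sizes keep the full suite in the
tens-of-seconds range while leaving Monte-Carlo error well below the
asserted margins.  Change-point evidence is computed with prefix sums
(O(n) per split scan) in the `mean_shift` mode and cached order-statistic
profiles in `ranked_null`.  Region-level degenerate inputs (zero
variance, empty categories, too-short sequences) degrade to flagged
missing values rather than errors wherever a single region would
otherwise abort a whole-cohort run.
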