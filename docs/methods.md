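# Methods

## Problem setting

A radiomic feature is *reproducible* across two scans of the same object
when its per-region values agree.  The package operationalizes this with a
phantom paradigm: one physical phantom, many scans under different
acquisition/reconstruction settings, a fixed grid of 160 cubic volumes of
interest (10 layers × 16 VOIs of 2 × 2 × 2 cm), and 91 handcrafted features
per VOI (18 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM —
the pinned "original image" registry).  Every unordered pair of scans is a
*scenario*; the scenario outcome is the percent of features whose
concordance across the pair exceeds 0.9.

## Pair encoding

Eight parameters describe a scan: vendor, model, tube current (mA),
exposure (mAs), exposure time (ms), slice thickness (mm), pixel spacing
(mm), convolution kernel.  A pair is encoded componentwise into [0, 1]:
vendor/model as exact-equality indicators; the five numeric parameters as
min/max ratios; the kernel as the min/max ratio of the two kernels' schema
ranks.  Design choices:

- **Kernel schema.** Kernels are ranked by limiting frequency (soft →
  sharp).  The packaged schema (`data/kernel_schema.csv`) covers common
  GE/Siemens/Philips/Toshiba kernels and is an editable stand-in ordered by
  published kernel characteristics, not a vendor table; site-specific
  kernels should be added by the user.  Cross-vendor kernels judged
  equivalent may share a rank (they then encode to 1.0 against each other).
- **Kernel pairing rule.** The per-kernel ranks are combined as a min/max
  ratio, the same rule as the other continuous parameters.
- **Anisotropic pixel spacing** is averaged (row/column) before the ratio.
- **Missing metadata** is a hard error by default; a `drop-pair` policy
  excludes affected pairs instead.  Dose-related header values of 0 are
  treated as missing, not as settings.

## Reproducibility (Lin's CCC)

`lin_ccc` uses population (1/n) moments, Lin's original definition; a
`ddof=1` flag provides the sample-moment variant used by some reference
implementations (at n = 160 the difference is < 1%, but the convention is
explicit).  A feature is reproducible iff CCC > 0.9, *strictly*: a value at
exactly the threshold fails.  When both columns are constant the CCC is
undefined; such features are flagged NA, counted non-reproducible, and
reported via a warning.  CCC is computed jointly over all 160 VOIs of a
pair (not per layer).  Confidence intervals are not computed; the decision
rule uses the point estimate only.

`pairwise_reproducibility` vectorizes the per-feature CCCs of all C(n, 2)
pairs through batched moment arithmetic; a test pins it to the scalar
implementation.

## ComBat harmonization

Parametric empirical-Bayes ComBat, following the canonical location/scale
model: features are standardized by the grand mean and pooled within-batch
residual variance; per-batch means/variances of the standardized data are
shrunk toward a normal prior (moment-matched) and an inverse-gamma prior
(moment-matched), with coupled posterior updates iterated to a relative
change below 1e-4 (at most 100 iterations).  A non-parametric mode weights
candidate effects by the empirical likelihood over the other features.  The
implementation is cross-checked against the Bioconductor `sva::ComBat`
reference in the test suite (agreement to ~1e-4 absolute on the adjusted
values, limited by iteration convergence).

In the scenario pipeline the two scans of a pair are the two batches
(160 VOI samples each); the phantom is identical across scans, so no
covariates are preserved.  A "global" usage (one batch per unique protocol
across a whole cohort) is possible by passing explicit batch labels to
`fit_combat`.  Zero-variance features cannot be standardized and pass
through unadjusted.

## Resampling arms

Three processing arms: `original` (native grid), `median_resample`
(0.68 × 0.68 × 1.5 mm) and `largest_resample` (0.98 × 0.98 × 3.75 mm),
all binned at 25 HU during extraction.  Resampling uses cosine-windowed-sinc
interpolation with the output grid anchored at the input origin and
dimensions `ceil(extent / target)`; the padding value is −1024 HU (air).
Feature mathematics are *delegated*: the package defines an extractor
contract (per-VOI voxel array + bin width → feature dict) rather than
re-implementing texture matrices, since everything the package contributes
is downstream of extraction.  VOI boxes live in physical mm (half-open
intervals, centered 4 × 4 in-plane layout) and are mapped to voxel indices
by flooring the start and ceiling the end.

## Score model

A regression random forest (500 trees, 3 candidate variables per split,
fixed seed) maps the 8 encodings to percent reproducible.  Variance
explained is reported as out-of-bag R² (the convention of the classic R
implementation).  Importances are permutation importances (mean decrease in
MSE, 5 repeats) by default — they are comparable across the mixed
binary/continuous encodings — with impurity importance behind a flag.
`derive_weights` keeps the top k = 3 parameters and normalizes their
importances to sum to 1; negative (noise-level) permutation importances are
clipped to zero first.  Percent (not count) of reproducible features is
the outcome, making the model registry-size-invariant.

The packaged **published weights** are kernel 0.48, slice thickness 0.33,
pixel spacing 0.19, and are the default scoring mode; refitted weights are
labelled `fitted` and never silently replace them.

ROC analysis: pairs are labelled 1 iff percent reproducible strictly
exceeds the threshold (10–90%); AUC is the Mann–Whitney rank statistic
(pinned to an exhaustive pairwise-concordance oracle in the tests); the
cutoff maximizes Youden's J.  The packaged cutoff table
(`data/published_cutoffs.csv`) carries the published per-threshold cutoffs
and operating characteristics, including the 0.94 cutoff at the 70%
threshold that backs the screening workflows.  The robustness harness
repeats cutoff selection over seeded 80/20 splits (master seed fanned out
through `SeedSequence(seed, spawn_key=(run,))`, recorded per run); by
default the score weights stay fixed across splits and only the cutoff is
re-selected — the score, not the forest, is the object under test — with
`refit_weights=True` refitting the forest per split.  Splits lacking both
classes at a threshold are recorded as NA, not dropped silently.

## Screening workflows

- **Prospective inclusion**: all pairwise scores (published weights); a
  pair passes iff score > cutoff (default 0.94); the per-scan summary
  (minimum pair score, failing-pair count) identifies exclusion candidates.
- **Retrospective audit**: fraction of pairs above the cutoff; the verdict
  is positive only for a *strict* majority (> 50%); exactly half is
  negative.

## Synthetic cohort generator

The generator makes every stage testable with known ground truth.  Each
feature has a fixed per-VOI signature `base(v, f) = μ_f + σ_f t_{v,f}`
shared by all scans (`t` standard normal, `σ_f = |μ_f| / 5` so texture
spread is 20% of the mean — this mean-to-spread ratio controls how hard a
location shift hits CCC).  A scan's settings produce a feature distortion

    value(v, f) = base(v, f) · (1 + Σ_p β_{f,p} d_p(scan)) + ε,
    ε ~ N(0, (0.02 σ_f)²),

with `d_p` the scan's parameter standardized on the **log scale** to
[−1/2, 1/2] (acquisition effects act multiplicatively, and the pairwise
distortion difference is then a monotone function of the min/max-ratio
encoding).  Each sensitive feature responds to one primary parameter,
drawn with probability proportional to the parameter's effect size —
mirroring how texture families are dominated by a single resolution factor
— with per-feature strength `effect_p · (0.3 + |N(0,1)|)`, bounded away
from zero so every sensitive feature reacts.  Default effect sizes:
kernel 0.80 > slice thickness 0.50 > pixel spacing 0.30 ≫ tube
current/exposure/exposure time 0.04 > vendor/model 0.  Four first-order
features (mean, median, root mean squared, total energy — the statistics
that track calibrated HU directly) have all β = 0 and are insensitive by
design.

Kernels are sampled independently of vendor: the schema makes kernels
comparable across vendors, and tying kernel pools to vendors would let the
null vendor/model predictors inherit importance from the kernel.

Under these defaults a 40-scan cohort (780 pairs) yields a mean percent
reproducible around 40–60% with sd ≈ 20–25, importance-ordering recovery
in ≥ 95 of 100 seeded runs, and published-weight score vs outcome Spearman
ρ ≈ 0.88–0.93.  A `combat_adverse` flag makes distortions VOI-dependent
(an interaction the location/scale model cannot remove), used to show that
harmonizability depends on the distortion regime.

**What the generator does not emulate**: real scanner noise textures,
partial-volume effects at VOI borders, non-multiplicative feature
responses, inter-feature correlation structure, or the actual kernel rank
table of any vendor.  Passing tests therefore demonstrate internal
consistency of the pipeline and recoverability of designed effects — not
that the published weights are correct for any particular scanner fleet.

## Problem sizes

Tests run on 40-scan cohorts (780 pairs; the generator's default, chosen as
the smallest size at which forest importance rankings stabilize); the
251-scan scale of a full phantom campaign (31,375 pairs) is exercised for
pair enumeration and grid arithmetic, and is fully supported by the
vectorized CCC path (a 251-scan cohort needs ~45 MB for the pairwise CCC
tensor).

## Known limitations

- The kernel schema ships as an ordering stand-in; scoring fidelity on real
  data depends on a site-validated schema, including cross-vendor
  equivalences.
- The score ignores dose parameters entirely; pairs differing wildly in mAs
  but matched in resolution score 1.0.  This is by construction (dose had
  negligible importance) but untested for low-dose extremes.
- ComBat here is the plain two-batch location/scale variant: no covariates,
  no reference batch, no longitudinal extensions.
- Applicability is limited to non-contrast CT radiomics with the fixed
  25 HU bin width; other modalities and bin widths are out of scope.
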