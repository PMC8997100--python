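# maaspenn

Reproducibility scoring for CT-based handcrafted radiomic features (HRFs).

Radiomic signatures are built from hundreds of texture and intensity
statistics extracted from CT images, but a large fraction of those features
change when the scans are acquired or reconstructed differently — a sharper
convolution kernel, a thicker slice, a coarser in-plane grid.  A study that
pools scans from heterogeneous protocols may therefore be training on
acquisition artifacts.  `maaspenn` quantifies that risk *from scan metadata
alone*: it implements the MaasPenn radiomics reproducibility score, a
weighted agreement measure over the acquisition parameters of a scan pair,
together with the full pipeline the score is derived from.

## What it computes

For each unordered pair of scans, eight acquisition parameters (vendor,
model, tube current, exposure, exposure time, slice thickness, pixel
spacing, convolution kernel) are encoded as similarities in [0, 1]:
categorical parameters as 0/1 equality, numeric ones as min/max ratios, and
kernels as the min/max ratio of their schema ranks (kernels ranked by
limiting frequency).  Reproducibility of a feature across a pair is Lin's
concordance correlation coefficient over the phantom's 160 paired VOI
values,

    CCC = 2 cov(x, y) / ( var(x) + var(y) + (mean(x) − mean(y))² ),

with a feature called reproducible when CCC > 0.9.  A regression random
forest (500 trees, 3 variables per split) maps the 8 encodings to the
percent of reproducible features per pair; the top three parameters by
importance — convolution kernel, slice thickness, pixel spacing — are
normalized into the published score weights:

    MaasPenn(pair) = 0.48·kernel + 0.33·slice_thickness + 0.19·pixel_spacing

on the encoded similarities, giving a score in (0, 1] that is 1 exactly
when the three resolution parameters match.  ROC analyses against
percent-reproducible thresholds turn the score into screening rules; the
packaged cutoff table includes the 0.94 cutoff at the 70% threshold used to
screen scans for inclusion, and a signature-audit workflow checks whether a
strict majority of a dataset's pairs clears it.

The package also ships empirical-Bayes ComBat harmonization (location/scale
batch correction per scan pair), resampling arms (cosine-windowed-sinc to
the median or largest voxel size) behind a delegated feature-extractor
contract, and a synthetic phantom-cohort generator with known ground truth
for every stage.

## Worked example

```python
from maaspenn import (GeneratorConfig, RFConfig, simulate_experiment, fit_rf,
                      derive_weights, maaspenn_score, published_weights,
                      score_outcome_correlation, roc_select_cutoff)

# a 40-scan synthetic phantom cohort: 780 scan pairs, 160 VOIs x 91 HRFs each
frame, ds = simulate_experiment(GeneratorConfig(n_scans=40, seed=7))
print("mean pct reproducible: %.1f" % frame.pct_reproducible.mean())

rf = fit_rf(frame, frame.pct_reproducible.to_numpy(), RFConfig(seed=7))
print("variance explained: %.1f%%" % rf.variance_explained_pct)
print(derive_weights(rf.importances.to_dict(), k=3).weights)

s = maaspenn_score(frame, published_weights())
print("spearman rho: %.3f" % score_outcome_correlation(s, frame.pct_reproducible))
rule = roc_select_cutoff(s, (frame.pct_reproducible > 70).astype(int), 70)
print("70% threshold: cutoff %.3f, AUC %.3f" % (rule.score_cutoff, rule.auc))
```

prints

```
mean pct reproducible: 39.7
variance explained: 99.4%
{'kernel': 0.727, 'slice_thickness': 0.227, 'pixel_spacing': 0.047}
spearman rho: 0.891
70% threshold: cutoff 0.677, AUC 0.944
```

On this cohort roughly 40% of features survive an average protocol change;
the forest explains nearly all pair-to-pair variance from the encodings
and recovers the designed importance ordering kernel > slice thickness >
pixel spacing; the published-weight score tracks the outcome at rho ≈ 0.89.
(The fitted weights are cohort-specific; use `published_weights()` for the
published 0.48/0.33/0.19 score.)

The same pipeline is available from the shell:

```bash
maaspenn simulate --n-scans 40 --seed 7 --out cohort/
maaspenn encode --metadata cohort/metadata.csv --schema cohort/kernel_schema.csv --out encodings.csv
maaspenn screen --metadata cohort/metadata.csv --cutoff 0.94 --out screen.csv
maaspenn audit  --metadata cohort/metadata.csv
```

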