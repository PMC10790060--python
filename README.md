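# csecnn

Cross-sample entropy connectivity volumes and 3-D CNN classification for
resting-state fMRI cohorts.

## What this is

Predicting suicidality in late-life depression from resting-state fMRI
is a two-class problem — depressed patients without suicidal thought or
behavior versus patients with suicidal ideation or past attempts — where
the informative signal is the *asynchrony* between regional BOLD time
series.  This package implements that analysis as a reusable, tested
pipeline for researchers working with ROI time series or 4-D volumes:

- **Cross-sample entropy (CSE)** between every pair of the 90 regions of
  an anatomical parcellation: CSE(x, y) = −ln(A/B), the negative log of
  the conditional probability that templates of length m = 2 matching
  within tolerance r = 0.6 (Chebyshev, SD units) still match at length
  m + 1.  Low CSE = high synchrony.
- **Reference normalization**: each subject's 90 × 90 CSE matrix is
  z-scored against the non-suicidal group's mean and SD.
- **Seed-region volumes**: row i of the normalized matrix is painted
  into atlas space (91 × 109 × 91 on the 2-mm MNI grid), one volume per
  seed region.
- **A 3-D CNN per seed region** (avgpool → conv 32/64/128 → three fc 500
  layers → softmax), trained with Adam, categorical cross-entropy, and
  early stopping — implemented in pure numpy, deterministic by seed.
- **Stratified sixfold cross-validation** with per-region mean
  accuracies, 95% CIs, a strict >75% flag, an every-fold "reliable"
  flag, and a majority-vote ensemble over regions.
- **A synthetic cohort generator** with a tunable coupling contrast, so
  the whole pipeline is testable end to end without patient data.

The scikit-learn idiom is used throughout: `CrossSampleEntropy` and
`ReferenceNormalizer` are transformers, `CNNVolumeClassifier` is a
classifier with `fit` / `predict` / `predict_proba`, and module-level
functions wrap them for scripting.

## Worked example

Simulate a small cohort with two coupled "effect" regions in the
suicidal group, compute entropies, and cross-validate every seed region:

```python
import numpy as np
from csecnn import (
    SimulationConfig, simulate_cohort, make_toy_atlas,
    CrossSampleEntropy, make_folds, run_full_cv, rank_rois,
)

config = SimulationConfig(
    n_rois=20, group_sizes=(24, 12, 12),
    effect_rois=(2, 9), coupling_ns=0.0, coupling_s=0.8, seed=1,
)
manifest, data = simulate_cohort(config)           # 48 subjects, 180 TRs
atlas = make_toy_atlas((24, 24, 24), 20, seed=1)
matrices = {sid: CrossSampleEntropy().fit_transform(ts)
            for sid, ts in data.items()}
folds = make_folds(manifest, k=3, seed=1)
result = run_full_cv(matrices, manifest, folds, atlas, reduced=True, seed=1)
report = result["report"].sort_values("mean_accuracy", ascending=False)
print(report[["roi_label", "mean_accuracy", "ci_low", "ci_high"]].head(3))
print("above 75%:", rank_rois(report)[0])
```

Output:

```
   roi_label  mean_accuracy    ci_low   ci_high
1          2       0.937500  0.782241  1.000000
8          9       0.895833  0.658672  1.000000
0          1       0.687500  0.532241  0.842759
above 75%: [2, 9]
```

The two planted effect regions (2 and 9) top the ranking with mean
accuracies of 0.94 and 0.90 and are the only regions whose mean exceeds
the 75% reporting threshold; the remaining regions stay inside the exact
binomial chance band for 48 test predictions.

The same pipeline is scriptable from the shell:

```bash
csecnn simulate --out cohort/ --n-rois 20 --group-sizes 24 12 12 \
       --effect-rois 2,9 --coupling-s 0.8 --seed 1
csecnn entropy  --data-dir cohort/ --out cse/
csecnn cv       --matrices-dir cse/ --atlas cohort/atlas.nii.gz \
       --out cv/ --k 3 --reduced --seed 1
csecnn report   --report cv/report.tsv
```

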