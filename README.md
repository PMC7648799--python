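# organseg

Multi-organ segmentation of volumetric whole-body mouse scans, with
annotator-disagreement prediction, evaluation metrics and organ
volumetry.

Whole-body imaging of mice (micro-CT, light-sheet microscopy of cleared
tissue) underpins quantitative studies of cancer spread, drug delivery
and organ pathology, but every such analysis first needs the organs
delineated voxel by voxel. Manual delineation is slow and — especially
for low-contrast organs like the spleen in native CT — subjective:
independent experts produce visibly different annotations of the same
scan. `organseg` implements a complete deep-learning pipeline for this
problem:

* **Segmentation.** Scans are sliced into coronal 2D images, z-score
  normalized and resampled; a configurable U-Net-style encoder–decoder
  (two conv-BN-ReLU + max-pool per encoding level, channel doubling from
  32 up to 1024 at six levels; bilinear upsampling, skip concatenation
  and three convolutions per decoding level; per-class sigmoid outputs)
  is trained with the soft-Dice loss
  `L = 1 − mean_c (2Σpt+ε)/(Σp+Σt+ε)`, ε = 1e-5, under
  leave-one-mouse-out cross-validation split strictly by subject.
  Slice predictions are reconstructed in 3D, optionally median-voted
  across an ensemble, and binarized with a softmax over the organ
  scores plus a synthetic background competitor.
* **Disagreement prediction.** Trained on the voxel-wise agreement of
  two annotators plus an extra channel holding their XOR, the network
  also predicts a heatmap of the regions where human experts are likely
  to disagree — turning annotation ambiguity into a quantity.
* **Evaluation.** ε-smoothed Dice `(2TP+ε)/(2TP+FP+FN+ε)`, percentile
  Hausdorff surface distance (p = 50, 95) in physical µm,
  center-of-mass displacement, and a union-reference Dice that counts a
  predicted voxel correct when it matches at least one of two
  annotations.
* **Volumetry.** Organ volumes with a three-way variability
  decomposition — intersubject, interannotator, intraannotator
  (population standard deviations, absolute and relative) — and
  metastasis-to-organ allocation with count error.
* **Phantom cohorts.** A synthetic generator producing mouse-like
  cohorts (ellipsoidal organs under analytic rigid posture jitter, one
  deliberately low-contrast spleen-like organ, two annotators differing
  by a structured bias plus boundary noise, known metastasis points) so
  the entire pipeline is testable without external data.

The network, its backpropagation and the Adam optimizer are implemented
in NumPy; I/O uses nibabel (NIfTI), image operations scipy.ndimage,
tables pandas. See `docs/methods.md` for the full model description and
design rationale.

## Worked example

```python
import organseg as og
from organseg.nn import NetConfig
from organseg.pipeline import (TrainConfig, split_cv, train_ensemble,
                               predict_volume, binarize_softmax)
from organseg.metrics import dice

cohort = og.build_cohort(og.default_spec())        # 6 mice x 2 scans
members = train_ensemble(                          # fold 0: mouse 1 held out
    cohort, 0,
    NetConfig(levels=3, base_channels=8, n_classes=4),
    TrainConfig(epochs=8, initial_lr=5e-3, ensemble_size=3, seed=1),
)
split = split_cv(cohort, fold=0, seed=1)
scan = cohort.scans_of(split.test_mice[0])[0]      # held-out mouse
maps = predict_volume([n for n, _ in members], scan.volume, cohort.codes)
pred, _ = binarize_softmax(maps, cohort.code_table)
for code, name in cohort.code_table.items():
    print(name, round(dice(pred.data == code, scan.labels[1].data == code), 3))
```

Output (about three minutes on one CPU core):

```
heart 0.996
liver 0.994
kidney 0.998
spleen 0.305
```

The three high-contrast organs are segmented with Dice ≈ 0.99 on the
unseen mouse; the spleen-like organ — whose mean intensity sits within
one noise standard deviation of the surrounding tissue — scores far
lower, the same qualitative gap real studies report between the spleen
and well-contrasted organs in native CT.

The same objects drive the CLI: `organseg simulate | train | predict |
evaluate | volumetry | allocate` (see `organseg --help`), which write
NIfTI volumes, per-organ CSV reports and resolved-config provenance
files.

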