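# Methods

## Overview

`organseg` is an end-to-end pipeline for multi-organ segmentation of
volumetric whole-body mouse scans. A volumetric scan is sliced into 2D
coronal images, each slice is z-score normalized and resampled to a
working resolution, and a U-Net-style encoder–decoder maps every slice
to per-organ probability maps. Slice predictions are stacked back into
3D, optionally merged across an ensemble of independently trained models
by a voxel-wise median, and binarized into a label volume. The same
network can additionally be trained to predict a heatmap of the image
regions where two human annotators are likely to disagree.

Because real whole-body datasets require GPU-scale training, the package
ships a synthetic phantom generator that reproduces the *statistical
structure* of such a study — a cohort of mice, repeat scans with rigid
posture changes, organs of differing contrast, two annotators with a
structured bias — so that every stage of the pipeline can be exercised
and validated end to end on a CPU in minutes.

## Preprocessing

* **Slicing.** Axis 0 of the in-memory volume is dorsoventral; a coronal
  slice is a fixed index along it (axis 1 rostrocaudal, axis 2
  left–right). The array convention is the package's own choice; NIfTI
  inputs are reoriented to the closest canonical orientation on load.
* **Normalization.** Intensities are normalized by subtracting the mean
  and dividing by the standard deviation. The scope is per volume by
  default, with a per-slice switch. Per-volume statistics preserve the
  intensity calibration across slices; per-slice z-scoring rescales
  organ-free slices so that their noise spans the numeric range organs
  occupy elsewhere, which invites false positives on slice types the
  training filter never exposes. The divisor is floored at 1e-6 so
  constant slices map to zeros rather than NaN.
* **Resampling.** Bilinear for intensities, nearest neighbor for masks;
  the working resolution defaults to 240 µm/px. The new shape is
  `round(shape × scale / target)`; shapes below 8 px are rejected.
* **Training-slice filtering.** Only slices containing at least one
  organ voxel are used for training; at inference every slice of the
  volume is predicted.
* **Augmentation.** A random in-plane rotation uniform in ±10° (image
  bilinear, masks nearest, out-of-bounds filled with 0 — the normalized
  background mean) followed by a random axis-aligned crop with area
  uniform in [80 %, 100 %] of the slice, aspect ratio preserved, resized
  back to the original shape so batch shapes stay fixed.

## Network

For `levels = L` and `base_channels = b`, encoding unit *l* applies two
3×3 convolutions (padding 1, stride 1), each followed by batch
normalization and ReLU, producing `b·2^(l−1)` channels, and ends in 2×2
max pooling — so the defaults (L=6, b=32) give the channel sequence
32, 64, …, 1024. Decoding unit *l* bilinearly upsamples its input,
concatenates the skip connection from encoding unit *l*, and applies
three 3×3 conv-BN-ReLU blocks down to that level's channel count. A
final 1×1 convolution maps the 32 first-level channels to the prediction
classes and a per-class sigmoid yields independent probability maps;
mutual exclusivity is imposed only at postprocessing. Input spatial
dimensions must be divisible by 2^L (a zero-padding helper restores the
native shape after prediction).

The network, its backpropagation, the Adam optimizer and the plateau
learning-rate scheduler are implemented directly in NumPy. The 3×3
convolution runs as nine strided matrix products against the padded
channel-last input; its backward pass accumulates the weight gradient
from the same nine shifted views. Batch-normalization statistics are
frozen at inference (running mean/variance), which makes evaluation-mode
forwards bit-reproducible — the basis of the package's determinism
contracts. Gradient correctness is pinned by finite-difference tests.

## Training

The loss is the soft-Dice loss

    L = 1 − mean (2 Σ p·t + ε) / (Σ p + Σ t + ε),  ε = 1e-5,

with the sums over the spatial axes and the mean over all
(sample, class) pairs with equal weights; ε is the same smoothing
constant used by the evaluation Dice. Averaging per sample rather than
pooling the batch keeps a rare organ's gradient at full strength on the
slices where it appears; a pooled batch denominator dilutes small
classes by every other slice's probability mass. Optimization uses Adam. After every epoch the mean soft-Dice on
the validation mouse's slices is evaluated; when it has not improved for
`plateau_patience` (default 5) epochs the learning rate is multiplied by
`lr_factor` (default 0.1 — the conventional plateau-scheduler choice;
the monitored quantity and factor are package choices).

Cross-validation is leave-one-mouse-out and always splits on the level
of individual mice, never scans, so no scan of a test mouse can reach
training or validation; the training loop records the provenance of
every sample it consumed, and a dedicated audit asserts the absence of
leakage on every fold. Per fold an ensemble (default 10 members at full
scale) can be trained, each member with a different validation mouse and
seed; when fewer non-test mice than members exist the validation mouse
rotates and members differ by seed.

Defaults for full-scale data follow the training recipe the pipeline is
built around: 30 epochs, initial learning rate 1e-3, ensemble of 10.
The phantom-scale configuration used by the tests and the acceptance
script is 8 epochs at learning rate 5e-3 with a tiny network (levels 3,
base 8) and a three-member ensemble per fold: the four-organ phantom is
far simpler than real anatomy and a small network at a larger step size
converges in a few hundred updates, but individual short runs
occasionally misrank one organ on the held-out mouse — the voxel-wise
median across members eliminates these outlier runs, which is precisely
the role ensemble voting plays in the pipeline. The output-head bias is
initialized to −2 so the sigmoids start near 0.12: organ classes cover
a small fraction of each slice, and a large initial probability mass
drowns the soft-Dice gradient of small classes (a standard
stabilization for Dice-family losses).

## Postprocessing

Ensemble probability maps are combined voxel-wise and channel-wise by
the median. For binarization a synthetic background score
`1 − max(anatomical probabilities)` is appended — the independent
sigmoids need an explicit background competitor for an arg-max rule —
the channels pass through a per-voxel softmax and each voxel takes the
arg-max class, ties broken by lowest channel index with background last.
A plain 0.5-threshold-then-argmax rule is available as a switch. The
disagreement channel bypasses binarization and is returned as a heatmap.
No further postprocessing (filtering, morphology) is applied.

When the maps come from the network directly, the ranking is computed
on the pre-sigmoid logits: sigmoid and softmax are monotone, and the
`p = 0.5` background competitor is exactly logit 0, so the decisions
coincide with the probability formulation — but confident float32
probabilities saturate at exactly 1.0, which erases the ordering
between two strongly firing classes, while logits preserve it. The
ensemble median is taken on logits too (the median commutes with the
monotone sigmoid).

## Disagreement prediction

Given two annotations of the same scan, the training targets become: per
organ the voxel-wise *agreement* of both annotators (a config switch
reverts to annotator 1 alone), plus one extra channel containing the
union over organs of the XOR of the two annotators' masks — the actual
human disagreement. The extra channel trains with the same soft-Dice
loss and predicts, at inference, a disagreement heatmap. Its quality is
scored by binarizing at 50 % and computing the Dice score against the
true XOR region.

## Evaluation metrics

* **Dice** `(2TP+ε)/(2TP+FP+FN+ε)`, ε = 1e-5, computed on the
  reconstructed 3D volume per organ per scan; two empty masks score 1 by
  the ε limit. Human-vs-human agreement reuses the same score with one
  annotation as reference; it is symmetric under interchange.
* **Percentile Hausdorff distance**: the p-th percentile (linear
  interpolation between order statistics) of the directed distances from
  every reference-surface voxel to the nearest predicted-surface voxel,
  in physical µm using the per-axis spacing. Surface voxels are mask
  voxels with at least one face-adjacent (6-connected) background
  neighbor; array-edge voxels count as surface. The directed form is the
  package's reading of the percentile-of-minimum construction; a
  symmetric variant pooling both directions is available by flag.
  p = 50 and 95 are reported.
* **Center-of-mass displacement**: Euclidean distance between the two
  masks' voxel-center centroids in µm.
* **Union-reference Dice** against two annotations jointly: TP where the
  prediction matches at least one annotation, FP only outside both, FN
  only where both annotations agree.
* Metrics undefined on empty masks (distances, centroids) are reported
  as missing values with a machine-readable reason — never coerced to 0
  or ∞ — since mislabeled or absent organs do occur in practice.

## Volumetry and variability

Organ volume is voxel count × physical voxel volume. The variability of
volume estimates decomposes into intersubject (sd across mice of the
scan-mean volume, annotator 1), interannotator (mean over scans of the
per-scan sd across annotators) and intraannotator (mean over mice of the
sd across repeat scans, annotator 1). All three use *population*
standard deviations (÷N under the root); the unnormalized
sum-of-squares-under-the-root form is available via `as_printed=True`
for literal comparison with conventions that omit the 1/N factor.
Relative forms divide by the mean organ volume. Metastasis points take
the label of their containing voxel (floor of continuous voxel
coordinates); per organ the allocated count and the relative error
|count − true| / true are reported (undefined → missing when the true
count is 0).

## Phantom generator

Organs are ellipsoids evaluated analytically: each voxel center is
pulled back through the inverse rigid transform and tested against the
ellipsoid inequality, so rigid posture changes never resample the mask
and the true organ volume is invariant across scans up to voxel
discretization. The organs sit inside an unlabeled soft-tissue "body"
ellipsoid (intensity 160 on an air background of 100): real whole-body
scans show tissue in every slice of the field of view, and without the
body, organ-free slices are pure noise that per-slice statistics would
inflate into spurious structure. Like real scans the body may be
cropped by the field of view. Per mouse, organ semi-axes are scaled by
N(1, 0.08) (clipped at ±3 sd) and centers shifted uniformly within
±1.5 vx — the anatomical (intersubject) variability; per scan, the
whole body shifts uniformly within ±3 vx and rotates in the coronal
plane within ±8° — the posture (intraannotator) variability.
Intensities carry Gaussian noise of sd 10. The default cohort (6 mice ×
2 scans, 64×64×96 voxels at 240 µm) has four organs: three
high-contrast (means 220–350, i.e. 6–19 noise sd above the body) and
one spleen-like organ at mean 150 — within one noise sd of the
surrounding tissue — whose boundary is genuinely ambiguous,
reproducing the qualitative structure that low-contrast organs score
lower and drive annotator disagreement.

Annotator 1 is the unperturbed ground truth. Annotator 2 dilates or
erodes each organ by a per-organ number of voxels (default: the
spleen-like organ dilated by 1 — a structured, systematic bias) and then
flips each voxel of the one-voxel boundary shell independently with
probability 0.05. Metastases are points sampled uniformly inside organ
voxels plus background points, with the true organ recorded.

What the phantom does *not* emulate: imaging physics (beam hardening,
scatter, PSF), textured or heterogeneous organ interiors, deformable
posture, touching organ boundaries, field-of-view truncation. Passing
the phantom suite therefore demonstrates the correctness of the
pipeline's mechanics and the qualitative contrast/disagreement
phenomenology — not segmentation quality on real scans.

## Numerical choices and degenerate inputs

* ε = 1e-5 in both loss and Dice; constant-slice guard sd ≥ 1e-6.
* Percentile = NumPy linear interpolation, pinned for bit-stable tests.
* Arg-max ties → lowest channel index (determinism).
* Empty training set, non-finite loss, organs escaping the grid after
  jitter, geometry mismatches and out-of-grid metastasis points all
  raise typed errors naming the offending object.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit integer lists; identical seeds give bit-identical cohorts,
  training curves and evaluation CSVs.

## Problem sizes

The test suite runs the full pipeline at phantom scale: 6 mice × 2
scans of 64×64×96 voxels, leave-one-mouse-out with a three-member
ensemble per fold (18 models, 8 epochs each), plus one
disagreement-mode ensemble on a single fold. The acceptance script
runs the same study on the first four folds. These sizes were chosen
so each study executes on a single CPU core in well under half an hour
while leaving every scientific property (convergence, contrast
ordering, ensemble behavior, disagreement localization, variability
ordering) measurable.

## Known limitations

* 2D slice-wise prediction only; no 3D convolutions.
* The NumPy backbone is single-threaded and CPU-bound; it is meant for
  correctness and phantom-scale studies, not GPU-scale training.
* The softmax binarization with a synthetic background competitor is one
  of several defensible readings of sigmoid-output binarization; the
  threshold rule is provided as the alternative.
* Interannotator variability with A = 2 reduces to half the absolute
  volume difference per scan; with more annotators the same code applies
  unchanged.
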