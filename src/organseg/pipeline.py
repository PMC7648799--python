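"""Subject-level cross-validation, training, whole-volume prediction,
ensemble median voting, binarization and disagreement targets.

Cross-validation is leave-one-mouse-out: the dataset is always split on
the level of individual mice, never on the level of scans, so no scan of
a test mouse can leak into training or validation.  Per fold an ensemble
of models can be trained, each with a different validation mouse (and a
different seed); their probability maps are merged by a voxel-wise,
channel-wise median before binarization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .nn import Adam, NetConfig, ReduceLROnPlateau, UNet, soft_dice_grad, soft_dice_loss
from .preprocess import (
    PreprocessConfig,
    SliceSample,
    augment,
    filter_training_slices,
    normalize_intensity,
    resample_slice,
)
from .volumes import GeometryError, LabelVolume, ProbMaps, VoxelVolume

__all__ = [
    "TrainConfig",
    "CVSplit",
    "split_cv",
    "ensemble_splits",
    "make_disagreement_targets",
    "train_model",
    "train_ensemble",
    "predict_volume",
    "ensemble_median",
    "binarize_softmax",
    "reconstruct_3d",
    "pad_to_divisible",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    initial_lr: float = 1e-3
    plateau_patience: int = 5
    lr_factor: float = 0.1
    batch_size: int = 8
    ensemble_size: int = 10
    augment_data: bool = True
    grad_clip: float | None = 1.0  # global gradient-norm ceiling
    # organ targets when training with a disagreement head: the
    # annotator intersection ("intersection") or annotator 1 as-is
    disagreement_organ_targets: str = "intersection"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.ensemble_size < 1 or self.batch_size < 1:
            raise ValueError("epochs, ensemble_size and batch_size must be >= 1")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.disagreement_organ_targets not in ("intersection", "annotator1"):
            raise ValueError("disagreement_organ_targets must be 'intersection' or 'annotator1'")


@dataclass(frozen=True)
class CVSplit:
    test_mice: tuple[int, ...]
    validation_mice: tuple[int, ...]
    training_mice: tuple[int, ...]

    def __post_init__(self) -> None:
        groups = [set(self.test_mice), set(self.validation_mice), set(self.training_mice)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("test/validation/training mice must be disjoint")
        if not self.training_mice:
            raise ValueError("training set is empty")


def split_cv(cohort: Cohort, fold: int, seed: int, member: int = 0) -> CVSplit:
    """Leave-one-mouse-out split: fold ``fold``'s subject is the test set,
    one remaining subject (rotated by ensemble ``member``) is validation,
    the rest are training."""
    subjects = cohort.subjects
    if len(subjects) < 3:
        raise ValueError(f"need at least 3 subjects, cohort has {len(subjects)}")
    if not 0 <= fold < len(subjects):
        raise ValueError(f"fold {fold} outside 0..{len(subjects) - 1}")
    test = subjects[fold]
    rest = [s for s in subjects if s != test]
    rng = np.random.default_rng([seed, 3, fold])
    rest = [rest[i] for i in rng.permutation(len(rest))]
    val = rest[member % len(rest)]
    train = tuple(s for s in rest if s != val)
    return CVSplit((test,), (val,), train)


def ensemble_splits(
    cohort: Cohort, fold: int, seed: int, ensemble_size: int
) -> list[CVSplit]:
    """One split per ensemble member, each with a different validation
    mouse where enough non-test mice exist (members beyond that differ by
    seed only)."""
    return [split_cv(cohort, fold, seed, member=j) for j in range(ensemble_size)]


def make_disagreement_targets(a1: LabelVolume, a2: LabelVolume) -> np.ndarray:
    """Per-class training targets from two annotations.

    Channel o (one per organ code, ascending) is the voxel-wise agreement
    of both annotators on organ o; the final channel is the union over
    organs of the XOR of the two annotators' organ masks (the actual
    human disagreement).  Shape: (n_organs + 1, *grid).
    """
    a1.check_geometry(a2)
    if a1.codes != a2.codes:
        raise ValueError("annotations carry different code tables")
    channels = []
    xor = np.zeros(a1.shape, bool)
    for code in a1.codes:
        m1 = a1.data == code
        m2 = a2.data == code
        channels.append(m1 & m2)
        xor |= m1 ^ m2
    channels.append(xor)
    return np.stack(channels)


def pad_to_divisible(arr: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad the two trailing axes up to the next multiple of ``div``;
    returns the padded array and the original (H, W)."""
    h, w = arr.shape[-2:]
    ph = (-h) % div
    pw = (-w) % div
    if ph == 0 and pw == 0:
        return arr, (h, w)
    pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(arr, pad), (h, w)


# ---------------------------------------------------------------------------
# training


def _scan_training_slices(
    scan, pre_cfg: PreprocessConfig, disagreement: bool, organ_targets: str
) -> list[SliceSample]:
    """Normalized, resampled training slices with target masks for one scan."""
    vol = scan.volume
    truth = scan.labels[1]
    codes = truth.codes
    if disagreement:
        if 2 not in scan.labels:
            raise ValueError(
                f"scan ({scan.mouse}, {scan.scan}) lacks a second annotation "
                "needed for disagreement training"
            )
        targets = make_disagreement_targets(truth, scan.labels[2])
        if organ_targets == "annotator1":
            for i, code in enumerate(codes):
                targets[i] = truth.data == code
    else:
        targets = np.stack([truth.data == c for c in codes])
    scale = (vol.spacing[1], vol.spacing[2])
    out = []
    if pre_cfg.normalize_scope == "volume":
        norm_vol = normalize_intensity(vol.data)
    for i in range(vol.shape[0]):
        image = (
            norm_vol[i]
            if pre_cfg.normalize_scope == "volume"
            else normalize_intensity(vol.data[i])
        )
        s = SliceSample(
            image,
            targets[:, i],
            codes + ((-1,) if disagreement else ()),
            (scan.mouse, scan.scan, i),
            scale,
        )
        out.append(resample_slice(s, pre_cfg.target_scale_um))
    return out


def _stack_batch(samples: list[SliceSample], div: int):
    images = np.stack([pad_to_divisible(s.image, div)[0] for s in samples])[:, None]
    targets = np.stack([pad_to_divisible(s.masks, div)[0] for s in samples])
    return images.astype(np.float32), targets


def train_model(
    cohort: Cohort,
    split: CVSplit,
    net_cfg: NetConfig,
    train_cfg: TrainConfig,
    pre_cfg: PreprocessConfig | None = None,
    disagreement: bool = False,
) -> tuple[UNet, pd.DataFrame]:
    """Train one network on the split's training mice.

    Adam minimizes the soft-Dice loss on filtered, augmented training
    slices; after every epoch the mean soft-Dice on the validation mice's
    slices is evaluated and the learning rate is multiplied by
    ``lr_factor`` when that metric has stagnated for ``plateau_patience``
    epochs.  Returns the trained network and a per-epoch history frame
    (columns: epoch, train_loss, val_dice, lr); ``history.attrs`` records
    the mice whose slices entered training/validation batches.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    n_organs = len(cohort.codes)
    expected = n_organs + (1 if disagreement else 0)
    if net_cfg.n_classes != expected:
        raise ValueError(
            f"net_cfg.n_classes = {net_cfg.n_classes} but cohort needs {expected}"
        )

    def collect(mice):
        samples = []
        for m in mice:
            for scan in cohort.scans_of(m):
                samples.extend(
                    _scan_training_slices(
                        scan, pre_cfg, disagreement, train_cfg.disagreement_organ_targets
                    )
                )
        return filter_training_slices(samples)

    train_samples = collect(split.training_mice)
    val_samples = collect(split.validation_mice)
    if not train_samples:
        raise ValueError("no training slices remain after filtering")
    seen_mice = {s.source[0] for s in train_samples} | {
        s.source[0] for s in val_samples
    }
    assert not seen_mice & set(split.test_mice), "test mice leaked into training"

    div = 2**net_cfg.levels
    rng = np.random.default_rng([train_cfg.seed, 7])
    net = UNet(net_cfg, np.random.default_rng([train_cfg.seed, 13]))
    opt = Adam(net.params(), lr=train_cfg.initial_lr)
    sched = ReduceLROnPlateau(
        opt, factor=train_cfg.lr_factor, patience=train_cfg.plateau_patience
    )

    val_images, val_targets = (
        _stack_batch(val_samples, div) if val_samples else (None, None)
    )

    history = []
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [train_samples[i] for i in order[start : start + train_cfg.batch_size]]
            if train_cfg.augment_data:
                batch = [augment(s, rng) for s in batch]
            images, targets = _stack_batch(batch, div)
            probs = net.forward(images, train=True)
            loss, grad = soft_dice_grad(probs, targets)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // train_cfg.batch_size}"
                )
            net.backward(grad)
            if train_cfg.grad_clip is not None:
                gnorm = np.sqrt(sum(float((p.grad**2).sum()) for p in net.params()))
                if gnorm > train_cfg.grad_clip:
                    scale = train_cfg.grad_clip / gnorm
                    for p in net.params():
                        p.grad *= scale
            opt.step()
            opt.zero_grad()
            losses.append(loss)
        val_dice = np.nan
        if val_images is not None:
            val_probs = _forward_batched(net, val_images)
            val_dice = 1.0 - soft_dice_loss(val_probs, val_targets)
            sched.step(val_dice)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_dice": float(val_dice),
                "lr": opt.lr,
            }
        )
    hist = pd.DataFrame(history)
    hist.attrs["seen_mice"] = sorted(seen_mice)
    hist.attrs["test_mice"] = list(split.test_mice)
    return net, hist


def _forward_batched(net: UNet, images: np.ndarray, batch: int = 16,
                     return_logits: bool = False) -> np.ndarray:
    outs = [
        net.forward(images[i : i + batch], train=False, return_logits=return_logits)
        for i in range(0, len(images), batch)
    ]
    return np.concatenate(outs)


def train_ensemble(
    cohort: Cohort,
    fold: int,
    net_cfg: NetConfig,
    train_cfg: TrainConfig,
    pre_cfg: PreprocessConfig | None = None,
    disagreement: bool = False,
) -> list[tuple[UNet, pd.DataFrame]]:
    """Train ``ensemble_size`` models for one fold, each with a rotated
    validation mouse and a distinct seed."""
    members = []
    for j, split in enumerate(
        ensemble_splits(cohort, fold, train_cfg.seed, train_cfg.ensemble_size)
    ):
        member_seed = int(
            np.random.SeedSequence([train_cfg.seed, 19, fold, j]).generate_state(1)[0]
            % (2**31)
        )
        cfg_j = replace(train_cfg, seed=member_seed)
        members.append(
            train_model(cohort, split, net_cfg, cfg_j, pre_cfg, disagreement)
        )
    return members


# ---------------------------------------------------------------------------
# prediction


def reconstruct_3d(slice_maps) -> np.ndarray:
    """Stack ordered per-slice class maps (C, H, W) back into (C, D, H, W)."""
    slice_maps = list(slice_maps)
    if not slice_maps:
        raise ValueError("no slices to reconstruct")
    shapes = {m.shape for m in slice_maps}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    return np.stack(slice_maps, axis=1)


def _predict_single(
    net: UNet, v: VoxelVolume, pre_cfg: PreprocessConfig, batch: int = 16
) -> np.ndarray:
    from scipy import ndimage

    div = 2**net.cfg.levels
    scale = (v.spacing[1], v.spacing[2])
    norm_vol = normalize_intensity(v.data) if pre_cfg.normalize_scope == "volume" else None
    prepared = []
    for i in range(v.shape[0]):
        image = norm_vol[i] if norm_vol is not None else normalize_intensity(v.data[i])
        s = SliceSample(image, None, (), (0, 0, i), scale)
        s = resample_slice(s, pre_cfg.target_scale_um)
        padded, orig = pad_to_divisible(s.image, div)
        prepared.append((padded, orig))
    images = np.stack([p for p, _ in prepared])[:, None].astype(np.float32)
    logits = _forward_batched(net, images, batch, return_logits=True)
    native_hw = v.shape[1:]
    slice_maps = []
    for k in range(v.shape[0]):
        h, w = prepared[k][1]
        pm = logits[k][:, :h, :w]
        if (h, w) != native_hw:
            factors = (native_hw[0] / h, native_hw[1] / w)
            pm = np.stack(
                [
                    ndimage.zoom(ch, factors, order=1, grid_mode=True, mode="grid-constant")[
                        : native_hw[0], : native_hw[1]
                    ]
                    for ch in pm
                ]
            )
        slice_maps.append(pm)
    return reconstruct_3d(slice_maps)


def predict_volume(
    networks,
    v: VoxelVolume,
    class_codes: tuple[int, ...],
    pre_cfg: PreprocessConfig | None = None,
    has_disagreement: bool = False,
    batch: int = 16,
) -> ProbMaps:
    """Predict per-class probability maps for a whole volume.

    Every coronal slice is normalized, resampled to the working
    resolution, forwarded in evaluation mode (no augmentation), resampled
    back to the native grid and stacked in slice order.  With several
    networks the voxel-wise median of their probability maps is returned.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    if isinstance(networks, UNet):
        networks = [networks]
    if not networks:
        raise ValueError("need at least one network")
    n_classes = {net.cfg.n_classes for net in networks}
    if len(n_classes) != 1:
        raise ValueError(f"ensemble members disagree on class count: {n_classes}")
    expected = len(class_codes) + (1 if has_disagreement else 0)
    if n_classes.pop() != expected:
        raise ValueError(
            f"networks predict a different class count than the {expected} requested"
        )
    all_logits = [_predict_single(net, v, pre_cfg, batch) for net in networks]
    logits = (
        all_logits[0] if len(all_logits) == 1
        else np.median(np.stack(all_logits), axis=0)
    )
    # the sigmoid is monotone, so the voxel-wise median commutes with it;
    # logits are kept alongside to preserve ranking where p saturates
    probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -60.0, 60.0)))
    return ProbMaps(probs, class_codes, v.spacing, has_disagreement, logits=logits)


def ensemble_median(maps: list[ProbMaps]) -> ProbMaps:
    """Voxel-wise, channel-wise median of several probability maps."""
    if not maps:
        raise ValueError("need at least one probability map")
    first = maps[0]
    for m in maps[1:]:
        if m.data.shape != first.data.shape or m.class_codes != first.class_codes:
            raise GeometryError("probability maps disagree in geometry or classes")
    if len(maps) == 1:
        return first
    data = np.median(np.stack([m.data for m in maps]), axis=0)
    logits = None
    if all(m.logits is not None for m in maps):
        logits = np.median(np.stack([m.logits for m in maps]), axis=0)
    return ProbMaps(data, first.class_codes, first.spacing,
                    first.has_disagreement, logits=logits)


def binarize_softmax(
    maps: ProbMaps,
    code_table: dict[int, str] | None = None,
    rule: str = "softmax_argmax",
) -> tuple[LabelVolume, np.ndarray | None]:
    """Binarize anatomical probability maps into a label volume.

    A synthetic background score ``1 - max(anatomical probabilities)`` is
    appended, the channels are passed through a per-voxel softmax, and
    each voxel takes the arg-max class (ties broken by lowest channel
    index, background last).  The disagreement channel, if present, is
    returned unchanged as a heatmap.  ``rule='threshold'`` instead labels
    a voxel background unless some class probability exceeds 0.5.
    No further postprocessing (filtering, morphology) is applied.
    """
    anat = maps.anatomical
    codes = maps.class_codes
    if code_table is None:
        code_table = {c: f"organ_{c}" for c in codes}
    if maps.logits is not None:
        # rank on logits: sigmoid and softmax are monotone, and logit 0
        # is exactly the p = 0.5 background competitor, so the decisions
        # coincide with the probability formulation but survive float
        # saturation at p = 1
        anat_scores = maps.logits[: len(codes)].astype(np.float64)
        bg = np.zeros((1,) + anat_scores.shape[1:])
    else:
        anat_scores = anat.astype(np.float64)
        bg = 1.0 - anat_scores.max(axis=0, keepdims=True)
    scores = np.concatenate([anat_scores, bg], axis=0)
    if rule == "softmax_argmax":
        scores = scores - scores.max(axis=0, keepdims=True)
        expd = np.exp(scores)
        softmax = expd / expd.sum(axis=0, keepdims=True)
        idx = softmax.argmax(axis=0)
    elif rule == "threshold":
        idx = anat_scores.argmax(axis=0)
        fg = (
            anat_scores.max(axis=0) > 0.0
            if maps.logits is not None
            else anat.max(axis=0) > 0.5
        )
        idx = np.where(fg, idx, len(codes))
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    lut = np.asarray(list(codes) + [0], dtype=np.int32)
    labels = LabelVolume(lut[idx], maps.spacing, code_table)
    heatmap = None if maps.disagreement is None else maps.disagreement.copy()
    return labels, heatmap


# ---------------------------------------------------------------------------
# model persistence


def save_model(net: UNet, path, class_codes: tuple[int, ...],
               code_table: dict[int, str] | None = None,
               has_disagreement: bool = False) -> Path:
    """Store weights, architecture config and the class table in one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "levels": net.cfg.levels,
        "base_channels": net.cfg.base_channels,
        "n_classes": net.cfg.n_classes,
        "in_channels": net.cfg.in_channels,
        "class_codes": list(class_codes),
        "code_table": {str(k): v for k, v in (code_table or {}).items()},
        "has_disagreement": has_disagreement,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_dict())
    return path


def load_model(path) -> tuple[UNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = NetConfig(
            levels=meta["levels"],
            base_channels=meta["base_channels"],
            n_classes=meta["n_classes"],
            in_channels=meta["in_channels"],
        )
        net = UNet(cfg, 0)
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    meta["class_codes"] = tuple(meta["class_codes"])
    meta["code_table"] = {int(k): v for k, v in meta["code_table"].items()}
    return net, meta
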