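"""Preprocessing: coronal slicing, intensity normalization, resampling,
training-slice filtering and 2D augmentation.

The pipeline consumes 2D coronal slices (fixed index along axis 0).  Each
slice is z-score normalized (per slice by default), resampled to the
working resolution, and — during training only — restricted to slices
showing at least one organ voxel and augmented by a random in-plane
rotation and a random crop resized back to the original shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, VoxelVolume

__all__ = [
    "PreprocessConfig",
    "SliceSample",
    "slice_coronal",
    "normalize_intensity",
    "resample_slice",
    "filter_training_slices",
    "augment",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_scale_um: float = 240.0  # working resolution, um per pixel
    rotation_deg: float = 10.0  # augmentation: max |rotation|
    min_crop_area: float = 0.8  # augmentation: min crop area fraction
    normalize_scope: str = "volume"  # "volume" (default) or "slice"

    def __post_init__(self) -> None:
        if self.target_scale_um <= 0:
            raise ValueError("target_scale_um must be positive")
        if not 0 < self.min_crop_area <= 1:
            raise ValueError("min_crop_area must lie in (0, 1]")
        if self.normalize_scope not in ("slice", "volume"):
            raise ValueError("normalize_scope must be 'slice' or 'volume'")


@dataclass
class SliceSample:
    """One coronal slice with optional per-class binary masks.

    ``masks`` has shape (n_classes, H, W) ordered by ``codes``; ``scale``
    is um per pixel along the two in-plane axes.
    """

    image: np.ndarray
    masks: np.ndarray | None
    codes: tuple[int, ...]
    source: tuple[int, int, int]  # (mouse, scan, slice index)
    scale: tuple[float, float]

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError("slice image must be 2D")
        if self.masks is not None:
            self.masks = np.asarray(self.masks, dtype=bool)
            if self.masks.shape != (len(self.codes),) + self.image.shape:
                raise ValueError(
                    f"masks shape {self.masks.shape} does not match "
                    f"{(len(self.codes),) + self.image.shape}"
                )


def slice_coronal(
    v: VoxelVolume,
    labels: LabelVolume | None = None,
    mouse: int = 0,
    scan: int = 0,
    extra_masks: np.ndarray | None = None,
    extra_codes: tuple[int, ...] = (),
) -> list[SliceSample]:
    """Slice a volume along the coronal axis (axis 0), in index order.

    When labels are given, each sample carries one-hot masks per organ
    code.  ``extra_masks`` (shape (n_extra, *v.shape)) appends additional
    target channels (e.g. a disagreement channel) after the organ masks.
    """
    if labels is not None:
        labels.check_geometry(v)
    scale = (v.spacing[1], v.spacing[2])
    samples = []
    codes: tuple[int, ...] = ()
    if labels is not None:
        codes = labels.codes
    for i in range(v.shape[0]):
        masks = None
        if labels is not None:
            plane = labels.data[i]
            masks = np.stack([plane == c for c in codes]) if codes else np.zeros(
                (0,) + plane.shape, bool
            )
            if extra_masks is not None:
                masks = np.concatenate([masks, extra_masks[:, i].astype(bool)])
        samples.append(
            SliceSample(
                v.data[i],
                masks,
                codes + tuple(extra_codes),
                (mouse, scan, i),
                scale,
            )
        )
    return samples


def normalize_intensity(image: np.ndarray, sd_floor: float = 1e-6) -> np.ndarray:
    """Z-score an image: subtract its mean, divide by its standard
    deviation.  Constant images map to all zeros (the sd is floored)."""
    image = np.asarray(image, dtype=np.float32)
    mean = float(image.mean())
    sd = float(image.std())
    return (image - mean) / max(sd, sd_floor)


def resample_slice(s: SliceSample, target_scale: float) -> SliceSample:
    """Resample a slice to ``target_scale`` um/px (bilinear for the image,
    nearest neighbor for masks).  New shape = round(old * old_scale /
    target)."""
    if target_scale <= 0:
        raise ValueError("target_scale must be positive")
    old_shape = np.asarray(s.image.shape)
    new_shape = np.rint(old_shape * np.asarray(s.scale) / target_scale).astype(int)
    if (new_shape < 8).any():
        raise ValueError(
            f"resampling to {target_scale} um/px gives shape {tuple(new_shape)}; "
            "minimum is 8 px per axis"
        )
    if tuple(new_shape) == tuple(old_shape):
        return replace(s, scale=(target_scale, target_scale))
    factors = new_shape / old_shape
    image = ndimage.zoom(s.image, factors, order=1, grid_mode=True, mode="grid-constant")
    image = image[: new_shape[0], : new_shape[1]].astype(np.float32)
    masks = None
    if s.masks is not None:
        masks = np.stack(
            [
                ndimage.zoom(
                    m.astype(np.float32), factors, order=0, grid_mode=True,
                    mode="grid-constant",
                )[: new_shape[0], : new_shape[1]]
                > 0.5
                for m in s.masks
            ]
        ) if len(s.masks) else np.zeros((0, *new_shape), bool)
    return SliceSample(image, masks, s.codes, s.source, (target_scale, target_scale))


def filter_training_slices(samples: list[SliceSample]) -> list[SliceSample]:
    """Keep exactly the slices showing at least one organ voxel (training
    only; at inference every slice of the volume is used)."""
    kept = []
    for s in samples:
        if s.masks is None:
            raise ValueError("filter_training_slices requires masks")
        if s.masks.any():
            kept.append(s)
    if not kept:
        warnings.warn("no slice shows any organ voxel", stacklevel=2)
    return kept


def augment(s: SliceSample, rng: np.random.Generator | int) -> SliceSample:
    """Random in-plane rotation (uniform in +-rotation_deg) followed by a
    random axis-aligned crop with area uniform in [min_crop_area, 1],
    aspect ratio preserved, resized back to the original shape.

    The image is interpolated bilinearly (out-of-bounds filled with 0,
    the normalized background mean); masks use nearest neighbor and stay
    binary.  Deterministic given the generator state / seed.
    """
    if s.masks is None:
        raise ValueError("augment requires masks")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = PreprocessConfig()
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    area = rng.uniform(cfg.min_crop_area, 1.0)
    return _apply_augment(s, angle, area, rng)


def _apply_augment(
    s: SliceSample, angle_deg: float, crop_area: float, rng: np.random.Generator
) -> SliceSample:
    h, w = s.image.shape
    image = s.image
    masks = s.masks
    if angle_deg != 0.0:
        image = ndimage.rotate(
            image, angle_deg, reshape=False, order=1, mode="constant", cval=0.0
        )
        if len(masks):
            masks = ndimage.rotate(
                masks.astype(np.uint8), angle_deg, axes=(1, 2), reshape=False,
                order=0, mode="constant", cval=0,
            ).astype(bool)
    if crop_area < 1.0:
        side = np.sqrt(crop_area)
        ch = max(1, int(round(h * side)))
        cw = max(1, int(round(w * side)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        image = image[top : top + ch, left : left + cw]
        masks = masks[:, top : top + ch, left : left + cw]
        factors = (h / ch, w / cw)
        image = ndimage.zoom(image, factors, order=1, grid_mode=True, mode="grid-constant")
        image = image[:h, :w]
        if len(masks):
            masks = ndimage.zoom(
                masks.astype(np.uint8), (1,) + factors, order=0, grid_mode=True,
                mode="grid-constant",
            )[:, :h, :w].astype(bool)
        else:
            masks = np.zeros((0, h, w), bool)
    return SliceSample(
        image.astype(np.float32), masks.astype(bool), s.codes, s.source, s.scale
    )
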