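"""Segmentation-quality metrics.

All metrics are computed on the reconstructed 3D volume of an entire
scan, one score per organ per scan:

* Dice score, epsilon-smoothed: (2 TP + eps) / (2 TP + FP + FN + eps)
  with eps = 1e-5, so that two empty masks score 1 instead of 0/0.
* Percentile Hausdorff distance: the p-th percentile of the directed
  surface-distance set {min over predicted-surface voxels s_hat of
  ||s_hat - s|| : s on the reference surface}, in physical units (um).
  A voxel belongs to the surface when it has at least one face-adjacent
  (6-connected) background neighbor; voxels on the array boundary count
  as surface.  A symmetric variant pooling both directions is available.
* Center-of-mass displacement: Euclidean distance between the two masks'
  voxel-center centroids in physical units.
* Union-reference Dice: a prediction voxel counts as correct when it
  matches at least one of two annotations; a miss is only charged where
  both annotations agree.
* Disagreement Dice: Dice between a predicted disagreement heatmap
  binarized at 50% and the actual annotator XOR region.

Metrics undefined on empty masks raise :class:`EmptyMaskError`; the
report builder records them as missing values with the reason instead of
coercing to 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import GeometryError, LabelVolume

__all__ = [
    "EPS",
    "ConfusionCounts",
    "EmptyMaskError",
    "dice",
    "surface_voxels",
    "hausdorff_percentile",
    "com_displacement",
    "union_reference_dice",
    "disagreement_mask",
    "disagreement_dice",
    "evaluate_scan",
]

EPS = 1e-5

STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """A distance metric was requested for an empty mask."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def dice(self) -> float:
        return (2.0 * self.tp + EPS) / (2.0 * self.tp + self.fp + self.fn + EPS)


def _as_bool(mask) -> np.ndarray:
    mask = np.asarray(mask)
    return mask if mask.dtype == bool else mask.astype(bool)


def _check_pair(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred, ref = _as_bool(pred), _as_bool(ref)
    if pred.shape != ref.shape:
        raise GeometryError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    return pred, ref


def dice(pred, ref, eps: float = EPS) -> float:
    """Epsilon-smoothed Dice overlap; symmetric in its arguments."""
    pred, ref = _check_pair(pred, ref)
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    return (2.0 * tp + eps) / (2.0 * tp + fp + fn + eps)


def surface_voxels(mask) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background neighbor
    (6-connectivity); array-boundary voxels of the mask are surface."""
    mask = _as_bool(mask)
    if mask.ndim != 3:
        raise ValueError("surface extraction expects a 3D mask")
    eroded = ndimage.binary_erosion(mask, STRUCT_6, border_value=0)
    return mask & ~eroded


def _surface_coords(mask, spacing) -> np.ndarray:
    coords = np.argwhere(surface_voxels(mask)).astype(np.float64)
    return coords * np.asarray(spacing, dtype=np.float64)


def hausdorff_percentile(
    pred, ref, p: float, spacing, symmetric: bool = False
) -> float:
    """p-th percentile (linear interpolation) of surface distances in um.

    Directed by default: distances run from every reference-surface voxel
    to its nearest predicted-surface voxel.  ``symmetric=True`` pools
    both directions before taking the percentile.
    """
    pred, ref = _check_pair(pred, ref)
    if not pred.any():
        raise EmptyMaskError("predicted mask is empty")
    if not ref.any():
        raise EmptyMaskError("reference mask is empty")
    pred_surf = _surface_coords(pred, spacing)
    ref_surf = _surface_coords(ref, spacing)
    dists = cKDTree(pred_surf).query(ref_surf)[0]
    if symmetric:
        back = cKDTree(ref_surf).query(pred_surf)[0]
        dists = np.concatenate([dists, back])
    return float(np.percentile(dists, p))


def com_displacement(pred, ref, spacing) -> float:
    """Euclidean distance between the masks' centers of mass in um."""
    pred, ref = _check_pair(pred, ref)
    if not pred.any():
        raise EmptyMaskError("predicted mask is empty")
    if not ref.any():
        raise EmptyMaskError("reference mask is empty")
    spacing = np.asarray(spacing, dtype=np.float64)
    com_pred = np.argwhere(pred).mean(axis=0) * spacing
    com_ref = np.argwhere(ref).mean(axis=0) * spacing
    return float(np.linalg.norm(com_pred - com_ref))


def union_reference_dice(pred, a1, a2, eps: float = EPS) -> float:
    """Dice against two annotations jointly: a predicted voxel is a true
    positive when it matches at least one annotation and a false negative
    only where both annotations agree on the organ."""
    pred, a1 = _check_pair(pred, a1)
    _, a2 = _check_pair(pred, a2)
    union = a1 | a2
    inter = a1 & a2
    tp = int(np.count_nonzero(pred & union))
    fp = int(np.count_nonzero(pred & ~union))
    fn = int(np.count_nonzero(~pred & inter))
    return (2.0 * tp + eps) / (2.0 * tp + fp + fn + eps)


def disagreement_mask(a1: LabelVolume, a2: LabelVolume) -> np.ndarray:
    """Union over organs of the XOR of the two annotators' masks."""
    a1.check_geometry(a2)
    xor = np.zeros(a1.shape, bool)
    for code in a1.codes:
        xor |= (a1.data == code) ^ (a2.data == code)
    return xor


def disagreement_dice(heatmap, a1: LabelVolume, a2: LabelVolume) -> float:
    """Dice between the heatmap binarized at 50% and the actual
    annotator disagreement."""
    heatmap = np.asarray(heatmap)
    if heatmap.shape != a1.shape:
        raise GeometryError(
            f"heatmap shape {heatmap.shape} does not match labels {a1.shape}"
        )
    return dice(heatmap > 0.5, disagreement_mask(a1, a2))


def evaluate_scan(
    pred: LabelVolume,
    ref: LabelVolume,
    ref2: LabelVolume | None = None,
    heatmap=None,
    percentiles: tuple[float, ...] = (50.0, 95.0),
) -> pd.DataFrame:
    """Per-organ metric report for one scan.

    Columns: organ_code, organ, dice, hd50_um, hd95_um, com_um and, when a
    second annotation is given, interannotator_dice and union_dice; a
    final row (organ_code -1) carries the disagreement Dice when a
    heatmap and a second annotation are supplied.  Metrics undefined on
    empty masks are missing (NaN) with the reason in the ``note`` column.
    """
    pred.check_geometry(ref)
    spacing = ref.spacing
    rows = []
    for code in ref.codes:
        name = ref.code_table.get(code, f"organ_{code}")
        pm = pred.data == code
        rm = ref.data == code
        row = {
            "organ_code": code,
            "organ": name,
            "dice": dice(pm, rm),
            "note": "",
        }
        try:
            for p in percentiles:
                row[f"hd{int(p)}_um"] = hausdorff_percentile(pm, rm, p, spacing)
            row["com_um"] = com_displacement(pm, rm, spacing)
        except EmptyMaskError as exc:
            for p in percentiles:
                row.setdefault(f"hd{int(p)}_um", np.nan)
            row["com_um"] = np.nan
            row["note"] = str(exc)
        if ref2 is not None:
            r2 = ref2.data == code
            row["interannotator_dice"] = dice(rm, r2)
            row["union_dice"] = union_reference_dice(pm, rm, r2)
        rows.append(row)
    if heatmap is not None and ref2 is not None:
        rows.append(
            {
                "organ_code": -1,
                "organ": "disagreement",
                "dice": disagreement_dice(heatmap, ref, ref2),
                "note": "heatmap vs annotator XOR",
            }
        )
    return pd.DataFrame(rows)
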