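"""Organ volumetry, its variability decomposition, and metastasis
allocation.

Volumes are voxel counts times the physical voxel volume (mm^3).  The
variability of organ-volume estimates is decomposed into three sources:

* intersubject: the standard deviation, across mice, of each mouse's
  scan-averaged volume (annotator 1) — natural anatomical variability;
* interannotator: the mean (over mice and scans) of the per-scan
  standard deviation across annotators — subjective annotation bias;
* intraannotator: the mean (over mice) of the per-mouse standard
  deviation across repeat scans by annotator 1 — repositioning plus
  annotation noise.

All three use the population convention (divide by the number of items
under the square root); the literal unnormalized form — the sum of
squared deviations under the root without the 1/N factor — is available
with ``as_printed=True``.  Relative forms divide by the mean organ
volume, giving a "standard deviation relative to average volume".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .volumes import LabelVolume

__all__ = [
    "organ_volume",
    "volumetry_table",
    "intersubject_variability",
    "interannotator_variability",
    "intraannotator_variability",
    "variability_report",
    "allocate_metastases",
    "metastasis_count_error",
    "mean_intensity_projection",
]


def organ_volume(labels: LabelVolume, organ: int) -> float:
    """Volume of one organ in mm^3 (voxel count x voxel volume)."""
    if organ not in labels.code_table:
        raise KeyError(f"unknown organ code {organ}")
    count = int(np.count_nonzero(labels.data == organ))
    return count * labels.voxel_volume_mm3


def volumetry_table(cohort: Cohort) -> pd.DataFrame:
    """Long-format organ volumes: one row per (mouse, scan, annotator,
    organ), columns mouse, scan, annotator, organ_code, organ,
    volume_mm3."""
    rows = []
    for s in cohort.scans:
        for a, lab in sorted(s.labels.items()):
            for code in cohort.codes:
                rows.append(
                    {
                        "mouse": s.mouse,
                        "scan": s.scan,
                        "annotator": a,
                        "organ_code": code,
                        "organ": cohort.code_table[code],
                        "volume_mm3": organ_volume(lab, code)
                        if code in lab.code_table
                        else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _pop_sd(values: np.ndarray, as_printed: bool) -> float:
    dev = values - values.mean()
    ss = float((dev**2).sum())
    return np.sqrt(ss) if as_printed else np.sqrt(ss / len(values))


def _organ_frame(tab: pd.DataFrame, organ: int) -> pd.DataFrame:
    sub = tab[tab["organ_code"] == organ].dropna(subset=["volume_mm3"])
    if sub.empty:
        raise ValueError(f"no volumes for organ code {organ}")
    return sub


def intersubject_variability(
    tab: pd.DataFrame, organ: int, relative: bool = False, as_printed: bool = False
) -> float:
    """Standard deviation across mice of the scan-mean volume (annotator 1)."""
    sub = _organ_frame(tab, organ)
    sub = sub[sub["annotator"] == 1]
    per_mouse = sub.groupby("mouse")["volume_mm3"].mean()
    if len(per_mouse) < 2:
        raise ValueError("intersubject variability needs at least 2 mice")
    out = _pop_sd(per_mouse.to_numpy(), as_printed)
    if relative:
        out /= per_mouse.to_numpy().mean()
    return float(out)


def interannotator_variability(
    tab: pd.DataFrame, organ: int, relative: bool = False, as_printed: bool = False
) -> float:
    """Mean over scans of the per-scan volume sd across annotators.

    Scans lacking a second annotation are excluded (with a warning when
    any are dropped); invariant under permuting the annotator labels."""
    import warnings

    sub = _organ_frame(tab, organ)
    n_annot = sub.groupby(["mouse", "scan"])["annotator"].nunique()
    incomplete = n_annot[n_annot < 2]
    if len(incomplete):
        warnings.warn(
            f"{len(incomplete)} scan(s) lack a second annotation and are "
            "excluded from interannotator variability",
            stacklevel=2,
        )
    keep = n_annot[n_annot >= 2].index
    if not len(keep):
        raise ValueError("no scan has two annotations")
    sub = sub.set_index(["mouse", "scan"]).loc[keep].reset_index()
    per_scan = sub.groupby(["mouse", "scan"])["volume_mm3"].apply(
        lambda v: _pop_sd(v.to_numpy(), as_printed)
    )
    # mean over scans within mouse, then over mice (equal weight per mouse)
    out = per_scan.groupby("mouse").mean().mean()
    if relative:
        ref = sub[sub["annotator"] == 1]["volume_mm3"].mean()
        out /= ref
    return float(out)


def intraannotator_variability(
    tab: pd.DataFrame, organ: int, relative: bool = False, as_printed: bool = False
) -> float:
    """Mean over mice of the volume sd across repeat scans (annotator 1)."""
    sub = _organ_frame(tab, organ)
    sub = sub[sub["annotator"] == 1]
    n_scans = sub.groupby("mouse")["scan"].nunique()
    if (n_scans < 2).all():
        raise ValueError("intraannotator variability needs repeat scans")
    per_mouse = (
        sub.groupby("mouse")["volume_mm3"]
        .apply(lambda v: _pop_sd(v.to_numpy(), as_printed) if len(v) > 1 else np.nan)
        .dropna()
    )
    out = per_mouse.mean()
    if relative:
        out /= sub["volume_mm3"].mean()
    return float(out)


def variability_report(tab: pd.DataFrame, as_printed: bool = False) -> pd.DataFrame:
    """Per-organ volumetry summary: mean volume plus the three
    variability measures, absolute (mm^3) and relative (fraction of the
    mean volume)."""
    rows = []
    for code, grp in tab.groupby("organ_code"):
        ref = grp[grp["annotator"] == 1]["volume_mm3"]
        row = {
            "organ_code": code,
            "organ": grp["organ"].iloc[0],
            "mean_volume_mm3": float(ref.mean()),
        }
        for name, fn in [
            ("intersubject", intersubject_variability),
            ("interannotator", interannotator_variability),
            ("intraannotator", intraannotator_variability),
        ]:
            try:
                row[name + "_mm3"] = fn(tab, code, as_printed=as_printed)
                row[name + "_rel"] = fn(tab, code, relative=True, as_printed=as_printed)
            except ValueError:
                row[name + "_mm3"] = np.nan
                row[name + "_rel"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def allocate_metastases(points: pd.DataFrame, seg: LabelVolume,
                        column: str = "allocated_code") -> pd.DataFrame:
    """Assign each metastasis point the label of its containing voxel
    (floor of the continuous voxel coordinates; 0 = unallocated)."""
    coords = points[["x0", "x1", "x2"]].to_numpy(dtype=np.float64)
    idx = np.floor(coords).astype(np.int64)
    shape = np.asarray(seg.shape)
    if (idx < 0).any() or (idx >= shape).any():
        bad = np.argwhere((idx < 0).any(axis=1) | (idx >= shape).any(axis=1))[:, 0]
        raise ValueError(f"points outside the grid at rows {bad.tolist()}")
    out = points.copy()
    out[column] = seg.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def metastasis_count_error(
    alloc: pd.DataFrame, organ: int,
    truth_col: str = "true_code", alloc_col: str = "allocated_code",
) -> tuple[int, float]:
    """Allocated metastasis count for one organ and the relative error to
    the true count (NaN when the true count is zero)."""
    if truth_col not in alloc.columns:
        raise ValueError(f"missing truth column {truth_col!r}")
    count = int((alloc[alloc_col] == organ).sum())
    true_count = int((alloc[truth_col] == organ).sum())
    if true_count == 0:
        return count, float("nan")
    return count, abs(count - true_count) / true_count


def mean_intensity_projection(data: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean-intensity projection along one axis (dorsoventral by default);
    a simple visualization aid for overlaying segmentations."""
    return np.asarray(data, dtype=np.float64).mean(axis=axis)
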