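"""NIfTI input/output and cohort indexing.

Volumes are stored on disk as NIfTI-1 (``.nii``/``.nii.gz``) with voxel
spacing carried by the header in millimeters (the NIfTI convention);
in memory spacing is micrometers.  Images are reoriented to the closest
canonical (RAS-like) axis ordering on load so that the in-memory axis
convention of :mod:`organseg.volumes` is consistent regardless of the
on-disk affine.  Intensities are always loaded as 32-bit floats; labels
as integers.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Cohort, Scan
from .volumes import GeometryError, LabelVolume, VoxelVolume

__all__ = [
    "read_volume",
    "read_labels",
    "write_volume",
    "index_cohort",
    "write_cohort",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["mouse", "scan", "annotator", "image_path", "label_path"]


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(os.fspath(path))
    img = nib.as_closest_canonical(img)
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    spacing_mm = img.header.get_zooms()[:3]
    spacing_um = tuple(float(z) * 1000.0 for z in spacing_mm)
    return data, spacing_um


def read_volume(path) -> VoxelVolume:
    """Read an intensity volume; header zooms (mm) become spacing in um."""
    data, spacing = _load_canonical(path)
    data = np.asarray(data, dtype=np.float32)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite values")
    return VoxelVolume(data, spacing)


def read_labels(path, code_table: dict[int, str] | None = None) -> LabelVolume:
    """Read a label volume; codes are rounded to the nearest integer."""
    data, spacing = _load_canonical(path)
    idata = np.rint(np.asarray(data)).astype(np.int32)
    if code_table is None:
        present = sorted(int(c) for c in np.unique(idata) if c != 0)
        code_table = {c: f"organ_{c}" for c in present}
    return LabelVolume(idata, spacing, code_table)


def write_volume(v: VoxelVolume | LabelVolume, path) -> Path:
    """Write a volume as NIfTI; labels are stored as int16, images as float32."""
    path = Path(path)
    spacing_mm = np.asarray(v.spacing, dtype=np.float64) / 1000.0
    affine = np.diag(np.append(spacing_mm, 1.0))
    if isinstance(v, LabelVolume):
        data = v.data.astype(np.int16)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing_mm)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, os.fspath(path))
    return path


def index_cohort(manifest, code_table: dict[int, str] | None = None) -> Cohort:
    """Build a :class:`Cohort` from a manifest CSV.

    The manifest has columns ``mouse,scan,annotator,image_path,label_path``;
    relative paths are resolved against the manifest's directory.  Each
    (mouse, scan) pair must reference a single image; every label volume
    must match its image's geometry exactly.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    dup = df.duplicated(subset=["mouse", "scan", "annotator"])
    if dup.any():
        rows = df.loc[dup, ["mouse", "scan", "annotator"]].to_records(index=False)
        raise ValueError(f"duplicate (mouse, scan, annotator) rows: {list(rows)}")

    root = manifest.parent

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else root / p

    scans: list[Scan] = []
    merged_codes: dict[int, str] = dict(code_table or {})
    for (mouse, scan), grp in df.groupby(["mouse", "scan"], sort=True):
        image_paths = set(grp["image_path"])
        if len(image_paths) != 1:
            raise ValueError(
                f"scan ({mouse}, {scan}) references several images: {sorted(image_paths)}"
            )
        volume = read_volume(_resolve(image_paths.pop()))
        labels: dict[int, LabelVolume] = {}
        for _, row in grp.iterrows():
            lab = read_labels(_resolve(row["label_path"]), code_table)
            try:
                lab.check_geometry(volume)
            except GeometryError as exc:
                raise GeometryError(
                    f"scan ({mouse}, {scan}) annotator {row['annotator']}: {exc}"
                ) from exc
            labels[int(row["annotator"])] = lab
            for c, name in lab.code_table.items():
                merged_codes.setdefault(c, name)
        scans.append(Scan(int(mouse), int(scan), volume, labels))
    return Cohort(scans, merged_codes)


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write every scan of a cohort as NIfTI plus a manifest CSV.

    Files are named ``mouse{m}_scan{t}.nii.gz`` and
    ``mouse{m}_scan{t}_annot{a}.nii.gz``.  Returns the manifest path; if
    the cohort carries a metastasis table it is written next to it as
    ``metastases.csv`` (columns x,y,z in voxel coordinates plus the true
    organ code).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.scans:
        image_name = f"mouse{s.mouse}_scan{s.scan}.nii.gz"
        write_volume(s.volume, outdir / image_name)
        for a, lab in sorted(s.labels.items()):
            label_name = f"mouse{s.mouse}_scan{s.scan}_annot{a}.nii.gz"
            write_volume(lab, outdir / label_name)
            rows.append(
                {
                    "mouse": s.mouse,
                    "scan": s.scan,
                    "annotator": a,
                    "image_path": image_name,
                    "label_path": label_name,
                }
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    codes = pd.DataFrame(
        sorted(cohort.code_table.items()), columns=["code", "organ"]
    )
    codes.to_csv(outdir / "codes.csv", index=False)
    if cohort.metastases is not None:
        cohort.metastases.to_csv(outdir / "metastases.csv", index=False)
    return manifest
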