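"""Core in-memory containers for volumetric scans and label maps.

Axis convention (fixed package-wide): axis 0 is dorsoventral (a "coronal
slice" is a fixed index along axis 0), axis 1 is rostrocaudal, axis 2 is
left-right.  Voxel coordinates are 0-based array indices; the physical
position of a voxel center is ``index * spacing`` with spacing in
micrometers per voxel along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "LabelVolume", "ProbMaps", "GeometryError"]


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing}")
    return spacing


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with per-axis voxel spacing in micrometers."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in cubic millimeters."""
        um3 = float(np.prod(self.spacing))
        return um3 / 1e9


@dataclass
class LabelVolume:
    """A 3D integer grid; 0 is background, positive codes are organ classes."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    code_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be an integer array")
        self.data = self.data.astype(np.int32, copy=False)
        if self.data.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.code_table = {int(k): str(v) for k, v in self.code_table.items()}
        if any(k <= 0 for k in self.code_table):
            raise ValueError("label codes must be positive")
        present = set(np.unique(self.data)) - {0}
        if self.code_table and not present <= set(self.code_table):
            raise ValueError(
                f"labels contain codes {sorted(present - set(self.code_table))} "
                "absent from the code table"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def codes(self) -> tuple[int, ...]:
        """Organ codes in ascending order (the canonical class order)."""
        return tuple(sorted(self.code_table))

    @property
    def voxel_volume_mm3(self) -> float:
        um3 = float(np.prod(self.spacing))
        return um3 / 1e9

    def mask(self, code: int) -> np.ndarray:
        if code not in self.code_table:
            raise KeyError(f"unknown organ code {code}")
        return self.data == code

    def check_geometry(self, other) -> None:
        if self.data.shape != other.data.shape:
            raise GeometryError(
                f"grid shapes differ: {self.data.shape} vs {other.data.shape}"
            )
        if not np.allclose(self.spacing, other.spacing, rtol=1e-5):
            raise GeometryError(
                f"spacings differ: {self.spacing} vs {other.spacing}"
            )


@dataclass
class ProbMaps:
    """Per-class probability grids in [0, 1].

    ``data`` has shape (n_channels, *grid_shape).  The first
    ``len(class_codes)`` channels are anatomical classes in ``class_codes``
    order; when ``has_disagreement`` is set the last channel is the
    annotator-disagreement heatmap (kept out of any mutual-exclusivity
    rule).
    """

    data: np.ndarray
    class_codes: tuple[int, ...]
    spacing: tuple[float, float, float]
    has_disagreement: bool = False
    # optional pre-sigmoid scores with the same layout as ``data``; they
    # preserve the class ranking where float probabilities saturate at 1
    logits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("ProbMaps data must be (channels, z, y, x)")
        self.class_codes = tuple(int(c) for c in self.class_codes)
        expected = len(self.class_codes) + (1 if self.has_disagreement else 0)
        if self.data.shape[0] != expected:
            raise ValueError(
                f"expected {expected} channels, got {self.data.shape[0]}"
            )
        self.spacing = _check_spacing(self.spacing)
        if self.data.size and (self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.logits is not None:
            self.logits = np.asarray(self.logits, dtype=np.float32)
            if self.logits.shape != self.data.shape:
                raise ValueError("logits must match the probability layout")

    @property
    def anatomical(self) -> np.ndarray:
        return self.data[: len(self.class_codes)]

    @property
    def disagreement(self) -> np.ndarray | None:
        return self.data[-1] if self.has_disagreement else None
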