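"""Cohort container: subjects ("mice") -> scans ("timepoints") -> annotations.

A cohort indexes one intensity volume per (mouse, scan) plus one label
volume per annotator.  Annotator 1 is the reference annotation by
convention; a second annotator is optional and may cover only a subset of
subjects, mirroring real studies where only some scans are annotated twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .volumes import LabelVolume, VoxelVolume

__all__ = ["Scan", "Cohort"]


@dataclass
class Scan:
    mouse: int
    scan: int
    volume: VoxelVolume
    labels: dict[int, LabelVolume]  # annotator index (1-based) -> labels

    def __post_init__(self) -> None:
        for a, lab in self.labels.items():
            if a < 1:
                raise ValueError("annotator indices are 1-based")
            lab.check_geometry(self.volume)


@dataclass
class Cohort:
    scans: list[Scan]
    code_table: dict[int, str]
    metastases: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.scans:
            for a in s.labels:
                key = (s.mouse, s.scan, a)
                if key in seen:
                    raise ValueError(f"duplicate (mouse, scan, annotator) {key}")
                seen.add(key)
        if not self.scans:
            raise ValueError("cohort has no scans")

    @property
    def subjects(self) -> tuple[int, ...]:
        return tuple(sorted({s.mouse for s in self.scans}))

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(sorted(self.code_table))

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.scans[0].volume.spacing

    def scans_of(self, mouse: int) -> list[Scan]:
        return sorted((s for s in self.scans if s.mouse == mouse), key=lambda s: s.scan)

    def get(self, mouse: int, scan: int) -> Scan:
        for s in self.scans:
            if s.mouse == mouse and s.scan == scan:
                return s
        raise KeyError(f"no scan ({mouse}, {scan}) in cohort")

    def n_annotators(self, mouse: int) -> int:
        return max(max(s.labels) for s in self.scans_of(mouse))

    def __len__(self) -> int:
        return len(self.scans)
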