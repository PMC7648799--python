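"""Synthetic mouse-like phantom cohorts.

The generator emulates the statistical structure of a whole-body imaging
study: a cohort of mice, each scanned at several timepoints after being
repositioned (rigid posture jitter), with several organs of differing
contrast — including one deliberately low-contrast organ standing in for
the spleen — and two annotators whose label volumes differ by a
systematic boundary bias plus random boundary noise.  Organs are
ellipsoids evaluated analytically under the rigid transform, so true
organ volumes are invariant across scans up to voxel discretization and
voxel counts have brute-force oracles.

Annotator 1 is the unperturbed ground truth by convention; annotator 2
is derived from it by per-organ morphological dilation/erosion (the
systematic bias) followed by random flips of boundary-shell voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import Cohort, Scan
from .volumes import LabelVolume, VoxelVolume

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "GenerationError",
    "generate_phantom",
    "simulate_annotator",
    "sample_metastases",
    "build_cohort",
    "default_spec",
]

# 6-connectivity: face-adjacent neighbors only, matching the surface
# definition used by the evaluation metrics.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class GenerationError(RuntimeError):
    """An organ does not fit inside the grid after posture jitter."""


@dataclass(frozen=True)
class OrganSpec:
    code: int
    name: str
    center: tuple[float, float, float]  # voxel coordinates in the reference pose
    semi_axes: tuple[float, float, float]  # voxels
    mean_intensity: float
    intensity_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.code <= 0:
            raise ValueError("organ codes must be positive")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"{self.name}: semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort; same seed => identical cohort."""

    grid_shape: tuple[int, int, int] = (64, 64, 96)
    voxel_spacing: tuple[float, float, float] = (240.0, 240.0, 240.0)  # um
    organs: tuple[OrganSpec, ...] = ()
    background_intensity: float = 100.0
    background_noise_sd: float = 10.0
    # unlabeled soft-tissue "body" the organs sit inside; like real scans
    # it may be cropped by the field of view, so it is exempt from the
    # escape check.  None disables it.
    body_center: tuple[float, float, float] | None = None
    body_semi_axes: tuple[float, float, float] | None = None
    body_intensity: float = 160.0
    low_contrast_labels: frozenset[int] = frozenset()
    n_mice: int = 6
    scans_per_mouse: int = 2
    jitter_shift_vx: float = 3.0  # max rigid shift per axis between scans
    jitter_rot_deg: float = 8.0  # max in-plane rotation (about the coronal axis)
    shape_variability: float = 0.08  # per-mouse sd of semi-axis scale factors
    center_jitter_vx: float = 1.5  # per-mouse max offset of each organ center
    n_annotators: int = 2
    annotator2_bias: dict[int, int] = field(default_factory=dict)  # code -> voxels
    annotator_noise_sd: float = 0.0  # probability of flipping a boundary voxel
    mets_per_organ: int = 5
    mets_background: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        codes = [o.code for o in self.organs]
        if len(codes) != len(set(codes)):
            raise ValueError("organ codes must be unique")
        if self.n_mice < 1 or self.scans_per_mouse < 1:
            raise ValueError("need at least one mouse and one scan")
        if self.n_annotators not in (1, 2):
            raise ValueError("n_annotators must be 1 or 2")
        if self.annotator_noise_sd < 0:
            raise ValueError("annotator_noise_sd must be >= 0")

    @property
    def code_table(self) -> dict[int, str]:
        return {o.code: o.name for o in self.organs}

    def validate_fit(self) -> None:
        """Conservative check that every organ stays inside the grid
        under maximal posture jitter and 3-sigma shape variation."""
        center = (np.asarray(self.grid_shape, float) - 1) / 2.0
        theta = np.deg2rad(self.jitter_rot_deg)
        for organ in self.organs:
            c = np.asarray(organ.center, float)
            a = np.asarray(organ.semi_axes, float)
            scale = 1.0 + 3.0 * self.shape_variability
            r = np.linalg.norm((c - center)[1:])
            rot_disp = 2.0 * r * np.sin(theta / 2.0)
            reach = (
                a.max() * scale
                + self.jitter_shift_vx
                + self.center_jitter_vx
                + rot_disp
                + 1.0
            )
            lo = c - reach
            hi = c + reach
            if (lo < 0).any() or (hi > np.asarray(self.grid_shape) - 1).any():
                raise GenerationError(
                    f"organ '{organ.name}' (code {organ.code}) may escape the "
                    f"grid under maximal jitter"
                )


def default_spec(**overrides) -> PhantomSpec:
    """The standard study conditions: 4 organs (one spleen-like,
    low-contrast), 6 mice x 2 scans on a 64x64x96 grid at 240 um."""
    organs = (
        OrganSpec(1, "heart", (32.0, 32.0, 24.0), (8.0, 7.0, 7.0), 300.0),
        OrganSpec(2, "liver", (32.0, 30.0, 48.0), (10.0, 12.0, 14.0), 220.0),
        OrganSpec(3, "kidney", (32.0, 42.0, 74.0), (6.0, 5.0, 7.0), 350.0),
        # spleen analog: mean within one noise sd of the surrounding body
        OrganSpec(4, "spleen", (32.0, 19.0, 70.0), (6.0, 5.0, 6.0), 150.0),
    )
    spec = PhantomSpec(
        organs=organs,
        body_center=(32.0, 32.0, 48.0),
        body_semi_axes=(30.0, 26.0, 45.0),
        low_contrast_labels=frozenset({4}),
        annotator2_bias={4: 1},
        annotator_noise_sd=0.05,
    )
    return replace(spec, **overrides) if overrides else spec


def _mouse_params(spec: PhantomSpec, mouse_index: int):
    """Per-mouse organ geometry: scaled semi-axes and shifted centers,
    constant across all scans of that mouse."""
    rng = np.random.default_rng([spec.seed, 17, mouse_index])
    params = []
    for organ in spec.organs:
        scales = 1.0 + spec.shape_variability * rng.standard_normal(3)
        scales = np.clip(scales, 1.0 - 3 * spec.shape_variability, 1.0 + 3 * spec.shape_variability)
        offset = rng.uniform(-spec.center_jitter_vx, spec.center_jitter_vx, size=3)
        params.append(
            (
                np.asarray(organ.center, float) + offset,
                np.asarray(organ.semi_axes, float) * scales,
            )
        )
    return params


def _scan_pose(spec: PhantomSpec, mouse_index: int, scan_index: int):
    """Rigid posture: per-axis shift plus in-plane rotation angle (radians)."""
    rng = np.random.default_rng([spec.seed, 29, mouse_index, scan_index])
    shift = rng.uniform(-spec.jitter_shift_vx, spec.jitter_shift_vx, size=3)
    theta = np.deg2rad(rng.uniform(-spec.jitter_rot_deg, spec.jitter_rot_deg))
    return shift, theta


def _organ_mask(grid_shape, center, semi_axes, shift, theta) -> np.ndarray:
    """Voxels whose centers fall inside the rigidly moved ellipsoid.

    The rigid transform rotates the whole body about the grid center in
    the plane of axes (1, 2) and then translates it; the mask is obtained
    by pulling each voxel back into the reference pose and testing the
    ellipsoid inequality, so no resampling occurs.
    """
    g = (np.asarray(grid_shape, float) - 1) / 2.0
    idx = np.indices(grid_shape, dtype=np.float64)
    # inverse translate, then inverse rotate about the grid center
    p0 = idx[0] - shift[0]
    p1 = idx[1] - shift[1] - g[1]
    p2 = idx[2] - shift[2] - g[2]
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    q1 = cos_t * p1 + sin_t * p2 + g[1]
    q2 = -sin_t * p1 + cos_t * p2 + g[2]
    d = (
        ((p0 - center[0]) / semi_axes[0]) ** 2
        + ((q1 - center[1]) / semi_axes[1]) ** 2
        + ((q2 - center[2]) / semi_axes[2]) ** 2
    )
    return d <= 1.0


def generate_phantom(
    spec: PhantomSpec, mouse_index: int, scan_index: int
) -> tuple[VoxelVolume, LabelVolume]:
    """Generate the intensity volume and ground-truth labels of one scan.

    Organs of one mouse keep identical shape parameters across scans and
    differ only by the rigid posture jitter.  Deterministic given
    (spec.seed, mouse_index, scan_index).
    """
    if not (1 <= mouse_index <= spec.n_mice):
        raise ValueError(f"mouse index {mouse_index} outside 1..{spec.n_mice}")
    if not (1 <= scan_index <= spec.scans_per_mouse):
        raise ValueError(f"scan index {scan_index} outside 1..{spec.scans_per_mouse}")

    params = _mouse_params(spec, mouse_index)
    shift, theta = _scan_pose(spec, mouse_index, scan_index)

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    intensity = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    noise_sd = np.full(spec.grid_shape, spec.background_noise_sd, dtype=np.float64)
    if spec.body_semi_axes is not None:
        body = _organ_mask(
            spec.grid_shape, spec.body_center, spec.body_semi_axes, shift, theta
        )
        intensity[body] = spec.body_intensity
    for organ, (center, semi_axes) in zip(spec.organs, params):
        mask = _organ_mask(spec.grid_shape, center, semi_axes, shift, theta)
        if not mask.any():
            raise GenerationError(f"organ '{organ.name}' produced an empty mask")
        border = np.zeros(spec.grid_shape, bool)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        if (mask & border).any():
            raise GenerationError(
                f"organ '{organ.name}' (code {organ.code}) escaped the grid "
                f"after posture jitter in scan ({mouse_index}, {scan_index})"
            )
        fresh = mask & (labels == 0)
        labels[fresh] = organ.code
        intensity[fresh] = organ.mean_intensity
        noise_sd[fresh] = organ.intensity_noise_sd

    rng = np.random.default_rng([spec.seed, 43, mouse_index, scan_index])
    intensity = intensity + noise_sd * rng.standard_normal(spec.grid_shape)
    volume = VoxelVolume(intensity.astype(np.float32), spec.voxel_spacing)
    label_volume = LabelVolume(labels, spec.voxel_spacing, spec.code_table)
    return volume, label_volume


def simulate_annotator(
    truth: LabelVolume,
    bias_vx: dict[int, int] | None,
    noise_sd: float,
    seed: int,
) -> LabelVolume:
    """Derive a second annotator's labels from the ground truth.

    Each organ is dilated (positive bias) or eroded (negative bias) by
    ``bias_vx[code]`` voxels using 6-connected morphology, then each voxel
    of the one-voxel boundary shell is flipped independently with
    probability ``noise_sd``.  Overlaps between perturbed organs are
    resolved in ascending code order.  Deterministic given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    bias_vx = bias_vx or {}
    rng = np.random.default_rng(seed)
    out = np.zeros_like(truth.data)
    for code in truth.codes:
        mask = truth.data == code
        b = int(bias_vx.get(code, 0))
        if b > 0:
            mask = ndimage.binary_dilation(mask, STRUCT_6, iterations=b)
        elif b < 0:
            mask = ndimage.binary_erosion(mask, STRUCT_6, iterations=-b)
        if noise_sd > 0:
            outer = ndimage.binary_dilation(mask, STRUCT_6) & ~mask
            inner = mask & ~ndimage.binary_erosion(mask, STRUCT_6)
            add = outer & (rng.random(truth.data.shape) < noise_sd)
            remove = inner & (rng.random(truth.data.shape) < noise_sd)
            mask = (mask | add) & ~remove
        out[(out == 0) & mask] = code
    return LabelVolume(out, truth.spacing, truth.code_table)


def sample_metastases(
    truth: LabelVolume,
    n_per_organ: int,
    n_background: int,
    seed: int,
) -> pd.DataFrame:
    """Sample metastasis point coordinates inside each organ plus some
    background points; coordinates are continuous voxel coordinates whose
    floor is the containing voxel.  Columns: x0, x1, x2, true_code."""
    rng = np.random.default_rng(seed)
    rows = []
    for code in list(truth.codes) + [0]:
        n = n_background if code == 0 else n_per_organ
        if n == 0:
            continue
        voxels = np.argwhere(truth.data == code)
        if len(voxels) == 0:
            continue
        picks = voxels[rng.integers(0, len(voxels), size=n)]
        coords = picks + rng.random((n, 3))
        for c in coords:
            rows.append({"x0": c[0], "x1": c[1], "x2": c[2], "true_code": code})
    return pd.DataFrame(rows, columns=["x0", "x1", "x2", "true_code"])


def build_cohort(spec: PhantomSpec) -> Cohort:
    """Generate the full cohort: n_mice x scans_per_mouse scans, each with
    the ground-truth annotation (annotator 1) and, when two annotators are
    requested, a biased/noisy second annotation.  A metastasis table is
    sampled from the ground truth of every scan."""
    spec.validate_fit()
    scans = []
    met_rows = []
    for m in range(1, spec.n_mice + 1):
        for t in range(1, spec.scans_per_mouse + 1):
            volume, truth = generate_phantom(spec, m, t)
            labels = {1: truth}
            if spec.n_annotators == 2:
                annot_seed = np.random.SeedSequence(
                    [spec.seed, 57, m, t]
                ).generate_state(1)[0] % (2**31)
                labels[2] = simulate_annotator(
                    truth, spec.annotator2_bias, spec.annotator_noise_sd, int(annot_seed)
                )
            scans.append(Scan(m, t, volume, labels))
            if spec.mets_per_organ or spec.mets_background:
                met_seed = np.random.SeedSequence(
                    [spec.seed, 71, m, t]
                ).generate_state(1)[0] % (2**31)
                mets = sample_metastases(
                    truth, spec.mets_per_organ, spec.mets_background, int(met_seed)
                )
                mets.insert(0, "scan", t)
                mets.insert(0, "mouse", m)
                met_rows.append(mets)
    metastases = pd.concat(met_rows, ignore_index=True) if met_rows else None
    return Cohort(scans, spec.code_table, metastases)
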