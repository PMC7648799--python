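"""Organ volumetry, variability decomposition, metastasis allocation."""

import numpy as np
import pandas as pd
import pytest

from organseg.volumetry import (
    allocate_metastases,
    interannotator_variability,
    intersubject_variability,
    intraannotator_variability,
    metastasis_count_error,
    organ_volume,
    variability_report,
    volumetry_table,
)
from organseg.volumes import LabelVolume

MM3_PER_VOXEL = 0.24**3  # 240 um isotropic


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["mouse", "scan", "annotator", "organ_code", "organ", "volume_mm3"]
    )


def row(m, t, a, v, code=1):
    return (m, t, a, code, "organ", v)


class TestOrganVolume:
    def test_empty_organ_zero(self):
        lab = LabelVolume(np.zeros((4, 4, 4), np.int32), (240.0,) * 3, {1: "a"})
        assert organ_volume(lab, 1) == 0.0

    def test_unit_arithmetic(self):
        data = np.zeros((10, 10, 10), np.int32)
        data.ravel()[:1000] = 1
        lab = LabelVolume(data, (240.0,) * 3, {1: "a"})
        assert organ_volume(lab, 1) == pytest.approx(1000 * 0.013824)

    def test_ellipsoid_volume_near_analytic(self, tiny_cohort):
        lab = tiny_cohort.get(1, 1).labels[1]
        count = int((lab.data == 1).sum())
        assert organ_volume(lab, 1) == pytest.approx(count * MM3_PER_VOXEL)
        # heart semi-axes ~(5, 4, 4) vx, per-mouse scale ±3 sd of 5%
        analytic = 4 / 3 * np.pi * 5 * 4 * 4 * MM3_PER_VOXEL
        assert organ_volume(lab, 1) == pytest.approx(analytic, rel=0.35)

    def test_unknown_code(self):
        lab = LabelVolume(np.zeros((4, 4, 4), np.int32), (240.0,) * 3, {1: "a"})
        with pytest.raises(KeyError):
            organ_volume(lab, 9)


class TestIntersubject:
    def test_identical_mice_zero(self):
        tab = make_table([row(m, t, 1, 10.0) for m in (1, 2, 3) for t in (1, 2)])
        assert intersubject_variability(tab, 1) == 0.0

    def test_two_mice_population_sd(self):
        tab = make_table([row(1, 1, 1, 10.0), row(2, 1, 1, 14.0)])
        assert intersubject_variability(tab, 1) == pytest.approx(2.0)
        # as-printed form omits the 1/M factor under the root
        assert intersubject_variability(tab, 1, as_printed=True) == pytest.approx(
            np.sqrt(8.0)
        )

    def test_translation_invariance_of_absolute_form(self):
        tab1 = make_table([row(1, 1, 1, 10.0), row(2, 1, 1, 14.0)])
        tab2 = make_table([row(1, 1, 1, 110.0), row(2, 1, 1, 114.0)])
        assert intersubject_variability(tab1, 1) == pytest.approx(
            intersubject_variability(tab2, 1)
        )

    def test_scan_mean_taken_first(self):
        tab = make_table(
            [row(1, 1, 1, 8.0), row(1, 2, 1, 12.0), row(2, 1, 1, 14.0), row(2, 2, 1, 14.0)]
        )
        # per-mouse means 10 and 14 -> population sd 2
        assert intersubject_variability(tab, 1) == pytest.approx(2.0)

    def test_single_mouse_rejected(self):
        tab = make_table([row(1, 1, 1, 10.0)])
        with pytest.raises(ValueError):
            intersubject_variability(tab, 1)


class TestInterannotator:
    def test_identical_annotators_zero(self):
        tab = make_table(
            [row(1, 1, a, 9.0) for a in (1, 2)] + [row(1, 2, a, 11.0) for a in (1, 2)]
        )
        assert interannotator_variability(tab, 1) == 0.0

    def test_single_scan_hand_value(self):
        tab = make_table([row(1, 1, 1, 8.0), row(1, 1, 2, 12.0)])
        assert interannotator_variability(tab, 1) == pytest.approx(2.0)

    def test_annotator_permutation_symmetric(self):
        tab = make_table([row(1, 1, 1, 8.0), row(1, 1, 2, 12.0)])
        swapped = make_table([row(1, 1, 1, 12.0), row(1, 1, 2, 8.0)])
        assert interannotator_variability(tab, 1) == pytest.approx(
            interannotator_variability(swapped, 1)
        )

    def test_scans_without_second_annotation_excluded(self):
        tab = make_table(
            [row(1, 1, 1, 8.0), row(1, 1, 2, 12.0), row(1, 2, 1, 100.0)]
        )
        with pytest.warns(UserWarning, match="second annotation"):
            out = interannotator_variability(tab, 1)
        assert out == pytest.approx(2.0)


class TestIntraannotator:
    def test_constant_over_time_zero(self):
        tab = make_table([row(1, t, 1, 10.0) for t in (1, 2, 3)])
        assert intraannotator_variability(tab, 1) == 0.0

    def test_two_scan_hand_value(self):
        tab = make_table([row(1, 1, 1, 9.0), row(1, 2, 1, 11.0)])
        assert intraannotator_variability(tab, 1) == pytest.approx(1.0)

    def test_homogeneity_and_relative_invariance(self):
        tab = make_table([row(1, 1, 1, 9.0), row(1, 2, 1, 11.0)])
        scaled = make_table([row(1, 1, 1, 27.0), row(1, 2, 1, 33.0)])
        assert intraannotator_variability(scaled, 1) == pytest.approx(
            3 * intraannotator_variability(tab, 1)
        )
        assert intraannotator_variability(scaled, 1, relative=True) == pytest.approx(
            intraannotator_variability(tab, 1, relative=True)
        )

    def test_needs_repeat_scans(self):
        tab = make_table([row(1, 1, 1, 10.0), row(2, 1, 1, 12.0)])
        with pytest.raises(ValueError):
            intraannotator_variability(tab, 1)


class TestVariabilityReport:
    def test_report_covers_all_organs(self, tiny_cohort):
        tab = volumetry_table(tiny_cohort)
        rep = variability_report(tab)
        assert sorted(rep["organ_code"]) == sorted(tiny_cohort.codes)
        assert (rep["mean_volume_mm3"] > 0).all()
        assert {"intersubject_rel", "interannotator_rel", "intraannotator_rel"} <= set(
            rep.columns
        )


class TestMetastases:
    def _seg(self):
        data = np.zeros((8, 8, 8), np.int32)
        data[2:6, 2:6, 2:6] = 1
        return LabelVolume(data, (240.0,) * 3, {1: "a"})

    def test_centroid_point_allocated_to_organ(self):
        seg = self._seg()
        pts = pd.DataFrame([{"x0": 4.0, "x1": 4.0, "x2": 4.0, "true_code": 1}])
        out = allocate_metastases(pts, seg)
        assert out["allocated_code"].iloc[0] == 1

    def test_background_point_unallocated(self):
        seg = self._seg()
        pts = pd.DataFrame([{"x0": 0.5, "x1": 0.5, "x2": 0.5, "true_code": 0}])
        assert allocate_metastases(pts, seg)["allocated_code"].iloc[0] == 0

    def test_matches_direct_indexing_oracle(self, rng):
        seg = self._seg()
        pts = pd.DataFrame(
            {
                "x0": rng.uniform(0, 7.99, 50),
                "x1": rng.uniform(0, 7.99, 50),
                "x2": rng.uniform(0, 7.99, 50),
                "true_code": 0,
            }
        )
        out = allocate_metastases(pts, seg)
        for _, r in out.iterrows():
            assert r["allocated_code"] == seg.data[int(r.x0), int(r.x1), int(r.x2)]

    def test_out_of_grid_rejected(self):
        seg = self._seg()
        pts = pd.DataFrame([{"x0": 9.0, "x1": 0.0, "x2": 0.0, "true_code": 0}])
        with pytest.raises(ValueError, match="outside"):
            allocate_metastases(pts, seg)

    def test_count_error_perfect_and_off_by_one(self):
        alloc = pd.DataFrame({"true_code": [1] * 10, "allocated_code": [1] * 9 + [0]})
        count, err = metastasis_count_error(alloc, 1)
        assert count == 9 and err == pytest.approx(0.1)
        perfect = pd.DataFrame({"true_code": [1] * 5, "allocated_code": [1] * 5})
        assert metastasis_count_error(perfect, 1) == (5, 0.0)

    def test_zero_true_count_is_missing(self):
        alloc = pd.DataFrame({"true_code": [0, 0], "allocated_code": [1, 0]})
        count, err = metastasis_count_error(alloc, 1)
        assert count == 1 and np.isnan(err)

    def test_dilated_segmentation_counts_monotone(self, rng):
        from scipy import ndimage

        seg = self._seg()
        big = LabelVolume(
            ndimage.binary_dilation(seg.data == 1).astype(np.int32),
            seg.spacing,
            seg.code_table,
        )
        pts = pd.DataFrame(
            {
                "x0": rng.uniform(0, 7.99, 80),
                "x1": rng.uniform(0, 7.99, 80),
                "x2": rng.uniform(0, 7.99, 80),
                "true_code": 0,
            }
        )
        n_true = (allocate_metastases(pts, seg)["allocated_code"] == 1).sum()
        n_big = (allocate_metastases(pts, big)["allocated_code"] == 1).sum()
        assert n_big >= n_true
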