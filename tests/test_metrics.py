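"""Metric oracle checks: Dice, percentile Hausdorff, center-of-mass
displacement, union-reference Dice, disagreement Dice."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from organseg.metrics import (
    EPS,
    EmptyMaskError,
    com_displacement,
    dice,
    disagreement_dice,
    disagreement_mask,
    evaluate_scan,
    hausdorff_percentile,
    surface_voxels,
    union_reference_dice,
)
from organseg.volumes import GeometryError, LabelVolume

SPACING = (240.0, 240.0, 240.0)


def brute_force_surface(mask):
    """Oracle: voxel-by-voxel 6-neighborhood test."""
    out = np.zeros_like(mask)
    idx = np.argwhere(mask)
    for i, j, k in idx:
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (
                0 <= ni < mask.shape[0]
                and 0 <= nj < mask.shape[1]
                and 0 <= nk < mask.shape[2]
            ) or not mask[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def brute_force_hd(pred, ref, p, spacing):
    """Oracle: exhaustive pairwise distances between surface voxels."""
    ps = np.argwhere(brute_force_surface(pred)) * np.asarray(spacing)
    rs = np.argwhere(brute_force_surface(ref)) * np.asarray(spacing)
    d = cdist(rs, ps).min(axis=1)
    return float(np.percentile(d, p))


class TestDice:
    def test_identical_nonempty_exactly_one(self, rng):
        m = rng.random((8, 8, 8)) < 0.3
        m[0, 0, 0] = True
        assert dice(m, m) == 1.0

    def test_both_empty_is_one_via_eps(self):
        z = np.zeros((4, 4, 4), bool)
        assert dice(z, z) == 1.0

    def test_hand_computed_half_overlap(self):
        pred = np.zeros((4, 4, 4), bool)
        ref = np.zeros((4, 4, 4), bool)
        pred[0, 0, :4] = True  # |pred| = 4
        ref[0, 0, 2:4] = True
        ref[0, 1, :2] = True  # |ref| = 4, overlap = 2
        expected = (2 * 2 + EPS) / (2 * 2 + 2 + 2 + EPS)
        assert dice(pred, ref) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5000006, abs=1e-7)

    def test_symmetric(self, rng):
        a = rng.random((6, 6, 6)) < 0.4
        b = rng.random((6, 6, 6)) < 0.4
        assert dice(a, b) == dice(b, a)

    def test_monotone_in_overlap(self, rng):
        ref = rng.random((6, 6, 6)) < 0.5
        pred = ref.copy()
        prev = dice(pred, ref)
        hits = np.argwhere(pred & ref)
        for i, j, k in hits[:5]:
            pred[i, j, k] = False
            cur = dice(pred, ref)
            assert cur < prev
            prev = cur

    def test_geometry_mismatch(self):
        with pytest.raises(GeometryError):
            dice(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 5), bool))


class TestHausdorff:
    def test_identical_is_zero(self, rng):
        m = rng.random((8, 8, 8)) < 0.3
        m[4, 4, 4] = True
        for p in (50, 95, 100):
            assert hausdorff_percentile(m, m, p, SPACING) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        for p in (0, 50, 95, 100):
            assert hausdorff_percentile(a, b, p, SPACING) == pytest.approx(720.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            a = rng.random((10, 9, 11)) < 0.15
            b = rng.random((10, 9, 11)) < 0.15
            if not a.any() or not b.any():
                continue
            for p in (50, 95):
                got = hausdorff_percentile(a, b, p, SPACING)
                assert got == brute_force_hd(a, b, p, SPACING)

    def test_percentile_ordering(self, rng):
        a = rng.random((10, 10, 10)) < 0.2
        b = rng.random((10, 10, 10)) < 0.2
        a[5, 5, 5] = b[2, 2, 2] = True
        h50 = hausdorff_percentile(a, b, 50, SPACING)
        h95 = hausdorff_percentile(a, b, 95, SPACING)
        h100 = hausdorff_percentile(a, b, 100, SPACING)
        assert h100 >= h95 >= h50

    def test_empty_mask_raises(self):
        z = np.zeros((4, 4, 4), bool)
        m = z.copy()
        m[1, 1, 1] = True
        with pytest.raises(EmptyMaskError):
            hausdorff_percentile(z, m, 50, SPACING)
        with pytest.raises(EmptyMaskError):
            hausdorff_percentile(m, z, 50, SPACING)

    def test_surface_definition_matches_oracle(self, rng):
        m = rng.random((9, 9, 9)) < 0.4
        np.testing.assert_array_equal(surface_voxels(m), brute_force_surface(m))

    def test_symmetric_variant_pools_directions(self, rng):
        a = rng.random((8, 8, 8)) < 0.2
        b = rng.random((8, 8, 8)) < 0.2
        a[1, 1, 1] = b[6, 6, 6] = True
        sym = hausdorff_percentile(a, b, 100, SPACING, symmetric=True)
        d1 = hausdorff_percentile(a, b, 100, SPACING)
        d2 = hausdorff_percentile(b, a, 100, SPACING)
        assert sym == pytest.approx(max(d1, d2))


class TestCoM:
    def test_identical_zero(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[3, 3, 3] = True
        assert com_displacement(m, m, SPACING) == 0.0

    def test_pure_translation(self):
        a = np.zeros((10, 8, 8), bool)
        a[2:5, 2:5, 2:5] = True
        b = np.roll(a, 3, axis=0)
        assert com_displacement(b, a, SPACING) == pytest.approx(720.0)

    def test_matches_centroid_oracle(self, rng):
        a = rng.random((7, 8, 9)) < 0.3
        b = rng.random((7, 8, 9)) < 0.3
        a[0, 0, 0] = b[6, 7, 8] = True
        ca = np.argwhere(a).mean(axis=0) * np.asarray(SPACING)
        cb = np.argwhere(b).mean(axis=0) * np.asarray(SPACING)
        assert com_displacement(a, b, SPACING) == pytest.approx(
            np.linalg.norm(ca - cb)
        )

    def test_collinear_translation_equivariance(self):
        a = np.zeros((16, 8, 8), bool)
        a[2:4, 2:4, 2:4] = True
        d0 = com_displacement(np.roll(a, 2, axis=0), a, SPACING)
        d1 = com_displacement(np.roll(a, 5, axis=0), a, SPACING)
        assert d1 - d0 == pytest.approx(3 * 240.0)


class TestUnionReference:
    def test_all_equal_is_one(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[0, 0, 0] = True
        assert union_reference_dice(m, m, m) == 1.0

    def test_prediction_matching_subset_annotation_is_one(self):
        a1 = np.zeros((6, 6, 6), bool)
        a1[2:4, 2:4, 2:4] = True
        a2 = a1.copy()
        a2[1, 2:4, 2:4] = True  # a2 strictly contains a1
        assert union_reference_dice(a1, a1, a2) == 1.0

    def test_superset_annotation_never_hurts(self, rng):
        for _ in range(20):
            pred = rng.random((6, 6, 6)) < 0.4
            a1 = rng.random((6, 6, 6)) < 0.4
            a2 = a1 | (rng.random((6, 6, 6)) < 0.2)
            assert union_reference_dice(pred, a1, a2) >= dice(pred, a1)

    def test_matches_set_algebra_oracle(self, rng):
        pred = rng.random((6, 6, 6)) < 0.4
        a1 = rng.random((6, 6, 6)) < 0.4
        a2 = rng.random((6, 6, 6)) < 0.4
        tp = (pred & (a1 | a2)).sum()
        fp = (pred & ~(a1 | a2)).sum()
        fn = (~pred & (a1 & a2)).sum()
        expected = (2 * tp + EPS) / (2 * tp + fp + fn + EPS)
        assert union_reference_dice(pred, a1, a2) == pytest.approx(expected)


class TestDisagreement:
    def test_exact_heatmap_scores_one(self, label_pair):
        a1, a2 = label_pair
        xor = disagreement_mask(a1, a2)
        assert disagreement_dice(xor.astype(np.float32), a1, a2) == 1.0

    def test_zero_heatmap_scores_near_zero(self, label_pair):
        a1, a2 = label_pair
        heat = np.zeros(a1.shape, np.float32)
        assert disagreement_dice(heat, a1, a2) < 1e-3

    def test_half_overlap_matches_confusion_oracle(self, label_pair, rng):
        a1, a2 = label_pair
        xor = disagreement_mask(a1, a2)
        heat = (xor & (rng.random(xor.shape) < 0.5)).astype(np.float32)
        tp = (heat > 0.5) & xor
        fn = ~(heat > 0.5) & xor
        expected = (2 * tp.sum() + EPS) / (2 * tp.sum() + fn.sum() + EPS)
        assert disagreement_dice(heat, a1, a2) == pytest.approx(expected)


class TestHumanVsHuman:
    def test_annotator_interchange_symmetric(self, label_pair):
        a1, a2 = label_pair
        for code in a1.codes:
            assert dice(a1.data == code, a2.data == code) == dice(
                a2.data == code, a1.data == code
            )


class TestEvaluateScan:
    def test_report_schema_and_empty_handling(self, label_pair):
        a1, a2 = label_pair
        pred_data = a1.data.copy()
        pred_data[pred_data == 2] = 0  # organ 2 missing from the prediction
        pred = LabelVolume(pred_data, a1.spacing, a1.code_table)
        rep = evaluate_scan(pred, a1, a2, heatmap=np.zeros(a1.shape, np.float32))
        assert {"dice", "hd50_um", "hd95_um", "com_um", "union_dice"} <= set(rep.columns)
        row2 = rep[rep["organ_code"] == 2].iloc[0]
        assert np.isnan(row2["hd50_um"]) and row2["note"] != ""
        assert rep[rep["organ_code"] == -1]["organ"].iloc[0] == "disagreement"
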