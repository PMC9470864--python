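"""Surface-distance metrics against exhaustive brute-force references."""

import numpy as np
import pytest
from scipy import ndimage, stats
from scipy.spatial.distance import cdist

from ossiseg.metrics import (
    PairedTTest,
    UndefinedSurfaceError,
    asd,
    dsc,
    evaluate_case,
    hausdorff,
    paired_ttest,
    surface_points,
)
from ossiseg.volume_io import LabelVolume, UsageError


def brute_surface(mask, spacing):
    """6-neighbor boundary via explicit per-voxel neighbor checks."""
    pts = []
    shape = mask.shape
    for idx in np.argwhere(mask):
        for ax in range(3):
            for d in (-1, 1):
                n = idx.copy()
                n[ax] += d
                if not (0 <= n[ax] < shape[ax]) or not mask[tuple(n)]:
                    pts.append(idx * np.asarray(spacing, float))
                    break
            else:
                continue
            break
    return np.array(pts)


def brute_distances(x, y):
    d = cdist(x, y)
    return d.min(axis=1)


class TestDSC:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        assert dsc(a, b) == 0.0

    def test_direct_substitution(self):
        a = np.zeros((8,), bool).reshape(2, 2, 2)
        b = np.zeros((8,), bool).reshape(2, 2, 2)
        a.reshape(-1)[:4] = True
        b.reshape(-1)[2:6] = True
        assert dsc(a, b) == 0.5

    def test_empty_vs_empty_is_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dsc(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(UsageError):
            dsc(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))

    def test_erosion_never_increases_dsc_against_original(self):
        truth = np.zeros((10, 10, 10), bool)
        truth[2:8, 2:8, 2:8] = True
        prev = dsc(truth, truth)
        pred = truth
        for _ in range(3):
            pred = ndimage.binary_erosion(pred)
            cur = dsc(truth, pred)
            assert cur <= prev
            prev = cur


class TestSurfacePoints:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        pts = surface_points(m, (1, 1, 1))
        np.testing.assert_array_equal(pts, [[1, 1, 1]])

    @pytest.mark.parametrize("side,expected", [(3, 26), (5, 98)])
    def test_solid_cube_boundary_counts(self, side, expected):
        m = np.zeros((side + 2,) * 3, bool)
        m[1:-1, 1:-1, 1:-1] = True
        assert len(surface_points(m, (1, 1, 1))) == expected

    def test_matches_brute_force_neighbor_check(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[2, 2, 2] = True
        got = surface_points(m, (0.5, 1.0, 2.0))
        expect = brute_surface(m, (0.5, 1.0, 2.0))
        assert sorted(map(tuple, got)) == sorted(map(tuple, expect))

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedSurfaceError):
            surface_points(np.zeros((2, 2, 2), bool), (1, 1, 1))


class TestSurfaceDistances:
    def test_asd_zero_for_identical_sets(self):
        x = np.array([[0, 0, 0], [1, 1, 1]], float)
        assert asd(x, x) == 0.0

    def test_asd_345_triangle(self):
        assert asd(np.array([[0, 0, 0.0]]), np.array([[3, 4, 0.0]])) == pytest.approx(5.0)

    def test_hd_singletons(self):
        hd, hd95 = hausdorff(np.array([[0, 0, 0.0]]), np.array([[0, 0, 2.0]]))
        assert hd == pytest.approx(2.0) and hd95 == pytest.approx(2.0)

    def test_random_masks_match_exhaustive_oracle(self, rng):
        for _ in range(5):
            a = rng.random((12, 12, 12)) < 0.3
            b = rng.random((12, 12, 12)) < 0.3
            a[5, 5, 5] = b[6, 6, 6] = True
            sp = (0.7, 1.1, 0.9)
            x, y = surface_points(a, sp), surface_points(b, sp)
            d_xy, d_yx = brute_distances(x, y), brute_distances(y, x)
            assert asd(x, y, symmetric=False) == pytest.approx(d_xy.mean(), abs=1e-9)
            assert asd(x, y) == pytest.approx((d_xy.mean() + d_yx.mean()) / 2, abs=1e-9)
            hd, hd95 = hausdorff(x, y)
            pooled = np.concatenate([d_xy, d_yx])
            assert hd == pytest.approx(pooled.max(), abs=1e-9)
            assert hd95 == pytest.approx(np.percentile(pooled, 95), abs=1e-9)
            assert hd95 <= hd + 1e-12

    def test_scale_equivariance(self, rng):
        a = rng.random((8, 8, 8)) < 0.3
        b = rng.random((8, 8, 8)) < 0.3
        a[4, 4, 4] = b[3, 3, 3] = True
        x1, y1 = surface_points(a, (1, 1, 1)), surface_points(b, (1, 1, 1))
        x2, y2 = surface_points(a, (2, 2, 2)), surface_points(b, (2, 2, 2))
        assert asd(x2, y2) == pytest.approx(2 * asd(x1, y1))
        assert hausdorff(x2, y2)[0] == pytest.approx(2 * hausdorff(x1, y1)[0])
        assert dsc(a, b) == dsc(a, b)  # dsc has no spacing dependence


class TestEvaluateCase:
    def _volumes(self, truth, pred, spacing=(1, 1, 1)):
        return (
            LabelVolume(pred.astype(np.uint8), spacing),
            LabelVolume(truth.astype(np.uint8), spacing),
        )

    def test_perfect_prediction(self, rng):
        lab = rng.integers(0, 4, (8, 8, 8))
        pred, truth = self._volumes(lab, lab)
        m = evaluate_case(pred, truth)
        for s in m.per_structure.values():
            assert s.dsc == 1.0 and s.asd == 0.0 and s.hd == 0.0 and s.hd95 == 0.0

    def test_erased_stapes_flags_undefined_distances(self, rng):
        lab = np.zeros((8, 8, 8), int)
        lab[1:3, 1:3, 1:3] = 1
        lab[4:6, 4:6, 4:6] = 2
        lab[6:8, 6:8, 6:8] = 3
        pred_arr = lab.copy()
        pred_arr[pred_arr == 3] = 0
        pred, truth = self._volumes(lab, pred_arr)
        m = evaluate_case(pred, truth)
        assert m.per_structure["stapes"].dsc == 0.0
        assert m.per_structure["stapes"].undefined_distances
        assert m.per_structure["malleus"].dsc == 1.0
        assert m.per_structure["incus"].dsc == 1.0

    def test_absent_from_both_scores_perfect(self):
        lab = np.zeros((4, 4, 4), int)
        lab[1:3, 1:3, 1:3] = 1
        pred, truth = self._volumes(lab, lab)
        m = evaluate_case(pred, truth)
        assert m.per_structure["stapes"].dsc == 1.0
        assert m.per_structure["stapes"].asd == 0.0

    def test_shifted_cube_matches_brute_force(self):
        truth_arr = np.zeros((10, 10, 10), int)
        truth_arr[2:6, 2:6, 2:6] = 1
        pred_arr = np.zeros((10, 10, 10), int)
        pred_arr[3:7, 2:6, 2:6] = 1  # one-voxel shift along axis 0
        sp = (0.8, 0.8, 0.8)
        pred, truth = self._volumes(truth_arr, pred_arr, sp)
        m = evaluate_case(pred, truth).per_structure["malleus"]
        assert m.dsc == pytest.approx(dsc(truth_arr == 1, pred_arr == 1))
        x = brute_surface(truth_arr == 1, sp)
        y = brute_surface(pred_arr == 1, sp)
        d_xy, d_yx = brute_distances(x, y), brute_distances(y, x)
        assert m.asd == pytest.approx((d_xy.mean() + d_yx.mean()) / 2, abs=1e-9)
        pooled = np.concatenate([d_xy, d_yx])
        assert m.hd == pytest.approx(pooled.max(), abs=1e-9)
        assert m.hd95 == pytest.approx(np.percentile(pooled, 95), abs=1e-9)

    def test_geometry_mismatch_rejected(self):
        a = LabelVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        b = LabelVolume(np.zeros((4, 4, 4), np.uint8), (2, 2, 2))
        with pytest.raises(UsageError):
            evaluate_case(a, b)


class TestPairedTTest:
    def test_identical_lists_degenerate(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate

    def test_constant_difference_degenerate(self):
        res = paired_ttest([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.degenerate

    def test_matches_closed_form(self):
        a = np.array([0.90, 0.92, 0.88, 0.95])
        b = np.array([0.85, 0.87, 0.80, 0.91])
        res = paired_ttest(a, b)
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t == pytest.approx(t_expect, rel=1e-9)
        p_expect = 2 * stats.t.sf(abs(t_expect), df=len(d) - 1)
        assert res.p == pytest.approx(p_expect, rel=1e-9)
        assert not res.degenerate

    def test_length_contracts(self):
        with pytest.raises(UsageError):
            paired_ttest([1.0], [2.0])
        with pytest.raises(UsageError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])
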