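"""Dice, Hausdorff, centerline overlap, six-radius masking."""

import numpy as np
import pytest

from seqseg import (
    LabelVolume,
    centerline_overlap,
    dice,
    evaluate,
    evaluation_mask,
    hausdorff,
    wilcoxon_signed_rank,
)
from seqseg.centerline import Branch, CenterlineTree
from seqseg.errors import EmptyCenterline, EmptySet, ShapeMismatch
from seqseg.metrics import _boundary_voxels

from oracles import boundary_voxels_bruteforce, brute_hausdorff


def _mask(shape=(10, 10, 10)):
    return np.zeros(shape, np.uint8)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = _mask()
        m[2:5] = 1
        assert dice(m, m.copy()) == 1.0

    def test_disjoint_masks(self):
        a, b = _mask(), _mask()
        a[0] = 1
        b[9] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a, b = _mask((10, 10, 12)), _mask((10, 10, 12))
        a[0, 0, :8] = 1
        b[0, 0, 4:12] = 1  # |a|=|b|=8 sharing 4
        assert dice(a, b) == 0.5

    def test_symmetry_and_empty_convention(self, rng):
        a = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        b = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        assert dice(a, b) == dice(b, a)
        assert dice(_mask(), _mask()) == 0.0

    def test_adding_true_positives_never_decreases_dice(self, rng):
        truth = (rng.random((8, 8, 8)) > 0.6).astype(np.uint8)
        pred = truth.copy()
        missing = np.argwhere(truth > 0)
        rng.shuffle(missing)
        pred[tuple(missing[: len(missing) // 2].T)] = 0
        scores = []
        for k in range(0, len(missing) // 2, 5):
            p = pred.copy()
            p[tuple(missing[:k].T)] = truth[tuple(missing[:k].T)]
            scores.append(dice(p, truth))
        assert all(s1 >= s0 for s0, s1 in zip(scores, scores[1:]))


class TestHausdorff:
    def test_identical_masks_distance_zero(self):
        m = _mask()
        m[3:6, 3:6, 3:6] = 1
        assert hausdorff(m, m.copy()) == 0.0

    def test_single_voxels_three_apart(self):
        a, b = _mask(), _mask()
        a[2, 5, 5] = 1
        b[5, 5, 5] = 1
        assert hausdorff(a, b) == 3.0

    def test_matches_allpairs_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b = _mask((12, 12, 12)), _mask((12, 12, 12))
            a[tuple(rng.integers(0, 12, (rng.integers(1, 50), 3)).T)] = 1
            b[tuple(rng.integers(0, 12, (rng.integers(1, 50), 3)).T)] = 1
            expected = brute_hausdorff(
                boundary_voxels_bruteforce(a > 0), boundary_voxels_bruteforce(b > 0)
            )
            assert hausdorff(a, b) == expected

    def test_mm_units_scale_with_spacing(self):
        a, b = _mask(), _mask()
        a[2, 5, 5] = 1
        b[5, 5, 5] = 1
        va = LabelVolume(a, (2.0, 1.0, 1.0), (0, 0, 0))
        vb = LabelVolume(b, (2.0, 1.0, 1.0), (0, 0, 0))
        assert hausdorff(va, vb, units="mm") == 6.0

    def test_empty_set_rejected(self):
        m = _mask()
        m[0] = 1
        with pytest.raises(EmptySet):
            hausdorff(m, _mask())

    def test_boundary_extraction_matches_bruteforce(self, rng):
        m = (rng.random((9, 9, 9)) > 0.5)
        got = {tuple(v) for v in _boundary_voxels(m)}
        # the brute-force oracle also counts grid-border foreground voxels;
        # align by adding a zero pad ring to both
        p = np.pad(m, 1)
        got = {tuple(v) for v in _boundary_voxels(p)}
        want = {tuple(v) for v in boundary_voxels_bruteforce(p)}
        assert got == want


class TestCenterlineOverlap:
    def _line_tree(self, x0=0.0, x1=9.0, y=5.0):
        pts = np.stack([np.linspace(x0, x1, 30), np.full(30, y), np.full(30, y)], axis=1)
        return CenterlineTree(branches=[Branch(pts, np.full(30, 1.0))],
                              source=pts[0], targets=[pts[-1]])

    def test_fully_covered_centerline(self):
        m = np.ones((10, 10, 10), np.uint8)
        vol = LabelVolume(m, (1, 1, 1), (0, 0, 0))
        assert centerline_overlap(vol, self._line_tree()) == 1.0

    def test_empty_prediction(self):
        vol = LabelVolume(_mask(), (1, 1, 1), (0, 0, 0))
        assert centerline_overlap(vol, self._line_tree()) == 0.0

    def test_half_covered_line(self):
        m = _mask()
        m[:5] = 1  # first half of the x-axis
        vol = LabelVolume(m, (1, 1, 1), (0, 0, 0))
        co = centerline_overlap(vol, self._line_tree())
        assert co == pytest.approx(0.5, abs=0.06)

    def test_empty_centerline_rejected(self):
        vol = LabelVolume(np.ones((4, 4, 4), np.uint8), (1, 1, 1), (0, 0, 0))
        with pytest.raises(EmptyCenterline):
            centerline_overlap(vol, CenterlineTree())


class TestEvaluationMask:
    def _tube_tree(self, radius=1.0, n=40):
        pts = np.stack([np.linspace(5, 35, n), np.full(n, 20.0), np.full(n, 20.0)], axis=1)
        return CenterlineTree(branches=[Branch(pts, np.full(n, radius))],
                              source=pts[0], targets=[pts[-1]])

    def test_five_radii_inside_seven_outside(self):
        from seqseg import ImageVolume

        ref = ImageVolume(np.zeros((40, 40, 40)), (1, 1, 1), (0, 0, 0))
        mask = evaluation_mask(self._tube_tree(radius=1.0), ref)
        assert mask.data[20, 25, 20] == 1  # 5 radii off-axis
        assert mask.data[20, 27, 20] == 0  # 7 radii off-axis

    def test_tube_mask_volume_near_analytic_cylinder(self):
        from seqseg import ImageVolume

        ref = ImageVolume(np.zeros((40, 40, 40)), (1, 1, 1), (0, 0, 0))
        mask = evaluation_mask(self._tube_tree(radius=1.0), ref)
        # cylinder of radius 6, length 30, plus hemispherical end caps
        analytic = np.pi * 36 * 30 + 4 / 3 * np.pi * 216
        assert abs(mask.data.sum() - analytic) / analytic < 0.15

    def test_masking_contract(self, rng):
        # metrics of masked inputs equal metrics restricted to the mask
        a = (rng.random((16, 16, 16)) > 0.5).astype(np.uint8)
        b = (rng.random((16, 16, 16)) > 0.5).astype(np.uint8)
        m = np.zeros((16, 16, 16), np.uint8)
        m[4:12] = 1
        assert dice(a * m, b * m) == dice(a[4:12], b[4:12])


class TestEvaluate:
    def test_report_fields_and_masking_flag(self, rng):
        truth = _mask((20, 20, 20))
        truth[5:15, 8:12, 8:12] = 1
        pred = truth.copy()
        pred[14] = 0
        pts = np.stack([np.linspace(5, 14, 10), np.full(10, 10.0), np.full(10, 10.0)], axis=1)
        tree = CenterlineTree(branches=[Branch(pts, np.full(10, 2.0))],
                              source=pts[0], targets=[pts[-1]])
        tv = LabelVolume(truth, (1, 1, 1), (0, 0, 0))
        pv = LabelVolume(pred, (1, 1, 1), (0, 0, 0))
        rep = evaluate(pv, tv, tree, mask_six_radius=True)
        assert rep.mask_applied
        assert 0.8 < rep.dice <= 1.0
        assert 0.8 < rep.centerline_overlap <= 1.0
        assert rep.hausdorff >= 0.0


def test_wilcoxon_wrapper_detects_a_shift(rng):
    a = rng.normal(0.9, 0.02, 30)
    stat, p = wilcoxon_signed_rank(a, a - 0.05)
    assert p < 0.01
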