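import numpy as np
import pytest

from filascan.evaluate import (EvalCounts, ROCPoint, consensus_mask,
                               convex_hull_points, match_detection, rates,
                               roc_grid)
from filascan.io import PipelineConfig
from filascan.synthetic import SceneSpec, generate_scene


class TestConsensus:
    def test_unanimous_masks_reproduced(self, rng):
        m = rng.random((10, 10)) > 0.5
        assert np.array_equal(consensus_mask([m] * 5, 3), m)

    def test_vote_boundary(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = True
        two = [m, m] + [np.zeros((4, 4), bool)] * 3
        three = [m, m, m] + [np.zeros((4, 4), bool)] * 2
        assert not consensus_mask(two, 3)[1, 1]     # 2 of 5: rejected
        assert consensus_mask(three, 3)[1, 1]       # 3 of 5: accepted

    def test_shape_mismatch_and_too_few_masks(self):
        with pytest.raises(ValueError):
            consensus_mask([np.zeros((3, 3), bool), np.zeros((4, 4), bool),
                            np.zeros((3, 3), bool)], 3)
        with pytest.raises(ValueError):
            consensus_mask([np.zeros((3, 3), bool)], 3)


class TestMatching:
    def test_perfect_detection(self, rng):
        ref = rng.random((20, 20)) > 0.7
        c = match_detection(ref, ref, 3)
        assert (c.tp, c.fn, c.fp) == (ref.sum(), 0, 0)
        assert c.p == ref.sum()

    def test_empty_detection(self, rng):
        ref = rng.random((20, 20)) > 0.7
        c = match_detection(ref, np.zeros_like(ref), 3)
        assert (c.tp, c.fn, c.fp) == (0, ref.sum(), 0)

    def test_unit_shift_forgiven_by_dilation(self):
        ref = np.zeros((20, 20), bool)
        ref[10, 3:17] = True
        det = np.roll(ref, 1, axis=0)
        c = match_detection(ref, det, 1)
        assert c.fn == 0 and c.fp == 0

    def test_zero_radius_is_exact_pixel_agreement(self):
        ref = np.zeros((10, 10), bool)
        ref[5, 5] = True
        det = np.zeros_like(ref)
        det[5, 6] = True
        c = match_detection(ref, det, 0)
        assert (c.tp, c.fn, c.fp) == (0, 1, 1)

    def test_counts_partition_the_frame(self, rng):
        ref = rng.random((15, 15)) > 0.6
        det = rng.random((15, 15)) > 0.6
        c = match_detection(ref, det, 2)
        assert c.tp + c.fn == ref.sum()  # P is partitioned
        assert c.tp + c.fn + c.fp + c.tn == ref.size


class TestRates:
    def test_arithmetic(self):
        tpr, fpr, spec = rates(EvalCounts(tp=70, fp=0, fn=30, tn=0))
        assert tpr == pytest.approx(0.70)
        tpr, fpr, spec = rates(EvalCounts(tp=50, fp=14, fn=50, tn=0))
        assert fpr == pytest.approx(0.14)
        assert spec == pytest.approx(0.86)

    def test_ideal_point(self):
        assert rates(EvalCounts(tp=10, fp=0, fn=0, tn=90)) == (1.0, 0.0, 1.0)

    def test_no_positives_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            rates(EvalCounts(tp=0, fp=5, fn=0, tn=5))


def _pt(tpr, fpr):
    return ROCPoint(1e-3, 6.4, 3.2, tpr, fpr, 1 - fpr)


class TestConvexHull:
    def test_single_point(self):
        pts = [_pt(0.5, 0.1)]
        assert convex_hull_points(pts) == pts

    def test_dominated_point_excluded(self):
        good, bad = _pt(0.8, 0.1), _pt(0.6, 0.3)
        assert convex_hull_points([good, bad]) == [good]

    def test_collinear_frontier_retained(self):
        pts = [_pt(0.2, 0.0), _pt(0.5, 0.15), _pt(0.8, 0.3)]
        assert convex_hull_points(pts) == pts

    def test_hull_mutually_non_dominated_on_random_points(self, rng):
        pts = [_pt(t, f) for t, f in rng.random((60, 2))]
        hull = convex_hull_points(pts)
        for a in hull:
            for b in hull:
                if a is not b:
                    assert not (b.tpr >= a.tpr and b.fpr <= a.fpr
                                and (b.tpr > a.tpr or b.fpr < a.fpr))


@pytest.fixture(scope="module")
def small_scene():
    img, gt = generate_scene(SceneSpec(image_size=(200, 260), n_filaments=2,
                                       filament_length_px_range=(60, 150),
                                       n_flocs=1, n_debris=3, seed=5))
    return img, gt.filament_mask


class TestROCGrid:
    def test_singleton_grid_gives_one_point(self, small_scene):
        img, ref = small_scene
        pts = roc_grid([img], [ref], [10.5e-4], [6.4], [3.2])
        assert len(pts) == 1
        assert pts[0].specificity == pytest.approx(1 - pts[0].fpr)

    def test_rrg_sweep_trades_sensitivity_for_specificity(self, small_scene):
        img, ref = small_scene
        pts = roc_grid([img], [ref], [10.5e-4], [6.4], [2.0, 3.2, 6.0, 12.0])
        tprs = [p.tpr for p in pts]
        fprs = [p.fpr for p in pts]
        # raising the RRG cut only removes detections
        assert all(a >= b - 1e-12 for a, b in zip(tprs, tprs[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(fprs, fprs[1:]))

    def test_empty_grid_rejected(self, small_scene):
        img, ref = small_scene
        with pytest.raises(ValueError):
            roc_grid([img], [ref], [], [6.4], [3.2])
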