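"""Point matching, rate arithmetic, stratification, overlays, summaries."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from fppl.detect import Detection
from fppl.evaluate import (
    CYAN,
    LIGHT_GREEN,
    RED,
    EvaluationResult,
    ReferenceSet,
    compute_rates,
    evaluate_detections,
    match_points,
    render_overlay,
    size_stratified_rates,
    summarize_images,
)


def _dets(*rc):
    return [Detection(row=r, col=c) for r, c in rc]


class TestMatching:
    def test_identity_matches_everything(self):
        pts = np.array([[10.0, 10.0], [30.0, 40.0], [50.0, 5.0]])
        pairs, ur, ud = match_points(_dets(*map(tuple, pts)),
                                     ReferenceSet(points=pts), 5.0)
        assert len(pairs) == 3 and ur == [] and ud == []
        assert all(d == 0.0 for _, _, d in pairs)

    def test_no_detections(self):
        ref = ReferenceSet(points=np.column_stack([np.arange(10) * 7.0 + 5,
                                                   np.full(10, 5.0)]))
        pairs, ur, ud = match_points([], ref, 5.0)
        assert pairs == [] and len(ur) == 10 and ud == []

    def test_equidistant_tie_broken_by_scan_order(self):
        ref = ReferenceSet(points=np.array([[20.0, 20.0]]))
        pairs, ur, ud = match_points(_dets((20, 17), (20, 23)), ref, 5.0)
        assert len(pairs) == 1
        assert pairs[0][0] == 0      # first detection wins the tie
        assert ud == [1]

    def test_one_to_one_cardinality_bound(self):
        rng = np.random.default_rng(0)
        det = rng.uniform(0, 100, (12, 2))
        ref = ReferenceSet(points=rng.uniform(0, 100, (8, 2)))
        pairs, ur, ud = match_points(det, ref, 10.0)
        assert len(pairs) <= min(12, 8)
        assert len(pairs) + len(ur) == 8
        assert len(pairs) + len(ud) == 12

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_agrees_with_optimal_assignment_when_sparse(self, seed):
        """At realistic particle spacing, greedy matching is maximal."""
        rng = np.random.default_rng(seed)
        grid = np.stack(np.meshgrid(np.arange(5) * 25.0 + 15,
                                    np.arange(5) * 25.0 + 15), -1).reshape(-1, 2)
        ref_pts = grid + rng.uniform(-3, 3, grid.shape)
        keep = rng.random(len(grid)) < 0.8
        det_pts = grid[keep] + rng.uniform(-3, 3, (keep.sum(), 2))
        extra = rng.uniform(0, 130, (3, 2))
        det_pts = np.vstack([det_pts, extra])
        tol = 5.0
        pairs, _, _ = match_points(det_pts, ReferenceSet(points=ref_pts), tol)
        dist = np.hypot(det_pts[:, None, 0] - ref_pts[None, :, 0],
                        det_pts[:, None, 1] - ref_pts[None, :, 1])
        adj = csr_matrix((dist <= tol).astype(int))
        optimal = int((maximum_bipartite_matching(adj, "column") >= 0).sum())
        assert len(pairs) == optimal

    def test_rates_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        ref_pts = rng.uniform(10, 90, (20, 2))
        det_pts = ref_pts[:15] + rng.uniform(-2, 2, (15, 2))
        ref = ReferenceSet(points=ref_pts)
        base = evaluate_detections(det_pts, ref, 5.0)
        perm = rng.permutation(15)
        shuffled = evaluate_detections(
            det_pts[perm], ReferenceSet(points=ref_pts[rng.permutation(20)]), 5.0
        )
        assert shuffled.rates == base.rates


class TestRates:
    @pytest.mark.parametrize(
        "counts,expected",
        [((9, 1, 1), (90.0, 10.0, 10.0)),
         ((0, 10, 0), (0.0, 100.0, 0.0)),
         ((144, 0, 0), (100.0, 0.0, 0.0))],
    )
    def test_rate_arithmetic(self, counts, expected):
        res = compute_rates(*counts)
        assert (res.detection_rate, res.false_negative_rate,
                res.false_positive_rate) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_rates(-1, 0, 0)

    def test_detection_and_miss_rates_are_complementary(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            c, r, g = (int(v) for v in rng.integers(0, 500, 3))
            res = compute_rates(c, r, g)
            if c + r:
                assert res.detection_rate + res.false_negative_rate == \
                    pytest.approx(100.0, abs=1e-9)

    def test_no_reference_yields_nan_rates(self):
        res = compute_rates(0, 0, 5)
        assert np.isnan(res.detection_rate) and np.isnan(res.false_negative_rate)
        assert res.false_positive_rate == 100.0

    def test_no_detections_yields_zero_fp_rate(self):
        assert compute_rates(0, 7, 0).false_positive_rate == 0.0


class TestSizeStratified:
    def _ref(self):
        pts = np.array([[20.0, 20 + 15.0 * k] for k in range(6)])
        sizes = np.array([2.0, 2, 2, 8, 8, 8])
        return ReferenceSet(points=pts, sizes=sizes)

    def test_single_bin_equals_global(self):
        ref = self._ref()
        table = size_stratified_rates(ref.points, ref, 5.0, size_bins=(0, 17))
        assert len(table) == 1
        assert table.detection_rate.iloc[0] == 100.0
        assert table.n_reference.iloc[0] == 6

    def test_perfect_detector_in_every_bin(self):
        ref = self._ref()
        table = size_stratified_rates(ref.points, ref, 5.0, size_bins=(0, 4, 17))
        assert (table.detection_rate == 100.0).all()

    def test_detector_blind_to_smallest_bin(self):
        ref = self._ref()
        dets = ref.points[ref.sizes == 8.0]
        table = size_stratified_rates(dets, ref, 5.0, size_bins=(0, 4, 17))
        assert table.detection_rate.tolist() == [0.0, 100.0]

    def test_missing_sizes_rejected(self):
        ref = ReferenceSet(points=np.array([[5.0, 5.0]]))
        with pytest.raises(ValueError):
            size_stratified_rates([], ref, 5.0)


class TestOverlay:
    def test_empty_overlay_is_the_gray_image(self):
        rng = np.random.default_rng(2)
        image = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        out = render_overlay(image, [], [], [])
        assert out.shape == (20, 20, 3)
        assert (out == image[..., None]).all()

    def test_marks_carry_the_three_colours(self):
        image = np.zeros((60, 60), np.uint8)
        out = render_overlay(image, [(10, 10), (10, 30)], [(30, 10)], [(50, 50)])
        assert tuple(out[10, 10]) == CYAN
        assert tuple(out[10, 30]) == CYAN
        assert tuple(out[30, 10]) == RED
        assert tuple(out[50, 50]) == LIGHT_GREEN


class TestSummaries:
    def _res(self, dr):
        return EvaluationResult(n_cyan=0, n_red=0, n_green=0,
                                detection_rate=dr,
                                false_negative_rate=100 - dr,
                                false_positive_rate=0.0)

    def test_single_image_flags_undefined_se(self):
        table = summarize_images([self._res(80.0)])
        assert table.loc["detection_rate", "se"] == 0.0
        assert not table.loc["detection_rate", "se_defined"]

    def test_two_point_mean_and_se(self):
        table = summarize_images([self._res(80.0), self._res(100.0)])
        assert table.loc["detection_rate", "mean"] == 90.0
        assert table.loc["detection_rate", "se"] == pytest.approx(10.0)

    def test_batch_agrees_with_direct_formulas(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(50, 100, 9)
        table = summarize_images([self._res(v) for v in values])
        assert table.loc["detection_rate", "mean"] == pytest.approx(values.mean())
        assert table.loc["detection_rate", "se"] == pytest.approx(
            values.std(ddof=1) / 3.0
        )

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            summarize_images([])
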