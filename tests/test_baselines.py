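"""Binarize-and-label baselines, preprocessors and template matching."""

import numpy as np
import pytest

from fppl.baselines import (
    BplParams,
    bpl_detect,
    bpl_pipeline,
    brighter_than_periphery_filter,
    default_templates,
    find_edges,
    make_disc_template,
    mtm_detect,
    sbp_bpl_pipeline,
    subtract_background,
    template_similarity,
    _similarity_map,
)
from fppl.detect import Detection

from conftest import similarity_oracle


class TestBpl:
    def test_black_image_yields_nothing(self):
        assert bpl_detect(np.zeros((50, 50), np.uint8)) == []

    def test_single_blob_at_centroid(self):
        image = np.zeros((40, 40), np.uint8)
        image[10, 10:14] = 200
        image[11, 11] = 200
        dets = bpl_detect(image, BplParams(binarize_threshold=100))
        assert len(dets) == 1
        assert dets[0].row == pytest.approx(10.2)   # (4*10 + 11) / 5
        assert dets[0].col == pytest.approx(11.4)   # (10+11+12+13+11) / 5

    def test_area_band_filters_small_and_large(self):
        image = np.zeros((60, 60), np.uint8)
        image[5, 5:7] = 200            # 2 px, below min_area 3
        image[20:37, 20:37] = 200      # 289 px, above max_area 200
        assert bpl_detect(image) == []

    def test_invalid_area_band_rejected(self):
        with pytest.raises(ValueError):
            BplParams(min_area=10, max_area=5)

    def test_exclude_on_edges(self):
        image = np.zeros((30, 30), np.uint8)
        image[0:3, 10:13] = 200
        assert len(bpl_detect(image)) == 1
        assert bpl_detect(image, BplParams(exclude_on_edges=True)) == []


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        out = subtract_background(np.full((50, 50), 90, np.uint8))
        assert (out == 0).all()

    def test_small_dot_survives_on_flat_background(self):
        image = np.full((60, 60), 50, np.uint8)
        image[30, 30] = 250
        image[30, 31] = 250
        image[31, 30] = 250
        out = subtract_background(image)
        assert out[30, 30] > 150          # dot stands at ~dot - background
        assert out[5, 5] <= 5             # background flattened to ~0

    def test_wide_plateau_is_flattened(self):
        image = np.full((120, 120), 20, np.uint8)
        image[30:90, 30:90] = 180         # 60-px plateau, wider than the ball
        out = subtract_background(image, radius=20)
        assert out.max() < 180


class TestFindEdges:
    def test_constant_image_has_no_edges(self):
        assert (find_edges(np.full((30, 30), 128, np.uint8)) == 0).all()

    def test_vertical_step_responds_on_the_step(self):
        image = np.zeros((30, 30), np.uint8)
        image[:, 15:] = 200
        out = find_edges(image)
        assert out[15, 14:16].max() == 255      # clamped strong response
        assert out[15, 2] == 0 and out[15, 27] == 0

    def test_dot_produces_closed_bright_contour(self):
        image = np.full((40, 40), 30, np.uint8)
        image[18:23, 18:23] = 220
        out = find_edges(image)
        ring = out > 100
        assert ring.any()
        assert not ring[20, 20]  # interior is flat -> no response at centre


class TestBrightnessFilter:
    def _dets(self, *rc):
        return [Detection(row=r, col=c) for r, c in rc]

    def test_bright_dot_kept_dark_hole_removed(self):
        image = np.full((60, 60), 100, np.uint8)
        image[20, 20] = 250                       # bright particle
        image[38:43, 38:43] = 10                  # dark-centred artifact
        kept = brighter_than_periphery_filter(
            image, self._dets((20, 20), (40, 40))
        )
        assert [(d.row, d.col) for d in kept] == [(20, 20)]

    def test_mixed_population_splits_exactly(self):
        image = np.full((200, 60), 100, np.uint8)
        dets = []
        for k in range(10):
            r = 12 + 18 * k
            image[r - 1 : r + 2, 29:32] = 240 if k % 2 == 0 else 10
            dets.append(Detection(row=r, col=30))
        kept = brighter_than_periphery_filter(image, dets)
        assert [d.row for d in kept] == [12 + 18 * k for k in range(0, 10, 2)]

    def test_annulus_ordering_validated(self):
        with pytest.raises(ValueError):
            brighter_than_periphery_filter(np.zeros((10, 10)), [], 5, 5)


class TestTemplates:
    def test_disc_template_geometry(self):
        for tpl, (side, thr, bg) in zip(
            default_templates(), [(5, 0.80, 55), (7, 0.77, 60),
                                  (9, 0.74, 65), (11, 0.70, 70)]
        ):
            assert tpl.side == side
            assert tpl.similarity_threshold == thr
            assert tpl.background_level == bg
            centre = tpl.pixels[side // 2, side // 2]
            assert centre == 255
            assert tpl.pixels[0, 0] == bg
            # rendered disc spans side - 2 pixels
            on = np.argwhere(tpl.pixels == 255)
            assert on[:, 0].max() - on[:, 0].min() + 1 == side - 2

    def test_self_match_is_perfect(self):
        tpl = make_disc_template(7, 0.77, 60)
        image = np.zeros((20, 20), np.uint8)
        image[5:12, 5:12] = tpl.pixels
        assert template_similarity(image, tpl, (5, 5)) == 1.0

    def test_maximal_distance_gives_zero(self):
        from fppl.baselines import Template

        tpl = Template(side=5, pixels=np.full((5, 5), 255, np.uint8),
                       similarity_threshold=0.8, background_level=255)
        assert template_similarity(np.zeros((10, 10), np.uint8), tpl, (0, 0)) == 0.0

    def test_similarity_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        image = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        tpl = make_disc_template(5, 0.8, 55)
        for r, c in [(0, 0), (3, 7), (25, 25)]:
            assert template_similarity(image, tpl, (r, c)) == pytest.approx(
                similarity_oracle(image, tpl.pixels, r, c), abs=1e-12
            )

    def test_out_of_bounds_window_rejected(self):
        tpl = make_disc_template(5, 0.8, 55)
        with pytest.raises(ValueError):
            template_similarity(np.zeros((10, 10), np.uint8), tpl, (8, 8))


class TestMtm:
    def test_blank_image_yields_nothing(self):
        assert mtm_detect(np.zeros((60, 60), np.uint8)) == []

    def test_exact_template_copy_is_found(self):
        tpl = make_disc_template(5, 0.80, 55)
        image = np.zeros((40, 40), np.uint8)
        image[20:25, 20:25] = tpl.pixels
        dets = mtm_detect(image, [tpl])
        assert len(dets) >= 1
        assert min(np.hypot(d.row - 22, d.col - 22) for d in dets) <= 1.5

    def test_hit_count_monotone_in_similarity_threshold(self):
        rng = np.random.default_rng(5)
        image = np.clip(
            rng.normal(70, 40, (80, 80)), 0, 255
        ).astype(np.uint8)
        tpl = make_disc_template(7, 0.77, 60)
        sim = _similarity_map(image, tpl)
        counts = [(sim > thr).sum() for thr in (0.6, 0.7, 0.8, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_union_over_templates_dominates_each_single(self):
        image = np.zeros((60, 200), np.uint8)
        for k, tpl in enumerate(default_templates()):
            s = tpl.side
            image[20 : 20 + s, 20 + 45 * k : 20 + 45 * k + s] = tpl.pixels
        all_dets = mtm_detect(image)
        for tpl in default_templates():
            assert len(mtm_detect(image, [tpl])) <= len(all_dets)


def test_sbp_loses_low_amplitude_dots_that_bpl_keeps():
    """Background subtraction trims faint particles down below threshold."""
    image = np.full((120, 120), 40.0)
    for k in range(5):
        r, c = 20 + 20 * k, 60
        yy, xx = np.mgrid[r - 4 : r + 5, c - 4 : c + 5]
        image[r - 4 : r + 5, c - 4 : c + 5] += 50.0 * np.exp(
            -(np.hypot(yy - r, xx - c) ** 2) / 3.0
        )
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    n_bpl = len(bpl_pipeline(image))
    n_sbp = len(sbp_bpl_pipeline(image))
    assert n_bpl == 5
    assert n_sbp < n_bpl
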