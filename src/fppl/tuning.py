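"""Threshold selection for the pattern discriminant.

The two discriminant thresholds have no universal values: ``th1`` (the
absolute core-brightness floor) must sit between the background level and
the faintest particles of interest, and ``th2`` (the core-periphery
contrast margin) is bounded above by the contrast the image class can
actually deliver -- a particle on a near-white background can only be a
few gray levels brighter than its surroundings.  Thresholds are therefore
tuned per fixture family by a small grid search, the same way binarization
thresholds are optimised for conventional particle labeling.

The selection criterion is the mean, over the tuning fixtures, of
``detection_rate - false_negative_rate - false_positive_rate``; ties are
broken toward the larger (more conservative) ``th2``, then larger ``th1``.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .detect import DEFAULT_DEDUP_RADIUS, DEFAULT_SCALES, detect_multiscale
from .evaluate import DEFAULT_TOLERANCE, evaluate_detections
from .pattern import DiscriminantParams, PatternGeometry, build_pattern
from .synth import FixtureBundle

#: grid for clean dot-array benchmarks (gradient bands, random blocks):
#: backgrounds reach near-saturation, so very small contrast margins are in play
CLEAN_ARRAY_TH1_GRID = (60.0, 80.0, 100.0, 120.0)
CLEAN_ARRAY_TH2_GRID = (2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0)

#: grid for textured micrograph-like images
MICROGRAPH_TH1_GRID = (50.0, 60.0, 70.0, 80.0, 100.0)
MICROGRAPH_TH2_GRID = (20.0, 25.0, 30.0, 40.0)


def grid_search_thresholds(
    fixtures: Sequence[FixtureBundle],
    th1_grid: Sequence[float] = CLEAN_ARRAY_TH1_GRID,
    th2_grid: Sequence[float] = CLEAN_ARRAY_TH2_GRID,
    pattern: PatternGeometry | None = None,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    dedup_radius: float = DEFAULT_DEDUP_RADIUS,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[DiscriminantParams, pd.DataFrame]:
    """Pick the best thresholds for a fixture family by exhaustive search.

    Returns the winning :class:`DiscriminantParams` and the full score
    table (one row per grid point, with the mean detection and error rates
    across fixtures).
    """
    if not fixtures:
        raise ValueError("at least one tuning fixture is required")
    if pattern is None:
        pattern = build_pattern(2)
    rows = []
    for th1 in th1_grid:
        for th2 in th2_grid:
            params = DiscriminantParams(th1=th1, th2=th2)
            dr = fn = fp = 0.0
            for fx in fixtures:
                dets = detect_multiscale(
                    fx.image, scales, pattern, params, dedup_radius
                )
                res = evaluate_detections(dets, fx.reference, tolerance)
                dr += res.detection_rate
                fn += res.false_negative_rate
                fp += res.false_positive_rate
            n = len(fixtures)
            rows.append(
                {
                    "th1": th1,
                    "th2": th2,
                    "detection_rate": dr / n,
                    "false_negative_rate": fn / n,
                    "false_positive_rate": fp / n,
                    "score": (dr - fn - fp) / n,
                }
            )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["score", "th2", "th1"], ascending=[False, False, False]
    ).iloc[0]
    return DiscriminantParams(th1=float(best.th1), th2=float(best.th2)), table
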