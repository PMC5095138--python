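"""Benchmark harness: run several detectors over several fixtures.

Ties the detectors, the synthetic generators and the evaluator together:
for every (detector, fixture) pair the detector runs, the detections are
matched against the fixture's ground truth, and per-image rates are
collected; the summary reports each detector's mean and standard error
across images.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .baselines import (
    BplParams,
    bpl_pipeline,
    default_templates,
    fep_bpl_pipeline,
    mtm_detect,
    sbp_bpl_pipeline,
)
from .detect import Detection, detect_multiscale
from .evaluate import evaluate_detections, summarize_images
from .imgio import RunConfig
from .pattern import DiscriminantParams, build_pattern
from .synth import FixtureBundle

logger = logging.getLogger("fppl")


def run_detector(name: str, image: np.ndarray, config: RunConfig) -> list[Detection]:
    """Dispatch one detector by name with parameters from the config."""
    if name == "fppl":
        return detect_multiscale(
            image,
            scales=config.scales,
            pattern=build_pattern(config.gap_width),
            params=DiscriminantParams(th1=config.th1, th2=config.th2),
            dedup_radius=config.dedup_radius,
        )
    bpl_params = BplParams(
        binarize_threshold=config.binarize_threshold,
        min_area=config.min_area,
        max_area=config.max_area,
    )
    if name == "bpl":
        return bpl_pipeline(image, bpl_params)
    if name == "sbp_bpl":
        return sbp_bpl_pipeline(image, bpl_params, radius=config.rolling_ball_radius)
    if name == "fep_bpl":
        return fep_bpl_pipeline(image, bpl_params)
    if name == "mtm":
        return mtm_detect(
            image, default_templates(), dedup_radius=config.dedup_radius
        )
    raise ValueError(f"unknown detector {name!r}")


def run_benchmark(
    config: RunConfig,
    fixtures: list[FixtureBundle],
    detectors: tuple[str, ...] = ("fppl", "sbp_bpl", "fep_bpl", "bpl", "mtm"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every detector on every fixture.

    Returns ``(per_image, summary)``: one row per (detector, image) with
    counts and rates, and one row per (detector, rate) with mean and SE
    across images.  A failure in any stage aborts with the failing pair
    named in the log.
    """
    if not fixtures:
        raise ValueError("at least one fixture is required")
    if not detectors:
        raise ValueError("at least one detector is required")
    rows = []
    per_detector: dict[str, list] = {d: [] for d in detectors}
    for name in detectors:
        for k, fx in enumerate(fixtures):
            label = fx.provenance.get("generator", "fixture")
            seed = fx.provenance.get("seed", "-")
            try:
                dets = run_detector(name, fx.image, config)
                res = evaluate_detections(dets, fx.reference, config.tolerance)
            except Exception:
                logger.exception(
                    "benchmark failed at detector=%s fixture=%s#%s (index %d)",
                    name, label, seed, k,
                )
                raise
            per_detector[name].append(res)
            rows.append(
                {
                    "detector": name,
                    "fixture": f"{label}#{seed}",
                    "n_cyan": res.n_cyan,
                    "n_red": res.n_red,
                    "n_green": res.n_green,
                    "detection_rate": res.detection_rate,
                    "false_negative_rate": res.false_negative_rate,
                    "false_positive_rate": res.false_positive_rate,
                }
            )
            logger.info(
                "%s on %s#%s: DR=%.1f%% FN=%.1f%% FP=%.1f%%",
                name, label, seed, res.detection_rate,
                res.false_negative_rate, res.false_positive_rate,
            )
    per_image = pd.DataFrame(rows)
    summaries = []
    for name in detectors:
        s = summarize_images(per_detector[name]).reset_index()
        s.insert(0, "detector", name)
        summaries.append(s)
    return per_image, pd.concat(summaries, ignore_index=True)
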