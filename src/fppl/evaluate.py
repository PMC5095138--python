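"""Matching detections to reference annotations and scoring detectors.

A detector is scored against manually marked reference points by one-to-one
spatial matching within a distance tolerance.  Matched detections are
*cyan*, unmatched references *red* (false negatives) and unmatched
detections *light green* (false positives), and three rates follow:

* detection rate       = 100 * N_cyan / (N_cyan + N_red)
* false-negative rate  = 100 * N_red  / (N_cyan + N_red)
* false-positive rate  = 100 * N_green / (N_cyan + N_green)

Detection and false-negative rates are exact complements.  The matching
tolerance is a genuine free parameter of the evaluation (annotation
positions are only accurate to a few pixels), so it is carried in every
result record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Detection

DEFAULT_TOLERANCE = 5.0

#: overlay colours (RGB)
CYAN = (0, 255, 255)
RED = (255, 64, 64)
LIGHT_GREEN = (144, 238, 144)


@dataclass(frozen=True)
class ReferenceSet:
    """Ground-truth particle positions, optionally with per-point sizes.

    ``points`` is an (n, 2) array of (row, col) pixel coordinates; ``sizes``
    (dot height in pixels) is optional and enables size-stratified rates.
    """

    points: np.ndarray
    sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[1] != 2:
            raise ValueError("reference points must be (n, 2) (row, col)")
        object.__setattr__(self, "points", pts)
        if self.sizes is not None:
            sizes = np.asarray(self.sizes, dtype=float)
            if sizes.shape[0] != pts.shape[0]:
                raise ValueError("sizes must align with points")
            if (sizes <= 0).any():
                raise ValueError("sizes must be positive")
            object.__setattr__(self, "sizes", sizes)

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class EvaluationResult:
    """Counts and rates of one detector run on one image."""

    n_cyan: int
    n_red: int
    n_green: int
    detection_rate: float
    false_negative_rate: float
    false_positive_rate: float
    tolerance: float = DEFAULT_TOLERANCE

    @property
    def rates(self) -> dict[str, float]:
        return {
            "detection_rate": self.detection_rate,
            "false_negative_rate": self.false_negative_rate,
            "false_positive_rate": self.false_positive_rate,
        }


def _coords(detections: list[Detection] | np.ndarray) -> np.ndarray:
    if isinstance(detections, np.ndarray):
        arr = np.atleast_2d(detections.astype(float))
        return arr.reshape(0, 2) if arr.size == 0 else arr
    return np.array([(d.row, d.col) for d in detections], dtype=float).reshape(-1, 2)


def match_points(
    detections: list[Detection] | np.ndarray,
    reference: ReferenceSet,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Greedy nearest-first one-to-one matching within a tolerance.

    Candidate (detection, reference) pairs with distance <= tolerance are
    sorted by ascending distance (ties broken by detection then reference
    index) and accepted greedily while both members are unused.

    Returns ``(pairs, unmatched_reference_indices, unmatched_detection_indices)``
    where each pair is ``(detection_index, reference_index, distance)``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    det = _coords(detections)
    ref = reference.points
    pairs: list[tuple[int, int, float]] = []
    if len(det) and len(ref):
        dist = np.hypot(
            det[:, 0:1] - ref[None, :, 0], det[:, 1:2] - ref[None, :, 1]
        )
        cand = np.argwhere(dist <= tolerance)
        order = sorted(
            ((dist[i, j], i, j) for i, j in cand), key=lambda t: (t[0], t[1], t[2])
        )
        used_det: set[int] = set()
        used_ref: set[int] = set()
        for d, i, j in order:
            if i in used_det or j in used_ref:
                continue
            used_det.add(int(i))
            used_ref.add(int(j))
            pairs.append((int(i), int(j), float(d)))
    matched_det = {i for i, _, _ in pairs}
    matched_ref = {j for _, j, _ in pairs}
    unmatched_ref = [j for j in range(len(ref)) if j not in matched_ref]
    unmatched_det = [i for i in range(len(det)) if i not in matched_det]
    return pairs, unmatched_ref, unmatched_det


def compute_rates(
    n_cyan: int, n_red: int, n_green: int, tolerance: float = DEFAULT_TOLERANCE
) -> EvaluationResult:
    """Rates from matched / false-negative / false-positive counts.

    Degenerate denominators: with no references the detection and
    false-negative rates are NaN (not applicable); with no detections the
    false-positive rate is 0.
    """
    if min(n_cyan, n_red, n_green) < 0:
        raise ValueError("counts must be non-negative")
    n_ref = n_cyan + n_red
    n_det = n_cyan + n_green
    det_rate = 100.0 * n_cyan / n_ref if n_ref else float("nan")
    fn_rate = 100.0 * n_red / n_ref if n_ref else float("nan")
    fp_rate = 100.0 * n_green / n_det if n_det else 0.0
    return EvaluationResult(
        n_cyan=int(n_cyan),
        n_red=int(n_red),
        n_green=int(n_green),
        detection_rate=det_rate,
        false_negative_rate=fn_rate,
        false_positive_rate=fp_rate,
        tolerance=tolerance,
    )


def evaluate_detections(
    detections: list[Detection] | np.ndarray,
    reference: ReferenceSet,
    tolerance: float = DEFAULT_TOLERANCE,
) -> EvaluationResult:
    """Match and score in one step."""
    pairs, unmatched_ref, unmatched_det = match_points(
        detections, reference, tolerance
    )
    return compute_rates(
        len(pairs), len(unmatched_ref), len(unmatched_det), tolerance=tolerance
    )


def size_stratified_rates(
    detections: list[Detection] | np.ndarray,
    reference: ReferenceSet,
    tolerance: float = DEFAULT_TOLERANCE,
    size_bins: tuple[float, ...] = (0.0, 4.0, 8.0, 17.0),
) -> pd.DataFrame:
    """Detection rates per particle-size bin.

    Matching is done once, globally; references are then partitioned by the
    ``size_bins`` edges (bin i covers ``[edges[i], edges[i+1])``) and the
    detection / false-negative rates are computed per bin.  False positives
    carry no reference size, so the false-positive rate is only defined
    globally and is not part of the table.
    """
    if reference.sizes is None:
        raise ValueError("size-stratified rates require a reference with sizes")
    edges = np.asarray(size_bins, dtype=float)
    if (reference.sizes < edges[0]).any() or (reference.sizes >= edges[-1]).any():
        raise ValueError("size_bins do not cover all reference sizes")
    pairs, _, _ = match_points(detections, reference, tolerance)
    matched_ref = {j for _, j, _ in pairs}
    which = np.digitize(reference.sizes, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        idx = np.flatnonzero(which == b)
        n_cyan = sum(1 for j in idx if j in matched_ref)
        n_red = len(idx) - n_cyan
        res = compute_rates(n_cyan, n_red, 0, tolerance=tolerance)
        rows.append(
            {
                "size_lo": edges[b],
                "size_hi": edges[b + 1],
                "n_reference": len(idx),
                "n_cyan": n_cyan,
                "n_red": n_red,
                "detection_rate": res.detection_rate,
                "false_negative_rate": res.false_negative_rate,
            }
        )
    return pd.DataFrame(rows)


def _draw_disc(canvas: np.ndarray, row: float, col: float, radius: int, color) -> None:
    h, w = canvas.shape[:2]
    r0 = int(round(row))
    c0 = int(round(col))
    rows = np.arange(max(0, r0 - radius), min(h, r0 + radius + 1))
    cols = np.arange(max(0, c0 - radius), min(w, c0 + radius + 1))
    if rows.size == 0 or cols.size == 0:
        return
    dr = rows[:, None] - row
    dc = cols[None, :] - col
    mask = np.hypot(dr, dc) <= radius
    patch = canvas[np.ix_(rows, cols)]
    patch[mask] = color
    canvas[np.ix_(rows, cols)] = patch


def render_overlay(
    image: np.ndarray,
    matched: np.ndarray | list,
    unmatched_refs: np.ndarray | list,
    unmatched_dets: np.ndarray | list,
    mark_radius: int = 3,
) -> np.ndarray:
    """Colour-coded result image.

    Cyan discs mark matched detections, red discs unmatched references and
    light-green discs unmatched detections, composited over the grayscale
    image.  Returns an (H, W, 3) uint8 array.
    """
    gray = np.asarray(image)
    canvas = np.stack([gray] * 3, axis=-1).astype(np.uint8)
    for pts, color in (
        (matched, CYAN),
        (unmatched_refs, RED),
        (unmatched_dets, LIGHT_GREEN),
    ):
        for p in np.atleast_2d(np.asarray(pts, dtype=float)).reshape(-1, 2):
            _draw_disc(canvas, p[0], p[1], mark_radius, color)
    return canvas


def summarize_images(results: list[EvaluationResult]) -> pd.DataFrame:
    """Mean and standard error of each rate across images.

    SE = sd / sqrt(n) with the sample (n-1) standard deviation.  For a
    single image the SE is undefined and reported as 0 with
    ``se_defined = False``.
    """
    if not results:
        raise ValueError("at least one evaluation result is required")
    n = len(results)
    rows = []
    for rate in ("detection_rate", "false_negative_rate", "false_positive_rate"):
        values = np.array([getattr(r, rate) for r in results], dtype=float)
        mean = float(np.nanmean(values))
        if n > 1:
            se = float(np.nanstd(values, ddof=1) / math.sqrt(n))
            defined = True
        else:
            se = 0.0
            defined = False
        rows.append(
            {"rate": rate, "mean": mean, "se": se, "n": n, "se_defined": defined}
        )
    return pd.DataFrame(rows).set_index("rate")
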