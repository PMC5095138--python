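"""Conventional particle-labeling baselines.

Four comparison detectors, mirroring an ImageJ-style workflow:

* **BPL** (basic particle labeling): global binarization, connected
  components, area filter.
* **SBP+BPL**: rolling-ball background subtraction before BPL, which
  flattens broad background structures (hole-like artifacts) but also
  lowers the brightness of small faint particles.
* **FEP+BPL**: Sobel gradient-magnitude edge enhancement before BPL, which
  recovers small low-contrast particles but also enhances background mesh
  edges into false positives.
* **MTM** (multiple template matching): normalized L1 similarity against
  several disc templates of different sizes, each with its own similarity
  threshold.

All baselines emit the same :class:`~fppl.detect.Detection` records as the
pattern detector so one evaluation path serves every method.  BPL-family
outputs are post-filtered by a brighter-than-periphery test on the original
image, since the target particles are brighter than their background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, restoration

from .detect import DEFAULT_DEDUP_RADIUS, Detection


@dataclass(frozen=True)
class BplParams:
    """Binarize-and-label parameters (ImageJ ``Analyze Particles`` style)."""

    binarize_threshold: float = 60.0
    min_area: int = 3
    max_area: int = 200
    exclude_on_edges: bool = False
    include_holes: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_area <= self.max_area):
            raise ValueError(
                f"need 0 < min_area <= max_area, got {self.min_area}, {self.max_area}"
            )


def bpl_detect(image: np.ndarray, params: BplParams | None = None) -> list[Detection]:
    """Threshold, label 8-connected components, keep those in the area band.

    Pixels strictly above ``binarize_threshold`` are foreground.  Components
    with ``min_area <= area <= max_area`` become detections at their
    centroid (``core_mean`` is the component's mean intensity).
    """
    if params is None:
        params = BplParams()
    image = np.asarray(image)
    mask = image > params.binarize_threshold
    if params.include_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    detections: list[Detection] = []
    for region in measure.regionprops(labels, intensity_image=image):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        if params.exclude_on_edges:
            r0, c0, r1, c1 = region.bbox
            if r0 == 0 or c0 == 0 or r1 == image.shape[0] or c1 == image.shape[1]:
                continue
        cy, cx = region.centroid
        detections.append(
            Detection(
                row=float(cy),
                col=float(cx),
                scale=1.0,
                core_mean=float(region.intensity_mean),
            )
        )
    detections.sort(key=lambda d: (d.row, d.col))
    return detections


def subtract_background(image: np.ndarray, radius: float = 20.0) -> np.ndarray:
    """Rolling-ball background subtraction (no pre-smoothing).

    A ball of the given radius rolled under the intensity surface yields the
    background estimate; subtracting it flattens structures broader than the
    ball while preserving small bright features.  Output is clamped to
    0-255.
    """
    if radius <= 0:
        raise ValueError("rolling-ball radius must be positive")
    image = np.asarray(image)
    background = restoration.rolling_ball(image.astype(float), radius=radius)
    return np.clip(np.rint(image.astype(float) - background), 0, 255).astype(np.uint8)


def find_edges(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, clamped to 0-255 (ImageJ ``Find Edges``)."""
    img = np.asarray(image).astype(float)
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    return np.clip(np.rint(np.hypot(gx, gy)), 0, 255).astype(np.uint8)


def brighter_than_periphery_filter(
    image: np.ndarray,
    detections: list[Detection],
    annulus_inner: float = 3.0,
    annulus_outer: float = 8.0,
) -> list[Detection]:
    """Drop detections that are not brighter than their surroundings.

    Keeps a detection only when the mean intensity within a disc of radius
    ``annulus_inner`` around it exceeds the mean in the annulus
    ``(annulus_inner, annulus_outer]``.  Out-of-bounds parts of the annulus
    are ignored.  Removes dark-centre artifacts (e.g. hole-like structures)
    that a binarization or edge detector can otherwise latch onto.
    """
    if not annulus_inner < annulus_outer:
        raise ValueError("annulus_inner must be smaller than annulus_outer")
    image = np.asarray(image).astype(float)
    h, w = image.shape
    kept: list[Detection] = []
    r_out = int(math.ceil(annulus_outer))
    for det in detections:
        r0 = int(round(det.row))
        c0 = int(round(det.col))
        rows = np.arange(max(0, r0 - r_out), min(h, r0 + r_out + 1))
        cols = np.arange(max(0, c0 - r_out), min(w, c0 + r_out + 1))
        dr = rows[:, None] - det.row
        dc = cols[None, :] - det.col
        dist = np.hypot(dr, dc)
        patch = image[np.ix_(rows, cols)]
        inner = dist <= annulus_inner
        outer = (dist > annulus_inner) & (dist <= annulus_outer)
        if not inner.any() or not outer.any():
            continue
        if patch[inner].mean() > patch[outer].mean():
            kept.append(det)
    return kept


# ---------------------------------------------------------------------------
# multiple template matching


@dataclass(frozen=True, eq=False)
class Template:
    """One disc template with its similarity threshold.

    ``pixels`` renders a bright (255) disc of diameter ``side - 2`` centred
    on a uniform field at ``background_level``; an image window counts as a
    match when ``Sim > similarity_threshold``.
    """

    side: int
    pixels: np.ndarray = field(repr=False)
    similarity_threshold: float
    background_level: int

    def __post_init__(self) -> None:
        if self.side % 2 == 0 or self.side < 3:
            raise ValueError("template side must be odd and >= 3")
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.pixels.shape != (self.side, self.side):
            raise ValueError("template pixel array does not match side")


def make_disc_template(
    side: int, similarity_threshold: float, background_level: int
) -> Template:
    """Render a centred bright disc of diameter ``side - 2``."""
    half = (side - 1) // 2
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    disc = np.hypot(rr, cc) <= (side - 2) / 2.0
    pixels = np.full((side, side), background_level, dtype=np.uint8)
    pixels[disc] = 255
    return Template(
        side=side,
        pixels=pixels,
        similarity_threshold=similarity_threshold,
        background_level=background_level,
    )


def default_templates() -> list[Template]:
    """The four disc templates used for micrograph template matching.

    Sides 5/7/9/11 with similarity thresholds 0.80/0.77/0.74/0.70 and
    template background levels 55/60/65/70.
    """
    spec = [(5, 0.80, 55), (7, 0.77, 60), (9, 0.74, 65), (11, 0.70, 70)]
    return [make_disc_template(s, t, b) for s, t, b in spec]


def template_similarity(
    image: np.ndarray, template: Template, position: tuple[int, int]
) -> float:
    """Normalized L1 similarity of one image window against a template.

    With the window anchored at ``position`` (top-left, (row, col)):

    ``D = (1 / (255 * w * h)) * sum_ij |I(row+i, col+j) - T(i, j)|`` and
    ``Sim = 1 - D``, in [0, 1].
    """
    image = np.asarray(image)
    r, c = position
    s = template.side
    if r < 0 or c < 0 or r + s > image.shape[0] or c + s > image.shape[1]:
        raise ValueError(f"template window at {position} falls outside the image")
    window = image[r : r + s, c : c + s].astype(np.int64)
    d = np.abs(window - template.pixels.astype(np.int64)).sum() / (255.0 * s * s)
    return 1.0 - d


def _similarity_map(image: np.ndarray, template: Template) -> np.ndarray:
    """``Sim`` at every valid top-left anchor, via shifted accumulation."""
    img = np.asarray(image).astype(np.int64)
    s = template.side
    n_r = img.shape[0] - s + 1
    n_c = img.shape[1] - s + 1
    acc = np.zeros((n_r, n_c), dtype=np.int64)
    tpl = template.pixels.astype(np.int64)
    for i in range(s):
        for j in range(s):
            acc += np.abs(img[i : i + n_r, j : j + n_c] - tpl[i, j])
    return 1.0 - acc / (255.0 * s * s)


def mtm_detect(
    image: np.ndarray,
    templates: list[Template] | None = None,
    dedup_radius: float = DEFAULT_DEDUP_RADIUS,
) -> list[Detection]:
    """Multiple template matching.

    For each template, centre positions where ``Sim`` exceeds that
    template's similarity threshold are clustered (8-connectivity) into
    candidate detections scored by their best ``Sim``.  Candidates from all
    templates are then unified: within ``dedup_radius`` the highest-scoring
    candidate wins.
    """
    if templates is None:
        templates = default_templates()
    if not templates:
        raise ValueError("at least one template is required")
    image = np.asarray(image)

    scored: list[tuple[float, Detection]] = []
    for template in templates:
        s = template.side
        if image.shape[0] < s or image.shape[1] < s:
            continue
        sim = _similarity_map(image, template)
        hits = sim > template.similarity_threshold
        labels = measure.label(hits, connectivity=2)
        half = s // 2
        for lab in range(1, labels.max() + 1):
            coords = np.argwhere(labels == lab)
            best = float(sim[coords[:, 0], coords[:, 1]].max())
            row = float(coords[:, 0].mean()) + half
            col = float(coords[:, 1].mean()) + half
            scored.append(
                (
                    best,
                    Detection(
                        row=row,
                        col=col,
                        scale=1.0,
                        core_mean=float(image[int(round(row)), int(round(col))]),
                    ),
                )
            )

    scored.sort(key=lambda t: (-t[0], t[1].row, t[1].col))
    kept: list[Detection] = []
    for _, det in scored:
        if any(
            (det.row - k.row) ** 2 + (det.col - k.col) ** 2 <= dedup_radius**2
            for k in kept
        ):
            continue
        kept.append(det)
    kept.sort(key=lambda d: (d.row, d.col))
    return kept


# ---------------------------------------------------------------------------
# full baseline pipelines (preprocess -> label -> brightness filter)


def bpl_pipeline(
    image: np.ndarray,
    params: BplParams | None = None,
    brightness_filter: bool = True,
) -> list[Detection]:
    """Plain binarize-and-label detection with the brightness post-filter."""
    dets = bpl_detect(image, params)
    if brightness_filter:
        dets = brighter_than_periphery_filter(image, dets)
    return dets


def sbp_bpl_pipeline(
    image: np.ndarray,
    params: BplParams | None = None,
    radius: float = 20.0,
    brightness_filter: bool = True,
) -> list[Detection]:
    """Rolling-ball background subtraction followed by binarize-and-label."""
    dets = bpl_detect(subtract_background(image, radius=radius), params)
    if brightness_filter:
        dets = brighter_than_periphery_filter(image, dets)
    return dets


def fep_bpl_pipeline(
    image: np.ndarray,
    params: BplParams | None = None,
    brightness_filter: bool = True,
) -> list[Detection]:
    """Sobel edge enhancement followed by binarize-and-label."""
    dets = bpl_detect(find_edges(image), params)
    if brightness_filter:
        dets = brighter_than_periphery_filter(image, dets)
    return dets
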