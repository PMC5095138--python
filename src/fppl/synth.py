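"""Synthetic test-image generators with exact ground truth.

Every generator returns a :class:`FixtureBundle` holding the 8-bit image,
a machine-readable reference point set (with per-dot sizes) and a
provenance record sufficient to regenerate the image bit-exactly.  The
fixtures emulate the situations a particle detector for electron
micrographs has to cope with:

* a panel of bright dots of graded size and ellipticity on black, for
  mapping a pattern's detectable size/shape range;
* a 144-dot array (12 x 12, three dot sizes, peak intensities 145-255)
  over four horizontal grayscale gradient bands;
* the same dot array with each dot centred on a square block of uniformly
  random brightness in [2, 247];
* micrograph-like images: textured background, bright soft-profile
  particles, optional dark hole artifacts with a nebulous bright centre,
  and optional thin bright mesh strands;
* a size ladder of isolated dots for scale-coverage experiments, and a
  clutter image with large elongated blobs for over-shrinking experiments.

Dots are composited *additively with saturation* (pixel = min(255,
background + profile)), the way a bright particle adds signal on top of
whatever lies beneath it; this keeps every dot at least marginally brighter
than its local background, as the imaging physics dictates.  Dot profiles
are hard (binary ellipse), soft (1-px anti-aliased edge) or gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import ndimage

from .evaluate import ReferenceSet

__all__ = [
    "DotSpec",
    "FixtureBundle",
    "render_dot",
    "make_dot_panel",
    "make_gradient_band_image",
    "make_random_block_image",
    "make_sem_like_image",
    "make_scale_ladder",
    "make_clutter_image",
    "regenerate",
    "GENERATORS",
]


@dataclass(frozen=True)
class DotSpec:
    """One rendered dot: centre, height (px), width/height ratio, peak."""

    row: float
    col: float
    height: float
    aspect: float = 1.0
    peak: float = 255.0
    dot_id: int = 0

    def __post_init__(self) -> None:
        if self.height < 1:
            raise ValueError("dot height must be >= 1 px")
        if self.aspect < 1:
            raise ValueError("aspect is width/height and must be >= 1")
        if not (0 <= self.peak <= 255):
            raise ValueError("peak intensity must be in [0, 255]")


@dataclass(frozen=True)
class FixtureBundle:
    """Image + ground truth + provenance for one synthetic fixture."""

    image: np.ndarray
    reference: ReferenceSet
    provenance: dict[str, Any]
    dots: tuple[DotSpec, ...] = ()


def _snap(coord: float, size: int) -> float:
    """Centre coordinate aligned to the pixel grid for an exact bounding box.

    Odd sizes centre on a pixel, even sizes on a pixel boundary, so a hard
    dot of height ``h`` covers exactly ``h`` rows.
    """
    return round(coord) if size % 2 == 1 else np.floor(coord) + 0.5


def render_dot(
    canvas: np.ndarray,
    dot: DotSpec,
    profile: str = "soft",
) -> None:
    """Composite one dot onto a float canvas, additively with saturation."""
    h = float(dot.height)
    w = max(1.0, round(dot.height * dot.aspect))
    semi_y, semi_x = h / 2.0, w / 2.0
    reach = int(np.ceil(max(semi_y, semi_x))) + 2
    r0 = int(np.floor(dot.row)) - reach
    c0 = int(np.floor(dot.col)) - reach
    rows = np.arange(max(0, r0), min(canvas.shape[0], r0 + 2 * reach + 2))
    cols = np.arange(max(0, c0), min(canvas.shape[1], c0 + 2 * reach + 2))
    if rows.size == 0 or cols.size == 0:
        return
    dy = (rows[:, None] - dot.row) / semi_y
    dx = (cols[None, :] - dot.col) / semi_x
    val = dy**2 + dx**2
    if profile == "hard":
        cov = (val <= 1.0).astype(float)
    elif profile == "soft":
        t = (1.0 - np.sqrt(val)) * min(semi_x, semi_y)
        cov = np.clip(t + 0.5, 0.0, 1.0)
    elif profile == "gaussian":
        cov = np.where(val <= 4.0, np.exp(-2.3 * val), 0.0)
    else:
        raise ValueError(f"unknown dot profile {profile!r}")
    patch = canvas[np.ix_(rows, cols)]
    np.minimum(patch + dot.peak * cov, 255.0, out=patch)
    canvas[np.ix_(rows, cols)] = patch


def _bundle(
    canvas: np.ndarray,
    dots: Sequence[DotSpec],
    provenance: dict[str, Any],
) -> FixtureBundle:
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    pts = np.array([(d.row, d.col) for d in dots], dtype=float).reshape(-1, 2)
    sizes = np.array([d.height for d in dots], dtype=float)
    ref = ReferenceSet(points=pts, sizes=sizes if len(dots) else None)
    return FixtureBundle(
        image=image, reference=ref, provenance=provenance, dots=tuple(dots)
    )


# ---------------------------------------------------------------------------
# deterministic panels


PANEL_HEIGHTS = (2, 4, 8, 16)
PANEL_ASPECTS = (1.0, 1.5, 2.0, 3.0)


def make_dot_panel(profile: str = "hard") -> FixtureBundle:
    """4 x 4 panel of white dots of graded size and shape on black.

    Sixteen dots with heights {2, 4, 8, 16} crossed with width/height
    ratios {1.0, 1.5, 2.0, 3.0}, all at peak 255 on a 0 background, spaced
    three times the largest dot width apart so neighbouring dots never
    interact with the scanning pattern.
    """
    largest_width = round(PANEL_HEIGHTS[-1] * PANEL_ASPECTS[-1])
    pitch = 3 * largest_width
    margin = 80
    side = 2 * margin + (len(PANEL_HEIGHTS) - 1) * pitch
    canvas = np.zeros((side, side), dtype=float)
    dots = []
    for i, h in enumerate(PANEL_HEIGHTS):
        for j, a in enumerate(PANEL_ASPECTS):
            w = round(h * a)
            dot = DotSpec(
                row=_snap(margin + i * pitch, h),
                col=_snap(margin + j * pitch, w),
                height=h,
                aspect=a,
                peak=255.0,
                dot_id=i * len(PANEL_ASPECTS) + j,
            )
            render_dot(canvas, dot, profile=profile)
            dots.append(dot)
    return _bundle(
        canvas, dots, {"generator": "dot_panel", "params": {"profile": profile}}
    )


#: canonical dimensions of the 144-dot benchmark images
_ARRAY_SHAPE = (360, 480)
#: the three dot heights used in the 144-dot arrays
_ARRAY_DOT_SIZES = (3, 5, 9)
#: horizontal gradients of the four background bands (left value, right value)
_BAND_GRADIENTS = ((255, 0), (43, 232), (232, 43), (0, 255))


def _array_dots() -> list[DotSpec]:
    """The fixed 12 x 12 dot layout shared by the two benchmark images.

    Columns step the peak intensity from 145 (left) to 255 (right); the
    three rows within each band cycle through the three dot sizes.
    """
    dots = []
    for i in range(12):
        h = _ARRAY_DOT_SIZES[i % 3]
        for j in range(12):
            dots.append(
                DotSpec(
                    row=_snap(15 + 30 * i, h),
                    col=_snap(20 + 40 * j, h),
                    height=h,
                    aspect=1.0,
                    peak=145.0 + 10.0 * j,
                    dot_id=i * 12 + j,
                )
            )
    return dots


def make_gradient_band_image(profile: str = "hard") -> FixtureBundle:
    """144-dot array over four horizontal grayscale gradient bands.

    Bands (top to bottom) run linearly white-to-black (255 -> 0),
    43 -> 232, 232 -> 43 and black-to-white (0 -> 255) across the image
    width; dot peaks span 145-255 by column.  Deterministic.
    """
    h, w = _ARRAY_SHAPE
    canvas = np.zeros((h, w), dtype=float)
    x = np.arange(w) / (w - 1)
    band_height = h // len(_BAND_GRADIENTS)
    for b, (left, right) in enumerate(_BAND_GRADIENTS):
        canvas[b * band_height : (b + 1) * band_height, :] = left + (right - left) * x
    dots = _array_dots()
    for dot in dots:
        render_dot(canvas, dot, profile=profile)
    return _bundle(
        canvas,
        dots,
        {"generator": "gradient_bands", "params": {"profile": profile}},
    )


def make_random_block_image(seed: int, profile: str = "hard") -> FixtureBundle:
    """The same 144-dot layout, each dot centred on a random-brightness block.

    Every dot sits on its own 30 x 30 square whose uniform brightness is
    drawn from the integers [2, 247] with the seeded generator; the dot
    layout itself is fixed, so different seeds share identical ground truth.
    """
    rng = np.random.default_rng(seed)
    h, w = _ARRAY_SHAPE
    canvas = np.zeros((h, w), dtype=float)
    dots = _array_dots()
    half_block = 15
    for dot in dots:
        level = float(rng.integers(2, 248))
        r0 = int(round(dot.row - half_block))
        c0 = int(round(dot.col - half_block))
        canvas[max(0, r0) : r0 + 2 * half_block, max(0, c0) : c0 + 2 * half_block] = (
            level
        )
    for dot in dots:
        render_dot(canvas, dot, profile=profile)
    return _bundle(
        canvas,
        dots,
        {
            "generator": "random_blocks",
            "seed": int(seed),
            "params": {"profile": profile},
        },
    )


# ---------------------------------------------------------------------------
# micrograph-like images


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, std: float
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to a target standard deviation."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = raw.std()
    return raw * (std / s) if s > 0 else raw


#: particle heights (px) and their sampling weights in micrograph-like
#: fixtures -- strongly biased toward small particles, as in tissue images
#: where sub-micron particles dominate.
_SEM_HEIGHTS = (2, 3, 4, 5, 6, 8, 10, 12, 14, 16)
_SEM_WEIGHTS = (0.22, 0.18, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04, 0.03, 0.02)


def make_sem_like_image(
    n_particles: int = 40,
    seed: int = 0,
    holes: bool = True,
    mesh: bool = True,
    shape: tuple[int, int] = (360, 360),
) -> FixtureBundle:
    """Micrograph-like fixture: textured background, particles, artifacts.

    The background is smoothed noise around level 40 (coarse undulation plus
    fine texture).  ``n_particles`` gaussian-profile dots with seeded sizes
    (2-16 px, small-biased) and peaks uniform in [90, 255] are placed with a
    14-px border margin and 18-px minimum separation, away from hole
    centres.  Optional artifacts: dark hole-like discs (radius 22, floor
    ~20) with a nebulous bright centre, and thin bright mesh-like strands a
    little below the typical binarization threshold.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    canvas = (
        38.0
        + _smooth_noise(rng, shape, sigma=24.0, std=5.0)
        + _smooth_noise(rng, shape, sigma=2.0, std=3.0)
    )
    canvas = np.clip(canvas, 0, 255)

    hole_centres: list[tuple[float, float]] = []
    if holes:
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(2):
            cy = float(rng.uniform(50, h - 50))
            cx = float(rng.uniform(50, w - 50))
            hole_centres.append((cy, cx))
            dist = np.hypot(yy - cy, xx - cx)
            inside = np.clip((22.0 - dist) / 2.0 + 0.5, 0.0, 1.0)  # soft rim
            canvas = canvas * (1 - inside) + 20.0 * inside
            canvas += 55.0 * np.exp(-(dist**2) / (2 * 8.0**2))  # nebulous centre

    if mesh:
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(12):
            y0 = rng.uniform(20, h - 20)
            x0 = rng.uniform(20, w - 20)
            ang = rng.uniform(0, 2 * np.pi)
            curv = rng.uniform(-0.02, 0.02)
            t = np.linspace(0, rng.uniform(25, 40), 60)
            ys = y0 + t * np.sin(ang) + curv * t**2
            xs = x0 + t * np.cos(ang)
            strand = np.zeros(shape)
            for y, x in zip(ys, xs):
                if 2 <= y < h - 2 and 2 <= x < w - 2:
                    strand[int(round(y)), int(round(x))] = 1.0
            strand = ndimage.gaussian_filter(strand, 0.5)
            if strand.max() > 0:
                # bright but (mostly) below the usual binarization
                # threshold: edge enhancement turns these sharp strands
                # into detections that plain binarization rarely sees
                canvas += 16.0 * strand / strand.max()
    canvas = np.clip(canvas, 0, 255)

    margin, min_sep, hole_clear = 14.0, 18.0, 34.0
    dots: list[DotSpec] = []
    attempts = 0
    while len(dots) < n_particles and attempts < 20000:
        attempts += 1
        row = rng.uniform(margin, h - margin)
        col = rng.uniform(margin, w - margin)
        if any(np.hypot(row - d.row, col - d.col) < min_sep for d in dots):
            continue
        if any(np.hypot(row - cy, col - cx) < hole_clear for cy, cx in hole_centres):
            continue
        height = int(rng.choice(_SEM_HEIGHTS, p=_SEM_WEIGHTS))
        dots.append(
            DotSpec(
                row=row,
                col=col,
                height=height,
                aspect=float(rng.uniform(1.0, 1.6)),
                peak=float(rng.uniform(90, 255)),
                dot_id=len(dots),
            )
        )
    if len(dots) < n_particles:
        raise RuntimeError("could not place all particles; lower n_particles")
    for dot in dots:
        render_dot(canvas, dot, profile="gaussian")
    return _bundle(
        canvas,
        dots,
        {
            "generator": "sem_like",
            "seed": int(seed),
            "params": {
                "n_particles": int(n_particles),
                "holes": bool(holes),
                "mesh": bool(mesh),
                "shape": [int(h), int(w)],
            },
        },
    )


def make_scale_ladder(
    sizes: Sequence[int] = (2, 4, 8, 16), seed: int = 0
) -> FixtureBundle:
    """One soft-profile dot per requested size on a clean background.

    Used to map which sizes each pyramid scale detects.  The modest peak
    (120 over a level-20 background) makes the smallest dots genuinely
    sub-resolution at native scale: a 2-px dot dilutes below the core
    brightness floor until the image is enlarged, while the plateau top of
    a 16-px dot floods the peripheral blocks until the image is shrunk.
    """
    if not sizes:
        raise ValueError("sizes must be nonempty")
    rng = np.random.default_rng(seed)  # reserved for future jitter; unused
    del rng
    pitch = 80
    h = 160
    w = 2 * 80 + (len(sizes) - 1) * pitch
    canvas = np.full((h, w), 20.0)
    dots = []
    for k, size in enumerate(sizes):
        dots.append(
            DotSpec(
                row=_snap(h / 2, int(size)),
                col=_snap(80 + k * pitch, int(size)),
                height=int(size),
                aspect=1.0,
                peak=120.0,
                dot_id=k,
            )
        )
    for dot in dots:
        render_dot(canvas, dot, profile="soft")
    return _bundle(
        canvas,
        dots,
        {
            "generator": "scale_ladder",
            "seed": int(seed),
            "params": {"sizes": [int(s) for s in sizes]},
        },
    )


def make_clutter_image(seed: int = 0) -> FixtureBundle:
    """Small target dots plus large elongated bright clutter blobs.

    The clutter blobs (heights 14-20 px, strongly elongated) are far larger
    than the scanning pattern at native scale and at 50% but collapse to
    pattern size at 25%, so an over-shrunk pyramid starts labelling them --
    the hazard that motivates stopping the scale range at 50%.  Only the
    small dots are listed in the reference.
    """
    rng = np.random.default_rng(seed)
    del rng  # layout is fixed; the seed is provenance only
    canvas = np.full((240, 320), 15.0)
    dots = [
        DotSpec(row=60.0, col=60.0, height=4, aspect=1.0, peak=230.0, dot_id=0),
        DotSpec(row=60.0, col=160.0, height=6, aspect=1.0, peak=230.0, dot_id=1),
        DotSpec(row=60.0, col=260.0, height=3, aspect=1.0, peak=230.0, dot_id=2),
    ]
    for dot in dots:
        render_dot(canvas, dot, profile="gaussian")
    clutter = [
        DotSpec(row=160.0, col=80.0, height=16, aspect=2.0, peak=220.0, dot_id=100),
        DotSpec(row=170.0, col=200.0, height=20, aspect=2.5, peak=220.0, dot_id=101),
        DotSpec(row=150.0, col=290.0, height=16, aspect=1.8, peak=220.0, dot_id=102),
    ]
    for blob in clutter:
        render_dot(canvas, blob, profile="soft")
    return _bundle(
        canvas, dots, {"generator": "clutter", "seed": int(seed), "params": {}}
    )


# ---------------------------------------------------------------------------
# provenance

GENERATORS: dict[str, Callable[..., FixtureBundle]] = {
    "dot_panel": make_dot_panel,
    "gradient_bands": make_gradient_band_image,
    "random_blocks": make_random_block_image,
    "sem_like": make_sem_like_image,
    "scale_ladder": make_scale_ladder,
    "clutter": make_clutter_image,
}


def regenerate(provenance: dict[str, Any]) -> FixtureBundle:
    """Rebuild a fixture bit-exactly from its provenance record."""
    name = provenance["generator"]
    fn = GENERATORS[name]
    kwargs = dict(provenance.get("params", {}))
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if "sizes" in kwargs:
        kwargs["sizes"] = tuple(kwargs["sizes"])
    if "seed" in provenance:
        kwargs["seed"] = provenance["seed"]
    return fn(**kwargs)
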