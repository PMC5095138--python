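"""Image, annotation and configuration I/O.

Images are 8-bit grayscale PNG or TIFF; colour inputs are converted by
luminance weighting and 16-bit inputs are rescaled linearly to 8 bits.
Detections and reference annotations travel as small CSV files with an
``x,y`` convention (x = column, y = row), matching common image-annotation
tools.  Run configuration is a flat ``key = value`` text file; every CLI
run writes its resolved configuration (including the seed) next to its
outputs so any result can be regenerated bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .detect import DEFAULT_DEDUP_RADIUS, DEFAULT_SCALES, Detection
from .evaluate import DEFAULT_TOLERANCE, ReferenceSet

DETECTOR_NAMES = ("fppl", "bpl", "sbp_bpl", "fep_bpl", "mtm")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit grayscale array.

    Colour images are reduced with the standard luminance weights; 16-bit
    grayscale is rescaled linearly (x / 257) to 8-bit depth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as img:
            if img.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(img, dtype=np.float64)
                return np.clip(np.rint(arr / 257.0), 0, 255).astype(np.uint8)
            if img.mode != "L":
                img = img.convert("L")
            return np.asarray(img, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read {path} as a grayscale image: {exc}") from exc


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a uint8 grayscale or RGB array as PNG/TIFF."""
    Image.fromarray(np.asarray(image)).save(Path(path))


# ---------------------------------------------------------------------------
# CSV conventions: comma-separated, UTF-8, mandatory header, '.' decimals,
# floats with two decimals -- a bit-exact contract for reproducibility tests.


def write_detections_csv(path: str | Path, detections: list[Detection]) -> None:
    lines = ["x,y,scale,core_mean,min_contrast"]
    for d in detections:
        lines.append(
            f"{d.col:.2f},{d.row:.2f},{d.scale:.2f},"
            f"{d.core_mean:.2f},{d.min_contrast:.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_detections_csv(path: str | Path) -> list[Detection]:
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if not lines or lines[0].split(",")[:2] != ["x", "y"]:
        raise ValueError(f"{path}: expected a detections CSV with an x,y header")
    out = []
    for line in lines[1:]:
        x, y, scale, core_mean, min_contrast = (float(v) for v in line.split(","))
        out.append(
            Detection(
                row=y, col=x, scale=scale, core_mean=core_mean,
                min_contrast=min_contrast,
            )
        )
    return out


def write_reference_csv(path: str | Path, reference: ReferenceSet) -> None:
    has_size = reference.sizes is not None
    lines = ["x,y,size" if has_size else "x,y"]
    for i, (row, col) in enumerate(reference.points):
        rec = f"{col:.2f},{row:.2f}"
        if has_size:
            rec += f",{reference.sizes[i]:.2f}"
        lines.append(rec)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_reference_csv(path: str | Path) -> ReferenceSet:
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if not lines or lines[0].split(",")[:2] != ["x", "y"]:
        raise ValueError(f"{path}: expected a reference CSV with an x,y header")
    has_size = lines[0].split(",")[2:] == ["size"]
    points, sizes = [], []
    for line in lines[1:]:
        vals = [float(v) for v in line.split(",")]
        points.append((vals[1], vals[0]))
        if has_size:
            sizes.append(vals[2])
    return ReferenceSet(
        points=np.array(points, dtype=float).reshape(-1, 2),
        sizes=np.array(sizes) if has_size and sizes else None,
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved parameters of one detection/evaluation run."""

    detector: str = "fppl"
    gap_width: int = 2
    th1: float = 70.0
    th2: float = 25.0
    scales: tuple[float, ...] = DEFAULT_SCALES
    dedup_radius: float = DEFAULT_DEDUP_RADIUS
    binarize_threshold: float = 60.0
    min_area: int = 3
    max_area: int = 200
    rolling_ball_radius: float = 20.0
    annulus_inner: float = 3.0
    annulus_outer: float = 8.0
    tolerance: float = DEFAULT_TOLERANCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detector not in DETECTOR_NAMES:
            raise ValueError(
                f"unknown detector {self.detector!r}; choose from {DETECTOR_NAMES}"
            )
        self.scales = tuple(float(s) for s in self.scales)
        if any(s <= 0 for s in self.scales):
            raise ValueError("all scale factors must be positive")

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "scales":
                value = ",".join(repr(s) for s in value)
            lines.append(f"{f.name} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            if key == "scales":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key == "detector":
                kwargs[key] = value
            elif key in ("gap_width", "min_area", "max_area", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))

    def hash(self) -> str:
        """Short digest identifying the resolved configuration."""
        return hashlib.sha1(self.to_text().encode()).hexdigest()[:12]
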