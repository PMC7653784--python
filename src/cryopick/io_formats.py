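"""Micrograph and coordinate I/O in the community formats the pipeline touches.

Internal coordinate convention (fixed once, applied everywhere):
0-based, top-left origin, half-open boxes ``[x, x+w) x [y, y+h)``.
Dialect conversions (EMAN .box lower-left origin, RELION STAR centers)
happen only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import imageio.v3 as iio
import numpy as np

__all__ = [
    "Micrograph",
    "BoundingBox",
    "ParticleCandidate",
    "PickSet",
    "Config",
    "MicrographFormatError",
    "read_micrograph",
    "write_micrograph",
    "write_box",
    "read_box",
    "write_star",
    "read_star",
    "write_truth_tsv",
    "read_truth_tsv",
    "load_config",
]


class MicrographFormatError(ValueError):
    """Raised when a micrograph file cannot be parsed; names the offending field."""


@dataclass(eq=False)
class Micrograph:
    """A 2D intensity grid with optional pixel-size metadata (Angstrom/px)."""

    pixels: np.ndarray
    pixel_size: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"micrograph must be 2D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("micrograph dimensions must be >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [x, x+w) x [y, y+h), top-left origin."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width and height must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> int:
        return self.w * self.h

    def intersects_image(self, height: int, width: int) -> bool:
        return self.x < width and self.y < height and self.x + self.w > 0 and self.y + self.h > 0


@dataclass(frozen=True)
class ParticleCandidate:
    """A detection: bounding box, class label, and a probability score in [0, 1]."""

    box: BoundingBox
    score: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class PickSet:
    """All candidates picked from one micrograph."""

    micrograph_id: str
    candidates: list[ParticleCandidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)


# ---------------------------------------------------------------------------
# MRC / PNG / TIFF micrographs
# ---------------------------------------------------------------------------

_MRC_MODE_BYTES = {0: 1, 1: 2, 2: 4, 6: 2}


def _validate_mrc_header(path: Path) -> None:
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise MicrographFormatError(
            f"{path}: truncated MRC header ({len(raw)} bytes, need 1024)"
        )
    nx, ny, nz, mode = struct.unpack("<4i", raw[:16])
    if mode not in _MRC_MODE_BYTES:
        raise MicrographFormatError(
            f"{path}: unsupported MRC header field 'mode' = {mode} (supported: 0, 1, 2, 6)"
        )
    for name, val in (("nx", nx), ("ny", ny), ("nz", nz)):
        if val < 1:
            raise MicrographFormatError(f"{path}: invalid MRC header field '{name}' = {val}")
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    expected = 1024 + nsymbt + nx * ny * nz * _MRC_MODE_BYTES[mode]
    if len(raw) < expected:
        raise MicrographFormatError(
            f"{path}: truncated MRC data (header field 'nx*ny*nz' implies "
            f"{expected} bytes, file has {len(raw)})"
        )


def read_micrograph(path: str | Path, format_hint: str | None = None) -> Micrograph:
    """Read an MRC (modes 0/1/2/6), PNG or TIFF micrograph.

    MRC pixel size is recovered from the cell dimensions when present
    (cell_a / nx); files written with a unit cell report no pixel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt in ("mrc", "mrcs", "map"):
        _validate_mrc_header(path)
        ccp4 = gemmi.read_ccp4_map(str(path))
        arr = np.array(ccp4.grid, copy=True)  # (nx, ny, nz), x fastest in file
        if arr.ndim != 3 or arr.shape[2] != 1:
            raise MicrographFormatError(
                f"{path}: MRC header field 'nz' = {arr.shape[2] if arr.ndim == 3 else '?'}; "
                "expected a single 2D section"
            )
        img = arr[:, :, 0].T  # -> (ny, nx) row-major image
        spacing = ccp4.grid.spacing[0]
        pixel_size = float(spacing) if abs(spacing * ccp4.grid.nu - ccp4.grid.nu) > 1e-9 else None
        return Micrograph(img.astype(np.float64), pixel_size=pixel_size, source_path=str(path))
    if fmt in ("png", "tif", "tiff"):
        img = np.asarray(iio.imread(path)).astype(np.float64)
        if img.ndim == 3:  # collapse RGB(A) to gray
            img = img[..., :3].mean(axis=2)
        return Micrograph(img, source_path=str(path))
    raise MicrographFormatError(f"{path}: unknown micrograph format '{fmt}'")


def write_micrograph(m: Micrograph, path: str | Path) -> None:
    """Write MRC mode 2 (32-bit float), or PNG/TIFF by extension."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt in ("mrc", "map"):
        data = np.ascontiguousarray(m.pixels.T[:, :, None].astype(np.float32))
        grid = gemmi.FloatGrid(data)
        if m.pixel_size is not None:
            grid.set_unit_cell(
                gemmi.UnitCell(
                    m.width * m.pixel_size, m.height * m.pixel_size, m.pixel_size, 90, 90, 90
                )
            )
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))
    elif fmt == "png":
        lo, hi = float(m.pixels.min()), float(m.pixels.max())
        scaled = np.zeros_like(m.pixels) if hi == lo else (m.pixels - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
    elif fmt in ("tif", "tiff"):
        iio.imwrite(path, m.pixels.astype(np.float32))
    else:
        raise MicrographFormatError(f"{path}: unknown output format '{fmt}'")


# ---------------------------------------------------------------------------
# EMAN .box coordinates (lower-left origin)
# ---------------------------------------------------------------------------

def write_box(pickset: PickSet, path: str | Path, image_height: int | None = None) -> None:
    """EMAN .box dialect: one ``x_ll y_ll w h`` line per particle, lower-left origin.

    The vertical flip ``y_box = H - (y + h)`` needs the image height.
    """
    if image_height is None:
        raise ValueError("write_box requires image_height for the lower-left-origin flip")
    lines = []
    for cand in pickset.candidates:
        b = cand.box
        lines.append(f"{b.x}\t{image_height - (b.y + b.h)}\t{b.w}\t{b.h}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_box(path: str | Path, image_height: int, label: str = "particle") -> PickSet:
    candidates = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        x, y_ll, w, h = (int(round(float(v))) for v in line.split())
        candidates.append(
            ParticleCandidate(BoundingBox(x, image_height - (y_ll + h), w, h), 1.0, label)
        )
    return PickSet(micrograph_id=str(path), candidates=candidates)


# ---------------------------------------------------------------------------
# RELION coordinate STAR (box centers)
# ---------------------------------------------------------------------------

_STAR_HEADER = """
data_

loop_
_rlnCoordinateX #1
_rlnCoordinateY #2
_rlnAutopickFigureOfMerit #3
""".lstrip()


def write_star(pickset: PickSet, path: str | Path) -> None:
    """RELION coordinate STAR: box centers in 0-based pixel units plus score."""
    rows = []
    for cand in pickset.candidates:
        cx, cy = cand.box.center
        rows.append(f"{cx:.6f} {cy:.6f} {cand.score:.6f}")
    Path(path).write_text(_STAR_HEADER + "\n".join(rows) + ("\n" if rows else ""))


def read_star(path: str | Path, box_w: int, box_h: int, label: str = "particle") -> PickSet:
    """Rebuild boxes from a coordinate STAR given the known box size."""
    candidates = []
    in_loop = False
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("loop_"):
            in_loop = True
            continue
        if not in_loop or not stripped or stripped.startswith(("_", "data_", "#")):
            continue
        parts = stripped.split()
        cx, cy = float(parts[0]), float(parts[1])
        score = float(parts[2]) if len(parts) > 2 else 1.0
        box = BoundingBox(int(round(cx - box_w / 2)), int(round(cy - box_h / 2)), box_w, box_h)
        candidates.append(ParticleCandidate(box, min(max(score, 0.0), 1.0), label))
    return PickSet(micrograph_id=str(path), candidates=candidates)


# ---------------------------------------------------------------------------
# Ground-truth TSV (x_center, y_center, width, height, label)
# ---------------------------------------------------------------------------

def write_truth_tsv(boxes: Sequence[BoundingBox], labels: Sequence[str], path: str | Path) -> None:
    lines = ["x_center\ty_center\twidth\theight\tlabel"]
    for box, label in zip(boxes, labels, strict=True):
        cx, cy = box.center
        lines.append(f"{cx:.1f}\t{cy:.1f}\t{box.w}\t{box.h}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tsv(path: str | Path) -> tuple[list[BoundingBox], list[str]]:
    boxes, labels = [], []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        cx, cy, w, h, label = line.split("\t")
        w, h = int(w), int(h)
        boxes.append(BoundingBox(int(round(float(cx) - w / 2)), int(round(float(cy) - h / 2)), w, h))
        labels.append(label)
    return boxes, labels


# ---------------------------------------------------------------------------
# Plain-text key=value configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Pipeline configuration with the published defaults.

    window: CNN input patch edge (227 px). scaling_step: candidate scale-factor
    step (0.125). learning_rate: initial SGD eta (1e-4). Remaining keys are
    detection/selection defaults; stride of 0 means "window // 4".
    """

    window: int = 227
    scaling_step: float = 0.125
    learning_rate: float = 0.0001
    stride: int = 0
    score_threshold: float = 0.5
    closeness_tol: float = 0.2
    max_region_area: int = 0
    iou_threshold: float = 0.3
    particle_size: int = 180
    jaccard_min: float = 0.8
    area_frac: float = 0.7
    overlap_factor: float = 1.5
    cht_vote_frac: float = 0.5
    min_area: int = 20
    border_margin: int = 1
    seed: int = 0
    classes: tuple[str, ...] = ("top_view", "side_view", "irregular", "background", "negative")

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.stride < 0:
            raise ValueError("stride must be >= 0 (0 means window // 4)")
        if self.scaling_step <= 0:
            raise ValueError("scaling_step must be positive")

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride > 0 else max(1, self.window // 4)

    @property
    def effective_max_region_area(self) -> int:
        if self.max_region_area > 0:
            return self.max_region_area
        return int(2 * (self.window / self.effective_stride) ** 2)


def load_config(path: str | Path) -> Config:
    """Parse a ``key = value`` text file; unknown keys error listing valid ones."""
    valid = {f.name: f for f in dataclasses.fields(Config)}
    kwargs: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = stripped.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise ValueError(
                f"{path}:{lineno}: unknown config key '{key}'; valid keys: "
                + ", ".join(sorted(valid))
            )
        ftype = valid[key].type
        if key == "classes":
            kwargs[key] = tuple(v.strip() for v in value.split(","))
        elif ftype == "int":
            kwargs[key] = int(value)
        elif ftype == "float":
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return Config(**kwargs)
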