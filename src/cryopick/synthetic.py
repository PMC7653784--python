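"""Synthetic low-SNR micrograph generator with known particle coordinates.

Emulates the three projection classes seen in single-particle cryo-EM data —
circular top views, square side views, and irregular/complex shapes — drawn
bright on a dark background, with optional intensity gradient, bright ice-like
artifacts, and additive Gaussian noise. Every run is fully determined by the
spec's seed, so downstream stages can be regression-tested without external
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .io_formats import BoundingBox, Micrograph

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PlacementError",
    "generate_micrograph",
    "generate_with_clean",
    "estimate_snr",
    "noise_sigma_for_snr",
]

_SHAPES = ("disc", "square", "irregular")
_MAX_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested particles."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic micrograph.

    Intensities are relative units; the clean image is background_level plus
    particle_intensity inside particles, before noise. ``target_snr``, when
    set, overrides ``noise_sigma`` so that var(clean signal) / var(noise)
    equals the requested ratio.
    """

    image_height: int = 360
    image_width: int = 360
    particle_shape: str = "disc"
    n_particles: int = 20
    particle_size: int = 28
    particle_intensity: float = 0.6
    background_level: float = 0.2
    noise_sigma: float = 0.1
    target_snr: float | None = None
    n_ice_blobs: int = 2
    min_separation: int = 48
    n_clipped_particles: int = 0
    gradient_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particle_shape not in _SHAPES:
            raise ValueError(f"particle_shape must be one of {_SHAPES}")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.particle_size >= min(self.image_height, self.image_width):
            raise ValueError("particle_size must be smaller than the image")


@dataclass
class GroundTruth:
    """Tight boxes, class labels and clipped flags for the generated particles."""

    boxes: list[BoundingBox] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    clipped: list[bool] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes and labels must have equal length")

    def centers(self) -> np.ndarray:
        """(n, 2) array of (x, y) box centers."""
        return np.array([b.center for b in self.boxes], dtype=float).reshape(-1, 2)


def _draw_particle(rng: np.random.Generator, shape: str, size: int, canvas: np.ndarray,
                   cy: float, cx: float, value: float) -> tuple[slice, slice]:
    """Add one particle to the canvas; returns row/col slices of its tight box."""
    h, w = canvas.shape
    if shape == "disc":
        rr, cc = draw_disk((cy, cx), size / 2.0, shape=canvas.shape)
    elif shape == "square":
        half = size // 2
        r0, r1 = int(cy) - half, int(cy) - half + size
        c0, c1 = int(cx) - half, int(cx) - half + size
        rr, cc = np.mgrid[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)]
        rr, cc = rr.ravel(), cc.ravel()
    else:  # irregular: union of 3-6 overlapping random ellipses in the bounding size
        n_lobes = int(rng.integers(3, 7))
        rows, cols = [], []
        for _ in range(n_lobes):
            dy, dx = rng.uniform(-size / 5, size / 5, size=2)
            a = rng.uniform(size / 6, size / 3.2)
            b = rng.uniform(size / 6, size / 3.2)
            theta = rng.uniform(0, math.pi)
            r_e, c_e = draw_ellipse(cy + dy, cx + dx, a, b, shape=canvas.shape, rotation=theta)
            rows.append(r_e)
            cols.append(c_e)
        rr = np.concatenate(rows)
        cc = np.concatenate(cols)
    canvas[rr, cc] = np.maximum(canvas[rr, cc], value)
    return (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))


def _place_centers(rng: np.random.Generator, spec: SyntheticSpec,
                   existing: list[tuple[float, float]], n: int,
                   lo_margin: float, hi_margin: float) -> list[tuple[float, float]]:
    """Rejection-sample n centers at min_separation from every existing center."""
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= _MAX_ATTEMPTS:
            raise PlacementError(
                f"cannot place {n} particles at min_separation={spec.min_separation} "
                f"in a {spec.image_height}x{spec.image_width} image after {_MAX_ATTEMPTS} attempts"
            )
        attempts += 1
        cy = rng.uniform(lo_margin, spec.image_height - hi_margin)
        cx = rng.uniform(lo_margin, spec.image_width - hi_margin)
        if all((cy - ey) ** 2 + (cx - ex) ** 2 >= spec.min_separation ** 2
               for ey, ex in existing + placed):
            placed.append((cy, cx))
    return placed


def generate_with_clean(spec: SyntheticSpec) -> tuple[Micrograph, Micrograph, GroundTruth]:
    """Generate (noisy, clean, truth); the clean image is the pre-noise signal."""
    rng = np.random.default_rng(spec.seed)
    clean = np.full((spec.image_height, spec.image_width), spec.background_level, dtype=float)

    margin = spec.particle_size / 2 + 2
    n_interior = spec.n_particles - spec.n_clipped_particles
    if n_interior < 0:
        raise ValueError("n_clipped_particles cannot exceed n_particles")
    centers = _place_centers(rng, spec, [], n_interior, margin, margin)
    # clipped particles: centers sit within a quarter-size band of the border so
    # part of the shape falls outside the frame (emulates edge-cut particles)
    clipped_centers: list[tuple[float, float]] = []
    for _ in range(spec.n_clipped_particles):
        for attempt in range(_MAX_ATTEMPTS):
            side = rng.integers(0, 4)
            off = rng.uniform(0, spec.particle_size / 4)
            along_y = rng.uniform(margin, spec.image_height - margin)
            along_x = rng.uniform(margin, spec.image_width - margin)
            cand = [(off, along_x), (spec.image_height - 1 - off, along_x),
                    (along_y, off), (along_y, spec.image_width - 1 - off)][side]
            if all((cand[0] - ey) ** 2 + (cand[1] - ex) ** 2 >= spec.min_separation ** 2
                   for ey, ex in centers + clipped_centers):
                clipped_centers.append(cand)
                break
        else:
            raise PlacementError("cannot place clipped particles at min_separation")

    level = spec.background_level + spec.particle_intensity
    truth = GroundTruth(seed=spec.seed)
    for (cy, cx), is_clipped in [(c, False) for c in centers] + [(c, True) for c in clipped_centers]:
        rows, cols = _draw_particle(rng, spec.particle_shape, spec.particle_size,
                                    clean, cy, cx, level)
        truth.boxes.append(BoundingBox(int(cols.start), int(rows.start),
                                       int(cols.stop - cols.start), int(rows.stop - rows.start)))
        truth.labels.append(spec.particle_shape)
        truth.clipped.append(is_clipped)

    # bright ice-like artifacts, kept clear of particles and of the border
    ice_centers = _place_centers(rng, spec, centers + clipped_centers, spec.n_ice_blobs,
                                 margin, margin) if spec.n_ice_blobs else []
    for cy, cx in ice_centers:
        # ice contamination: bright, irregular, elongated - unlike any particle
        ice_level = level * rng.uniform(1.2, 1.5)
        theta = rng.uniform(0, math.pi)
        for _ in range(int(rng.integers(2, 5))):
            dy, dx = rng.uniform(-spec.particle_size / 4, spec.particle_size / 4, size=2)
            a = rng.uniform(spec.particle_size * 0.5, spec.particle_size * 0.9)
            b = rng.uniform(spec.particle_size * 0.15, spec.particle_size * 0.35)
            rr, cc = draw_ellipse(cy + dy, cx + dx, a, b, shape=clean.shape,
                                  rotation=theta + rng.uniform(-0.3, 0.3))
            clean[rr, cc] = np.maximum(clean[rr, cc], ice_level)

    if spec.gradient_strength:
        # linear illumination gradient across the field
        gy = np.linspace(-1, 1, spec.image_height)[:, None]
        gx = np.linspace(-1, 1, spec.image_width)[None, :]
        clean = clean + spec.gradient_strength * (gy + 0.5 * gx)

    sigma = spec.noise_sigma
    if spec.target_snr is not None:
        sigma = noise_sigma_for_snr(clean, spec.target_snr)
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean.copy()

    tag = f"synthetic:{spec.particle_shape}:seed{spec.seed}"
    return (Micrograph(noisy, source_path=tag),
            Micrograph(clean, source_path=tag + ":clean"), truth)


def generate_micrograph(spec: SyntheticSpec) -> tuple[Micrograph, GroundTruth]:
    """Generate one noisy synthetic micrograph and its ground truth."""
    noisy, _clean, truth = generate_with_clean(spec)
    return noisy, truth


def noise_sigma_for_snr(clean: np.ndarray | Micrograph, snr: float) -> float:
    """Noise sd giving var(clean - mean) / var(noise) == snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    arr = clean.pixels if isinstance(clean, Micrograph) else np.asarray(clean)
    return float(np.sqrt(arr.var() / snr))


def estimate_snr(clean: Micrograph, noisy: Micrograph) -> float:
    """var(clean - mean(clean)) / var(noisy - clean); infinite when noise-free."""
    if clean.pixels.shape != noisy.pixels.shape:
        raise ValueError("clean and noisy micrographs must share dimensions")
    signal_var = float(clean.pixels.var())
    noise_var = float((noisy.pixels - clean.pixels).var())
    if noise_var == 0.0:
        return math.inf
    return signal_var / noise_var
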