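"""Fully automated picking on test micrographs.

The testing pipeline: choose a scaling factor (multiples of 0.125) that brings
the average detected particle size just under the sliding window, rescale and
zero-pad the micrograph to even dimensions, enhance it, score every window
position with the trained classifier, clean the resulting score map by
connected-region analysis, and reduce overlapping candidates by greedy
non-maximum suppression. Picked boxes are mapped back to original-micrograph
coordinates by dividing by the scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .classifier import Network, _predict_in_batches
from .io_formats import BoundingBox, Config, Micrograph, ParticleCandidate, PickSet
from .preprocess import PreprocessParams, preprocess_chain

__all__ = [
    "ScalingDecision",
    "ScoreMap",
    "ParticleCandidate",
    "select_scaling",
    "rescale_and_pad",
    "sliding_window_scores",
    "clean_score_map",
    "iou",
    "nms",
    "pick_particles",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScalingDecision:
    """Outcome of automatic micrograph scaling selection."""

    operation: str  # "up" | "down" | "none"
    factor: float   # multiple of the step; 1.0 when operation == "none"
    scaled_particle: int

    def __post_init__(self) -> None:
        if self.operation not in ("up", "down", "none"):
            raise ValueError("operation must be 'up', 'down' or 'none'")
        if self.factor <= 0:
            raise ValueError("factor must be positive")


@dataclass(eq=False)
class ScoreMap:
    """Class-probability vectors over the sliding-window grid.

    scores: (gy, gx, C); grid position (i, j) corresponds to the window whose
    top-left corner is (y = i * stride, x = j * stride).
    """

    scores: np.ndarray
    stride: int
    window: int
    class_names: list[str]

    def __post_init__(self) -> None:
        if self.scores.ndim != 3 or self.scores.shape[2] != len(self.class_names):
            raise ValueError("scores must be (gy, gx, n_classes)")


# ---------------------------------------------------------------------------
# automatic scaling
# ---------------------------------------------------------------------------

def select_scaling(avg_particle: float, window: int, step: float = 0.125
                   ) -> ScalingDecision:
    """Choose the scale factor bringing the average particle size closest to,
    but not above, the sliding window.

    Candidate factors are multiples of ``step`` (> 1 for up-sampling when the
    particle is smaller than the window, < 1 for down-sampling otherwise).
    When even the smallest up-sampling factor overshoots the window, no
    scaling is selected.
    """
    if avg_particle <= 0 or window <= 0 or step <= 0:
        raise ValueError("avg_particle, window and step must be positive")
    if avg_particle == window:
        return ScalingDecision("none", 1.0, int(avg_particle))
    if avg_particle < window:
        operation = "up"
        n_max = int(math.ceil((window * 1.0 / avg_particle) / step)) + 2
        factors = [1.0 + k * step for k in range(1, n_max + 1)]
    else:
        operation = "down"
        n_max = int(1.0 / step)
        factors = [1.0 - k * step for k in range(1, n_max) if 1.0 - k * step > 0]
    best: tuple[int, float] | None = None
    for f in factors:
        scaled = _round_half_up(avg_particle * f)
        if scaled <= window and (best is None or scaled > best[0]):
            best = (scaled, f)
    if best is None or (operation == "up" and best[0] <= _round_half_up(avg_particle)):
        # the smallest admissible factor does not improve on the unscaled size
        return ScalingDecision("none", 1.0, _round_half_up(avg_particle))
    return ScalingDecision(operation, best[1], best[0])


def rescale_and_pad(m: Micrograph, decision: ScalingDecision) -> Micrograph:
    """Bilinear rescale by the chosen factor, then zero-pad the right/bottom
    edge so both dimensions are even."""
    a = m.pixels
    if decision.operation != "none" and decision.factor != 1.0:
        new_h = _round_half_up(m.height * decision.factor)
        new_w = _round_half_up(m.width * decision.factor)
        a = resize(a, (new_h, new_w), order=1, preserve_range=True,
                   anti_aliasing=decision.factor < 1.0)
    pad_h = a.shape[0] % 2
    pad_w = a.shape[1] % 2
    if pad_h or pad_w:
        a = np.pad(a, ((0, pad_h), (0, pad_w)))
    return Micrograph(a, pixel_size=m.pixel_size, source_path=m.source_path)


# ---------------------------------------------------------------------------
# sliding-window scoring
# ---------------------------------------------------------------------------

def sliding_window_scores(m: Micrograph | np.ndarray, model: Network,
                          window: int, stride: int, batch: int = 256) -> ScoreMap:
    """Score every window position with the classifier, scanning top-left to
    bottom-right at a constant step."""
    a = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)
    h, w = a.shape
    if window > h or window > w:
        raise ValueError(f"window {window} exceeds micrograph dims {a.shape}")
    if window != model.input_size:
        raise ValueError(f"window {window} does not match model input {model.input_size}")
    gy = (h - window) // stride + 1
    gx = (w - window) // stride + 1
    patches = np.empty((gy * gx, 1, window, window))
    for i in range(gy):
        for j in range(gx):
            y, x = i * stride, j * stride
            patches[i * gx + j, 0] = a[y:y + window, x:x + window]
    if model.input_channels > 1:
        patches = np.repeat(patches, model.input_channels, axis=1)
    probs = _predict_in_batches(model, patches, batch=batch)
    class_names = model.class_names or [f"class{i}" for i in range(model.class_count)]
    return ScoreMap(probs.reshape(gy, gx, -1), stride=stride, window=window,
                    class_names=list(class_names))


# ---------------------------------------------------------------------------
# score-map cleaning
# ---------------------------------------------------------------------------

def clean_score_map(sm: ScoreMap, particle_class: str, score_threshold: float = 0.5,
                    max_region_area: int | None = None,
                    closeness_tol: float = 0.2) -> list[ParticleCandidate]:
    """Threshold the particle-class scores, join 8-neighboring positions whose
    scores are within ``closeness_tol``, drop regions larger than
    ``max_region_area`` (smeared false positives), and emit one candidate per
    surviving region at its maximum-score position."""
    ci = sm.class_names.index(particle_class)
    grid = sm.scores[:, :, ci]
    gy, gx = grid.shape
    above = grid >= score_threshold
    # union-find over above-threshold neighbors with close scores
    parent = {idx: idx for idx in zip(*np.nonzero(above))}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for (y, x) in list(parent):
        for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (y + dy, x + dx)
            if nb in parent and abs(grid[y, x] - grid[nb]) <= closeness_tol:
                union((y, x), nb)
    regions: dict[tuple, list[tuple]] = {}
    for idx in parent:
        regions.setdefault(find(idx), []).append(idx)
    out: list[ParticleCandidate] = []
    for members in regions.values():
        if max_region_area is not None and len(members) > max_region_area:
            continue
        best = max(members, key=lambda ij: (grid[ij], -ij[0], -ij[1]))
        y, x = best
        box = BoundingBox(x * sm.stride, y * sm.stride, sm.window, sm.window)
        out.append(ParticleCandidate(box, float(grid[best]), particle_class))
    out.sort(key=lambda c: (-c.score, c.box.x, c.box.y))
    return out


# ---------------------------------------------------------------------------
# IoU and non-maximum suppression
# ---------------------------------------------------------------------------

def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ix = max(0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def nms(candidates: list[ParticleCandidate], iou_threshold: float = 0.3
        ) -> list[ParticleCandidate]:
    """Greedy per-class suppression: keep the highest-scored box, discard all
    boxes of the same class overlapping it at or above the IoU threshold,
    repeat. Ties break by (score desc, x asc, y asc) for determinism."""
    kept: list[ParticleCandidate] = []
    by_class: dict[str, list[ParticleCandidate]] = {}
    for c in candidates:
        by_class.setdefault(c.label, []).append(c)
    for label in sorted(by_class):
        pool = sorted(by_class[label], key=lambda c: (-c.score, c.box.x, c.box.y))
        while pool:
            best = pool.pop(0)
            kept.append(best)
            pool = [c for c in pool if iou(best.box, c.box) < iou_threshold]
    kept.sort(key=lambda c: (-c.score, c.box.x, c.box.y))
    return kept


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def pick_particles(m: Micrograph, model: Network, config: Config,
                   avg_particle: float | None = None,
                   particle_classes: list[str] | None = None,
                   preprocess_params: PreprocessParams | None = None,
                   preprocess: bool = True) -> PickSet:
    """End-to-end picking on one micrograph.

    avg_particle defaults to config.particle_size (normally the Stage-1
    average detected particle size). Boxes are reported in the original,
    unscaled coordinate frame.
    """
    window = config.window
    avg = float(avg_particle if avg_particle is not None else config.particle_size)
    decision = select_scaling(avg, window, config.scaling_step)
    scaled = rescale_and_pad(m, decision)
    a = scaled.pixels
    if preprocess:
        a = preprocess_chain(a, preprocess_params or PreprocessParams())
    sm = sliding_window_scores(a, model, window, config.effective_stride)
    model_classes = sm.class_names
    if particle_classes is None:
        particle_classes = [c for c in model_classes if c not in ("background", "negative")]
    candidates: list[ParticleCandidate] = []
    for cls in particle_classes:
        candidates.extend(clean_score_map(sm, cls, config.score_threshold,
                                          config.effective_max_region_area,
                                          config.closeness_tol))
    candidates = nms(candidates, config.iou_threshold)
    factor = decision.factor
    out: list[ParticleCandidate] = []
    for c in candidates:
        if factor != 1.0:
            w = max(1, _round_half_up(c.box.w / factor))
            h = max(1, _round_half_up(c.box.h / factor))
            box = BoundingBox(_round_half_up(c.box.x / factor),
                              _round_half_up(c.box.y / factor), w, h)
        else:
            box = c.box
        out.append(ParticleCandidate(box, c.score, c.label))
    return PickSet(micrograph_id=m.source_path or "micrograph", candidates=out)
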