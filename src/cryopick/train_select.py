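"""Stage-2 automated good/bad particle selection and training-set generation.

Each particle mask from Stage 1 is judged without human labels:

* top views (circles): circularity = perimeter^2 / (4 pi area) compared to the
  batch-average roundness, plus overlap with the perfect circle rebuilt from
  the Hough fit;
* side views (squares): Feret min/max ratio near 1/sqrt(2), overlap removal by
  Feret length against the batch median, mask replaced by the perfect square;
* irregular blobs: area against the batch mean and a patch-centering rule.

Accepted crops, background crops and rejected ("negative") crops form a
five-class dataset, balanced by rotation augmentation plus subsampling and
split 80/20/(80/20) into train/validation/test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .cluster_pick import Circle, ComponentMask, feret_diameters
from .io_formats import BoundingBox, Micrograph

__all__ = [
    "TrainingSample",
    "MaskStats",
    "DatasetSplit",
    "CLASS_NAMES",
    "circularity",
    "circularity_value",
    "batch_mask_stats",
    "make_perfect_circle_mask",
    "select_good_topview",
    "select_good_sideview",
    "select_good_irregular",
    "harvest_negatives",
    "augment_rotations",
    "balance_and_split",
]

CLASS_NAMES = ("top_view", "side_view", "irregular", "background", "negative")


@dataclass(frozen=True, eq=False)
class TrainingSample:
    """One labeled fixed-size patch with provenance."""

    patch: np.ndarray
    label: str
    source: str = ""
    rotation: int = 0

    def __post_init__(self) -> None:
        if self.label not in CLASS_NAMES:
            raise ValueError(f"label must be one of {CLASS_NAMES}, got {self.label!r}")
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0, 90, 180, 270")


@dataclass(frozen=True)
class MaskStats:
    """Shape statistics of one mask within its batch context."""

    circularity: float
    area: int
    mean_circularity: float
    mean_area: float

    def __post_init__(self) -> None:
        if self.circularity <= 0 or self.area < 1:
            raise ValueError("circularity must be positive and area >= 1")


@dataclass
class DatasetSplit:
    """Balanced, disjoint train/validation/test samples."""

    train: list[TrainingSample]
    validation: list[TrainingSample]
    test: list[TrainingSample]
    per_class_target: int
    seed: int


# ---------------------------------------------------------------------------
# circularity (roundness)
# ---------------------------------------------------------------------------

def circularity_value(perimeter: float, area: float) -> float:
    """perimeter^2 / (4 pi area); 1 for an ideal circle, 4/pi for a square."""
    if area <= 0:
        raise ValueError("area must be positive")
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return perimeter ** 2 / (4.0 * math.pi * area)


def circularity(c: ComponentMask) -> float:
    """Roundness of a connected component from its contour perimeter and area."""
    return circularity_value(c.perimeter, c.area)


def batch_mask_stats(components: list[ComponentMask]) -> list[MaskStats]:
    """Per-component circularity/area annotated with the batch means."""
    if not components:
        return []
    circs = [circularity(c) for c in components]
    areas = [c.area for c in components]
    mean_c = float(np.mean(circs))
    mean_a = float(np.mean(areas))
    return [MaskStats(ci, a, mean_c, mean_a) for ci, a in zip(circs, areas)]


# ---------------------------------------------------------------------------
# perfect-shape masks
# ---------------------------------------------------------------------------

def _disc_pixels(cy: float, cx: float, radius: float) -> set:
    """Pixel centers within Euclidean distance <= radius of (cy, cx)."""
    r0 = int(math.floor(cy - radius))
    r1 = int(math.ceil(cy + radius)) + 1
    c0 = int(math.floor(cx - radius))
    c1 = int(math.ceil(cx + radius)) + 1
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2
    return {(int(a), int(b)) for a, b in zip(rr[inside], cc[inside])}


def make_perfect_circle_mask(circle: Circle, patch_shape: tuple[int, int]) -> np.ndarray:
    """Filled rasterized disc at the Hough center/radius.

    Pixels within Euclidean distance <= radius are set, so radius 1 rasterizes
    to the 5-pixel plus shape.
    """
    cy, cx = circle.center[1], circle.center[0]
    h, w = patch_shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("circle center lies outside the patch")
    if cx - circle.radius < -0.5 or cx + circle.radius > w - 0.5 \
            or cy - circle.radius < -0.5 or cy + circle.radius > h - 0.5:
        raise ValueError("circle extends outside the patch")
    mask = np.zeros(patch_shape, dtype=bool)
    for r, c in _disc_pixels(cy, cx, circle.radius):
        if 0 <= r < h and 0 <= c < w:
            mask[r, c] = True
    return mask


def _jaccard_pixels(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _component_pixel_set(c: ComponentMask) -> set:
    return {(int(r), int(col)) for r, col in c.pixel_index_list}


# ---------------------------------------------------------------------------
# good/bad selection
# ---------------------------------------------------------------------------

# Roundness acceptance band as a multiple of the batch-average deviation from
# the ideal circle. At 1.0 the rule rejects the above-average half of even a
# clean batch (deviations are one-sided for rasterized discs); 2.0 keeps the
# batch-relative comparison as a gross-outlier filter while the perfect-circle
# overlap floor does the fine discrimination.
ROUNDNESS_BAND_FACTOR = 2.0


def select_good_topview(components: list[ComponentMask],
                        circles: list[Circle | None],
                        jaccard_min: float = 0.8,
                        band_factor: float = ROUNDNESS_BAND_FACTOR,
                        ) -> tuple[list[ComponentMask], list[ComponentMask]]:
    """Partition top-view components into (good, bad).

    A component is good iff a Hough circle was fitted, its roundness achieves
    the batch average (|circ - 1| within ``band_factor`` times |mean_circ - 1|),
    and its overlap with the perfect circle rebuilt from the fit reaches
    ``jaccard_min``.
    """
    if len(components) != len(circles):
        raise ValueError("components and circles must be aligned lists")
    if not components:
        return [], []
    stats = batch_mask_stats(components)
    threshold = band_factor * abs(stats[0].mean_circularity - 1.0)
    good, bad = [], []
    for comp, circ_fit, st in zip(components, circles, stats):
        ok = circ_fit is not None and abs(st.circularity - 1.0) <= threshold + 1e-12
        if ok:
            circle_pixels = _disc_pixels(circ_fit.center[1], circ_fit.center[0],
                                         circ_fit.radius)
            ok = _jaccard_pixels(_component_pixel_set(comp), circle_pixels) >= jaccard_min
        (good if ok else bad).append(comp)
    return good, bad


# min/max Feret of an ideal square = 1/sqrt(2) ~ 0.707; boundary noise biases
# the measured ratio of rasterized squares upward (toward ~0.8), so the band
# reaches 0.9 while still excluding ideal discs (ratio ~ 0.96-1.0)
_SQUARE_RATIO_BAND = (0.6, 0.9)


def select_good_sideview(components: list[ComponentMask],
                         ratio_band: tuple[float, float] = _SQUARE_RATIO_BAND,
                         overlap_factor: float = 1.5,
                         ) -> tuple[list[ComponentMask], list[ComponentMask]]:
    """Partition side-view components into (good, bad).

    Non-square shapes (Feret min/max ratio outside the square band, or area
    below 0.8 * min_diameter^2) are bad; components whose max Feret diameter
    exceeds ``overlap_factor`` times the batch median are removed as
    overlapped particles. Survivors are replaced by the perfect square mask
    built from their Feret dimensions.
    """
    if not components:
        return [], []
    ferets = [feret_diameters(c) for c in components]
    square_like = [
        ratio_band[0] <= f.ratio <= ratio_band[1] and c.area >= 0.8 * f.min_diameter ** 2
        for c, f in zip(components, ferets)
    ]
    max_ds = [f.max_diameter for f, s in zip(ferets, square_like) if s]
    median_max = float(np.median(max_ds)) if max_ds else 0.0
    good, bad = [], []
    for comp, f, is_sq in zip(components, ferets, square_like):
        if not is_sq or f.max_diameter > overlap_factor * median_max:
            bad.append(comp)
            continue
        side = max(1, int(round(f.min_diameter)))
        cx, cy = comp.centroid
        x0, y0 = int(round(cx - side / 2)), int(round(cy - side / 2))
        square = np.ones((side, side), dtype=bool)
        coords = np.stack(np.mgrid[y0:y0 + side, x0:x0 + side], axis=-1).reshape(-1, 2)
        good.append(ComponentMask(
            mask=square, offset=(x0, y0), area=side * side,
            perimeter=4.0 * (side - 1) if side > 1 else 1.0,
            centroid=(x0 + (side - 1) / 2, y0 + (side - 1) / 2),
            pixel_index_list=coords, patch_shape=comp.patch_shape,
        ))
    return good, bad


def select_good_irregular(components: list[ComponentMask], area_frac: float = 0.7,
                          ) -> tuple[list[ComponentMask], list[ComponentMask]]:
    """Partition irregular components into (good, bad).

    Good iff area >= area_frac * batch mean area (rejects fragments) and the
    centroid lies within the central half of the component's extraction patch
    (rejects edge-cut particles).
    """
    if not components:
        return [], []
    mean_area = float(np.mean([c.area for c in components]))
    good, bad = [], []
    for comp in components:
        ok = comp.area >= area_frac * mean_area
        if ok:
            if comp.patch_shape is not None:
                # component was labeled inside an extraction patch: centroid is
                # already in the patch frame
                ph, pw = comp.patch_shape
                local_cx, local_cy = comp.centroid
            else:
                ph, pw = comp.mask.shape
                local_cx = comp.centroid[0] - comp.offset[0]
                local_cy = comp.centroid[1] - comp.offset[1]
            ok = (pw / 4 <= local_cx <= 3 * pw / 4) and (ph / 4 <= local_cy <= 3 * ph / 4)
        (good if ok else bad).append(comp)
    return good, bad


# ---------------------------------------------------------------------------
# negatives and background
# ---------------------------------------------------------------------------

def harvest_negatives(m: Micrograph | np.ndarray, particle_boxes: list[BoundingBox],
                      n: int, patch_size: int, seed: int = 0,
                      bad_components: list[ComponentMask] | None = None,
                      ) -> list[TrainingSample]:
    """Background crops disjoint from all particle boxes, plus crops of the
    rejected components labeled as the negative-detection class."""
    a = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)
    h, w = a.shape
    rng = np.random.default_rng(seed)
    samples: list[TrainingSample] = []
    attempts = 0
    while len(samples) < n and attempts < 10_000:
        attempts += 1
        x0 = int(rng.integers(0, w - patch_size + 1))
        y0 = int(rng.integers(0, h - patch_size + 1))
        crop_box = BoundingBox(x0, y0, patch_size, patch_size)
        if any(_boxes_intersect(crop_box, b) for b in particle_boxes):
            continue
        samples.append(TrainingSample(a[y0:y0 + patch_size, x0:x0 + patch_size].copy(),
                                      "background", source=f"bg:{x0},{y0}"))
    if len(samples) < n:
        warnings.warn(f"harvest_negatives found only {len(samples)}/{n} background crops",
                      stacklevel=2)
    for comp in bad_components or []:
        cx, cy = comp.centroid
        x0 = min(max(int(round(cx - patch_size / 2)), 0), w - patch_size)
        y0 = min(max(int(round(cy - patch_size / 2)), 0), h - patch_size)
        samples.append(TrainingSample(a[y0:y0 + patch_size, x0:x0 + patch_size].copy(),
                                      "negative", source=f"bad:{x0},{y0}"))
    return samples


def _boxes_intersect(a: BoundingBox, b: BoundingBox) -> bool:
    return a.x < b.x + b.w and b.x < a.x + a.w and a.y < b.y + b.h and b.y < a.y + a.h


# ---------------------------------------------------------------------------
# augmentation, balancing, splitting
# ---------------------------------------------------------------------------

def augment_rotations(sample: TrainingSample) -> list[TrainingSample]:
    """The sample plus its 90/180/270-degree rotations (labels preserved)."""
    if sample.patch.shape[0] != sample.patch.shape[1]:
        raise ValueError("rotation augmentation requires square patches")
    out = [sample]
    for k, deg in ((1, 90), (2, 180), (3, 270)):
        out.append(replace(sample, patch=np.rot90(sample.patch, k).copy(), rotation=deg))
    return out


def write_dataset(split: DatasetSplit, outdir) -> None:
    """Write the labeled dataset as per-class PNG directories plus a manifest
    TSV (path, label, source, rotation, split)."""
    import imageio.v3 as iio
    from pathlib import Path

    outdir = Path(outdir)
    rows = ["path\tlabel\tsource\trotation\tsplit"]
    for part, samples in (("train", split.train), ("validation", split.validation),
                          ("test", split.test)):
        for i, s in enumerate(samples):
            d = outdir / part / s.label
            d.mkdir(parents=True, exist_ok=True)
            path = d / f"{i:05d}.png"
            patch = np.asarray(s.patch, dtype=float)
            lo, hi = patch.min(), patch.max()
            scaled = np.zeros_like(patch) if hi == lo else (patch - lo) / (hi - lo)
            iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
            rows.append(f"{path.relative_to(outdir)}\t{s.label}\t{s.source}\t{s.rotation}\t{part}")
    (outdir / "manifest.tsv").write_text("\n".join(rows) + "\n")


def _split_80_20(n: int) -> tuple[int, int]:
    """(larger, smaller) sizes of an 80/20 split; the larger part is floored
    and the smaller takes the remainder (1500 -> 1200/300, 8 -> 6/2)."""
    larger = int(math.floor(0.8 * n))
    return larger, n - larger


def balance_and_split(samples_by_class: dict[str, list[TrainingSample]],
                      per_class_target: int, seed: int = 0) -> DatasetSplit:
    """Balance every class to ``per_class_target`` and split 80/20, then 80/20.

    Classes short of the target are expanded by rotation augmentation first;
    a class that still cannot reach the target raises an error naming it.
    Sampling and splitting are seeded and disjoint by construction.
    """
    rng = np.random.default_rng(seed)
    train: list[TrainingSample] = []
    val: list[TrainingSample] = []
    test: list[TrainingSample] = []
    for cls in sorted(samples_by_class):
        pool = list(samples_by_class[cls])
        if len(pool) < per_class_target:
            pool = [aug for s in pool for aug in augment_rotations(s)]
        if len(pool) < per_class_target:
            raise ValueError(
                f"class '{cls}' has only {len(pool)} samples after augmentation, "
                f"need {per_class_target}"
            )
        idx = rng.permutation(len(pool))[:per_class_target]
        chosen = [pool[i] for i in idx]
        n_trainval, n_test = _split_80_20(per_class_target)
        trainval, test_c = chosen[:n_trainval], chosen[n_trainval:]
        n_train, _n_val = _split_80_20(n_trainval)
        train.extend(trainval[:n_train])
        val.extend(trainval[n_train:])
        test.extend(test_c)
    return DatasetSplit(train=train, validation=val, test=test,
                        per_class_target=per_class_target, seed=seed)
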