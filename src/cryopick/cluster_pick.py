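"""Stage-1 unsupervised particle localization.

Clusters a preprocessed micrograph into a binary particle mask (intensity
k-means, or superpixel + k-means for irregular shapes), cleans the mask, and
detects particle objects: circles via a circular Hough transform, squares and
irregular blobs via connected components with Feret-diameter shape measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, morphology, segmentation, transform
from sklearn.cluster import KMeans

from .io_formats import BoundingBox, Micrograph

__all__ = [
    "ComponentMask",
    "Circle",
    "FeretMeasure",
    "ibc_cluster",
    "superpixel_kmeans_cluster",
    "clean_mask",
    "label_components",
    "contour_perimeter",
    "detect_circles_cht",
    "fit_circle_cht",
    "smooth_mask",
    "feret_diameters",
    "extract_particles",
]


@dataclass(eq=False)
class ComponentMask:
    """One connected binary object in micrograph coordinates.

    ``mask`` is the local binary patch; ``offset`` = (x, y) of its top-left
    corner in the micrograph frame; ``perimeter`` is the step-length sum along
    the 8-connected outer contour (axial steps count 1, diagonal sqrt(2));
    ``patch_shape``, when set, records the extraction patch the component was
    cut from (used by centering rules).
    """

    mask: np.ndarray
    offset: tuple[int, int]
    area: int
    perimeter: float
    centroid: tuple[float, float]  # (x, y), micrograph frame
    pixel_index_list: np.ndarray  # (n, 2) array of (row, col), micrograph frame
    patch_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area != int(self.mask.sum()) or self.area < 1:
            raise ValueError("area must equal the count of true pixels and be >= 1")
        if self.perimeter <= 0:
            raise ValueError("perimeter must be positive")

    @property
    def bounding_box(self) -> BoundingBox:
        return BoundingBox(self.offset[0], self.offset[1],
                           self.mask.shape[1], self.mask.shape[0])


@dataclass(frozen=True)
class Circle:
    """A detected circle: center (x, y) and radius, pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class FeretMeasure:
    """Max/min caliper diameters over rotating directions, and the max angle."""

    max_diameter: float
    min_diameter: float
    max_angle: float  # degrees

    def __post_init__(self) -> None:
        if not self.max_diameter >= self.min_diameter > 0:
            raise ValueError("require max_diameter >= min_diameter > 0")

    @property
    def ratio(self) -> float:
        return self.min_diameter / self.max_diameter


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means with quantile initialization; returns
    (labels, centers) with centers in ascending-intensity order."""
    uniq = np.unique(values)
    if uniq.size < k:
        raise ValueError(f"need at least {k} distinct intensities, found {uniq.size}")
    init = np.quantile(values, [(i + 0.5) / k for i in range(k)]).reshape(-1, 1)
    init = init + np.arange(k).reshape(-1, 1) * 1e-9  # break exact-duplicate inits
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=0)
    labels = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[labels], centers[order]


def ibc_cluster(m: Micrograph | np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-based clustering: 1-D k-means on pixel intensity.

    Returns (label_map, particle_mask); labels are ordered by ascending cluster
    mean so the particle mask is ``label_map == k - 1`` (highest intensity).
    The assignment depends on intensity only, never on pixel position.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    a = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)
    labels, _ = _kmeans_1d(a.ravel(), k)
    label_map = labels.reshape(a.shape)
    return label_map, label_map == k - 1


def superpixel_kmeans_cluster(m: Micrograph | np.ndarray, n_superpixels: int = 400,
                              k: int = 2, compactness: float = 0.1) -> np.ndarray:
    """Super-k-means segmentation: SLIC over-segmentation into compact regions,
    then k-means on per-superpixel mean intensity; particle mask = the cluster
    with the highest mean."""
    if n_superpixels < k:
        raise ValueError("n_superpixels must be >= k")
    a = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)
    segments = segmentation.slic(a, n_segments=n_superpixels, compactness=compactness,
                                 channel_axis=None, start_label=0)
    n_seg = segments.max() + 1
    means = np.array([a[segments == s].mean() for s in range(n_seg)])
    labels, _ = _kmeans_1d(means, k)
    particle_superpixels = np.flatnonzero(labels == k - 1)
    return np.isin(segments, particle_superpixels)


# ---------------------------------------------------------------------------
# mask cleaning and component labeling
# ---------------------------------------------------------------------------

def clean_mask(mask: np.ndarray, min_area: int = 0, border_margin: int = 0) -> np.ndarray:
    """Drop components smaller than min_area or touching the border band.

    Never increases the component count; min_area=0, border_margin=0 is the
    identity.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=2)
    out = np.zeros_like(mask)
    h, w = mask.shape
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        if border_margin > 0 and (r0 < border_margin or c0 < border_margin
                                  or r1 > h - border_margin or c1 > w - border_margin):
            continue
        out[labeled == region.label] = True
    return out


def smooth_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Binary closing then opening with a disc: the closing fills boundary
    concavities left by noise, the opening removes thin tendrils and specks.
    Does not merge components separated by more than 2*radius."""
    m = np.asarray(mask, dtype=bool)
    footprint = morphology.disk(radius)
    return morphology.opening(morphology.closing(m, footprint), footprint)


def contour_perimeter(mask: np.ndarray) -> float:
    """Step-length sum along the 8-connected outer contour (Moore tracing).

    Axial steps count 1, diagonal steps sqrt(2); an isolated pixel has
    perimeter 1 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 1:
        return 1.0
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # first foreground pixel in raster order
    # Moore neighborhood in clockwise order starting west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    offset_idx = {d: i for i, d in enumerate(nbrs)}
    current = start
    backtrack = (start[0], start[1] - 1)  # background by raster order
    # The walk is a deterministic map on (pixel, backtrack) states, so it must
    # enter a cycle = the outer contour; sum step lengths around that cycle.
    seen: dict[tuple[tuple[int, int], tuple[int, int]], float] = {}
    total = 0.0
    while True:
        state = (current, backtrack)
        if state in seen:
            return total - seen[state]
        seen[state] = total
        b_idx = offset_idx[(backtrack[0] - current[0], backtrack[1] - current[1])]
        nxt = None
        for k in range(1, 9):
            idx = (b_idx + k) % 8
            dr, dc = nbrs[idx]
            cand = (current[0] + dr, current[1] + dc)
            if padded[cand]:
                nxt = cand
                new_backtrack = (current[0] + nbrs[(idx - 1) % 8][0],
                                 current[1] + nbrs[(idx - 1) % 8][1])
                break
        if nxt is None:  # no neighbor: isolated pixel (handled above), defensive
            return 1.0
        total += math.hypot(nxt[0] - current[0], nxt[1] - current[1])
        current, backtrack = nxt, new_backtrack


def label_components(mask: np.ndarray,
                     patch_shape: tuple[int, int] | None = None) -> list[ComponentMask]:
    """8-connectivity labeling; each component carries area, contour perimeter,
    centroid and its pixel index list in micrograph coordinates."""
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=2)
    components: list[ComponentMask] = []
    for region in measure.regionprops(labeled):
        r0, c0, r1, c1 = region.bbox
        local = labeled[r0:r1, c0:c1] == region.label
        cy, cx = region.centroid
        components.append(ComponentMask(
            mask=local,
            offset=(c0, r0),
            area=int(region.area),
            perimeter=contour_perimeter(local),
            centroid=(cx, cy),
            pixel_index_list=region.coords.copy(),
            patch_shape=patch_shape,
        ))
    return components


# ---------------------------------------------------------------------------
# circle detection (circular Hough transform)
# ---------------------------------------------------------------------------

def _mask_edges(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    return mask & ~morphology.erosion(mask)


def detect_circles_cht(mask: np.ndarray, r_min: int, r_max: int,
                       vote_frac: float = 0.5) -> list[Circle]:
    """Circle detection by Hough vote accumulation over the mask's edge pixels.

    Keeps accumulator maxima whose normalized votes (fraction of the full
    circle perimeter present) exceed ``vote_frac``, deduplicated greedily by
    center distance > r_min.
    """
    if not 0 < r_min < r_max:
        raise ValueError("require 0 < r_min < r_max")
    edges = _mask_edges(mask)
    if not edges.any():
        return []
    radii = np.arange(r_min, r_max + 1)
    accum = transform.hough_circle(edges, radii)  # normalized votes in [0, ~1]
    peaks: list[tuple[float, float, float, float]] = []  # (votes, x, y, r)
    for layer, r in zip(accum, radii):
        ys, xs = np.nonzero(layer >= vote_frac)
        for y, x in zip(ys, xs):
            peaks.append((float(layer[y, x]), float(x), float(y), float(r)))
    peaks.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    circles: list[Circle] = []
    for votes, x, y, r in peaks:
        if all(math.hypot(x - c.center[0], y - c.center[1]) > r_min for c in circles):
            circles.append(Circle(center=(x, y), radius=r))
    return circles


def fit_circle_cht(mask: np.ndarray, r_min: int, r_max: int) -> Circle | None:
    """Best-fit circle for a single particle mask: the global Hough-accumulator
    maximum over the radius range, with no vote threshold.

    Used to generate the perfect circle on top of one component's mask; the
    good/bad decision is made downstream by roundness and mask overlap, so a
    weak fit is still returned. None only when the mask has no edge pixels.
    """
    if not 0 < r_min < r_max:
        raise ValueError("require 0 < r_min < r_max")
    edges = _mask_edges(np.pad(np.asarray(mask, dtype=bool), r_max))
    if not edges.any():
        return None
    radii = np.arange(r_min, r_max + 1)
    accum = transform.hough_circle(edges, radii)
    k, y, x = np.unravel_index(int(np.argmax(accum)), accum.shape)
    return Circle(center=(float(x - r_max), float(y - r_max)), radius=float(radii[k]))


# ---------------------------------------------------------------------------
# Feret diameters
# ---------------------------------------------------------------------------

def feret_diameters(c: ComponentMask, angle_step: float = 1.0) -> FeretMeasure:
    """Rotating-caliper diameters of the component over 1-degree directions.

    Pixels are treated as unit squares (their four corners are projected), so
    an axis-aligned n x n square measures exactly n along the axes and
    n*sqrt(2) along the diagonal.
    """
    if c.area == 1:
        return FeretMeasure(1.0, 1.0, 0.0)
    rows, cols = np.nonzero(c.mask)
    pts = np.stack([cols, rows], axis=1).astype(float)
    corners = np.concatenate([pts + d for d in
                              ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])])
    try:
        hull = corners[ConvexHull(corners).vertices]
    except QhullError:  # degenerate (colinear) component
        hull = corners
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = hull @ dirs.T  # (n_hull, n_angles)
    extents = proj.max(axis=0) - proj.min(axis=0)
    i_max = int(np.argmax(extents))
    return FeretMeasure(
        max_diameter=float(extents[i_max]),
        min_diameter=float(extents.min()),
        max_angle=float(np.rad2deg(angles[i_max])),
    )


# ---------------------------------------------------------------------------
# fixed-size particle extraction
# ---------------------------------------------------------------------------

def _detection_center(det) -> tuple[float, float]:
    if isinstance(det, Circle):
        return det.center
    if isinstance(det, ComponentMask):
        return det.centroid
    if isinstance(det, BoundingBox):
        return det.center
    x, y = det  # bare (x, y) pair
    return float(x), float(y)


def extract_particles(m: Micrograph | np.ndarray, detections, patch_size: int
                      ) -> list[tuple[np.ndarray, BoundingBox]]:
    """Fixed-size crops centered on each detection.

    Detections whose fixed box would exceed the image are dropped, so the
    number of crops is at most the number of detections.
    """
    a = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)
    h, w = a.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds image dims {a.shape}")
    out: list[tuple[np.ndarray, BoundingBox]] = []
    for det in detections:
        cx, cy = _detection_center(det)
        x0 = int(round(cx - patch_size / 2))
        y0 = int(round(cy - patch_size / 2))
        if x0 < 0 or y0 < 0 or x0 + patch_size > w or y0 + patch_size > h:
            continue
        box = BoundingBox(x0, y0, patch_size, patch_size)
        out.append((a[y0:y0 + patch_size, x0:x0 + patch_size].copy(), box))
    return out
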