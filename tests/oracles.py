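"""Independent brute-force oracles used to check the package implementations.

Each oracle recomputes a quantity by a different algorithm (naive loops,
exhaustive grids) and never shares code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def naive_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                 stride: int = 1, pad: int = 0) -> np.ndarray:
    """Triple-loop cross-correlation; x (N,C,H,W), w (F,C,kh,kw)."""
    n, c, h, wid = x.shape
    f, _, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (wid + 2 * pad - kw) // stride + 1
    out = np.zeros((n, f, oh, ow))
    for ni in range(n):
        for fi in range(f):
            for i in range(oh):
                for j in range(ow):
                    win = x[ni, :, i * stride:i * stride + kh, j * stride:j * stride + kw]
                    out[ni, fi, i, j] = (win * w[fi]).sum() + b[fi]
    return out


def naive_maxpool(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    out = np.zeros((n, c, oh, ow))
    for ni in range(n):
        for ci in range(c):
            for i in range(oh):
                for j in range(ow):
                    out[ni, ci, i, j] = x[ni, ci, i * stride:i * stride + k,
                                          j * stride:j * stride + k].max()
    return out


def naive_loss(probs: np.ndarray, onehot: np.ndarray, weights: list[np.ndarray],
               l2: float) -> float:
    total = 0.0
    for i in range(probs.shape[0]):
        for c in range(probs.shape[1]):
            if onehot[i, c]:
                total -= onehot[i, c] * np.log(max(probs[i, c], 1e-12))
    for w in weights:
        total += l2 * float((w ** 2).sum())
    return total


def brute_nms(cands, iou_threshold: float):
    """Quadratic reference NMS with the same (score desc, x, y) tie rule."""
    def iou(a, b):
        ix = max(0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
        iy = max(0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
        inter = ix * iy
        union = a.w * a.h + b.w * b.h - inter
        return inter / union if union else 0.0

    kept = []
    by_class = {}
    for c in cands:
        by_class.setdefault(c.label, []).append(c)
    for label in sorted(by_class):
        pool = sorted(by_class[label], key=lambda c: (-c.score, c.box.x, c.box.y))
        suppressed = [False] * len(pool)
        for i in range(len(pool)):
            if suppressed[i]:
                continue
            kept.append(pool[i])
            for j in range(i + 1, len(pool)):
                if not suppressed[j] and iou(pool[i].box, pool[j].box) >= iou_threshold:
                    suppressed[j] = True
    kept.sort(key=lambda c: (-c.score, c.box.x, c.box.y))
    return kept


def brute_cht(mask: np.ndarray, r_min: int, r_max: int, vote_frac: float = 0.5):
    """Exhaustive (x, y, r) accumulator over the mask's edge pixels.

    Votes at (x, y, r) = edge pixels within half a pixel of the circle,
    normalized by the circle circumference point count (as the transform
    does); returns peaks above vote_frac, greedily deduplicated by center
    distance > r_min. Output: list of (x, y, r, votes)."""
    from scipy.ndimage import binary_erosion
    mask = np.asarray(mask, dtype=bool)
    edges = mask & ~binary_erosion(mask, np.ones((3, 3)))
    ys, xs = np.nonzero(edges)
    if len(xs) == 0:
        return []
    h, w = mask.shape
    gy, gx = np.mgrid[0:h, 0:w]
    peaks = []
    for r in range(r_min, r_max + 1):
        n_template = max(int(round(2 * np.pi * r)), 1)
        d = np.sqrt((gx[..., None] - xs) ** 2 + (gy[..., None] - ys) ** 2)
        votes = (np.abs(d - r) <= 0.5).sum(axis=2) / n_template
        yy, xx = np.nonzero(votes >= vote_frac)
        for y, x in zip(yy, xx):
            peaks.append((float(votes[y, x]), int(x), int(y), int(r)))
    peaks.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    out = []
    for v, x, y, r in peaks:
        if all(np.hypot(x - ox, y - oy) > r_min for ox, oy, _, _ in out):
            out.append((x, y, r, v))
    return out


def allpairs_feret(mask: np.ndarray, angle_step: float = 1.0):
    """Feret extents by projecting every pixel corner onto every direction
    (no convex hull); returns (max_diameter, min_diameter)."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    pts = np.stack([cols, rows], axis=1).astype(float)
    corners = np.concatenate([pts + d for d in
                              ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])])
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = corners @ dirs.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    return float(extents.max()), float(extents.min())


def angle_ordered_perimeter(mask: np.ndarray) -> float:
    """Contour length of a star-convex component: order its boundary pixels by
    polar angle about the centroid and sum consecutive step lengths around the
    ring. Valid for the convex-ish shapes used in tests."""
    from scipy.ndimage import binary_erosion
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 1:
        return 1.0
    # 4-boundary: pixels with an axial background neighbor (the walked contour
    # cuts diagonally past pixels exposed only at a corner)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    boundary = mask & ~binary_erosion(mask, cross, border_value=0)
    ys, xs = np.nonzero(boundary)
    cy, cx = ys.mean(), xs.mean()
    order = np.argsort(np.arctan2(ys - cy, xs - cx))
    ys, xs = ys[order], xs[order]
    total = 0.0
    for i in range(len(ys)):
        j = (i + 1) % len(ys)
        total += float(np.hypot(ys[j] - ys[i], xs[j] - xs[i]))
    return total
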