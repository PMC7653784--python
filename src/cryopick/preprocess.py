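"""Seven-step micrograph enhancement chain and training-time augmentation.

The chain raises the particle/background contrast of very low-SNR micrographs
before unsupervised clustering: min-max normalization, percentile contrast
stretch, global histogram equalization, local adaptive Wiener restoration,
contrast-limited adaptive histogram equalization, guided filtering, and a
grayscale morphological open-close. Every step maps [0, 1] images into [0, 1]
and preserves shape; outputs are re-clipped at each stage boundary so the
composition is insensitive to range drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import exposure, morphology

from .io_formats import Micrograph

__all__ = [
    "PreprocessParams",
    "normalize",
    "contrast_enhance",
    "hist_equalize",
    "wiener_restore",
    "clahe",
    "guided_filter",
    "morph_enhance",
    "preprocess_chain",
    "augment_patch",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Defaults for the enhancement chain; the method names the steps but not
    their parameters, so these are standard values, all overridable."""

    p_low: float = 1.0
    p_high: float = 99.0
    wiener_window: int = 5
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    guided_radius: int = 4
    guided_eps: float = 1e-3
    morph_radius: int = 3
    augment_sd_range: tuple[float, float] = (0.0, 1.0)
    augment_mask_sizes: tuple[int, ...] = (3, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wiener_window < 1 or self.guided_radius < 1 or self.morph_radius < 1:
            raise ValueError("all window/radius sizes must be >= 1")
        lo, hi = self.augment_sd_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("augment_sd_range must be within [0, 1]")


def _as_array(m: Micrograph | np.ndarray) -> np.ndarray:
    return m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)


def _clip01(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 0.0, 1.0)


def normalize(m: Micrograph | np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1]; a constant image maps to zeros."""
    a = _as_array(m)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def contrast_enhance(m: Micrograph | np.ndarray, p_low: float = 1.0,
                     p_high: float = 99.0) -> np.ndarray:
    """Percentile stretch: clip to [p_low, p_high] percentiles, rescale to [0,1]."""
    a = _as_array(m)
    lo, hi = np.percentile(a, [p_low, p_high])
    if hi == lo:
        return np.zeros_like(a)
    return _clip01((np.clip(a, lo, hi) - lo) / (hi - lo))


def hist_equalize(m: Micrograph | np.ndarray, nbins: int = 256) -> np.ndarray:
    """Global histogram equalization on 256 bins; output in [0, 1]."""
    a = _as_array(m)
    if a.max() == a.min():
        return a.copy()
    return _clip01(exposure.equalize_hist(a, nbins=nbins))


def wiener_restore(m: Micrograph | np.ndarray, window: int = 5) -> np.ndarray:
    """Local adaptive Wiener filter; noise power = mean of local variances."""
    a = _as_array(m)
    if window > min(a.shape):
        raise ValueError(f"wiener window {window} exceeds image dims {a.shape}")
    mean = ndimage.uniform_filter(a, window)
    var = ndimage.uniform_filter(a * a, window) - mean * mean
    noise = float(var.mean())
    if noise <= 0:
        return a.copy()
    # scipy.signal.wiener with the same local statistics; guard var >= noise
    out = signal.wiener(a, mysize=window, noise=noise)
    return _clip01(out)


def clahe(m: Micrograph | np.ndarray, clip: float = 0.01, tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization over a tiles x tiles grid."""
    a = _as_array(m)
    if tiles < 2:
        raise ValueError("clahe needs at least a 2x2 tile grid")
    if a.max() == a.min():
        return a.copy()
    kernel = (max(2, a.shape[0] // tiles), max(2, a.shape[1] // tiles))
    return _clip01(exposure.equalize_adapthist(_clip01(a), kernel_size=kernel, clip_limit=clip))


def guided_filter(p: Micrograph | np.ndarray, I: Micrograph | np.ndarray | None = None,
                  radius: int = 4, eps: float = 1e-3) -> np.ndarray:
    """Edge-preserving smoothing of p steered by guidance image I (He-style).

    Each window fits the ridge-regularized linear model q = a*I + b; per-pixel
    coefficients are the box averages of the window fits. With I constant or
    eps -> inf the output collapses to the box mean of p.
    """
    p_arr = _as_array(p)
    i_arr = p_arr if I is None else _as_array(I)
    if p_arr.shape != i_arr.shape:
        raise ValueError("input and guidance images must share shape")
    if radius >= min(p_arr.shape) / 2:
        raise ValueError(f"guided radius {radius} too large for image {p_arr.shape}")
    size = 2 * radius + 1
    mean_i = ndimage.uniform_filter(i_arr, size)
    mean_p = ndimage.uniform_filter(p_arr, size)
    corr_ip = ndimage.uniform_filter(i_arr * p_arr, size)
    corr_ii = ndimage.uniform_filter(i_arr * i_arr, size)
    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    mean_a = ndimage.uniform_filter(a, size)
    mean_b = ndimage.uniform_filter(b, size)
    return _clip01(mean_a * i_arr + mean_b)


def morph_enhance(m: Micrograph | np.ndarray, radius: int = 3) -> np.ndarray:
    """Grayscale opening then closing with a disc structuring element."""
    a = _as_array(m)
    footprint = morphology.disk(radius)
    return _clip01(morphology.closing(morphology.opening(a, footprint), footprint))


def preprocess_chain(m: Micrograph | np.ndarray,
                     params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Apply the seven enhancement steps in their canonical order."""
    a = normalize(m)
    a = contrast_enhance(a, params.p_low, params.p_high)
    a = hist_equalize(a)
    a = wiener_restore(a, params.wiener_window)
    a = clahe(a, params.clahe_clip, params.clahe_tiles)
    a = guided_filter(a, None, params.guided_radius, params.guided_eps)
    a = morph_enhance(a, params.morph_radius)
    return a


def _gaussian_mask(sd: float, size: int) -> np.ndarray:
    """Normalized Gaussian kernel; sd -> 0 degenerates to the identity kernel."""
    half = size // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    if sd <= 1e-6:
        kernel = np.zeros((size, size))
        kernel[half, half] = 1.0
        return kernel
    kernel = np.exp(-(yy * yy + xx * xx) / (2.0 * sd * sd))
    return kernel / kernel.sum()


def augment_patch(patch: np.ndarray, params: PreprocessParams = PreprocessParams(),
                  seed: int = 0) -> np.ndarray:
    """Stochastic training-time augmentation.

    Draws a Gaussian-mask standard deviation from ``augment_sd_range`` and a
    mask size from ``augment_mask_sizes``, convolves the patch with the mask,
    then applies the guided filter. Seeded, shape-preserving.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.augment_sd_range
    sd = float(rng.uniform(lo, hi))
    size = int(rng.choice(np.asarray(params.augment_mask_sizes)))
    blurred = ndimage.convolve(np.asarray(patch, dtype=float),
                               _gaussian_mask(sd, size), mode="reflect")
    radius = min(params.guided_radius, (min(patch.shape) - 1) // 2 - 1)
    if radius < 1:
        return _clip01(blurred)
    return guided_filter(blurred, None, radius, params.guided_eps)
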