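"""High-level orchestration: Stage-1 unsupervised picking, automated training
dataset generation, and model training, composed from the library modules.

These helpers are the programmatic equivalents of the command-line workflows:
micrograph -> enhancement -> clustering -> good-particle selection -> labeled
balanced dataset -> trained classifier -> sliding-window picking.
"""

from __future__ import annotations

import numpy as np

from .classifier import Network, TrainingConfig, toy_arch, train
from .cluster_pick import (Circle, ComponentMask, clean_mask, extract_particles,
                           fit_circle_cht, ibc_cluster, label_components,
                           smooth_mask, superpixel_kmeans_cluster)
from .io_formats import Micrograph
from .preprocess import PreprocessParams, preprocess_chain
from .synthetic import SyntheticSpec, generate_micrograph
from .train_select import (TrainingSample, balance_and_split, harvest_negatives,
                           select_good_irregular, select_good_sideview,
                           select_good_topview)

__all__ = [
    "stage1_pick",
    "select_good",
    "build_synthetic_dataset",
    "train_toy_model",
    "TOY_TRAINING",
]

# defaults for the reduced-preset optimizer (see docs/methods.md)
TOY_TRAINING = dict(learning_rate=0.5, lr_decay=0.9, epochs=20, batch_size=16)

_SHAPE_TO_CLASS = {"disc": "top_view", "square": "side_view", "irregular": "irregular"}


def stage1_pick(m: Micrograph | np.ndarray, particle_size: int,
                method: str = "ibc", k: int = 2, n_superpixels: int = 400,
                min_area: int | None = None, border_margin: int = 1,
                params: PreprocessParams | None = None,
                preprocessed: bool = False,
                ) -> tuple[np.ndarray, np.ndarray, list[ComponentMask]]:
    """Enhance, cluster and clean one micrograph; return (enhanced image,
    particle mask, components)."""
    a = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)
    pre = a if preprocessed else preprocess_chain(a, params or PreprocessParams())
    if method == "ibc":
        _, mask = ibc_cluster(pre, k)
    elif method == "superpixel":
        mask = superpixel_kmeans_cluster(pre, n_superpixels, k)
    else:
        raise ValueError("method must be 'ibc' or 'superpixel'")
    if min_area is None:
        min_area = int(0.25 * particle_size ** 2)
    mask = smooth_mask(mask)
    mask = clean_mask(mask, min_area=min_area, border_margin=border_margin)
    return pre, mask, label_components(mask)


def select_good(components: list[ComponentMask], shape: str,
                particle_size: int) -> tuple[list[ComponentMask], list[ComponentMask]]:
    """Dispatch to the shape-specific good/bad selection rule."""
    if shape == "disc":
        r = particle_size // 2
        circles: list[Circle | None] = []
        for c in components:
            fit = fit_circle_cht(c.mask, max(2, int(0.6 * r)), int(1.4 * r))
            if fit is not None:
                fit = Circle((fit.center[0] + c.offset[0],
                              fit.center[1] + c.offset[1]), fit.radius)
            circles.append(fit)
        return select_good_topview(components, circles)
    if shape == "square":
        return select_good_sideview(components)
    if shape == "irregular":
        return select_good_irregular(components)
    raise ValueError(f"unknown shape {shape!r}")


def build_synthetic_dataset(patch_size: int = 32, per_class_target: int = 200,
                            micrographs_per_class: int = 8, seed: int = 0,
                            base_spec: SyntheticSpec | None = None,
                            jitter: int = 4, include_negative: bool = False,
                            ):
    """Fully automated labeled dataset from synthetic micrographs.

    For each shape class, micrographs are generated, scaled with the same
    automatic rule the testing pipeline uses (so training and test particles
    occupy the same fraction of the window), enhanced and clustered; good
    particles become class samples cropped from the enhanced image at their
    centroid plus a small random offset (up to ``jitter`` px, emulating
    sliding-grid misalignment), background crops away from detections become
    the background class, and rejected components the negative class. Classes
    are balanced to ``per_class_target`` (rotation augmentation, then
    subsampling) and split 80/20/(80/20).
    """
    from .detect import rescale_and_pad, select_scaling

    base = base_spec or SyntheticSpec()
    decision = select_scaling(base.particle_size, patch_size)
    scaled_size = decision.scaled_particle
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[TrainingSample]] = {
        "top_view": [], "side_view": [], "irregular": [], "background": []}
    if include_negative:
        by_class["negative"] = []
    for si, shape in enumerate(("disc", "square", "irregular")):
        cls = _SHAPE_TO_CLASS[shape]
        for mi in range(micrographs_per_class):
            spec = SyntheticSpec(**{**vars(base), "particle_shape": shape,
                                    "seed": seed + 1000 * si + mi})
            m, _truth = generate_micrograph(spec)
            m = rescale_and_pad(m, decision)
            pre, _mask, comps = stage1_pick(m, scaled_size)
            good, bad = select_good(comps, shape, scaled_size)
            centers = [(c.centroid[0] + rng.integers(-jitter, jitter + 1),
                        c.centroid[1] + rng.integers(-jitter, jitter + 1))
                       for c in good] if jitter else [c.centroid for c in good]
            crops = extract_particles(pre, centers, patch_size)
            for patch, box in crops:
                by_class[cls].append(TrainingSample(
                    patch, cls, source=f"{m.source_path}:{box.x},{box.y}"))
            det_boxes = [c.bounding_box for c in comps]
            harvested = harvest_negatives(pre, det_boxes, n=8,
                                          patch_size=patch_size,
                                          seed=spec.seed, bad_components=bad)
            by_class["background"].extend(
                s for s in harvested if s.label == "background")
            if include_negative:
                by_class["negative"].extend(
                    s for s in harvested if s.label == "negative")
    return balance_and_split(by_class, per_class_target, seed=seed)


def train_toy_model(split=None, seed: int = 0, patch_size: int = 32,
                    **dataset_kwargs) -> tuple[Network, object]:
    """Train the reduced-preset network on the synthetic 4-class dataset."""
    if split is None:
        split = build_synthetic_dataset(patch_size=patch_size, seed=seed,
                                        **dataset_kwargs)
    cfg = TrainingConfig(seed=seed, **TOY_TRAINING)
    return train(split, cfg, arch=toy_arch(patch_size, channels=1))
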