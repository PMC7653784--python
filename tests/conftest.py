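"""Shared fixtures: synthetic study conditions and one trained model reused
across classifier/detector/acceptance tests (training is the expensive step)."""

from __future__ import annotations

import numpy as np
import pytest

from cryopick.pipeline import build_synthetic_dataset, train_toy_model
from cryopick.synthetic import SyntheticSpec


BASE_SPEC = SyntheticSpec(target_snr=0.3)


@pytest.fixture(scope="session")
def toy_split():
    """Balanced 4-class dataset built by the fully automated pipeline
    (200 samples/class, 32x32 patches, centroid jitter up to 4 px)."""
    return build_synthetic_dataset(per_class_target=200, seed=1,
                                   base_spec=BASE_SPEC, jitter=4)


@pytest.fixture(scope="session")
def toy_model(toy_split):
    """Reduced-preset network trained on the 4-class synthetic dataset."""
    net, state = train_toy_model(toy_split, seed=1)
    return net, state


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
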