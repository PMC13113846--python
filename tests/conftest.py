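import numpy as np
import pytest

from mcgscreen import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free cohort with known beat timing (no jitter)."""
    noise = synthetic.NoiseSpec(white_sd=0.0, powerline_amp=0.0, wander_amp=0.0)
    return synthetic.generate_cohort(
        3, 2, 30, 1000.0, noise, seed=7, template_jitter=0.0, rr_jitter=0.0
    )


def make_quadrant_images(n: int, rng: np.random.Generator):
    """Linearly separable 224x224 image classes: class 1 has a bright
    top-left quadrant, class 0 a dark one; backgrounds are noisy."""
    labels = rng.integers(0, 2, n)
    images = 0.1 + 0.05 * rng.random((n, 224, 224))
    for k, y in enumerate(labels):
        if y == 1:
            images[k, :112, :112] += 0.8
    return images.astype(np.float32), labels
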