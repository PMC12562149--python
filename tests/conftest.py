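"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

import adzus

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


def random_attention_tensor(resolution: int, rng: np.random.Generator) -> np.ndarray:
    """A random valid attention tensor: every slice a distribution."""
    t = rng.gamma(1.0, 1.0, size=(resolution,) * 4) + 1e-6
    return t / t.sum(axis=(-2, -1), keepdims=True)


@st.composite
def attention_sets(draw, max_tensors: int = 3, resolutions=(8, 16)):
    """Small random AttentionTensorSet instances for property tests."""
    n = draw(st.integers(1, max_tensors))
    res = [draw(st.sampled_from(resolutions)) for _ in range(n)]
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    return adzus.AttentionTensorSet(
        tensors=[random_attention_tensor(r, rng) for r in res]
    )


@st.composite
def probability_maps(draw, side: int = 8):
    """Random probability maps, occasionally sparse (exact zeros)."""
    seed = draw(st.integers(0, 2**31 - 1))
    sparse = draw(st.booleans())
    rng = np.random.default_rng(seed)
    m = rng.gamma(1.0, 1.0, size=(side, side))
    if sparse:
        m = m * (rng.random((side, side)) > 0.4)
        if m.sum() == 0:
            m[0, 0] = 1.0
    return m / m.sum()


@pytest.fixture(scope="session")
def two_region_scene():
    """Noiseless planted scene with two regions (exact within-region ties)."""
    return adzus.generate_scene(2, seed=11, noise_level=0.0)


@pytest.fixture(scope="session")
def three_region_scene():
    return adzus.generate_scene(3, seed=5, noise_level=0.0)


@pytest.fixture(scope="session")
def two_region_attention(two_region_scene):
    return adzus.synthesize_attention(two_region_scene)


@pytest.fixture(scope="session")
def two_region_aggregated(two_region_attention):
    return adzus.aggregate(two_region_attention)


@pytest.fixture(scope="session")
def noisy_scene_attention():
    """A noisy 3-region scene aggregated once for reuse across tests."""
    scene = adzus.generate_scene(3, seed=23, noise_level=0.05)
    return scene, adzus.aggregate(adzus.synthesize_attention(scene))
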