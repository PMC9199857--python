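import numpy as np
import pytest

from mamlp.io import FeatureMatrix
from mamlp.registry import AtlasRegistry, AtlasVersion
from mamlp.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_registry():
    """Three families, two of them multi-version, mixed depths."""
    return AtlasRegistry(versions=(
        AtlasVersion("A1", "A", 40, (0, 4)),
        AtlasVersion("A2", "A", 120, (4, 10)),
        AtlasVersion("B1", "B", 60, (10, 14)),
        AtlasVersion("C1", "C", 30, (14, 16)),
        AtlasVersion("C2", "C", 15, (16, 18)),
    ))


@pytest.fixture(scope="session")
def small_registry():
    """Contiguous two-atlas layout for fast training tests."""
    return AtlasRegistry(versions=(
        AtlasVersion("deep", "deep", 150, (0, 300)),
        AtlasVersion("shallow", "shallow", 50, (300, 400)),
    ))


@pytest.fixture(scope="session")
def small_cohort(small_registry):
    """Separable synthetic cohort on the small registry (clean, no
    contamination) used by the fast training tests."""
    cfg = SimConfig(class_counts=(120, 120, 120), registry=small_registry,
                    effect_size=2.0, affected_fraction=0.5,
                    scale_range=(2.0, 20.0),
                    nan_rate=0.0, inf_rate=0.0, seed=7)
    matrix, truth = generate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_matrix(rng):
    values = rng.normal(5.0, 3.0, size=(17, 11))
    return FeatureMatrix(values=values)
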