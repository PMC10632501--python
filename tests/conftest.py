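import numpy as np
import pytest

from synthrig.pipeline import generate, validate_config
from synthrig.primitives import make_stick_subject


@pytest.fixture(scope="session")
def stick_model():
    return make_stick_subject()


def small_config(n_samples=4, resolution=(96, 96), population=2, seed=7, **overrides):
    """Desk-scale generator config used across the suite."""
    data = {
        "general": {"n_samples": n_samples, "resolution": list(resolution), "dataset_name": "fixture"},
        "subjects": {"population_size": population},
        "environment": {"terrain_resolution": 48, "terrain_extent": 12.0, "terrain_amplitude": 0.5},
        "debug": {"seed": seed},
    }
    for block, kv in overrides.items():
        data.setdefault(block, {}).update(kv)
    return validate_config(data)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small generated dataset shared by annotation/exporter tests."""
    out = tmp_path_factory.mktemp("ds")
    cfg = small_config()
    return generate(cfg, out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
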