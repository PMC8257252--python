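import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from asymparc import SpeciesSpec


def small_spec(
    name: str = "toy",
    n_subjects: int = 4,
    n_seeds: int = 12,
    n_targets: int = 9,
    k_true: int = 3,
    noise_sd: float = 0.0,
    volume_noise_sd: float = 0.0,
    **overrides,
) -> SpeciesSpec:
    """A tiny, fully controlled species spec for unit tests."""
    profiles = np.zeros((k_true, n_targets))
    width = n_targets // k_true
    for c in range(k_true):
        profiles[c] = 0.5
        profiles[c, c * width : (c + 1) * width] = 3.0
    fields = dict(
        name=name,
        n_subjects=n_subjects,
        n_seeds=n_seeds,
        n_targets=n_targets,
        k_true=k_true,
        block_assignment=1 + (np.arange(n_seeds) * k_true) // n_seeds,
        cluster_profiles=profiles,
        noise_sd=noise_sd,
        scaling_exponent=np.full(k_true, 1.2),
        scaling_intercept=np.full(k_true, np.log(2.0)),
        volume_ai=np.zeros(k_true),
        gmv_range=(1e4, 1e5),
        volume_noise_sd=volume_noise_sd,
    )
    fields.update(overrides)
    return SpeciesSpec(**fields)


@pytest.fixture
def toy_spec() -> SpeciesSpec:
    return small_spec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
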