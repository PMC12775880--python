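import numpy as np
import pytest

from statpilot.dataset_io import Dataset, Observation
from statpilot.fixtures import FixtureSpec, generate


@pytest.fixture
def s1_like() -> Dataset:
    """Three well-separated normal homoscedastic groups (genotype-style data)."""
    return generate(FixtureSpec("three_group_clean", seed=1))


@pytest.fixture
def s2_like() -> Dataset:
    """Five-group viability-style dataset violating the parametric prerequisites."""
    return generate(FixtureSpec("viability_dirty", seed=1))


def make_dataset(groups: dict[str, list[float]], subjects: bool = False) -> Dataset:
    obs = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            obs.append(Observation(g, float(v), subject=f"s{i}" if subjects else None))
    return Dataset(obs, list(groups))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
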