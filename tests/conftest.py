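import numpy as np
import pytest

from rewisa import (BlockSpec, MethylationProfile, NormalizedProfile, SimulationSpec,
                    generate)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 200x10 dataset with two planted hyper-methylated blocks."""
    spec = SimulationSpec(
        n_sites=200,
        n_conditions=10,
        blocks=(
            BlockSpec(sites=(0, 40), conditions=(0, 4)),
            BlockSpec(sites=(40, 80), conditions=(4, 8)),
        ),
    )
    return generate(spec, random_state=11)


@pytest.fixture(scope="session")
def small_profile(small_dataset):
    return small_dataset.profile()


@pytest.fixture
def toy_profile():
    """3x3 profile with unit weights; normalisation supplied by hand in tests."""
    P = np.full((3, 3), 0.5)
    W = np.ones((3, 3))
    return MethylationProfile(["s1", "s2", "s3"], ["c1", "c2", "c3"], P, W)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
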