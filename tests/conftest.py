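import numpy as np
import pytest

from woafs import SyntheticSpec, generate_feature_table


@pytest.fixture(scope="session")
def standard_table():
    """The standard fixture: 300 samples x 40 features, 5 informative at
    effect size 2.0, 3 redundant noisy copies."""
    return generate_feature_table(SyntheticSpec())


@pytest.fixture(scope="session")
def small_table():
    """120 samples x 8 features with 2 informative columns — small enough
    for exhaustive subset enumeration."""
    spec = SyntheticSpec(
        n_samples=120,
        n_features=8,
        informative_idx=(0, 1),
        effect_size=2.0,
        redundancy_pairs=(),
        seed=11,
    )
    return generate_feature_table(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
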