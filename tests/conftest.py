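import numpy as np
import pytest

from vocdx.features import FeatureMatrix
from vocdx.synthetic import SyntheticConfig, generate_enose_cohort, generate_faims_cohort


@pytest.fixture(scope="session")
def small_faims_cohort():
    """10-sample FAIMS cohort with a clear planted effect."""
    config = SyntheticConfig(
        n_case=5, n_control=5, seed=11, effect_size=4.0, noise_sd=0.05,
        age_decay_rate=0.0,
    )
    return generate_faims_cohort(config)


@pytest.fixture(scope="session")
def small_enose_cohort():
    config = SyntheticConfig(
        n_case=6, n_control=6, seed=7, effect_size=3.0, noise_sd=0.05,
        age_decay_rate=0.0,
    )
    return generate_enose_cohort(config)


def make_feature_matrix(X, labels=None, prefix="f"):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if labels is None:
        labels = ["case"] * (n // 2) + ["control"] * (n - n // 2)
    return FeatureMatrix(
        values=X,
        feature_names=[f"{prefix}{i}" for i in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=np.asarray(labels, dtype=object),
    )


@pytest.fixture
def toy_features():
    """16 samples x 6 features; feature 0 separates the classes perfectly."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(16, 6))
    y = np.array([1] * 8 + [0] * 8)
    X[:, 0] = y * 3.0 + rng.normal(0, 0.1, 16)
    return make_feature_matrix(X, ["case"] * 8 + ["control"] * 8)
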