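import numpy as np
import pytest

from robustcox import ScenarioConfig, SurvivalDataset, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_survival_arrays(rng, n=20, p=3, censor_frac=0.3):
    """Small random survival data with at least one event."""
    X = rng.standard_normal((n, p))
    time = rng.uniform(0.1, 5.0, n)
    status = (rng.uniform(size=n) > censor_frac).astype(int)
    if status.sum() == 0:
        status[0] = 1
    return X, time, status


@pytest.fixture(scope="session")
def small_dataset():
    """Clean moderate dataset with known sparse truth."""
    beta = np.array([1.0, -0.5, 0.0])
    cfg = ScenarioConfig("custom", n=200, p=3, beta=beta, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def s3_dataset():
    return generate_dataset(ScenarioConfig.preset("S3", seed=7))
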