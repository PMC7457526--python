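import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gpgee import LongitudinalDataset, Table1Design, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng) -> LongitudinalDataset:
    """2 subjects x 2 conditions x 3 channels with two covariates."""
    n, J, K = 2, 2, 3
    response = rng.standard_normal((n, J * K))
    covariates = pd.DataFrame(
        rng.standard_normal((n * J * K, 2)), columns=["age", "dose"]
    )
    ds = LongitudinalDataset(
        subjects=np.array(["s1", "s2"]),
        conditions=["standard", "oddball"],
        channels=["ch1", "ch2", "ch3"],
        response=response,
        covariates=covariates,
    )
    ds.validate()
    return ds


@pytest.fixture
def erp_like_dataset() -> LongitudinalDataset:
    """Small synthetic dataset with ERP-style layout (subjects x 2 x 5)."""
    design = Table1Design(n_subjects=12, n_channels=5, beta=np.array([1.0, 0.0, 0.5]))
    return generate_dataset(design, seed=7)
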