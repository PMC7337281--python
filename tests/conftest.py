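import numpy as np
import pandas as pd
import pytest

from trialbounds import TrialDataset


@pytest.fixture
def toy_lee_dataset() -> TrialDataset:
    """4 control (all observed) vs 4 treated (2 observed): trim share 0.5."""
    y = np.array([10.0, 20.0, np.nan, np.nan, 1.0, 2.0, 3.0, 4.0])
    t = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    return TrialDataset.from_arrays(y, t)


@pytest.fixture
def balanced_covariate_dataset() -> TrialDataset:
    """Fully observed trial with a covariate unrelated to arm or outcome."""
    rng = np.random.default_rng(7)
    n = 120
    t = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
    x = rng.normal(size=n)
    y = 5.0 + 2.0 * t + rng.normal(size=n)
    return TrialDataset.from_arrays(y, t, covariates={"x": x})


def make_trial(
    rng: np.random.Generator,
    n_treated: int = 100,
    n_control: int = 100,
    obs_rate_treated: float = 0.8,
    obs_rate_control: float = 0.8,
    mean_treated: float = 1.0,
    mean_control: float = 0.0,
    sd: float = 1.0,
) -> TrialDataset:
    n = n_treated + n_control
    t = np.r_[np.ones(n_treated, int), np.zeros(n_control, int)]
    y = np.where(t == 1, mean_treated, mean_control) + rng.normal(0, sd, size=n)
    rate = np.where(t == 1, obs_rate_treated, obs_rate_control)
    s = rng.uniform(size=n) < rate
    return TrialDataset.from_arrays(np.where(s, y, np.nan), t)
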