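import numpy as np
import pandas as pd
import pytest

from cpatt import (EffectProfile, SyntheticConfig, generate_cohort,
                   inject_missingness)
from cpatt.pipeline import prepare_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate targeted-selection cohort with the default effect profile."""
    cfg = SyntheticConfig(seed=42)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def prepared_cohort(default_cohort):
    cohort, truth, cfg = default_cohort
    prep = prepare_cohort(inject_missingness(cohort, cfg))
    return prep, truth, cfg


@pytest.fixture(scope="session")
def null_cohort():
    cfg = SyntheticConfig(seed=7, effect_profile=EffectProfile(deltas=(0, 0, 0, 0)))
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def small_regression():
    """Small nonlinear regression problem for sampler checks."""
    rng = np.random.RandomState(3)
    n = 300
    X = rng.randn(n, 5)
    y = np.sin(X[:, 0]) + X[:, 1] + 0.7 * rng.randn(n)
    return X, y
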