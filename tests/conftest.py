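"""Shared fixtures: small simulated outcomes and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aptrisk.simulate import (CohortConfig, generate_expression_cohort,
                              generate_null_expression_cohort)
from aptrisk.survival import SurvivalOutcome


def simulate_outcome(n: int, rng: np.random.Generator, beta: np.ndarray,
                     x: np.ndarray, rate: float = 0.08,
                     cens_lo: float = 2.0, cens_hi: float = 30.0
                     ) -> SurvivalOutcome:
    """Plain proportional-hazards draw used by unit tests (independent of the
    package's own cohort generator)."""
    eta = x @ beta if x.ndim > 1 else x * beta
    t = rng.exponential(1.0 / (rate * np.exp(eta)))
    c = rng.uniform(cens_lo, cens_hi, size=n)
    return SurvivalOutcome(np.minimum(t, c), (t <= c).astype(int))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160219)


@pytest.fixture(scope="session")
def medium_cox_data():
    """80 samples, 2 covariates, moderate effects; ~50 events."""
    r = np.random.default_rng(1)
    x = r.standard_normal((80, 2))
    out = simulate_outcome(80, r, np.array([0.8, -0.5]), x, rate=0.05,
                           cens_lo=5, cens_hi=40)
    return x, out


@pytest.fixture(scope="session")
def null_cohort():
    cfg = CohortConfig(n_samples=60, n_features=100, seed=3)
    mat, clin, truth = generate_null_expression_cohort(cfg)
    return mat, clin, truth


@pytest.fixture(scope="session")
def signal_cohort():
    """Strong-signal cohort: 3 informative features, event count comparable
    to the emulated 227-patient study."""
    cfg = CohortConfig(n_samples=60, n_features=100, n_informative=3,
                       beta_true=np.array([1.0, 1.0, -1.0]),
                       censor_rate_target=0.55, baseline_scale=0.03,
                       seed=11)
    mat, clin, truth = generate_expression_cohort(cfg)
    return mat, clin, truth


@pytest.fixture()
def toy_clinical():
    """Hand-sized clinical table for reporting tests."""
    n = 12
    return pd.DataFrame({
        "sample_id": [f"S{i:02d}" for i in range(n)],
        "time_months": [12.0, 24.0, 36.0, 48.0, 70.0, 18.0,
                        9.0, 30.0, 44.0, 61.0, 15.0, 27.0],
        "event": [1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0],
        "age_group": ["<60", ">=60"] * 6,
        "sex": ["male", "female"] * 6,
        "chemo": ["yes"] * 10 + ["no"] * 2,
        "clinical_risk": ["no", "yes"] * 6,
        "cea_group": ["<=5"] * 8 + [">5"] * 3 + [None],
    })
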