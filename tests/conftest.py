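import numpy as np
import pytest

from uroflow import (
    BVTrajectory,
    CohortConfig,
    FitRecord,
    generate_cohort,
)

#: regression-truth coefficients (v0 ml/min, k_age ml/min/yr, k_wat ml/min/ml)
REGRESSION_TRUTH = (3.115, -0.047, 0.007)
#: iterative-truth coefficients
ITERATIVE_TRUTH = (2.587, -0.040, 0.007)

SCAN_TIMES = tuple(float(t) for t in range(0, 70, 10))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_config():
    """Generator config with all stochastic terms switched off."""
    return CohortConfig(
        n_patients=12, rate_residual_sd=0.0, noise_cv=0.0, time_jitter_max=0.0,
        residual_urine_range=(0.0, 0.0), seed=42)


@pytest.fixture
def default_config():
    return CohortConfig(n_patients=25, seed=42)


@pytest.fixture
def small_cohort(default_config):
    return generate_cohort(default_config)


def make_line_trajectory(patient_id="P1", intercept=5.0, slope=2.0,
                         times=(0.0, 10.0, 20.0, 30.0, 40.0), sigma_v=1.0,
                         sigma_t=None):
    """Exact straight-line trajectory fixture."""
    t = np.asarray(times, dtype=float)
    v = intercept + slope * t
    sv = np.full(t.size, sigma_v) if sigma_v is not None else None
    st = np.full(t.size, sigma_t) if sigma_t is not None else None
    return BVTrajectory.from_arrays(patient_id, t, v, sv, st)


def make_noiseless_records(truth, n=40, seed=0, water_values=None):
    """FitRecords whose rates follow the linear model exactly (no noise)."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(40, 75, size=n)
    if water_values is None:
        water = rng.uniform(60, 600, size=n)
    else:
        water = rng.choice(np.asarray(water_values, dtype=float), size=n)
    bmi = rng.uniform(17.6, 28.2, size=n)
    v0, k_age, k_wat = truth
    y = v0 + k_age * age + k_wat * water
    return [
        FitRecord(patient_id=f"P{i}", age=float(age[i]), water=float(water[i]),
                  bmi=float(bmi[i]), vtot_hat=float(y[i]), vtot_se=0.05)
        for i in range(n)
    ]
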