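"""Synthetic patient cohorts and bladder-volume trajectories.

The generator emulates the statistical structure assumed by the downstream
analysis: patient covariates (age, pre-session water intake, BMI) drawn over
clinically observed ranges, a latent mean urinary inflow rate ``v_tot``
(ml/min) built as a linear superposition of covariate effects

    v_tot = v0 + k_age * age + k_wat * water + k_bmi * bmi + scatter,

linear bladder-volume growth over time from a post-void residual, multiplicative
measurement noise on the recorded volume, and bounded jitter on the recorded
scan time.  All times are minutes since bladder voiding.

Everything is driven by a single integer seed so that identical configurations
reproduce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .inflow import BVMeasurement, BVTrajectory

__all__ = [
    "CohortConfig",
    "PatientProfile",
    "generate_cohort",
    "simulate_trajectory",
    "simulate_cohort_trajectories",
    "write_cohort",
    "read_cohort",
    "write_trajectories",
    "read_trajectories",
    "COHORT_COLUMNS",
    "TRAJECTORY_COLUMNS",
]

#: Physiological floor for the latent inflow rate (ml/min).
VTOT_FLOOR = 0.05

COHORT_COLUMNS = [
    "patient_id",
    "age_yr",
    "water_ml",
    "bmi_kgm2",
    "v_plan_ml",
    "true_vtot_mlmin",
    "residual_ml",
]
_COHORT_REQUIRED = COHORT_COLUMNS[:5]

TRAJECTORY_COLUMNS = ["patient_id", "t_min", "volume_ml", "sigma_v_ml", "sigma_t_min"]
_TRAJECTORY_REQUIRED = TRAJECTORY_COLUMNS[:3]


@dataclass(frozen=True)
class CohortConfig:
    """Generating truth and noise settings for a synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Number of patients to generate.
    age_range, water_range, bmi_range : (low, high)
        Covariate ranges: age in years, pre-session water intake in ml,
        body-mass index in kg/m².  Defaults follow the observed cohort
        (age 40-75 yr, water 60-600 ml, BMI 17.6-28.2 kg/m²).
    v_plan_range : (low, high)
        Planning-CT bladder volume range, ml.
    residual_urine_range : (low, high)
        Post-void residual urine range, ml.
    truth_v0, truth_k_age, truth_k_wat, truth_k_bmi : float
        Generating coefficients of the linear inflow-rate model
        (ml/min, ml/min per yr, ml/min per ml, ml/min per kg/m²).
        Defaults are the two-covariate regression coefficients
        (3.115, -0.047, 0.007, 0).
    rate_residual_sd : float
        Patient-level scatter of the true rate around the linear model,
        ml/min.  Default 0.5 spreads rates over roughly 0.2-5 ml/min.
    noise_cv : float
        Multiplicative coefficient of variation of a volume measurement.
    time_jitter_max : float
        Half-width (min) of the uniform jitter on recorded scan times.
        Default 2.18 min, the maximum timing uncertainty from repeated
        sub-scans per measurement.
    covariate_dist : {"uniform", "truncnorm"}
        Covariate sampling scheme.  ``truncnorm`` centres each covariate on
        the cohort mean with sd = range/4, truncated to the range.
    water_round_ml : float, optional
        If set, round water intake to the nearest multiple (ml) so that
        equal-water subgroups exist (needed to initialise the alternating
        population fit on small cohorts).
    sigma_floor_ml : float
        Absolute floor (ml) on the per-point volume uncertainty recorded in
        trajectories, preventing zero-uncertainty points at empty bladder.
    seed : int
        Master seed for the cohort stream.
    """

    n_patients: int = 25
    age_range: tuple[float, float] = (40.0, 75.0)
    water_range: tuple[float, float] = (60.0, 600.0)
    bmi_range: tuple[float, float] = (17.6, 28.2)
    v_plan_range: tuple[float, float] = (150.0, 450.0)
    residual_urine_range: tuple[float, float] = (0.0, 30.0)
    truth_v0: float = 3.115
    truth_k_age: float = -0.047
    truth_k_wat: float = 0.007
    truth_k_bmi: float = 0.0
    rate_residual_sd: float = 0.5
    noise_cv: float = 0.05
    time_jitter_max: float = 2.18
    covariate_dist: str = "uniform"
    water_round_ml: Optional[float] = None
    sigma_floor_ml: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in ("age_range", "water_range", "bmi_range", "v_plan_range",
                     "residual_urine_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name} must satisfy low <= high, got {(lo, hi)}")
        if self.rate_residual_sd < 0:
            raise ConfigurationError("rate_residual_sd must be >= 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.time_jitter_max < 0:
            raise ConfigurationError("time_jitter_max must be >= 0")
        if self.covariate_dist not in ("uniform", "truncnorm"):
            raise ConfigurationError(
                f"covariate_dist must be 'uniform' or 'truncnorm', got {self.covariate_dist!r}")

    def replace(self, **changes) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for name in ("age_range", "water_range", "bmi_range", "v_plan_range",
                     "residual_urine_range"):
            if name in d and d[name] is not None:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class PatientProfile:
    """One synthetic patient.

    ``true_vtot`` (ml/min) and ``residual_urine`` (ml) are latent generator
    truth; they are optional so that real cohort tables without them can be
    read into the same structure.
    """

    patient_id: str
    age: float            # years
    water: float          # ml drunk before the session
    bmi: float            # kg/m^2
    v_plan: float         # planning-CT bladder volume, ml
    true_vtot: Optional[float] = None   # ml/min, latent
    residual_urine: float = 0.0         # ml, post-void

    def true_volume(self, t: float) -> float:
        """Latent bladder volume (ml) at ``t`` minutes after voiding."""
        if self.true_vtot is None:
            raise InputError(f"patient {self.patient_id} has no latent rate")
        return self.residual_urine + self.true_vtot * t


def _sample_covariate(rng: np.random.Generator, n: int, rng_lohi, dist: str) -> np.ndarray:
    lo, hi = rng_lohi
    if lo == hi:
        return np.full(n, float(lo))
    if dist == "uniform":
        return rng.uniform(lo, hi, size=n)
    # truncated normal centred on the midpoint, sd = range/4
    mu, sd = 0.5 * (lo + hi), (hi - lo) / 4.0
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mu, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(config: CohortConfig) -> list[PatientProfile]:
    """Generate ``config.n_patients`` patients with latent inflow rates.

    The latent rate is ``max(0.05, v0 + k_age*age + k_wat*water + k_bmi*bmi
    + N(0, rate_residual_sd))``; draws below the 0.05 ml/min physiological
    floor are truncated there.  Identical configs give identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    age = _sample_covariate(rng, n, config.age_range, config.covariate_dist)
    water = _sample_covariate(rng, n, config.water_range, config.covariate_dist)
    if config.water_round_ml:
        water = np.round(water / config.water_round_ml) * config.water_round_ml
        water = np.clip(water, *config.water_range)
    bmi = _sample_covariate(rng, n, config.bmi_range, config.covariate_dist)
    v_plan = rng.uniform(*config.v_plan_range, size=n) if config.v_plan_range[0] != config.v_plan_range[1] \
        else np.full(n, config.v_plan_range[0])
    residual = rng.uniform(*config.residual_urine_range, size=n) \
        if config.residual_urine_range[0] != config.residual_urine_range[1] \
        else np.full(n, config.residual_urine_range[0])

    mean_rate = (config.truth_v0 + config.truth_k_age * age
                 + config.truth_k_wat * water + config.truth_k_bmi * bmi)
    scatter = rng.normal(0.0, config.rate_residual_sd, size=n) if config.rate_residual_sd > 0 \
        else np.zeros(n)
    vtot = np.maximum(VTOT_FLOOR, mean_rate + scatter)

    width = max(3, len(str(n)))
    return [
        PatientProfile(
            patient_id=f"P{i + 1:0{width}d}",
            age=float(age[i]),
            water=float(water[i]),
            bmi=float(bmi[i]),
            v_plan=float(v_plan[i]),
            true_vtot=float(vtot[i]),
            residual_urine=float(residual[i]),
        )
        for i in range(n)
    ]


def simulate_trajectory(
    patient: PatientProfile,
    scan_times: Sequence[float],
    config: CohortConfig,
    rng: np.random.Generator,
) -> BVTrajectory:
    """Simulate one session of bladder-volume scans for ``patient``.

    The latent volume at nominal time ``t`` (min since void) is
    ``residual + v_tot * t``.  The recorded volume carries multiplicative
    Gaussian noise ``(1 + N(0, noise_cv))`` floored at 0 ml; the recorded
    time carries uniform jitter of half-width ``time_jitter_max`` floored at
    0 min, re-sorted so recorded times stay increasing.  Per-point
    uncertainties stored with the trajectory are ``noise_cv`` times the
    latent volume (floored at ``sigma_floor_ml``) and ``time_jitter_max``.
    """
    t = np.asarray(scan_times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("scan_times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise InputError("scan_times must be >= 0 (minutes since void)")
    if np.any(np.diff(t) <= 0):
        raise InputError("scan_times must be strictly increasing")

    true_vol = patient.residual_urine + float(patient.true_vtot) * t
    if config.noise_cv > 0:
        vol = true_vol * (1.0 + rng.normal(0.0, config.noise_cv, size=t.size))
        vol = np.maximum(vol, 0.0)
        sigma_v = np.maximum(config.noise_cv * true_vol, config.sigma_floor_ml)
    else:
        vol = true_vol.copy()
        sigma_v = np.zeros(t.size)

    if config.time_jitter_max > 0:
        t_rec = t + rng.uniform(-config.time_jitter_max, config.time_jitter_max, size=t.size)
        t_rec = np.maximum(t_rec, 0.0)
        t_rec = np.sort(t_rec)  # order-preserving record
        for i in range(1, t_rec.size):  # break rare ties from the floor at 0
            if t_rec[i] <= t_rec[i - 1]:
                t_rec[i] = t_rec[i - 1] + 1e-6
        sigma_t = np.full(t.size, config.time_jitter_max)
    else:
        t_rec = t.copy()
        sigma_t = np.zeros(t.size)

    measurements = [
        BVMeasurement(t=float(t_rec[i]), volume=float(vol[i]),
                      sigma_v=float(sigma_v[i]), sigma_t=float(sigma_t[i]))
        for i in range(t.size)
    ]
    return BVTrajectory(patient_id=patient.patient_id, measurements=measurements)


def simulate_cohort_trajectories(
    cohort: Sequence[PatientProfile],
    scan_times: Sequence[float],
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[BVTrajectory]:
    """Simulate one trajectory per patient with a shared random stream."""
    return [simulate_trajectory(p, scan_times, config, rng) for p in cohort]


# ---------------------------------------------------------------------------
# CSV plumbing

_FLOAT_FMT = "%.6f"


def cohort_to_frame(cohort: Sequence[PatientProfile]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": p.patient_id,
            "age_yr": p.age,
            "water_ml": p.water,
            "bmi_kgm2": p.bmi,
            "v_plan_ml": p.v_plan,
            "true_vtot_mlmin": np.nan if p.true_vtot is None else p.true_vtot,
            "residual_ml": p.residual_urine,
        }
        for p in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: Sequence[PatientProfile], path) -> None:
    """Write a cohort table to CSV (header always present)."""
    cohort_to_frame(cohort).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise InputError(
                f"{path}: non-numeric value in column {col!r}, row {int(bad[0]) + 2} "
                f"(value {df.loc[bad[0], col]!r})")
        df[col] = converted
    return df


def read_cohort(path) -> list[PatientProfile]:
    """Read a cohort CSV; latent columns (true rate, residual) are optional."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing cohort columns {missing}")
    numeric = [c for c in COHORT_COLUMNS[1:] if c in df.columns]
    df = _check_numeric(df, numeric, path)
    out = []
    for _, row in df.iterrows():
        vtot = row.get("true_vtot_mlmin", np.nan)
        out.append(PatientProfile(
            patient_id=str(row["patient_id"]),
            age=float(row["age_yr"]),
            water=float(row["water_ml"]),
            bmi=float(row["bmi_kgm2"]),
            v_plan=float(row["v_plan_ml"]),
            true_vtot=None if pd.isna(vtot) else float(vtot),
            residual_urine=float(row.get("residual_ml", 0.0) or 0.0),
        ))
    return out


def trajectories_to_frame(trajectories: Sequence[BVTrajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for m in traj.measurements:
            rows.append({
                "patient_id": traj.patient_id,
                "t_min": m.t,
                "volume_ml": m.volume,
                "sigma_v_ml": np.nan if m.sigma_v is None else m.sigma_v,
                "sigma_t_min": np.nan if m.sigma_t is None else m.sigma_t,
            })
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def write_trajectories(trajectories: Sequence[BVTrajectory], path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectories(path) -> list[BVTrajectory]:
    """Read a trajectory CSV, grouping rows by patient in file order."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _TRAJECTORY_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing trajectory columns {missing}")
    numeric = [c for c in TRAJECTORY_COLUMNS[1:] if c in df.columns]
    df = _check_numeric(df, numeric, path)
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        measurements = []
        for _, row in grp.iterrows():
            sv = row.get("sigma_v_ml", np.nan)
            st = row.get("sigma_t_min", np.nan)
            measurements.append(BVMeasurement(
                t=float(row["t_min"]),
                volume=float(row["volume_ml"]),
                sigma_v=None if pd.isna(sv) else float(sv),
                sigma_t=None if pd.isna(st) else float(st),
            ))
        out.append(BVTrajectory(patient_id=str(pid), measurements=measurements))
    return out
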