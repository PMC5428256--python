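"""Model-guided pre-treatment scan scheduling.

Simulates the adaptive workflow for one radiotherapy fraction: the patient
voids, drinks, and the first ultrasound scan is taken at the time the
population model predicts the bladder reaches the planning volume.  If the
measured volume is within the ±15% consistency band, treatment proceeds.
Otherwise the scan-implied rate replaces the model rate (the difference is
the correction factor): an underfull bladder leads to a wait and re-scan, an
overfull one (by default) to voiding and a restart with the corrected rate.
Scan counts and waiting times over a cohort summarise the workflow cost.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import CohortConfig, PatientProfile
from .exceptions import ConfigurationError, InputError
from .population import InflowModel, PREDICTION_FLOOR

__all__ = [
    "ScheduleConfig",
    "SessionOutcome",
    "predict_first_scan_time",
    "correction_factor",
    "run_session",
    "simulate_cohort_schedule",
    "ScheduleSummary",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Protocol settings for a scheduled session.

    ``bv_tolerance_frac`` is the half-width of the consistency band around
    the planning volume (default ±15%); ``rescan_interval_min`` the minimum
    gap between scans (default 10 min); ``scan_duration_min`` the time one
    full measurement takes (about 1 min), counted in elapsed time but not as
    waiting.  ``restart_on_overfull`` selects void-and-restart on an
    overfull bladder; the alternative accepts mild overfilling up to twice
    the tolerance before voiding.
    """

    bv_tolerance_frac: float = 0.15
    rescan_interval_min: float = 10.0
    max_scans: int = 6
    restart_on_overfull: bool = True
    scan_duration_min: float = 1.0

    def __post_init__(self):
        if not 0 < self.bv_tolerance_frac < 1:
            raise ConfigurationError("bv_tolerance_frac must be in (0, 1)")
        if self.rescan_interval_min <= 0:
            raise ConfigurationError("rescan_interval_min must be > 0")
        if self.max_scans < 1:
            raise ConfigurationError("max_scans must be >= 1")
        if self.scan_duration_min < 0:
            raise ConfigurationError("scan_duration_min must be >= 0")


@dataclass
class SessionOutcome:
    """Log of one simulated pre-treatment session.

    ``wait_min`` accumulates all waiting after the first scan (the first scan
    is taken at the predicted treat time, so any further waiting is workflow
    overhead).  ``actions`` is an ordered log of tuples:
    ``("scan", t_min, bv_ml)``, ``("wait", minutes)``, ``("void", t_min)``,
    ``("treat", t_min)``, ``("abort", t_min)``.
    """

    patient_id: str
    n_scans: int
    wait_min: float
    actions: list = field(default_factory=list)
    success: bool = False
    final_bv: float = float("nan")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def predict_first_scan_time(v_plan: float, residual: float, vtot_pred: float) -> float:
    """Minutes after voiding at which the bladder is predicted to reach v_plan."""
    if vtot_pred <= 0:
        raise InputError(f"predicted rate must be > 0, got {vtot_pred}")
    if v_plan < residual:
        raise InputError("planning volume below the post-void residual")
    return (v_plan - residual) / vtot_pred


def correction_factor(bv_measured: float, residual: float, t: float,
                      vtot_old: float) -> tuple[float, float]:
    """Scan-implied inflow rate and the correction relative to the old rate.

    ``vtot_new = (bv_measured - residual)/t`` floored at 0.05 ml/min; the
    correction factor is ``vtot_old - vtot_new``.
    """
    if t <= 0:
        raise InputError(f"elapsed time must be > 0, got {t}")
    vtot_new = max(PREDICTION_FLOOR, (bv_measured - residual) / t)
    return vtot_new, vtot_old - vtot_new


def _predicted_rate(patient: PatientProfile,
                    model: Union[InflowModel, float]) -> float:
    if isinstance(model, InflowModel):
        return model.predict(patient.age, patient.water, patient.bmi,
                             warn_extrapolation=False)
    return max(PREDICTION_FLOOR, float(model))


def run_session(
    patient: PatientProfile,
    model: Union[InflowModel, float],
    config: ScheduleConfig = ScheduleConfig(),
    rng: Optional[np.random.Generator] = None,
    noise_cv: float = 0.0,
) -> SessionOutcome:
    """Simulate one pre-treatment session for ``patient``.

    The patient's bladder fills at their latent ``true_vtot`` from the
    post-void residual; the session logic only ever sees the (noisy) scans.
    ``model`` may be a fitted :class:`InflowModel` or a rate in ml/min.
    Waits are rounded up to whole minutes and never shorter than the re-scan
    interval; each scan consumes ``scan_duration_min`` of elapsed time.
    """
    if patient.v_plan <= 0:
        raise InputError("v_plan must be > 0")
    if patient.true_vtot is None:
        raise InputError(f"patient {patient.patient_id} has no latent rate to simulate")
    rng = rng if rng is not None else np.random.default_rng(0)

    v_plan = patient.v_plan
    residual = min(patient.residual_urine, v_plan)
    lower = v_plan * (1.0 - config.bv_tolerance_frac)
    upper = v_plan * (1.0 + config.bv_tolerance_frac)

    vtot_cur = _predicted_rate(patient, model)
    clock = predict_first_scan_time(v_plan, residual, vtot_cur)
    void_time = 0.0
    actions: list = []
    wait_min = 0.0
    n_scans = 0
    success = False
    final_bv = float("nan")

    while n_scans < config.max_scans:
        t_since_void = clock - void_time
        bv_true = residual + patient.true_vtot * t_since_void
        bv = bv_true * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else bv_true
        bv = max(bv, 0.0)
        n_scans += 1
        actions.append(("scan", round(clock, 3), round(bv, 3)))
        clock += config.scan_duration_min

        if lower <= bv <= upper:
            actions.append(("treat", round(clock, 3)))
            success, final_bv = True, bv
            break

        if t_since_void > 0:
            vtot_cur, _ = correction_factor(bv, residual, t_since_void, vtot_cur)

        if bv > upper:
            if not config.restart_on_overfull and bv <= v_plan * (1.0 + 2 * config.bv_tolerance_frac):
                # sensitivity-analysis variant: accept mild overfilling
                actions.append(("treat", round(clock, 3)))
                success, final_bv = True, bv
                break
            actions.append(("void", round(clock, 3)))
            void_time = clock
            wait = max(math.ceil((v_plan - residual) / vtot_cur),
                       config.rescan_interval_min)
        else:
            wait = max(math.ceil((v_plan - bv) / vtot_cur),
                       config.rescan_interval_min)

        if n_scans >= config.max_scans:
            break
        actions.append(("wait", float(wait)))
        wait_min += wait
        clock += wait

    if not success:
        actions.append(("abort", round(clock, 3)))
        final_bv = bv
    return SessionOutcome(
        patient_id=patient.patient_id, n_scans=n_scans, wait_min=wait_min,
        actions=actions, success=success, final_bv=final_bv)


@dataclass
class ScheduleSummary:
    """Cohort-level workflow statistics over simulated fractions."""

    fractions: pd.DataFrame            # fraction_id, patient_id, n_scans, wait_min, outcome
    frac_one_scan: float
    frac_within_3_scans: float
    frac_within_5_scans: float
    frac_success: float
    mean_wait_min: float
    median_wait_min: float
    scan_histogram: pd.DataFrame       # bins 1..(max_scans-1), "max+"
    wait_histogram: pd.DataFrame       # 12-min bins

    def to_dict(self) -> dict:
        return {
            "frac_one_scan": self.frac_one_scan,
            "frac_within_3_scans": self.frac_within_3_scans,
            "frac_within_5_scans": self.frac_within_5_scans,
            "frac_success": self.frac_success,
            "mean_wait_min": self.mean_wait_min,
            "median_wait_min": self.median_wait_min,
        }


def simulate_cohort_schedule(
    cohort: Sequence[PatientProfile],
    model: Union[InflowModel, float],
    config: ScheduleConfig = ScheduleConfig(),
    n_reps: int = 1,
    rng: Optional[np.random.Generator] = None,
    noise_cv: float = 0.05,
    wait_bin_min: float = 12.0,
) -> ScheduleSummary:
    """Run ``n_reps`` fractions per patient and summarise scans and waits."""
    if not cohort:
        raise InputError("empty cohort")
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for rep in range(n_reps):
        for patient in cohort:
            out = run_session(patient, model, config, rng, noise_cv=noise_cv)
            rows.append({
                "fraction_id": f"{patient.patient_id}_f{rep + 1}",
                "patient_id": patient.patient_id,
                "n_scans": out.n_scans,
                "wait_min": out.wait_min,
                "outcome": "treat" if out.success else "abort",
            })
    df = pd.DataFrame(rows)
    n = len(df)
    treated = df["outcome"] == "treat"

    max_bin = config.max_scans
    scan_counts = []
    for k in range(1, max_bin):
        scan_counts.append({"n_scans": str(k),
                            "fraction": float((df["n_scans"] == k).mean())})
    scan_counts.append({"n_scans": f"{max_bin}+",
                        "fraction": float((df["n_scans"] >= max_bin).mean())})
    scan_hist = pd.DataFrame(scan_counts)

    edges = np.arange(0.0, df["wait_min"].max() + wait_bin_min + 1e-9, wait_bin_min)
    counts, _ = np.histogram(df["wait_min"], bins=edges)
    wait_hist = pd.DataFrame({
        "wait_lo_min": edges[:-1], "wait_hi_min": edges[1:],
        "fraction": counts / n,
    })

    return ScheduleSummary(
        fractions=df,
        frac_one_scan=float(((df["n_scans"] == 1) & treated).mean()),
        frac_within_3_scans=float(((df["n_scans"] <= 3) & treated).mean()),
        frac_within_5_scans=float(((df["n_scans"] <= 5) & treated).mean()),
        frac_success=float(treated.mean()),
        mean_wait_min=float(df["wait_min"].mean()),
        median_wait_min=float(df["wait_min"].median()),
        scan_histogram=scan_hist,
        wait_histogram=wait_hist,
    )
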