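"""Per-patient inflow-rate estimation from bladder-volume trajectories.

The bladder volume of a single patient grows linearly with time, so the mean
urinary inflow rate ``v_tot`` (ml/min) is the slope of a straight-line fit to
the scan series.  Two fits are provided:

* :func:`fit_inflow_plain` — weighted least squares ignoring scan-time
  uncertainty, minimising ``sum(((V_i - a - v*t_i)/sigma_v_i)**2)``.
* :func:`fit_inflow_tu` — an effective-variance fit that propagates a time
  uncertainty ``sigma_t`` into the weights via
  ``sigma_eff_i**2 = sigma_v_i**2 + (v*sigma_t_i)**2`` and iterates to a
  self-consistent slope.

Goodness of fit is summarised by the chi-square survival probability
``P(X > chi2)`` with ``ndf = n - 2`` degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from .exceptions import (
    ConvergenceError,
    DegenerateDesignError,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "BVMeasurement",
    "BVTrajectory",
    "InflowFit",
    "relative_volume",
    "fit_inflow_plain",
    "fit_inflow_tu",
    "chi2_survival",
    "deviation_stats",
]

#: fallback coefficient of variation used when a measurement carries no sigma_v
DEFAULT_SIGMA_CV = 0.05


@dataclass
class BVMeasurement:
    """One ultrasound bladder-volume reading.

    ``t`` is minutes since bladder voiding; ``volume`` is ml.  ``sigma_v``
    (ml) and ``sigma_t`` (min) are optional 1-sigma uncertainties.
    """

    t: float
    volume: float
    sigma_v: Optional[float] = None
    sigma_t: Optional[float] = None

    def __post_init__(self):
        if self.t < 0:
            raise InputError(f"measurement time must be >= 0, got {self.t}")
        if self.volume < 0:
            raise InputError(f"volume must be >= 0, got {self.volume}")
        for name in ("sigma_v", "sigma_t"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise InputError(f"{name} must be >= 0, got {val}")


@dataclass
class BVTrajectory:
    """Time-ordered bladder-volume measurements for one session.

    ``v0_ref`` is the volume of the first scan, the reference for relative
    volumes.
    """

    patient_id: str
    measurements: list[BVMeasurement] = field(default_factory=list)

    def __post_init__(self):
        t = self.t
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise InputError(
                f"trajectory {self.patient_id}: times must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return np.array([m.t for m in self.measurements], dtype=float)

    @property
    def volume(self) -> np.ndarray:
        return np.array([m.volume for m in self.measurements], dtype=float)

    @property
    def v0_ref(self) -> float:
        if not self.measurements:
            raise InputError("empty trajectory has no reference volume")
        return self.measurements[0].volume

    def __len__(self) -> int:
        return len(self.measurements)

    @classmethod
    def from_arrays(cls, patient_id, t, volume, sigma_v=None, sigma_t=None) -> "BVTrajectory":
        t = np.asarray(t, dtype=float)
        volume = np.asarray(volume, dtype=float)
        if t.shape != volume.shape:
            raise InputError("t and volume must have the same length")
        n = t.size
        sv = np.full(n, np.nan) if sigma_v is None else np.asarray(sigma_v, dtype=float)
        st = np.full(n, np.nan) if sigma_t is None else np.asarray(sigma_t, dtype=float)
        ms = [
            BVMeasurement(
                t=float(t[i]), volume=float(volume[i]),
                sigma_v=None if np.isnan(sv[i]) else float(sv[i]),
                sigma_t=None if np.isnan(st[i]) else float(st[i]),
            )
            for i in range(n)
        ]
        return cls(patient_id=str(patient_id), measurements=ms)

    def to_frame(self) -> pd.DataFrame:
        from .cohort import trajectories_to_frame
        return trajectories_to_frame([self])


@dataclass
class InflowFit:
    """Result of a straight-line inflow fit.

    ``vtot`` is the slope in ml/min with standard error ``vtot_se``;
    ``prob`` is the chi-square survival probability of the fit.
    """

    patient_id: str
    vtot: float
    vtot_se: float
    intercept: float
    intercept_se: float
    chi2: float
    ndf: int
    prob: float
    method: str          # "plain" or "time_uncertainty"
    n_points: int
    iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "method": self.method,
            "vtot": self.vtot,
            "vtot_se": self.vtot_se,
            "intercept": self.intercept,
            "chi2": self.chi2,
            "ndf": self.ndf,
            "prob": self.prob,
            "n_points": self.n_points,
        }


def chi2_survival(chi2: float, ndf: int) -> float:
    """Chi-square fit probability ``P(X > chi2)`` for ``ndf`` degrees of freedom.

    Computed as the regularized upper incomplete gamma function
    ``Q(ndf/2, chi2/2)``; decreasing in ``chi2``, equal to 1 at ``chi2 = 0``.
    """
    if ndf < 1:
        raise InputError(f"ndf must be >= 1, got {ndf}")
    if chi2 < 0:
        raise InputError(f"chi2 must be >= 0, got {chi2}")
    return float(special.gammaincc(ndf / 2.0, chi2 / 2.0))


def relative_volume(traj: BVTrajectory) -> pd.DataFrame:
    """Relative volume series: ``dv = V(t) - V_0`` and ``rel = dv / V_0``.

    ``V_0`` is the first scan's volume.  If ``V_0 == 0`` the ratio is
    undefined; ``dv`` is still returned and ``rel`` is NaN (with a warning).
    """
    if len(traj) == 0:
        raise InputError("empty trajectory")
    t = traj.t
    v = traj.volume
    dv = v - traj.v0_ref
    if traj.v0_ref > 0:
        rel = dv / traj.v0_ref
    else:
        warnings.warn(f"trajectory {traj.patient_id}: V_0 = 0, relative volume undefined")
        rel = np.full_like(dv, np.nan)
    return pd.DataFrame({"t_min": t, "dv_ml": dv, "rel_dv": rel})


def _resolve_sigma_v(traj: BVTrajectory, default_cv: float) -> np.ndarray:
    """Per-point volume sigmas: recorded sigma, else default_cv*volume, else unit.

    A trajectory with no usable sigma anywhere (noiseless fixtures) falls back
    to unit weights, which leaves slope and chi2 of an exact line unchanged.
    """
    v = traj.volume
    sigma = np.array(
        [m.sigma_v if (m.sigma_v is not None and m.sigma_v > 0) else np.nan
         for m in traj.measurements])
    fallback = default_cv * v
    sigma = np.where(np.isnan(sigma), fallback, sigma)
    sigma[sigma <= 0] = np.nan
    if np.all(np.isnan(sigma)):
        return np.ones(len(v))
    # any remaining holes take the smallest positive sigma present
    sigma = np.where(np.isnan(sigma), np.nanmin(sigma), sigma)
    return sigma


def _wls_line(t: np.ndarray, v: np.ndarray, sigma: np.ndarray):
    """Weighted straight-line fit V = a + b*t via the normal equations.

    Returns (intercept a, slope b, se_a, se_b, chi2).  Standard errors come
    from the inverse weighted normal matrix (chi-square convention, no
    residual rescaling).
    """
    w = 1.0 / sigma**2
    S = w.sum()
    Sx = (w * t).sum()
    Sy = (w * v).sum()
    Sxx = (w * t * t).sum()
    Sxy = (w * t * v).sum()
    delta = S * Sxx - Sx * Sx
    if delta <= 0 or not np.isfinite(delta):
        raise DegenerateDesignError("all scan times identical; slope undefined")
    a = (Sxx * Sy - Sx * Sxy) / delta
    b = (S * Sxy - Sx * Sy) / delta
    se_a = math.sqrt(Sxx / delta)
    se_b = math.sqrt(S / delta)
    chi2 = float((((v - a - b * t) / sigma) ** 2).sum())
    return a, b, se_a, se_b, chi2


def fit_inflow_plain(traj: BVTrajectory, default_sigma_cv: float = DEFAULT_SIGMA_CV) -> InflowFit:
    """Weighted least-squares line fit with no scan-time uncertainty.

    Minimises ``sum(((V_i - a - v*t_i)/sigma_v_i)**2)``; the reported
    ``chi2`` is the minimum, ``ndf = n - 2`` and ``prob`` the chi-square
    survival probability.  Measurements without ``sigma_v`` use
    ``default_sigma_cv * volume``.
    """
    n = len(traj)
    if n < 3:
        raise InsufficientDataError(
            f"trajectory {traj.patient_id}: need >= 3 points, got {n}")
    t, v = traj.t, traj.volume
    sigma = _resolve_sigma_v(traj, default_sigma_cv)
    a, b, se_a, se_b, chi2 = _wls_line(t, v, sigma)
    ndf = n - 2
    return InflowFit(
        patient_id=traj.patient_id, vtot=b, vtot_se=se_b, intercept=a,
        intercept_se=se_a, chi2=chi2, ndf=ndf, prob=chi2_survival(chi2, ndf),
        method="plain", n_points=n)


def fit_inflow_tu(
    traj: BVTrajectory,
    default_sigma_t: Optional[float] = None,
    default_sigma_cv: float = DEFAULT_SIGMA_CV,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> InflowFit:
    """Straight-line fit propagating scan-time uncertainty (effective variance).

    Iterates weighted fits with ``sigma_eff_i**2 = sigma_v_i**2 +
    (v*sigma_t_i)**2`` until the slope changes by less than ``tol`` ml/min.
    With all ``sigma_t = 0`` this reduces exactly to the plain fit; with
    ``sigma_t > 0`` the slope standard error is enlarged.
    """
    n = len(traj)
    if n < 3:
        raise InsufficientDataError(
            f"trajectory {traj.patient_id}: need >= 3 points, got {n}")
    t, v = traj.t, traj.volume
    sigma_v = _resolve_sigma_v(traj, default_sigma_cv)
    sigma_t = np.array(
        [m.sigma_t if m.sigma_t is not None
         else (default_sigma_t if default_sigma_t is not None else 0.0)
         for m in traj.measurements], dtype=float)

    plain = fit_inflow_plain(traj, default_sigma_cv)
    if np.all(sigma_t == 0):
        return InflowFit(**{**plain.__dict__, "method": "time_uncertainty"})

    b = plain.vtot
    trace = [b]
    for it in range(1, max_iter + 1):
        sigma_eff = np.sqrt(sigma_v**2 + (b * sigma_t) ** 2)
        a, b_new, se_a, se_b, chi2 = _wls_line(t, v, sigma_eff)
        trace.append(b_new)
        if abs(b_new - b) < tol:
            ndf = n - 2
            return InflowFit(
                patient_id=traj.patient_id, vtot=b_new, vtot_se=se_b,
                intercept=a, intercept_se=se_a, chi2=chi2, ndf=ndf,
                prob=chi2_survival(chi2, ndf), method="time_uncertainty",
                n_points=n, iterations=it)
        b = b_new
    raise ConvergenceError(
        f"effective-variance fit did not converge in {max_iter} iterations", trace=trace)


def deviation_stats(traj: BVTrajectory, default_sigma_cv: float = DEFAULT_SIGMA_CV):
    """Relative residuals about the fitted line: (mean, sd, gaussian gof prob).

    Residuals are ``(V_i - a - v*t_i)/V_0``.  The goodness-of-fit probability
    compares binned residuals against the Gaussian with the sample mean and
    sd, using ``ceil(sqrt(n))`` equal-probability bins and ``ndf = bins - 3``
    (two estimated parameters plus normalisation).  With too few bins for a
    positive ndf, or zero-variance residuals, ``gof_prob`` is NaN.
    """
    n = len(traj)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 points for deviation stats, got {n}")
    if traj.v0_ref <= 0:
        raise InputError("V_0 must be > 0 for relative deviations")
    fit = fit_inflow_plain(traj, default_sigma_cv)
    resid = (traj.volume - fit.intercept - fit.vtot * traj.t) / traj.v0_ref
    mean = float(resid.mean())
    sd = float(resid.std(ddof=1))
    if sd == 0:
        return mean, sd, float("nan")

    nbins = math.ceil(math.sqrt(n))
    ndf = nbins - 3
    if ndf < 1:
        return mean, sd, float("nan")
    from scipy import stats
    edges = stats.norm.ppf(np.linspace(0, 1, nbins + 1), loc=mean, scale=sd)
    observed, _ = np.histogram(resid, bins=edges)
    expected = n / nbins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return mean, sd, chi2_survival(chi2, ndf)
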