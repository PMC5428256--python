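"""Population model for the mean urinary inflow rate.

The per-patient mean inflow rate ``v_tot`` (ml/min) is decomposed as a linear
superposition of covariate effects

    v_tot = v0 + k_age * P_age + k_wat * P_wat + k_bmi * P_bmi,

where ``v0`` is the net urinary inflow rate (the intercept), ``P_age`` is age
in years, ``P_wat`` the pre-session water intake in ml and ``P_bmi`` the
body-mass index in kg/m².  Two estimators are provided:

* multivariable ordinary least squares (with or without the BMI term), and
* an iterative alternating fit that decomposes the rate covariate by
  covariate: initialise the age slope from the largest equal-water subgroup,
  then alternate a water fit on the age-corrected rates with an age fit on
  the water-corrected rates until both coefficients stabilise.

The public surface follows the familiar model/results idiom:
``InflowRateModel(records).fit(method=...)`` returns an :class:`InflowModel`
results object with coefficients, standard errors, p-values, prediction and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    ConvergenceError,
    DegenerateDesignError,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "FitRecord",
    "InflowModel",
    "InflowRateModel",
    "fit_regression",
    "iterative_fit",
    "predict_vtot",
    "pearson_r",
    "paired_ttest",
    "PREDICTION_FLOOR",
]

#: Physiological floor applied to predicted inflow rates, ml/min.
PREDICTION_FLOOR = 0.05

_COEF_NAMES = ("v0", "k_age", "k_wat", "k_bmi")


@dataclass
class FitRecord:
    """One patient's covariates and estimated inflow rate."""

    patient_id: str
    age: float          # years
    water: float        # ml
    bmi: float          # kg/m^2
    vtot_hat: float     # ml/min, per-patient slope estimate
    vtot_se: float = 0.0

    def __post_init__(self):
        if self.vtot_se < 0:
            raise InputError("vtot_se must be >= 0")


@dataclass
class InflowModel:
    """Fitted population inflow-rate model (results object).

    ``method`` is one of ``regression3`` (intercept + age + water + BMI),
    ``regression2`` (BMI dropped) or ``iterative`` (alternating fit, BMI
    fixed to zero).  Standard errors for the iterative method come from its
    final-pass component fits, which is a method-dependent estimator.
    """

    method: str
    v0: float
    k_age: float
    k_wat: float
    k_bmi: float
    se: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    n: int = 0
    iterations: Optional[int] = None
    train_ranges: Optional[dict] = None

    def __post_init__(self):
        if self.method not in ("regression3", "regression2", "iterative"):
            raise InputError(f"unknown method {self.method!r}")
        if self.method in ("regression2", "iterative") and self.k_bmi != 0.0:
            raise InputError(f"method {self.method} requires k_bmi = 0")

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            [self.v0, self.k_age, self.k_wat, self.k_bmi], index=_COEF_NAMES)

    @property
    def bse(self) -> pd.Series:
        return pd.Series({k: self.se.get(k, np.nan) for k in _COEF_NAMES})

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({k: self.p.get(k, np.nan) for k in _COEF_NAMES})

    def predict(self, age, water, bmi=0.0, warn_extrapolation: bool = True):
        """Predicted mean inflow rate (ml/min), floored at 0.05 ml/min.

        Warns when a covariate lies outside the training range (if known).
        """
        age = np.asarray(age, dtype=float)
        water = np.asarray(water, dtype=float)
        bmi = np.asarray(bmi, dtype=float)
        if warn_extrapolation and self.train_ranges:
            checks = [("age", age), ("water", water)]
            if self.k_bmi != 0.0:
                checks.append(("bmi", bmi))
            for name, vals in checks:
                rng = self.train_ranges.get(name)
                if rng and (np.any(vals < rng[0]) or np.any(vals > rng[1])):
                    warnings.warn(
                        f"predicting outside the training {name} range {rng}",
                        stacklevel=2)
        raw = self.v0 + self.k_age * age + self.k_wat * water + self.k_bmi * bmi
        clamped = np.maximum(raw, PREDICTION_FLOOR)
        return float(clamped) if clamped.ndim == 0 else clamped

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "v0": self.v0, "k_age": self.k_age,
            "k_wat": self.k_wat, "k_bmi": self.k_bmi,
            "se": dict(self.se), "p": dict(self.p),
            "n": self.n, "iterations": self.iterations,
            "train_ranges": self.train_ranges,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "InflowModel":
        d = {k: d[k] for k in
             ("method", "v0", "k_age", "k_wat", "k_bmi", "se", "p",
              "n", "iterations", "train_ranges") if k in d}
        if d.get("train_ranges"):
            d["train_ranges"] = {k: tuple(v) for k, v in d["train_ranges"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, text_or_path) -> "InflowModel":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text_or_path) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def summary(self) -> str:
        lines = [
            "Population inflow-rate model",
            f"  method: {self.method}    n = {self.n}"
            + (f"    iterations = {self.iterations}" if self.iterations else ""),
            f"  {'coef':>6} {'estimate':>12} {'std err':>10} {'p-value':>10}",
        ]
        for name in _COEF_NAMES:
            if self.method in ("regression2", "iterative") and name == "k_bmi":
                continue
            est = getattr(self, name)
            se = self.se.get(name, float("nan"))
            pv = self.p.get(name, float("nan"))
            lines.append(f"  {name:>6} {est:12.4f} {se:10.4f} {pv:10.4f}")
        return "\n".join(lines)


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = ("patient_id", "age", "water", "bmi", "vtot_hat")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(f"records frame missing columns {missing}")
        if "vtot_se" not in df.columns:
            df["vtot_se"] = 0.0
        return df
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


class InflowRateModel:
    """Model object holding per-patient rate estimates and covariates.

    Parameters
    ----------
    records : sequence of FitRecord or DataFrame
        One row per patient with ``age``, ``water``, ``bmi`` and the
        estimated rate ``vtot_hat`` (columns as named, when a DataFrame).
    """

    def __init__(self, records):
        self.data = _records_to_frame(records)
        if len(self.data) == 0:
            raise InsufficientDataError("no records")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "InflowRateModel":
        return cls(df)

    @property
    def nobs(self) -> int:
        return len(self.data)

    def _train_ranges(self) -> dict:
        return {
            "age": (float(self.data["age"].min()), float(self.data["age"].max())),
            "water": (float(self.data["water"].min()), float(self.data["water"].max())),
            "bmi": (float(self.data["bmi"].min()), float(self.data["bmi"].max())),
        }

    def fit(self, method: str = "regression2", **kwargs) -> InflowModel:
        """Fit by ``regression2``, ``regression3`` or ``iterative``."""
        if method in ("regression2", "regression3"):
            return self.fit_regression(include_bmi=(method == "regression3"), **kwargs)
        if method == "iterative":
            return self.fit_iterative(**kwargs)
        raise InputError(f"unknown fit method {method!r}")

    # -- ordinary least squares ------------------------------------------

    def fit_regression(self, include_bmi: bool = False) -> InflowModel:
        """Multivariable OLS of ``vtot_hat`` on the covariates.

        Coefficient standard errors use the unbiased residual-variance
        estimate; p-values are two-sided from the t distribution with
        ``n - p`` degrees of freedom.
        """
        df = self.data
        names = ["k_age", "k_wat"] + (["k_bmi"] if include_bmi else [])
        cols = ["age", "water"] + (["bmi"] if include_bmi else [])
        n, p = len(df), len(cols) + 1
        if n <= p:
            raise InsufficientDataError(f"need more than {p} records, got {n}")
        X = sm.add_constant(df[cols].to_numpy(dtype=float), has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            degen = [c for c in cols if df[c].nunique() <= 1]
            raise DegenerateDesignError(
                f"collinear design; offending covariates: {degen or cols}")
        res = sm.OLS(df["vtot_hat"].to_numpy(dtype=float), X).fit()
        coef = {"v0": float(res.params[0])}
        se = {"v0": float(res.bse[0])}
        pv = {"v0": float(res.pvalues[0])}
        for i, name in enumerate(names, start=1):
            coef[name] = float(res.params[i])
            se[name] = float(res.bse[i])
            pv[name] = float(res.pvalues[i])
        if not include_bmi:
            coef["k_bmi"], se["k_bmi"], pv["k_bmi"] = 0.0, 0.0, 1.0
        return InflowModel(
            method="regression3" if include_bmi else "regression2",
            v0=coef["v0"], k_age=coef["k_age"], k_wat=coef["k_wat"],
            k_bmi=coef["k_bmi"], se=se, p=pv, n=n,
            train_ranges=self._train_ranges())

    # -- iterative alternating fit ---------------------------------------

    def fit_iterative(
        self,
        conv_tol: float = 0.01,
        max_iter: int = 100,
        water_bin_ml: float = 50.0,
        age_fit_intercept: str = "free",
    ) -> InflowModel:
        """Alternating covariate-by-covariate fit with BMI fixed to zero.

        Initialisation regresses ``vtot_hat`` on age within the largest
        subgroup sharing one water value (binned to ``water_bin_ml`` when no
        exact ties exist), giving ``k_age_ini``.  Each pass then

        1. fits ``vtot_hat - k_age*age`` against water (free intercept),
           yielding ``v0`` and ``k_wat``;
        2. fits ``vtot_hat - v0 - k_wat*water`` against age, yielding the
           next ``k_age`` (its intercept is absorbed into ``v0`` on the next
           water fit, or forced to zero with ``age_fit_intercept="zero"``).

        Passes repeat until both coefficient changes fall below ``conv_tol``
        (absolute, in each coefficient's own units).
        """
        df = self.data
        if age_fit_intercept not in ("free", "zero"):
            raise InputError("age_fit_intercept must be 'free' or 'zero'")
        if df["age"].nunique() < 2:
            raise DegenerateDesignError("all ages equal; k_age unidentifiable")
        if df["water"].nunique() < 2:
            raise DegenerateDesignError("all water intakes equal; k_wat unidentifiable")

        age = df["age"].to_numpy(dtype=float)
        water = df["water"].to_numpy(dtype=float)
        y = df["vtot_hat"].to_numpy(dtype=float)
        n = len(df)

        k_age = self._initial_k_age(age, water, y, water_bin_ml)

        prev = (k_age, np.nan)
        k_wat = np.nan
        trace = []
        for it in range(1, max_iter + 1):
            # water fit on age-corrected rates -> v0, k_wat
            r = y - k_age * age
            v0, k_wat, se_v0, se_kw, p_v0, p_kw = _ols_line_stats(water, r)
            # age fit on water-corrected rates -> k_age
            s = y - v0 - k_wat * water
            if age_fit_intercept == "free":
                _, k_age_new, _, se_ka, _, p_ka = _ols_line_stats(age, s)
            else:
                k_age_new, se_ka, p_ka = _ols_through_origin(age, s)
            trace.append((v0, k_age_new, k_wat))
            d_age = abs(k_age_new - prev[0])
            d_wat = abs(k_wat - prev[1]) if not np.isnan(prev[1]) else np.inf
            prev = (k_age_new, k_wat)
            k_age = k_age_new
            if d_age < conv_tol and d_wat < conv_tol:
                # final water refit so v0/k_wat are consistent with k_age
                r = y - k_age * age
                v0, k_wat, se_v0, se_kw, p_v0, p_kw = _ols_line_stats(water, r)
                return InflowModel(
                    method="iterative", v0=float(v0), k_age=float(k_age),
                    k_wat=float(k_wat), k_bmi=0.0,
                    se={"v0": float(se_v0), "k_age": float(se_ka),
                        "k_wat": float(se_kw), "k_bmi": 0.0},
                    p={"v0": float(p_v0), "k_age": float(p_ka),
                       "k_wat": float(p_kw), "k_bmi": 1.0},
                    n=n, iterations=it, train_ranges=self._train_ranges())
        raise ConvergenceError(
            f"alternating fit did not converge in {max_iter} passes", trace=trace)

    @staticmethod
    def _initial_k_age(age, water, y, water_bin_ml) -> float:
        """k_age from the largest equal-water subgroup (50-ml binning fallback).

        Within a subgroup of constant water intake the water term is constant,
        so the slope of rate vs. age estimates k_age directly.  Ties in group
        size break toward the larger age spread.
        """
        def best_group(keys):
            groups = {}
            for i, k in enumerate(keys):
                groups.setdefault(k, []).append(i)
            candidates = [idx for idx in groups.values()
                          if len(idx) >= 2 and len(set(age[idx])) >= 2]
            if not candidates:
                return None
            return max(candidates, key=lambda idx: (len(idx), float(np.ptp(age[idx]))))

        group = best_group(water)
        if group is None and water_bin_ml:
            binned = np.round(water / water_bin_ml) * water_bin_ml
            group = best_group(binned)
        if group is None:
            raise DegenerateDesignError(
                "no equal-water subgroup for initialization; "
                "bin water intakes (e.g. to the nearest 50 ml) and retry")
        idx = np.asarray(group)
        _, slope, *_ = _ols_line_stats(age[idx], y[idx])
        return float(slope)


def _ols_line_stats(x: np.ndarray, y: np.ndarray):
    """OLS line y = a + b*x with classical SEs and two-sided t p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        raise DegenerateDesignError("need >= 2 distinct x values for a line fit")
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    b = ((x - xbar) * (y - ybar)).sum() / sxx
    a = ybar - b * xbar
    resid = y - a - b * x
    dof = n - 2
    if dof > 0:
        s2 = (resid**2).sum() / dof
        se_b = math.sqrt(s2 / sxx)
        se_a = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
        p_b = 2 * stats.t.sf(abs(b) / se_b, dof) if se_b > 0 else (0.0 if b else 1.0)
        p_a = 2 * stats.t.sf(abs(a) / se_a, dof) if se_a > 0 else (0.0 if a else 1.0)
    else:
        se_a = se_b = 0.0
        p_a = p_b = float("nan")
    return a, b, se_a, se_b, p_a, p_b


def _ols_through_origin(x: np.ndarray, y: np.ndarray):
    """OLS slope of y = b*x with classical SE and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = (x**2).sum()
    if sxx == 0:
        raise DegenerateDesignError("x identically zero")
    b = (x * y).sum() / sxx
    dof = x.size - 1
    s2 = ((y - b * x) ** 2).sum() / dof if dof > 0 else 0.0
    se_b = math.sqrt(s2 / sxx)
    p_b = 2 * stats.t.sf(abs(b) / se_b, dof) if se_b > 0 else (0.0 if b else 1.0)
    return b, se_b, p_b


# ---------------------------------------------------------------------------
# functional wrappers and cohort statistics

def fit_regression(records, include_bmi: bool = False) -> InflowModel:
    """OLS population fit; see :meth:`InflowRateModel.fit_regression`."""
    return InflowRateModel(records).fit_regression(include_bmi=include_bmi)


def iterative_fit(records, conv_tol: float = 0.01, max_iter: int = 100,
                  **kwargs) -> InflowModel:
    """Alternating population fit; see :meth:`InflowRateModel.fit_iterative`."""
    return InflowRateModel(records).fit_iterative(
        conv_tol=conv_tol, max_iter=max_iter, **kwargs)


def predict_vtot(model: InflowModel, age, water, bmi=0.0, **kwargs):
    """Predicted mean inflow rate (ml/min) from a fitted model, floored at 0.05."""
    return model.predict(age, water, bmi, **kwargs)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value (t transform, n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("series must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("correlation undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Classical paired t-test: returns (t, df, two-sided p).

    Identical series (zero-variance, zero-mean differences) are reported as
    t = 0, p = 1; zero-variance differences with a nonzero mean are
    degenerate and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise InputError("series must have equal length")
    if a.size < 2:
        raise InsufficientDataError("need >= 2 pairs")
    d = a - b
    df = a.size - 1
    if np.std(d, ddof=1) == 0:
        if np.all(d == d[0]) and d[0] == 0:
            return 0.0, df, 1.0
        raise DegenerateDesignError("zero-variance nonzero differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)
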