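"""Population model: OLS and alternating fits, prediction, cohort statistics."""

import numpy as np
import pytest

from uroflow import (
    DegenerateDesignError,
    FitRecord,
    InflowModel,
    InflowRateModel,
    InsufficientDataError,
    fit_regression,
    iterative_fit,
    paired_ttest,
    pearson_r,
    predict_vtot,
)
from uroflow.experiments import simulate_and_fit

from conftest import ITERATIVE_TRUTH, REGRESSION_TRUTH, make_noiseless_records


class TestRegression:
    def test_noiseless_records_recover_truth_exactly(self):
        records = make_noiseless_records(REGRESSION_TRUTH, n=40, seed=1)
        m = fit_regression(records)
        assert m.v0 == pytest.approx(3.115, abs=1e-9)
        assert m.k_age == pytest.approx(-0.047, abs=1e-9)
        assert m.k_wat == pytest.approx(0.007, abs=1e-9)
        assert m.k_bmi == 0.0
        assert m.method == "regression2"

    def test_matches_normal_equations_oracle_on_fixture(self):
        """Coefficients and SEs equal an explicit normal-equations solve
        with the unbiased residual variance on a fixed 6-row fixture."""
        rows = [
            ("P1", 45.0, 100.0, 20.0, 2.10),
            ("P2", 52.0, 250.0, 22.0, 2.45),
            ("P3", 58.0, 300.0, 24.0, 2.30),
            ("P4", 63.0, 400.0, 25.0, 2.95),
            ("P5", 70.0, 500.0, 27.0, 3.05),
            ("P6", 49.0, 600.0, 21.0, 4.60),
        ]
        records = [FitRecord(pid, a, w, b, y) for pid, a, w, b, y in rows]
        m = fit_regression(records, include_bmi=True)
        X = np.column_stack([np.ones(6)] + [np.array([r[i] for r in rows])
                                            for i in (1, 2, 3)])
        y = np.array([r[4] for r in rows])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (6 - 4)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert m.v0 == pytest.approx(beta[0], rel=1e-9)
        assert m.k_age == pytest.approx(beta[1], rel=1e-9)
        assert m.k_wat == pytest.approx(beta[2], rel=1e-9)
        assert m.k_bmi == pytest.approx(beta[3], rel=1e-9)
        assert m.se["v0"] == pytest.approx(se[0], rel=1e-9)
        assert m.se["k_bmi"] == pytest.approx(se[3], rel=1e-9)

    def test_null_bmi_effect_is_rarely_significant(self, rng):
        """With BMI pure noise relative to the rate, the BMI p-value exceeds
        0.05 in about 95% of null replicates (type-I calibration)."""
        hits = 0
        reps = 200
        for i in range(reps):
            records = make_noiseless_records(REGRESSION_TRUTH, n=30, seed=1000 + i)
            for r in records:
                r.vtot_hat += rng.normal(0, 0.3)
            m = fit_regression(records, include_bmi=True)
            hits += m.p["k_bmi"] > 0.05
        assert hits / reps == pytest.approx(0.95, abs=0.05)

    def test_collinear_design_raises(self):
        records = make_noiseless_records(REGRESSION_TRUTH, n=10, seed=2)
        for r in records:
            r.age = 55.0
        with pytest.raises(DegenerateDesignError):
            fit_regression(records)

    def test_regression2_equals_regression3_when_bmi_inert(self):
        """With zero BMI effect and noiseless rates the two regressions give
        identical age/water coefficients (exact interpolation)."""
        records = make_noiseless_records(REGRESSION_TRUTH, n=25, seed=3)
        m2 = fit_regression(records, include_bmi=False)
        m3 = fit_regression(records, include_bmi=True)
        assert m3.k_bmi == pytest.approx(0.0, abs=1e-9)
        assert m2.k_age == pytest.approx(m3.k_age, abs=1e-9)
        assert m2.k_wat == pytest.approx(m3.k_wat, abs=1e-9)


class TestIterativeFit:
    def test_noiseless_records_converge_to_truth(self):
        records = make_noiseless_records(
            ITERATIVE_TRUTH, n=40, seed=4,
            water_values=np.arange(100, 650, 50))
        m = iterative_fit(records, conv_tol=0.01)
        assert m.method == "iterative"
        assert m.iterations >= 1
        assert m.v0 == pytest.approx(2.587, abs=0.01)
        assert m.k_age == pytest.approx(-0.040, abs=0.01)
        assert m.k_wat == pytest.approx(0.007, abs=0.01)
        assert m.k_bmi == 0.0

    def test_continuous_water_uses_binning_fallback(self):
        records = make_noiseless_records(ITERATIVE_TRUTH, n=60, seed=5)
        m = iterative_fit(records)
        assert m.v0 == pytest.approx(2.587, abs=0.05)
        assert m.k_age == pytest.approx(-0.040, abs=0.005)

    def test_equal_ages_unidentifiable(self):
        records = make_noiseless_records(ITERATIVE_TRUTH, n=10, seed=6,
                                         water_values=[200, 300, 400])
        for r in records:
            r.age = 60.0
        with pytest.raises(DegenerateDesignError):
            iterative_fit(records)

    def test_invariant_to_record_order_and_id_relabeling(self):
        records = make_noiseless_records(
            ITERATIVE_TRUTH, n=30, seed=7, water_values=np.arange(100, 650, 50))
        rng = np.random.default_rng(0)
        for r in records:
            r.vtot_hat += rng.normal(0, 0.2)
        m1 = iterative_fit(records)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        for j, r in enumerate(shuffled):
            r.patient_id = f"Q{j + 100}"
        m2 = iterative_fit(shuffled)
        assert m2.v0 == pytest.approx(m1.v0, rel=1e-12)
        assert m2.k_age == pytest.approx(m1.k_age, rel=1e-12)
        assert m2.k_wat == pytest.approx(m1.k_wat, rel=1e-12)

    def test_agrees_with_regression_within_combined_se_on_noisy_cohorts(self):
        """The alternating fit and the two-covariate regression give
        compatible coefficients on the same noisy cohorts, and a paired
        t-test of their per-patient predictions is non-significant — the two
        parameterizations are statistically interchangeable."""
        nonsig = 0
        reps = 10
        for i in range(reps):
            m_iter, records = simulate_and_fit(
                ITERATIVE_TRUTH, "iterative", seed=5000 + i, n_patients=100,
                water_round_ml=50.0)
            m_reg = InflowRateModel(records).fit_regression()
            for name in ("v0", "k_age", "k_wat"):
                diff = abs(getattr(m_iter, name) - getattr(m_reg, name))
                combined = np.hypot(m_iter.se[name], m_reg.se[name])
                assert diff < combined
            pred_i = [m_iter.predict(r.age, r.water, warn_extrapolation=False)
                      for r in records]
            pred_r = [m_reg.predict(r.age, r.water, warn_extrapolation=False)
                      for r in records]
            _, _, p = paired_ttest(pred_i, pred_r)
            nonsig += p > 0.05
        assert nonsig >= 9


class TestPrediction:
    def _model(self, truth, method="regression2"):
        return InflowModel(method=method, v0=truth[0], k_age=truth[1],
                           k_wat=truth[2], k_bmi=0.0)

    def test_regression_model_prediction_arithmetic(self):
        m = self._model(REGRESSION_TRUTH)
        assert m.predict(55, 300) == pytest.approx(2.630, abs=1e-9)

    def test_constant_model(self):
        m = InflowModel(method="regression2", v0=1.0, k_age=0.0, k_wat=0.0, k_bmi=0.0)
        assert m.predict(70, 60) == 1.0

    def test_physiological_floor_engages(self):
        """An old patient drinking little under the alternating-fit model
        has a raw prediction of 0.007 ml/min, clamped to the 0.05 floor."""
        m = self._model(ITERATIVE_TRUTH, method="iterative")
        assert predict_vtot(m, 75, 60) == pytest.approx(0.05)

    def test_extrapolation_warns_when_ranges_known(self):
        m = self._model(REGRESSION_TRUTH)
        m.train_ranges = {"age": (40, 75), "water": (60, 600), "bmi": (17.6, 28.2)}
        with pytest.warns(UserWarning, match="age"):
            m.predict(95, 300)

    def test_model_json_roundtrip(self, tmp_path):
        records = make_noiseless_records(REGRESSION_TRUTH, n=20, seed=8)
        m = fit_regression(records)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = InflowModel.from_json(path)
        assert back.to_dict() == m.to_dict()


class TestStatistics:
    def test_pearson_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x + 7)[0] == pytest.approx(-1.0)
        with pytest.raises(DegenerateDesignError):
            pearson_r(x, np.ones(4))

    def test_correlation_signs_on_synthetic_cohort(self):
        """Estimated rates correlate positively with water intake and
        negatively with age, matching the directions seen clinically."""
        _, records = simulate_and_fit(REGRESSION_TRUTH, "regression2", seed=77)
        vtot = [r.vtot_hat for r in records]
        r_wat, p_wat = pearson_r([r.water for r in records], vtot)
        r_age, p_age = pearson_r([r.age for r in records], vtot)
        assert r_wat > 0.3 and p_wat < 0.01
        assert r_age < -0.1 and p_age < 0.05

    def test_paired_ttest_identical_series(self):
        t, df, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_paired_ttest_matches_closed_form(self):
        """Hand-computed 4-element fixture: d = [1, 2, 3, 2], mean 2,
        sd sqrt(2/3), t = 2 / (sqrt(2/3)/2) = 4.898979..."""
        a = [5.0, 7.0, 9.0, 8.0]
        b = [4.0, 5.0, 6.0, 6.0]
        t, df, p = paired_ttest(a, b)
        assert df == 3
        assert t == pytest.approx(2.0 / (np.sqrt(2.0 / 3.0) / 2.0), rel=1e-12)

    def test_paired_ttest_type_one_error_calibration(self, rng):
        """Under the null the rejection rate at alpha = 0.05 is about 5%."""
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 1, size=15)
            b = rng.normal(0, 1, size=15)
            rejections += paired_ttest(a, b)[2] < 0.05
        rate = rejections / reps
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_degenerate_paired_differences_raise(self):
        with pytest.raises(DegenerateDesignError):
            paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


def test_recovery_bias_below_ten_percent_at_n200():
    """Parameter recovery: at n = 200 and default noise both estimators
    recover each generating coefficient with bias under 10% of its
    magnitude, averaged over seeds."""
    from uroflow.experiments import recovery_experiment
    for truth, method, round_ml in (
            (REGRESSION_TRUTH, "regression2", None),
            (ITERATIVE_TRUTH, "iterative", 50.0)):
        res = recovery_experiment(truth, method, master_seed=3, n_seeds=8,
                                  water_round_ml=round_ml)
        assert abs(res["v0"] - truth[0]) < 0.1 * abs(truth[0])
        assert abs(res["k_age"] - truth[1]) < 0.1 * abs(truth[1])
        assert abs(res["k_wat"] - truth[2]) < 0.1 * abs(truth[2])
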