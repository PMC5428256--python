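"""Inflow-rate estimation: WLS fits, chi-square probabilities, residual stats."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from uroflow import (
    BVTrajectory,
    CohortConfig,
    InputError,
    InsufficientDataError,
    chi2_survival,
    deviation_stats,
    fit_inflow_plain,
    fit_inflow_tu,
    generate_cohort,
    relative_volume,
    simulate_trajectory,
)
from uroflow.exceptions import DegenerateDesignError

from conftest import make_line_trajectory


class TestRelativeVolume:
    def test_arithmetic(self):
        traj = BVTrajectory.from_arrays("P1", [0, 10, 20], [100, 120, 140])
        out = relative_volume(traj)
        assert np.allclose(out["dv_ml"], [0, 20, 40])
        assert np.allclose(out["rel_dv"], [0, 0.2, 0.4])

    def test_constant_volumes_give_zero_dv(self):
        traj = BVTrajectory.from_arrays("P1", [0, 5, 10], [80, 80, 80])
        assert np.allclose(relative_volume(traj)["dv_ml"], 0)

    def test_zero_reference_returns_dv_with_nan_ratio(self):
        traj = BVTrajectory.from_arrays("P1", [0, 10], [0, 30])
        with pytest.warns(UserWarning):
            out = relative_volume(traj)
        assert np.allclose(out["dv_ml"], [0, 30])
        assert out["rel_dv"].isna().all()

    def test_noiseless_generator_output_is_linear_in_t(self, noiseless_config, rng):
        cohort = generate_cohort(noiseless_config)
        traj = simulate_trajectory(cohort[0], [10, 20, 30, 40], noiseless_config, rng)
        rel = relative_volume(traj)["rel_dv"].to_numpy()
        assert np.allclose(np.diff(rel, 2), 0, atol=1e-12)


class TestPlainFit:
    def test_exact_line_recovered_with_zero_chi2(self):
        fit = fit_inflow_plain(make_line_trajectory(intercept=5, slope=2, sigma_v=3.0))
        assert fit.vtot == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-10)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)
        assert fit.prob == pytest.approx(1.0)
        assert fit.ndf == fit.n_points - 2

    def test_matches_independent_wls_oracle(self, rng):
        """Slope/SE/chi2 agree with statsmodels WLS (unscaled covariance)
        on a noisy 5-point fixture to 1e-9 relative."""
        t = np.array([0.0, 11.0, 19.0, 31.0, 42.0])
        v = np.array([21.0, 55.3, 80.1, 118.9, 150.2])
        sigma = np.array([2.0, 3.1, 4.0, 5.5, 7.0])
        traj = BVTrajectory.from_arrays("P1", t, v, sigma)
        fit = fit_inflow_plain(traj)
        X = sm.add_constant(t)
        res = sm.WLS(v, X, weights=1.0 / sigma**2).fit()
        se = np.sqrt(np.diag(res.normalized_cov_params))
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-9)
        assert fit.vtot == pytest.approx(res.params[1], rel=1e-9)
        assert fit.vtot_se == pytest.approx(se[1], rel=1e-9)
        chi2 = float((((v - res.fittedvalues) / sigma) ** 2).sum())
        assert fit.chi2 == pytest.approx(chi2, rel=1e-9)

    def test_result_invariant_under_point_relabeling(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        v = np.array([12.0, 35.0, 52.0, 78.0])
        s = np.array([1.0, 2.0, 1.5, 2.5])
        base = fit_inflow_plain(BVTrajectory.from_arrays("P1", t, v, s))
        perm = [2, 0, 3, 1]
        order = np.argsort(t[perm])
        shuffled = fit_inflow_plain(BVTrajectory.from_arrays(
            "P1", t[perm][order], v[perm][order], s[perm][order]))
        assert shuffled.vtot == pytest.approx(base.vtot, rel=1e-12)
        assert shuffled.chi2 == pytest.approx(base.chi2, rel=1e-12)

    def test_too_few_points_and_degenerate_design_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_inflow_plain(BVTrajectory.from_arrays("P1", [0, 10], [0, 20]))
        with pytest.raises((InputError, DegenerateDesignError)):
            fit_inflow_plain(BVTrajectory.from_arrays("P1", [5, 5, 5], [1, 2, 3]))


class TestTimeUncertaintyFit:
    def test_zero_sigma_t_reduces_to_plain_fit(self):
        traj = make_line_trajectory(sigma_v=2.0, sigma_t=0.0)
        plain = fit_inflow_plain(traj)
        tu = fit_inflow_tu(traj)
        assert tu.vtot == plain.vtot
        assert tu.vtot_se == plain.vtot_se
        assert tu.method == "time_uncertainty"

    def test_time_uncertainty_enlarges_the_slope_se(self, rng):
        """Property over random fixtures: sigma_t > 0 never shrinks the SE."""
        for _ in range(20):
            t = np.sort(rng.uniform(0, 60, size=7))
            t += np.arange(7) * 1e-3
            slope = rng.uniform(0.5, 5.0)
            v = 20 + slope * t + rng.normal(0, 3, size=7)
            v = np.maximum(v, 0.0)
            sv = np.full(7, 3.0)
            plain = fit_inflow_plain(BVTrajectory.from_arrays("P", t, v, sv))
            tu = fit_inflow_tu(BVTrajectory.from_arrays(
                "P", t, v, sv, np.full(7, 2.18)))
            assert tu.vtot_se >= plain.vtot_se - 1e-12

    def test_both_methods_agree_within_one_combined_se(self, rng):
        """On data like a typical hour-long session (7 scans, 10-min spacing,
        up to 2.18-min timing uncertainty) the two fits give compatible
        slopes — the motivation for using the plain fit in practice."""
        cfg = CohortConfig(noise_cv=0.05, time_jitter_max=2.18, seed=6)
        cohort = generate_cohort(cfg.replace(n_patients=20))
        n_agree = 0
        for p in cohort:
            traj = simulate_trajectory(p, np.arange(0.0, 70.0, 10.0), cfg, rng)
            plain = fit_inflow_plain(traj)
            tu = fit_inflow_tu(traj)
            combined = np.hypot(plain.vtot_se, tu.vtot_se)
            n_agree += abs(plain.vtot - tu.vtot) <= combined
        assert n_agree >= 18


class TestChi2Survival:
    @pytest.mark.parametrize("chi2,ndf,expected", [
        (5.647, 11, 0.896),
        (4.145, 10, 0.940),
        (8.873, 16, 0.918),
    ])
    def test_reported_fit_probabilities(self, chi2, ndf, expected):
        assert chi2_survival(chi2, ndf) == pytest.approx(expected, abs=1e-3)

    def test_whole_support_at_zero(self):
        for ndf in (1, 2, 5, 16):
            assert chi2_survival(0.0, ndf) == 1.0

    @given(st.floats(min_value=0.01, max_value=30.0))
    @settings(max_examples=30, deadline=None)
    def test_two_dof_closed_form(self, x):
        """For 2 degrees of freedom the survival function is exp(-x/2)."""
        assert chi2_survival(x, 2) == pytest.approx(np.exp(-x / 2), rel=1e-9)

    def test_monotone_decreasing_in_chi2(self):
        grid = np.linspace(0, 40, 100)
        vals = [chi2_survival(x, 9) for x in grid]
        assert np.all(np.diff(vals) <= 0)

    def test_domain_errors(self):
        with pytest.raises(InputError):
            chi2_survival(1.0, 0)
        with pytest.raises(InputError):
            chi2_survival(-1.0, 3)


class TestDeviationStats:
    def test_noiseless_line_has_zero_residuals(self):
        traj = make_line_trajectory(times=tuple(range(0, 60, 5)), sigma_v=1.0)
        mean, sd, prob = deviation_stats(traj)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(prob)

    def test_gaussian_residuals_give_spread_out_probabilities(self, rng):
        """Null calibration: with Gaussian noise the GOF probability is
        spread over [0, 1] rather than collapsing near 0."""
        probs = []
        for _ in range(300):
            t = np.arange(0.0, 100.0, 2.0)
            v = 100 + 3 * t + rng.normal(0, 5, size=t.size)
            traj = BVTrajectory.from_arrays("P", t, np.maximum(v, 0),
                                            np.full(t.size, 5.0))
            probs.append(deviation_stats(traj)[2])
        probs = np.asarray(probs)
        assert 0.2 < np.median(probs) < 0.85
        assert (probs < 0.1).mean() < 0.35

    def test_heavy_tails_lower_the_gof_probability(self, rng):
        """Power check: t(1)-distributed residuals score lower than Gaussian."""
        def median_prob(heavy):
            out = []
            for _ in range(150):
                t = np.arange(0.0, 100.0, 2.0)
                noise = (rng.standard_cauchy(t.size) * 2.0 if heavy
                         else rng.normal(0, 5, size=t.size))
                v = np.maximum(200 + 3 * t + noise, 0.0)
                traj = BVTrajectory.from_arrays("P", t, v, np.full(t.size, 5.0))
                out.append(deviation_stats(traj)[2])
            return np.median(out)
        assert median_prob(True) < median_prob(False)

    def test_requires_four_points(self):
        with pytest.raises(InsufficientDataError):
            deviation_stats(make_line_trajectory(times=(0, 10, 20)))
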