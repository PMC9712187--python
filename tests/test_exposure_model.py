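"""Intake distributions, moment matching and counterfactual transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from upfburden import (
    ExposureDistribution,
    Scenario,
    Stratum,
    apply_scenario,
    fit_exposure,
    quintile_cutpoint,
)


class TestFitExposure:
    def test_moment_matching_parameters(self):
        # national-level mean and SD of the UPF energy share
        dist = fit_exposure(19.4, 8.7)
        s2 = np.log(1 + (8.7 / 19.4) ** 2)
        assert dist.sigma_ln == pytest.approx(np.sqrt(s2), abs=1e-4)
        assert dist.mu_ln == pytest.approx(np.log(19.4) - s2 / 2, abs=1e-4)
        # truncation at a 100% energy share perturbs the moments by ~1e-4
        mean, sd = dist.numeric_moments()
        assert mean == pytest.approx(19.4, rel=1e-3)
        assert sd == pytest.approx(8.7, rel=5e-3)

    def test_zero_sd_degenerates_to_point_mass(self):
        dist = fit_exposure(19.4, 0.0)
        assert dist.family == "point_mass"
        assert dist.location == 19.4

    @given(
        mean=st.floats(1.0, 40.0),
        cv=st.floats(0.05, 1.0),
    )
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_normalization_and_truncated_moments(self, mean, cv):
        """The truncated density integrates to one and its quadrature
        moments match the analytic truncated-log-normal moments."""
        dist = fit_exposure(mean, cv * mean)
        grid = np.linspace(0, 100, 100_001)
        mass = np.trapezoid(dist.pdf(grid), grid)
        assert mass == pytest.approx(1.0, abs=1e-6)
        m, s = dist.numeric_moments()
        mu, sg = dist.mu_ln, dist.sigma_ln
        z = (np.log(100.0) - mu) / sg
        norm = stats.norm.cdf(z)
        m1 = np.exp(mu + sg**2 / 2) * stats.norm.cdf(z - sg) / norm
        m2 = np.exp(2 * mu + 2 * sg**2) * stats.norm.cdf(z - 2 * sg) / norm
        assert m == pytest.approx(m1, rel=1e-4)
        assert s == pytest.approx(np.sqrt(m2 - m1**2), rel=1e-3)

    def test_round_trip_at_survey_scale(self):
        """For realistic intake parameters the fitted distribution's
        moments reproduce the inputs to well within 0.1%."""
        dist = fit_exposure(19.4, 8.7)
        m, s = dist.numeric_moments()
        assert m == pytest.approx(19.4, rel=1e-3)
        assert s == pytest.approx(8.7, rel=5e-3)

    @pytest.mark.parametrize("mean", [0.0, -3.0, 100.0, 150.0])
    def test_out_of_range_mean_rejected(self, mean):
        with pytest.raises(ValueError):
            fit_exposure(mean, 1.0)


class TestScenarios:
    def test_point_mass_proportional_scaling(self):
        dist = fit_exposure(20.0, 0.0)
        out = apply_scenario(dist, Scenario.proportional(0.1))
        assert out.family == "point_mass"
        assert out.location == pytest.approx(18.0)

    def test_zero_reduction_is_identity(self):
        dist = fit_exposure(17.0, 7.0)
        out = apply_scenario(dist, Scenario.proportional(0.0))
        assert out == dist

    def test_proportional_reduction_preserves_cv(self):
        dist = fit_exposure(17.0, 7.0)
        out = apply_scenario(dist, Scenario.proportional(0.3))
        # exact on the parent: scale shifts mu_ln, leaves sigma_ln alone
        assert out.sd_pct / out.mean_pct == pytest.approx(dist.sd_pct / dist.mean_pct, rel=1e-12)
        assert out.sigma_ln == dist.sigma_ln
        # and numerically, up to truncation at 100 (tiny at these sizes)
        m0, s0 = dist.numeric_moments()
        m1, s1 = out.numeric_moments()
        assert m1 == pytest.approx(0.7 * m0, rel=1e-4)
        assert s1 / m1 == pytest.approx(s0 / m0, rel=5e-4)

    def test_full_elimination_collapses_to_zero_intake(self):
        out = apply_scenario(fit_exposure(17.0, 7.0), Scenario.proportional(1.0))
        assert out.family == "point_mass"
        assert out.location == 0.0

    def test_first_quintile_truncates_and_renormalizes(self):
        dist = fit_exposure(19.4, 8.7)
        out = apply_scenario(dist, Scenario.first_quintile())
        cut = quintile_cutpoint(dist, 0.2)
        assert out.upper == pytest.approx(cut)
        grid = np.linspace(0, cut, 200_001)
        assert np.trapezoid(out.pdf(grid), grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(out.pdf(np.array([cut + 0.01, 50.0])) == 0.0)

    def test_first_quintile_is_stochastically_dominated(self):
        dist = fit_exposure(19.4, 8.7)
        out = apply_scenario(dist, Scenario.first_quintile())
        x = np.linspace(0.1, 99.0, 500)
        assert np.all(out.cdf(x) >= dist.cdf(x) - 1e-12)

    def test_point_mass_q1_mean_mode(self):
        dist = fit_exposure(19.4, 8.7)
        out = apply_scenario(dist, Scenario.first_quintile(), mode="point_mass_q1_mean")
        assert out.family == "point_mass"
        # bottom-quintile mean lies below the quintile cutpoint
        assert 0 < out.location < quintile_cutpoint(dist, 0.2)

    @pytest.mark.parametrize("r", [-0.1, 1.5])
    def test_invalid_reduction_rejected(self, r):
        with pytest.raises(ValueError):
            Scenario.proportional(r)

    @pytest.mark.parametrize(
        "text,kind,r",
        [
            ("baseline", "baseline", None),
            ("proportional:0.10", "proportional_reduction", 0.1),
            ("quintile:1", "first_quintile", None),
        ],
    )
    def test_cli_scenario_parsing(self, text, kind, r):
        sc = Scenario.parse(text)
        assert sc.kind == kind
        assert sc.reduction_fraction == r


class TestQuintileCutpoint:
    def test_point_mass_returns_location(self):
        assert quintile_cutpoint(fit_exposure(19.4, 0.0), 0.2) == 19.4

    def test_lognormal_quantile_formula(self):
        dist = fit_exposure(19.4, 8.7)
        expected = np.exp(dist.mu_ln + stats.norm.ppf(0.2) * dist.sigma_ln)
        # truncation at 100 leaves the 20th percentile essentially untouched
        assert quintile_cutpoint(dist, 0.2) == pytest.approx(expected, rel=1e-4)
        # exp(2.8737 - 0.8416 * 0.4281) = 12.35 to three figures
        assert quintile_cutpoint(dist, 0.2) == pytest.approx(12.346, abs=0.01)

    def test_mass_below_cutpoint_is_q(self):
        dist = fit_exposure(15.0, 6.0)
        cut = quintile_cutpoint(dist, 0.2)
        grid = np.linspace(0, cut, 200_001)
        assert np.trapezoid(dist.pdf(grid), grid) == pytest.approx(0.2, abs=1e-6)


class TestStratum:
    def test_age_restriction(self):
        with pytest.raises(ValueError, match="30-69"):
            Stratum("male", "25-29", 1000)

    def test_valid_stratum(self):
        s = Stratum("female", "65-69", 1e6)
        assert s.label == "female 65-69"
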