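"""Monte Carlo propagation and deterministic sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from upfburden import (
    DEFAULT_RR_SPECS,
    DEFAULT_SCENARIOS,
    EventTable,
    MonteCarloConfig,
    SensitivityScenario,
    StudyInputs,
    oracle_pif,
    run_deterministic,
    run_monte_carlo,
    run_sensitivity,
    summarize,
)
from upfburden.pipeline import ATTRIBUTABLE_LABEL


def _single_stratum_inputs(sd_pct=0.0):
    exposure = pd.DataFrame(
        [
            {
                "sex": "male",
                "age_group": "50-54",
                "mean_pct": 19.4,
                "sd_pct": sd_pct,
                "se_mean_pct": 0.5,
                "population": 1_000_000,
            }
        ]
    )
    events = EventTable(
        pd.DataFrame(
            [
                {
                    "sex": "male",
                    "age_group": "50-54",
                    "outcome": "chd",
                    "metric": "deaths",
                    "value": 1000.0,
                    "ui_low": 700.0,
                    "ui_high": 1300.0,
                }
            ]
        )
    )
    return StudyInputs(exposure, events, {"chd": DEFAULT_RR_SPECS["chd"]})


class TestMonteCarlo:
    def test_flags_off_reproduces_deterministic_run(self, study):
        config = MonteCarloConfig(
            n_draws=3, seed=1, perturb_rr=False, perturb_events=False, perturb_intake=False
        )
        mc = run_monte_carlo(study.inputs, DEFAULT_SCENARIOS, config)
        det = summarize(run_deterministic(study.inputs, DEFAULT_SCENARIOS))
        det = det.set_index(["scenario", "metric", "outcome", "sex"])["events"]
        got = mc.summary.set_index(["scenario", "metric", "outcome", "sex"])
        np.testing.assert_allclose(got["median"], det.loc[got.index], rtol=1e-12)
        assert (got["ui_high"] - got["ui_low"]).abs().max() == 0.0

    def test_same_seed_bitwise_identical(self, study):
        config = MonteCarloConfig(n_draws=40, seed=99)
        a = run_monte_carlo(study.inputs, DEFAULT_SCENARIOS[:1], config)
        b = run_monte_carlo(study.inputs, DEFAULT_SCENARIOS[:1], config)
        assert np.array_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_ui_ordering_and_coverage_of_point_estimate(self, study):
        config = MonteCarloConfig(n_draws=200, seed=3)
        mc = run_monte_carlo(study.inputs, DEFAULT_SCENARIOS[:1], config)
        s = mc.summary
        assert ((s.ui_low <= s["median"]) & (s["median"] <= s.ui_high)).all()
        det = summarize(run_deterministic(study.inputs, DEFAULT_SCENARIOS[:1]))
        det = det.set_index(["scenario", "metric", "outcome", "sex"])["events"]
        joined = s.set_index(["scenario", "metric", "outcome", "sex"]).join(
            det.rename("det")
        )
        inside = (joined.ui_low <= joined.det) & (joined.det <= joined.ui_high)
        assert inside.all()

    def test_missing_se_column_rejected(self, study):
        inputs = StudyInputs(
            study.inputs.exposure.drop(columns="se_mean_pct"),
            study.inputs.events,
            study.inputs.rr_specs,
        )
        with pytest.raises(ValueError, match="se_mean_pct"):
            run_monte_carlo(inputs, (), MonteCarloConfig(n_draws=2, seed=0))

    def test_event_quantiles_converge_to_analytic_truncnorm(self):
        """With only event counts perturbed on a point-mass stratum, the
        output is PIF x (truncated-normal draw), so the empirical UI must
        converge to the analytic quantiles."""
        inputs = _single_stratum_inputs()
        config = MonteCarloConfig(
            n_draws=50_000, seed=12, perturb_rr=False, perturb_intake=False
        )
        mc = run_monte_carlo(inputs, (), config)
        row = mc.summary[
            (mc.summary.scenario == ATTRIBUTABLE_LABEL)
            & (mc.summary.outcome == "chd")
            & (mc.summary.sex == "male")
        ].iloc[0]
        pif = oracle_pif(DEFAULT_RR_SPECS["chd"], 19.4, 0.0, None)
        sd = (1300.0 - 700.0) / (2 * 1.959963984540054)
        a = (0.0 - 1000.0) / sd
        analytic = {
            q: pif * stats.truncnorm.ppf(q, a, np.inf, loc=1000.0, scale=sd)
            for q in (0.025, 0.5, 0.975)
        }
        tol = 0.05 * pif * sd  # a few quantile standard errors
        assert abs(row.ui_low - analytic[0.025]) < tol
        assert abs(row["median"] - analytic[0.5]) < tol
        assert abs(row.ui_high - analytic[0.975]) < tol


class TestSensitivity:
    def test_null_perturbation_warns_and_changes_nothing(self, study):
        null = SensitivityScenario("rr_same", rr_multiplier=1.0)
        with pytest.warns(UserWarning, match="does not alter"):
            table = run_sensitivity(study.inputs, [null])
        assert np.allclose(table["pct_change"], 0.0, atol=1e-9)

    def test_higher_rr_increases_attributable_events(self, study):
        table = run_sensitivity(
            study.inputs, [SensitivityScenario("rr_up", rr_multiplier=1.1)]
        )
        assert (table["pct_change"] > 0).all()
        table_dn = run_sensitivity(
            study.inputs, [SensitivityScenario("rr_dn", rr_multiplier=0.9)]
        )
        assert (table_dn["pct_change"] < 0).all()

    def test_tmrel_shift_agrees_with_oracle_recomputation(self, study):
        """Raising the TMREL to 12% re-anchors the curve; the pipeline's
        percentage change must match an independent oracle recomputation
        of both totals."""
        table = run_sensitivity(
            study.inputs,
            [SensitivityScenario("tmrel_12", x_tmrel=12.0, x_tmrel_sd=5.0)],
        )
        exposure = study.inputs.exposure.set_index(["sex", "age_group"])
        ev = study.inputs.events.frame
        base_total = alt_total = 0.0
        for row in ev[ev.metric == "deaths"].itertuples(index=False):
            mean = exposure.loc[(row.sex, row.age_group), "mean_pct"]
            sd = exposure.loc[(row.sex, row.age_group), "sd_pct"]
            spec = study.inputs.rr_specs[row.outcome]
            base_total += oracle_pif(spec, mean, sd, None) * row.value
            alt_total += (
                oracle_pif(spec.with_anchors(x_tmrel=12.0), mean, sd, None) * row.value
            )
        expected = 100.0 * (alt_total - base_total) / base_total
        got = table.loc[table.metric == "deaths", "pct_change"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-3, abs=1e-4)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            SensitivityScenario("both", x_tmrel=10.0, rr_multiplier=1.1)
        with pytest.raises(ValueError):
            SensitivityScenario("neither")
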