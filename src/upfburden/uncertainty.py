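"""Monte Carlo uncertainty propagation and deterministic sensitivity runs.

Uncertainty in four input groups — the pooled RRs, the stratified event
counts, and the stratum mean intakes (prevalence/incidence uncertainty
enters this model only through the event counts) — is propagated by
recomputing the full pipeline for each of ``n_draws`` joint input draws
and reporting the per-cell median and 2.5th/97.5th percentiles.  Draws
are synchronised across strata within an iteration: one RR draw per
outcome is applied to every stratum, matching the shared meta-analytic
parameter.

Sampling families: RR ~ log-normal matched to the 95% CI; event counts ~
normal matched to the 95% UI (SD = width / 3.92), truncated at zero;
intake means ~ normal with the supplied standard error, truncated to
(0, 100).  Everything is driven by one seeded generator, so output is a
pure function of (inputs, seed, n_draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .burden import METRICS
from .dose_response import Outcome, sample_rr
from .exposure_model import SEXES, Scenario
from .pif_engine import DEFAULT_GRID_STEP, DEFAULT_UPPER_LIMIT
from .pipeline import (
    ATTRIBUTABLE_LABEL,
    StudyInputs,
    _baseline_distributions,
    _pif_table,
    run_deterministic,
)

__all__ = [
    "MonteCarloConfig",
    "MonteCarloResult",
    "SensitivityScenario",
    "DEFAULT_SENSITIVITY_SCENARIOS",
    "run_monte_carlo",
    "run_sensitivity",
]

_Z95_SPAN = 2.0 * 1.959963984540054


@dataclass(frozen=True)
class MonteCarloConfig:
    """Monte Carlo settings: draw count, seed, and which inputs to perturb.

    ``perturb_prevalence`` is accepted for completeness; in this model
    prevalence/incidence uncertainty is carried by the event-count
    intervals, so the flag is an alias folded into ``perturb_events``.
    """

    n_draws: int = 5000
    seed: int = 0
    perturb_rr: bool = True
    perturb_events: bool = True
    perturb_intake: bool = True
    perturb_prevalence: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")


@dataclass
class MonteCarloResult:
    """Summary table plus raw per-group draws (groups x draws)."""

    summary: pd.DataFrame
    groups: pd.DataFrame
    draws: np.ndarray


def _group_matrix(events: pd.DataFrame, labels: Sequence[str]):
    """Indicator matrix mapping event rows to every reported aggregate:
    (scenario, metric, outcome-or-cvd, sex-or-total)."""
    rows = []
    masks = []
    for label in labels:
        for metric in METRICS:
            base = (events.metric == metric).to_numpy()
            if not base.any():
                continue
            for outcome in (*Outcome.ALL, "cvd"):
                mo = base if outcome == "cvd" else base & (events.outcome == outcome).to_numpy()
                for sex in (*SEXES, "total"):
                    ms = mo if sex == "total" else mo & (events.sex == sex).to_numpy()
                    rows.append(
                        {"scenario": label, "metric": metric, "outcome": outcome, "sex": sex}
                    )
                    masks.append(ms.astype(float))
    return pd.DataFrame(rows), np.vstack(masks)


def _truncated_normal_draws(
    rng: np.random.Generator,
    loc: np.ndarray,
    scale: np.ndarray,
    lower: float,
    upper: float,
    n_draws: int,
) -> np.ndarray:
    """(n_draws, len(loc)) truncated-normal draws; zero scale is degenerate."""
    loc = np.asarray(loc, float)
    scale = np.asarray(scale, float)
    safe = np.where(scale > 0, scale, 1.0)
    a = (lower - loc) / safe
    b = (upper - loc) / safe if np.isfinite(upper) else np.full_like(loc, np.inf)
    draws = stats.truncnorm.rvs(
        a, b, loc=loc, scale=safe, size=(n_draws, len(loc)), random_state=rng
    )
    return np.where(scale > 0, draws, loc)


def run_monte_carlo(
    inputs: StudyInputs,
    scenarios: Sequence[Scenario] = (),
    config: MonteCarloConfig = MonteCarloConfig(),
    grid_step: float = DEFAULT_GRID_STEP,
    m: float = DEFAULT_UPPER_LIMIT,
    quintile_mode: str = "truncate",
) -> MonteCarloResult:
    """Propagate input uncertainty through the full pipeline.

    Each iteration draws one RR per outcome, one count per event row and
    one mean per stratum (subject to the perturbation flags), recomputes
    every PIF and aggregate, and the summary reports the median and 95%
    uncertainty interval of each aggregate across iterations.
    """
    events = inputs.events.frame
    values = events["value"].to_numpy(float)
    n = config.n_draws
    rng = np.random.default_rng(config.seed)

    outcomes = sorted(inputs.rr_specs)
    labels = [ATTRIBUTABLE_LABEL] + [sc.label for sc in scenarios]

    # --- pre-draw all randomness in a fixed order -------------------
    rr_draws = None
    if config.perturb_rr:
        rr_draws = {
            o: np.asarray(sample_rr(inputs.rr_specs[o], rng, size=n))
            for o in outcomes
        }
    event_draws = None
    if config.perturb_events or config.perturb_prevalence:
        sd = (events["ui_high"].to_numpy(float) - events["ui_low"].to_numpy(float)) / _Z95_SPAN
        if np.isnan(sd).any():
            raise ValueError("event perturbation requires ui_low/ui_high on every row")
        event_draws = _truncated_normal_draws(rng, values, sd, 0.0, np.inf, n)
    intake_draws = None
    strata = inputs.strata()
    if config.perturb_intake:
        if "se_mean_pct" not in inputs.exposure.columns:
            raise ValueError("intake perturbation requires an se_mean_pct column")
        se = inputs.exposure["se_mean_pct"].to_numpy(float)
        if np.isnan(se).any():
            raise ValueError("intake perturbation requires se_mean_pct on every row")
        means = inputs.exposure["mean_pct"].to_numpy(float)
        intake_draws = _truncated_normal_draws(rng, means, se, 0.0, 100.0, n)

    groups, G = _group_matrix(events, labels)
    row_keys = [
        (r.sex, r.age_group, r.outcome) for r in events.itertuples(index=False)
    ]

    draws_out = np.empty((len(groups), n))
    for d in range(n):
        intake_overrides = (
            dict(zip(strata, intake_draws[d])) if intake_draws is not None else None
        )
        rr_overrides = (
            {o: float(rr_draws[o][d]) for o in outcomes} if rr_draws is not None else None
        )
        dists = _baseline_distributions(inputs.exposure, intake_overrides)
        pifs = _pif_table(
            dists, inputs.rr_specs, scenarios, grid_step, m, quintile_mode, rr_overrides
        )
        vals = event_draws[d] if event_draws is not None else values
        cell = np.empty((len(labels), len(events)))
        for li, label in enumerate(labels):
            cell[li] = np.array([pifs[(*k, label)] for k in row_keys]) * vals
        draws_out[:, d] = _group_sums(G, cell, len(labels))

    med, lo, hi = np.percentile(draws_out, [50.0, 2.5, 97.5], axis=1)
    summary = groups.copy()
    summary["median"] = med
    summary["ui_low"] = lo
    summary["ui_high"] = hi
    return MonteCarloResult(summary=summary, groups=groups, draws=draws_out)


def _group_sums(G: np.ndarray, cell: np.ndarray, n_labels: int) -> np.ndarray:
    """Apply the per-label blocks of the indicator matrix to the per-label
    attributable-event rows."""
    block = len(G) // n_labels
    out = np.empty(len(G))
    for li in range(n_labels):
        out[li * block : (li + 1) * block] = G[li * block : (li + 1) * block] @ cell[li]
    return out


# ---------------------------------------------------------------------
# deterministic sensitivity analyses
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityScenario:
    """One deterministic perturbation of the model's RR parametrization.

    Exactly one family per scenario: either alternative curve anchors
    (``x_tmrel`` and/or ``x_ref``, with their survey SDs carried as
    metadata) or a multiplicative shift of the pooled RRs.
    """

    label: str
    x_tmrel: float | None = None
    x_ref: float | None = None
    rr_multiplier: float | None = None
    x_tmrel_sd: float | None = None
    x_ref_sd: float | None = None

    def __post_init__(self) -> None:
        has_anchor = self.x_tmrel is not None or self.x_ref is not None
        has_rr = self.rr_multiplier is not None
        if has_anchor == has_rr:
            raise ValueError(
                "a sensitivity scenario perturbs either the curve anchors "
                "or the RRs, not both and not neither"
            )
        if has_rr and self.rr_multiplier <= 0:
            raise ValueError("rr_multiplier must be positive")


#: The deterministic sensitivity set: alternative TMREL anchors (10.0 +/-
#: 4.1 and 12.0 +/- 5.0 % energy), alternative reference-intake anchors
#: (20.0 +/- 8.2 and 24.0 +/- 10.6 % energy), and +/-10% pooled RRs.
DEFAULT_SENSITIVITY_SCENARIOS: tuple[SensitivityScenario, ...] = (
    SensitivityScenario("tmrel_10pct", x_tmrel=10.0, x_tmrel_sd=4.1),
    SensitivityScenario("tmrel_12pct", x_tmrel=12.0, x_tmrel_sd=5.0),
    SensitivityScenario("ref_20pct", x_ref=20.0, x_ref_sd=8.2),
    SensitivityScenario("ref_24pct", x_ref=24.0, x_ref_sd=10.6),
    SensitivityScenario("rr_minus_10pct", rr_multiplier=0.9),
    SensitivityScenario("rr_plus_10pct", rr_multiplier=1.1),
)


def _total_attributable(inputs: StudyInputs, rr_specs, grid_step, m) -> pd.Series:
    alt = StudyInputs(inputs.exposure, inputs.events, rr_specs)
    cells = run_deterministic(alt, (), grid_step=grid_step, m=m)
    att = cells[cells.scenario == ATTRIBUTABLE_LABEL]
    return att.groupby("metric", sort=False)["attributable"].sum()


def run_sensitivity(
    inputs: StudyInputs,
    scenarios: Sequence[SensitivityScenario] = DEFAULT_SENSITIVITY_SCENARIOS,
    grid_step: float = DEFAULT_GRID_STEP,
    m: float = DEFAULT_UPPER_LIMIT,
) -> pd.DataFrame:
    """Re-run the deterministic pipeline under each alternative assumption.

    Returns one row per scenario x metric with the primary-model total
    attributable CVD events, the alternative total, and the percentage
    change 100 * (alternative - primary) / primary.
    """
    import warnings

    primary = _total_attributable(inputs, inputs.rr_specs, grid_step, m)
    records = []
    for sc in scenarios:
        if sc.rr_multiplier is not None:
            specs = {
                o: s.with_rr(s.rr_ref * sc.rr_multiplier)
                for o, s in inputs.rr_specs.items()
            }
        else:
            specs = {
                o: s.with_anchors(x_tmrel=sc.x_tmrel, x_ref=sc.x_ref)
                for o, s in inputs.rr_specs.items()
            }
        alt = _total_attributable(inputs, specs, grid_step, m)
        for metric in primary.index:
            change = 100.0 * (alt[metric] - primary[metric]) / primary[metric]
            records.append(
                {
                    "label": sc.label,
                    "metric": metric,
                    "primary": primary[metric],
                    "alternative": alt[metric],
                    "pct_change": change,
                }
            )
        if np.allclose(alt.to_numpy(), primary.to_numpy(), rtol=1e-12):
            warnings.warn(
                f"sensitivity scenario {sc.label!r} does not alter the model",
                stacklevel=2,
            )
    return pd.DataFrame(records)
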