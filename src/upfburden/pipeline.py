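"""Deterministic model pipeline: exposures -> PIFs -> stratified burden.

This is the computational core that the command-line interface, the Monte
Carlo uncertainty engine and the analysis drivers all call.  One run:

1. moment-match a log-normal intake distribution per age-sex stratum;
2. build the log-linear RR curve per outcome;
3. compute the PAF (counterfactual at the TMREL) and the PIF of every
   requested counterfactual scenario, per outcome x stratum;
4. multiply PIFs by the stratified baseline events (deaths, incident
   cases, DALYs) to get attributable and averted events per cell.

The PAF cells appear under the reserved scenario label ``"attributable"``.
All overrides (Monte Carlo draws, sensitivity multipliers) enter through
explicit arguments so a run is a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import EventTable
from .dose_response import Outcome, RRSpec, build_rr_curve
from .exposure_model import (
    ExposureDistribution,
    Scenario,
    apply_scenario,
    fit_exposure,
)
from .pif_engine import DEFAULT_GRID_STEP, DEFAULT_UPPER_LIMIT, compute_pif, mean_rr

__all__ = ["StudyInputs", "run_deterministic", "summarize", "ATTRIBUTABLE_LABEL"]

#: reserved scenario label for baseline-attributable (PAF) cells
ATTRIBUTABLE_LABEL = "attributable"

_EXPOSURE_COLUMNS = ["sex", "age_group", "mean_pct", "sd_pct", "population"]


@dataclass
class StudyInputs:
    """Complete input bundle for one model run.

    ``exposure``: DataFrame with columns sex, age_group, mean_pct, sd_pct,
    population and optionally se_mean_pct (standard error of the stratum
    mean, used only by the Monte Carlo engine).
    ``events``: validated :class:`~upfburden.burden.EventTable`.
    ``rr_specs``: one anchored :class:`~upfburden.dose_response.RRSpec`
    per outcome.
    """

    exposure: pd.DataFrame
    events: EventTable
    rr_specs: Mapping[str, RRSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _EXPOSURE_COLUMNS if c not in self.exposure.columns]
        if missing:
            raise ValueError(f"exposure table missing columns {missing}")
        dup = self.exposure.duplicated(subset=["sex", "age_group"])
        if dup.any():
            raise ValueError("duplicate strata in exposure table")
        for outcome in sorted(set(self.events.frame["outcome"])):
            if outcome not in self.rr_specs:
                raise ValueError(f"no RR specification for outcome {outcome!r}")

    def strata(self) -> list[tuple[str, str]]:
        return [
            (r.sex, r.age_group)
            for r in self.exposure.itertuples(index=False)
        ]


def _baseline_distributions(
    exposure: pd.DataFrame,
    intake_overrides: Mapping[tuple[str, str], float] | None = None,
) -> dict[tuple[str, str], ExposureDistribution]:
    dists: dict[tuple[str, str], ExposureDistribution] = {}
    for row in exposure.itertuples(index=False):
        key = (row.sex, row.age_group)
        mean = row.mean_pct
        if intake_overrides and key in intake_overrides:
            mean = intake_overrides[key]
        dists[key] = fit_exposure(mean, row.sd_pct)
    return dists


def _pif_table(
    dists: Mapping[tuple[str, str], ExposureDistribution],
    rr_specs: Mapping[str, RRSpec],
    scenarios: Sequence[Scenario],
    grid_step: float,
    m: float,
    quintile_mode: str,
    rr_overrides: Mapping[str, float] | None = None,
) -> dict[tuple[str, str, str, str], float]:
    """PIF per (sex, age_group, outcome, scenario label), including the
    PAF under the reserved ``attributable`` label."""
    curves = {
        o: build_rr_curve(spec, (rr_overrides or {}).get(o))
        for o, spec in rr_specs.items()
    }
    out: dict[tuple[str, str, str, str], float] = {}
    for key, dist in dists.items():
        counterfactuals = {
            ATTRIBUTABLE_LABEL: None,  # placeholder: PAF per outcome below
        }
        for sc in scenarios:
            counterfactuals[sc.label] = apply_scenario(dist, sc, mode=quintile_mode)
        for outcome, curve in curves.items():
            denom = mean_rr(curve, dist, grid_step, m)
            for label, cf in counterfactuals.items():
                if label == ATTRIBUTABLE_LABEL:
                    cf = ExposureDistribution(
                        curve.spec.x_tmrel, 0.0, "point_mass",
                        location=curve.spec.x_tmrel,
                    )
                numer = mean_rr(curve, cf, grid_step, m)
                if denom <= 0 or not np.isfinite(denom):
                    raise ArithmeticError("non-positive baseline mean RR")
                out[(*key, outcome, label)] = 1.0 - numer / denom
    return out


def run_deterministic(
    inputs: StudyInputs,
    scenarios: Sequence[Scenario] = (),
    grid_step: float = DEFAULT_GRID_STEP,
    m: float = DEFAULT_UPPER_LIMIT,
    quintile_mode: str = "truncate",
    rr_overrides: Mapping[str, float] | None = None,
    intake_overrides: Mapping[tuple[str, str], float] | None = None,
    event_overrides: np.ndarray | None = None,
) -> pd.DataFrame:
    """One deterministic pass of the full model.

    Returns the per-cell table with columns scenario, sex, age_group,
    outcome, metric, baseline_events, pif, attributable — where
    ``attributable`` holds PAF x events for the ``"attributable"`` rows
    and PIF x events (averted events) for counterfactual-scenario rows.
    """
    dists = _baseline_distributions(inputs.exposure, intake_overrides)
    pifs = _pif_table(
        dists, inputs.rr_specs, scenarios, grid_step, m, quintile_mode, rr_overrides
    )
    events = inputs.events.frame
    values = events["value"].to_numpy(dtype=float)
    if event_overrides is not None:
        values = np.asarray(event_overrides, dtype=float)
        if values.shape != (len(events),):
            raise ValueError("event_overrides must align with the event table")

    labels = [ATTRIBUTABLE_LABEL] + [sc.label for sc in scenarios]
    records = []
    for label in labels:
        for i, row in enumerate(events.itertuples(index=False)):
            pif = pifs[(row.sex, row.age_group, row.outcome, label)]
            records.append(
                (
                    label, row.sex, row.age_group, row.outcome, row.metric,
                    values[i], pif, pif * values[i],
                )
            )
    return pd.DataFrame(
        records,
        columns=[
            "scenario", "sex", "age_group", "outcome", "metric",
            "baseline_events", "pif", "attributable",
        ],
    )


def summarize(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell results scenario by scenario (see
    :func:`upfburden.burden.aggregate`)."""
    from .burden import aggregate

    parts = [
        aggregate(cells[cells.scenario == label])
        for label in cells["scenario"].unique()
    ]
    return pd.concat(parts, ignore_index=True)
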