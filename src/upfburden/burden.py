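"""Burden accounting: from PIFs to attributable / averted events.

Baseline deaths, incident cases and DALYs per age-sex stratum and outcome
(GBD-style rows with 95% uncertainty intervals) are multiplied by the
cause-, age- and sex-specific PIF, then summed over age strata within
sex, over sexes, and over the two outcomes to give total-CVD estimates.
Rounding to the nearest hundred (half away from zero) happens only at the
reporting layer, never inside the computation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exposure_model import AGE_GROUPS, SEXES
from .dose_response import Outcome

__all__ = [
    "METRICS",
    "EventTable",
    "attributable_events",
    "aggregate",
    "report_rounding",
    "percent_attributable",
]

METRICS = ("deaths", "incident_cases", "dalys")

_EVENT_COLUMNS = ["sex", "age_group", "outcome", "metric", "value", "ui_low", "ui_high"]


class EventTable:
    """Stratified baseline event counts with 95% uncertainty intervals.

    Wraps a DataFrame with columns sex, age_group, outcome, metric, value,
    ui_low, ui_high.  Validation is strict: rows outside the 30-69 age
    range are rejected (the model covers premature events only), as are
    negative counts or inverted intervals.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        frame = frame[_EVENT_COLUMNS].copy()
        for i, row in frame.iterrows():
            where = f"event row {i} ({row.sex}, {row.age_group}, {row.outcome}, {row.metric})"
            if row.age_group not in AGE_GROUPS:
                raise ValueError(
                    f"{where}: age group outside the modelled 30-69 range"
                )
            if row.sex not in SEXES:
                raise ValueError(f"{where}: unknown sex")
            if row.outcome not in Outcome.ALL:
                raise ValueError(f"{where}: unknown outcome")
            if row.metric not in METRICS:
                raise ValueError(f"{where}: unknown metric")
            if row.value < 0 or row.ui_low < 0:
                raise ValueError(f"{where}: negative event count")
            if not (row.ui_low <= row.value <= row.ui_high):
                raise ValueError(f"{where}: interval does not bracket the value")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def total(self, metric: str) -> float:
        """Total events across strata and outcomes for one metric."""
        f = self.frame
        return float(f.loc[f.metric == metric, "value"].sum())


def attributable_events(pif: float, baseline_events: float) -> float:
    """Events attributable to (or averted from) UPF intake: PIF x events."""
    if baseline_events < 0:
        raise ValueError("baseline events must be non-negative")
    if pif < 0 or pif > 1:
        raise ValueError(f"PIF must lie in [0, 1], got {pif}")
    return pif * baseline_events


def report_rounding(value: float) -> float:
    """Nearest-hundred rounding, half away from zero (reporting layer only)."""
    if value < 0:
        raise ValueError("reported event counts must be non-negative")
    return math.floor(value / 100.0 + 0.5) * 100.0


def percent_attributable(attributable: float, total_events: float) -> int:
    """Attributable share of all events, as an integer percentage."""
    if total_events <= 0:
        raise ValueError("total events must be positive")
    if attributable < 0:
        raise ValueError("attributable events must be non-negative")
    return int(math.floor(100.0 * attributable / total_events + 0.5))


def aggregate(cells: pd.DataFrame, value_col: str = "attributable") -> pd.DataFrame:
    """Aggregate per-stratum attributable/averted events into summary rows.

    ``cells`` must carry columns scenario, sex, age_group, outcome, metric
    and ``value_col``, all rows sharing one scenario.  Returns one row per
    (metric, outcome-or-'cvd', sex-or-'total') with the summed events and
    integer percentage shares: each outcome's share of total CVD and each
    sex's share, both within the metric.
    """
    required = {"scenario", "sex", "age_group", "outcome", "metric", value_col}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"aggregation input missing columns {sorted(missing)}")
    scenarios = cells["scenario"].unique()
    if len(scenarios) != 1:
        raise ValueError(
            f"aggregate() expects a single scenario, got {sorted(scenarios)}"
        )
    scenario = scenarios[0]

    rows = []
    for metric, dm in cells.groupby("metric", sort=False):
        total = dm[value_col].sum()
        for outcome in (*Outcome.ALL, "cvd"):
            do = dm if outcome == "cvd" else dm[dm.outcome == outcome]
            for sex in (*SEXES, "total"):
                ds = do if sex == "total" else do[do.sex == sex]
                events = ds[value_col].sum()
                rows.append(
                    {
                        "scenario": scenario,
                        "metric": metric,
                        "outcome": outcome,
                        "sex": sex,
                        "events": events,
                        "share_pct": percent_attributable(events, total)
                        if total > 0
                        else 0,
                        "events_rounded": report_rounding(events),
                    }
                )
    out = pd.DataFrame(rows)
    # conservation guard: grouped sums must reproduce the grand total
    for metric, dm in cells.groupby("metric", sort=False):
        expect = dm[value_col].sum()
        got = float(
            out.loc[
                (out.outcome == "cvd") & (out.sex == "total") & (out.metric == metric),
                "events",
            ].iloc[0]
        )
        if not np.isclose(got, expect, rtol=1e-12, atol=1e-9):
            raise AssertionError("aggregation failed conservation check")
    return out
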