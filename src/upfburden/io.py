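"""Reading and writing the delimited input/output tables.

All tables are UTF-8 comma-separated text with a header row:

* exposure table: sex, age_group, mean_pct, sd_pct, se_mean_pct
  (optional), population
* event table: sex, age_group, outcome, metric, value, ui_low, ui_high
* RR table: outcome, rr, ci_low, ci_high, x_ref_pct, x_tmrel_pct
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .burden import EventTable
from .dose_response import RRSpec
from .pipeline import StudyInputs

__all__ = [
    "load_exposure_table",
    "load_event_table",
    "load_rr_table",
    "load_bundle",
    "write_bundle",
    "write_manifest",
]

EXPOSURE_FILE = "exposure.csv"
EVENTS_FILE = "events.csv"
RR_FILE = "relative_risks.csv"


def load_exposure_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"sex", "age_group", "mean_pct", "sd_pct", "population"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: exposure table missing columns {sorted(missing)}")
    return frame


def load_event_table(path: str | Path) -> EventTable:
    return EventTable(pd.read_csv(path))


def load_rr_table(path: str | Path) -> dict[str, RRSpec]:
    frame = pd.read_csv(path)
    required = {"outcome", "rr", "ci_low", "ci_high", "x_ref_pct", "x_tmrel_pct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: RR table missing columns {sorted(missing)}")
    specs = {}
    for row in frame.itertuples(index=False):
        specs[row.outcome] = RRSpec(
            row.outcome, row.rr, row.ci_low, row.ci_high,
            x_ref=row.x_ref_pct, x_tmrel=row.x_tmrel_pct,
        )
    return specs


def load_bundle(directory: str | Path) -> StudyInputs:
    """Load a bundle directory holding the three canonical tables."""
    directory = Path(directory)
    return StudyInputs(
        exposure=load_exposure_table(directory / EXPOSURE_FILE),
        events=load_event_table(directory / EVENTS_FILE),
        rr_specs=load_rr_table(directory / RR_FILE),
    )


def write_bundle(inputs: StudyInputs, directory: str | Path) -> Path:
    """Materialise a bundle directory in the same formats the loaders read."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    inputs.exposure.to_csv(directory / EXPOSURE_FILE, index=False)
    inputs.events.frame.to_csv(directory / EVENTS_FILE, index=False)
    rows = [
        {
            "outcome": s.outcome,
            "rr": s.rr_ref,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "x_ref_pct": s.x_ref,
            "x_tmrel_pct": s.x_tmrel,
        }
        for s in inputs.rr_specs.values()
    ]
    pd.DataFrame(rows).to_csv(directory / RR_FILE, index=False)
    return directory


def write_manifest(path: str | Path, **entries) -> Path:
    """Write a machine-readable run manifest (inputs, seed, versions)."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    payload = {
        "versions": {
            "upfburden": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        **entries,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
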