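import pandas as pd
import pytest

from upfburden import (
    DEFAULT_RR_SPECS,
    DEFAULT_SCENARIOS,
    generate_study,
    run_deterministic,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study bundle with oracle ground truth."""
    return generate_study()


@pytest.fixture(scope="session")
def cells(study):
    """Deterministic pipeline output on the default bundle."""
    return run_deterministic(study.inputs, DEFAULT_SCENARIOS)


@pytest.fixture(scope="session")
def chd_spec():
    return DEFAULT_RR_SPECS["chd"]


@pytest.fixture(scope="session")
def stroke_spec():
    return DEFAULT_RR_SPECS["stroke"]


@pytest.fixture()
def tiny_events():
    """One-stratum event frame for focused burden tests."""
    return pd.DataFrame(
        [
            {
                "sex": "male",
                "age_group": "50-54",
                "outcome": "chd",
                "metric": "deaths",
                "value": 1000.0,
                "ui_low": 800.0,
                "ui_high": 1200.0,
            }
        ]
    )
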