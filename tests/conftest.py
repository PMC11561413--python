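import pandas as pd
import pytest
from hypothesis import settings

from sparscreen import (
    DesignSpec,
    SyntheticConfig,
    fixture_design,
    generate,
    load_default_panel,
    load_table3_fixture,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def fixture_means():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def design():
    return fixture_design()


@pytest.fixture(scope="session")
def synthetic_obs(fixture_means):
    """One replicate-level synthetic trial from the packaged means (cv=0.10)."""
    return generate(SyntheticConfig(mean_source=fixture_means, cv=0.10, seed=11))


@pytest.fixture(scope="session")
def noiseless_obs(fixture_means):
    return generate(SyntheticConfig(mean_source=fixture_means, cv=0.0, seed=0))


@pytest.fixture
def toy_design():
    """Minimal balanced two-hybrid, two-treatment, two-block design."""
    return DesignSpec(
        hybrids=("H1", "H2"), treatments=("T1", "T2"), n_replicates=2, control_label="T2"
    )


@pytest.fixture
def toy_obs(toy_design):
    rows = []
    values = {
        ("H1", "T1"): [10.0, 12.0],
        ("H1", "T2"): [20.0, 19.0],
        ("H2", "T1"): [11.0, 14.0],
        ("H2", "T2"): [25.0, 22.0],
    }
    for (h, t), vals in values.items():
        for rep, v in enumerate(vals, start=1):
            rows.append(dict(hybrid=h, treatment=t, replicate=rep, trait="PH", value=v))
    from sparscreen import ObservationTable

    return ObservationTable(pd.DataFrame(rows))
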