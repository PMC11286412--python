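import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from faerskit import DrugEntry, ReportRecord, SyntheticConfig, generate

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_report(
    report_id="R1",
    case_id="C1",
    date="2020-06-15",
    drugs=("lisinopril",),
    reactions=("Angioedema",),
    outcomes=(),
    sex="F",
    occupation="HEALTH_PROFESSIONAL",
    country="US",
    age=50.0,
):
    """Terse report factory for hand-built test cases."""
    return ReportRecord(
        report_id=report_id,
        case_id=case_id,
        receipt_date=dt.date.fromisoformat(date) if date else None,
        age_years=age,
        sex=sex,
        occupation=occupation,
        country=country,
        drugs=[DrugEntry(verbatim_name=d, standardized_name=d) for d in drugs],
        reactions=list(reactions),
        outcomes=list(outcomes),
    )


@pytest.fixture(scope="session")
def fixture_config():
    """The standard test dataset configuration: 2,000 reports, seed 42."""
    return SyntheticConfig(n_reports=2000, seed=42)


@pytest.fixture(scope="session")
def fixture_dataset(fixture_config):
    """2,000 primaries + 240 injected duplicates, deterministic."""
    return generate(fixture_config)
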