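import datetime

import pytest
from hypothesis import HealthCheck, settings

from pvror.model import DrugEntry, Report

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def data_dir():
    """Directory of shipped term lists and the fixture drug dictionary."""
    from pathlib import Path

    import pvror

    return Path(pvror.__file__).parent / "data"


@pytest.fixture
def make_report():
    """Factory for Report objects with sensible defaults."""

    def _make(
        primary_id="10000011",
        case_id="1000001",
        case_version=1,
        receipt_date=datetime.date(2015, 6, 1),
        age=(45.0, "YR"),
        sex="F",
        event_date=datetime.date(2015, 5, 1),
        reporter_country="US",
        drugs=(DrugEntry("PS", "MEROPENEM"),),
        reactions=frozenset({"RHABDOMYOLYSIS"}),
    ):
        return Report(
            primary_id=primary_id,
            case_id=case_id,
            case_version=case_version,
            receipt_date=receipt_date,
            age=age,
            sex=sex,
            event_date=event_date,
            reporter_country=reporter_country,
            drugs=tuple(drugs),
            reactions=frozenset(reactions),
        )

    return _make
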