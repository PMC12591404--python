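import datetime

import pytest

from pvsex.faers_io import DrugEntry, ReportRecord


def make_record(
    case_id="C1",
    version_id=1,
    report_date=datetime.date(2020, 1, 1),
    sex="F",
    age_years=40.0,
    country="US",
    drugs=(("CHANTIX", "VARENICLINE", "PS", None),),
    events=("Nausea",),
    outcomes=("UNKNOWN",),
    interaction_attributed=False,
):
    """Terse ReportRecord builder for fixtures."""
    return ReportRecord(
        case_id=case_id,
        version_id=version_id,
        report_date=report_date,
        sex=sex,
        age_years=age_years,
        country=country,
        drugs=tuple(DrugEntry(*d) for d in drugs),
        events=frozenset(events),
        outcomes=frozenset(outcomes),
        interaction_attributed=interaction_attributed,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort():
    """Tiny analysis universe: 2 varenicline reports (1 with nausea) and
    2 background reports (1 with nausea)."""
    return [
        make_record("A1", events=("Nausea", "Headache")),
        make_record("A2", events=("Insomnia",)),
        make_record("B1", drugs=(("IBUPROFEN", "", "PS", None),), events=("Nausea",)),
        make_record("B2", drugs=(("IBUPROFEN", "", "PS", None),), events=("Rash",)),
    ]
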