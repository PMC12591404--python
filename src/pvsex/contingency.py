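"""2x2 contingency tables and demographic summaries for report cohorts.

The counting unit is always the report, never the event mention: for a
drug-event pair in a stratum, ``a`` is the number of analysis-universe
reports carrying both the drug class and the event, ``b`` the drug reports
without the event, and ``c``/``d`` the same split among all remaining
reports ("all other drugs").  Reports with sex OTHER/UNKNOWN contribute to
the ALL stratum but to neither sex stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import GIEventList, ReportRecord, TermDictionary
from .preprocess import ROLE_POLICIES, flag_gi_events, match_drug_classes

#: aggregate event label: any gastrointestinal PT on the report
ANY_GI = "ANY_GI"

STRATA = ("ALL", "M", "F")

AGE_BANDS = ("<25", "25-40", "40-55", ">55")

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening event",
    "HO": "Hospitalization",
    "DS": "Disability",
    "RI": "Required intervention",
    "OT": "Other adverse events",
    "UNKNOWN": "Unknown",
}


def age_band(age_years: float | None) -> str | None:
    """Map an age in years to the reporting band (40 and 55 fall in 40-55)."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return None
    if age_years < 25:
        return "<25"
    if age_years < 40:
        return "25-40"
    if age_years <= 55:
        return "40-55"
    return ">55"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair in one stratum.

    Cells are real-valued so the table can carry the Haldane-Anscombe 0.5
    continuity correction (``corrected`` is then set).
    """

    drug: str
    event: str
    stratum: str
    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def has_zero_cell(self) -> bool:
        return 0.0 in self.cells


# ---------------------------------------------------------------------------
# annotation

def annotate(
    reports: Iterable[ReportRecord],
    dictionary: TermDictionary,
    gi_list: GIEventList,
    role_policy: str = "PS_only",
) -> pd.DataFrame:
    """One row per report with the derived columns the tables need:
    matched classes (under ``role_policy`` roles), casefolded events, GI
    events, sex, age band, country and outcomes.  The dictionary's class
    names are recorded in ``df.attrs['known_classes']``."""
    roles = ROLE_POLICIES[role_policy]
    rows = []
    for r in reports:
        rows.append(
            {
                "case_id": r.case_id,
                "sex": r.sex,
                "age_band": age_band(r.age_years),
                "country": r.country,
                "classes": frozenset(match_drug_classes(r, dictionary, roles=roles)),
                "events": frozenset(pt.casefold() for pt in r.events),
                "gi_events": frozenset(pt.casefold() for pt in flag_gi_events(r, gi_list)),
                "outcomes": frozenset(r.outcomes),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["case_id", "sex", "age_band", "country", "classes", "events", "gi_events", "outcomes"],
    )
    df.attrs["known_classes"] = tuple(dictionary.class_names)
    return df


def build_table(
    annotated: pd.DataFrame,
    drug: str,
    event: str,
    stratum: str = "ALL",
    background_exclude: Sequence[str] = (),
) -> ContingencyTable:
    """2x2 table for ``drug`` versus all other reports in ``stratum``.

    ``event`` is a Preferred Term (case-insensitive) or :data:`ANY_GI`.  A
    report naming the event under both the target drug and another drug
    counts only in ``a`` (report-level accounting).  ``background_exclude``
    drops reports matching those other classes from the background — a
    sensitivity option; by default the background is every non-target report
    including the other target classes.
    """
    known = annotated.attrs.get("known_classes", ())
    if known and drug not in known:
        raise KeyError(f"unknown drug class {drug!r}")
    sub = annotated if stratum == "ALL" else annotated[annotated["sex"] == stratum]
    if background_exclude:
        excluded = set(background_exclude) - {drug}
        sub = sub[
            sub["classes"].map(lambda cs: drug in cs or not (cs & excluded))
        ]
    in_drug = sub["classes"].map(lambda cs: drug in cs)
    if event == ANY_GI:
        has_event = sub["gi_events"].map(bool)
    else:
        pt = event.casefold()
        has_event = sub["events"].map(lambda es: pt in es)
    a = int((in_drug & has_event).sum())
    b = int((in_drug & ~has_event).sum())
    c = int((~in_drug & has_event).sum())
    d = int((~in_drug & ~has_event).sum())
    return ContingencyTable(drug=drug, event=event, stratum=stratum, a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# demographic summary

def percentage(count: float, total: float) -> float:
    """Percentage of ``total``, rounded to two decimals as reported."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 2)


def _block(counts: Mapping[str, int], total: int) -> dict[str, tuple[int, float]]:
    return {cat: (n, percentage(n, total)) for cat, n in counts.items()}


def demographic_summary(
    annotated: pd.DataFrame,
    drug_classes: Sequence[str] | None = None,
    other_country_threshold: float = 0.01,
) -> dict[str, dict]:
    """Per-class counts and percentages over sex, age band, country and
    outcome, on the class's own report total.

    Countries individually below ``other_country_threshold`` of the class's
    reports are aggregated into "Other countries" (UNKNOWN stays separate).
    Outcome codes are not mutually exclusive, so that block may exceed 100%.
    """
    if drug_classes is None:
        drug_classes = list(annotated.attrs.get("known_classes", ()))
    summary: dict[str, dict] = {}
    for drug in drug_classes:
        sub = annotated[annotated["classes"].map(lambda cs: drug in cs)]
        total = len(sub)
        sex_counts = {
            label: int((sub["sex"] == code).sum())
            for code, label in (("F", "Female"), ("M", "Male"), ("OTHER", "Other"), ("UNKNOWN", "Unknown"))
        }
        age_counts = {band: int((sub["age_band"] == band).sum()) for band in AGE_BANDS}
        n_age_unknown = int(sub["age_band"].isna().sum())
        if n_age_unknown:
            age_counts["Unknown"] = n_age_unknown

        raw_country = sub[sub["country"] != "UNKNOWN"]["country"].value_counts()
        country_counts: dict[str, int] = {}
        other = 0
        for country, n in raw_country.items():
            if total and n / total < other_country_threshold:
                other += int(n)
            else:
                country_counts[country] = int(n)
        if other:
            country_counts["Other countries"] = other
        country_counts["Unknown"] = int((sub["country"] == "UNKNOWN").sum())

        outcome_counts = {
            label: int(sub["outcomes"].map(lambda os, c=code: c in os).sum())
            for code, label in OUTCOME_LABELS.items()
        }

        summary[drug] = {
            "total": total,
            "sex": _block(sex_counts, total),
            "age": _block(age_counts, total),
            "country": _block(country_counts, total),
            "outcome": _block(outcome_counts, total),
        }
    return summary


def summary_frame(summary: Mapping[str, dict]) -> pd.DataFrame:
    """Tidy (drug, block, category, n, pct) view of a demographic summary."""
    rows = []
    for drug, blocks in summary.items():
        for block in ("sex", "age", "country", "outcome"):
            for category, (n, pct) in blocks[block].items():
                rows.append({"drug": drug, "block": block, "category": category, "n": n, "pct": pct})
    return pd.DataFrame(rows, columns=["drug", "block", "category", "n", "pct"])


def load_reference_demographics() -> pd.DataFrame:
    """Published demographic/outcome report counts for the three
    smoking-cessation therapies in FAERS (2004 Q1 - 2024 Q2), as
    (drug, block, category, count) rows.  Used to validate the summary
    arithmetic against the published percentages."""
    with resources.files("pvsex.data").joinpath("reference_demographics.csv").open() as fh:
        return pd.read_csv(fh)
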