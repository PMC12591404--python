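"""Report-selection logic: drug-class matching, deduplication and filtering.

The selection pipeline mirrors standard spontaneous-reporting practice:

1. match each report to drug classes through the search-term dictionary
   (verbatim drugname / active-ingredient fields, exclusion terms honoured);
2. deduplicate — first retain only the most recent version of each case,
   then collapse records sharing the full identifying key;
3. keep reports where the class drug carries a qualifying role (primary
   suspect by default), dropping reports whose gastrointestinal event the
   reporter attributed to a drug-drug interaction or concomitant medication.
"""

from __future__ import annotations

import datetime
import re
from collections import defaultdict
from typing import Iterable, Mapping

from .faers_io import (
    DrugEntry,
    GIEventList,
    ReportRecord,
    SearchTerm,
    TermDictionary,
    _norm_text,
    serialize_record,
)

#: roles that qualify a drug entry under each policy
ROLE_POLICIES: Mapping[str, frozenset[str]] = {
    "PS_only": frozenset({"PS"}),
    "suspect_or_interacting": frozenset({"PS", "SS", "I"}),
}


def _term_matches(term: SearchTerm, text: str) -> bool:
    """Case-insensitive, whitespace-normalised match of one search term."""
    if not text:
        return False
    if term.word_boundary:
        pattern = rf"(?<![a-z0-9]){re.escape(term.term)}(?![a-z0-9])"
        return re.search(pattern, text) is not None
    return term.term in text


def _entry_classes(entry: DrugEntry, dictionary: TermDictionary) -> set[str]:
    """Classes matched by a single drug entry; an exclusion-term hit on the
    entry removes it from every class it matched."""
    texts = [_norm_text(entry.drugname_verbatim), _norm_text(entry.prod_ai_verbatim)]
    for excl in dictionary.exclusions:
        if any(excl in t for t in texts):
            return set()
    matched = set()
    for name, terms in dictionary.classes.items():
        if any(_term_matches(term, t) for term in terms for t in texts):
            matched.add(name)
    return matched


def match_drug_classes(
    record: ReportRecord,
    dictionary: TermDictionary,
    roles: frozenset[str] | None = None,
) -> set[str]:
    """Drug classes matched by any drug entry of the report.

    ``roles`` restricts matching to entries with those role codes (e.g. only
    primary suspects); ``None`` considers every entry.
    """
    classes: set[str] = set()
    for entry in record.drugs:
        if roles is not None and entry.role not in roles:
            continue
        classes |= _entry_classes(entry, dictionary)
    return classes


# ---------------------------------------------------------------------------
# deduplication

def _stage1_sort_key(record: ReportRecord) -> tuple:
    return (
        record.version_id,
        record.report_date or datetime.date.min,
        serialize_record(record),
    )


def _stage2_key(record: ReportRecord) -> tuple:
    """Full identifying key: case id, report date, sorted drug names, sorted
    indications, sex, country and age at integer-year precision (missing age
    matches missing age)."""
    return (
        record.case_id,
        record.report_date,
        tuple(sorted(d.drugname_verbatim.casefold() for d in record.drugs)),
        tuple(sorted((d.indication or "").casefold() for d in record.drugs)),
        record.sex,
        record.country,
        None if record.age_years is None else int(record.age_years),
    )


def deduplicate_with_audit(
    reports: Iterable[ReportRecord],
) -> tuple[list[ReportRecord], dict[str, int]]:
    """Two-stage deduplication with per-rule removal counts.

    Stage 1 groups by case id and keeps the highest version, breaking ties by
    the latest report date and then by the lexicographically greatest
    serialized record (a documented deterministic tie-break).  Stage 2
    collapses surviving records that share the full identifying key.  Output
    is sorted by case id.
    """
    reports = list(reports)
    audit = {
        "input": len(reports),
        "exact_duplicates_removed": 0,
        "superseded_versions_removed": 0,
        "stage2_collapsed": 0,
    }

    by_case: dict[str, list[ReportRecord]] = defaultdict(list)
    for r in reports:
        by_case[r.case_id].append(r)

    survivors = []
    for case_id, group in by_case.items():
        best_i = max(range(len(group)), key=lambda i: _stage1_sort_key(group[i]))
        kept = group[best_i]
        kept_ser = serialize_record(kept)
        for i, r in enumerate(group):
            if i == best_i:
                continue
            if serialize_record(r) == kept_ser:
                audit["exact_duplicates_removed"] += 1
            else:
                audit["superseded_versions_removed"] += 1
        survivors.append(kept)

    by_key: dict[tuple, list[ReportRecord]] = defaultdict(list)
    for r in survivors:
        by_key[_stage2_key(r)].append(r)
    final = []
    for group in by_key.values():
        kept = max(group, key=serialize_record)
        audit["stage2_collapsed"] += len(group) - 1
        final.append(kept)

    final.sort(key=lambda r: (r.case_id, r.version_id))
    audit["output"] = len(final)
    return final, audit


def deduplicate(reports: Iterable[ReportRecord]) -> list[ReportRecord]:
    """See :func:`deduplicate_with_audit`; returns only the survivors."""
    return deduplicate_with_audit(reports)[0]


# ---------------------------------------------------------------------------
# analysis-set filtering

def flag_gi_events(record: ReportRecord, gi_list: GIEventList) -> set[str]:
    """Report events (original casing) that are gastrointestinal PTs."""
    return {pt for pt in record.events if pt in gi_list}


def filter_analysis_set(
    reports: Iterable[ReportRecord],
    drug_class: str,
    dictionary: TermDictionary,
    role_policy: str = "PS_only",
    gi_list: GIEventList | None = None,
) -> list[ReportRecord]:
    """Reports where ``drug_class`` is matched by an entry whose role
    satisfies ``role_policy``.

    Reports with ``interaction_attributed`` set are dropped when they would
    otherwise contribute a gastrointestinal event (any event, when no GI list
    is supplied) — the reporter blamed an interaction, not the suspect drug.
    """
    if drug_class not in dictionary.classes:
        raise KeyError(f"unknown drug class {drug_class!r}")
    roles = ROLE_POLICIES[role_policy]
    kept = []
    for r in reports:
        if drug_class not in match_drug_classes(r, dictionary, roles=roles):
            continue
        if r.interaction_attributed:
            if gi_list is None or flag_gi_events(r, gi_list):
                continue
        kept.append(r)
    return kept
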