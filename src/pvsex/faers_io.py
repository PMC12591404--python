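"""Reading and writing FAERS-like report tables and analysis dictionaries.

A spontaneous-reporting cohort is exchanged as four flat tables keyed by
``(case_id, version_id)`` — demographics, drugs, reactions and outcomes —
mirroring the quarterly ASCII layout of the FDA Adverse Event Reporting
System (FAERS).  Two dialects are supported: the FAERS-style ``$``-delimited
layout and plain CSV.  The module also loads the two configuration
dictionaries the analysis depends on: the drug-class search-term dictionary
(generic names, brand names and formulation terms for nicotine-replacement
therapy, varenicline and bupropion) and the list of gastrointestinal MedDRA
Preferred Terms.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SEX_CODES = ("M", "F", "OTHER", "UNKNOWN")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "RI", "OT", "UNKNOWN")
ROLE_CODES = ("PS", "SS", "I", "C")

_DELIMS = {"dollar_delimited": "$", "csv": ","}

#: file names used by :func:`write_reports` inside a cohort directory
COHORT_FILES = {"demo": "demo.csv", "drug": "drug.csv", "reac": "reac.csv", "outc": "outc.csv"}


def _norm_text(s: str) -> str:
    """Collapse internal whitespace and casefold."""
    return " ".join(s.split()).casefold()


@dataclass(frozen=True, order=True)
class DrugEntry:
    """One drug row of a report.

    ``role`` follows FAERS role codes: PS (primary suspect), SS (secondary
    suspect), I (interacting), C (concomitant).
    """

    drugname_verbatim: str = ""
    prod_ai_verbatim: str = ""
    role: str = "PS"
    indication: str | None = None

    def __post_init__(self) -> None:
        if not (self.drugname_verbatim.strip() or self.prod_ai_verbatim.strip()):
            raise ValueError("DrugEntry needs a drugname or an active-ingredient string")
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown role code {self.role!r}; expected one of {ROLE_CODES}")


@dataclass(frozen=True)
class ReportRecord:
    """One individual case safety report (ICSR), possibly one of several versions.

    ``sex`` is one of M/F/OTHER/UNKNOWN, ``country`` an ISO-like code or
    ``UNKNOWN`` and ``outcomes`` a set of FAERS outcome codes (``UNKNOWN``
    when no outcome row was filed).  ``interaction_attributed`` marks reports
    where the reporter blamed a drug-drug interaction or a concomitant
    medication rather than the suspect drug.
    """

    case_id: str
    version_id: int
    report_date: datetime.date | None
    sex: str
    age_years: float | None
    country: str
    drugs: tuple[DrugEntry, ...]
    events: frozenset[str]
    outcomes: frozenset[str]
    interaction_attributed: bool = False

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.version_id < 1:
            raise ValueError("version_id must be >= 1")
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be one of {SEX_CODES}, got {self.sex!r}")
        if not self.outcomes:
            raise ValueError("outcomes must be populated (use UNKNOWN)")
        bad = set(self.outcomes) - set(OUTCOME_CODES)
        if bad:
            raise ValueError(f"unknown outcome codes {sorted(bad)}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be nonnegative")


def serialize_record(record: ReportRecord) -> str:
    """Canonical single-line serialization, used for deterministic tie-breaks
    and bitwise record comparison (events/outcomes sorted, drugs in order)."""
    drugs = ";".join(
        f"{d.drugname_verbatim}|{d.prod_ai_verbatim}|{d.role}|{d.indication or ''}"
        for d in record.drugs
    )
    return "\x1f".join(
        [
            record.case_id,
            str(record.version_id),
            record.report_date.isoformat() if record.report_date else "",
            record.sex,
            "" if record.age_years is None else repr(float(record.age_years)),
            record.country,
            drugs,
            ";".join(sorted(record.events)),
            ";".join(sorted(record.outcomes)),
            "1" if record.interaction_attributed else "0",
        ]
    )


# ---------------------------------------------------------------------------
# field normalisation

def normalize_sex(raw: str) -> str:
    v = raw.strip().upper()
    if v in {"M", "F"}:
        return v
    if v in {"", "U", "UNK", "UNKNOWN", "NS"}:
        return "UNKNOWN"
    return "OTHER"


def normalize_country(raw: str) -> str:
    v = " ".join(raw.split()).upper()
    return v if v else "UNKNOWN"


def _parse_date(raw: str) -> datetime.date | None:
    v = raw.strip()
    if not v:
        return None
    return datetime.date.fromisoformat(v)


def _parse_age(raw: str) -> float | None:
    v = raw.strip()
    if not v:
        return None
    age = float(v)
    if age < 0:
        raise ValueError(f"negative age {raw!r}")
    return age


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in {"1", "true", "t", "y", "yes"}


# ---------------------------------------------------------------------------
# report reading / writing

def _read_table(path: str | Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("case_id", "version_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing join key column {col!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_reports(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    dialect: str = "csv",
) -> list[ReportRecord]:
    """Join the four report tables into one :class:`ReportRecord` per distinct
    ``(case_id, version_id)`` pair.

    Blank demographic fields map to ``UNKNOWN``; reaction/drug/outcome rows
    whose key matches no demographic row, and reaction rows with a blank PT,
    are skipped with a logged count.  No deduplication happens here — every
    report version is returned.
    """
    sep = _DELIMS[dialect]
    demo = _read_table(demo_path, sep, ("report_date", "sex", "age", "country"))
    drug = _read_table(drug_path, sep, ("drugname", "prod_ai", "role_cod"))
    reac = _read_table(reac_path, sep, ("pt",))
    outc = _read_table(outc_path, sep, ("outc_cod",))

    base: dict[tuple[str, int], dict] = {}
    for row in demo.itertuples(index=False):
        key = (str(row.case_id), int(row.version_id))
        base[key] = {
            "report_date": _parse_date(row.report_date),
            "sex": normalize_sex(row.sex),
            "age_years": _parse_age(row.age),
            "country": normalize_country(row.country),
            "interaction_attributed": _parse_bool(getattr(row, "interaction_attributed", "")),
            "drugs": [],
            "events": set(),
            "outcomes": set(),
        }

    skipped = {"drug": 0, "reac": 0, "outc": 0}

    for row in drug.itertuples(index=False):
        key = (str(row.case_id), int(row.version_id))
        if key not in base:
            skipped["drug"] += 1
            continue
        name = str(row.drugname).strip()
        ai = str(row.prod_ai).strip()
        if not (name or ai):
            skipped["drug"] += 1
            continue
        indication = str(getattr(row, "indi_pt", "")).strip() or None
        base[key]["drugs"].append(
            DrugEntry(name, ai, str(row.role_cod).strip().upper() or "PS", indication)
        )

    for row in reac.itertuples(index=False):
        key = (str(row.case_id), int(row.version_id))
        pt = str(row.pt).strip()
        if key not in base or not pt:
            skipped["reac"] += 1
            continue
        base[key]["events"].add(pt)

    for row in outc.itertuples(index=False):
        key = (str(row.case_id), int(row.version_id))
        cod = str(row.outc_cod).strip().upper()
        if key not in base or cod not in OUTCOME_CODES:
            skipped["outc"] += 1
            continue
        base[key]["outcomes"].add(cod)

    for table, n in skipped.items():
        if n:
            logger.warning("read_reports: skipped %d malformed/unmatched %s rows", n, table)

    records = []
    for (case_id, version_id), payload in sorted(base.items()):
        records.append(
            ReportRecord(
                case_id=case_id,
                version_id=version_id,
                report_date=payload["report_date"],
                sex=payload["sex"],
                age_years=payload["age_years"],
                country=payload["country"],
                drugs=tuple(payload["drugs"]),
                events=frozenset(payload["events"]),
                outcomes=frozenset(payload["outcomes"]) or frozenset({"UNKNOWN"}),
                interaction_attributed=payload["interaction_attributed"],
            )
        )
    if not records:
        raise ValueError("read_reports: zero joined records")
    return records


def write_reports(
    reports: Iterable[ReportRecord], out_dir: str | Path, dialect: str = "csv"
) -> dict[str, Path]:
    """Serialize a report collection as the four canonical tables.

    Inverse of :func:`read_reports` for collections without verbatim
    duplicates (reading collapses rows sharing ``(case_id, version_id)``).
    """
    sep = _DELIMS[dialect]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
    for r in reports:
        key = {"case_id": r.case_id, "version_id": r.version_id}
        demo_rows.append(
            {
                **key,
                "report_date": r.report_date.isoformat() if r.report_date else "",
                "sex": r.sex,
                "age": "" if r.age_years is None else f"{r.age_years:g}",
                "country": r.country,
                "interaction_attributed": int(r.interaction_attributed),
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    **key,
                    "drugname": d.drugname_verbatim,
                    "prod_ai": d.prod_ai_verbatim,
                    "role_cod": d.role,
                    "indi_pt": d.indication or "",
                }
            )
        for pt in sorted(r.events):
            reac_rows.append({**key, "pt": pt})
        for cod in sorted(r.outcomes):
            outc_rows.append({**key, "outc_cod": cod})

    paths = {}
    for name, rows, cols in (
        ("demo", demo_rows, ["case_id", "version_id", "report_date", "sex", "age", "country", "interaction_attributed"]),
        ("drug", drug_rows, ["case_id", "version_id", "drugname", "prod_ai", "role_cod", "indi_pt"]),
        ("reac", reac_rows, ["case_id", "version_id", "pt"]),
        ("outc", outc_rows, ["case_id", "version_id", "outc_cod"]),
    ):
        path = out / COHORT_FILES[name]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
        paths[name] = path
    return paths


def read_cohort_dir(cohort_dir: str | Path, dialect: str = "csv") -> list[ReportRecord]:
    """Read a cohort directory produced by :func:`write_reports`."""
    d = Path(cohort_dir)
    return read_reports(
        d / COHORT_FILES["demo"],
        d / COHORT_FILES["drug"],
        d / COHORT_FILES["reac"],
        d / COHORT_FILES["outc"],
        dialect=dialect,
    )


# ---------------------------------------------------------------------------
# term dictionary

@dataclass(frozen=True)
class SearchTerm:
    """One search term; ``word_boundary`` restricts matching to whole words so
    short generic terms (e.g. ``gum``) do not over-capture."""

    term: str
    word_boundary: bool = False

    def __post_init__(self) -> None:
        if not _norm_text(self.term):
            raise ValueError("empty search term")


@dataclass(frozen=True)
class TermDictionary:
    """Drug-class search terms plus exclusion terms.

    A class matches a report when any of its terms matches the verbatim
    drug name or active-ingredient string of any drug entry; an entry that
    also matches an exclusion term contributes no classes (e.g. Wellbutrin,
    a bupropion brand prescribed mainly for depression, is excluded from the
    smoking-cessation bupropion class).
    """

    classes: Mapping[str, tuple[SearchTerm, ...]]
    exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("TermDictionary needs at least one class")
        for name, terms in self.classes.items():
            if not terms:
                raise ValueError(f"class {name!r} has no search terms")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.classes)


def _parse_terms(raw_terms: Sequence) -> tuple[SearchTerm, ...]:
    terms = []
    for item in raw_terms:
        if isinstance(item, str):
            terms.append(SearchTerm(_norm_text(item)))
        else:
            terms.append(SearchTerm(_norm_text(item["term"]), bool(item.get("word_boundary", False))))
    return tuple(terms)


def load_term_dictionary(path: str | Path = "default") -> TermDictionary:
    """Load a term dictionary from YAML, or the shipped smoking-cessation
    default (NRT / Varenicline / Bupropion, Wellbutrin excluded)."""
    if path == "default":
        with resources.files("pvsex.data").joinpath("terms_smoking_cessation.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    classes = {name: _parse_terms(terms) for name, terms in raw["classes"].items()}
    exclusions = tuple(_norm_text(t) for t in raw.get("exclusions", []))
    return TermDictionary(classes=classes, exclusions=exclusions)


# ---------------------------------------------------------------------------
# gastrointestinal event list

@dataclass(frozen=True)
class GIEventList:
    """Case-insensitive set of gastrointestinal MedDRA Preferred Terms."""

    preferred_terms: frozenset[str]  # casefolded

    def __post_init__(self) -> None:
        if not self.preferred_terms:
            raise ValueError("GI event list is empty")

    def __contains__(self, pt: str) -> bool:
        return pt.casefold() in self.preferred_terms

    def __len__(self) -> int:
        return len(self.preferred_terms)


def load_gi_event_list(path: str | Path = "default") -> GIEventList:
    """Load a PT list (one term per line, ``#`` comments), or the shipped
    default covering the gastrointestinal SOC terms analysed here plus
    oral/digestive terms commonly reported with smoking-cessation drugs
    (dry mouth, hiccups, dental caries, ...).  The list is user-replaceable."""
    if path == "default":
        text = resources.files("pvsex.data").joinpath("gi_preferred_terms.txt").read_text()
    else:
        text = Path(path).read_text()
    terms = frozenset(
        _norm_text(line)
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    return GIEventList(preferred_terms=terms)
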