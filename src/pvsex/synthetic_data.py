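"""Synthetic spontaneous-report cohorts with known disproportionality structure.

The generator emulates the statistical skeleton of a FAERS extract: each
report draws one suspect drug (a named drug class or a generic background
drug), a sex, an age band and a country; each adverse event occurs
independently with probability ``q`` where ``odds(q) = odds(p0) * psi`` for
the report's (drug, sex) combination.  ``psi`` is the true reporting odds
ratio — the estimand the downstream ROR recovers — specified per
(drug, event, sex) and 1.0 elsewhere.  Duplicate report versions and exact
duplicate records are injected at configurable rates so the deduplication
stage is exercised end to end.

Default parameters mirror the study conditions of the smoking-cessation
analysis: sex margins of roughly 62% female / 36% male with a small
other/unknown remainder, the four reporting age bands, a US-dominated
country mix, and sex-specific reporting odds ratios for the
gastrointestinal events with published sex-stratified signals (e.g.
varenicline-nausea stronger in women, NRT-nausea stronger in men).
Background event odds are generator conventions (0.001-0.05 per report),
not published facts.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .contingency import ContingencyTable
from .faers_io import DrugEntry, ReportRecord, SEX_CODES

_EPOCH = datetime.date(2004, 1, 1)
_DAYS = 7487  # through 2024-06-30

#: event assigned when no catalog event fires, so every report carries a PT
FALLBACK_EVENT = "Drug ineffective"

_AGE_RANGES = {"<25": (18, 24), "25-40": (25, 39), "40-55": (40, 55), ">55": (56, 90)}


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1 / (1 + math.exp(-x))


@dataclass(frozen=True)
class DrugClassSpec:
    """One target drug class: marginal report probability plus the verbatim
    strings written on generated reports (so the term dictionary can match)."""

    name: str
    probability: float
    verbatim: str | None = None
    prod_ai: str = ""
    indication: str | None = None

    @property
    def drugname(self) -> str:
        return self.verbatim if self.verbatim is not None else self.name


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int
    drug_classes: tuple[DrugClassSpec, ...]
    background_drug_count: int
    sex_probabilities: Mapping[str, float]
    event_catalog: tuple[tuple[str, float], ...]
    effect_table: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    duplicate_version_rate: float = 0.0
    exact_duplicate_rate: float = 0.0
    interaction_attributed_rate: float = 0.0
    outcome_probabilities: Mapping[str, float] = field(default_factory=dict)
    age_distribution: Mapping[str, float] = field(default_factory=dict)
    country_distribution: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        if self.background_drug_count < 1:
            raise ValueError("background_drug_count must be positive")
        class_p = sum(s.probability for s in self.drug_classes)
        if not 0 <= class_p <= 1:
            raise ValueError("drug class probabilities must lie in [0, 1]")
        if abs(sum(self.sex_probabilities.values()) - 1) > 1e-9:
            raise ValueError("sex_probabilities must sum to 1")
        if set(self.sex_probabilities) - set(SEX_CODES):
            raise ValueError(f"sex codes must be among {SEX_CODES}")
        for pt, p0 in self.event_catalog:
            if not 0 < p0 < 1:
                raise ValueError(f"background probability for {pt!r} must lie in (0, 1)")
        events = {pt for pt, _ in self.event_catalog}
        drugs = {s.name for s in self.drug_classes}
        for (drug, event, sex), psi in self.effect_table.items():
            if drug not in drugs:
                raise ValueError(f"effect_table references unknown drug {drug!r}")
            if event not in events:
                raise ValueError(f"effect_table references unknown event {event!r}")
            if sex not in SEX_CODES:
                raise ValueError(f"effect_table references unknown sex {sex!r}")
            if psi <= 0:
                raise ValueError("true reporting odds ratios must be positive")
        for rate in (
            self.duplicate_version_rate,
            self.exact_duplicate_rate,
            self.interaction_attributed_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.age_distribution and abs(sum(self.age_distribution.values()) - 1) > 1e-9:
            raise ValueError("age_distribution must sum to 1")
        if self.country_distribution and abs(sum(self.country_distribution.values()) - 1) > 1e-9:
            raise ValueError("country_distribution must sum to 1")

    # -- derived categorical layouts -------------------------------------
    @property
    def drug_labels(self) -> tuple[str, ...]:
        bg = tuple(f"BG{i:02d}" for i in range(1, self.background_drug_count + 1))
        return tuple(s.name for s in self.drug_classes) + bg

    @property
    def drug_probs(self) -> np.ndarray:
        class_p = [s.probability for s in self.drug_classes]
        rest = 1.0 - sum(class_p)
        bg = [rest / self.background_drug_count] * self.background_drug_count
        return np.asarray(class_p + bg)

    def psi(self, drug: str, event: str, sex: str) -> float:
        return float(self.effect_table.get((drug, event, sex), 1.0))

    def event_prob(self, drug: str, event: str, sex: str) -> float:
        """P(event on a report | drug, sex) under the odds model."""
        p0 = dict(self.event_catalog)[event]
        return _expit(_logit(p0) + math.log(self.psi(drug, event, sex)))


def default_config(**overrides) -> GeneratorConfig:
    """The standard study-like configuration (desk-scale).

    100,000 reports with three target classes against 20 background drugs;
    sex-specific true reporting odds ratios follow the published
    sex-stratified GI signal pattern for the three therapies.
    """
    params = dict(
        n_reports=100_000,
        drug_classes=(
            DrugClassSpec("NRT", 0.040, "NICOTINE PATCH", "NICOTINE", "SMOKING CESSATION"),
            DrugClassSpec("Varenicline", 0.045, "CHANTIX", "VARENICLINE TARTRATE", "SMOKING CESSATION"),
            DrugClassSpec("Bupropion", 0.030, "ZYBAN", "BUPROPION HYDROCHLORIDE", "SMOKING CESSATION"),
        ),
        background_drug_count=20,
        sex_probabilities={"F": 0.616, "M": 0.359, "OTHER": 0.001, "UNKNOWN": 0.024},
        event_catalog=(
            ("Nausea", 0.030),
            ("Vomiting", 0.015),
            ("Constipation", 0.010),
            ("Diarrhoea", 0.018),
            ("Dyspepsia", 0.006),
            ("Abdominal pain upper", 0.008),
            ("Dry mouth", 0.008),
            ("Hiccups", 0.002),
            ("Flatulence", 0.004),
            ("Decreased appetite", 0.006),
            ("Dental caries", 0.002),
            ("Salivary hypersecretion", 0.001),
            ("Headache", 0.040),
            ("Dizziness", 0.035),
            ("Insomnia", 0.025),
            (FALLBACK_EVENT, 0.050),
        ),
        effect_table={
            ("Varenicline", "Nausea", "M"): 5.10,
            ("Varenicline", "Nausea", "F"): 6.41,
            ("Varenicline", "Constipation", "M"): 2.51,
            ("Varenicline", "Constipation", "F"): 3.41,
            ("Varenicline", "Flatulence", "M"): 7.45,
            ("Varenicline", "Flatulence", "F"): 10.16,
            ("NRT", "Hiccups", "M"): 42.70,
            ("NRT", "Hiccups", "F"): 109.81,
            ("NRT", "Nausea", "M"): 3.09,
            ("NRT", "Nausea", "F"): 2.45,
            ("NRT", "Dyspepsia", "M"): 4.74,
            ("NRT", "Dyspepsia", "F"): 3.30,
            ("NRT", "Dental caries", "M"): 12.06,
            ("NRT", "Dental caries", "F"): 4.32,
            ("Bupropion", "Nausea", "M"): 1.35,
            ("Bupropion", "Nausea", "F"): 1.97,
            ("Bupropion", "Constipation", "M"): 1.68,
            ("Bupropion", "Constipation", "F"): 2.21,
            ("Bupropion", "Dry mouth", "M"): 4.42,
            ("Bupropion", "Dry mouth", "F"): 4.42,
        },
        duplicate_version_rate=0.02,
        exact_duplicate_rate=0.01,
        interaction_attributed_rate=0.01,
        outcome_probabilities={"DE": 0.01, "LT": 0.005, "HO": 0.05, "DS": 0.005, "RI": 0.002, "OT": 0.20},
        age_distribution={"<25": 0.055, "25-40": 0.27, "40-55": 0.42, ">55": 0.255},
        country_distribution={
            "US": 0.913, "GB": 0.012, "CA": 0.011, "JP": 0.004,
            "FR": 0.020, "DE": 0.020, "AU": 0.009, "UNKNOWN": 0.011,
        },
        seed=0,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


# ---------------------------------------------------------------------------
# vectorised core

def generate_frame(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-report attributes as a flat DataFrame (no duplicates,
    no record objects) — the generative core shared by :func:`generate_cohort`
    and the fast simulation paths.

    Columns: ``drug``, ``sex``, ``age_years``, ``country``,
    ``interaction_attributed`` plus one boolean column per catalog event;
    ``df.attrs['event_columns']`` lists the event columns.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_reports

    drug_idx = rng.choice(len(config.drug_labels), size=n, p=config.drug_probs)
    drugs = np.asarray(config.drug_labels, dtype=object)[drug_idx]

    sex_codes = list(config.sex_probabilities)
    sex = np.asarray(sex_codes, dtype=object)[
        rng.choice(len(sex_codes), size=n, p=list(config.sex_probabilities.values()))
    ]

    age_dist = config.age_distribution or {"<25": 0.1, "25-40": 0.3, "40-55": 0.35, ">55": 0.25}
    bands = list(age_dist)
    band_idx = rng.choice(len(bands), size=n, p=list(age_dist.values()))
    age = np.empty(n)
    for i, band in enumerate(bands):
        lo, hi = _AGE_RANGES[band]
        mask = band_idx == i
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    country_dist = config.country_distribution or {"US": 1.0}
    countries = np.asarray(list(country_dist), dtype=object)[
        rng.choice(len(country_dist), size=n, p=list(country_dist.values()))
    ]

    interaction = rng.random(n) < config.interaction_attributed_rate

    df = pd.DataFrame(
        {
            "drug": drugs,
            "sex": sex,
            "age_years": age,
            "country": countries,
            "interaction_attributed": interaction,
        }
    )

    # event occurrence: odds multiplied by psi for the report's (drug, sex)
    event_cols = []
    for pt, p0 in config.event_catalog:
        q = np.full(n, p0)
        for (drug, event, sx), psi in config.effect_table.items():
            if event != pt or psi == 1.0:
                continue
            mask = (drugs == drug) & (sex == sx)
            if mask.any():
                q[mask] = _expit(_logit(p0) + math.log(psi))
        df[pt] = rng.random(n) < q
        event_cols.append(pt)
    df.attrs["event_columns"] = event_cols
    return df


def frame_table(
    frame: pd.DataFrame, drug: str, event: str, stratum: str = "ALL"
) -> ContingencyTable:
    """2x2 report counts for a generator frame (drug label vs all others)."""
    sub = frame if stratum == "ALL" else frame[frame["sex"] == stratum]
    in_drug = (sub["drug"] == drug).to_numpy()
    has_event = sub[event].to_numpy()
    return ContingencyTable(
        drug=drug,
        event=event,
        stratum=stratum,
        a=int((in_drug & has_event).sum()),
        b=int((in_drug & ~has_event).sum()),
        c=int((~in_drug & has_event).sum()),
        d=int((~in_drug & ~has_event).sum()),
    )


# ---------------------------------------------------------------------------
# record materialisation

def generate_cohort(config: GeneratorConfig) -> list[ReportRecord]:
    """Full cohort as :class:`ReportRecord` objects, bit-for-bit reproducible
    for a fixed seed.

    The base cohort and the duplicate injection use independent sub-seeds of
    ``config.seed``, so toggling the duplicate rates does not perturb the
    base cohort.  Output order is randomised under the seed.  Reports whose
    event draw comes up empty receive the fallback PT so every report
    carries at least one event.
    """
    ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    frame = generate_frame(config, rng=rng)
    event_cols = frame.attrs["event_columns"]

    dates = rng.integers(0, _DAYS, size=config.n_reports)
    outcome_draws = {
        code: rng.random(config.n_reports) < p for code, p in config.outcome_probabilities.items()
    }

    specs = {s.name: s for s in config.drug_classes}
    entry_cache = {
        label: (
            DrugEntry(specs[label].drugname, specs[label].prod_ai, "PS", specs[label].indication)
            if label in specs
            else DrugEntry(f"BACKGROUND DRUG {label[2:]}", "", "PS", None)
        )
        for label in config.drug_labels
    }
    event_matrix = frame[event_cols].to_numpy()
    drug_arr = frame["drug"].to_numpy()
    sex_arr = frame["sex"].to_numpy()
    age_arr = frame["age_years"].to_numpy()
    country_arr = frame["country"].to_numpy()
    interaction_arr = frame["interaction_attributed"].to_numpy()
    outcome_codes = list(outcome_draws)

    records = []
    for i in range(config.n_reports):
        events = frozenset(pt for pt, flag in zip(event_cols, event_matrix[i]) if flag)
        if not events:
            events = frozenset({FALLBACK_EVENT})
        outcomes = frozenset(code for code in outcome_codes if outcome_draws[code][i])
        records.append(
            ReportRecord(
                case_id=f"SYN{i:07d}",
                version_id=1,
                report_date=_EPOCH + datetime.timedelta(days=int(dates[i])),
                sex=sex_arr[i],
                age_years=float(age_arr[i]),
                country=country_arr[i],
                drugs=(entry_cache[drug_arr[i]],),
                events=events,
                outcomes=outcomes or frozenset({"UNKNOWN"}),
                interaction_attributed=bool(interaction_arr[i]),
            )
        )

    order = rng.permutation(len(records))
    records = [records[j] for j in order]

    if config.duplicate_version_rate or config.exact_duplicate_rate:
        dup_seed = int(ss[1].generate_state(1)[0] % (2**31))
        records = inject_duplicates(
            records, config.duplicate_version_rate, config.exact_duplicate_rate, dup_seed
        )
    return records


def inject_duplicates(
    reports: Sequence[ReportRecord],
    version_rate: float,
    exact_rate: float,
    seed: int,
) -> list[ReportRecord]:
    """Inject version duplicates (version_id + 1, later report date) and
    verbatim exact duplicates at the given per-report rates; the pre-injection
    cohort is recoverable by deduplication."""
    for rate in (version_rate, exact_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(reports)
    for r in reports:
        if rng.random() < version_rate:
            base = r.report_date or _EPOCH
            out.append(
                replace(
                    r,
                    version_id=r.version_id + 1,
                    report_date=base + datetime.timedelta(days=int(rng.integers(1, 181))),
                )
            )
        if rng.random() < exact_rate:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# analytic and sampling oracles

def expected_table(
    config: GeneratorConfig, drug: str, event: str, stratum: str = "ALL"
) -> ContingencyTable:
    """Expected (real-valued) 2x2 cells under the generative model, before
    duplicate injection — the analytic oracle for parameter-recovery tests."""
    if drug not in config.drug_labels:
        raise KeyError(f"unknown drug {drug!r}")
    if event not in {pt for pt, _ in config.event_catalog}:
        raise KeyError(f"unknown event {event!r}")
    if stratum not in ("ALL", "M", "F"):
        raise ValueError("stratum must be ALL, M or F")
    sexes = list(config.sex_probabilities) if stratum == "ALL" else [stratum]
    n = config.n_reports
    labels = config.drug_labels
    probs = config.drug_probs
    a = b = c = d = 0.0
    for sx in sexes:
        w = config.sex_probabilities.get(sx, 0.0)
        for label, p_drug in zip(labels, probs):
            q = config.event_prob(label, event, sx)
            mass = n * w * p_drug
            if label == drug:
                a += mass * q
                b += mass * (1 - q)
            else:
                c += mass * q
                d += mass * (1 - q)
    return ContingencyTable(drug=drug, event=event, stratum=stratum, a=a, b=b, c=c, d=d)


def simulate_stratified_counts(
    config: GeneratorConfig,
    drug: str,
    event: str,
    n_reps: int,
    seed: int,
    strata: Sequence[str] = ("M", "F"),
) -> np.ndarray:
    """Monte-Carlo draws of the per-stratum 2x2 cells, shape
    ``(n_reps, len(strata), 4)``.

    Draws the sufficient statistics of :func:`generate_frame` directly
    (multinomial sex and drug splits, binomial event counts), which follows
    the identical generative law at a fraction of the cost — used by the
    calibration and power simulations.
    """
    if drug not in config.drug_labels:
        raise KeyError(f"unknown drug {drug!r}")
    rng = np.random.default_rng(seed)
    n = config.n_reports
    sex_codes = list(config.sex_probabilities)
    sex_p = np.asarray(list(config.sex_probabilities.values()))
    labels = config.drug_labels
    drug_p = config.drug_probs
    d_idx = labels.index(drug)

    n_by_sex = rng.multinomial(n, sex_p, size=n_reps)  # (reps, n_sexes)
    out = np.zeros((n_reps, len(strata), 4))
    for si, sx in enumerate(strata):
        n_s = n_by_sex[:, sex_codes.index(sx)]
        n_drugs = rng.multinomial(n_s, np.broadcast_to(drug_p, (n_reps, len(labels))))
        a = rng.binomial(n_drugs[:, d_idx], config.event_prob(drug, event, sx))
        b = n_drugs[:, d_idx] - a
        c = np.zeros(n_reps, dtype=np.int64)
        other_total = np.zeros(n_reps, dtype=np.int64)
        for j, label in enumerate(labels):
            if j == d_idx:
                continue
            cj = rng.binomial(n_drugs[:, j], config.event_prob(label, event, sx))
            c += cj
            other_total += n_drugs[:, j]
        out[:, si, 0] = a
        out[:, si, 1] = b
        out[:, si, 2] = c
        out[:, si, 3] = other_total - c
    return out


# ---------------------------------------------------------------------------
# YAML configuration

def config_from_yaml(path) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML file; omitted fields fall
    back to :func:`default_config`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    overrides: dict = {}
    if "drug_classes" in raw:
        overrides["drug_classes"] = tuple(
            DrugClassSpec(
                name=item["name"],
                probability=float(item["probability"]),
                verbatim=item.get("verbatim"),
                prod_ai=item.get("prod_ai", ""),
                indication=item.get("indication"),
            )
            for item in raw.pop("drug_classes")
        )
    if "event_catalog" in raw:
        overrides["event_catalog"] = tuple(
            (item["pt"], float(item["p0"])) for item in raw.pop("event_catalog")
        )
    if "effect_table" in raw:
        overrides["effect_table"] = {
            (item["drug"], item["event"], item["sex"]): float(item["psi"])
            for item in raw.pop("effect_table")
        }
    overrides.update(raw)
    return default_config(**overrides)
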