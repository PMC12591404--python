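"""Canned calibration studies for the statistical machinery.

Each study fixes a generator configuration chosen so the asymptotic
chi-square machinery is on safe ground (expected cell counts well above
single digits) and measures an operating characteristic by Monte-Carlo:

* :func:`breslow_day_size` — type-I error of the homogeneity screen under a
  common (non-null) reporting odds ratio in both sexes;
* :func:`breslow_day_power` — rejection rate under a planted sex difference
  (psi 4.0 in women vs 1.5 in men, about 330/780 expected co-reports per
  stratum);
* :func:`woolf_coverage` — coverage of the Woolf 95% CI for a planted
  pooled reporting odds ratio of 3.

The size and power studies draw the sufficient statistics of the generator
directly (:func:`~pvsex.synthetic_data.simulate_stratified_counts`); the
coverage study exercises the full per-report frame draw.
"""

from __future__ import annotations

import numpy as np

from .contingency import ContingencyTable
from .disproportionality import breslow_day_statistic, ror
from .synthetic_data import (
    DrugClassSpec,
    GeneratorConfig,
    default_config,
    frame_table,
    generate_frame,
    simulate_stratified_counts,
)


def _study_config(
    n_reports: int,
    p_drug: float,
    p0: float,
    psi_m: float,
    psi_f: float,
    sex_f: float = 0.6,
) -> GeneratorConfig:
    """One target drug against a single pooled background drug, one event."""
    effects = {}
    if psi_m != 1.0:
        effects[("D", "Nausea", "M")] = psi_m
    if psi_f != 1.0:
        effects[("D", "Nausea", "F")] = psi_f
    return default_config(
        n_reports=n_reports,
        drug_classes=(DrugClassSpec("D", p_drug, "DRUG D"),),
        background_drug_count=1,
        sex_probabilities={"F": sex_f, "M": round(1 - sex_f, 12)},
        event_catalog=(("Nausea", p0),),
        effect_table=effects,
        age_distribution={"<25": 0.2, "25-40": 0.3, "40-55": 0.3, ">55": 0.2},
        country_distribution={"US": 1.0},
        duplicate_version_rate=0.0,
        exact_duplicate_rate=0.0,
        interaction_attributed_rate=0.0,
        seed=0,
    )


def _rejection_rate(config: GeneratorConfig, n_reps: int, seed: int, alpha: float) -> float:
    counts = simulate_stratified_counts(config, "D", "Nausea", n_reps, seed=seed)
    rejected = 0
    for k in range(n_reps):
        tables = [
            ContingencyTable("D", "Nausea", stratum, *counts[k, i])
            for i, stratum in enumerate(("M", "F"))
        ]
        rejected += breslow_day_statistic(tables)[2] < alpha
    return rejected / n_reps


def breslow_day_size(n_reps: int = 5000, seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate under homogeneity: psi = 2 in both sexes, 20,000
    reports per replicate (about 57/38 expected co-reports in the
    female/male strata).  Should sit near ``alpha``."""
    config = _study_config(20_000, p_drug=0.05, p0=0.05, psi_m=2.0, psi_f=2.0)
    return _rejection_rate(config, n_reps, seed, alpha)


def breslow_day_power(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate under heterogeneity: psi 4.0 (F) vs 1.5 (M) with at
    least 300 expected co-reports per stratum (60,000 reports, drug share
    0.15, equal sex split)."""
    config = _study_config(60_000, p_drug=0.15, p0=0.05, psi_m=1.5, psi_f=4.0, sex_f=0.5)
    return _rejection_rate(config, n_reps, seed, alpha)


def woolf_coverage(n_reps: int = 400, seed: int = 0, psi: float = 3.0) -> float:
    """Fraction of replicates whose Woolf 95% CI covers the planted pooled
    reporting odds ratio (50,000 reports per replicate; since the odds
    multiplier is identical in both sexes and the background rate does not
    depend on sex, the pooled estimand equals ``psi`` exactly)."""
    config = _study_config(50_000, p_drug=0.05, p0=0.02, psi_m=psi, psi_f=psi)
    covered = 0
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        frame = generate_frame(config, rng=np.random.default_rng(child))
        _, (lo, hi) = ror(frame_table(frame, "D", "Nausea", "ALL"))
        covered += lo <= psi <= hi
    return covered / n_reps
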