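"""End-to-end pipeline orchestration and presentation artifacts.

``run_pipeline`` sequences generation/ingestion, deduplication, analysis-set
filtering, contingency-table construction, signal computation and the
Breslow-Day sex-heterogeneity screen, writing every artifact as CSV plus a
YAML manifest that records the seed and every convention flag.  Figures are
emitted as data files: the heat-map matrix holds log10(PRR) for qualifying
pairs (blank cells mean "no qualifying reports", never zero) and the forest
table holds one row per sex for each significant heterogeneity result.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contingency import (
    ANY_GI,
    ContingencyTable,
    annotate,
    build_table,
    demographic_summary,
    summary_frame,
)
from .disproportionality import (
    HeterogeneityResult,
    SignalResult,
    compute_signal,
    stratified_screen,
)
from .faers_io import (
    load_gi_event_list,
    load_term_dictionary,
    read_cohort_dir,
)
from .preprocess import deduplicate_with_audit, flag_gi_events, match_drug_classes, ROLE_POLICIES
from .synthetic_data import config_from_yaml, default_config, generate_cohort

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "dedup_audit.csv",
    "analysis_sets.csv",
    "demographic_summary.csv",
    "signals.csv",
    "heterogeneity.csv",
    "heatmap_ALL.csv",
    "heatmap_M.csv",
    "heatmap_F.csv",
    "forest.csv",
)


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the failed stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _fmt(x: float) -> str:
    return "" if (isinstance(x, float) and math.isnan(x)) else f"{x:.4f}"


def signals_frame(signals: Sequence[SignalResult]) -> pd.DataFrame:
    rows = []
    for s in signals:
        rows.append(
            {
                "drug": s.drug,
                "event": s.event,
                "stratum": s.stratum,
                "de": s.de,
                "prr": _fmt(s.prr),
                "prr_lo": _fmt(s.prr_ci95[0]),
                "prr_hi": _fmt(s.prr_ci95[1]),
                "ror": _fmt(s.ror),
                "ror_lo": _fmt(s.ror_ci95[0]),
                "ror_hi": _fmt(s.ror_ci95[1]),
                "chi2": _fmt(s.chi2),
                "prr_signal": int(s.prr_signal),
                "ror_signal": int(s.ror_signal),
                "corrected": int(s.corrected),
            }
        )
    return pd.DataFrame(rows)


def heterogeneity_frame(results: Sequence[HeterogeneityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "drug": r.drug,
                "event": r.event,
                "de_male": r.de_male,
                "de_female": r.de_female,
                "ror_male": _fmt(r.ror_male),
                "ror_male_lo": _fmt(r.ror_male_ci95[0]),
                "ror_male_hi": _fmt(r.ror_male_ci95[1]),
                "ror_female": _fmt(r.ror_female),
                "ror_female_lo": _fmt(r.ror_female_ci95[0]),
                "ror_female_hi": _fmt(r.ror_female_ci95[1]),
                "or_mh": _fmt(r.or_mh),
                "bd_stat": _fmt(r.bd_stat),
                "df": r.df,
                "p_value": f"{r.p_value:.6g}",
                "stability_pass": int(r.stability_pass),
                "significant": int(r.significant),
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)


def heatmap_matrix(signals: Iterable[SignalResult], stratum: str) -> pd.DataFrame:
    """Drug x event matrix of log10(PRR) for pairs passing the dual filter
    DE >= 3 and PRR >= 2 in ``stratum``; other cells are missing (blank when
    serialized), never zero."""
    qualifying = [
        s
        for s in signals
        if s.stratum == stratum and s.de >= 3 and not math.isnan(s.prr) and s.prr >= 2
    ]
    drugs = sorted({s.drug for s in qualifying})
    events = sorted({s.event for s in qualifying})
    mat = pd.DataFrame(np.nan, index=drugs, columns=events, dtype=float)
    for s in qualifying:
        mat.loc[s.drug, s.event] = math.log10(s.prr)
    mat.index.name = "drug"
    return mat


def forest_data(results: Iterable[HeterogeneityResult]) -> pd.DataFrame:
    """Forest-plot table: one row per sex for every significant result
    (stability filter passed and Breslow-Day p below alpha); the reference
    line at ROR = 1 is implied by the format."""
    rows = []
    for r in results:
        if not r.significant:
            continue
        for sex, point, ci in (
            ("M", r.ror_male, r.ror_male_ci95),
            ("F", r.ror_female, r.ror_female_ci95),
        ):
            rows.append(
                {
                    "drug": r.drug,
                    "event": r.event,
                    "sex": sex,
                    "ror": round(point, 4),
                    "ci_low": round(ci[0], 4),
                    "ci_high": round(ci[1], 4),
                    "direction": r.direction,
                }
            )
    return pd.DataFrame(rows, columns=["drug", "event", "sex", "ror", "ci_low", "ci_high", "direction"])


# ---------------------------------------------------------------------------
# pipeline

_DEFAULTS = {
    "role_policy": "PS_only",
    "yates": False,
    "tarone": False,
    "alpha": 0.05,
    "stability_min": 20,
    "dictionary": "default",
    "gi_list": "default",
}


def run_pipeline(
    config: Mapping | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run the full analysis and write every artifact into ``out_dir``.

    ``config`` is a mapping (or YAML path) with optional keys ``generator``
    (generator overrides or a generator YAML path), ``cohort_dir`` (read an
    existing cohort instead), ``dictionary``/``gi_list`` paths, ``drug_classes``
    and the convention flags (``role_policy``, ``yates``, ``tarone``,
    ``alpha``, ``stability_min``).  Identical config and seed produce
    byte-identical artifacts; only the manifest carries a timestamp.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**_DEFAULTS, **dict(config)}
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg.get("seed", 0))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: input ----------------------------------------------------
    stage = "input"
    try:
        dictionary = load_term_dictionary(cfg["dictionary"])
        gi_list = load_gi_event_list(cfg["gi_list"])
        if cfg.get("cohort_dir"):
            reports = read_cohort_dir(cfg["cohort_dir"])
        else:
            gen_spec = cfg.get("generator") or {}
            if isinstance(gen_spec, (str, Path)):
                gen_config = config_from_yaml(gen_spec)
                gen_config = dataclasses.replace(gen_config, seed=seed)
            else:
                gen_config = default_config(**{**gen_spec, "seed": seed})
            reports = generate_cohort(gen_config)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, str(exc)) from exc

    # -- stage: preprocess ------------------------------------------------
    stage = "preprocess"
    try:
        drug_classes = list(cfg.get("drug_classes") or dictionary.class_names)
        unknown = [d for d in drug_classes if d not in dictionary.classes]
        if unknown:
            raise KeyError(f"unknown drug class(es) {unknown}")
        deduped, audit = deduplicate_with_audit(reports)
        n_before = len(deduped)
        analysis_universe = [
            r for r in deduped if not (r.interaction_attributed and flag_gi_events(r, gi_list))
        ]
        audit["interaction_attributed_removed"] = n_before - len(analysis_universe)
        roles = ROLE_POLICIES[cfg["role_policy"]]
        set_rows = []
        for r in analysis_universe:
            for name in sorted(match_drug_classes(r, dictionary, roles=roles)):
                if name in drug_classes:
                    set_rows.append({"drug": name, "case_id": r.case_id})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: tables ----------------------------------------------------
    stage = "tables"
    try:
        annotated = annotate(analysis_universe, dictionary, gi_list, role_policy=cfg["role_policy"])
        summary = demographic_summary(annotated, drug_classes)
        observed_pts = sorted(
            {pt for events in annotated["gi_events"] for pt in events}
        )
        tables: dict[tuple[str, str, str], ContingencyTable] = {}
        for drug in drug_classes:
            for event in [ANY_GI, *observed_pts]:
                for stratum in ("ALL", "M", "F"):
                    tables[(drug, event, stratum)] = build_table(annotated, drug, event, stratum)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: signals ---------------------------------------------------
    stage = "signals"
    try:
        signals = []
        for (drug, event, stratum), t in sorted(tables.items()):
            signals.append(
                compute_signal(t, yates=cfg["yates"], correct_zero=(stratum != "ALL"))
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: screen ----------------------------------------------------
    stage = "screen"
    try:
        pairs = sorted({(d, e) for (d, e, _s) in tables})
        screen = stratified_screen(
            [(tables[(d, e, "M")], tables[(d, e, "F")]) for d, e in pairs],
            alpha=cfg["alpha"],
            stability_min=cfg["stability_min"],
            tarone=cfg["tarone"],
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: report ----------------------------------------------------
    stage = "report"
    try:
        pd.DataFrame([audit]).to_csv(out / "dedup_audit.csv", index=False)
        pd.DataFrame(set_rows, columns=["drug", "case_id"]).to_csv(
            out / "analysis_sets.csv", index=False
        )
        summary_frame(summary).to_csv(out / "demographic_summary.csv", index=False)
        signals_frame(signals).to_csv(out / "signals.csv", index=False)
        heterogeneity_frame(screen).to_csv(out / "heterogeneity.csv", index=False)
        for stratum in ("ALL", "M", "F"):
            heatmap_matrix(signals, stratum).to_csv(out / f"heatmap_{stratum}.csv")
        forest_data(screen).to_csv(out / "forest.csv", index=False)

        hashes = {}
        digest = hashlib.sha256()
        for name in ARTIFACTS:
            data = (out / name).read_bytes()
            hashes[name] = hashlib.sha256(data).hexdigest()
            digest.update(data)
        manifest = {
            "package": "pvsex",
            "version": __version__,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "seed": seed,
            "conventions": {
                "role_policy": cfg["role_policy"],
                "yates": bool(cfg["yates"]),
                "tarone": bool(cfg["tarone"]),
                "alpha": cfg["alpha"],
                "stability_min": cfg["stability_min"],
            },
            "counts": {
                "reports_in": len(reports),
                "after_dedup": audit["output"],
                "analysis_universe": len(analysis_universe),
            },
            "content_hash": digest.hexdigest(),
            "artifact_hashes": hashes,
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    logger.info("pipeline complete: %d artifacts in %s", len(ARTIFACTS) + 1, out)
    return out
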