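"""Disproportionality statistics and the sex-heterogeneity screen.

For a 2x2 report table (a, b, c, d) the two frequentist signal metrics are

* PRR — proportional reporting ratio, ``[a/(a+b)] / [c/(c+d)]``;
* ROR — reporting odds ratio, ``(a*d)/(b*c)``;

both with Woolf (log-normal) 95% confidence intervals, plus the Pearson
chi-square (optionally Yates-corrected).  A drug-event pair is a PRR signal
when DE >= 3, PRR >= 2 and chi-square >= 4, and an ROR signal when DE >= 3
and the lower CI bound exceeds 1 (DE = a, the number of co-reports).

Sex heterogeneity of the ROR is tested with the Breslow-Day chi-square for
homogeneity of odds ratios across the male/female strata, using the
Mantel-Haenszel common odds ratio as the homogeneity null (Tarone's
adjustment optional).  Zero cells receive the Haldane-Anscombe 0.5
correction.  Sparse pairs are screened out by a stability filter requiring
DE_male + DE_female strictly above a minimum (default 20); significance is
two-sided p < 0.05 with no multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy import stats

from .contingency import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality metrics and signal flags for one drug-event-stratum.

    Metrics are NaN when undefined (zero cells without correction); flags are
    then False.  ``de`` is the integer co-report count before any correction.
    """

    drug: str
    event: str
    stratum: str
    de: int
    prr: float
    prr_ci95: tuple[float, float]
    ror: float
    ror_ci95: tuple[float, float]
    chi2: float
    prr_signal: bool
    ror_signal: bool
    corrected: bool = False


@dataclass(frozen=True)
class HeterogeneityResult:
    """Breslow-Day sex-heterogeneity screen result for one drug-event pair."""

    drug: str
    event: str
    de_male: int
    de_female: int
    ror_male: float
    ror_male_ci95: tuple[float, float]
    ror_female: float
    ror_female_ci95: tuple[float, float]
    or_mh: float
    bd_stat: float
    df: int
    p_value: float
    stability_pass: bool
    significant: bool
    direction: str  # F_GT_M, M_GT_F or NONE


# ---------------------------------------------------------------------------
# point metrics

def apply_haldane_anscombe(t: ContingencyTable) -> ContingencyTable:
    """Add 0.5 to every cell iff any cell is zero; identity otherwise."""
    if t.has_zero_cell():
        return replace(t, a=t.a + 0.5, b=t.b + 0.5, c=t.c + 0.5, d=t.d + 0.5, corrected=True)
    return t


def prr(t: ContingencyTable) -> tuple[float, tuple[float, float]]:
    """Proportional reporting ratio with Woolf 95% CI.

    Undefined cells (a=0, c=0 or empty margins) yield NaN — an
    undefined-signal marker, not an error.
    """
    a, b, c, d = t.cells
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return math.nan, (math.nan, math.nan)
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_point = math.log(point)
    return point, (math.exp(log_point - Z95 * se), math.exp(log_point + Z95 * se))


def ror(t: ContingencyTable) -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio with Woolf 95% CI; NaN on zero cells."""
    a, b, c, d = t.cells
    if min(a, b, c, d) <= 0:
        return math.nan, (math.nan, math.nan)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_point = math.log(point)
    return point, (math.exp(log_point - Z95 * se), math.exp(log_point + Z95 * se))


def chi_square(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table; 0.0 for degenerate tables (a
    zero margin).  With ``yates`` the statistic uses the continuity-corrected
    difference ``max(0, |ad - bc| - n/2)``."""
    a, b, c, d = t.cells
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff * diff / denom


def compute_signal(
    t: ContingencyTable, yates: bool = False, correct_zero: bool = False
) -> SignalResult:
    """Full signal evaluation of one table.

    ``correct_zero`` applies the Haldane-Anscombe correction first (the
    stratified convention); without it, zero-cell tables are reported as
    no-signal since DE >= 3 excludes them anyway.
    """
    de = int(round(t.a))
    used = apply_haldane_anscombe(t) if correct_zero else t
    prr_point, prr_ci = prr(used)
    ror_point, ror_ci = ror(used)
    chi2 = chi_square(used, yates=yates)
    prr_signal = de >= 3 and prr_point >= 2 and chi2 >= 4
    ror_signal = de >= 3 and ror_ci[0] > 1
    return SignalResult(
        drug=t.drug,
        event=t.event,
        stratum=t.stratum,
        de=de,
        prr=prr_point,
        prr_ci95=prr_ci,
        ror=ror_point,
        ror_ci95=ror_ci,
        chi2=chi2,
        prr_signal=bool(prr_signal),
        ror_signal=bool(ror_signal),
        corrected=used.corrected,
    )


# ---------------------------------------------------------------------------
# stratified analysis

def mantel_haenszel_or(tables: Sequence[ContingencyTable]) -> float:
    """Mantel-Haenszel common odds ratio across strata,
    ``sum(a_k d_k / n_k) / sum(b_k c_k / n_k)``; zero denominators are
    resolved by applying the Haldane-Anscombe correction per stratum."""
    if len(tables) < 2:
        raise ValueError("need at least two strata")
    if any(t.n <= 0 for t in tables):
        raise ValueError("every stratum must contain reports")
    num = sum(t.a * t.d / t.n for t in tables)
    den = sum(t.b * t.c / t.n for t in tables)
    if den == 0 or num == 0:
        tables = [apply_haldane_anscombe(t) for t in tables]
        num = sum(t.a * t.d / t.n for t in tables)
        den = sum(t.b * t.c / t.n for t in tables)
    return num / den


def _expected_a(t: ContingencyTable, or_mh: float, tol: float = 1e-10) -> float:
    """Expected ``a`` cell under the common odds ratio: the root of
    ``R (r1 - E)(c1 - E) = E (n - r1 - c1 + E)`` inside the admissible range
    ``(max(0, r1 + c1 - n), min(r1, c1))``, solved in closed form."""
    r1 = t.a + t.b
    c1 = t.a + t.c
    n = t.n
    lo = max(0.0, r1 + c1 - n)
    hi = min(r1, c1)
    if abs(or_mh - 1.0) < 1e-14:
        return r1 * c1 / n
    qa = or_mh - 1.0
    qb = -(or_mh * (r1 + c1) + (n - r1 - c1))
    qc = or_mh * r1 * c1
    disc = qb * qb - 4 * qa * qc
    if disc < 0:
        if disc > -tol:
            disc = 0.0
        else:
            raise ValueError(f"no real root for stratum {t.stratum!r} ({t.drug}/{t.event})")
    sq = math.sqrt(disc)
    for root in ((-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)):
        if lo - tol < root < hi + tol:
            return min(max(root, lo), hi)
    raise ValueError(
        f"no admissible expected cell for stratum {t.stratum!r} ({t.drug}/{t.event}); "
        "table may be corrupted"
    )


def breslow_day_statistic(
    tables: Sequence[ContingencyTable], tarone: bool = False
) -> tuple[float, int, float, float]:
    """Breslow-Day homogeneity test across strata.

    Returns ``(statistic, df, p_value, or_mh)``.  Strata with a zero cell
    receive the Haldane-Anscombe correction first; ``tarone`` subtracts the
    Tarone adjustment term.  ``df`` is the number of strata minus one and the
    p-value comes from the upper chi-square tail.
    """
    if len(tables) < 2:
        raise ValueError("need at least two strata")
    corrected = [apply_haldane_anscombe(t) for t in tables]
    or_mh = mantel_haenszel_or(corrected)
    stat = 0.0
    sum_dev = 0.0
    sum_var = 0.0
    for t in corrected:
        e = _expected_a(t, or_mh)
        r1 = t.a + t.b
        c1 = t.a + t.c
        n = t.n
        inv_var = 1 / e + 1 / (r1 - e) + 1 / (c1 - e) + 1 / (n - r1 - c1 + e)
        var = 1 / inv_var
        dev = t.a - e
        stat += dev * dev / var
        sum_dev += dev
        sum_var += var
    if tarone:
        stat -= sum_dev * sum_dev / sum_var
        stat = max(stat, 0.0)
    df = len(tables) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p, or_mh


def breslow_day(
    tables: Sequence[ContingencyTable],
    tarone: bool = False,
    alpha: float = 0.05,
    stability_min: int = 20,
) -> HeterogeneityResult:
    """Sex-heterogeneity evaluation of one drug-event pair.

    ``tables`` are the raw (uncorrected) per-sex tables; DE counts come from
    their ``a`` cells, zero cells are corrected internally for estimation.
    The stability filter requires ``DE_male + DE_female`` strictly greater
    than ``stability_min``.
    """
    stat, df, p, or_mh = breslow_day_statistic(tables, tarone=tarone)
    by_stratum = {t.stratum: t for t in tables}
    t_m = by_stratum.get("M", tables[0])
    t_f = by_stratum.get("F", tables[-1])
    ror_m, ci_m = ror(apply_haldane_anscombe(t_m))
    ror_f, ci_f = ror(apply_haldane_anscombe(t_f))
    de_m = int(round(t_m.a))
    de_f = int(round(t_f.a))
    stability = (de_m + de_f) > stability_min
    significant = bool(stability and p < alpha)
    if significant and ror_f > ror_m:
        direction = "F_GT_M"
    elif significant and ror_m > ror_f:
        direction = "M_GT_F"
    else:
        direction = "NONE"
    return HeterogeneityResult(
        drug=t_m.drug,
        event=t_m.event,
        de_male=de_m,
        de_female=de_f,
        ror_male=ror_m,
        ror_male_ci95=ci_m,
        ror_female=ror_f,
        ror_female_ci95=ci_f,
        or_mh=or_mh,
        bd_stat=stat,
        df=df,
        p_value=p,
        stability_pass=bool(stability),
        significant=significant,
        direction=direction,
    )


def stratified_screen(
    sex_tables: Iterable[tuple[ContingencyTable, ContingencyTable]],
    alpha: float = 0.05,
    stability_min: int = 20,
    tarone: bool = False,
) -> list[HeterogeneityResult]:
    """Breslow-Day screen over (male table, female table) pairs.

    Every pair is returned with its sex-specific RORs; ``significant``
    requires the stability filter and p < ``alpha`` (no multiplicity
    adjustment).
    """
    results = []
    for t_m, t_f in sex_tables:
        results.append(
            breslow_day([t_m, t_f], tarone=tarone, alpha=alpha, stability_min=stability_min)
        )
    return results
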