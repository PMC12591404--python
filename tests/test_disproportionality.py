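"""Signal metrics, Haldane-Anscombe correction and the Breslow-Day screen."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from _oracles import chi2_oracle, prr_oracle, ror_oracle
from pvsex.contingency import ContingencyTable
from pvsex.disproportionality import (
    apply_haldane_anscombe,
    breslow_day,
    breslow_day_statistic,
    chi_square,
    compute_signal,
    mantel_haenszel_or,
    prr,
    ror,
    stratified_screen,
)


def T(a, b, c, d, stratum="ALL", drug="D", event="E"):
    return ContingencyTable(drug=drug, event=event, stratum=stratum, a=a, b=b, c=c, d=d)


class TestPointMetrics:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((10, 90, 100, 9900), 10.0),
            ((5, 95, 50, 950), 1.0),
            ((3, 997, 3, 99697), 99.7),
        ],
    )
    def test_prr_point(self, cells, expected):
        assert prr(T(*cells))[0] == pytest.approx(expected, rel=1e-12)

    def test_ror_point_and_woolf_ci(self):
        point, (lo, hi) = ror(T(10, 90, 100, 9900))
        assert point == pytest.approx(11.0, rel=1e-12)
        assert (lo, hi) == pytest.approx((5.5596, 21.7642), abs=2e-4)

    def test_ror_unit_when_odds_equal(self):
        assert ror(T(10, 20, 30, 60))[0] == pytest.approx(1.0, rel=1e-12)

    def test_chi_square_example(self):
        assert chi_square(T(10, 90, 100, 9900)) == pytest.approx(74.447, abs=1e-3)

    def test_chi_square_zero_at_independence(self):
        assert chi_square(T(10, 20, 30, 60)) == 0.0

    def test_yates_never_exceeds_plain(self):
        t = T(10, 90, 100, 9900)
        assert chi_square(t, yates=True) <= chi_square(t, yates=False)

    def test_degenerate_margin_gives_zero(self):
        assert chi_square(T(0, 0, 5, 5)) == 0.0

    def test_zero_cell_gives_nan_marker_not_crash(self):
        point, ci = ror(T(0, 50, 10, 940))
        assert math.isnan(point) and math.isnan(ci[0])
        assert math.isnan(prr(T(0, 100, 5, 995))[0])

    def test_brute_force_grid_equivalence(self):
        """PRR/ROR/chi-square match the brute-force oracle on every table
        with cells in 1..6 to 1e-12 relative."""
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            t = T(a, b, c, d)
            assert prr(t)[0] == pytest.approx(prr_oracle(a, b, c, d)[0], rel=1e-12)
            assert ror(t)[0] == pytest.approx(ror_oracle(a, b, c, d)[0], rel=1e-12)
            assert chi_square(t) == pytest.approx(chi2_oracle(a, b, c, d), rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    def test_ror_column_swap_inversion(self, a, b, c, d):
        assert ror(T(a, b, c, d))[0] * ror(T(b, a, d, c))[0] == pytest.approx(1.0, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.integers(1, 40), b=st.integers(5000, 20000),
        c=st.integers(10, 400), d=st.integers(50000, 200000),
    )
    def test_prr_approaches_ror_for_rare_events(self, a, b, c, d):
        """In the rare-event regime (both proportions < 1%) PRR and ROR agree
        within 2%."""
        t = T(a, b, c, d)
        if a / (a + b) >= 0.01 or c / (c + d) >= 0.01:
            return
        assert abs(prr(t)[0] - ror(t)[0]) / ror(t)[0] < 0.02


class TestHaldaneAnscombe:
    def test_zero_cell_corrected(self):
        t = apply_haldane_anscombe(T(0, 50, 10, 940))
        assert t.cells == (0.5, 50.5, 10.5, 940.5)
        assert t.corrected

    def test_no_zero_cell_identity(self):
        t = T(1, 1, 1, 1)
        assert apply_haldane_anscombe(t) is t

    def test_corrected_ror(self):
        point, _ = ror(apply_haldane_anscombe(T(0, 50, 10, 940)))
        assert point == pytest.approx(0.5 * 940.5 / (50.5 * 10.5), rel=1e-12)
        assert point == pytest.approx(0.887, abs=1e-3)


class TestSignalFlags:
    @pytest.mark.parametrize(
        "cells, prr_sig, ror_sig",
        [
            ((2, 8, 100, 9900), False, False),     # strong PRR but DE < 3
            ((10, 990, 1000, 99000), False, False),  # PRR below 2
            ((10, 90, 100, 9900), True, True),
        ],
    )
    def test_thresholds(self, cells, prr_sig, ror_sig):
        s = compute_signal(T(*cells))
        assert s.prr_signal is prr_sig and s.ror_signal is ror_sig

    def test_de_floor_is_strict(self):
        s = compute_signal(T(3, 7, 100, 9900))
        assert s.de == 3 and s.prr_signal

    def test_zero_cell_without_correction_is_no_signal(self):
        s = compute_signal(T(0, 10, 100, 9900))
        assert not s.prr_signal and not s.ror_signal and math.isnan(s.ror)

    def test_stratified_correction_flagged(self):
        s = compute_signal(T(0, 10, 100, 9900, stratum="M"), correct_zero=True)
        assert s.corrected and not math.isnan(s.ror)


class TestMantelHaenszel:
    def test_worked_example(self):
        tables = [T(20, 80, 100, 9900, "M"), T(5, 95, 100, 9900, "F")]
        assert mantel_haenszel_or(tables) == pytest.approx(247500 / 17500, rel=1e-12)

    def test_identical_strata_equal_stratum_or(self):
        t = T(10, 90, 100, 9900)
        stratum_or = ror(t)[0]
        for k in (2, 3, 5):
            assert mantel_haenszel_or([t] * k) == pytest.approx(stratum_or, rel=1e-12)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            mantel_haenszel_or([T(1, 2, 3, 4)])


class TestBreslowDay:
    def test_identical_strata_perfect_homogeneity(self):
        tables = [T(10, 90, 100, 9900, "M"), T(10, 90, 100, 9900, "F")]
        stat, df, p, _ = breslow_day_statistic(tables)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1 and p == pytest.approx(1.0, abs=1e-9)

    def test_heterogeneous_example_rejects(self):
        stat, df, p, _ = breslow_day_statistic(
            [T(20, 80, 100, 9900, "M"), T(5, 95, 100, 9900, "F")]
        )
        assert p < 0.05

    def test_permutation_null_agrees_with_chi2_tail(self):
        """Cross-check the analytic p-value against a label-permutation null
        on a moderate table."""
        rng = np.random.default_rng(0)
        t_m, t_f = T(30, 170, 300, 9700, "M"), T(18, 182, 310, 9690, "F")
        observed = breslow_day_statistic([t_m, t_f])[0]
        # permute: pool the drug/event indicators and resplit by sex margins
        n_m, n_f = int(t_m.n), int(t_f.n)
        pooled = np.zeros((n_m + n_f, 2), dtype=int)
        k = 0
        for t in (t_m, t_f):
            for (drug, event), count in zip(
                [(1, 1), (1, 0), (0, 1), (0, 0)], [int(t.a), int(t.b), int(t.c), int(t.d)]
            ):
                pooled[k : k + count] = (drug, event)
                k += count
        exceed = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = rng.permutation(n_m + n_f)
            grp_m, grp_f = pooled[perm[:n_m]], pooled[perm[n_m:]]
            ts = []
            for stratum, grp in (("M", grp_m), ("F", grp_f)):
                a = int(((grp[:, 0] == 1) & (grp[:, 1] == 1)).sum())
                b = int(((grp[:, 0] == 1) & (grp[:, 1] == 0)).sum())
                c = int(((grp[:, 0] == 0) & (grp[:, 1] == 1)).sum())
                d = int(((grp[:, 0] == 0) & (grp[:, 1] == 0)).sum())
                ts.append(T(max(a, 0), b, c, d, stratum))
            exceed += breslow_day_statistic(ts)[0] >= observed
        p_perm = exceed / n_perm
        p_analytic = breslow_day_statistic([t_m, t_f])[2]
        assert abs(p_perm - p_analytic) < 3 * math.sqrt(p_analytic * (1 - p_analytic) / n_perm) + 0.02

    def test_tarone_never_exceeds_uncorrected(self):
        tables = [T(20, 80, 100, 9900, "M"), T(5, 95, 100, 9900, "F")]
        assert breslow_day_statistic(tables, tarone=True)[0] <= breslow_day_statistic(tables)[0]

    @settings(max_examples=60, deadline=None)
    @given(
        cells=st.tuples(*[st.integers(1, 150) for _ in range(8)]),
    )
    def test_expected_cell_reconstructs_common_or(self, cells):
        """The fitted expected cell reproduces the Mantel-Haenszel OR from
        its own 2x2 reconstruction."""
        tables = [T(*cells[:4], "M"), T(*cells[4:], "F")]
        or_mh = mantel_haenszel_or(tables)
        from pvsex.disproportionality import _expected_a

        for t in tables:
            e = _expected_a(t, or_mh)
            r1, c1, n = t.a + t.b, t.a + t.c, t.n
            rebuilt = (e * (n - r1 - c1 + e)) / ((r1 - e) * (c1 - e))
            assert rebuilt == pytest.approx(or_mh, rel=1e-8)

    def test_matches_statsmodels(self):
        """Independent cross-check against statsmodels' StratifiedTable."""
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(7)
        for _ in range(50):
            cells = rng.integers(1, 300, size=8)
            tables = [T(*cells[:4], "M"), T(*cells[4:], "F")]
            arr = np.stack([np.array([[t.a, t.b], [t.c, t.d]]) for t in tables], axis=2)
            res = StratifiedTable(arr.astype(float)).test_equal_odds()
            stat, _, p, _ = breslow_day_statistic(tables)
            assert stat == pytest.approx(res.statistic, rel=1e-9)
            assert p == pytest.approx(res.pvalue, rel=1e-9, abs=1e-12)


class TestStratifiedScreen:
    def test_stability_filter_is_strict(self):
        # DE_male + DE_female == 20 must fail; 21 passes
        at_20 = breslow_day([T(12, 88, 100, 9900, "M"), T(8, 92, 100, 9900, "F")])
        assert at_20.de_male + at_20.de_female == 20 and not at_20.stability_pass
        at_21 = breslow_day([T(13, 87, 100, 9900, "M"), T(8, 92, 100, 9900, "F")])
        assert at_21.stability_pass

    def test_direction_labels(self):
        res = breslow_day([T(50, 450, 100, 9900, "M"), T(250, 250, 100, 9900, "F")])
        assert res.significant and res.direction == "F_GT_M"
        res2 = breslow_day([T(250, 250, 100, 9900, "M"), T(50, 450, 100, 9900, "F")])
        assert res2.direction == "M_GT_F"
        null = breslow_day([T(10, 90, 100, 9900, "M"), T(10, 90, 100, 9900, "F")])
        assert null.direction == "NONE"

    def test_screen_returns_every_pair(self):
        pairs = [
            (T(30, 70, 100, 9900, "M", drug="A"), T(40, 60, 100, 9900, "F", drug="A")),
            (T(3, 97, 100, 9900, "M", drug="B"), T(4, 96, 100, 9900, "F", drug="B")),
        ]
        results = stratified_screen(pairs)
        assert len(results) == 2
        assert [r.drug for r in results] == ["A", "B"]
        assert not results[1].stability_pass

    def test_zero_cell_stratum_handled_via_correction(self):
        res = breslow_day([T(0, 100, 100, 9900, "M"), T(30, 70, 100, 9900, "F")])
        assert math.isfinite(res.bd_stat) and math.isfinite(res.p_value)
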