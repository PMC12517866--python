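"""ROR and BCPNN IC estimators, the dual signal rule, and 2x2 construction."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from faerspv.cohort import Cohort
from faerspv.disproportionality import (ContingencyTable,
                                        DisproportionalityModel, MIN_CASES,
                                        build_table, decide_signal, estimate,
                                        information_component, ror)
from _oracles import ic_oracle, ror_oracle


def random_tables(n, seed, low=1, high=400):
    rng = np.random.default_rng(seed)
    while True:
        cells = rng.integers(low, high, size=(n, 4))
        if (cells > 0).all():
            return [ContingencyTable(*map(int, row)) for row in cells]


class TestRor:
    def test_balanced_table_is_unity_with_log_symmetric_ci(self):
        point, lo, hi, defined = ror(ContingencyTable(5, 5, 5, 5))
        assert defined and point == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_example_table_point_value(self):
        point, lo, hi, _ = ror(ContingencyTable(10, 90, 100, 9900))
        assert point == pytest.approx(11.0, abs=1e-12)
        exp_point, exp_lo, exp_hi = ror_oracle(10, 90, 100, 9900)
        assert lo == pytest.approx(exp_lo, rel=1e-9)
        assert hi == pytest.approx(exp_hi, rel=1e-9)

    def test_agrees_with_high_precision_oracle_and_scipy(self):
        """200 random tables vs exact-rational recomputation and the sample
        odds ratio from scipy's exact-test machinery."""
        from scipy.stats.contingency import odds_ratio as scipy_or

        for table in random_tables(200, seed=7):
            point, lo, hi, _ = ror(table)
            exp_point, exp_lo, exp_hi = ror_oracle(table.a, table.b,
                                                   table.c, table.d)
            assert point == pytest.approx(exp_point, rel=1e-9)
            assert lo == pytest.approx(exp_lo, rel=1e-9)
            assert hi == pytest.approx(exp_hi, rel=1e-9)
            sample = scipy_or([[table.a, table.b], [table.c, table.d]],
                              kind="sample").statistic
            assert point == pytest.approx(sample, rel=1e-9)

    def test_swap_symmetries(self):
        for t in random_tables(50, seed=8):
            fwd, *_ = ror(t)
            swapped, *_ = ror(ContingencyTable(t.d, t.c, t.b, t.a))
            inverse, *_ = ror(ContingencyTable(t.b, t.a, t.d, t.c))
            assert fwd == pytest.approx(swapped, rel=1e-12)
            assert fwd == pytest.approx(1.0 / inverse, rel=1e-12)

    def test_monotone_in_a(self):
        for t in random_tables(50, seed=9):
            bigger, *_ = ror(ContingencyTable(t.a + 1, t.b, t.c, t.d))
            assert bigger > ror(t)[0]

    def test_zero_cell_yields_marker_not_exception(self):
        point, lo, hi, defined = ror(ContingencyTable(0, 10, 5, 100))
        assert not defined and math.isnan(point)
        point_h, *_, defined_h = ror(ContingencyTable(0, 10, 5, 100),
                                     zero_cell="haldane")
        assert defined_h and point_h > 0

    def test_null_ci_coverage(self):
        """Woolf interval covers the null OR=1 in ~95% of simulated tables."""
        rng = np.random.default_rng(42)
        probs = np.array([0.02, 0.08, 0.18, 0.72])  # independent margins
        covered = 0
        reps = 2000
        for counts in rng.multinomial(4000, probs, size=reps):
            if (counts == 0).any():
                reps -= 1
                continue
            _, lo, hi, _ = ror(ContingencyTable(*map(int, counts)))
            covered += lo <= 1.0 <= hi
        assert 0.93 <= covered / reps <= 0.97


class TestInformationComponent:
    def test_independence_table_gives_zero(self):
        ic, *_ = information_component(ContingencyTable(1, 9, 99, 891))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_point_value_matches_high_precision_oracle(self):
        ic, *_ = information_component(ContingencyTable(10, 90, 100, 9900))
        assert ic == pytest.approx(math.log2(10 * 10100 / (100 * 110)),
                                   abs=1e-12)
        for t in random_tables(200, seed=10):
            ic, *_ = information_component(t)
            assert ic == pytest.approx(ic_oracle(t.a, t.b, t.c, t.d), rel=1e-9)

    @pytest.mark.parametrize("variance", ["bcpnn", "delta"])
    def test_interval_brackets_point(self, variance):
        for t in random_tables(100, seed=11):
            ic, lo, hi, _ = information_component(t, variance)
            assert lo < ic < hi

    def test_monotone_in_a_in_sparse_regime(self):
        """One extra co-report strictly raises the IC whenever the co-report
        count does not dominate its margins (a <= min(b, c)) — the regime of
        case/non-case data, where both drug and event are minorities."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = int(rng.integers(1, 50))
            b, c = (int(rng.integers(a, 500)) for _ in range(2))
            d = int(rng.integers(1, 5000))
            t = ContingencyTable(a, b, c, d)
            bigger, *_ = information_component(
                ContingencyTable(t.a + 1, t.b, t.c, t.d))
            assert bigger > information_component(t)[0]

    def test_zero_a_falls_back_to_shrinkage_with_flag(self):
        ic, lo, hi, shrunk = information_component(ContingencyTable(0, 50, 100, 5000))
        assert shrunk and np.isfinite(ic) and lo < ic < hi

    def test_converges_to_log2_of_planted_reporting_ratio(self):
        """IC estimates log2 of the observed/expected reporting ratio; its
        error shrinks as the table grows under a planted ratio."""
        theta = 2.0
        pe, pc = 0.1, 0.1
        p_a = theta * pe * pc
        probs = np.array([p_a, pe - p_a, pc - p_a, 1 - pe - pc + p_a])
        rng = np.random.default_rng(13)
        limit = math.log2(theta)  # expected co-reporting ratio is theta here
        med_err = []
        for n in [1_000, 10_000, 100_000]:
            errs = [abs(information_component(
                        ContingencyTable(*map(int, counts)))[0] - limit)
                    for counts in rng.multinomial(n, probs, size=20)]
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[-1]
        assert med_err[-1] < 0.05


class TestDecideSignal:
    def test_headline_style_estimate_is_signal(self):
        est = estimate(ContingencyTable(8211, 100000, 150000, 5000000))
        # a large, clearly disproportionate table fires both arms
        dec = decide_signal(est)
        assert dec.ror_positive and dec.ic_positive and dec.signal

    def test_count_rule_boundary(self):
        est = estimate(ContingencyTable(9, 10, 100, 10000))
        dec = decide_signal(est)
        assert est.ror_ci_low > 1 and not dec.signal
        assert "fewer than 10 cases" in dec.reason
        est10 = estimate(ContingencyTable(10, 10, 100, 10000))
        assert decide_signal(est10).signal

    def test_conjunction_requires_both_methods(self):
        from faerspv.disproportionality import SignalEstimate

        dec = decide_signal(SignalEstimate(
            ror=2.05, ror_ci_low=2.02, ror_ci_high=2.08,
            ic=0.96, ic025=0.93, ic975=0.99, n_cases=8211))
        assert dec.signal
        dec2 = decide_signal(SignalEstimate(
            ror=1.8, ror_ci_low=1.5, ror_ci_high=2.2,
            ic=0.2, ic025=-0.1, ic975=0.5, n_cases=50))
        assert dec2.ror_positive and not dec2.ic_positive and not dec2.signal

    def test_undefined_estimate_never_signals(self):
        dec = decide_signal(estimate(ContingencyTable(0, 10, 100, 1000)))
        assert not dec.signal and dec.reason == "undefined estimate"

    def test_null_dual_criterion_is_conservative(self):
        """Under independence with expected a~20, the ROR/IC conjunction
        fires well below its nominal one-sided rate."""
        rng = np.random.default_rng(21)
        pe, pc = 0.05, 0.08
        probs = np.array([pe * pc, pe * (1 - pc), (1 - pe) * pc,
                          (1 - pe) * (1 - pc)])
        n = int(20 / (pe * pc))
        fired = 0
        for counts in rng.multinomial(n, probs, size=1000):
            dec = decide_signal(estimate(ContingencyTable(*map(int, counts))))
            fired += dec.signal
        assert fired / 1000 < 0.05


def _cohort_from_flags(exposed: list[bool], case: list[bool]) -> Cohort:
    flags = pd.DataFrame({
        "sex": "F", "age_years": 50.0,
        "drug": exposed, "case": case,
    }, index=pd.Index(range(1, len(exposed) + 1), name="primaryid"))
    reac = pd.DataFrame({"primaryid": [], "pt_code": [], "pt": []})
    return Cohort(flags=flags, reactions=reac, meddra=None,
                  target_soc=0, drugs=("drug",))


class TestBuildTable:
    def test_hand_enumerated_universe(self):
        """10 reports, 4 exposed, 3 cases, 2 overlapping -> (2,2,1,5)."""
        exposed = [True, True, True, True] + [False] * 6
        case = [True, True, False, False, True] + [False] * 5
        t = build_table(_cohort_from_flags(exposed, case), "drug")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)
        assert t.n == 10

    def test_empty_exposure_degenerate(self):
        t = build_table(_cohort_from_flags([False] * 5, [True, False, False,
                                                         False, False]), "drug")
        assert t.a == 0 and t.b == 0 and t.n == 5

    def test_margins_identities(self, fixture_cohort):
        demo, kids, cohort = fixture_cohort
        for drug in cohort.drugs:
            t = build_table(cohort, drug)
            assert t.n == cohort.n_reports
            assert t.drug_margin == int(cohort.flags[drug].sum())
            assert t.event_margin == int(cohort.flags["case"].sum())


class TestModelResults:
    def test_results_sorted_and_complete(self, fixture_cohort):
        demo, kids, cohort = fixture_cohort
        res = DisproportionalityModel.from_cohort(cohort, pt_level=True).fit()
        assert res.n_tests == len(res.frame)
        rors = res.frame["ror"].dropna().tolist()
        assert rors == sorted(rors, reverse=True)
        soc_rows = res.frame[res.frame["event"].str.startswith("SOC:")]
        assert set(soc_rows["drug"]) == set(cohort.drugs)

    def test_summary_and_tsv_round_trip(self, fixture_cohort, tmp_path):
        demo, kids, cohort = fixture_cohort
        res = DisproportionalityModel.from_cohort(cohort).fit()
        text = res.summary()
        assert "atorvastatin" in text and "IC025" in text
        res.to_tsv(tmp_path / "signals.tsv")
        back = pd.read_csv(tmp_path / "signals.tsv", sep="\t")
        assert list(back.columns) == res.TSV_COLUMNS

    def test_ic_variance_choice_recorded(self, fixture_cohort):
        demo, kids, cohort = fixture_cohort
        res = DisproportionalityModel.from_cohort(cohort).fit(ic_variance="delta")
        assert res.ic_variance == "delta"
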