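import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import oracles
from pvsignal import signal_stats
from pvsignal.signal_stats import (
    ContingencyTable,
    FrequentistStats,
    Thresholds,
    bonferroni,
    build_contingency,
    classify,
    ic_stats,
    p_value,
    prr_stats,
    ror_stats,
)
from pvsignal.vocab import TargetEventSet

cells = st.integers(min_value=0, max_value=2000)


class TestBuildContingency:
    def test_hand_enumerated_fixture(self, toy_cases):
        t = build_contingency(
            toy_cases, "DRUGX", TargetEventSet.from_pts("y", ["EVENTY"])
        )
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_absent_drug_gives_empty_row(self, toy_cases):
        t = build_contingency(
            toy_cases, "NOSUCH", TargetEventSet.from_pts("y", ["EVENTY"])
        )
        assert (t.a, t.b) == (0, 0)
        assert t.c + t.d == t.n == 6

    def test_duplicate_ps_listing_counts_once(self, toy_cases):
        extra = toy_cases.drugs.iloc[[0]]
        toy_cases.drugs = pd.concat([toy_cases.drugs, extra], ignore_index=True)
        t = build_contingency(
            toy_cases, "DRUGX", TargetEventSet.from_pts("y", ["EVENTY"])
        )
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_non_ps_roles_excluded(self, toy_cases):
        toy_cases.drugs.loc[0, "role_cod"] = "SS"  # P1 no longer PS for DRUGX
        t = build_contingency(
            toy_cases, "DRUGX", TargetEventSet.from_pts("y", ["EVENTY"])
        )
        assert (t.a, t.b) == (1, 1)

    def test_empty_universe_is_hard_error(self, toy_cases):
        toy_cases.drugs["canonical"] = None
        with pytest.raises(ValueError, match="universe"):
            build_contingency(
                toy_cases, "DRUGX", TargetEventSet.from_pts("y", ["EVENTY"]),
                universe="study_drugs_only",
            )

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestRor:
    def test_closed_form_example(self):
        ror, lo, hi = ror_stats(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0, rel=1e-12)
        # 1.96*sqrt(1/10+1/90+1/100+1/9900) = 0.68238 on ln 11
        assert lo == pytest.approx(5.559, abs=2e-3)
        assert hi == pytest.approx(21.77, abs=2e-2)

    def test_uniform_table_symmetric_about_one(self):
        ror, lo, hi = ror_stats(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0, rel=1e-10)

    def test_zero_cell_uses_continuity_correction(self):
        got = ror_stats(ContingencyTable(0, 10, 10, 100))
        want = oracles.ror_oracle(0, 10, 10, 100)
        assert got == pytest.approx(want, rel=1e-12)
        assert got[0] == pytest.approx((0.5 * 100.5) / (10.5 * 10.5), rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_transpose_and_inversion_invariance(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ror = ror_stats(t)[0]
        assert ror == pytest.approx(ror_stats(ContingencyTable(d, c, b, a))[0],
                                    rel=1e-9)
        inv = ror_stats(ContingencyTable(b, a, d, c))[0]
        assert ror * inv == pytest.approx(1.0, rel=1e-9)


class TestPrr:
    def test_formula_example_and_scipy_yates_agreement(self):
        prr, chi2 = prr_stats(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0, rel=1e-12)
        assert chi2 == pytest.approx(66.33, abs=5e-3)
        ref = scipy.stats.chi2_contingency(
            [[10, 90], [100, 9900]], correction=True
        ).statistic
        assert chi2 == pytest.approx(ref, rel=1e-12)

    def test_no_association(self):
        prr, chi2 = prr_stats(ContingencyTable(5, 5, 5, 5))
        assert prr == 1.0 and chi2 == 0.0

    def test_zero_margin_flagged_undefined(self):
        prr, chi2 = prr_stats(ContingencyTable(2, 0, 0, 0))
        assert math.isnan(prr) and math.isnan(chi2)

    def test_yates_floor_at_zero(self):
        # |ad-bc| = 2 <= n/2 = 3 -> floored
        assert prr_stats(ContingencyTable(2, 1, 2, 1))[1] == 0.0

    def test_rare_event_agreement_with_ror(self):
        # PRR -> ROR as the event becomes rare in both arms
        for a, b, c, d in [(5, 10_000, 50, 100_000), (3, 50_000, 20, 400_000)]:
            ror = ror_stats(ContingencyTable(a, b, c, d))[0]
            prr = prr_stats(ContingencyTable(a, b, c, d))[0]
            assert ror / prr == pytest.approx(1.0, abs=2e-3)


class TestIc:
    def test_formula_example(self):
        ic, ic025 = ic_stats(ContingencyTable(10, 90, 100, 9900))
        assert ic == pytest.approx(math.log2(10.5 / (1.0891089108910892 + 0.5)),
                                   rel=1e-12)
        assert ic == pytest.approx(2.724, abs=1e-3)
        assert ic025 == pytest.approx(1.647, abs=1e-3)

    def test_degenerate_zero_table_centers_at_zero(self):
        ic, _ = ic_stats(ContingencyTable(0, 0, 0, 1))
        assert ic == 0.0

    def test_doubling_cells_moves_shrunken_ratio_toward_raw(self):
        a, b, c, d = 6, 30, 40, 800
        raw = a * (a + b + c + d) / ((a + b) * (a + c))  # constant under doubling
        prev_gap = None
        for k in (1, 2, 4, 8, 16):
            ic, _ = ic_stats(ContingencyTable(a * k, b * k, c * k, d * k))
            gap = abs(2**ic - raw)
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic025_strictly_below_ic(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ic, ic025 = ic_stats(ContingencyTable(a, b, c, d))
        assert ic025 < ic


class TestFisher:
    def test_independent_table(self):
        assert p_value(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_perfect_separation_exact_value(self):
        # both extreme tables are equally probable: p = 2 / C(20,10)
        assert p_value(ContingencyTable(10, 0, 0, 10)) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-12
        )

    def test_row_swap_symmetry(self):
        p1 = p_value(ContingencyTable(7, 2, 5, 11))
        p2 = p_value(ContingencyTable(5, 11, 7, 2))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 60, 4)
            ours = p_value(ContingencyTable(int(a), int(b), int(c), int(d)))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            ours = p_value(ContingencyTable(a, b, c, d))
            assert ours == pytest.approx(
                oracles.fisher_exact_oracle(a, b, c, d), abs=1e-10
            )


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], 12) == [pytest.approx(0.12)]
        assert bonferroni([0.2], 12) == [1.0]
        assert bonferroni([0.3], 1) == [pytest.approx(0.3)]  # m=1: identity

    def test_never_decreases_and_caps_at_one(self):
        ps = [0.0, 1e-8, 0.04, 0.5, 1.0]
        adj = bonferroni(ps, 5)
        assert all(x >= p for x, p in zip(adj, ps))
        assert max(adj) <= 1.0

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestClassify:
    def _stats(self, **kw):
        base = dict(a=14, ror=2.0, ror_lo=1.18, ror_hi=3.37, prr=2.0,
                    chi2=6.95, ic=1.0, ic025=0.16, ebgm=1.99, ebgm05=1.18,
                    p_raw=0.001, p_adj=0.014)
        base.update(kw)
        return FrequentistStats(**base)

    def test_reported_positive_example(self):
        # a=14 with ROR 95% CI lower bound 1.18 > 1 -> positive signal
        v = classify(self._stats())
        assert v.ror_pos and v.min_case_ok and v.overall

    def test_minimum_count_gate(self):
        v = classify(self._stats(a=2))
        assert not v.min_case_ok and not v.overall

    def test_all_negative_methods(self):
        v = classify(self._stats(a=10, ror_lo=0.8, prr=1.0, chi2=0.5,
                                 ic025=-0.5, ebgm05=0.9))
        assert not any([v.ror_pos, v.prr_pos, v.ic_pos, v.ebgm_pos])
        assert not v.overall

    def test_undefined_method_counts_negative(self):
        v = classify(self._stats(prr=math.nan, chi2=math.nan, ror_lo=0.5,
                                 ic025=-1.0, ebgm05=0.5))
        assert not v.prr_pos and not v.overall

    def test_all_rule_requires_all_four(self):
        thr = Thresholds(rule="all")
        v = classify(self._stats(ebgm05=1.18), thr)  # ebgm criterion fails
        assert not v.overall
        v2 = classify(self._stats(ebgm05=2.5, ic025=0.2), thr)
        assert v2.overall

    def test_monotone_in_case_count(self):
        # raising a with ratios fixed can only turn the verdict on, never off
        low = classify(self._stats(a=3))
        high = classify(self._stats(a=300))
        assert high.overall >= low.overall


def test_randomized_grid_matches_brute_force_oracles():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 500, 4))
        if a + b + c + d == 0:
            continue
        t = ContingencyTable(a, b, c, d)
        assert ror_stats(t) == pytest.approx(oracles.ror_oracle(a, b, c, d),
                                             rel=1e-12)
        ic = ic_stats(t)
        assert ic == pytest.approx(oracles.ic_oracle(a, b, c, d), rel=1e-12)
        if a + b and c + d and a + c and b + d:
            assert prr_stats(t) == pytest.approx(
                oracles.prr_chi2_oracle(a, b, c, d), rel=1e-12
            )
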