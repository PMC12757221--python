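"""Disproportionality statistics against independent oracles and properties."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from faerspv.signal import (
    ContingencyTable,
    build_contingency,
    compute_signal_table,
    rank_signals,
    score_signal,
)


def brute_force_scores(a, b, c, d):
    """Direct textbook evaluation of the four algorithms, kept deliberately
    independent of the implementation (chi-square via scipy)."""
    n = a + b + c + d
    ror = (a / c) / (b / d)
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = stats.chi2_contingency([[a, b], [c, d]], correction=False)[0]
    ebgm = a * n / ((a + b) * (a + c))
    ic = math.log(ebgm, 2)
    v = 1 / a + 1 / b + 1 / c + 1 / d
    z, z1 = 1.959963984540054, 1.6448536269514722
    return {
        "ror": ror,
        "ror_low": ror * math.exp(-z * math.sqrt(v)),
        "ror_high": ror * math.exp(z * math.sqrt(v)),
        "prr": prr,
        "chi2": chi2,
        "ebgm": ebgm,
        "ebgm05": ebgm * math.exp(-z1 * math.sqrt(v)),
        "ic": ic,
        "ic025": ic - z * math.sqrt(v) / math.log(2),
    }


class TestScoreSignal:
    def test_uniform_table_is_exactly_null(self):
        s = score_signal(ContingencyTable(25, 25, 25, 25))
        assert s.ror == 1 and s.prr == 1 and s.ebgm == 1
        assert s.ic == 0 and s.chi2 == 0

    def test_hand_checked_example(self):
        s = score_signal(ContingencyTable(10, 90, 100, 9900))
        assert s.ror == pytest.approx(11.0)
        assert s.prr == pytest.approx(10.0)
        assert s.ebgm == pytest.approx(9.1818, abs=1e-4)
        assert s.ic == pytest.approx(3.199, abs=1e-3)
        assert s.chi2 == pytest.approx(74.45, abs=0.01)
        assert s.ror_ci95[0] == pytest.approx(5.56, abs=0.01)
        assert s.ror_ci95[1] == pytest.approx(21.77, abs=0.01)

    def test_matches_brute_force_on_all_small_tables(self):
        """All 6^4 tables with cells 1..6 agree with the independent oracle."""
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            s = score_signal(ContingencyTable(a, b, c, d))
            expect = brute_force_scores(a, b, c, d)
            for got, want in [
                (s.ror, expect["ror"]), (s.ror_ci95[0], expect["ror_low"]),
                (s.ror_ci95[1], expect["ror_high"]), (s.prr, expect["prr"]),
                (s.chi2, expect["chi2"]), (s.ebgm, expect["ebgm"]),
                (s.ebgm05, expect["ebgm05"]), (s.ic, expect["ic"]),
                (s.ic025, expect["ic025"]),
            ]:
                assert got == pytest.approx(want, rel=1e-12)

    def test_zero_cell_yields_no_bounds_and_no_flags(self):
        s = score_signal(ContingencyTable(0, 10, 10, 10))
        assert s.ror_ci95 is None and s.ebgm05 is None
        assert not (s.ror_signal or s.prr_signal or s.mgps_signal or s.bcpnn_signal)
        assert "zero cell" in s.reason

    def test_zero_marginal_yields_structured_absence(self):
        s = score_signal(ContingencyTable(0, 0, 10, 10))
        assert s.ror is None and s.chi2 is None
        assert s.reason == "zero marginal"

    def test_optional_continuity_correction(self):
        s = score_signal(ContingencyTable(5, 0, 10, 100), continuity_correction=True)
        assert s.ror is not None and s.ror_ci95 is not None

    @given(st.tuples(*[st.integers(1, 1000)] * 4))
    @settings(derandomize=True, max_examples=200)
    def test_ror_at_least_prr_when_above_one(self, cells):
        s = score_signal(ContingencyTable(*cells))
        if s.ror > 1:
            assert s.ror >= s.prr - 1e-12

    @given(st.integers(1, 50), st.tuples(*[st.integers(100, 5000)] * 3))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_target_count(self, a, bcd):
        """More target-event reports for the drug means stronger statistics.

        ROR and PRR are monotone in a unconditionally; the observed/expected
        ratio (EBGM, IC) is monotone only where the drug and event margins
        dwarf a — the spontaneous-reporting regime this property targets.
        """
        b, c, d = bcd
        prev = score_signal(ContingencyTable(a, b, c, d))
        nxt = score_signal(ContingencyTable(a + 1, b, c, d))
        assert nxt.ror > prev.ror and nxt.prr > prev.prr
        assert nxt.ebgm > prev.ebgm and nxt.ic > prev.ic

    @given(st.tuples(*[st.integers(1, 1000)] * 4))
    @settings(derandomize=True, max_examples=200)
    def test_ic_is_log2_of_ebgm(self, cells):
        s = score_signal(ContingencyTable(*cells))
        assert s.ic == pytest.approx(math.log2(s.ebgm), rel=1e-12)


class TestCalibrationUnderNull:
    def test_null_drug_flag_rate_within_band(self):
        """1,000 simulated null drugs: the ROR-signal rate stays below 5%.

        The criterion (lower 95% bound > 1) is one-sided at nominal ~2.5%;
        with 1,000 replicates the Monte-Carlo band keeps the rate under 5%.
        """
        rng = np.random.default_rng(2024)
        n_exposed, n_other, p = 2000, 40_000, 0.02
        flags = 0
        for _ in range(1000):
            a = rng.binomial(n_exposed, p)
            c = rng.binomial(n_other, p)
            s = score_signal(ContingencyTable(int(a), n_exposed - int(a), int(c), n_other - int(c)))
            flags += bool(s.ror_signal)
        assert flags / 1000 <= 0.05


class TestContingencyAndRanking:
    def _corpus(self):
        from faerspv.faers_io import CaseReport, DrugEntry

        def rep(i, drug, pt):
            return CaseReport(
                primaryid=str(i), caseid=str(i),
                drugs=[DrugEntry(drugname_raw=drug, role="PS", drugname_norm=drug)],
                reaction_pts={pt},
            )

        return [
            rep(1, "drugx", "Hepatotoxicity"), rep(2, "drugx", "Nausea"),
            rep(3, "drugy", "Hepatotoxicity"), rep(4, "drugy", "Rash"),
        ]

    def test_enumerated_counts(self):
        t = build_contingency(self._corpus(), "drugx", "Hepatotoxicity")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_absent_event_gives_zero_target_column(self):
        t = build_contingency(self._corpus(), "drugx", "Agranulocytosis")
        assert t.a == 0 and t.c == 0

    def test_absent_drug_gives_zero_exposure_rows(self):
        t = build_contingency(self._corpus(), "drugz", "Hepatotoxicity")
        assert t.a == 0 and t.b == 0 and t.n == 4

    def test_tables_match_truth_ledger(self, small_analysis):
        cfg, reports, _, truth = small_analysis
        for drug in truth.drugs:
            t = build_contingency(reports, drug, cfg.target_pt)
            assert (t.a, t.b, t.c, t.d) == truth.contingency(drug)

    def test_ranking_orders_by_descending_ror(self):
        df = pd.DataFrame(
            {
                "drug": ["a", "b"], "atc_code": ["", ""], "cases": [50, 50],
                "ror": [5.0, 10.0], "ror_ci_low": [2.0, 4.0],
                "ror_ci_high": [10.0, 20.0], "prr": [4, 9], "chi2": [50, 80],
                "ebgm": [4, 9], "ebgm05": [2, 4], "ic": [2, 3], "ic025": [1, 2],
                "ror_signal": [True, True], "prr_signal": [True, True],
                "mgps_signal": [True, True], "bcpnn_signal": [True, True],
            }
        )
        ranked = rank_signals(df)
        assert list(ranked["drug"]) == ["b", "a"]
        assert list(ranked["rank"]) == [1, 2]

    def test_non_signal_drug_excluded(self):
        df = pd.DataFrame(
            {
                "drug": ["a", "b"], "atc_code": ["", ""], "cases": [50, 2],
                "ror": [5.0, 10.0], "ror_ci_low": [2.0, 4.0],
                "ror_ci_high": [10.0, 20.0], "prr": [4, 9], "chi2": [50, 80],
                "ebgm": [4, 9], "ebgm05": [2, 4], "ic": [2, 3], "ic025": [1, 2],
                "ror_signal": [True, False], "prr_signal": [True, True],
                "mgps_signal": [True, True], "bcpnn_signal": [True, True],
            }
        )
        assert list(rank_signals(df)["drug"]) == ["a"]

    def test_injected_drug_ranks_first_among_nulls(self, recovery_run):
        ranked = rank_signals(recovery_run["score_table"])
        assert ranked.iloc[0]["drug"] == "riskdrug05"  # the true-ROR-10 drug
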