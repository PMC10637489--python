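"""Disproportionality estimators, criteria, screening, ranking, novelty."""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerskit import cohort
from faerskit.disprop import (
    ContingencyTable,
    apply_criteria,
    build_contingency,
    compute_signal_stats,
    flag_unexpected,
    pt_signal_table,
    rank_and_filter,
    screen_signals,
    soc_level_signals,
)


class TestEstimators:
    def test_null_table(self):
        r = compute_signal_stats(ContingencyTable(5, 5, 5, 5))
        assert r.ror == 1.0 and r.prr == 1.0 and r.chi2 == 0.0
        assert r.ic == 0.0 and r.ebgm == 1.0
        flags = apply_criteria(r)
        assert not (flags.ror_pos or flags.prr_pos or flags.bcpnn_pos
                    or flags.mgps_pos or flags.all_four)

    def test_frozen_example_values(self):
        """Direct-arithmetic oracle for the (10, 90, 100, 9800) table:
        ROR = 10*9800/(90*100), PRR = 10*9900/(100*100),
        chi2 = (10*9800-90*100)^2 * 10000 / (100*9900*110*9890),
        IC = log2(10*10000/(110*100)), EBGM = 2**IC,
        interval spread = sqrt(1/10+1/90+1/100+1/9800)."""
        r = compute_signal_stats(ContingencyTable(10, 90, 100, 9800))
        assert r.ror == pytest.approx(10.889, abs=5e-4)
        assert r.ror_lo == pytest.approx(5.503, abs=5e-3)
        assert r.ror_hi == pytest.approx(21.545, abs=5e-3)
        assert r.prr == pytest.approx(9.900, abs=5e-4)
        assert r.chi2 == pytest.approx(73.55, abs=5e-3)
        assert r.ic == pytest.approx(3.184, abs=5e-4)
        assert r.ebgm == pytest.approx(9.091, abs=5e-4)
        assert r.ebgm05 == pytest.approx(4.595, abs=5e-4)

    def test_zero_cell_yields_nan_sentinels(self):
        r = compute_signal_stats(ContingencyTable(0, 100, 50, 9000))
        assert math.isnan(r.ror) and math.isnan(r.ror_lo)
        assert math.isnan(r.ic) and math.isnan(r.ebgm05)
        flags = apply_criteria(r)
        assert not flags.all_four

    def test_haldane_correction_optional(self):
        r = compute_signal_stats(ContingencyTable(0, 100, 50, 9000), haldane=0.5)
        assert not math.isnan(r.ror)

    @given(
        a=st.integers(1, 500), b=st.integers(1, 5000),
        c=st.integers(1, 5000), d=st.integers(1, 100000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_two_to_the_ic_equals_ebgm(self, a, b, c, d):
        r = compute_signal_stats(ContingencyTable(a, b, c, d))
        assert 2.0 ** r.ic == pytest.approx(r.ebgm, rel=1e-12)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 2000),
        k=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_independence_table_gives_unit_estimators(self, a, b, k):
        """ad = bc (rows proportional) forces ROR = PRR = EBGM = 1, IC = 0."""
        r = compute_signal_stats(ContingencyTable(a, b, a * k, b * k))
        assert r.ror == pytest.approx(1.0)
        assert r.prr == pytest.approx(1.0)
        assert r.ic == pytest.approx(0.0, abs=1e-12)
        assert r.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_a(self):
        b, c, d = 500, 300, 50000
        prev = compute_signal_stats(ContingencyTable(5, b, c, d))
        for a in (10, 50, 200):
            cur = compute_signal_stats(ContingencyTable(a, b, c, d))
            assert cur.ror > prev.ror and cur.prr > prev.prr
            assert cur.ic > prev.ic and cur.ebgm > prev.ebgm
            prev = cur

    @given(
        case=st.sampled_from([
            (874, 30.34), (386, 14.89), (43, 179.93), (145, 37.61), (417, 7.96),
        ]),
        c=st.integers(10, 100000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_prr_ror_identity_independent_of_c(self, case, c):
        """For fixed a, b and a table built with d = ROR*b*c/a, PRR equals
        (a + ROR*b)/(a + b) whatever c is."""
        a, ror = case
        b = 29723 - a
        d = ror * b * c / a
        r = compute_signal_stats(ContingencyTable(a, b, c, d))
        assert r.ror == pytest.approx(ror, rel=1e-12)
        assert r.prr == pytest.approx((a + ror * b) / (a + b), rel=1e-12)


class TestCriteria:
    def test_case_minimum_rule(self):
        # overwhelming ratios but only 2 cases
        r = apply_criteria(compute_signal_stats(ContingencyTable(2, 10, 5, 50000)))
        assert not r.ror_pos and not r.prr_pos
        r3 = apply_criteria(compute_signal_stats(ContingencyTable(3, 10, 5, 50000)))
        assert r3.ror_pos and r3.prr_pos

    def test_example_flags(self):
        r = apply_criteria(compute_signal_stats(ContingencyTable(10, 90, 100, 9800)))
        assert r.prr_pos and r.mgps_pos and r.ror_pos and r.bcpnn_pos and r.all_four


class TestContingency:
    def test_toy_database(self):
        pairs = pd.DataFrame({
            "primaryid": [1, 1, 2, 2],
            "pt": ["PT1", "PT2", "PT1", "PT2"],
            "target": [True, True, False, False],
        })
        t = build_contingency(pairs, "PT1")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_event_absent_from_target(self):
        pairs = pd.DataFrame({
            "primaryid": [1, 2], "pt": ["PT1", "PT2"], "target": [True, False],
        })
        t = build_contingency(pairs, "PT2")
        assert (t.a, t.b) == (0, 1)
        t_absent = build_contingency(pairs, "PT_NOWHERE")
        assert t_absent.a == 0 and t_absent.c == 0

    def test_cells_match_brute_force(self, small_dataset, etoposide_query):
        pairs = cohort.build_pair_database(small_dataset["records"], etoposide_query)
        for event in ("Febrile neutropenia", "Nausea", "Sepsis"):
            t = build_contingency(pairs, event)
            rows = list(pairs.itertuples(index=False))
            assert t.a == sum(1 for r in rows if r.target and r.pt == event)
            assert t.b == sum(1 for r in rows if r.target and r.pt != event)
            assert t.c == sum(1 for r in rows if not r.target and r.pt == event)
            assert t.d == sum(1 for r in rows if not r.target and r.pt != event)
            assert t.n == len(pairs)

    def test_table_screen_consistent_with_scalar_path(self, small_dataset, etoposide_query):
        pairs = cohort.build_pair_database(small_dataset["records"], etoposide_query)
        table = pt_signal_table(pairs)
        for pt in table["pt"].head(5):
            scalar = compute_signal_stats(build_contingency(pairs, pt))
            row = table[table["pt"] == pt].iloc[0]
            assert row["ror"] == pytest.approx(scalar.ror, nan_ok=True)
            assert row["ebgm05"] == pytest.approx(scalar.ebgm05, nan_ok=True)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestScreening:
    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=["pt", "a", "all_four"])
        assert len(screen_signals(empty)) == 0

    def test_failing_one_algorithm_excludes(self):
        df = pd.DataFrame({
            "pt": ["X"], "a": [50], "ror_pos": [True], "prr_pos": [True],
            "bcpnn_pos": [True], "mgps_pos": [False], "all_four": [False],
        })
        assert len(screen_signals(df)) == 0

    def test_planted_signal_detected_null_pts_rejected(self, planted_dataset):
        query = cohort.DrugQuery.from_names(
            ["TARGETDRUG"], roles=("PS", "SS", "C", "I")
        )
        pairs = cohort.build_pair_database(planted_dataset["reports"], query)
        sig = screen_signals(pt_signal_table(pairs))
        assert "Planted event" in set(sig["pt"])
        assert not (set(sig["pt"]) - {"Planted event"})

    def test_ebgm_recovers_planted_lambda_within_factor_two(self, planted_dataset):
        query = cohort.DrugQuery.from_names(
            ["TARGETDRUG"], roles=("PS", "SS", "C", "I")
        )
        pairs = cohort.build_pair_database(planted_dataset["reports"], query)
        table = pt_signal_table(pairs)
        row = table[table["pt"] == "Planted event"].iloc[0]
        assert row["a"] >= 20
        lam = planted_dataset["config"].planted_signals[0].lam
        assert lam / 2 <= row["ebgm"] <= lam * 2

    def test_null_calibration_false_positive_rates(self, null_dataset):
        """lambda = 1 everywhere: across all (drug, PT) pairs the ROR
        criterion fires on <= 10% and the four-way intersection on <= 5%."""
        reports = null_dataset["reports"]
        n_pairs = ror_flags = all_four_flags = 0
        for spec in null_dataset["config"].drug_catalog:
            query = cohort.DrugQuery.from_names([spec.name])
            pairs = cohort.build_pair_database(reports, query)
            table = pt_signal_table(pairs)
            n_pairs += len(table)
            ror_flags += int(table["ror_pos"].sum())
            all_four_flags += int(table["all_four"].sum())
        assert n_pairs >= 200
        assert ror_flags / n_pairs <= 0.10
        assert all_four_flags / n_pairs <= 0.05


class TestRanking:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["pt", "a", "ebgm05"])

    def test_strict_case_threshold(self):
        df = self._df([("X", 31, 5.0), ("Y", 30, 9.0)])
        out = rank_and_filter(df, min_a=30)
        assert list(out["pt"]) == ["X"]

    def test_ebgm05_descending(self):
        df = self._df([("X", 40, 4.2), ("Y", 40, 7.1), ("Z", 40, 5.0)])
        assert list(rank_and_filter(df)["ebgm05"]) == [7.1, 5.0, 4.2]

    def test_tie_breaks_by_case_count_then_name(self):
        df = self._df([("B", 50, 5.0), ("A", 50, 5.0), ("C", 90, 5.0)])
        assert list(rank_and_filter(df)["pt"]) == ["C", "A", "B"]


class TestSocLevel:
    def test_soc_table_aggregates_pt_records(self):
        # one SOC: the SOC row's cells are the PT rows' record counts summed
        pairs = pd.DataFrame({
            "primaryid": [1, 1, 2, 3, 3, 4],
            "pt": ["P1", "P2", "P1", "P1", "P2", "P2"],
            "target": [True, True, True, False, False, False],
            "soc": ["S"] * 6,
        })
        soc = soc_level_signals(pairs)
        assert len(soc) == 1
        row = soc.iloc[0]
        assert row["a"] == 3 and row["c"] == 3  # all records in the one SOC
        assert row["b"] == 0 and row["d"] == 0

    def test_soc_absent_from_target_has_zero_row(self):
        pairs = pd.DataFrame({
            "primaryid": [1, 2],
            "pt": ["P1", "P2"],
            "target": [True, False],
            "soc": ["S1", "S2"],
        })
        soc = soc_level_signals(pairs).set_index("soc")
        assert soc.loc["S2", "a"] == 0
        assert not soc.loc["S2", ["ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos"]].any()

    def test_requires_annotation(self):
        pairs = pd.DataFrame({"primaryid": [1], "pt": ["P"], "target": [True]})
        with pytest.raises(ValueError, match="soc"):
            soc_level_signals(pairs)


class TestNovelty:
    sig = pd.DataFrame({"pt": ["Thrombocytopenia", "Ovarian failure"]})

    def test_labeled_vs_unexpected(self):
        out = flag_unexpected(self.sig, {"Thrombocytopenia"})
        flagged = dict(zip(out["pt"], out["unexpected"]))
        assert flagged == {"Thrombocytopenia": False, "Ovarian failure": True}

    def test_case_insensitive(self):
        out = flag_unexpected(self.sig, {"THROMBOCYTOPENIA"})
        assert not out.set_index("pt").loc["Thrombocytopenia", "unexpected"]

    def test_empty_label_list_all_unexpected(self):
        out = flag_unexpected(self.sig, set())
        assert out["unexpected"].all()
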