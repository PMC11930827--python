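"""ETL: code validation, deduplication, recoding, exclusions, panel, matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import comorbnet as cn
from comorbnet.etl import (ConfigError, ExclusionReport, PanelEntry,
                           RecodeRule, filter_age)

from conftest import records_frame


@pytest.mark.parametrize("code,ok", [
    ("A01.001", True),
    ("I10", True),
    ("E03.8", True),
    ("K52.9", True),
    ("", False),
    ("1A0.b3", False),
    ("a01.001", False),
    (" A01.001", False),
    ("A01.001 ", False),
    ("A1", False),
    ("A012", False),
    ("A01.", False),
    ("A01.0001", False),
    ("AB1.001", False),
    (None, False),
])
def test_validate_icd10(code, ok):
    assert cn.validate_icd10(code) is ok


class TestDeduplicate:
    def test_repeat_visits_collapse(self):
        recs = records_frame([("P1", "male", 70, "I10")] * 3)
        assert len(cn.deduplicate(recs)) == 1

    def test_distinct_pairs_kept(self):
        recs = records_frame([("P1", "male", 70, "I10"),
                              ("P1", "male", 70, "E11.9"),
                              ("P2", "female", 65, "I10")])
        assert len(cn.deduplicate(recs)) == 3

    def test_first_occurrence_order(self):
        recs = records_frame([("P2", "male", 70, "I10"),
                              ("P1", "male", 70, "I10"),
                              ("P2", "male", 70, "I10")])
        out = cn.deduplicate(recs)
        assert list(out["patient_id"]) == ["P2", "P1"]

    @given(st.lists(st.tuples(st.sampled_from(["P1", "P2", "P3"]),
                              st.sampled_from(["I10", "E78", "K29.0"])),
                    max_size=20))
    def test_idempotent(self, pairs):
        recs = records_frame([(p, "male", 70, c) for p, c in pairs])
        once = cn.deduplicate(recs)
        twice = cn.deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRecoding:
    RULES = [RecodeRule("EE03", ("E03.8", "E03.9")),
             RecodeRule("II2520", ("I25", "I20"))]

    def test_exact_source_match(self):
        recs = records_frame([("P1", "male", 70, "E03.8")])
        out = cn.apply_recoding(recs, self.RULES)
        assert list(out["code"]) == ["EE03"]

    def test_prefix_merge_collapses_pair(self):
        recs = records_frame([("P1", "male", 70, "I25.1"),
                              ("P1", "male", 70, "I20.0")])
        out = cn.apply_recoding(recs, self.RULES)
        assert len(out) == 1
        assert out.loc[0, "code"] == "II2520"

    def test_unmatched_code_unchanged(self):
        recs = records_frame([("P1", "male", 70, "Z99.9")])
        out = cn.apply_recoding(recs, self.RULES)
        assert list(out["code"]) == ["Z99.9"]

    def test_longest_prefix_wins(self):
        rules = [RecodeRule("BROAD", ("I2",)), RecodeRule("NARROW", ("I25",))]
        recs = records_frame([("P1", "male", 70, "I25.1"),
                              ("P1", "male", 70, "I21.0")])
        with pytest.raises(ConfigError):
            # I2 is a prefix of I25 across distinct rules: configuration error
            cn.apply_recoding(recs, rules)
        # nested sources inside a single rule are fine and longest wins
        ok = [RecodeRule("NARROW", ("I25", "I25.9"))]
        out = cn.apply_recoding(records_frame([("P1", "male", 70, "I25.9")]), ok)
        assert out.loc[0, "code"] == "NARROW"

    def test_overlapping_sources_rejected(self):
        rules = [RecodeRule("A", ("I25",)), RecodeRule("B", ("I25",))]
        with pytest.raises(ConfigError):
            cn.apply_recoding(records_frame([]), rules)

    def test_garbled_code_never_recoded(self):
        recs = records_frame([("P1", "male", 70, "I25x!")])
        out = cn.apply_recoding(recs, self.RULES)
        assert list(out["code"]) == ["I25x!"]

    @given(st.lists(st.tuples(st.sampled_from(["P1", "P2"]),
                              st.sampled_from(["I25.1", "I20.0", "E03.8",
                                               "E03.9", "K29.0"])),
                    max_size=15))
    def test_never_increases_pair_count(self, pairs):
        recs = cn.deduplicate(
            records_frame([(p, "male", 70, c) for p, c in pairs]))
        out = cn.apply_recoding(recs, self.RULES)
        assert len(out) <= len(recs)


class TestExclusions:
    def test_low_prevalence_disease_dropped(self):
        # disease carried by 1 of 200 patients: 0.5% < 1%
        rows = []
        for i in range(200):
            rows.append((f"P{i}", "male", 70, "I10"))
            rows.append((f"P{i}", "male", 70, "E78"))
        rows.append(("P0", "male", 70, "M81"))
        out, report = cn.apply_exclusions(records_frame(rows),
                                          ["I10", "E78", "M81"], 0.01)
        assert "M81" not in set(out["code"])
        assert report.dropped("low-prevalence") == 1

    def test_single_disease_patient_dropped(self):
        rows = [("P1", "male", 70, "I10"), ("P1", "male", 70, "E78"),
                ("P2", "male", 70, "I10")]
        out, report = cn.apply_exclusions(records_frame(rows),
                                          ["I10", "E78"], 0.0)
        assert set(out["patient_id"]) == {"P1"}
        assert report.dropped("single-disease") == 1

    def test_invalid_and_nonchronic_stages(self):
        rows = [("P1", "male", 70, "I10"), ("P1", "male", 70, "EE03"),
                ("P1", "male", 70, "garbage"), ("P1", "male", 70, "Z99.9")]
        out, report = cn.apply_exclusions(records_frame(rows),
                                          ["I10", "EE03"], 0.0)
        assert report.dropped("invalid-code") == 1   # 'garbage'
        assert report.dropped("non-chronic") == 1    # Z99.9 valid but not listed
        assert set(out["code"]) == {"I10", "EE03"}

    def test_stage_arithmetic_balances(self):
        rows = [("P1", "male", 70, "I10"), ("P1", "male", 70, "E78"),
                ("P2", "male", 70, "bad"), ("P3", "male", 70, "I10")]
        _, report = cn.apply_exclusions(records_frame(rows), ["I10", "E78"], 0.0)
        for _, n_in, n_out, dropped in report.stages:
            assert n_in - n_out == dropped
        total_dropped = sum(d for *_, d in report.stages)
        assert total_dropped == report.stages[0][1] - report.stages[-1][2]

    def test_prevalence_filter_monotone(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(120):
            for code, prob in [("I10", 0.9), ("E78", 0.85), ("M81", 0.1),
                               ("K29", 0.03)]:
                if rng.random() < prob:
                    rows.append((f"P{i}", "male", 70, code))
        allow = ["I10", "E78", "M81", "K29"]
        kept = []
        for thr in (0.0, 0.02, 0.05, 0.2):
            out, _ = cn.apply_exclusions(records_frame(rows), allow, thr)
            kept.append(set(out["code"]))
        for a, b in zip(kept, kept[1:]):
            assert b <= a

    def test_empty_output_is_error(self):
        rows = [("P1", "male", 70, "I10")]
        with pytest.raises(cn.etl.PipelineError):
            cn.apply_exclusions(records_frame(rows), ["I10"], 0.0)


class TestBuildPanel:
    def test_union_saturates(self):
        rows = [("P1", "m", 70, "A"), ("P1", "m", 70, "B"),
                ("P2", "m", 70, "B"), ("P2", "m", 70, "C"),
                ("P3", "m", 70, "A"), ("P3", "m", 70, "C")]
        panel = cn.build_panel(records_frame(rows), n_top=3, n_comorbid=2)
        assert sorted(panel.codes) == ["A", "B", "C"]

    def test_too_few_diseases_error(self):
        rows = [("P1", "m", 70, "A"), ("P2", "m", 70, "A")]
        with pytest.raises(cn.etl.PipelineError):
            cn.build_panel(records_frame(rows), n_top=3, n_comorbid=2)

    def test_planted_toy_matches_hand_enumeration(self):
        # 5 diseases, 12 patients; comorbidity rates are hand-computable.
        # carriers: A={1..8}, B={1..6}, C={1,2,9}, D={7,8,9,10}, E={11,12,1}
        carriers = {"A": range(1, 9), "B": range(1, 7), "C": [1, 2, 9],
                    "D": [7, 8, 9, 10], "E": [11, 12, 1]}
        rows = [(f"P{i}", "m", 70, code)
                for code, pats in carriers.items() for i in pats]
        # top-1 by prevalence is A (8 carriers); rates with A:
        #   B: 6/8, D: 2/8, C: 2/8, E: 1/8 -> top-2 comorbid = {B, C} after
        #   lexicographic tie-break between C and D at 2/8
        panel = cn.build_panel(records_frame(rows), n_top=1, n_comorbid=2)
        assert set(panel.codes) == {"A", "B", "C"}
        assert panel.top5 == ["A"]
        # ordering is by overall prevalence descending
        assert panel.codes == ["A", "B", "C"]


class TestBuildMatrix:
    def _panel(self, codes):
        return cn.DiseasePanel([PanelEntry(c, c) for c in codes])

    def test_two_panel_diseases_two_ones(self):
        recs = records_frame([("P1", "male", 70, "II2520"),
                              ("P1", "male", 70, "K29"),
                              ("P1", "male", 70, "ZZZ")])
        m = cn.build_matrix(recs, self._panel(["II2520", "K29", "I10"]))
        assert m.values.sum() == 2
        assert m.n_patients == 1

    def test_empty_input(self):
        m = cn.build_matrix(records_frame([]), self._panel(["I10"]))
        assert m.n_patients == 0

    def test_column_sums_match_generator_counts(self):
        frame, ledger = cn.make_record_file(
            cn.CohortSpec(n_patients=300), cn.MessSpec(), seed=7)
        recs = frame.rename(columns={"icd10": "code"})
        panel, rules = cn.default_panel()
        matrix, built_panel, _ = cn.run_etl(recs, rules)
        counts = ledger.disease_patient_counts
        for code in built_panel.codes:
            assert matrix.data[code].sum() == counts[code]


class TestSampleBySex:
    def _matrix(self, n=40):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.integers(0, 2, (n, 3)),
                            index=[f"P{i}" for i in range(n)],
                            columns=["a", "b", "c"])
        sex = pd.Series(["male", "female"] * (n // 2), index=data.index)
        return cn.ComorbidityMatrix(data, sex)

    def test_same_seed_same_rows(self):
        m = self._matrix()
        s1 = cn.sample_by_sex(m, 5, seed=3)
        s2 = cn.sample_by_sex(m, 5, seed=3)
        assert list(s1.data.index) == list(s2.data.index)
        assert s1.sex.value_counts().to_dict() == {"male": 5, "female": 5}

    def test_small_stratum_returned_whole(self):
        m = self._matrix(10)
        with pytest.warns(UserWarning):
            out = cn.sample_by_sex(m, 100, seed=0)
        assert out.n_patients == 10


def test_age_window_filter():
    recs = records_frame([("P1", "male", 59, "I10"),
                          ("P2", "male", 60, "I10"),
                          ("P3", "male", 99, "I10"),
                          ("P4", "male", 100, "I10")])
    report = ExclusionReport()
    out = filter_age(recs, (60, 99), report)
    assert set(out["patient_id"]) == {"P2", "P3"}
    assert report.dropped("age-window") == 2


def test_pipeline_reproduces_generator_ledger():
    """Full ETL on a messy generated file matches the ledger stage by stage."""
    mess = cn.MessSpec(n_duplicates=40, n_invalid=25, n_nonchronic=30,
                       n_single_patients=15, n_out_of_age=8, n_merge_pairs=10,
                       rare_carriers=5)
    frame, ledger = cn.make_record_file(cn.CohortSpec(n_patients=800), mess,
                                        seed=11)
    recs = frame.rename(columns={"icd10": "code"})
    _, rules = cn.default_panel()
    _, _, report = cn.run_etl(recs, rules, min_prevalence=0.01)
    expected = ledger.expected_stage_drops(0.01)
    for stage, want in expected.items():
        assert report.dropped(stage) == want, stage
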