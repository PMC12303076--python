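"""Scoring harness: PPV semantics, rounding, table self-consistency."""

import pandas as pd
import pytest

from oncogate.inclusion import MatchReport
from oncogate.regimens import RegimenAssignment
from oncogate.scoring import (
    accuracy_table,
    round_half_up_pct,
    score_inclusion,
    score_regimens,
    score_retrospective,
    score_toxicity,
)
from oncogate.toxicity import ToxicityFinding


@pytest.mark.parametrize(
    "numer,denom,expected",
    [
        (1219, 1287, 95),  # 94.72 rounds up
        (11, 68, 16),
        (27, 68, 40),
        (30, 68, 44),
        (342, 384, 89),
        (192, 198, 97),
        (1, 2, 1 * 100 // 2 + (100 % 2 > 0)),  # 50
        (0, 0, None),  # undefined, printed blank
    ],
)
def test_whole_percent_rounding_is_half_up(numer, denom, expected):
    assert round_half_up_pct(numer, denom) == expected


def test_accuracy_table_totals_and_consistency():
    table = accuracy_table([("a", 10, 9), ("b", 5, 5), ("c", 0, 0)])
    total = table.iloc[-1]
    assert (total["n_predicted"], total["n_correct"], total["accuracy_pct"]) == (15, 14, 93)
    assert pd.isna(table.loc[table["stratum"] == "c", "accuracy_pct"]).all()


def test_accuracy_table_rejects_more_correct_than_predicted():
    with pytest.raises(AssertionError):
        accuracy_table([("a", 3, 4)])


def decisions_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "tumor_group", "decision", "reason"])


class TestScoreInclusion:
    def test_perfect_decisions_score_100(self):
        truth = decisions_frame([("P1", "AML", "include", "NONE"),
                                 ("P2", "AML", "exclude", "NON_RESIDENT")])
        score = score_inclusion(truth.copy(), truth)
        assert score.decision_table.iloc[-1]["accuracy_pct"] == 100
        assert score.include_pct == 50

    def test_printed_reason_breakdown(self):
        rows = [(f"I{i}", "AML", "include", "NONE") for i in range(1219)]
        rows += [(f"N{i}", "AML", "exclude", "NON_RESIDENT") for i in range(11)]
        rows += [(f"R{i}", "AML", "exclude", "RELAPSE_TRAJECTORY") for i in range(27)]
        rows += [(f"P{i}", "AML", "exclude", "PRELIMINARY_DIAGNOSIS") for i in range(30)]
        truth = decisions_frame(rows)
        score = score_inclusion(truth.copy(), truth)
        assert score.include_pct == 95
        assert list(score.reason_breakdown["pct"]) == [16, 40, 44]

    def test_universe_mismatch_is_a_scoring_error(self):
        truth = decisions_frame([("P1", "AML", "include", "NONE")])
        other = decisions_frame([("P2", "AML", "include", "NONE")])
        with pytest.raises(ValueError, match="universe"):
            score_inclusion(other, truth)

    def test_empty_inputs_give_empty_table(self):
        empty = decisions_frame([])
        score = score_inclusion(empty, empty)
        assert len(score.decision_table) == 0 and score.include_pct is None


def make_assignment(pid, name, start, end):
    return RegimenAssignment(patient_id=pid, name=name,
                             start=pd.Timestamp(start), end=pd.Timestamp(end))


def truth_frame(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "name", "start", "end", "category"])
    frame["start"] = pd.to_datetime(frame["start"])
    frame["end"] = pd.to_datetime(frame["end"])
    return frame


class TestScoreRegimens:
    def test_recovered_regimen_within_date_tolerance_is_correct(self, mm_catalog):
        truth = truth_frame([("P1", "D-Rd", "2021-01-01", "2021-02-18", "Anti-CD38")])
        a = [make_assignment("P1", "D-Rd", "2021-01-03", "2021-02-16")]
        score = score_regimens(a, truth, mm_catalog)
        assert score.n_correct_predicted == 1

    def test_four_day_shift_is_wrong(self, mm_catalog):
        truth = truth_frame([("P1", "D-Rd", "2021-01-01", "2021-02-18", "Anti-CD38")])
        a = [make_assignment("P1", "D-Rd", "2021-01-05", "2021-02-18")]
        assert score_regimens(a, truth, mm_catalog).n_correct_predicted == 0

    def test_merged_drd_counts_against_anti_cd38(self, mm_catalog):
        truth = truth_frame([
            ("P1", "D-mono", "2021-01-01", "2021-01-01", "Anti-CD38"),
            ("P1", "Rd", "2021-01-04", "2021-01-24", "IMID"),
        ])
        a = [make_assignment("P1", "D-Rd", "2021-01-01", "2021-01-24")]
        score = score_regimens(a, truth, mm_catalog)
        assert score.n_correct_predicted == 0
        row = score.by_predicted[score.by_predicted["stratum"] == "Anti-CD38"].iloc[0]
        assert (row["n_predicted"], row["n_correct"]) == (1, 0)
        # both truth regimens went unrecovered
        assert score.by_truth.iloc[-1]["n_correct"] == 0

    def test_one_truth_row_cannot_validate_two_predictions(self, mm_catalog):
        truth = truth_frame([("P1", "Rd", "2021-01-01", "2021-01-21", "IMID")])
        a = [make_assignment("P1", "Rd", "2021-01-01", "2021-01-21"),
             make_assignment("P1", "Rd", "2021-01-02", "2021-01-22")]
        assert score_regimens(a, truth, mm_catalog).n_correct_predicted == 1


class TestScoreToxicity:
    def find(self, pid, category, channels):
        return ToxicityFinding(patient_id=pid, category=category,
                               first_date=pd.Timestamp("2021-01-10"),
                               channels=frozenset(channels))

    def truth(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "category", "date", "channel"])

    def test_all_findings_with_truth_events_are_100(self):
        findings = [self.find("P1", "sepsis", {"drug"}),
                    self.find("P2", "sepsis", {"admission"})]
        truth = self.truth([("P1", "sepsis", "2021-01-10", "drug"),
                            ("P2", "sepsis", "2021-01-10", "admission")])
        table = score_toxicity(findings, truth)
        total = table[(table["category"] == "sepsis") & (table["row"] == "total")].iloc[0]
        assert (total["n_predicted"], total["accuracy_pct"]) == (2, 100)

    def test_channel_subrows_may_overlap(self):
        findings = [self.find("P1", "sepsis", {"drug", "admission"})]
        truth = self.truth([("P1", "sepsis", "2021-01-10", "drug")])
        table = score_toxicity(findings, truth)
        sub = table[table["category"] == "sepsis"].set_index("row")
        assert sub.loc["indicator", "n_predicted"] == 1
        assert sub.loc["admission", "n_predicted"] == 1

    def test_noise_finding_without_truth_lowers_ppv(self):
        findings = [self.find("P1", "sepsis", {"drug"}),
                    self.find("P2", "sepsis", {"drug"})]
        truth = self.truth([("P1", "sepsis", "2021-01-10", "drug")])
        table = score_toxicity(findings, truth)
        total = table[(table["category"] == "sepsis") & (table["row"] == "total")].iloc[0]
        assert total["accuracy_pct"] == 50

    def test_zero_predictions_print_blank_accuracy(self):
        table = score_toxicity([], self.truth([]))
        assert table["n_predicted"].sum() == 0
        assert table["accuracy_pct"].isna().all()


def test_retrospective_share_at_printed_scale():
    records = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(384)],
            "tumor_group": ["AML"] * 384,
            "diagnosis_year": [2018] * 384,
            "category": ["matched_same_year"] * 342 + ["year_mismatch"] * 14
            + ["diagnosis_mismatch"] * 28,
        }
    )
    counts = {c: int((records["category"] == c).sum())
              for c in ("matched_same_year", "year_mismatch", "diagnosis_mismatch", "absent")}
    table = score_retrospective(MatchReport(records=records, counts=counts))
    matched = table[table["category"] == "matched_same_year"].iloc[0]
    assert (matched["n"], matched["pct"]) == (342, 89)
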