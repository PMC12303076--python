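"""Toxicity engine: attribution windows, the four channels, finding combination."""

import pandas as pd
import pytest

from oncogate.regimens import RegimenAssignment
from oncogate.synthetic import generate_cohort
from oncogate.toxicity import (
    AttributionWindow,
    EvaluationError,
    attribution_window,
    combine_findings,
    detect_toxicity,
    eval_drug_indicator,
    eval_lab_indicator,
    map_admissions,
    scan_reports,
)

from conftest import rx_frame, small_config


def assignment(start, end, pid="P1", name="7+3"):
    return RegimenAssignment(patient_id=pid, name=name,
                             start=pd.Timestamp(start), end=pd.Timestamp(end))


class TestAttributionWindow:
    def test_window_extends_30_days_past_last_treatment_day(self):
        w = attribution_window([assignment("2021-01-01", "2021-02-01")])
        assert w.start == pd.Timestamp("2021-01-01")
        assert w.end == pd.Timestamp("2021-03-03")

    def test_transplant_truncates_to_its_eve(self):
        w = attribution_window([assignment("2021-01-01", "2021-02-01")],
                               sct_date=pd.Timestamp("2021-02-15"))
        assert w.end == pd.Timestamp("2021-02-14")

    def test_day_after_window_end_is_outside(self):
        w = attribution_window([assignment("2021-01-01", "2021-02-01")])
        assert w.contains(pd.Timestamp("2021-03-03"))
        assert not w.contains(pd.Timestamp("2021-03-04"))

    def test_transplant_before_treatment_end_can_empty_the_window(self):
        w = attribution_window([assignment("2021-01-10", "2021-02-01")],
                               sct_date=pd.Timestamp("2021-01-10"))
        assert w.empty

    def test_no_assignments_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            attribution_window([])


def window(start="2021-01-01", end="2021-03-01", pid="P1"):
    return AttributionWindow(patient_id=pid, start=pd.Timestamp(start),
                             end=pd.Timestamp(end))


def labs_frame(rows):
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            "loinc_code": ["2160-0"] * len(rows),
            "analyte_name": [r[1] for r in rows],
            "value": [float(r[2]) for r in rows],
            "unit": [r[3] for r in rows],
            "datetime": pd.to_datetime([r[4] for r in rows]),
        }
    )


class TestLabChannel:
    def test_creatinine_excursion_over_baseline_signals_renal_failure(self, rules):
        labs = labs_frame([
            ("P1", "creatinine", 80, "umol/L", "2020-12-20 09:00"),
            ("P1", "creatinine", 130, "umol/L", "2021-01-10 09:00"),
        ])
        sig = eval_lab_indicator(labs, rules["acute_renal_failure"], window())
        assert [s.date for s in sig] == [pd.Timestamp("2021-01-10")]
        assert sig[0].channel == "lab"

    def test_excursion_before_window_start_does_not_signal(self, rules):
        labs = labs_frame([
            ("P1", "creatinine", 80, "umol/L", "2020-11-01 09:00"),
            ("P1", "creatinine", 200, "umol/L", "2020-12-28 09:00"),
        ])
        assert eval_lab_indicator(labs, rules["acute_renal_failure"], window()) == []

    def test_missing_baseline_skips_the_relative_rule(self, rules):
        labs = labs_frame([("P1", "creatinine", 400, "umol/L", "2021-01-10 09:00")])
        assert eval_lab_indicator(labs, rules["acute_renal_failure"], window()) == []

    def test_absolute_bilirubin_threshold_signals_hepatic_toxicity(self, rules):
        labs = labs_frame([("P1", "bilirubin", 60, "umol/L", "2021-01-10 09:00")])
        sig = eval_lab_indicator(labs, rules["hepatic_toxicity"], window())
        assert len(sig) == 1 and sig[0].category == "hepatic_toxicity"

    def test_unit_mismatch_is_an_evaluation_error_naming_the_row(self, rules):
        labs = labs_frame([("P1", "bilirubin", 3.5, "mg/dL", "2021-01-10 09:00")])
        with pytest.raises(EvaluationError, match="row 1"):
            eval_lab_indicator(labs, rules["hepatic_toxicity"], window())


class TestDrugChannel:
    def test_in_window_carbapenem_signals_sepsis(self, rules):
        rx = rx_frame([("P1", "J01DH02", "meropenem", 3000, "2021-01-15", "2021-01-22")])
        sig = eval_drug_indicator(rx, rules["sepsis"], window())
        assert len(sig) == 1 and sig[0].date == pd.Timestamp("2021-01-15")

    def test_multi_drug_trigger_needs_costart_within_3_days(self, rules):
        together = rx_frame([
            ("P1", "J01DE01", "cefepime", 4000, "2021-01-15", "2021-01-22"),
            ("P1", "J01XD01", "metronidazole", 1500, "2021-01-17", "2021-01-24"),
        ])
        apart = rx_frame([
            ("P1", "J01DE01", "cefepime", 4000, "2021-01-15", "2021-01-22"),
            ("P1", "J01XD01", "metronidazole", 1500, "2021-01-25", "2021-02-01"),
        ])
        assert len(eval_drug_indicator(together, rules["typhlitis"], window())) == 1
        assert eval_drug_indicator(apart, rules["typhlitis"], window()) == []

    def test_no_prescriptions_no_signals(self, rules):
        assert eval_drug_indicator(rx_frame([]), rules["sepsis"], window()) == []


def reports_frame(rows):
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            "datetime": pd.to_datetime([r[1] for r in rows]),
            "modality": ["CT"] * len(rows),
            "text": [r[2] for r in rows],
        }
    )


class TestKeywordChannel:
    def test_keyword_in_window_signals(self, rules):
        rep = reports_frame([("P1", "2021-01-20 10:00",
                              "Nodules compatible with Aspergillosis.")])
        sig = scan_reports(rep, rules["invasive_aspergillosis"], window())
        assert len(sig) == 1 and sig[0].channel == "keyword"

    def test_negated_mention_still_signals(self, rules):
        rep = reports_frame([("P1", "2021-01-20 10:00",
                              "No evidence of aspergillosis.")])
        assert len(scan_reports(rep, rules["invasive_aspergillosis"], window())) == 1

    def test_substring_inside_a_word_does_not_signal(self, rules):
        rep = reports_frame([("P1", "2021-01-20 10:00", "Patient bleeds? unbleeding scan")])
        # "bleeding" embedded in "unbleeding" is not a whole-word hit
        assert scan_reports(rep, rules["hemorrhage"], window()) == []

    def test_report_outside_window_is_silent(self, rules):
        rep = reports_frame([("P1", "2021-05-20 10:00", "aspergillosis")])
        assert scan_reports(rep, rules["invasive_aspergillosis"], window()) == []


def admissions_frame(rows):
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            "admit_date": pd.to_datetime([r[1] for r in rows]),
            "discharge_date": pd.to_datetime([r[2] for r in rows]),
            "main_icd10": [r[3] for r in rows],
            "secondary_icd10": [r[4] for r in rows],
            "icu": [r[5] for r in rows],
        }
    )


class TestAdmissionChannel:
    def test_main_sepsis_code_in_window_signals(self, rules):
        adm = admissions_frame([("P1", "2021-01-15", "2021-01-25", "A41.9", [], False)])
        sig = map_admissions(adm, rules["sepsis"], window())
        assert len(sig) == 1 and sig[0].channel == "admission"

    def test_secondary_code_also_counts(self, rules):
        adm = admissions_frame([("P1", "2021-01-15", "2021-01-25", "Z51.1", ["B44.0"], False)])
        assert len(map_admissions(adm, rules["invasive_aspergillosis"], window())) == 1

    def test_icu_flag_signals_icu_admission(self, rules):
        adm = admissions_frame([("P1", "2021-01-15", "2021-01-18", "Z51.1", [], True)])
        sig = map_admissions(adm, rules["icu_admission"], window())
        assert len(sig) == 1 and sig[0].category == "icu_admission"

    def test_listed_code_outside_window_is_silent(self, rules):
        adm = admissions_frame([("P1", "2021-06-15", "2021-06-25", "A41.9", [], False)])
        assert map_admissions(adm, rules["sepsis"], window()) == []


class TestCombineFindings:
    def test_same_category_channels_merge_into_one_finding(self, rules):
        labs = labs_frame([("P1", "bilirubin", 60, "umol/L", "2021-01-10 09:00")])
        adm = admissions_frame([("P1", "2021-01-15", "2021-01-25", "A41.9", [], False)])
        rx = rx_frame([("P1", "J01DH02", "meropenem", 3000, "2021-01-20", "2021-01-27")])
        signals = (
            eval_lab_indicator(labs, rules["hepatic_toxicity"], window())
            + eval_drug_indicator(rx, rules["sepsis"], window())
            + map_admissions(adm, rules["sepsis"], window())
        )
        findings = combine_findings(signals)
        assert len(findings) == 2
        sepsis = next(f for f in findings if f.category == "sepsis")
        assert sepsis.channels == {"drug", "admission"}
        assert sepsis.first_date == pd.Timestamp("2021-01-15")

    def test_idempotent_and_order_invariant(self, rules):
        rx = rx_frame([("P1", "J01DH02", "meropenem", 3000, "2021-01-20", "2021-01-27")])
        signals = eval_drug_indicator(rx, rules["sepsis"], window()) * 2
        once = combine_findings(signals)
        assert combine_findings(list(reversed(signals))) == once
        assert combine_findings(signals + signals) == once

    def test_no_signals_no_findings(self):
        assert combine_findings([]) == []


def test_no_signal_outside_any_attribution_window(noisy_cohort, aml_catalog):
    ds, truth = noisy_cohort
    from oncogate.regimens import derive_sequence
    from oncogate.toxicity import attribution_windows

    aml = set(ds.trajectories.loc[ds.trajectories["tumor_group"] == "AML", "patient_id"])
    assignments = derive_sequence(ds, aml_catalog, patient_ids=aml)
    windows = attribution_windows(ds, aml_catalog, assignments=assignments)
    signals, _ = detect_toxicity(ds, assignments=assignments)
    assert signals  # the miniature plan plants events
    for s in signals:
        assert windows[s.patient_id].contains(s.date)


def test_every_planted_event_is_recovered(small_cohort, aml_catalog):
    ds, truth = small_cohort
    from oncogate.regimens import derive_sequence

    aml = set(ds.trajectories.loc[ds.trajectories["tumor_group"] == "AML", "patient_id"])
    assignments = derive_sequence(ds, aml_catalog, patient_ids=aml)
    _, findings = detect_toxicity(ds, assignments=assignments)
    found = {(f.patient_id, f.category) for f in findings}
    planted = {(t.patient_id, t.category) for t in truth.toxicity.itertuples(index=False)}
    assert planted <= found
    # without noise there are no spurious findings either
    assert found == planted
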