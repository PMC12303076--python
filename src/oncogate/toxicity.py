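"""CTCAE treatment-toxicity signaling from four evidence channels.

Ten CTCAE categories (acute renal failure, hemorrhage, hepatic toxicity,
ICU admission, invasive aspergillosis, invasive candidiasis, pulmonary
toxicity, sepsis, typhlitis, venous thrombosis) are signaled from:

* laboratory indicators — absolute thresholds or baseline-relative ratios
  (baseline = most recent value within 90 days before the window);
* indicator-drug prescriptions — ATC trigger sets whose members co-start
  within 3 days;
* imaging-report keywords — case-insensitive whole-word matching, with no
  negation handling (deliberately naive);
* admission ICD-10 diagnoses (main or secondary), plus the ICU flag for the
  ICU-admission category.

Every signal is confined to the patient's treatment attribution window:
first day of treatment to 30 days after the last day, truncated to the day
before a stem-cell transplantation when the transplant comes first.
Signals collapse into one finding per (patient, category) carrying the
earliest date and the union of contributing channels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .cdm import CDMDataset
from .regimens import DrugClassMapping, RegimenAssignment, RegimenCatalog, derive_sequence

__all__ = [
    "CATEGORIES",
    "AttributionWindow",
    "LabRule",
    "ToxicityIndicatorRule",
    "ToxicitySignal",
    "ToxicityFinding",
    "EvaluationError",
    "load_rules",
    "attribution_window",
    "attribution_windows",
    "eval_lab_indicator",
    "eval_drug_indicator",
    "scan_reports",
    "map_admissions",
    "combine_findings",
    "detect_toxicity",
]

CATEGORIES = (
    "acute_renal_failure",
    "hemorrhage",
    "hepatic_toxicity",
    "icu_admission",
    "invasive_aspergillosis",
    "invasive_candidiasis",
    "pulmonary_toxicity",
    "sepsis",
    "typhlitis",
    "venous_thrombosis",
)

POST_TREATMENT_DAYS = 30  # toxicity attributed up to 30 days past last treatment day
BASELINE_LOOKBACK_DAYS = 90
DRUG_TRIGGER_COSTART_DAYS = 3


class EvaluationError(Exception):
    """A rule could not be evaluated against a data row (e.g. unit mismatch)."""


@dataclass(frozen=True)
class AttributionWindow:
    patient_id: str
    start: pd.Timestamp
    end: pd.Timestamp  # may precede start (empty window) when SCT precedes treatment end

    @property
    def empty(self) -> bool:
        return self.end < self.start

    def contains(self, when: pd.Timestamp) -> bool:
        day = pd.Timestamp(when).normalize()
        return (not self.empty) and self.start <= day <= self.end


@dataclass(frozen=True)
class LabRule:
    analyte: str
    unit: str
    comparator: str  # ">" or "<"
    threshold: float
    baseline_relative: bool = False

    def fires(self, value: float, baseline: float | None) -> bool:
        bound = self.threshold * baseline if self.baseline_relative else self.threshold
        return value > bound if self.comparator == ">" else value < bound


@dataclass
class ToxicityIndicatorRule:
    """One CTCAE category's detection logic across the evidence channels."""

    category: str
    lab_rules: list[LabRule] = field(default_factory=list)
    drug_rules: list[list[str]] = field(default_factory=list)  # ATC trigger sets
    keyword_rules: list[str] = field(default_factory=list)
    admission_codes: list[str] = field(default_factory=list)
    icu_flag: bool = False

    def channels(self) -> set[str]:
        out = set()
        if self.lab_rules:
            out.add("lab")
        if self.drug_rules:
            out.add("drug")
        if self.keyword_rules:
            out.add("keyword")
        if self.admission_codes or self.icu_flag:
            out.add("admission")
        return out


@dataclass(frozen=True)
class ToxicitySignal:
    patient_id: str
    category: str
    date: pd.Timestamp
    channel: str  # lab | drug | keyword | admission
    evidence: tuple[str, int]  # (table, row label)


@dataclass(frozen=True)
class ToxicityFinding:
    patient_id: str
    category: str
    first_date: pd.Timestamp
    channels: frozenset[str]


def load_rules(path: str | Path | None = None) -> dict[str, ToxicityIndicatorRule]:
    """Load category rules from YAML; defaults to the shipped reconstruction."""
    if path is None:
        path = Path(str(resources.files("oncogate").joinpath("data", "ctcae_rules.yaml")))
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    rules: dict[str, ToxicityIndicatorRule] = {}
    for category, block in raw.items():
        block = block or {}
        rule = ToxicityIndicatorRule(
            category=category,
            lab_rules=[LabRule(**lr) for lr in block.get("lab_rules", [])],
            drug_rules=[list(s) for s in block.get("drug_rules", [])],
            keyword_rules=list(block.get("keyword_rules", [])),
            admission_codes=[str(c) for c in block.get("admission_codes", [])],
            icu_flag=bool(block.get("icu_flag", False)),
        )
        if not rule.channels():
            raise ValueError(f"category {category!r} has no non-empty channel")
        rules[category] = rule
    return rules


def attribution_window(
    assignments: list[RegimenAssignment], sct_date: pd.Timestamp | None = None
) -> AttributionWindow:
    """Build the treatment attribution window from one patient's assignments.

    Start is the earliest treatment day; end is the latest treatment day plus
    30 days, truncated to the day before the stem-cell transplantation when
    that comes first.  Overlapping courses merge into one window.
    """
    if not assignments:
        raise ValueError("attribution window requires at least one assignment")
    pid = assignments[0].patient_id
    start = min(a.start for a in assignments)
    end = max(a.end for a in assignments) + pd.Timedelta(days=POST_TREATMENT_DAYS)
    if sct_date is not None and pd.Timestamp(sct_date) - pd.Timedelta(days=1) < end:
        end = pd.Timestamp(sct_date) - pd.Timedelta(days=1)
    return AttributionWindow(patient_id=pid, start=start, end=end)


def attribution_windows(
    ds: CDMDataset,
    catalog: RegimenCatalog,
    mapping: DrugClassMapping | None = None,
    assignments: list[RegimenAssignment] | None = None,
) -> dict[str, AttributionWindow]:
    """One merged attribution window per treated patient.

    Event-based (HSCT) assignments bound the window rather than extend it:
    the earliest transplant on/after treatment start truncates the window.
    """
    if assignments is None:
        assignments = derive_sequence(ds, catalog, mapping)
    drug_assignments: dict[str, list[RegimenAssignment]] = {}
    for a in assignments:
        if a.category != "HSCT":
            drug_assignments.setdefault(a.patient_id, []).append(a)
    sct_dates = {
        str(pid): grp["date"].min()
        for pid, grp in ds.sct.groupby("patient_id")
    } if len(ds.sct) else {}
    windows = {}
    for pid, assigns in drug_assignments.items():
        windows[pid] = attribution_window(assigns, sct_dates.get(pid))
    return windows


def eval_lab_indicator(
    labs: pd.DataFrame, rule: ToxicityIndicatorRule, window: AttributionWindow
) -> list[ToxicitySignal]:
    """Evaluate the lab channel for one patient window.

    Each lab rule emits a signal at the first in-window timestamp where it
    fires.  Baseline-relative rules use the most recent value in the 90 days
    before the window as baseline and are skipped without one.  A unit
    mismatch between rule and row is an evaluation error naming the row.
    """
    signals: list[ToxicitySignal] = []
    if window.empty or not len(labs):
        return signals
    mine = labs[labs["patient_id"] == window.patient_id]
    for lr in rule.lab_rules:
        rows = mine[mine["analyte_name"].str.lower() == lr.analyte.lower()]
        if not len(rows):
            continue
        bad_unit = rows[rows["unit"].str.strip().str.lower() != lr.unit.strip().lower()]
        if len(bad_unit):
            raise EvaluationError(
                f"labs row {int(bad_unit.index[0]) + 1}: unit "
                f"{bad_unit['unit'].iloc[0]!r} does not match rule unit {lr.unit!r}"
            )
        rows = rows.sort_values(["datetime"], kind="stable")
        baseline = None
        if lr.baseline_relative:
            pre = rows[
                (rows["datetime"] < window.start)
                & (rows["datetime"] >= window.start - pd.Timedelta(days=BASELINE_LOOKBACK_DAYS))
            ]
            if not len(pre):
                continue  # no baseline → rule skipped
            baseline = float(pre["value"].iloc[-1])
        in_win = rows[
            (rows["datetime"].dt.normalize() >= window.start)
            & (rows["datetime"].dt.normalize() <= window.end)
        ]
        for idx in in_win.index:
            if lr.fires(float(in_win.at[idx, "value"]), baseline):
                signals.append(
                    ToxicitySignal(
                        patient_id=window.patient_id,
                        category=rule.category,
                        date=in_win.at[idx, "datetime"].normalize(),
                        channel="lab",
                        evidence=("labs", int(idx)),
                    )
                )
                break  # first firing timestamp only
    return signals


def eval_drug_indicator(
    prescriptions: pd.DataFrame, rule: ToxicityIndicatorRule, window: AttributionWindow
) -> list[ToxicitySignal]:
    """Drug channel: signal at the first in-window co-start of any trigger set.

    A multi-drug set triggers when every member ATC code has a prescription
    start within 3 days of the anchor start.
    """
    signals: list[ToxicitySignal] = []
    if window.empty or not len(prescriptions):
        return signals
    mine = prescriptions[prescriptions["patient_id"] == window.patient_id]
    costart = pd.Timedelta(days=DRUG_TRIGGER_COSTART_DAYS)
    for trigger_set in rule.drug_rules:
        members = mine[mine["atc_code"].isin(trigger_set)]
        if not len(members):
            continue
        anchors = members.sort_values(["start_date", "atc_code"], kind="stable")
        fired = None
        for idx in anchors.index:
            anchor = anchors.at[idx, "start_date"]
            if not window.contains(anchor):
                continue
            ok = all(
                ((members["atc_code"] == code)
                 & ((members["start_date"] - anchor).abs() <= costart)).any()
                for code in trigger_set
            )
            if ok:
                fired = (anchor, int(idx))
                break
        if fired:
            signals.append(
                ToxicitySignal(
                    patient_id=window.patient_id,
                    category=rule.category,
                    date=fired[0],
                    channel="drug",
                    evidence=("prescriptions", fired[1]),
                )
            )
    return signals


def _keyword_pattern(keywords: list[str]) -> re.Pattern:
    alts = "|".join(re.escape(k) for k in keywords)
    return re.compile(rf"(?<!\w)(?:{alts})(?!\w)", re.IGNORECASE)


def scan_reports(
    reports: pd.DataFrame, rule: ToxicityIndicatorRule, window: AttributionWindow
) -> list[ToxicitySignal]:
    """Keyword channel: whole-word, case-insensitive, negation-blind.

    "no evidence of aspergillosis" still signals — the naive matcher is part
    of the validated design, not an oversight.
    """
    signals: list[ToxicitySignal] = []
    if window.empty or not rule.keyword_rules or not len(reports):
        return signals
    pattern = _keyword_pattern(rule.keyword_rules)
    mine = reports[reports["patient_id"] == window.patient_id]
    in_win = mine[
        (mine["datetime"].dt.normalize() >= window.start)
        & (mine["datetime"].dt.normalize() <= window.end)
    ]
    for idx in in_win.index.sort_values():
        if pattern.search(str(in_win.at[idx, "text"])):
            signals.append(
                ToxicitySignal(
                    patient_id=window.patient_id,
                    category=rule.category,
                    date=in_win.at[idx, "datetime"].normalize(),
                    channel="keyword",
                    evidence=("reports", int(idx)),
                )
            )
    return signals


def map_admissions(
    admissions: pd.DataFrame, rule: ToxicityIndicatorRule, window: AttributionWindow
) -> list[ToxicitySignal]:
    """Admission channel: listed ICD-10 code as main or secondary diagnosis on
    an admission overlapping the window; the ICU category fires on the ICU flag.

    The signal date is the admission date clamped into the window (an
    admission that started before the window but overlaps it signals at the
    window start)."""
    signals: list[ToxicitySignal] = []
    if window.empty or not len(admissions):
        return signals
    mine = admissions[admissions["patient_id"] == window.patient_id]
    for idx in mine.index.sort_values():
        admit = mine.at[idx, "admit_date"]
        discharge = mine.at[idx, "discharge_date"]
        if pd.isna(discharge):
            discharge = admit
        if admit > window.end or discharge < window.start:
            continue
        hit = False
        if rule.icu_flag and bool(mine.at[idx, "icu"]):
            hit = True
        if rule.admission_codes:
            codes = [mine.at[idx, "main_icd10"], *mine.at[idx, "secondary_icd10"]]
            if any(c in rule.admission_codes for c in codes):
                hit = True
        if hit:
            signals.append(
                ToxicitySignal(
                    patient_id=window.patient_id,
                    category=rule.category,
                    date=max(admit, window.start),
                    channel="admission",
                    evidence=("admissions", int(idx)),
                )
            )
    return signals


def combine_findings(signals: list[ToxicitySignal]) -> list[ToxicityFinding]:
    """Collapse signals into one finding per (patient, category).

    Keeps the earliest date and the union of channels; idempotent and
    invariant under signal order.
    """
    grouped: dict[tuple[str, str], list[ToxicitySignal]] = {}
    for s in signals:
        grouped.setdefault((s.patient_id, s.category), []).append(s)
    findings = [
        ToxicityFinding(
            patient_id=pid,
            category=cat,
            first_date=min(s.date for s in group),
            channels=frozenset(s.channel for s in group),
        )
        for (pid, cat), group in grouped.items()
    ]
    findings.sort(key=lambda f: (f.patient_id, f.category))
    return findings


def detect_toxicity(
    ds: CDMDataset,
    rules: dict[str, ToxicityIndicatorRule] | None = None,
    catalog: RegimenCatalog | None = None,
    mapping: DrugClassMapping | None = None,
    assignments: list[RegimenAssignment] | None = None,
) -> tuple[list[ToxicitySignal], list[ToxicityFinding]]:
    """Run all channels of all categories over every treated patient's window."""
    rules = rules or load_rules()
    catalog = catalog or RegimenCatalog.aml_default()
    windows = attribution_windows(ds, catalog, mapping, assignments=assignments)
    signals: list[ToxicitySignal] = []
    for pid in sorted(windows):
        window = windows[pid]
        for category in sorted(rules):
            rule = rules[category]
            if rule.lab_rules:
                signals.extend(eval_lab_indicator(ds.labs, rule, window))
            if rule.drug_rules:
                signals.extend(eval_drug_indicator(ds.prescriptions, rule, window))
            if rule.keyword_rules:
                signals.extend(scan_reports(ds.reports, rule, window))
            if rule.admission_codes or rule.icu_flag:
                signals.extend(map_admissions(ds.admissions, rule, window))
    return signals, combine_findings(signals)
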