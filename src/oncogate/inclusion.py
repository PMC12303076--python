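"""New-diagnosis detection and registry inclusion/matching.

Prospective path: every (patient, tumor group) whose earliest care
trajectory has matured for at least 28 days ("included four weeks after
their initial contact") surfaces as a candidate case, and each candidate is
classified against the registry inclusion criteria — a new oncological
diagnosis coupled with Dutch residency.  Exclusion reasons are evaluated in
a fixed precedence: non-residency, then a new trajectory for
relapsed/refractory disease (a confirmed diagnosis of the same tumor group
predating the trajectory), then a merely preliminary diagnosis.

Retrospective path: a registry extract is cross-matched against the CDM —
each registry record is matched-same-year, year-mismatch or
diagnosis-mismatch depending on whether the patient's care trajectories
carry the same tumor group in the same calendar year; a patient wholly
absent from the CDM is flagged separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cdm import CDMDataset

__all__ = [
    "CandidateCase",
    "InclusionDecision",
    "MatchReport",
    "MATURATION_DAYS",
    "detect_candidates",
    "classify_inclusion",
    "decide_inclusion",
    "retrospective_match",
]

MATURATION_DAYS = 28  # four weeks between initial contact and surfacing

REASONS = ("NONE", "NON_RESIDENT", "RELAPSE_TRAJECTORY", "PRELIMINARY_DIAGNOSIS")
MATCH_CATEGORIES = ("matched_same_year", "year_mismatch", "diagnosis_mismatch", "absent")


@dataclass(frozen=True)
class CandidateCase:
    patient_id: str
    tumor_group: str
    first_contact_date: pd.Timestamp
    diagnosis_rows: tuple[int, ...]  # triggering diagnosis row labels
    as_of: pd.Timestamp


@dataclass(frozen=True)
class InclusionDecision:
    patient_id: str
    tumor_group: str
    decision: str  # include | exclude
    reason: str  # NONE iff include

    def __post_init__(self):
        assert (self.decision == "include") == (self.reason == "NONE")


@dataclass
class MatchReport:
    """Per-record retrospective match categories plus their counts."""

    records: pd.DataFrame  # patient_id, tumor_group, diagnosis_year, category
    counts: dict[str, int]

    @property
    def n_records(self) -> int:
        return len(self.records)


def detect_candidates(ds: CDMDataset, as_of: str | pd.Timestamp) -> list[CandidateCase]:
    """Surface one candidate per (patient, tumor group) with a matured trajectory.

    The earliest trajectory start of the pair is the initial contact; the
    candidate surfaces only when ``as_of`` is at least 28 days past it
    (boundary included).  Candidates are sorted by (first contact, patient).
    """
    as_of = pd.Timestamp(as_of)
    traj = ds.trajectories
    out: list[CandidateCase] = []
    if not len(traj):
        return out
    firsts = (
        traj.groupby(["patient_id", "tumor_group"], sort=True)["start_date"]
        .min()
        .reset_index()
    )
    diag = ds.diagnoses
    mature = firsts[firsts["start_date"] + pd.Timedelta(days=MATURATION_DAYS) <= as_of]
    for _, row in mature.iterrows():
        if len(diag):
            trig = diag.index[
                (diag["patient_id"] == row["patient_id"])
                & (diag["tumor_group"] == row["tumor_group"])
                & (diag["date"] <= as_of)
            ]
        else:
            trig = []
        out.append(
            CandidateCase(
                patient_id=str(row["patient_id"]),
                tumor_group=str(row["tumor_group"]),
                first_contact_date=row["start_date"],
                diagnosis_rows=tuple(int(i) for i in trig),
                as_of=as_of,
            )
        )
    out.sort(key=lambda c: (c.first_contact_date, c.patient_id))
    return out


def classify_inclusion(candidate: CandidateCase, ds: CDMDataset) -> InclusionDecision:
    """Classify one candidate against the registry inclusion criteria.

    Reason precedence is fixed: NON_RESIDENT, then RELAPSE_TRAJECTORY (a
    confirmed same-tumor-group diagnosis predates the trajectory start),
    then PRELIMINARY_DIAGNOSIS (no confirmed diagnosis exists by the
    surfacing date), else include.
    """
    pats = ds.patients
    row = pats[pats["patient_id"] == candidate.patient_id]
    if not len(row):
        raise KeyError(f"candidate patient {candidate.patient_id!r} not in dataset")

    def decision(reason: str) -> InclusionDecision:
        return InclusionDecision(
            patient_id=candidate.patient_id,
            tumor_group=candidate.tumor_group,
            decision="include" if reason == "NONE" else "exclude",
            reason=reason,
        )

    if not bool(row["resident_nl"].iloc[0]):
        return decision("NON_RESIDENT")

    diag = ds.diagnoses
    trig = diag.loc[list(candidate.diagnosis_rows)] if candidate.diagnosis_rows else diag.iloc[0:0]
    confirmed = trig[trig["status"] == "confirmed"]
    if len(confirmed) and (confirmed["date"] < candidate.first_contact_date).any():
        return decision("RELAPSE_TRAJECTORY")
    if not len(confirmed):
        # only preliminary rows (or none at all) by the surfacing date
        return decision("PRELIMINARY_DIAGNOSIS")
    return decision("NONE")


def decide_inclusion(ds: CDMDataset, as_of: str | pd.Timestamp) -> pd.DataFrame:
    """Detect and classify all candidates; one decision row per candidate."""
    decisions = [classify_inclusion(c, ds) for c in detect_candidates(ds, as_of)]
    return pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in decisions],
            "tumor_group": [d.tumor_group for d in decisions],
            "decision": [d.decision for d in decisions],
            "reason": [d.reason for d in decisions],
        }
    )


def retrospective_match(registry: pd.DataFrame, ds: CDMDataset) -> MatchReport:
    """Cross-match a registry extract against the CDM trajectories.

    A record is ``matched_same_year`` iff the patient has a trajectory of
    the same tumor group starting in the registry's diagnosis year;
    ``year_mismatch`` iff same patient and tumor group exist only in other
    years; ``diagnosis_mismatch`` iff the patient has trajectories of other
    tumor groups only; a patient absent from the CDM is flagged ``absent``.
    The categories partition the registry records.
    """
    traj = ds.trajectories
    known_patients = set(ds.patients["patient_id"]) if len(ds.patients) else set()
    categories = []
    for _, rec in registry.iterrows():
        pid, group, year = rec["patient_id"], rec["tumor_group"], int(rec["diagnosis_year"])
        mine = traj[traj["patient_id"] == pid] if len(traj) else traj
        if pid not in known_patients and not len(mine):
            categories.append("absent")
            continue
        same_group = mine[mine["tumor_group"] == group]
        if len(same_group) and (same_group["start_date"].dt.year == year).any():
            categories.append("matched_same_year")
        elif len(same_group):
            categories.append("year_mismatch")
        elif len(mine):
            categories.append("diagnosis_mismatch")
        else:
            categories.append("absent")
    records = registry[["patient_id", "tumor_group", "diagnosis_year"]].copy()
    records["category"] = categories
    counts = {c: int((records["category"] == c).sum()) for c in MATCH_CATEGORIES}
    assert sum(counts.values()) == len(records)
    return MatchReport(records=records, counts=counts)
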