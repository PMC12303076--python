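"""Accuracy scoring of every engine against ground truth.

All percentages use the printed-table convention of the validated system:
positive predictive value (correct predictions over all predictions),
rounded half-up to a whole percent; a stratum with zero predictions prints a
blank accuracy, never 0%.  For regimens, a truth-denominator (recall-style)
table is computed and labelled alongside the predicted-denominator table,
because both readings of a printed accuracy column are defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .inclusion import MatchReport
from .regimens import RegimenAssignment, RegimenCatalog, UNMATCHED
from .toxicity import CATEGORIES as TOXICITY_CATEGORIES
from .toxicity import ToxicityFinding

__all__ = [
    "round_half_up_pct",
    "accuracy_table",
    "check_table_consistency",
    "score_inclusion",
    "score_regimens",
    "score_toxicity",
    "score_retrospective",
    "score_lab_recovery",
]

REGIMEN_DATE_TOL_DAYS = 3


def round_half_up_pct(numer: float, denom: float) -> int | None:
    """100*numer/denom rounded half-up to a whole percent; None when undefined."""
    if denom == 0:
        return None
    return int(
        (Decimal(str(numer)) * 100 / Decimal(str(denom))).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def accuracy_table(rows: list[tuple[str, int, int]], overall_label: str = "Total") -> pd.DataFrame:
    """Build an accuracy table from (stratum, n_predicted, n_correct) rows."""
    recs = []
    for stratum, n_pred, n_corr in rows:
        assert n_corr <= n_pred, f"{stratum}: n_correct > n_predicted"
        recs.append(
            {
                "stratum": stratum,
                "n_predicted": n_pred,
                "n_correct": n_corr,
                "accuracy_pct": round_half_up_pct(n_corr, n_pred),
            }
        )
    total_pred = sum(r["n_predicted"] for r in recs)
    total_corr = sum(r["n_correct"] for r in recs)
    recs.append(
        {
            "stratum": overall_label,
            "n_predicted": total_pred,
            "n_correct": total_corr,
            "accuracy_pct": round_half_up_pct(total_corr, total_pred),
        }
    )
    table = pd.DataFrame(recs, columns=["stratum", "n_predicted", "n_correct", "accuracy_pct"])
    check_table_consistency(table)
    return table


def check_table_consistency(table: pd.DataFrame) -> None:
    """Every printed percentage must be recomputable from its printed counts."""
    for _, row in table.iterrows():
        expected = round_half_up_pct(row["n_correct"], row["n_predicted"])
        got = row["accuracy_pct"]
        ok = (expected is None and pd.isna(got)) or expected == got
        assert ok, f"inconsistent row {row['stratum']!r}: {got} != {expected}"


@dataclass
class InclusionScore:
    decision_table: pd.DataFrame  # include/exclude strata, PPV vs truth
    include_pct: int | None  # share of candidates meeting the criteria
    reason_breakdown: pd.DataFrame  # per exclusion reason: n, pct of exclusions
    reason_recovery_pct: int | None  # planted exclusion reasons recovered exactly


def score_inclusion(decisions: pd.DataFrame, truth: pd.DataFrame) -> InclusionScore:
    """Score inclusion decisions against planted truth.

    ``decisions`` and ``truth`` carry (patient_id, tumor_group, decision,
    reason) over the same candidate universe; a universe mismatch is a
    scoring error.
    """
    key = ["patient_id", "tumor_group"]
    if len(decisions) or len(truth):
        d_keys = set(map(tuple, decisions[key].itertuples(index=False)))
        t_keys = set(map(tuple, truth[key].itertuples(index=False)))
        if d_keys != t_keys:
            missing = t_keys - d_keys
            extra = d_keys - t_keys
            raise ValueError(
                f"candidate universe mismatch: {len(missing)} truth-only, {len(extra)} decision-only"
            )
    if not len(decisions):
        empty = pd.DataFrame(columns=["stratum", "n_predicted", "n_correct", "accuracy_pct"])
        return InclusionScore(empty, None, pd.DataFrame(columns=["reason", "n", "pct"]), None)

    merged = decisions.merge(truth, on=key, suffixes=("", "_true"))
    merged["correct"] = (merged["decision"] == merged["decision_true"]) & (
        merged["reason"] == merged["reason_true"]
    )
    rows = []
    for stratum in ("include", "exclude"):
        sub = merged[merged["decision"] == stratum]
        rows.append((stratum, len(sub), int(sub["correct"].sum())))
    table = accuracy_table(rows)

    include_pct = round_half_up_pct((merged["decision"] == "include").sum(), len(merged))

    excl = merged[merged["decision"] == "exclude"]
    breakdown = []
    for reason in ("NON_RESIDENT", "RELAPSE_TRAJECTORY", "PRELIMINARY_DIAGNOSIS"):
        n = int((excl["reason"] == reason).sum())
        breakdown.append({"reason": reason, "n": n, "pct": round_half_up_pct(n, len(excl))})
    breakdown = pd.DataFrame(breakdown, columns=["reason", "n", "pct"])

    excl_truth = merged[merged["decision_true"] == "exclude"]
    recovery = round_half_up_pct(
        int((excl_truth["reason"] == excl_truth["reason_true"]).sum()), len(excl_truth)
    ) if len(excl_truth) else None
    return InclusionScore(table, include_pct, breakdown, recovery)


@dataclass
class RegimenScore:
    by_predicted: pd.DataFrame  # PPV per catalog category (denominator = predictions)
    by_truth: pd.DataFrame  # recall per category (denominator = truth regimens)
    n_predicted: int
    n_correct_predicted: int
    mismatched: pd.DataFrame = field(default_factory=pd.DataFrame)  # wrong predictions


def _match_predictions(
    assignments: list[RegimenAssignment], truth: pd.DataFrame, tol_days: int
) -> tuple[list[bool], list[bool]]:
    """Greedy 1–1 matching of predictions to truth regimens on
    (patient, name, start±tol, end±tol); returns per-prediction and
    per-truth-row correctness flags."""
    tol = pd.Timedelta(days=tol_days)
    used = [False] * len(truth)
    truth_rows = list(truth.itertuples(index=False))
    pred_ok = []
    for a in assignments:
        hit = None
        for j, t in enumerate(truth_rows):
            if used[j]:
                continue
            if (
                t.patient_id == a.patient_id
                and t.name == a.name
                and abs(t.start - a.start) <= tol
                and abs(t.end - a.end) <= tol
            ):
                hit = j
                break
        if hit is not None:
            used[hit] = True
        pred_ok.append(hit is not None)
    return pred_ok, used


def score_regimens(
    assignments: list[RegimenAssignment],
    truth: pd.DataFrame,
    catalog: RegimenCatalog,
    date_tol_days: int = REGIMEN_DATE_TOL_DAYS,
) -> RegimenScore:
    """Score derived regimen assignments against planted truth regimens.

    A prediction is correct iff it matches a (still unmatched) truth regimen
    on patient, name, and both dates within ±``date_tol_days``.  The
    predicted-denominator table strata are catalog categories of the
    *predicted* names (spurious predictions count against their category);
    the truth-denominator table stratifies truth regimens the same way.
    """
    pred_ok, truth_ok = _match_predictions(assignments, truth, date_tol_days)

    def category_for(name: str) -> str:
        if name == UNMATCHED:
            return "Unmatched"
        return catalog.category_of(name) or "Not in catalog"

    cat_order: list[str] = []
    for e in catalog.entries:
        if e.category not in cat_order:
            cat_order.append(e.category)

    pred_rows: dict[str, list[int]] = {}
    for a, ok in zip(assignments, pred_ok):
        cat = category_for(a.name)
        pred_rows.setdefault(cat, [0, 0])
        pred_rows[cat][0] += 1
        pred_rows[cat][1] += int(ok)
    ordered = [c for c in cat_order if c in pred_rows] + [
        c for c in pred_rows if c not in cat_order
    ]
    by_predicted = accuracy_table([(c, *pred_rows[c]) for c in ordered])

    truth_rows: dict[str, list[int]] = {}
    for (_, t), ok in zip(truth.iterrows(), truth_ok):
        cat = category_for(t["name"])
        truth_rows.setdefault(cat, [0, 0])
        truth_rows[cat][0] += 1
        truth_rows[cat][1] += int(ok)
    ordered_t = [c for c in cat_order if c in truth_rows] + [
        c for c in truth_rows if c not in cat_order
    ]
    by_truth = accuracy_table([(c, *truth_rows[c]) for c in ordered_t])

    mism = pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "name": a.name,
                "start": a.start,
                "end": a.end,
                "category": category_for(a.name),
            }
            for a, ok in zip(assignments, pred_ok)
            if not ok
        ],
        columns=["patient_id", "name", "start", "end", "category"],
    )
    return RegimenScore(
        by_predicted=by_predicted,
        by_truth=by_truth,
        n_predicted=len(assignments),
        n_correct_predicted=int(sum(pred_ok)),
        mismatched=mism,
    )


INDICATOR_CHANNELS = {"lab", "drug", "keyword"}


def score_toxicity(findings: list[ToxicityFinding], truth: pd.DataFrame) -> pd.DataFrame:
    """Per-category toxicity accuracy with indicator / admission sub-rows.

    For every CTCAE category the total row counts patients signaled by any
    channel; sub-rows count patients signaled via indicator channels (lab,
    drug, keyword) and via the admission channel, which may overlap.  A
    signaled patient is correct iff the truth holds an event of that
    category for that patient.  Accuracy is PPV, blank when nothing was
    predicted.
    """
    truth_pairs = set(map(tuple, truth[["patient_id", "category"]].itertuples(index=False))) if len(truth) else set()
    recs = []
    for category in TOXICITY_CATEGORIES:
        cat_findings = [f for f in findings if f.category == category]
        groups = {
            "total": cat_findings,
            "indicator": [f for f in cat_findings if f.channels & INDICATOR_CHANNELS],
            "admission": [f for f in cat_findings if "admission" in f.channels],
        }
        for label, group in groups.items():
            n_pred = len({f.patient_id for f in group})
            n_corr = len({f.patient_id for f in group if (f.patient_id, category) in truth_pairs})
            recs.append(
                {
                    "category": category,
                    "row": label,
                    "n_predicted": n_pred,
                    "n_correct": n_corr,
                    "accuracy_pct": round_half_up_pct(n_corr, n_pred),
                }
            )
    return pd.DataFrame(recs, columns=["category", "row", "n_predicted", "n_correct", "accuracy_pct"])


def toxicity_recovery_pct(findings: list[ToxicityFinding], truth: pd.DataFrame) -> int | None:
    """Share of planted toxicity events recovered by any channel (sensitivity)."""
    if not len(truth):
        return None
    found = {(f.patient_id, f.category) for f in findings}
    planted = set(map(tuple, truth[["patient_id", "category"]].itertuples(index=False)))
    return round_half_up_pct(len(planted & found), len(planted))


def score_retrospective(report: MatchReport) -> pd.DataFrame:
    """Counts and whole-percent shares per retrospective match category."""
    total = report.n_records
    recs = []
    for category, n in report.counts.items():
        recs.append({"category": category, "n": n, "pct": round_half_up_pct(n, total)})
    recs.append({"category": "total", "n": total, "pct": 100 if total else None})
    return pd.DataFrame(recs, columns=["category", "n", "pct"])


def score_lab_recovery(report_verdicts: pd.DataFrame, typo_rows: pd.DataFrame) -> bool:
    """True iff the value-mismatch pairs are exactly the injected typo rows
    (compared on the pairing key)."""
    mismatch_keys = set(
        map(
            tuple,
            report_verdicts.loc[
                report_verdicts["verdict"] == "value_mismatch",
                ["patient_id", "analyte_name", "datetime"],
            ].itertuples(index=False),
        )
    )
    typo_keys = set(
        map(tuple, typo_rows[["patient_id", "analyte_name", "datetime"]].itertuples(index=False))
    )
    return mismatch_keys == typo_keys
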