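"""Treatment-regimen inference from ATC-coded prescription streams.

Named regimens (e.g. D-Rd = daratumumab + lenalidomide + dexamethasone) are
inferred in three steps:

1. every prescription is normalized to a drug *class* via an ATC → class
   mapping (dexamethasone and prednisone collapse to one shared
   ``corticosteroid`` class);
2. prescriptions of one patient are grouped into episodes by co-start:
   the earliest unassigned oncology-class prescription anchors a 7-day
   half-open window and every prescription starting inside it joins the
   episode ("combined when given within the same week");
3. each episode is matched against a regimen catalog by largest drug-class
   subset, with a dose-based lenalidomide-maintenance vs. Rd disambiguation,
   and consecutive same-name episodes separated by at most 60 days are merged
   into one assignment.  Stem-cell transplants enter the sequence as
   event-based assignments (Auto-SCT / Allo-SCT) taken from the SCT table,
   not from prescriptions.

The window, the shared corticosteroid class and the strictly structural
matching are what make the engine's characteristic failure modes possible:
a 15 mg/day lenalidomide maintenance reads as Rd, lenalidomide–prednisone
(not in the catalog) reads as Rd, and two regimens co-started within one
week merge into their union.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .cdm import ATC_RE, CDMDataset

__all__ = [
    "DrugClassMapping",
    "RegimenCatalog",
    "CatalogEntry",
    "DrugEpisode",
    "RegimenAssignment",
    "normalize_drug",
    "build_episodes",
    "match_regimen",
    "derive_sequence",
    "UNMATCHED",
]

UNMATCHED = "UNMATCHED"
CORTICOSTEROID = "corticosteroid"

#: default maximum daily lenalidomide dose (mg) still read as maintenance
MAINTENANCE_MAX_DOSE_MG = 10.0
#: default same-week co-start window (half-open, days)
WINDOW_DAYS = 7
#: default maximum gap (days) across which same-name episodes merge
MERGE_GAP_DAYS = 60


def _data_path(name: str) -> Path:
    return Path(str(resources.files("oncogate").joinpath("data", name)))


class DrugClassMapping:
    """ATC code → normalized drug class (many codes may share one class)."""

    def __init__(self, atc_to_class: dict[str, str], atc_to_name: dict[str, str] | None = None):
        self._map = dict(atc_to_class)
        self._names = dict(atc_to_name or {})

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugClassMapping":
        atc_to_class, atc_to_name = {}, {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                atc_to_class[row["atc_code"].strip()] = row["drug_class"].strip()
                atc_to_name[row["atc_code"].strip()] = row.get("drug_name", "").strip()
        return cls(atc_to_class, atc_to_name)

    @classmethod
    def default(cls) -> "DrugClassMapping":
        return cls.from_csv(_data_path("atc_classes.csv"))

    def drug_class(self, atc_code: str) -> str | None:
        return self._map.get(atc_code)

    def drug_name(self, atc_code: str) -> str:
        return self._names.get(atc_code, atc_code)

    def codes_for_class(self, drug_class: str) -> list[str]:
        return [c for c, k in self._map.items() if k == drug_class]

    def classes(self) -> set[str]:
        return set(self._map.values())

    def __contains__(self, atc_code: str) -> bool:
        return atc_code in self._map

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    category: str
    drug_classes: frozenset[str]
    maintenance: bool = False

    @property
    def event_based(self) -> bool:
        """HSCT entries are matched from transplant records, not prescriptions."""
        return not self.drug_classes


class RegimenCatalog:
    """Ordered regimen catalog; file order is the matching tie-break order."""

    def __init__(self, entries: list[CatalogEntry]):
        names = [e.name for e in entries]
        if len(names) != len(set(names)):
            raise ValueError("catalog names must be unique")
        self.entries = list(entries)
        self._by_name = {e.name: e for e in entries}

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegimenCatalog":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                classes = frozenset(
                    p.strip() for p in row["drug_classes"].split(";") if p.strip()
                )
                entries.append(
                    CatalogEntry(
                        name=row["name"].strip(),
                        category=row["category"].strip(),
                        drug_classes=classes,
                        maintenance=row.get("maintenance_flag", "false").strip().lower()
                        in ("true", "1", "yes"),
                    )
                )
        return cls(entries)

    @classmethod
    def mm_default(cls) -> "RegimenCatalog":
        """Multiple-myeloma catalog (triplets/quadruplets, bispecifics, CAR-T, HSCT)."""
        return cls.from_csv(_data_path("mm_catalog.csv"))

    @classmethod
    def aml_default(cls) -> "RegimenCatalog":
        """Starter AML catalog (7+3 variants, HMA-based, targeted, HSCT); user-replaceable."""
        return cls.from_csv(_data_path("aml_catalog.csv"))

    def get(self, name: str) -> CatalogEntry | None:
        return self._by_name.get(name)

    def category_of(self, name: str) -> str | None:
        entry = self._by_name.get(name)
        return entry.category if entry else None

    def drug_entries(self) -> list[CatalogEntry]:
        return [e for e in self.entries if not e.event_based]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DrugEpisode:
    """One same-week co-start group of oncology-class prescriptions."""

    patient_id: str
    classes: frozenset[str]
    members: tuple[int, ...]  # prescription row labels
    anchor: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp
    max_dose: dict[str, float] = field(default_factory=dict)  # per class, NaN-free


@dataclass
class RegimenAssignment:
    patient_id: str
    name: str  # catalog name, "Auto-SCT"/"Allo-SCT", or UNMATCHED
    start: pd.Timestamp
    end: pd.Timestamp
    category: str | None = None
    members: tuple[int, ...] = ()

    @property
    def matched(self) -> bool:
        return self.name != UNMATCHED


def normalize_drug(atc_code: str, mapping: DrugClassMapping) -> str | None:
    """Map one prescription's ATC code to its drug class.

    Returns ``None`` for well-formed codes outside the mapping (such
    prescriptions are ignored by episode building); raises ``ValueError``
    for malformed ATC codes.
    """
    code = str(atc_code).strip()
    if not ATC_RE.match(code):
        raise ValueError(f"malformed ATC code {code!r}")
    return mapping.drug_class(code)


def build_episodes(
    prescriptions: pd.DataFrame,
    mapping: DrugClassMapping,
    window_days: int = WINDOW_DAYS,
) -> list[DrugEpisode]:
    """Group one patient's (or one table's) prescriptions into co-start episodes.

    Greedy anchoring: the earliest unassigned oncology-class prescription
    opens an episode; every prescription starting within
    ``[anchor, anchor + window_days)`` joins it.  Prescriptions whose ATC
    code is outside the mapping never enter an episode.  The result is
    invariant under permutation of the input rows.
    """
    episodes: list[DrugEpisode] = []
    if not len(prescriptions):
        return episodes
    rx = prescriptions.copy()
    rx["_class"] = [normalize_drug(c, mapping) for c in rx["atc_code"]]
    rx = rx[rx["_class"].notna()]
    if not len(rx):
        return episodes
    # missing end_date means a single administration on start_date
    rx["_end"] = rx["end_date"].fillna(rx["start_date"])
    window = pd.Timedelta(days=window_days)
    for patient_id, grp in rx.groupby("patient_id", sort=True):
        # content sort makes episode membership independent of row order
        grp = grp.sort_values(
            ["start_date", "atc_code", "_end", "drug_name"], kind="stable"
        )
        remaining = grp
        while len(remaining):
            anchor = remaining["start_date"].iloc[0]
            in_win = remaining["start_date"] < anchor + window
            member_rows = remaining[in_win]
            max_dose = {
                cls: float(sub["dose_mg_per_day"].max())
                for cls, sub in member_rows.groupby("_class")
                if not math.isnan(float(sub["dose_mg_per_day"].max()))
            }
            episodes.append(
                DrugEpisode(
                    patient_id=str(patient_id),
                    classes=frozenset(member_rows["_class"]),
                    members=tuple(sorted(member_rows.index)),
                    anchor=anchor,
                    start=member_rows["start_date"].min(),
                    end=member_rows["_end"].max(),
                    max_dose=max_dose,
                )
            )
            remaining = remaining[~in_win]
    episodes.sort(key=lambda e: (e.patient_id, e.start))
    return episodes


def match_regimen(
    episode: DrugEpisode,
    catalog: RegimenCatalog,
    maintenance_max_dose: float = MAINTENANCE_MAX_DOSE_MG,
) -> RegimenAssignment:
    """Assign the catalog entry whose drug classes form the largest subset
    of the episode's class set.

    Ties break toward the larger entry, then catalog order.  An episode whose
    only anti-myeloma class is lenalidomide is read as lenalidomide
    maintenance iff its dose is at most ``maintenance_max_dose`` mg/day and no
    corticosteroid co-occurs, else as Rd; this reproduces the known
    15 mg-maintenance → Rd misread.  With no subset entry at all the episode
    is ``UNMATCHED``.
    """
    if not episode.classes:
        raise ValueError("cannot match an empty episode")
    best: CatalogEntry | None = None
    for entry in catalog.drug_entries():
        if entry.drug_classes <= episode.classes:
            if best is None or len(entry.drug_classes) > len(best.drug_classes):
                best = entry
    name = best.name if best else UNMATCHED

    # lenalidomide maintenance vs. Rd disambiguation (dose rule)
    non_steroid = episode.classes - {CORTICOSTEROID}
    if non_steroid == {"lenalidomide"} and catalog.get("Rd") is not None:
        maintenance_entry = next(
            (e for e in catalog.drug_entries()
             if e.maintenance and e.drug_classes == frozenset({"lenalidomide"})),
            None,
        )
        dose = episode.max_dose.get("lenalidomide")
        low_dose = dose is None or dose <= maintenance_max_dose
        if CORTICOSTEROID in episode.classes or not low_dose:
            name = "Rd"
        elif maintenance_entry is not None:
            name = maintenance_entry.name

    return RegimenAssignment(
        patient_id=episode.patient_id,
        name=name,
        start=episode.start,
        end=episode.end,
        category=catalog.category_of(name),
        members=episode.members,
    )


def _merge_consecutive(
    assignments: list[RegimenAssignment], merge_gap_days: int
) -> list[RegimenAssignment]:
    merged: list[RegimenAssignment] = []
    gap = pd.Timedelta(days=merge_gap_days)
    for a in assignments:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and a.name == prev.name
            and a.name != UNMATCHED
            and a.start - prev.end <= gap
        ):
            prev.end = max(prev.end, a.end)
            prev.members = tuple(sorted(set(prev.members) | set(a.members)))
        else:
            merged.append(a)
    return merged


def derive_sequence(
    ds: CDMDataset,
    catalog: RegimenCatalog,
    mapping: DrugClassMapping | None = None,
    window_days: int = WINDOW_DAYS,
    merge_gap_days: int = MERGE_GAP_DAYS,
    maintenance_max_dose: float = MAINTENANCE_MAX_DOSE_MG,
    patient_ids: set[str] | None = None,
) -> list[RegimenAssignment]:
    """Derive each patient's ordered regimen sequence from the full dataset.

    Prescription episodes are matched against the catalog; consecutive
    episodes with the same regimen name separated by at most
    ``merge_gap_days`` collapse into a single assignment whose start (end)
    is the earliest (latest) member prescription date.  Transplant records
    are emitted as event-based Auto-SCT / Allo-SCT assignments with
    start = end = transplant date.
    """
    mapping = mapping or DrugClassMapping.default()
    rx = ds.prescriptions
    sct = ds.sct
    if patient_ids is not None:
        rx = rx[rx["patient_id"].isin(patient_ids)]
        sct = sct[sct["patient_id"].isin(patient_ids)]

    episodes = build_episodes(rx, mapping, window_days=window_days)
    by_patient: dict[str, list[RegimenAssignment]] = {}
    for ep in episodes:
        by_patient.setdefault(ep.patient_id, []).append(
            match_regimen(ep, catalog, maintenance_max_dose=maintenance_max_dose)
        )

    out: list[RegimenAssignment] = []
    for pid in sorted(by_patient):
        drugs = sorted(by_patient[pid], key=lambda a: (a.start, a.name))
        out.extend(_merge_consecutive(drugs, merge_gap_days))

    for idx in sct.index:
        kind = sct.at[idx, "kind"]
        name = "Auto-SCT" if kind == "auto" else "Allo-SCT"
        date = sct.at[idx, "date"]
        out.append(
            RegimenAssignment(
                patient_id=str(sct.at[idx, "patient_id"]),
                name=name,
                start=date,
                end=date,
                category=catalog.category_of(name) or "HSCT",
                members=(),
            )
        )

    out.sort(key=lambda a: (a.patient_id, a.start, a.name))
    return out


def assignments_frame(assignments: list[RegimenAssignment]) -> pd.DataFrame:
    """Tabular view of a derived sequence (one row per assignment)."""
    return pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in assignments],
            "name": [a.name for a in assignments],
            "start": [a.start for a in assignments],
            "end": [a.end for a in assignments],
            "category": [a.category for a in assignments],
        }
    )
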