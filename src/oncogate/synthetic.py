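"""Seeded synthetic EHR cohort generator with known ground truth.

The generator emits a complete CDM dataset — a Dutch-hospital-style extract
with ICD-10 / ATC / LOINC coding — together with the ground truth of every
planted fact, so that every engine can be validated without any real patient
data.  Its defaults reproduce the composition of the validated study cohort:

* a prospective cohort of 1,287 AML + lung candidates of which 68 fail the
  registry inclusion criteria for three reasons (11 non-resident, 27
  relapsed/refractory trajectory, 30 preliminary-only diagnosis), plus the
  117 MM and 16 breast-cancer patients of the other validation arms;
* a multiple-myeloma treatment cohort whose prescriptions realize 198
  *derivable* regimens — 191 clean catalog regimens plus the five known
  misclassification scenarios (two 15 mg lenalidomide maintenances read as
  Rd, lenalidomide–prednisone read as Rd, melphalan–prednisone read as
  melphalan, a same-week D-mono + Rd co-start merged into D-Rd, and a
  late daratumumab add-on to ongoing maintenance read as D-mono);
* 254 treated AML patients with a 100%-recoverable regimen plan and planted
  CTCAE toxicity events realized through their stated evidence channels;
* a 384-record registry extract with 342 same-year matches, 14 year
  mismatches and 28 diagnosis mismatches;
* 1,689 laboratory items mirroring a trial-style manual registration, with
  a typo-injection operation for the manual copy.

Everything is deterministic per seed; with failure modes and background
noise disabled every engine recovers the planted truth exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cdm import CDMDataset
from .regimens import CatalogEntry, DrugClassMapping, RegimenCatalog

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "ConfigError",
    "FAILURE_MODES",
    "generate_cohort",
    "make_failure_fixture",
    "corrupt_manual_labs",
]

FAILURE_MODES = (
    "rd_vs_len15",
    "len_pred",
    "mel_pred",
    "drd_merge",
    "maint_dmono_vs_drd",
)

ICD10_BY_GROUP = {"AML": "C92.0", "MM": "C90.0", "lung": "C34.9", "breast": "C50.9"}

# 27 trial-style analytes: basic hematology, blood chemistry, tumor markers.
TIBET_ANALYTES: list[tuple[str, str, str, float, float]] = [
    ("hemoglobin", "718-7", "mmol/L", 8.0, 0.8),
    ("hematocrit", "4544-3", "L/L", 0.40, 0.04),
    ("erythrocytes", "789-8", "10*12/L", 4.5, 0.4),
    ("leukocytes", "6690-2", "10*9/L", 6.0, 1.8),
    ("neutrophils", "751-8", "10*9/L", 3.8, 1.2),
    ("lymphocytes", "731-0", "10*9/L", 1.8, 0.5),
    ("monocytes", "742-7", "10*9/L", 0.5, 0.15),
    ("eosinophils", "711-2", "10*9/L", 0.2, 0.08),
    ("basophils", "704-7", "10*9/L", 0.05, 0.02),
    ("platelets", "777-3", "10*9/L", 250.0, 60.0),
    ("sodium", "2951-2", "mmol/L", 140.0, 2.5),
    ("potassium", "2823-3", "mmol/L", 4.2, 0.3),
    ("calcium", "17861-6", "mmol/L", 2.40, 0.10),
    ("magnesium", "19123-9", "mmol/L", 0.85, 0.07),
    ("phosphate", "2777-1", "mmol/L", 1.10, 0.15),
    ("glucose", "2345-7", "mmol/L", 5.5, 0.8),
    ("urea", "3094-0", "mmol/L", 6.0, 1.5),
    ("creatinine", "2160-0", "umol/L", 75.0, 12.0),
    ("albumin", "1751-7", "g/L", 42.0, 3.0),
    ("bilirubin", "1975-2", "umol/L", 9.0, 3.0),
    ("alt", "1742-6", "U/L", 25.0, 8.0),
    ("ast", "1920-8", "U/L", 28.0, 8.0),
    ("alp", "6768-6", "U/L", 80.0, 20.0),
    ("ggt", "2324-2", "U/L", 35.0, 12.0),
    ("ldh", "2532-0", "U/L", 190.0, 35.0),
    ("ca 15-3", "6875-9", "kU/L", 22.0, 8.0),
    ("cea", "2039-6", "ug/L", 3.0, 1.2),
]

# benign background prescriptions (outside every regimen/toxicity mapping)
BENIGN_ATC = [
    ("C09AA02", "enalapril"),
    ("A02BC01", "omeprazole"),
    ("N02BE01", "paracetamol"),
    ("C07AB02", "metoprolol"),
    ("A10BA02", "metformin"),
]

# noise indicator-drug triggers exercising toxicity false-positive paths:
# (category they spuriously signal, list of ATC codes co-started)
NOISE_TRIGGERS = [
    ("sepsis", ["J01DH02"]),
    ("typhlitis", ["J01DE01", "J01XD01"]),
    ("invasive_aspergillosis", ["J02AC03"]),
    ("venous_thrombosis", ["B01AB05"]),
    ("invasive_candidiasis", ["J02AX04"]),
]

# planted toxicity evidence per channel (reconstruction-level defaults)
TOX_LAB_EVIDENCE = {
    "acute_renal_failure": ("creatinine", "2160-0", "umol/L", 80.0, 140.0),
    "hepatic_toxicity": ("bilirubin", "1975-2", "umol/L", None, 75.0),
}
TOX_DRUG_EVIDENCE = {
    "invasive_aspergillosis": ["J02AC03"],
    "invasive_candidiasis": ["J02AX04"],
    "sepsis": ["J01DH02"],
    "typhlitis": ["J01DE01", "J01XD01"],
    "venous_thrombosis": ["B01AB05"],
}
TOX_KEYWORD_EVIDENCE = {
    "hemorrhage": "Intracranial hemorrhage with midline shift.",
    "pulmonary_toxicity": "Diffuse ground-glass opacities suggestive of pneumonitis.",
    "invasive_aspergillosis": "Nodular lesion suspect for invasive aspergillosis.",
}
TOX_ADMISSION_EVIDENCE = {
    "hemorrhage": "K92.2",
    "invasive_aspergillosis": "B44.0",
    "invasive_candidiasis": "B37.7",
    "pulmonary_toxicity": "J70.2",
    "sepsis": "A41.9",
    "typhlitis": "K52.9",
}
ICU_NEUTRAL_CODE = "Z51.1"  # admission main code that triggers no category list


class ConfigError(Exception):
    """The generator plan is invalid or infeasible."""


@dataclass(frozen=True)
class RegimenPlanItem:
    """One planned block of regimens: a catalog name or a failure mode."""

    name: str | None
    count: int
    failure_mode: str | None = None


@dataclass(frozen=True)
class ToxicityPlanItem:
    category: str
    count: int
    channel: str  # lab | drug | keyword | admission | icu


def default_mm_plan() -> list[RegimenPlanItem]:
    clean = [
        ("D-VRd", 12), ("D-Rd", 12), ("D-VTd", 6), ("D-Vd", 5), ("D-VCd", 4),
        ("D-Pd", 4), ("D-mono", 3), ("D-VMP", 2), ("Isa-KRd", 2), ("Isa-Kd", 2),
        ("Isa-Pd", 1),
        ("VRd", 8), ("VCd", 5), ("VTd", 4), ("IRd", 3), ("Pom-Vd", 2),
        ("Vd", 8), ("KRd", 5), ("Kd", 3),
        ("Rd", 14), ("Lenalidomide maintenance", 8), ("Pd", 5), ("PCd", 3),
        ("P-mono", 2), ("Iberdomide maintenance", 1),
        ("Tec", 8), ("Elr", 4), ("Tal-Pd", 3), ("Trial", 2),
        ("CAR-T", 5),
        ("ERd", 3), ("Melphalan", 3), ("EPd", 2), ("Bridging", 1),
        ("Auto-SCT", 30), ("Allo-SCT", 6),
    ]
    plan = [RegimenPlanItem(name, count) for name, count in clean]
    plan += [
        RegimenPlanItem(None, 2, "rd_vs_len15"),
        RegimenPlanItem(None, 1, "len_pred"),
        RegimenPlanItem(None, 1, "mel_pred"),
        RegimenPlanItem(None, 1, "drd_merge"),
        RegimenPlanItem(None, 1, "maint_dmono_vs_drd"),
    ]
    return plan


def default_aml_plan() -> list[RegimenPlanItem]:
    return [
        RegimenPlanItem(name, count)
        for name, count in [
            ("7+3", 90), ("Aza-Ven", 70), ("Azacitidine", 30), ("Midostaurin-7+3", 30),
            ("Gilteritinib", 14), ("GO-7+3", 10), ("Hydroxyurea", 10),
        ]
    ]


def default_toxicity_plan() -> list[ToxicityPlanItem]:
    return [
        ToxicityPlanItem(cat, n, ch)
        for cat, ch, n in [
            ("acute_renal_failure", "lab", 5),
            ("hepatic_toxicity", "lab", 5),
            ("hemorrhage", "keyword", 2),
            ("hemorrhage", "admission", 3),
            ("icu_admission", "icu", 4),
            ("invasive_aspergillosis", "drug", 2),
            ("invasive_aspergillosis", "admission", 2),
            ("invasive_candidiasis", "drug", 2),
            ("invasive_candidiasis", "admission", 1),
            ("pulmonary_toxicity", "keyword", 1),
            ("pulmonary_toxicity", "admission", 2),
            ("sepsis", "drug", 4),
            ("sepsis", "admission", 2),
            ("typhlitis", "drug", 3),
            ("typhlitis", "admission", 2),
            ("venous_thrombosis", "drug", 3),
        ]
    ]


@dataclass
class GeneratorConfig:
    """Full study-condition plan for one synthetic hospital extract."""

    seed: int = 0
    n_prospective: dict[str, int] = field(
        default_factory=lambda: {"AML": 349, "lung": 938, "MM": 117, "breast": 16}
    )
    exclusion_scenario_counts: dict[str, int] = field(
        default_factory=lambda: {
            "non_resident": 11,
            "relapse_trajectory": 27,
            "preliminary_diagnosis": 30,
        }
    )
    mm_regimen_plan: list[RegimenPlanItem] = field(default_factory=default_mm_plan)
    aml_regimen_plan: list[RegimenPlanItem] = field(default_factory=default_aml_plan)
    toxicity_plan: list[ToxicityPlanItem] = field(default_factory=default_toxicity_plan)
    registry_counts: dict[str, int] = field(
        default_factory=lambda: {"matched": 342, "year_mismatch": 14, "diagnosis_mismatch": 28}
    )
    registry_tumor_counts: dict[str, int] = field(
        default_factory=lambda: {"AML": 168, "lung": 216}
    )
    n_lab_items: int = 1689
    lab_typo_count: int = 7
    background_noise: bool = True
    noise_fp_triggers: int = 5
    noise_benign_rx: int = 40
    noise_routine_labs: int = 60
    as_of: str = "2023-09-30"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_prospective": dict(self.n_prospective),
            "exclusion_scenario_counts": dict(self.exclusion_scenario_counts),
            "mm_regimen_plan": [
                {"name": p.name, "count": p.count, "failure_mode": p.failure_mode}
                for p in self.mm_regimen_plan
            ],
            "aml_regimen_plan": [
                {"name": p.name, "count": p.count, "failure_mode": p.failure_mode}
                for p in self.aml_regimen_plan
            ],
            "toxicity_plan": [
                {"category": p.category, "count": p.count, "channel": p.channel}
                for p in self.toxicity_plan
            ],
            "registry_counts": dict(self.registry_counts),
            "registry_tumor_counts": dict(self.registry_tumor_counts),
            "n_lab_items": self.n_lab_items,
            "lab_typo_count": self.lab_typo_count,
            "background_noise": self.background_noise,
            "noise_fp_triggers": self.noise_fp_triggers,
            "noise_benign_rx": self.noise_benign_rx,
            "noise_routine_labs": self.noise_routine_labs,
            "as_of": self.as_of,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        cfg = cls()
        for key in ("seed", "n_lab_items", "lab_typo_count", "background_noise",
                    "noise_fp_triggers", "noise_benign_rx", "noise_routine_labs", "as_of"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for key in ("n_prospective", "exclusion_scenario_counts", "registry_counts",
                    "registry_tumor_counts"):
            if key in raw:
                setattr(cfg, key, dict(raw[key]))
        for key in ("mm_regimen_plan", "aml_regimen_plan"):
            if key in raw:
                setattr(
                    cfg, key,
                    [RegimenPlanItem(p.get("name"), int(p["count"]), p.get("failure_mode"))
                     for p in raw[key]],
                )
        if "toxicity_plan" in raw:
            cfg.toxicity_plan = [
                ToxicityPlanItem(p["category"], int(p["count"]), p["channel"])
                for p in raw["toxicity_plan"]
            ]
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        for name, counts in (
            ("n_prospective", self.n_prospective),
            ("exclusion_scenario_counts", self.exclusion_scenario_counts),
            ("registry_counts", self.registry_counts),
            ("registry_tumor_counts", self.registry_tumor_counts),
        ):
            if any(v < 0 for v in counts.values()):
                raise ConfigError(f"negative count in {name}")
        for p in self.mm_regimen_plan + self.aml_regimen_plan:
            if p.count < 0:
                raise ConfigError("negative regimen plan count")
            if p.failure_mode is not None and p.failure_mode not in FAILURE_MODES:
                raise ConfigError(f"unknown failure mode {p.failure_mode!r}")
            if p.failure_mode is None and p.name is None:
                raise ConfigError("regimen plan item needs a name or a failure mode")
        n_excl = sum(self.exclusion_scenario_counts.values())
        n_pool = self.n_prospective.get("AML", 0) + self.n_prospective.get("lung", 0)
        if n_excl > n_pool:
            raise ConfigError("more exclusion scenarios than AML+lung candidates")
        if self.lab_typo_count > self.n_lab_items:
            raise ConfigError("lab_typo_count exceeds n_lab_items")
        n_treated = sum(p.count for p in self.aml_regimen_plan)
        if self.toxicity_plan and sum(p.count for p in self.toxicity_plan) and n_treated == 0:
            raise ConfigError("toxicity planted but no treated AML patients")
        if sum(self.registry_counts.values()) != sum(self.registry_tumor_counts.values()) and \
                sum(self.registry_counts.values()) > 0:
            raise ConfigError("registry category counts must sum to registry tumor counts")


@dataclass
class GroundTruth:
    """Generator-emitted truth against which every engine is scored."""

    inclusion: pd.DataFrame  # patient_id, tumor_group, decision, reason
    regimens: pd.DataFrame  # patient_id, name, start, end, category
    toxicity: pd.DataFrame  # patient_id, category, date, channel
    retrospective: pd.DataFrame  # patient_id, tumor_group, diagnosis_year, category
    manual_labs: pd.DataFrame  # manual copy of the lab table (with typos)
    lab_typo_rows: pd.DataFrame  # pairing keys of the typo'd manual rows


# ---------------------------------------------------------------------------
# the builder
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, config: GeneratorConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.mapping = DrugClassMapping.default()
        self.catalog = RegimenCatalog.mm_default()
        self.aml_catalog = RegimenCatalog.aml_default()
        self._pid = 0
        self.patients: list[dict] = []
        self.trajectories: list[dict] = []
        self.diagnoses: list[dict] = []
        self.prescriptions: list[dict] = []
        self.labs: list[dict] = []
        self.admissions: list[dict] = []
        self.reports: list[dict] = []
        self.sct: list[dict] = []
        self.registry: list[dict] = []
        self.truth_incl: list[dict] = []
        self.truth_reg: list[dict] = []
        self.truth_tox: list[dict] = []
        self.truth_retro: list[dict] = []

    # -- primitives ---------------------------------------------------------

    def new_patient(self, group: str, ref_year: int, resident: bool = True) -> str:
        self._pid += 1
        pid = f"P{self._pid:06d}"
        sex = "female" if group == "breast" else (
            "female" if self.rng.random() < 0.445 else "male")
        age = int(self.rng.integers(25, 91))
        self.patients.append(
            {"patient_id": pid, "birth_year": ref_year - age, "sex": sex,
             "resident_nl": resident}
        )
        return pid

    def add_trajectory(self, pid: str, group: str, start: pd.Timestamp,
                       hospital: str = "H1") -> None:
        self.trajectories.append(
            {"trajectory_id": f"T{len(self.trajectories) + 1:06d}", "patient_id": pid,
             "hospital_id": hospital, "start_date": start, "tumor_group": group}
        )

    def add_diagnosis(self, pid: str, group: str, date: pd.Timestamp,
                      status: str = "confirmed") -> None:
        self.diagnoses.append(
            {"patient_id": pid, "icd10_code": ICD10_BY_GROUP[group], "date": date,
             "status": status, "tumor_group": group}
        )

    def add_rx(self, pid: str, atc: str, start: pd.Timestamp,
               end: pd.Timestamp | None = None, dose: float = float("nan"),
               name: str | None = None) -> None:
        self.prescriptions.append(
            {"patient_id": pid, "atc_code": atc,
             "drug_name": name if name is not None else self.mapping.drug_name(atc),
             "dose_mg_per_day": dose, "start_date": start,
             "end_date": end if end is not None else pd.NaT}
        )

    def _random_start(self, lo: str, hi: str) -> pd.Timestamp:
        lo_ts, hi_ts = pd.Timestamp(lo), pd.Timestamp(hi)
        span = (hi_ts - lo_ts).days
        return lo_ts + pd.Timedelta(days=int(self.rng.integers(0, span + 1)))

    # -- prospective cohort -------------------------------------------------

    def build_prospective(self) -> None:
        cfg = self.cfg
        pool: list[tuple[str, str, pd.Timestamp]] = []  # (pid, group, start)
        for group in ("AML", "lung", "MM", "breast"):
            for _ in range(cfg.n_prospective.get(group, 0)):
                start = self._random_start("2021-01-04", "2023-06-30")
                pid = self.new_patient(group, start.year)
                self.add_trajectory(pid, group, start, hospital=f"H{1 + self._pid % 3}")
                if group in ("AML", "lung"):
                    pool.append((pid, group, start))
                else:
                    self.add_diagnosis(pid, group, start)
                    self.truth_incl.append(
                        {"patient_id": pid, "tumor_group": group,
                         "decision": "include", "reason": "NONE",
                         "cohort": "prospective"}
                    )

        order = self.rng.permutation(len(pool))
        scenarios = (
            ["non_resident"] * cfg.exclusion_scenario_counts.get("non_resident", 0)
            + ["relapse_trajectory"] * cfg.exclusion_scenario_counts.get("relapse_trajectory", 0)
            + ["preliminary_diagnosis"] * cfg.exclusion_scenario_counts.get("preliminary_diagnosis", 0)
        )
        assigned = {int(order[i]): scenarios[i] for i in range(len(scenarios))}
        self.included_aml: list[tuple[str, pd.Timestamp]] = []
        for i, (pid, group, start) in enumerate(pool):
            scenario = assigned.get(i)
            if scenario == "non_resident":
                for p in self.patients:
                    if p["patient_id"] == pid:
                        p["resident_nl"] = False
                self.add_diagnosis(pid, group, start)
                reason = "NON_RESIDENT"
            elif scenario == "relapse_trajectory":
                self.add_diagnosis(pid, group, start - pd.Timedelta(days=1000))
                self.add_diagnosis(pid, group, start)
                reason = "RELAPSE_TRAJECTORY"
            elif scenario == "preliminary_diagnosis":
                self.add_diagnosis(pid, group, start, status="preliminary")
                reason = "PRELIMINARY_DIAGNOSIS"
            else:
                self.add_diagnosis(pid, group, start)
                reason = "NONE"
                if group == "AML":
                    self.included_aml.append((pid, start))
            self.truth_incl.append(
                {"patient_id": pid, "tumor_group": group,
                 "decision": "include" if reason == "NONE" else "exclude",
                 "reason": reason, "cohort": "prospective"}
            )
        self.included_aml.sort()

    # -- regimens -----------------------------------------------------------

    def _entry(self, name: str, catalog: RegimenCatalog) -> CatalogEntry:
        entry = catalog.get(name)
        if entry is None:
            raise ConfigError(f"regimen {name!r} not in catalog")
        return entry

    def realize_clean_regimen(self, pid: str, entry: CatalogEntry,
                              anchor: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Emit prescriptions (or an SCT record) for one clean regimen; returns
        the realized (start, end) span recorded as truth."""
        if entry.event_based:
            kind = "auto" if entry.name == "Auto-SCT" else "allo"
            self.sct.append({"patient_id": pid, "date": anchor, "kind": kind})
            span = (anchor, anchor)
        elif entry.maintenance:
            cls = sorted(entry.drug_classes)[0]
            atc = self.mapping.codes_for_class(cls)[0]
            dose = 10.0 if cls == "lenalidomide" else 1.3
            end = anchor + pd.Timedelta(days=180)
            self.add_rx(pid, atc, anchor, end, dose=dose)
            span = (anchor, end)
        else:
            classes = sorted(entry.drug_classes)
            starts, ends = [], []
            for cycle in range(2):
                base = anchor + pd.Timedelta(days=28 * cycle)
                for j, cls in enumerate(classes):
                    atc = self.mapping.codes_for_class(cls)[0]
                    dose = {"lenalidomide": 25.0, "corticosteroid": 40.0}.get(cls, 100.0)
                    start = base + pd.Timedelta(days=min(j, 3))
                    end = start + pd.Timedelta(days=18)
                    self.add_rx(pid, atc, start, end, dose=dose)
                    starts.append(start)
                    ends.append(end)
            span = (min(starts), max(ends))
        self.truth_reg.append(
            {"patient_id": pid, "name": entry.name, "start": span[0], "end": span[1],
             "category": entry.category}
        )
        return span

    def realize_failure(self, pid: str, mode: str, anchor: pd.Timestamp) -> None:
        """Emit the prescription pattern of one narrated misclassification
        scenario; truth holds what the patient actually received."""
        d = pd.Timedelta
        len_atc = self.mapping.codes_for_class("lenalidomide")[0]
        dara_atc = self.mapping.codes_for_class("daratumumab")[0]
        dex_atc = "H02AB02"
        pred_atc = "H02AB07"
        mel_atc = self.mapping.codes_for_class("melphalan")[0]

        def truth(name, start, end, category):
            self.truth_reg.append({"patient_id": pid, "name": name, "start": start,
                                   "end": end, "category": category})

        if mode == "rd_vs_len15":
            # 15 mg/day lenalidomide maintenance, read as Rd by the dose rule
            end = anchor + d(days=180)
            self.add_rx(pid, len_atc, anchor, end, dose=15.0)
            truth("Lenalidomide maintenance", anchor, end, "IMID")
        elif mode == "len_pred":
            # lenalidomide–prednisone, a regimen outside the catalog
            self.add_rx(pid, len_atc, anchor, anchor + d(days=20), dose=25.0)
            self.add_rx(pid, pred_atc, anchor + d(days=1), anchor + d(days=21), dose=30.0)
            truth("Lenalidomide-prednisone", anchor, anchor + d(days=21), "Not in catalog")
        elif mode == "mel_pred":
            # melphalan–prednisone, outside the catalog
            self.add_rx(pid, mel_atc, anchor, anchor + d(days=4), dose=9.0)
            self.add_rx(pid, pred_atc, anchor, anchor + d(days=4), dose=60.0)
            truth("Melphalan-prednisone", anchor, anchor + d(days=4), "Not in catalog")
        elif mode == "drd_merge":
            # D-mono and Rd co-started inside one week, merged into D-Rd
            self.add_rx(pid, dara_atc, anchor, anchor)
            self.add_rx(pid, len_atc, anchor + d(days=3), anchor + d(days=23), dose=25.0)
            self.add_rx(pid, dex_atc, anchor + d(days=3), anchor + d(days=23), dose=40.0)
            truth("D-mono", anchor, anchor, "Anti-CD38")
            truth("Rd", anchor + d(days=3), anchor + d(days=23), "IMID")
        elif mode == "maint_dmono_vs_drd":
            # maintenance then a D-Rd whose lenalidomide arm was already running:
            # the late daratumumab (+dex) episode reads as D-mono
            m_end = anchor + d(days=200)
            self.add_rx(pid, len_atc, anchor, m_end, dose=10.0)
            self.add_rx(pid, dara_atc, anchor + d(days=100), anchor + d(days=100))
            self.add_rx(pid, dex_atc, anchor + d(days=100), anchor + d(days=120), dose=40.0)
            truth("Lenalidomide maintenance", anchor, m_end, "IMID")
            truth("D-Rd", anchor + d(days=100), anchor + d(days=120), "Anti-CD38")
        else:
            raise ConfigError(f"unknown failure mode {mode!r}")

    def build_mm_regimens(self) -> None:
        mm_pids = sorted(
            t["patient_id"] for t in self.trajectories if t["tumor_group"] == "MM"
        )
        instances: list[tuple[str | None, str | None]] = []
        for item in self.cfg.mm_regimen_plan:
            instances.extend([(item.name, item.failure_mode)] * item.count)
        if instances and not mm_pids:
            raise ConfigError("MM regimen plan set but no MM patients")
        starts = {t["patient_id"]: t["start_date"] for t in self.trajectories
                  if t["tumor_group"] == "MM"}
        slot_of: dict[str, int] = {pid: 0 for pid in mm_pids}
        for k, (name, failure) in enumerate(instances):
            pid = mm_pids[k % len(mm_pids)]
            slot = slot_of[pid]
            slot_of[pid] += 1
            anchor = starts[pid] + pd.Timedelta(days=10 + 260 * slot)
            if failure is not None:
                self.realize_failure(pid, failure, anchor)
            else:
                self.realize_clean_regimen(pid, self._entry(name, self.catalog), anchor)

    def build_aml_regimens(self) -> None:
        instances: list[str] = []
        for item in self.cfg.aml_regimen_plan:
            if item.failure_mode is not None:
                raise ConfigError("failure modes are defined for the MM plan only")
            instances.extend([item.name] * item.count)
        if len(instances) > len(self.included_aml):
            raise ConfigError(
                f"AML plan needs {len(instances)} treated patients but only "
                f"{len(self.included_aml)} included AML patients exist"
            )
        self.treated_aml: list[tuple[str, pd.Timestamp, pd.Timestamp]] = []
        for (pid, traj_start), name in zip(self.included_aml, instances):
            anchor = traj_start + pd.Timedelta(days=10)
            span = self.realize_clean_regimen(pid, self._entry(name, self.aml_catalog), anchor)
            self.treated_aml.append((pid, span[0], span[1]))

    # -- toxicity -----------------------------------------------------------

    def plant_toxicity(self) -> None:
        if not self.cfg.toxicity_plan:
            return
        planted: set[tuple[str, str]] = set()
        cursor = 0
        n = len(self.treated_aml)
        for item in self.cfg.toxicity_plan:
            for _ in range(item.count):
                for attempt in range(n + 1):
                    pid, t_start, t_end = self.treated_aml[cursor % n]
                    cursor += 1
                    if (pid, item.category) not in planted:
                        break
                else:
                    raise ConfigError(
                        f"cannot place {item.count} {item.category} events on {n} patients"
                    )
                planted.add((pid, item.category))
                offset = int(self.rng.integers(3, 16))
                date = t_start + pd.Timedelta(days=offset)
                self._emit_toxicity_evidence(pid, item.category, item.channel, date, t_start)
                self.truth_tox.append(
                    {"patient_id": pid, "category": item.category, "date": date,
                     "channel": "admission" if item.channel == "icu" else item.channel}
                )

    def _emit_toxicity_evidence(self, pid: str, category: str, channel: str,
                                date: pd.Timestamp, window_start: pd.Timestamp) -> None:
        ts = date + pd.Timedelta(hours=9)
        if channel == "lab":
            analyte, loinc, unit, baseline, value = TOX_LAB_EVIDENCE[category]
            if baseline is not None:
                self.labs.append(
                    {"patient_id": pid, "loinc_code": loinc, "analyte_name": analyte,
                     "value": baseline, "unit": unit,
                     "datetime": window_start - pd.Timedelta(days=10, hours=-9)}
                )
            self.labs.append(
                {"patient_id": pid, "loinc_code": loinc, "analyte_name": analyte,
                 "value": value, "unit": unit, "datetime": ts}
            )
        elif channel == "drug":
            for atc in TOX_DRUG_EVIDENCE[category]:
                self.add_rx(pid, atc, date, date + pd.Timedelta(days=7), dose=1000.0,
                            name=f"indicator:{atc}")
        elif channel == "keyword":
            self.reports.append(
                {"patient_id": pid, "datetime": ts, "modality": "CT",
                 "text": TOX_KEYWORD_EVIDENCE[category]}
            )
        elif channel == "admission":
            self.admissions.append(
                {"patient_id": pid, "admit_date": date,
                 "discharge_date": date + pd.Timedelta(days=5),
                 "main_icd10": TOX_ADMISSION_EVIDENCE[category],
                 "secondary_icd10": [], "icu": False}
            )
        elif channel == "icu":
            self.admissions.append(
                {"patient_id": pid, "admit_date": date,
                 "discharge_date": date + pd.Timedelta(days=3),
                 "main_icd10": ICU_NEUTRAL_CODE, "secondary_icd10": [], "icu": True}
            )
        else:
            raise ConfigError(f"unknown toxicity channel {channel!r}")

    # -- retrospective ------------------------------------------------------

    def build_retrospective(self) -> None:
        cfg = self.cfg
        groups = [g for g, n in sorted(cfg.registry_tumor_counts.items()) for _ in range(n)]
        categories = [c for c, n in
                      [("matched", cfg.registry_counts.get("matched", 0)),
                       ("year_mismatch", cfg.registry_counts.get("year_mismatch", 0)),
                       ("diagnosis_mismatch", cfg.registry_counts.get("diagnosis_mismatch", 0))]
                      for _ in range(n)]
        if not groups:
            return
        order = self.rng.permutation(len(groups))
        cat_of = {int(order[i]): categories[i] for i in range(len(categories))}
        other = {"AML": "lung", "lung": "AML", "MM": "AML", "breast": "AML"}
        for i, group in enumerate(groups):
            diagnosis_year = 2018 + (i % 2)
            category = cat_of.get(i, "matched")
            start = pd.Timestamp(f"{diagnosis_year}-01-15") + pd.Timedelta(
                days=int(self.rng.integers(0, 320)))
            pid = self.new_patient(group, diagnosis_year)
            if category == "matched":
                traj_group, traj_start = group, start
            elif category == "year_mismatch":
                traj_group = group
                traj_start = start.replace(year=diagnosis_year + 1)
            else:  # diagnosis_mismatch
                traj_group, traj_start = other[group], start
            self.add_trajectory(pid, traj_group, traj_start, hospital="H1")
            self.add_diagnosis(pid, traj_group, traj_start)
            self.registry.append(
                {"patient_id": pid, "tumor_group": group, "diagnosis_year": diagnosis_year,
                 "hospital_id": "H1"}
            )
            self.truth_retro.append(
                {"patient_id": pid, "tumor_group": group, "diagnosis_year": diagnosis_year,
                 "category": "matched_same_year" if category == "matched" else category}
            )
            self.truth_incl.append(
                {"patient_id": pid, "tumor_group": traj_group,
                 "decision": "include", "reason": "NONE",
                 "cohort": "retrospective"}
            )

    # -- labs ---------------------------------------------------------------

    def build_trial_labs(self) -> None:
        n = self.cfg.n_lab_items
        self.trial_lab_rows: list[int] = []
        if n == 0:
            return
        breast = sorted(t["patient_id"] for t in self.trajectories
                        if t["tumor_group"] == "breast")
        if not breast:
            raise ConfigError("lab items planned but no breast-cancer patients")
        starts = {t["patient_id"]: t["start_date"] for t in self.trajectories
                  if t["tumor_group"] == "breast"}
        n_analytes = len(TIBET_ANALYTES)
        for i in range(n):
            pid = breast[i % len(breast)]
            analyte, loinc, unit, mu, sd = TIBET_ANALYTES[(i // len(breast)) % n_analytes]
            visit = i // (len(breast) * n_analytes)
            ts = starts[pid] + pd.Timedelta(days=21 * visit, hours=8)
            value = round(float(self.rng.normal(mu, sd)), 2)
            self.trial_lab_rows.append(len(self.labs))
            self.labs.append(
                {"patient_id": pid, "loinc_code": loinc, "analyte_name": analyte,
                 "value": value, "unit": unit, "datetime": ts}
            )

    # -- background noise ---------------------------------------------------

    def add_noise(self) -> None:
        cfg = self.cfg
        if not cfg.background_noise:
            return
        all_pids = [p["patient_id"] for p in self.patients]
        for _ in range(cfg.noise_benign_rx):
            pid = all_pids[int(self.rng.integers(0, len(all_pids)))]
            atc, name = BENIGN_ATC[int(self.rng.integers(0, len(BENIGN_ATC)))]
            start = self._random_start("2021-01-04", "2023-06-30")
            self.add_rx(pid, atc, start, start + pd.Timedelta(days=90), dose=50.0, name=name)
        for _ in range(cfg.noise_routine_labs):
            pid = all_pids[int(self.rng.integers(0, len(all_pids)))]
            ts = self._random_start("2021-01-04", "2023-06-30") + pd.Timedelta(hours=10)
            self.labs.append(
                {"patient_id": pid, "loinc_code": "2951-2", "analyte_name": "sodium",
                 "value": round(float(self.rng.normal(140.0, 2.5)), 2),
                 "unit": "mmol/L", "datetime": ts}
            )
        # stray indicator-drug orders on treated patients with no matching
        # truth event: the designed false-positive path of the drug channel
        treated = getattr(self, "treated_aml", [])
        planted = {(t["patient_id"], t["category"]) for t in self.truth_tox}
        emitted = 0
        k = 0
        while emitted < cfg.noise_fp_triggers and treated and k < 10 * cfg.noise_fp_triggers:
            category, codes = NOISE_TRIGGERS[emitted % len(NOISE_TRIGGERS)]
            pid, t_start, t_end = treated[int(self.rng.integers(0, len(treated)))]
            k += 1
            if (pid, category) in planted:
                continue
            date = t_start + pd.Timedelta(days=int(self.rng.integers(16, 28)))
            for atc in codes:
                self.add_rx(pid, atc, date, date + pd.Timedelta(days=5), dose=500.0,
                            name=f"noise:{atc}")
            planted.add((pid, category))
            emitted += 1

    # -- assembly -----------------------------------------------------------

    def assemble(self) -> tuple[CDMDataset, GroundTruth]:
        ds = CDMDataset()
        frames = {
            "patients": self.patients,
            "trajectories": self.trajectories,
            "diagnoses": self.diagnoses,
            "prescriptions": self.prescriptions,
            "labs": self.labs,
            "admissions": self.admissions,
            "reports": self.reports,
            "sct": self.sct,
            "registry": self.registry,
        }
        for name, rows in frames.items():
            if rows:
                frame = pd.DataFrame(rows)
                for col in frame.columns:
                    if col in ("start_date", "end_date", "date", "datetime",
                               "admit_date", "discharge_date"):
                        frame[col] = pd.to_datetime(frame[col])
                setattr(ds, name, frame)
        ds.provenance = {"seed": self.cfg.seed, "config_digest": self.cfg.digest()}

        # the manually registered copy covers the trial lab items only
        trial_labs = ds.labs.iloc[getattr(self, "trial_lab_rows", [])].copy()
        manual, typo_keys = corrupt_manual_labs(
            trial_labs, min(self.cfg.lab_typo_count, len(trial_labs)), seed=self.cfg.seed
        )
        truth = GroundTruth(
            inclusion=pd.DataFrame(
                self.truth_incl,
                columns=["patient_id", "tumor_group", "decision", "reason", "cohort"]),
            regimens=pd.DataFrame(self.truth_reg,
                                  columns=["patient_id", "name", "start", "end", "category"]),
            toxicity=pd.DataFrame(self.truth_tox,
                                  columns=["patient_id", "category", "date", "channel"]),
            retrospective=pd.DataFrame(
                self.truth_retro,
                columns=["patient_id", "tumor_group", "diagnosis_year", "category"]),
            manual_labs=manual,
            lab_typo_rows=typo_keys,
        )
        return ds, truth


def generate_cohort(config: GeneratorConfig | None = None) -> tuple[CDMDataset, GroundTruth]:
    """Generate a full synthetic cohort with ground truth; deterministic per seed."""
    config = config or GeneratorConfig()
    b = _Builder(config)
    b.build_prospective()
    b.included_aml = getattr(b, "included_aml", [])
    b.treated_aml = []
    b.build_mm_regimens()
    b.build_aml_regimens()
    b.plant_toxicity()
    b.build_retrospective()
    b.build_trial_labs()
    b.add_noise()
    return b.assemble()


def make_failure_fixture(scenarios: list[str], seed: int = 0) -> tuple[CDMDataset, GroundTruth]:
    """Minimal fixture instantiating the given misclassification scenarios.

    One MM patient per scenario; the dataset's prescriptions drive the
    regimen engine into exactly the narrated misread while the ground truth
    holds what was actually received.  An empty scenario list yields an
    empty fixture.
    """
    for s in scenarios:
        if s not in FAILURE_MODES:
            raise ConfigError(f"unknown failure scenario {s!r}")
    cfg = GeneratorConfig(
        seed=seed,
        n_prospective={"MM": len(scenarios)},
        exclusion_scenario_counts={},
        mm_regimen_plan=[RegimenPlanItem(None, 1, s) for s in scenarios],
        aml_regimen_plan=[],
        toxicity_plan=[],
        registry_counts={},
        registry_tumor_counts={},
        n_lab_items=0,
        lab_typo_count=0,
        background_noise=False,
    )
    return generate_cohort(cfg)


def corrupt_manual_labs(
    labs: pd.DataFrame, n_typos: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Copy a lab table as its "manually registered" counterpart with typos.

    Exactly ``n_typos`` rows differ from the source, each by a single-digit
    substitution or a decimal shift in the value — the direction of error
    seen in practice (the manual copy is wrong, the extract is right).
    Returns the manual table and the pairing keys of the altered rows.
    """
    if n_typos > len(labs):
        raise ConfigError(f"cannot inject {n_typos} typos into {len(labs)} rows")
    rng = np.random.default_rng(seed)
    manual = labs.copy(deep=True)
    if n_typos == 0:
        return manual, labs.iloc[0:0][["patient_id", "analyte_name", "datetime"]].copy()
    rows = sorted(int(i) for i in rng.choice(len(labs), size=n_typos, replace=False))
    for pos in rows:
        idx = manual.index[pos]
        value = float(manual.at[idx, "value"])
        if rng.random() < 0.5 and value != 0:
            new = value * (10.0 if rng.random() < 0.5 else 0.1)  # decimal shift
        else:
            text = f"{value:.2f}"
            digit_positions = [i for i, ch in enumerate(text) if ch.isdigit()]
            i = digit_positions[int(rng.integers(0, len(digit_positions)))]
            old_digit = text[i]
            choices = [d for d in "0123456789" if d != old_digit]
            new_digit = choices[int(rng.integers(0, len(choices)))]
            new = float(text[:i] + new_digit + text[i + 1:])
        if new == value:  # degenerate (e.g. 0.0 shifted); force a visible change
            new = value + 1.0
        manual.at[idx, "value"] = new
    typo_keys = labs.iloc[rows][["patient_id", "analyte_name", "datetime"]].copy()
    return manual, typo_keys
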