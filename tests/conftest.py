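import pandas as pd
import pytest

from oncogate.regimens import DrugClassMapping, RegimenCatalog
from oncogate.synthetic import (
    GeneratorConfig,
    RegimenPlanItem,
    ToxicityPlanItem,
    generate_cohort,
)
from oncogate.toxicity import load_rules


@pytest.fixture(scope="session")
def mapping():
    return DrugClassMapping.default()


@pytest.fixture(scope="session")
def mm_catalog():
    return RegimenCatalog.mm_default()


@pytest.fixture(scope="session")
def aml_catalog():
    return RegimenCatalog.aml_default()


@pytest.fixture(scope="session")
def rules():
    return load_rules()


def small_config(seed: int = 7, noise: bool = False) -> GeneratorConfig:
    """A fast, fully-featured miniature of the default study plan."""
    return GeneratorConfig(
        seed=seed,
        n_prospective={"AML": 12, "lung": 10, "MM": 6, "breast": 3},
        exclusion_scenario_counts={
            "non_resident": 2,
            "relapse_trajectory": 2,
            "preliminary_diagnosis": 2,
        },
        mm_regimen_plan=[
            RegimenPlanItem("D-Rd", 2),
            RegimenPlanItem("VRd", 1),
            RegimenPlanItem("Rd", 1),
            RegimenPlanItem("Lenalidomide maintenance", 1),
            RegimenPlanItem("Tec", 1),
            RegimenPlanItem("Melphalan", 1),
            RegimenPlanItem("Auto-SCT", 2),
            RegimenPlanItem("Allo-SCT", 1),
        ],
        aml_regimen_plan=[RegimenPlanItem("7+3", 3), RegimenPlanItem("Aza-Ven", 2)],
        toxicity_plan=[
            ToxicityPlanItem("acute_renal_failure", 1, "lab"),
            ToxicityPlanItem("hepatic_toxicity", 1, "lab"),
            ToxicityPlanItem("sepsis", 1, "drug"),
            ToxicityPlanItem("typhlitis", 1, "drug"),
            ToxicityPlanItem("hemorrhage", 1, "keyword"),
            ToxicityPlanItem("invasive_aspergillosis", 1, "admission"),
            ToxicityPlanItem("icu_admission", 1, "icu"),
        ],
        registry_counts={"matched": 4, "year_mismatch": 2, "diagnosis_mismatch": 2},
        registry_tumor_counts={"AML": 4, "lung": 4},
        n_lab_items=60,
        lab_typo_count=3,
        background_noise=noise,
        noise_fp_triggers=2,
        noise_benign_rx=5,
        noise_routine_labs=5,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free miniature cohort: every engine must recover truth exactly."""
    return generate_cohort(small_config(noise=False))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Same miniature plan with background noise on (false-positive paths)."""
    return generate_cohort(small_config(noise=True))


def rx_frame(rows):
    """Build a prescriptions table from (pid, atc, name, dose, start, end) tuples."""
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            "atc_code": [r[1] for r in rows],
            "drug_name": [r[2] for r in rows],
            "dose_mg_per_day": [float(r[3]) if r[3] is not None else float("nan") for r in rows],
            "start_date": pd.to_datetime([r[4] for r in rows]),
            "end_date": pd.to_datetime([r[5] for r in rows]),
        }
    )
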