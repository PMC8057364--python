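import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from catex.io_model import MoneyConvention, SurveyDataset, CSV_COLUMNS

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def random_survey_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random valid household table (monthly, internal column names)."""
    total = rng.uniform(500, 20000, n)
    food = total * rng.uniform(0.05, 0.95, n)
    oop = {c: rng.exponential(300, n) * (rng.random(n) < 0.7)
           for c in ["oop_consultation", "oop_hospitalization",
                     "oop_medicines", "oop_diagnostics", "oop_transport"]}
    return pd.DataFrame({
        "household_id": [f"R{i}" for i in range(n)],
        "income": rng.uniform(1000, 30000, n),
        "expenditure_total": total,
        "expenditure_food": food,
        **oop,
        "household_size": rng.integers(1, 9, n),
        "patient_sex": rng.choice(["male", "female"], n),
        "patient_age": rng.integers(6, 80, n),
        "patient_education_years": rng.integers(0, 18, n),
        "patient_diagnosis": rng.choice(
            ["schizophrenia", "hyperactive", "anxiety", "other"], n),
        "patient_employed": rng.random(n) < 0.3,
        "caregiver_sex": rng.choice(["male", "female"], n),
        "caregiver_age": rng.integers(18, 85, n),
        "caregiver_education_years": rng.integers(0, 18, n),
        "caregiver_relationship": rng.choice(["mother", "sibling", "other"], n),
        "missed_work_days": rng.integers(0, 15, n),
        "marital_status": rng.choice(["single", "married"], n),
    })


def annual_dataset(frame: pd.DataFrame) -> SurveyDataset:
    """Wrap a monthly internal-name frame and annualize it."""
    from catex.io_model import annualize
    ds = SurveyDataset(frame=frame.reset_index(drop=True),
                       convention=MoneyConvention("MXN", 20.48, "monthly"))
    return annualize(ds)


@pytest.fixture
def rng():
    return np.random.default_rng(20180615)


@pytest.fixture
def survey_csv(tmp_path, rng):
    """A small well-formed survey CSV on disk (monthly schema names)."""
    frame = random_survey_frame(rng, 30)
    renames = {c: c + "_month" for c in
               ["income", "expenditure_total", "expenditure_food",
                "oop_consultation", "oop_hospitalization", "oop_medicines",
                "oop_diagnostics", "oop_transport"]}
    renames["missed_work_days"] = "missed_work_days_month"
    path = tmp_path / "survey.csv"
    frame.rename(columns=renames)[CSV_COLUMNS].to_csv(path, index=False)
    return path
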