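"""Survey data model, CSV ingestion with validation, and unit normalization.

A household survey is represented as a :class:`SurveyDataset`: a pandas
DataFrame with one validated row per household plus a :class:`MoneyConvention`
recording the currency and accounting period of every money column.  Carrying
the convention explicitly makes unit errors (double annualization, mixed
currencies) detectable instead of silent.

CSV columns use a ``_month`` suffix because the instrument asks about the
previous month; after loading, money columns are stored under period-neutral
names and the period lives on the convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MoneyConvention",
    "SurveyDataset",
    "SchemaError",
    "PeriodError",
    "MONEY_COLUMNS",
    "OOP_COLUMNS",
    "CSV_COLUMNS",
    "load_survey",
    "validate_frame",
    "annualize",
    "convert_currency",
    "convert_dataset",
    "oop_total",
    "write_survey",
]


class SchemaError(ValueError):
    """The input table does not match the survey schema."""


class PeriodError(ValueError):
    """An operation was applied to data in the wrong accounting period."""


#: Out-of-pocket health spending components: direct payments for psychiatric
#: care (consultations, hospitalizations, medicines, diagnostic tests) plus
#: the transport costs of reaching it.
OOP_COLUMNS = [
    "oop_consultation",
    "oop_hospitalization",
    "oop_medicines",
    "oop_diagnostics",
    "oop_transport",
]

#: All money-valued columns (affected by currency conversion / annualization).
MONEY_COLUMNS = ["income", "expenditure_total", "expenditure_food"] + OOP_COLUMNS

_CATEGORICAL_LEVELS = {
    "patient_sex": {"male", "female"},
    "caregiver_sex": {"male", "female"},
    "marital_status": {"single", "married"},
}

_INT_COLUMNS = ["household_size", "patient_education_years",
                "caregiver_education_years", "missed_work_days"]

_OTHER_COLUMNS = [
    "household_id", "household_size",
    "patient_sex", "patient_age", "patient_education_years",
    "patient_diagnosis", "patient_employed",
    "caregiver_sex", "caregiver_age", "caregiver_education_years",
    "caregiver_relationship", "missed_work_days", "marital_status",
]

#: Internal (period-neutral) column order of a SurveyDataset frame.
COLUMNS = ["household_id"] + MONEY_COLUMNS + _OTHER_COLUMNS[1:]

#: Column names expected in a raw survey CSV (monthly recall period).
CSV_COLUMNS = ["household_id"] + [c + "_month" for c in MONEY_COLUMNS] + [
    "household_size", "patient_sex", "patient_age", "patient_education_years",
    "patient_diagnosis", "patient_employed", "caregiver_sex", "caregiver_age",
    "caregiver_education_years", "caregiver_relationship",
    "missed_work_days_month", "marital_status",
]

_CSV_TO_INTERNAL = {c + "_month": c for c in MONEY_COLUMNS}
_CSV_TO_INTERNAL["missed_work_days_month"] = "missed_work_days"


@dataclass(frozen=True)
class MoneyConvention:
    """Currency and accounting period of every money field in a dataset.

    Parameters
    ----------
    currency : {"MXN", "USD"}
    exchange_rate_mxn_per_usd : float
        Pesos per US dollar (> 0).  Default 20.48, the mid-2018 rate.
    period : {"monthly", "annual"}
    """

    currency: str = "MXN"
    exchange_rate_mxn_per_usd: float = 20.48
    period: str = "monthly"

    def __post_init__(self) -> None:
        if self.currency not in ("MXN", "USD"):
            raise ValueError(f"unknown currency {self.currency!r}")
        if self.period not in ("monthly", "annual"):
            raise ValueError(f"unknown period {self.period!r}")
        if not (self.exchange_rate_mxn_per_usd > 0):
            raise ValueError("exchange rate must be positive")


@dataclass
class SurveyDataset:
    """Validated household records plus their money convention.

    ``frame`` has one row per accepted household (columns in :data:`COLUMNS`);
    ``rejects`` records row-indexed diagnostics for rows that failed
    validation.
    """

    frame: pd.DataFrame
    convention: MoneyConvention
    rejects: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.frame)


def _row_problems(df: pd.DataFrame) -> pd.Series:
    """Return a Series of semicolon-joined validation failures per row."""
    msgs = pd.Series("", index=df.index, dtype=object)

    def add(mask: pd.Series, msg: str) -> None:
        msgs[mask] = msgs[mask].where(msgs[mask] == "", msgs[mask] + "; ") + msg

    for col in MONEY_COLUMNS:
        x = df[col]
        add(x.isna(), f"{col} missing or non-numeric")
        add(~x.isna() & ~np.isfinite(x.astype(float)), f"{col} not finite")
        add(x.notna() & (x < 0), f"{col} negative")
    add(
        df["expenditure_food"].notna()
        & df["expenditure_total"].notna()
        & (df["expenditure_food"] > df["expenditure_total"]),
        "food expenditure exceeds total expenditure",
    )
    add(df["household_size"].isna() | (df["household_size"] < 1),
        "household_size must be >= 1")
    for col, levels in _CATEGORICAL_LEVELS.items():
        add(~df[col].isin(list(levels)), f"{col} outside {sorted(levels)}")
    add(df["patient_age"].isna() | (df["patient_age"] < 0), "patient_age invalid")
    for col in ("patient_education_years", "caregiver_education_years",
                "missed_work_days"):
        add(df[col].isna() | (df[col] < 0), f"{col} invalid")
    return msgs


def validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw (internal-name) frame into accepted rows and a reject log.

    Rows violating any invariant (negative money, food > total, bad
    categorical level, household_size < 1 ...) are rejected with a
    row-indexed reason, never clamped or imputed: the study design excluded
    households that did not record expenses, and this mirrors that rule.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy()
    for col in MONEY_COLUMNS + ["patient_age", "caregiver_age"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _INT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["patient_employed"].dtype == object:
        df["patient_employed"] = (
            df["patient_employed"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False,
                  "yes": True, "no": False})
        )
    df["patient_employed"] = df["patient_employed"].astype("boolean")

    msgs = _row_problems(df)
    bad = msgs != ""
    rejects = pd.DataFrame({"row": df.index[bad], "reason": msgs[bad].values})
    ok = df[~bad].copy()
    ok["household_size"] = ok["household_size"].astype(int)
    for col in _INT_COLUMNS:
        ok[col] = ok[col].astype(int)
    ok["patient_employed"] = ok["patient_employed"].astype(bool)
    return ok.reset_index(drop=True), rejects.reset_index(drop=True)


def load_survey(
    path: Union[str, Path],
    convention: MoneyConvention = MoneyConvention(),
    delimiter: str = ",",
) -> SurveyDataset:
    """Read a household-survey CSV, validate every row, and return a dataset.

    The file must carry a header naming every column in :data:`CSV_COLUMNS`.
    Accepted/rejected row counts are logged; rejected rows are kept in
    ``dataset.rejects`` with their reasons.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if convention.period != "monthly":
        raise PeriodError("survey CSVs carry monthly recall data")
    raw = pd.read_csv(path, sep=delimiter, dtype={"household_id": str})
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    raw = raw.rename(columns=_CSV_TO_INTERNAL)
    frame, rejects = validate_frame(raw)
    if len(frame) == 0:
        logger.warning("no valid household rows in %s", path)
    logger.info("loaded %s: %d accepted, %d rejected",
                path, len(frame), len(rejects))
    return SurveyDataset(frame=frame, convention=convention, rejects=rejects)


def write_survey(ds: SurveyDataset, path: Union[str, Path]) -> None:
    """Echo a validated dataset back to CSV (monthly-schema column names)."""
    inv = {v: k for k, v in _CSV_TO_INTERNAL.items()}
    ds.frame.rename(columns=inv).to_csv(path, index=False)


def annualize(ds: SurveyDataset) -> SurveyDataset:
    """Multiply every money field by 12, converting monthly to annual values.

    The recall period of the instrument is one month; the CHE statistic is
    defined on annual aggregates.  Raises :class:`PeriodError` if the dataset
    is already annual, so the factor of 12 can never be applied twice.
    """
    if ds.convention.period == "annual":
        raise PeriodError("dataset is already annual")
    frame = ds.frame.copy()
    frame[MONEY_COLUMNS] = frame[MONEY_COLUMNS] * 12.0
    return SurveyDataset(
        frame=frame,
        convention=replace(ds.convention, period="annual"),
        rejects=ds.rejects,
    )


def convert_currency(amount, convention: MoneyConvention, target: str):
    """Convert an amount (scalar or array) between MXN and USD.

    MXN→USD divides by the convention's rate, USD→MXN multiplies; converting
    to the currency the data are already in is the identity.
    """
    if target not in ("MXN", "USD"):
        raise ValueError(f"unknown target currency {target!r}")
    rate = convention.exchange_rate_mxn_per_usd
    if convention.currency == target:
        return amount
    if convention.currency == "MXN":  # → USD
        return amount / rate
    return amount * rate  # USD → MXN


def convert_dataset(ds: SurveyDataset, target: str) -> SurveyDataset:
    """Convert every money column of a dataset to ``target`` currency."""
    if ds.convention.currency == target:
        return ds
    frame = ds.frame.copy()
    frame[MONEY_COLUMNS] = convert_currency(
        frame[MONEY_COLUMNS], ds.convention, target
    )
    return SurveyDataset(
        frame=frame,
        convention=replace(ds.convention, currency=target),
        rejects=ds.rejects,
    )


def oop_total(frame_or_row) -> Union[pd.Series, float]:
    """Total out-of-pocket health spending: the sum of the five components.

    Accepts a DataFrame (returns a Series, one value per household) or a
    single row / mapping (returns a float).  Non-negative by construction.
    """
    if isinstance(frame_or_row, pd.DataFrame):
        return frame_or_row[OOP_COLUMNS].sum(axis=1)
    return float(sum(frame_or_row[c] for c in OOP_COLUMNS))
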