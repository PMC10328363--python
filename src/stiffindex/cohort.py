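"""Cohort table schema and delimited-text I/O.

A cohort is a plain :class:`pandas.DataFrame`, one row per participant,
with the column dictionary below. Booleans are stored as 0/1 integers, sex
as 1=male / 0=female, and the generator-only ground truth ``latent_class``
as one of ``none`` / ``positive`` / ``negative``.
"""

from __future__ import annotations

import warnings

import pandas as pd

#: column -> (dtype kind, description)
COLUMN_DICTIONARY: dict[str, tuple[str, str]] = {
    "id": ("str", "participant identifier"),
    "arm": ("str", "cohort arm: reference or hypertensive"),
    "age": ("float", "age, years"),
    "sex": ("int", "1=male, 0=female"),
    "sbp_raw": ("float", "automated-device systolic BP, mmHg"),
    "dbp_raw": ("float", "automated-device diastolic BP, mmHg"),
    "hr": ("float", "heart rate, bpm"),
    "asi_measured": ("float", "measured arterial stiffness index, m/s"),
    "alt": ("float", "alanine aminotransferase, U/L"),
    "ast": ("float", "aspartate aminotransferase, U/L"),
    "albumin": ("float", "serum albumin, g/L"),
    "hdl": ("float", "HDL cholesterol, mmol/L"),
    "ldl": ("float", "LDL cholesterol, mmol/L"),
    "total_cholesterol": ("float", "total cholesterol, mmol/L"),
    "triglycerides": ("float", "triglycerides, mmol/L"),
    "urate": ("float", "serum urate, umol/L"),
    "phosphate": ("float", "serum phosphate, mmol/L"),
    "cystatin_c": ("float", "cystatin C, mg/L"),
    "testosterone": ("float", "testosterone, nmol/L"),
    "creatinine": ("float", "serum creatinine, umol/L"),
    "glucose": ("float", "fasting glucose, mmol/L"),
    "pack_years": ("float", "smoking pack-years (0 for never-smokers)"),
    "antihypertensive": ("int", "on antihypertensive therapy, 0/1"),
    "antidiabetic": ("int", "on antidiabetic therapy, 0/1"),
    "statin": ("int", "on statin therapy, 0/1"),
    "dx_hypertension": ("int", "doctor-diagnosed hypertension, 0/1"),
    "dx_diabetes": ("int", "doctor-diagnosed diabetes, 0/1"),
    "dx_cvd": ("int", "doctor-diagnosed CV event (heart attack/angina/stroke), 0/1"),
    "latent_class": ("str", "generator ground truth: none/positive/negative"),
}

REQUIRED_COLUMNS = tuple(COLUMN_DICTIONARY)

#: the ten biomarkers screened for association with the stiffness index class
BIOMARKERS = (
    "alt",
    "ast",
    "albumin",
    "hdl",
    "triglycerides",
    "urate",
    "phosphate",
    "cystatin_c",
    "testosterone",
    "pack_years",
)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 comma-separated text."""
    cohort.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table, validating the header against the column dictionary.

    Unknown columns are preserved with a warning; missing required columns or
    non-numeric cells in numeric columns raise ``ValueError``.
    """
    try:
        table = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file, expected a cohort header") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: header mismatch, missing columns {missing}")
    extra = [c for c in table.columns if c not in COLUMN_DICTIONARY]
    if extra:
        warnings.warn(f"{path}: unknown columns preserved but ignored: {extra}")
    for col, (kind, _) in COLUMN_DICTIONARY.items():
        if kind in ("float", "int"):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric cell in numeric column {col!r} "
                    f"(first at row {int(bad.idxmax())})"
                )
            table[col] = coerced
    return table
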