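"""Measurement adjustment, clinical flag derivation and cohort selection.

The stages here turn raw automated-device records into the two analysis
cohorts: a "healthy" reference arm (no hypertension, diabetes, prior CV
event or CKD) used to fit the predicted-ASI equation, and a hypertensive
arm without CV events on which the stiffness index is classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS
from .constants import DEFAULT_CONSTANTS, ClinicalConstants


def adjust_bp(sbp_raw, dbp_raw, sex, constants: ClinicalConstants = DEFAULT_CONSTANTS):
    """Map automated-device SBP/DBP readings onto the sphygmomanometer scale.

    Affine, sex-specific adjustment (sex: 1=male, 0=female). Vectorised over
    array inputs. Negative readings signal a malformed record.
    """
    sbp_raw = np.asarray(sbp_raw, dtype=float)
    dbp_raw = np.asarray(dbp_raw, dtype=float)
    if np.any(sbp_raw < 0) or np.any(dbp_raw < 0):
        raise ValueError("negative blood-pressure reading: malformed record")
    sbp = constants.sbp_adjust.forward(sbp_raw, np.asarray(sex))
    dbp = constants.dbp_adjust.forward(dbp_raw, np.asarray(sex))
    return sbp, dbp


def invert_bp_adjustment(
    sbp_adjusted, dbp_adjusted, sex, constants: ClinicalConstants = DEFAULT_CONSTANTS
):
    """Inverse of :func:`adjust_bp`: recover raw device-scale readings.

    ``adjust_bp(*invert_bp_adjustment(s, d, sex), sex)`` returns ``(s, d)``
    to within 1e-9 mmHg.
    """
    sex = np.asarray(sex)
    sbp_raw = constants.sbp_adjust.inverse(np.asarray(sbp_adjusted, dtype=float), sex)
    dbp_raw = constants.dbp_adjust.inverse(np.asarray(dbp_adjusted, dtype=float), sex)
    return sbp_raw, dbp_raw


def mean_bp(sbp, dbp):
    """Mean arterial pressure estimate (SBP + 2*DBP) / 3, mmHg.

    Requires SBP >= DBP elementwise; a violation signals swapped fields.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp < dbp):
        raise ValueError("SBP < DBP: systolic/diastolic fields appear swapped")
    return (sbp + 2.0 * dbp) / 3.0


def egfr_ckd_epi(
    creatinine_umol, age, sex, constants: ClinicalConstants = DEFAULT_CONSTANTS
):
    """Creatinine-based CKD-EPI estimated GFR, mL/min/1.73m^2.

    ``creatinine_umol`` is serum creatinine in umol/L (divided by 88.4 to
    standardise to mg/dL); ``sex`` is 1=male, 0=female. The equation is
    141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209 * 0.993^age
    * 1.018 (if female), with sex-specific kappa and alpha.
    """
    cre = np.asarray(creatinine_umol, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if np.any(cre <= 0) or np.any(age <= 0):
        raise ValueError("creatinine and age must be positive")
    p = constants.ckd_epi
    kappa = np.where(sex == 1, p.kappa_male, p.kappa_female)
    alpha = np.where(sex == 1, p.alpha_male, p.alpha_female)
    scr = cre / p.creatinine_umol_per_mgdl
    ratio = scr / kappa
    egfr = (
        p.scale
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** p.max_exponent
        * p.age_base**age
        * np.where(sex == 1, 1.0, p.female_factor)
    )
    return egfr


#: columns a record must carry to be considered complete for the analysis
_REQUIRED_FOR_FLAGS = (
    "sbp_raw",
    "dbp_raw",
    "sex",
    "age",
    "creatinine",
    "glucose",
    "total_cholesterol",
    "ldl",
    "triglycerides",
)


def derive_flags(
    cohort: pd.DataFrame, constants: ClinicalConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Append adjusted BP, mean BP, eGFR and the four diagnostic flags.

    Flags follow OR-composition over their criteria. Rows missing any field
    required for flag derivation are marked ``incomplete`` (True) and their
    flags are left as best-effort; downstream selection is complete-case.
    """
    out = cohort.copy()
    incomplete = out[list(_REQUIRED_FOR_FLAGS)].isna().any(axis=1)
    sbp, dbp = adjust_bp(
        out["sbp_raw"].fillna(0.0), out["dbp_raw"].fillna(0.0), out["sex"], constants
    )
    out["sbp"] = np.where(out["sbp_raw"].notna(), sbp, np.nan)
    out["dbp"] = np.where(out["dbp_raw"].notna(), dbp, np.nan)
    out["mean_bp"] = mean_bp(out["sbp"].to_numpy(), out["dbp"].to_numpy())
    out["egfr"] = egfr_ckd_epi(
        out["creatinine"].fillna(1.0), out["age"].fillna(50.0), out["sex"], constants
    )
    out.loc[out["creatinine"].isna() | out["age"].isna(), "egfr"] = np.nan

    out["hypertension"] = (
        (out["sbp"] >= constants.sbp_hypertension)
        | (out["dbp"] >= constants.dbp_hypertension)
        | (out["antihypertensive"] == 1)
        | (out["dx_hypertension"] == 1)
    ).astype(int)
    out["diabetes"] = (
        (out["antidiabetic"] == 1)
        | (out["dx_diabetes"] == 1)
        | (out["glucose"] >= constants.glucose_diabetes)
    ).astype(int)
    out["dyslipidemia"] = (
        (out["total_cholesterol"] >= constants.tc_dyslipidemia)
        | (out["ldl"] >= constants.ldl_dyslipidemia)
        | (out["triglycerides"] > constants.tg_dyslipidemia)
        | (out["statin"] == 1)
    ).astype(int)
    out["ckd"] = (out["egfr"] < constants.egfr_ckd).astype(int)
    out["incomplete"] = incomplete.astype(int)
    return out


def exclude_asi_outliers(
    cohort: pd.DataFrame, constants: ClinicalConstants = DEFAULT_CONSTANTS
) -> tuple[pd.DataFrame, int]:
    """Drop extreme ASI values outside mean +/- 5 SD, in a single pass.

    The mean and SD are computed once on the input rows (pre-filter); the
    rule is deliberately not iterated, so a second application may drop
    further rows — the pipeline applies exactly one pass. Returns the
    filtered table and the number of rows dropped.
    """
    asi = cohort["asi_measured"].to_numpy(dtype=float)
    if asi.size < 2:
        raise ValueError("need at least 2 rows to estimate an outlier band")
    mean = float(np.nanmean(asi))
    sd = float(np.nanstd(asi, ddof=1))
    half_width = constants.asi_outlier_sd_multiplier * sd
    keep = np.abs(asi - mean) <= half_width
    keep |= np.isnan(asi)  # missing ASI handled by complete-case later
    return cohort.loc[keep].copy(), int((~keep).sum())


@dataclass
class SelectionLog:
    """Row counts at each cohort-selection step."""

    n_input: int = 0
    n_reference: int = 0
    n_analysis_raw: int = 0
    n_analysis: int = 0
    steps: list[str] = field(default_factory=list)


#: variables that must be observed for a hypertensive row to enter the analysis
_ANALYSIS_COMPLETE_CASE = ("asi_measured", "age", "sex", "hr") + tuple(BIOMARKERS)


def select_cohorts(
    cohort: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, SelectionLog]:
    """Split a flagged cohort into the reference and analysis tables.

    reference: no hypertension, no diabetes, no prior CV event, no CKD and a
    complete record. analysis: hypertension and no CV event, complete-case on
    every modelled variable (the tree stage cannot handle missing data). The
    two sets are disjoint by construction.
    """
    log = SelectionLog(n_input=len(cohort))
    complete = cohort["incomplete"] == 0
    healthy = (
        (cohort["hypertension"] == 0)
        & (cohort["diabetes"] == 0)
        & (cohort["dx_cvd"] == 0)
        & (cohort["ckd"] == 0)
        & complete
        & cohort["asi_measured"].notna()
    )
    reference = cohort.loc[healthy].copy()
    analysis_raw = (cohort["hypertension"] == 1) & (cohort["dx_cvd"] == 0)
    log.n_analysis_raw = int(analysis_raw.sum())
    cc = cohort[list(_ANALYSIS_COMPLETE_CASE)].notna().all(axis=1) & complete
    analysis = cohort.loc[analysis_raw & cc].copy()
    log.n_reference = len(reference)
    log.n_analysis = len(analysis)
    log.steps.append(f"input rows: {log.n_input}")
    log.steps.append(f"reference (healthy, complete): {log.n_reference}")
    log.steps.append(f"hypertensive without CV event: {log.n_analysis_raw}")
    log.steps.append(f"analysis after complete-case: {log.n_analysis}")
    if len(reference) == 0:
        raise ValueError("empty reference cohort after selection")
    if len(analysis) == 0:
        raise ValueError("empty analysis cohort after selection")
    return reference, analysis, log
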