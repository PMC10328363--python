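"""Clinical constants: device-adjustment coefficients, CKD-EPI parameters and
diagnostic thresholds.

All downstream stages read these values from a single frozen
:class:`ClinicalConstants` instance instead of hard-coding them, so a study
that uses different guideline cutoffs can swap one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BPAdjustment:
    """Affine map from automated-device readings to sphygmomanometer scale.

    adjusted = intercept + slope * raw + male_offset * sex  (sex: male=1, female=0)
    """

    intercept: float
    slope: float
    male_offset: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("adjustment slope must be nonzero")

    def forward(self, raw, sex):
        return self.intercept + self.slope * raw + self.male_offset * sex

    def inverse(self, adjusted, sex):
        return (adjusted - self.intercept - self.male_offset * sex) / self.slope


@dataclass(frozen=True)
class CKDEPIParams:
    """Sex-specific constants of the creatinine CKD-EPI eGFR equation."""

    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    scale: float = 141.0
    max_exponent: float = -1.209
    age_base: float = 0.993
    female_factor: float = 1.018
    creatinine_umol_per_mgdl: float = 88.4


@dataclass(frozen=True)
class ClinicalConstants:
    """Measurement adjustments and diagnostic definitions used throughout.

    Hypertension: adjusted SBP >= 140 or DBP >= 90 mmHg, or antihypertensive
    therapy, or doctor diagnosis. Diabetes: therapy, diagnosis, or fasting
    glucose >= 7 mmol/L. Dyslipidemia: total cholesterol >= 6.61 mmol/L, LDL
    >= 4.1 mmol/L, triglycerides > 1.7 mmol/L, or statin use. CKD: eGFR < 60
    mL/min/1.73m^2. ASI outliers: beyond mean +/- 5 SD.
    """

    sbp_adjust: BPAdjustment = field(
        default_factory=lambda: BPAdjustment(3.3171, 0.92019, 6.02468)
    )
    dbp_adjust: BPAdjustment = field(
        default_factory=lambda: BPAdjustment(14.5647, 0.80929, 2.01089)
    )
    ckd_epi: CKDEPIParams = field(default_factory=CKDEPIParams)
    sbp_hypertension: float = 140.0
    dbp_hypertension: float = 90.0
    glucose_diabetes: float = 7.0
    tc_dyslipidemia: float = 6.61
    ldl_dyslipidemia: float = 4.1
    tg_dyslipidemia: float = 1.7
    egfr_ckd: float = 60.0
    asi_outlier_sd_multiplier: float = 5.0


DEFAULT_CONSTANTS = ClinicalConstants()
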