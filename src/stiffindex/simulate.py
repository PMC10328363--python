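"""Seeded synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access to application-controlled survey
data:

* a "healthy" reference arm whose measured arterial stiffness index (ASI)
  is an affine function of age, sex, mean BP and heart rate plus Gaussian
  noise — the relationship the reference regression is meant to recover;
* a hypertensive arm carrying a latent positive/negative stiffness-index
  class drawn from a logistic model on the blood biomarkers, with the
  normalized stiffness index drawn class-conditionally (positive class
  truncated to > 0, negative to < 0) and measured ASI reconstructed as
  predicted * (1 + index).

Covariates are drawn independently per variable (sex-stratified for
testosterone; log-normal triglycerides; zero-inflated exponential
pack-years). Truncated-normal parents are solved numerically so that the
*truncated* distribution matches the configured mean/SD. Blood pressure is
drawn on the adjusted (sphygmomanometer) scale, where population moments
are reported, and inverted through the device-adjustment formulas so that
the generator emits raw device-scale readings and the preprocessing stage
has real work to do.

All randomness flows from a single seed through named substreams, one per
(arm, variable), so adding a variable does not perturb the draws of the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import DEFAULT_CONSTANTS, ClinicalConstants
from .preprocessing import egfr_ckd_epi, invert_bp_adjustment, mean_bp

__all__ = [
    "VariableSpec",
    "GeneratorConfig",
    "default_config",
    "interaction_demo_config",
    "simulate_cohort",
    "solve_truncnorm_params",
]


@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one covariate in one arm.

    family: ``truncnorm`` (normal truncated to [lower, upper], parent
    parameters solved so the truncated moments equal mean/sd),
    ``lognormal`` (moment-matched), ``zero_inflated_exp`` (point mass at 0
    plus exponential, moment-matched), or ``sex_mixture`` (two-component
    normal by sex with fixed female component; the male component is solved
    so the pooled moments match).
    """

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf
    family: str = "truncnorm"
    female_mean: float = 1.1
    female_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(f"truncation bounds must satisfy lower < upper")


def solve_truncnorm_params(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """Parent (mu, sigma) of a truncated normal with given truncated moments.

    With distant bounds the parent equals the target and the solver returns
    immediately; near a bound the parent is shifted so the truncated
    distribution still has the requested mean/sd. Raises if the target is
    infeasible on the interval.
    """
    if not np.isfinite(lower) and not np.isfinite(upper):
        return mean, sd

    def residual(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residual, [mean, np.log(sd)], method="hybr")
    if not sol.success or max(abs(np.asarray(residual(sol.x)))) > 1e-6:
        raise ValueError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"on [{lower}, {upper}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_variable(
    spec: VariableSpec,
    rng: np.random.Generator,
    n: int,
    sex=None,
    male_fraction: float | None = None,
):
    if spec.family == "truncnorm":
        mu, sigma = solve_truncnorm_params(spec.mean, spec.sd, spec.lower, spec.upper)
        a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)
    if spec.family == "lognormal":
        sigma2 = np.log1p(spec.sd**2 / spec.mean**2)
        mu = np.log(spec.mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if spec.family == "zero_inflated_exp":
        # (1-pi)*theta = mean; (1-pi)(1+pi)*theta^2 = var  =>  pi, theta closed form
        ratio = (spec.sd**2 + spec.mean**2) / spec.mean**2  # (1+pi)/(1-pi) + 1 ... no:
        # E[X]=(1-pi)theta, E[X^2]=2(1-pi)theta^2 => E[X^2]/E[X]^2 = 2/(1-pi)
        one_minus_pi = 2.0 * spec.mean**2 / (spec.sd**2 + spec.mean**2)
        if not 0 < one_minus_pi <= 1:
            raise ValueError("zero-inflated exponential needs sd >= mean")
        theta = spec.mean / one_minus_pi
        smoker = rng.random(n) < one_minus_pi
        return np.where(smoker, rng.exponential(theta, size=n), 0.0)
    if spec.family == "sex_mixture":
        if sex is None:
            raise ValueError("sex_mixture draw requires the sex vector")
        p = float(np.mean(sex)) if male_fraction is None else male_fraction
        if p <= 0 or p >= 1:
            raise ValueError("sex_mixture needs both sexes present")
        mu_f, sd_f = spec.female_mean, spec.female_sd
        mu_m = (spec.mean - (1 - p) * mu_f) / p
        var_m = (
            spec.sd**2 - (1 - p) * sd_f**2 - p * (1 - p) * (mu_m - mu_f) ** 2
        ) / p
        if var_m <= 0:
            raise ValueError("infeasible pooled moments for sex-stratified variable")
        vals = np.where(
            sex == 1,
            rng.normal(mu_m, np.sqrt(var_m), size=n),
            rng.normal(mu_f, sd_f, size=n),
        )
        return np.clip(vals, 0.05, None)
    raise ValueError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the two-arm synthetic cohort."""

    n_reference: int = 1000
    n_hypertensive: int = 1000
    seed: int = 0
    reference_moments: dict[str, VariableSpec] = field(default_factory=dict)
    hypertensive_moments: dict[str, VariableSpec] = field(default_factory=dict)
    male_fraction_reference: float = 0.4045
    male_fraction_hypertensive: float = 0.6039
    #: (b0, b_age per year, b_sex, b_meanBP per mmHg, b_HR per bpm), m/s
    reference_asi_coefficients: tuple[float, float, float, float, float] = (
        -1.167,
        0.0837,
        0.9337,
        0.0402,
        0.0203,
    )
    reference_noise_sd: float = 2.6
    class_logit_intercept: float = 0.4265
    class_logit_coefficients: dict[str, float] = field(default_factory=dict)
    #: optional interaction terms on standardised covariates: (v1, v2) -> coef
    class_logit_interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    index_pos_moments: tuple[float, float] = (0.2552, 0.2231)
    index_neg_moments: tuple[float, float] = (-0.2410, 0.1573)
    therapy_rates_reference: dict[str, float] = field(default_factory=dict)
    therapy_rates_hypertensive: dict[str, float] = field(default_factory=dict)
    attempt_cap_factor: int = 100

    def __post_init__(self) -> None:
        for frac in (self.male_fraction_reference, self.male_fraction_hypertensive):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("male fractions must lie in [0, 1]")
        if not self.index_pos_moments[0] > 0:
            raise ValueError("positive-class index mean must be > 0")
        if not self.index_neg_moments[0] < 0:
            raise ValueError("negative-class index mean must be < 0")
        for moments in (self.index_pos_moments, self.index_neg_moments):
            if moments[1] <= 0:
                raise ValueError("index sd must be positive")


_REFERENCE_MOMENTS = {
    "age": VariableSpec(53.71, 8.1778, 37.0, 73.0),
    "sbp": VariableSpec(121.81, 10.904, 70.0, 139.999),
    "dbp": VariableSpec(77.93, 6.0683, 40.0, 89.999),
    "hr": VariableSpec(66.931, 9.8395, 30.0, 150.0),
    "alt": VariableSpec(21.109, 12.002, 1.0, np.inf),
    "ast": VariableSpec(25.024, 8.7137, 1.0, np.inf),
    "albumin": VariableSpec(45.4, 2.5823, 20.0, np.inf),
    "hdl": VariableSpec(1.4959, 0.3652, 0.1, np.inf),
    "ldl": VariableSpec(3.5505, 0.7239, 0.3, np.inf),
    "total_cholesterol": VariableSpec(5.6879, 0.9294, 1.0, np.inf),
    "triglycerides": VariableSpec(1.533, 0.8623, family="lognormal"),
    "urate": VariableSpec(289.72, 72.559, 30.0, np.inf),
    "phosphate": VariableSpec(1.1973, 0.1537, 0.2, np.inf),
    "cystatin_c": VariableSpec(0.8638, 0.1242, 0.2, np.inf),
    "testosterone": VariableSpec(5.8239, 6.2163, family="sex_mixture"),
    "creatinine": VariableSpec(70.421, 12.701, 20.0, np.inf),
    "glucose": VariableSpec(4.9455, 0.5004, 2.0, 6.999),
    "pack_years": VariableSpec(5.1724, 11.634, family="zero_inflated_exp"),
}

_HYPERTENSIVE_MOMENTS = {
    "age": VariableSpec(58.91, 7.433, 37.0, 73.0),
    "sbp": VariableSpec(145.65, 15.188, 80.0, 250.0),
    "dbp": VariableSpec(87.13, 7.731, 40.0, 150.0),
    "hr": VariableSpec(70.088, 11.917, 30.0, 180.0),
    "alt": VariableSpec(25.431, 14.740, 1.0, np.inf),
    "ast": VariableSpec(27.362, 10.1514, 1.0, np.inf),
    "albumin": VariableSpec(45.5, 2.659, 20.0, np.inf),
    "hdl": VariableSpec(1.3971, 0.3573, 0.1, np.inf),
    "ldl": VariableSpec(3.4987, 0.7935, 0.3, np.inf),
    "total_cholesterol": VariableSpec(5.5862, 1.0392, 1.0, np.inf),
    "triglycerides": VariableSpec(1.8527, 1.0037, family="lognormal"),
    # printed marginal "33.20" is a dropped digit: the class-conditional values
    # 329.92 / 337.14 with the 54.6/45.4 split pool to exactly 333.20 umol/L
    "urate": VariableSpec(333.20, 79.401, 30.0, np.inf),
    "phosphate": VariableSpec(1.1612, 0.1607, 0.2, np.inf),
    "cystatin_c": VariableSpec(0.9397, 0.1864, 0.2, np.inf),
    "testosterone": VariableSpec(7.5242, 5.9183, family="sex_mixture"),
    "creatinine": VariableSpec(75.608, 19.829, 20.0, np.inf),
    "glucose": VariableSpec(5.3319, 1.2837, 2.0, np.inf),
    "pack_years": VariableSpec(7.5196, 15.563, family="zero_inflated_exp"),
}

#: per-unit log-odds of the positive stiffness class (screened biomarkers)
_CLASS_LOGIT = {
    "alt": 0.01,
    "albumin": -0.03,
    "testosterone": 0.006,
    "phosphate": 0.72,
    "ast": -0.01,
    "cystatin_c": -0.23,
    "pack_years": 0.01,
    "hdl": -0.31,
    "triglycerides": 0.07,
    "urate": 0.001,
}

_THERAPY_REFERENCE = {
    "antihypertensive": 0.0,
    "antidiabetic": 0.0,
    "statin": 0.0543,
    "dx_hypertension": 0.0,
    "dx_diabetes": 0.0,
    "dx_cvd": 0.0,
}

_THERAPY_HYPERTENSIVE = {
    "antihypertensive": 0.4083,
    "antidiabetic": 0.0559,
    "statin": 0.2521,
    "dx_hypertension": 1.0,
    "dx_diabetes": 0.06,
    "dx_cvd": 0.0,
}


def default_config(
    n_reference: int = 1000, n_hypertensive: int = 1000, seed: int = 0
) -> GeneratorConfig:
    """The default study conditions: population moments of the source survey.

    The class-logit intercept 0.4265 is calibrated (once, numerically) so
    the expected positive-class fraction equals the reported class split
    22,453 / 49,452 = 45.4%.
    """
    return GeneratorConfig(
        n_reference=n_reference,
        n_hypertensive=n_hypertensive,
        seed=seed,
        reference_moments=dict(_REFERENCE_MOMENTS),
        hypertensive_moments=dict(_HYPERTENSIVE_MOMENTS),
        class_logit_coefficients=dict(_CLASS_LOGIT),
        therapy_rates_reference=dict(_THERAPY_REFERENCE),
        therapy_rates_hypertensive=dict(_THERAPY_HYPERTENSIVE),
    )


def interaction_demo_config(
    n_reference: int = 1000, n_hypertensive: int = 1000, seed: int = 0
) -> GeneratorConfig:
    """Default conditions plus strong pairwise interactions in the class logit.

    Adds synergy between low HDL and smoking exposure and between phosphate
    and urate (on standardised scales), the kind of non-additive structure a
    main-effects logistic model cannot represent but a decision tree can.
    """
    cfg = default_config(n_reference, n_hypertensive, seed)
    return replace(
        cfg,
        class_logit_interactions={
            ("hdl", "pack_years"): -1.5,
            ("phosphate", "urate"): 1.5,
        },
    )


# ---------------------------------------------------------------------------
# simulation


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from the master seed and a stream name."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


class _Streams:
    def __init__(self, seed: int, arm: str):
        self.seed = seed
        self.arm = arm
        self._cache: dict[str, np.random.Generator] = {}

    def __getitem__(self, name: str) -> np.random.Generator:
        if name not in self._cache:
            self._cache[name] = _substream(self.seed, f"{self.arm}.{name}")
        return self._cache[name]


def _predict_reference_asi(coeffs, age, sex, meanbp, hr):
    b0, b_age, b_sex, b_mbp, b_hr = coeffs
    return b0 + b_age * age + b_sex * sex + b_mbp * meanbp + b_hr * hr


def _draw_arm_batch(
    config: GeneratorConfig,
    arm: str,
    n: int,
    streams: _Streams,
    constants: ClinicalConstants,
) -> pd.DataFrame:
    moments = (
        config.reference_moments if arm == "reference" else config.hypertensive_moments
    )
    male_frac = (
        config.male_fraction_reference
        if arm == "reference"
        else config.male_fraction_hypertensive
    )
    therapy = (
        config.therapy_rates_reference
        if arm == "reference"
        else config.therapy_rates_hypertensive
    )
    cols: dict[str, np.ndarray] = {}
    sex = (streams["sex"].random(n) < male_frac).astype(int)
    cols["sex"] = sex
    for name, spec in sorted(moments.items()):
        if name in ("sbp", "dbp"):
            continue
        cols[name] = _draw_variable(
            spec, streams[name], n, sex=sex, male_fraction=male_frac
        )
    sbp_adj = _draw_variable(moments["sbp"], streams["sbp"], n)
    dbp_adj = _draw_variable(moments["dbp"], streams["dbp"], n)
    cols["_sbp_adj"], cols["_dbp_adj"] = sbp_adj, dbp_adj
    sbp_raw, dbp_raw = invert_bp_adjustment(sbp_adj, dbp_adj, sex, constants)
    cols["sbp_raw"], cols["dbp_raw"] = sbp_raw, dbp_raw
    for flag, rate in sorted(therapy.items()):
        cols[flag] = (streams[flag].random(n) < rate).astype(int)
    return pd.DataFrame(cols)


def _eligible_reference(
    batch: pd.DataFrame, constants: ClinicalConstants
) -> np.ndarray:
    sbp, dbp = batch["_sbp_adj"].to_numpy(), batch["_dbp_adj"].to_numpy()
    egfr = egfr_ckd_epi(batch["creatinine"], batch["age"], batch["sex"], constants)
    return (
        (sbp < constants.sbp_hypertension)
        & (dbp < constants.dbp_hypertension)
        & (sbp > dbp)
        & (batch["glucose"].to_numpy() < constants.glucose_diabetes)
        & (batch["antihypertensive"].to_numpy() == 0)
        & (batch["antidiabetic"].to_numpy() == 0)
        & (batch["dx_cvd"].to_numpy() == 0)
        & (np.asarray(egfr) >= constants.egfr_ckd)
    )


def _collect_arm(
    config: GeneratorConfig, arm: str, n: int, constants: ClinicalConstants
) -> pd.DataFrame:
    """Rejection-sample an arm until n eligible rows are collected."""
    streams = _Streams(config.seed, arm)
    collected: list[pd.DataFrame] = []
    total = 0
    drawn = 0
    cap = config.attempt_cap_factor * max(n, 1)
    while total < n:
        batch_size = min(max(2 * (n - total), 1000), cap - drawn)
        if batch_size <= 0:
            raise RuntimeError(
                f"rejection sampling for arm {arm!r} exceeded the attempt cap "
                f"({cap} draws): infeasible generator configuration"
            )
        batch = _draw_arm_batch(config, arm, batch_size, streams, constants)
        drawn += batch_size
        if arm == "reference":
            keep = _eligible_reference(batch, constants)
        else:
            keep = (
                batch["_sbp_adj"].to_numpy() > batch["_dbp_adj"].to_numpy()
            ) & (batch["dx_cvd"].to_numpy() == 0)
        kept = batch.loc[keep]
        collected.append(kept)
        total += len(kept)
    out = pd.concat(collected, ignore_index=True).iloc[:n].reset_index(drop=True)
    return out


def simulate_cohort(
    config: GeneratorConfig, constants: ClinicalConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Generate the two-arm cohort table for a configuration.

    Returns ``n_reference + n_hypertensive`` rows in the cohort-table schema
    (raw device-scale BP; latent_class ground truth retained for testing).
    Identical config and seed give a bit-identical table.
    """
    frames = []
    if config.n_reference > 0:
        ref = _collect_arm(config, "reference", config.n_reference, constants)
        mbp = mean_bp(ref["_sbp_adj"].to_numpy(), ref["_dbp_adj"].to_numpy())
        pred = _predict_reference_asi(
            config.reference_asi_coefficients,
            ref["age"].to_numpy(),
            ref["sex"].to_numpy(),
            mbp,
            ref["hr"].to_numpy(),
        )
        noise_rng = _substream(config.seed, "reference.asi_noise")
        noise = (
            noise_rng.normal(0.0, config.reference_noise_sd, size=len(ref))
            if config.reference_noise_sd > 0
            else np.zeros(len(ref))
        )
        ref["asi_measured"] = pred + noise
        ref["arm"] = "reference"
        ref["latent_class"] = "none"
        frames.append(ref)

    if config.n_hypertensive > 0:
        hyp = _collect_arm(config, "hypertensive", config.n_hypertensive, constants)
        eta = np.full(len(hyp), config.class_logit_intercept)
        for name, beta in sorted(config.class_logit_coefficients.items()):
            eta += beta * hyp[name].to_numpy()
        for (v1, v2), beta in sorted(config.class_logit_interactions.items()):
            s1, s2 = config.hypertensive_moments[v1], config.hypertensive_moments[v2]
            z1 = (hyp[v1].to_numpy() - s1.mean) / s1.sd
            z2 = (hyp[v2].to_numpy() - s2.mean) / s2.sd
            eta += beta * z1 * z2
        p_pos = 1.0 / (1.0 + np.exp(-eta))
        positive = _substream(config.seed, "hypertensive.class").random(len(hyp)) < p_pos

        idx_rng = _substream(config.seed, "hypertensive.index")
        mp, sp = config.index_pos_moments
        mn, sn = config.index_neg_moments
        mu_p, sig_p = solve_truncnorm_params(mp, sp, 0.0, np.inf)
        mu_n, sig_n = solve_truncnorm_params(mn, sn, -np.inf, 0.0)
        # one stream for both classes: draw a uniform per row, invert the
        # class-appropriate truncated normal
        u = idx_rng.random(len(hyp))
        pos_index = stats.truncnorm.ppf(
            u, (0.0 - mu_p) / sig_p, np.inf, loc=mu_p, scale=sig_p
        )
        neg_index = stats.truncnorm.ppf(
            u, -np.inf, (0.0 - mu_n) / sig_n, loc=mu_n, scale=sig_n
        )
        index = np.where(positive, pos_index, neg_index)

        mbp = mean_bp(hyp["_sbp_adj"].to_numpy(), hyp["_dbp_adj"].to_numpy())
        pred = _predict_reference_asi(
            config.reference_asi_coefficients,
            hyp["age"].to_numpy(),
            hyp["sex"].to_numpy(),
            mbp,
            hyp["hr"].to_numpy(),
        )
        if np.any(pred <= 0):
            raise RuntimeError(
                "generating predicted ASI non-positive for some hypertensive rows; "
                "check covariate moments against the reference coefficients"
            )
        hyp["asi_measured"] = pred * (1.0 + index)
        hyp["arm"] = "hypertensive"
        hyp["latent_class"] = np.where(positive, "positive", "negative")
        frames.append(hyp)

    if not frames:
        raise ValueError("config requests an empty cohort")
    cohort = pd.concat(frames, ignore_index=True)
    cohort = cohort.drop(columns=["_sbp_adj", "_dbp_adj"])
    cohort.insert(0, "id", [f"P{i:07d}" for i in range(len(cohort))])
    from .cohort import REQUIRED_COLUMNS

    return cohort[list(REQUIRED_COLUMNS)]


# ---------------------------------------------------------------------------
# flat key-value config text round-trip (CLI interface)


def config_to_text(config: GeneratorConfig) -> str:
    """Serialise a configuration as flat ``key = value`` lines."""
    lines = []

    def put(key, value):
        lines.append(f"{key} = {value}")

    put("n_reference", config.n_reference)
    put("n_hypertensive", config.n_hypertensive)
    put("seed", config.seed)
    put("male_fraction_reference", config.male_fraction_reference)
    put("male_fraction_hypertensive", config.male_fraction_hypertensive)
    put(
        "reference_asi_coefficients",
        ",".join(str(v) for v in config.reference_asi_coefficients),
    )
    put("reference_noise_sd", config.reference_noise_sd)
    put("class_logit_intercept", config.class_logit_intercept)
    put("index_pos_moments", ",".join(str(v) for v in config.index_pos_moments))
    put("index_neg_moments", ",".join(str(v) for v in config.index_neg_moments))
    put("attempt_cap_factor", config.attempt_cap_factor)
    for arm, moments in (
        ("reference", config.reference_moments),
        ("hypertensive", config.hypertensive_moments),
    ):
        for name, spec in sorted(moments.items()):
            put(
                f"moments.{arm}.{name}",
                f"{spec.family},{spec.mean},{spec.sd},{spec.lower},{spec.upper}",
            )
    for name, beta in sorted(config.class_logit_coefficients.items()):
        put(f"class_logit.{name}", beta)
    for (v1, v2), beta in sorted(config.class_logit_interactions.items()):
        put(f"class_logit_interaction.{v1}*{v2}", beta)
    for arm, rates in (
        ("reference", config.therapy_rates_reference),
        ("hypertensive", config.therapy_rates_hypertensive),
    ):
        for name, rate in sorted(rates.items()):
            put(f"therapy.{arm}.{name}", rate)
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> GeneratorConfig:
    """Parse a configuration produced by :func:`config_to_text`."""
    scalars: dict[str, str] = {}
    moments: dict[str, dict[str, VariableSpec]] = {"reference": {}, "hypertensive": {}}
    logit: dict[str, float] = {}
    interactions: dict[tuple[str, str], float] = {}
    therapy: dict[str, dict[str, float]] = {"reference": {}, "hypertensive": {}}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("moments."):
            _, arm, name = key.split(".", 2)
            fam, mean, sd, lo, hi = value.split(",")
            moments[arm][name] = VariableSpec(
                float(mean), float(sd), float(lo), float(hi), family=fam
            )
        elif key.startswith("class_logit_interaction."):
            pair = key.split(".", 1)[1]
            v1, v2 = pair.split("*")
            interactions[(v1, v2)] = float(value)
        elif key.startswith("class_logit."):
            logit[key.split(".", 1)[1]] = float(value)
        elif key.startswith("therapy."):
            _, arm, name = key.split(".", 2)
            therapy[arm][name] = float(value)
        else:
            scalars[key] = value
    return GeneratorConfig(
        n_reference=int(scalars["n_reference"]),
        n_hypertensive=int(scalars["n_hypertensive"]),
        seed=int(scalars["seed"]),
        reference_moments=moments["reference"],
        hypertensive_moments=moments["hypertensive"],
        male_fraction_reference=float(scalars["male_fraction_reference"]),
        male_fraction_hypertensive=float(scalars["male_fraction_hypertensive"]),
        reference_asi_coefficients=tuple(
            float(v) for v in scalars["reference_asi_coefficients"].split(",")
        ),
        reference_noise_sd=float(scalars["reference_noise_sd"]),
        class_logit_intercept=float(scalars["class_logit_intercept"]),
        class_logit_coefficients=logit,
        class_logit_interactions=interactions,
        index_pos_moments=tuple(
            float(v) for v in scalars["index_pos_moments"].split(",")
        ),
        index_neg_moments=tuple(
            float(v) for v in scalars["index_neg_moments"].split(",")
        ),
        therapy_rates_reference=therapy["reference"],
        therapy_rates_hypertensive=therapy["hypertensive"],
        attempt_cap_factor=int(scalars["attempt_cap_factor"]),
    )
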