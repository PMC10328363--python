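"""Synthetic cohort generator: reproducibility, calibration, ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stiffindex as si
from stiffindex.constants import DEFAULT_CONSTANTS
from stiffindex.preprocessing import adjust_bp, egfr_ckd_epi, mean_bp
from stiffindex.simulate import (
    GeneratorConfig,
    VariableSpec,
    config_from_text,
    config_to_text,
    default_config,
    solve_truncnorm_params,
)


@pytest.fixture(scope="module")
def big_cohort():
    """n = 50,000 per arm: the scale at which calibration is asserted."""
    cfg = default_config(n_reference=50_000, n_hypertensive=50_000, seed=20_230_707)
    return cfg, si.simulate_cohort(cfg)


def _predict(coeffs, age, sex, mbp, hr):
    b0, b_age, b_sex, b_mbp, b_hr = coeffs
    return b0 + b_age * age + b_sex * sex + b_mbp * mbp + b_hr * hr


def _adjusted_mean_bp(cohort):
    sbp, dbp = adjust_bp(cohort["sbp_raw"], cohort["dbp_raw"], cohort["sex"])
    return mean_bp(sbp, dbp)


class TestTruncnormSolver:
    @pytest.mark.parametrize(
        "mean, sd, lo, hi",
        [(121.81, 10.904, 70, 140), (0.2552, 0.2231, 0, np.inf), (50, 5, -np.inf, np.inf)],
    )
    def test_truncated_moments_match_target(self, mean, sd, lo, hi):
        mu, sigma = solve_truncnorm_params(mean, sd, lo, hi)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert m == pytest.approx(mean, abs=1e-6)
        assert np.sqrt(v) == pytest.approx(sd, abs=1e-6)

    def test_infeasible_target_raises(self):
        # sd larger than the interval can support
        with pytest.raises(ValueError):
            solve_truncnorm_params(0.5, 10.0, 0.0, 1.0)


class TestConfigValidation:
    def test_bad_male_fraction(self):
        with pytest.raises(ValueError):
            GeneratorConfig(male_fraction_reference=1.2)

    def test_index_mean_signs_enforced(self):
        with pytest.raises(ValueError):
            GeneratorConfig(index_pos_moments=(-0.1, 0.2))
        with pytest.raises(ValueError):
            GeneratorConfig(index_neg_moments=(0.1, 0.2))

    def test_variable_spec_invariants(self):
        with pytest.raises(ValueError):
            VariableSpec(10.0, 0.0)
        with pytest.raises(ValueError):
            VariableSpec(10.0, 1.0, lower=5.0, upper=5.0)


class TestReproducibilityAndStructure:
    def test_bit_identical_under_same_seed(self):
        cfg = default_config(400, 400, seed=77)
        a = si.simulate_cohort(cfg)
        b = si.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_row_counts_and_arm_labels(self, small_cohort):
        cfg, cohort = small_cohort
        assert len(cohort) == cfg.n_reference + cfg.n_hypertensive
        assert (cohort["arm"] == "reference").sum() == cfg.n_reference

    def test_latent_class_by_arm(self, small_cohort):
        _, cohort = small_cohort
        ref = cohort[cohort["arm"] == "reference"]
        hyp = cohort[cohort["arm"] == "hypertensive"]
        assert (ref["latent_class"] == "none").all()
        assert set(hyp["latent_class"]) == {"positive", "negative"}

    def test_named_substreams_isolate_variables(self):
        """Dropping a biomarker from the logit leaves other draws unchanged."""
        cfg = default_config(0, 500, seed=31)
        smaller = dataclasses.replace(
            cfg,
            class_logit_coefficients={
                k: v for k, v in cfg.class_logit_coefficients.items() if k != "hdl"
            },
        )
        a = si.simulate_cohort(cfg)
        b = si.simulate_cohort(smaller)
        for col in ("age", "hdl", "urate", "sbp_raw", "hr"):
            np.testing.assert_array_equal(a[col].to_numpy(), b[col].to_numpy())


class TestReferenceArm:
    def test_zero_noise_asi_is_exact_linear_predictor(self):
        cfg = dataclasses.replace(
            default_config(100, 0, seed=5), reference_noise_sd=0.0
        )
        cohort = si.simulate_cohort(cfg)
        mbp = _adjusted_mean_bp(cohort)
        pred = _predict(
            cfg.reference_asi_coefficients,
            cohort["age"],
            cohort["sex"],
            mbp,
            cohort["hr"],
        )
        np.testing.assert_allclose(cohort["asi_measured"], pred, atol=1e-9)

    def test_reference_rows_satisfy_healthy_eligibility(self, big_cohort):
        _, cohort = big_cohort
        ref = cohort[cohort["arm"] == "reference"]
        sbp, dbp = adjust_bp(ref["sbp_raw"], ref["dbp_raw"], ref["sex"])
        assert np.all(sbp < 140) and np.all(dbp < 90)
        assert (ref["antihypertensive"] == 0).all()
        assert (ref["antidiabetic"] == 0).all()
        assert np.all(ref["glucose"] < 7)
        assert (ref["dx_cvd"] == 0).all()
        egfr = egfr_ckd_epi(ref["creatinine"], ref["age"], ref["sex"])
        assert np.all(egfr >= 60)

    def test_rejection_cap_signals_infeasible_config(self):
        cfg = default_config(50, 0, seed=9)
        bad = dataclasses.replace(
            cfg,
            reference_moments={
                **cfg.reference_moments,
                # glucose always >= 7: healthy eligibility can never be met
                "glucose": VariableSpec(8.0, 0.3, 7.5, 10.0),
            },
            attempt_cap_factor=20,
        )
        with pytest.raises(RuntimeError, match="attempt cap"):
            si.simulate_cohort(bad)


class TestCalibration:
    """Sample moments at n=50,000 against the configured population moments."""

    def test_hypertensive_moments_within_4_se(self, big_cohort):
        cfg, cohort = big_cohort
        hyp = cohort[cohort["arm"] == "hypertensive"]
        mbp = _adjusted_mean_bp(hyp)
        n = len(hyp)
        for name, spec in cfg.hypertensive_moments.items():
            if name in ("sbp", "dbp"):
                continue
            x = hyp[name].to_numpy()
            se_mean = spec.sd / np.sqrt(n)
            assert abs(x.mean() - spec.mean) < 4 * se_mean, name
            if spec.family == "truncnorm":
                se_sd = spec.sd / np.sqrt(2 * (n - 1))
                assert abs(x.std(ddof=1) - spec.sd) < 6 * se_sd, name
            else:
                # skewed families: normal-theory SE of the SD does not apply
                assert abs(x.std(ddof=1) - spec.sd) < 0.05 * spec.sd, name
        # adjusted-scale BP moments
        sbp, dbp = adjust_bp(hyp["sbp_raw"], hyp["dbp_raw"], hyp["sex"])
        for vals, spec in ((sbp, cfg.hypertensive_moments["sbp"]),
                           (dbp, cfg.hypertensive_moments["dbp"])):
            assert abs(np.mean(vals) - spec.mean) < 4 * spec.sd / np.sqrt(n)
        assert abs(np.mean(mbp) - 106.639) < 4 * np.std(mbp, ddof=1) / np.sqrt(n)
        assert abs(np.mean(hyp["sex"]) - cfg.male_fraction_hypertensive) < 4 * np.sqrt(
            0.25 / n
        )

    def test_reference_mean_bp_matches_population_value(self, big_cohort):
        _, cohort = big_cohort
        ref = cohort[cohort["arm"] == "reference"]
        mbp = _adjusted_mean_bp(ref)
        se = np.std(mbp, ddof=1) / np.sqrt(len(ref))
        assert abs(np.mean(mbp) - 92.558) < 3 * se

    def test_reference_moments_within_4_se_of_eligibility_oracle(self, big_cohort):
        """Healthy-arm moments, allowing for the eGFR eligibility filter.

        The eGFR >= 60 criterion rejects high-creatinine (mostly female)
        draws, shifting creatinine, testosterone, age and the sex mix away
        from the configured marginals. The oracle below redraws those
        variables directly with scipy (independent seed), applies the same
        filter, and supplies the filtered expectations.
        """
        cfg, cohort = big_cohort
        ref = cohort[cohort["arm"] == "reference"]
        n = len(ref)
        oracle_rng = np.random.default_rng(555)
        m = 400_000
        sex_o = (oracle_rng.random(m) < cfg.male_fraction_reference).astype(int)
        spec_a = cfg.reference_moments["age"]
        mu, sg = solve_truncnorm_params(spec_a.mean, spec_a.sd, spec_a.lower, spec_a.upper)
        age_o = stats.truncnorm.rvs(
            (spec_a.lower - mu) / sg, (spec_a.upper - mu) / sg, mu, sg, m,
            random_state=oracle_rng,
        )
        spec_c = cfg.reference_moments["creatinine"]
        mu, sg = solve_truncnorm_params(spec_c.mean, spec_c.sd, spec_c.lower, spec_c.upper)
        cre_o = stats.truncnorm.rvs(
            (spec_c.lower - mu) / sg, (spec_c.upper - mu) / sg, mu, sg, m,
            random_state=oracle_rng,
        )
        keep = egfr_ckd_epi(cre_o, age_o, sex_o) >= 60
        exp_male = sex_o[keep].mean()
        spec_t = cfg.reference_moments["testosterone"]
        mu_f, sd_f = spec_t.female_mean, spec_t.female_sd
        p = cfg.male_fraction_reference
        mu_m = (spec_t.mean - (1 - p) * mu_f) / p
        exp_testo = exp_male * mu_m + (1 - exp_male) * mu_f

        checks = {
            "age": (age_o[keep].mean(), spec_a.sd),
            "creatinine": (cre_o[keep].mean(), spec_c.sd),
            "testosterone": (exp_testo, spec_t.sd),
        }
        for name, (target, sd) in checks.items():
            got = ref[name].to_numpy().mean()
            assert abs(got - target) < 4 * sd / np.sqrt(n), name
        assert abs(ref["sex"].mean() - exp_male) < 4 * np.sqrt(0.25 / n)
        # unaffected covariates match the configured moments directly
        for name in ("hr", "alt", "ast", "albumin", "hdl", "ldl",
                     "total_cholesterol", "triglycerides", "urate", "phosphate",
                     "cystatin_c", "glucose", "pack_years"):
            spec = cfg.reference_moments[name]
            x = ref[name].to_numpy()
            assert abs(x.mean() - spec.mean) < 4 * spec.sd / np.sqrt(n), name


class TestHypertensiveArm:
    def test_index_sign_matches_latent_class(self, big_cohort):
        cfg, cohort = big_cohort
        hyp = cohort[cohort["arm"] == "hypertensive"]
        mbp = _adjusted_mean_bp(hyp)
        pred = _predict(
            cfg.reference_asi_coefficients, hyp["age"], hyp["sex"], mbp, hyp["hr"]
        )
        index = hyp["asi_measured"].to_numpy() / np.asarray(pred) - 1.0
        positive = hyp["latent_class"].to_numpy() == "positive"
        assert np.all(index[positive] > 0)
        assert np.all(index[~positive] < 0)

    def test_class_conditional_index_moments(self, big_cohort):
        cfg, cohort = big_cohort
        hyp = cohort[cohort["arm"] == "hypertensive"]
        mbp = _adjusted_mean_bp(hyp)
        pred = _predict(
            cfg.reference_asi_coefficients, hyp["age"], hyp["sex"], mbp, hyp["hr"]
        )
        index = hyp["asi_measured"].to_numpy() / np.asarray(pred) - 1.0
        pos = index[hyp["latent_class"].to_numpy() == "positive"]
        neg = index[hyp["latent_class"].to_numpy() == "negative"]
        assert np.mean(pos) == pytest.approx(
            cfg.index_pos_moments[0], abs=4 * cfg.index_pos_moments[1] / np.sqrt(len(pos))
        )
        assert np.mean(neg) == pytest.approx(
            cfg.index_neg_moments[0], abs=4 * cfg.index_neg_moments[1] / np.sqrt(len(neg))
        )

    def test_positive_fraction_matches_monte_carlo_oracle(self, big_cohort):
        """Latent prevalence vs direct numerical integration of the logit.

        The oracle redraws each logit biomarker from its configured marginal
        with scipy (independent seed) and averages the logistic response.
        """
        cfg, cohort = big_cohort
        hyp = cohort[cohort["arm"] == "hypertensive"]
        rng = np.random.default_rng(4321)
        m = 400_000
        sex_o = (rng.random(m) < cfg.male_fraction_hypertensive).astype(int)
        eta = np.full(m, cfg.class_logit_intercept)
        for name, beta in cfg.class_logit_coefficients.items():
            spec = cfg.hypertensive_moments[name]
            if spec.family == "truncnorm":
                mu, sg = solve_truncnorm_params(spec.mean, spec.sd, spec.lower, spec.upper)
                x = stats.truncnorm.rvs(
                    (spec.lower - mu) / sg, (spec.upper - mu) / sg, mu, sg, m,
                    random_state=rng,
                )
            elif spec.family == "lognormal":
                s2 = np.log1p(spec.sd**2 / spec.mean**2)
                x = rng.lognormal(np.log(spec.mean) - s2 / 2, np.sqrt(s2), m)
            elif spec.family == "zero_inflated_exp":
                q = 2 * spec.mean**2 / (spec.sd**2 + spec.mean**2)
                x = np.where(rng.random(m) < q, rng.exponential(spec.mean / q, m), 0.0)
            elif spec.family == "sex_mixture":
                p = cfg.male_fraction_hypertensive
                mu_m = (spec.mean - (1 - p) * spec.female_mean) / p
                var_m = (
                    spec.sd**2
                    - (1 - p) * spec.female_sd**2
                    - p * (1 - p) * (mu_m - spec.female_mean) ** 2
                ) / p
                x = np.where(
                    sex_o == 1,
                    rng.normal(mu_m, np.sqrt(var_m), m),
                    rng.normal(spec.female_mean, spec.female_sd, m),
                )
                x = np.clip(x, 0.05, None)
            eta += beta * x
        oracle = float(np.mean(1.0 / (1.0 + np.exp(-eta))))
        got = float((hyp["latent_class"] == "positive").mean())
        se = np.sqrt(oracle * (1 - oracle) / len(hyp) + oracle * (1 - oracle) / m)
        assert abs(got - oracle) < 4 * se


class TestConfigText:
    def test_round_trip(self):
        cfg = si.interaction_demo_config(123, 456, seed=9)
        back = config_from_text(config_to_text(cfg))
        assert back == dataclasses.replace(
            cfg,
            reference_moments=back.reference_moments,
            hypertensive_moments=back.hypertensive_moments,
        )
        for arm_a, arm_b in (
            (cfg.reference_moments, back.reference_moments),
            (cfg.hypertensive_moments, back.hypertensive_moments),
        ):
            assert set(arm_a) == set(arm_b)
            for k in arm_a:
                assert arm_a[k].mean == arm_b[k].mean
                assert arm_a[k].sd == arm_b[k].sd
                assert arm_a[k].family == arm_b[k].family
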