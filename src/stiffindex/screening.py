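"""Univariate screening, stepwise logistic selection and Youden thresholds.

Candidate biomarkers are screened one at a time (two-sample t test for
continuous variables, Pearson chi-square for categorical), the significant
ones enter a forward-backward logistic regression driven by likelihood-
ratio tests at 0.05 in both directions, and each retained classifier gets
an optimal decision threshold by maximising the Youden index
J = Se(c) + Sp(c) - 1 over candidate cutpoints.

ROC/AUC here is the package's own implementation (trapezoid over the
empirical ROC, identical to the tie-corrected rank-sum formulation);
scikit-learn is used only as an independent oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin


# ---------------------------------------------------------------------------
# univariate screening


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str  # "student_t" or "chi2"
    statistic: float
    p_value: float
    candidate: bool


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def univariate_screen(
    analysis: pd.DataFrame,
    label: str = "stiffness_class",
    variables: tuple[str, ...] | list[str] | None = None,
    categorical: set[str] | None = None,
    alpha: float = 0.05,
) -> list[UnivariateResult]:
    """Per-variable two-group comparison against the binary label.

    Continuous variables: two-sided pooled-variance Student t. Categorical
    variables (named in ``categorical``): Pearson chi-square without
    continuity correction. Variables with zero variance get p = 1 with a
    warning and are never candidates.
    """
    categorical = categorical or set()
    if variables is None:
        from .cohort import BIOMARKERS

        variables = BIOMARKERS
    y = analysis[label].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("univariate screening needs exactly two classes")
    results = []
    for var in variables:
        x = analysis[var].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xv, yv = x[ok], y[ok]
        if np.all(xv == xv[0]):
            warnings.warn(f"{var}: zero variance, excluded from candidates")
            results.append(UnivariateResult(var, "student_t", 0.0, 1.0, False))
            continue
        if var in categorical:
            table = pd.crosstab(xv, yv).to_numpy()
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            results.append(UnivariateResult(var, "chi2", float(chi2), float(p), p < alpha))
        else:
            t, p = _pooled_t(xv[yv == classes[1]], xv[yv == classes[0]])
            results.append(UnivariateResult(var, "student_t", t, p, p < alpha))
    return results


def chi2_test(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# logistic regression (maximum likelihood via statsmodels Newton/IRLS)


@dataclass
class LogisticModel:
    variables: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    converged: bool
    n: int
    separation: bool = False

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept)
        for var in self.variables:
            eta = eta + self.coefficients[var] * X[var].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(
    analysis: pd.DataFrame,
    variables,
    label: str = "stiffness_class",
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of the label on the given variables.

    Complete separation is flagged (``separation=True``) rather than raised;
    the stepwise selector excludes such fits.
    """
    variables = tuple(variables)
    y = analysis[label].to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    exog = sm.add_constant(
        analysis[list(variables)].to_numpy(dtype=float)
        if variables
        else np.empty((len(y), 0)),
        has_constant="add",
    )
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, tol=tol, maxiter=maxiter)
            converged = bool(res.mle_retvals.get("converged", True))
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            llf = float(res.llf)
        except Exception:  # perfect separation: the MLE diverges
            separation = True
            converged = False
            from scipy import optimize as _opt

            def nll(b):  # tiny ridge keeps the optimum finite
                eta = exog @ b
                return float(
                    np.sum(np.logaddexp(0.0, eta) - y * eta) + 1e-6 * b @ b
                )

            sol = _opt.minimize(nll, np.zeros(exog.shape[1]), method="BFGS")
            params = np.asarray(sol.x, dtype=float)
            bse = np.full_like(params, np.nan)
            eta = exog @ params
            llf = float(-np.sum(np.logaddexp(0.0, eta) - y * eta))
    if not separation and (not np.all(np.isfinite(params)) or np.any(np.abs(params) > 1e3)):
        separation = True
        converged = False
    if separation:
        warnings.warn(
            f"possible complete separation fitting {variables}; model flagged"
        )
    return LogisticModel(
        variables=variables,
        intercept=float(params[0]),
        coefficients={v: float(b) for v, b in zip(variables, params[1:])},
        standard_errors={
            v: float(se) for v, se in zip(("intercept",) + variables, bse)
        },
        log_likelihood=llf,
        converged=converged,
        n=len(y),
        separation=separation,
    )


def _lr_pvalue(ll_full: float, ll_reduced: float, df: int = 1) -> float:
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(lr, df))


def forward_backward_select(
    analysis: pd.DataFrame,
    candidates,
    label: str = "stiffness_class",
    enter_alpha: float = 0.05,
    stay_alpha: float = 0.05,
) -> LogisticModel:
    """Stepwise logistic selection driven by likelihood-ratio tests.

    Forward step: add the candidate with the smallest LR p-value if below
    ``enter_alpha``. Backward step: drop any included variable whose LR
    p-value is at or above ``stay_alpha`` (largest first). Alternate until
    stable. Deterministic: ties break alphabetically. If nothing enters, the
    intercept-only model is returned with a warning.
    """
    candidates = sorted(set(candidates))
    included: list[str] = []
    current = fit_logistic(analysis, (), label)
    while True:
        changed = False
        # forward
        best_p, best_var, best_model = None, None, None
        for var in candidates:
            if var in included:
                continue
            trial = fit_logistic(analysis, tuple(sorted(included + [var])), label)
            if trial.separation or not trial.converged:
                continue
            p = _lr_pvalue(trial.log_likelihood, current.log_likelihood)
            if p < enter_alpha and (best_p is None or p < best_p):
                best_p, best_var, best_model = p, var, trial
        if best_var is not None:
            included = sorted(included + [best_var])
            current = best_model
            changed = True
        # backward
        while len(included) > 0:
            worst_p, worst_var, worst_reduced = None, None, None
            for var in included:
                reduced_vars = tuple(v for v in included if v != var)
                reduced = fit_logistic(analysis, reduced_vars, label)
                p = _lr_pvalue(current.log_likelihood, reduced.log_likelihood)
                if p >= stay_alpha and (worst_p is None or p > worst_p):
                    worst_p, worst_var, worst_reduced = p, var, reduced
            if worst_var is None:
                break
            included = [v for v in included if v != worst_var]
            current = worst_reduced
            changed = True
        if not changed:
            break
    if not included:
        warnings.warn("no candidate entered the stepwise model; intercept-only")
    return current


class StepwiseLogistic(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper around the forward-backward logistic selection.

    Fitted attributes: ``model_`` (:class:`LogisticModel`),
    ``selected_`` (tuple of retained variable names), ``classes_``.
    """

    def __init__(self, candidates=None, enter_alpha: float = 0.05, stay_alpha: float = 0.05):
        self.candidates = candidates
        self.enter_alpha = enter_alpha
        self.stay_alpha = stay_alpha

    def fit(self, X: pd.DataFrame, y) -> "StepwiseLogistic":
        candidates = list(self.candidates) if self.candidates is not None else list(X.columns)
        frame = X.copy()
        frame["_label"] = np.asarray(y)
        self.model_ = forward_backward_select(
            frame, candidates, label="_label",
            enter_alpha=self.enter_alpha, stay_alpha=self.stay_alpha,
        )
        self.selected_ = self.model_.variables
        self.classes_ = np.unique(np.asarray(y))
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.model_.predict_proba(X)
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.model_.predict_proba(X) > 0.5).astype(int)


# ---------------------------------------------------------------------------
# ROC, AUC, Youden threshold


def roc_and_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC over all distinct thresholds and trapezoid AUC.

    Ties between a positive and a negative score contribute 1/2, so the
    trapezoid AUC equals the rank-sum (Mann-Whitney) formulation exactly.
    Positive class: label 1; predicted positive: score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)[::-1]
    tpr = np.concatenate([[0.0], [np.mean(pos >= t) for t in thresholds], [1.0]])
    fpr = np.concatenate([[0.0], [np.mean(neg >= t) for t in thresholds], [1.0]])
    curve = pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], thresholds, [-np.inf]]),
            "fpr": fpr,
            "tpr": tpr,
        }
    )
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


def rank_auc(scores, labels) -> float:
    """AUC via midranks: P(score_pos > score_neg) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0)
        / (len(pos) * len(neg))
    )


@dataclass(frozen=True)
class ThresholdedClassifier:
    """A single-variable decision rule: predict positive when
    ``value >= cutpoint`` (direction "ge") or ``value <= cutpoint`` ("le")."""

    variable: str
    direction: str  # "ge" or "le"
    cutpoint: float
    sensitivity: float
    specificity: float
    J: float
    auc: float

    def indicator(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction == "ge":
            return (values >= self.cutpoint).astype(int)
        return (values <= self.cutpoint).astype(int)

    def complement_direction(self) -> str:
        """Strict comparator of the opposite branch ('lt' for 'ge')."""
        return {"ge": "lt", "le": "gt"}[self.direction]


def youden_threshold(scores, labels, variable: str = "score") -> ThresholdedClassifier:
    """Youden-optimal cutpoint for a single continuous classifier.

    Orientation is chosen so the oriented AUC is >= 0.5: direction "ge"
    when higher values indicate the positive class, else "le". Candidate
    cutpoints are midpoints between consecutive distinct sorted values;
    ties in J break toward the smallest cutpoint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc = rank_auc(scores, labels)
    direction = "ge" if auc >= 0.5 else "le"
    oriented_auc = auc if auc >= 0.5 else 1.0 - auc
    distinct = np.unique(scores)
    if len(distinct) == 1:
        warnings.warn(f"{variable}: constant scores, degenerate threshold")
        return ThresholdedClassifier(variable, "ge", float(distinct[0]), 1.0, 0.0, 0.0, 0.5)
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    pos_sorted, neg_sorted = np.sort(pos), np.sort(neg)
    if direction == "ge":
        se = 1.0 - np.searchsorted(pos_sorted, cuts, side="left") / len(pos)
        sp = np.searchsorted(neg_sorted, cuts, side="left") / len(neg)
    else:
        se = np.searchsorted(pos_sorted, cuts, side="right") / len(pos)
        sp = 1.0 - np.searchsorted(neg_sorted, cuts, side="right") / len(neg)
    j = se + sp - 1.0
    # smallest cutpoint among J-ties (tolerance guards float noise in J)
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return ThresholdedClassifier(
        variable=variable,
        direction=direction,
        cutpoint=float(cuts[best]),
        sensitivity=float(se[best]),
        specificity=float(sp[best]),
        J=float(j[best]),
        auc=float(oriented_auc),
    )


def screen_report(
    univariate: list[UnivariateResult],
    model: LogisticModel,
    thresholds: dict[str, ThresholdedClassifier],
) -> pd.DataFrame:
    """Tabular analog of the published per-classifier summary: test p-value,
    logistic estimate (SE), oriented threshold and AUC per retained variable,
    with sensitivity/specificity rankings."""
    rows = []
    uni = {u.variable: u for u in univariate}
    for var in model.variables:
        thr = thresholds[var]
        rows.append(
            {
                "variable": var,
                "univariate_test": uni[var].test if var in uni else "",
                "univariate_p": uni[var].p_value if var in uni else np.nan,
                "estimate": model.coefficients[var],
                "se": model.standard_errors.get(var, np.nan),
                "direction": thr.direction,
                "threshold": thr.cutpoint,
                "sensitivity": thr.sensitivity,
                "specificity": thr.specificity,
                "J": thr.J,
                "auc": thr.auc,
            }
        )
    report = pd.DataFrame(rows)
    if len(report):
        # interpretation of the "most sensitive ... most specific" ranking:
        # order by sensitivity at the chosen cutpoint, descending
        report = report.sort_values("sensitivity", ascending=False).reset_index(drop=True)
    return report
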