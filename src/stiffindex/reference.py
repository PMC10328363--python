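"""Healthy-reference predicted-ASI regression and the stiffness index.

The reference model is an ordinary least squares fit of measured arterial
stiffness index (ASI, m/s) on age, sex (male=1), mean BP and heart rate in
the healthy cohort. Applying it to any participant yields a predicted ASI;
the stiffness index is the relative excess

    index = (measured ASI - predicted ASI) / predicted ASI

and a strictly positive index defines increased arterial stiffness. An
index of exactly zero is classed negative (the positive class is defined
strictly by "> 0").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

COVARIATES = ("age", "sex", "mean_bp", "hr")

#: coefficients of the published reference equation, for replication runs
PUBLISHED_COEFFICIENTS = {
    "intercept": -1.167,
    "age": 0.0837,
    "sex": 0.9337,
    "mean_bp": 0.0402,
    "hr": 0.0203,
}


class ReferenceASIModel(BaseEstimator, RegressorMixin):
    """OLS reference equation: predicted ASI from age, sex, mean BP, HR.

    Fitted attributes
    -----------------
    intercept_ : float
    coef_ : dict mapping covariate name -> coefficient (m/s per unit)
    bse_ : dict mapping "intercept" and covariate names -> classical SE
    r2_ : float
    n_fit_ : int

    The fit uses statsmodels OLS (pseudo-inverse / orthogonal
    decomposition, not the normal equations) with the classical
    homoskedastic covariance estimator.
    """

    def __init__(self, min_n_fit: int = 10):
        self.min_n_fit = min_n_fit

    @classmethod
    def from_coefficients(
        cls, coefficients: dict[str, float] | None = None
    ) -> "ReferenceASIModel":
        """Build an unfit model carrying frozen (e.g. published) coefficients."""
        coefficients = dict(coefficients or PUBLISHED_COEFFICIENTS)
        model = cls()
        model.intercept_ = float(coefficients.pop("intercept"))
        model.coef_ = {name: float(coefficients[name]) for name in COVARIATES}
        model.bse_ = {}
        model.r2_ = np.nan
        model.n_fit_ = 0
        model.frozen_ = True
        return model

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in COVARIATES if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        return X[list(COVARIATES)].to_numpy(dtype=float)

    def fit(self, X: pd.DataFrame, y) -> "ReferenceASIModel":
        """Fit OLS with intercept on complete cases of the four covariates."""
        design = self._design(X)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(design).all(axis=1) & np.isfinite(y)
        design, y = design[ok], y[ok]
        if len(y) < self.min_n_fit:
            raise ValueError(f"need at least {self.min_n_fit} complete rows to fit")
        exog = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise ValueError(
                "rank-deficient design (a covariate is constant or collinear)"
            )
        res = sm.OLS(y, exog).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = {name: float(b) for name, b in zip(COVARIATES, res.params[1:])}
        self.bse_ = {
            name: float(se)
            for name, se in zip(("intercept",) + COVARIATES, res.bse)
        }
        self.r2_ = float(res.rsquared)
        self.n_fit_ = int(len(y))
        self.frozen_ = False
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Affine evaluation of the reference equation, m/s."""
        design = self._design(X)
        coef = np.array([self.coef_[name] for name in COVARIATES])
        return self.intercept_ + design @ coef

    def to_text(self) -> str:
        """Serialise as flat ``name = value [se]`` lines."""
        lines = [f"n_fit = {self.n_fit_}", f"r2 = {self.r2_}"]
        for name in ("intercept",) + COVARIATES:
            value = self.intercept_ if name == "intercept" else self.coef_[name]
            se = self.bse_.get(name, float("nan"))
            lines.append(f"{name} = {value!r} (se {se!r})")
        return "\n".join(lines) + "\n"


def fit_reference_model(reference: pd.DataFrame) -> ReferenceASIModel:
    """Fit the reference equation on a flagged healthy cohort table."""
    return ReferenceASIModel().fit(reference, reference["asi_measured"])


def predict_asi(model: ReferenceASIModel, records: pd.DataFrame) -> np.ndarray:
    """Predicted ASI (m/s) for each record."""
    return model.predict(records)


def stiffness_index(asi_measured, predicted_asi) -> pd.DataFrame:
    """Normalized stiffness score and its binary class.

    Returns a frame with columns ``predicted_asi``, ``stiffness_index`` and
    ``stiffness_class`` (1 for index > 0, else 0). Requires predicted ASI
    strictly positive — a non-positive prediction is outside the
    physiological range of the reference model.
    """
    measured = np.asarray(asi_measured, dtype=float)
    predicted = np.asarray(predicted_asi, dtype=float)
    if np.any(predicted <= 0):
        raise ValueError("predicted ASI must be positive to form the index")
    index = (measured - predicted) / predicted
    return pd.DataFrame(
        {
            "predicted_asi": predicted,
            "stiffness_index": index,
            "stiffness_class": (index > 0).astype(int),
        }
    )
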