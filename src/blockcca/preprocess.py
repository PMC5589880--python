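"""Confound residualization and standardization.

Before any multivariate fit, each variable is replaced by its least-squares
residual on the nuisance covariates (age, sex, smoking) and then scaled to
unit sample standard deviation.  The transformer stores the training
coefficients, residual means and scales so test subjects can be adjusted with
training-fold parameters only — the leakage-free contract cross-validation
relies on.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def _as_array(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported")
    return arr


def _design(covariates: Optional[np.ndarray], n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates])


class ConfoundResidualizer(TransformerMixin, BaseEstimator):
    """Per-variable OLS residualization on covariates, then standardization.

    Parameters
    ----------
    standardize : bool, default True
        Divide residuals by their training-sample standard deviation
        (``n - 1`` divisor).  When True, a variable whose residual is
        constant raises at fit time.

    Attributes
    ----------
    coef_ : ndarray of shape (q + 1, p)
        Intercept plus covariate coefficients per variable.
    mean_ : ndarray of shape (p,)
        Residual means on the training data (numerically ~0).
    scale_ : ndarray of shape (p,)
        Residual sample standard deviations; all 1.0 if ``standardize=False``.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, covariates=None) -> "ConfoundResidualizer":
        Xa = _as_array(X)
        n, p = Xa.shape
        cov = None if covariates is None else _as_array(covariates)
        if cov is not None:
            q = cov.shape[1]
            if n <= q + 1:
                raise ValueError(f"need n > q + 1 subjects (n={n}, q={q})")
            self._check_collinearity(cov, covariates)
        D = _design(cov, n)
        coef, *_ = np.linalg.lstsq(D, Xa, rcond=None)
        resid = Xa - D @ coef
        mean = resid.mean(axis=0)
        if self.standardize:
            scale = resid.std(axis=0, ddof=1)
            tiny = scale < 1e-12
            if tiny.any():
                names = self._column_names(X, np.flatnonzero(tiny))
                raise ValueError(
                    f"zero post-residual variance for variables {names}; "
                    "constant (or covariate-determined) variables cannot be standardized"
                )
        else:
            scale = np.ones(p)
        self.coef_ = coef
        self.mean_ = mean
        self.scale_ = scale
        self.n_features_in_ = p
        return self

    def transform(self, X, covariates=None) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xa = _as_array(X)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} variables, model was fit with {self.n_features_in_}"
            )
        cov = None if covariates is None else _as_array(covariates)
        D = _design(cov, Xa.shape[0])
        if D.shape[1] != self.coef_.shape[0]:
            raise ValueError("covariate count does not match the fitted model")
        resid = Xa - D @ self.coef_
        return (resid - self.mean_) / self.scale_

    def fit_transform(self, X, covariates=None, **fit_params) -> np.ndarray:
        return self.fit(X, covariates).transform(X, covariates)

    @staticmethod
    def _check_collinearity(cov: np.ndarray, covariates) -> None:
        D = _design(cov, cov.shape[0])
        if np.linalg.matrix_rank(D) == D.shape[1]:
            return
        # identify the offending columns by greedy rank growth
        names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                 else [f"cov_{j}" for j in range(cov.shape[1])])
        kept = np.ones((cov.shape[0], 1))
        offenders = []
        for j in range(cov.shape[1]):
            cand = np.column_stack([kept, cov[:, j]])
            if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(kept):
                kept = cand
            else:
                offenders.append(names[j])
        raise ValueError(f"collinear covariates: {offenders}")

    @staticmethod
    def _column_names(X, idx: np.ndarray):
        if isinstance(X, pd.DataFrame):
            return [str(X.columns[i]) for i in idx]
        return [int(i) for i in idx]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps({
            "standardize": self.standardize,
            "coef": self.coef_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
        })

    @classmethod
    def from_json(cls, payload: str) -> "ConfoundResidualizer":
        data = json.loads(payload)
        model = cls(standardize=data["standardize"])
        model.coef_ = np.asarray(data["coef"], dtype=float)
        model.mean_ = np.asarray(data["mean"], dtype=float)
        model.scale_ = np.asarray(data["scale"], dtype=float)
        model.n_features_in_ = model.coef_.shape[1]
        return model


def fit_residualizer(X, covariates=None, standardize: bool = True) -> ConfoundResidualizer:
    """Functional wrapper over :class:`ConfoundResidualizer.fit`."""
    return ConfoundResidualizer(standardize=standardize).fit(X, covariates)


def transform(model: ConfoundResidualizer, X, covariates=None) -> np.ndarray:
    """Apply a fitted residualizer to (possibly new) subjects."""
    return model.transform(X, covariates)
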