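"""Two-class linear discriminant analysis on latent component scores.

Small, explicit implementation (weight = pooled-covariance-inverse times the
class-mean difference) so the decision rule applied to the 2-D component
space is fully transparent; the pooled covariance is ridge-stabilized when
singular and the stabilization is recorded.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


class BinaryLDA(ClassifierMixin, BaseEstimator):
    """Gaussian two-class LDA with empirical priors.

    Attributes
    ----------
    means_ : ndarray (2, d)        class means (row 0 = class 0)
    covariance_ : ndarray (d, d)   pooled within-class covariance
    priors_ : ndarray (2,)
    coef_ : ndarray (d,)           Sigma^{-1} (mu1 - mu0)
    threshold_ : float             decide class 1 when coef.x > threshold
    ridge_applied_ : bool
    """

    def fit(self, X, y) -> "BinaryLDA":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if not set(classes) <= {0, 1} or len(classes) != 2:
            raise ValueError("training labels must contain both classes 0 and 1")
        n, d = X.shape
        X0, X1 = X[y == 0], X[y == 1]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n - 2)
        self.ridge_applied_ = False
        try:
            coef = np.linalg.solve(S, mu1 - mu0)
            if not np.all(np.isfinite(coef)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            ridge = 1e-6 * np.trace(S) / d + 1e-12
            S = S + ridge * np.eye(d)
            coef = np.linalg.solve(S, mu1 - mu0)
            self.ridge_applied_ = True
            logger.warning("singular pooled covariance; ridge %.3e applied", ridge)
        priors = np.array([len(X0) / n, len(X1) / n])
        self.means_ = np.vstack([mu0, mu1])
        self.covariance_ = S
        self.priors_ = priors
        self.coef_ = coef
        self.threshold_ = float(0.5 * coef @ (mu0 + mu1) - np.log(priors[1] / priors[0]))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_ - self.threshold_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        pred = (scores > 0).astype(int)
        # exact ties (degenerate zero-weight fits) go to the larger-prior class
        ties = scores == 0
        if ties.any():
            pred[ties] = int(self.priors_[1] > self.priors_[0])
        return pred


def lda_fit(scores, labels) -> BinaryLDA:
    """Fit a two-class LDA on component scores."""
    return BinaryLDA().fit(scores, labels)


def lda_predict(model: BinaryLDA, scores) -> np.ndarray:
    """Predict 0/1 labels from component scores."""
    return model.predict(scores)
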