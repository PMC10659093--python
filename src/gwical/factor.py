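"""Generic two-stage factor-analytic case definition.

The strict research-style definition is built by principal-components factor
analysis of ordinal symptom scales: standardize the scales, extract the first
``n_factors`` principal components, varimax-rotate them, compute standardized
factor scores, and dichotomize each score at ``threshold_sd`` standard
deviations above the mean to form binary syndrome indicators.  A subject
meets the definition if positive on any indicator.

Only the generic machinery is provided here; the original instrument's 52
scales and fitted loadings are not reproduced.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a (p, k) loading matrix."""
    p, k = loadings.shape
    rotation = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T @ (rotated**3 - rotated * (rotated**2).sum(axis=0) / p)
        )
        rotation = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return rotation


class TwoStageFactorDefinition(BaseEstimator, TransformerMixin):
    """Principal-components factor scores dichotomized into syndrome indicators.

    Parameters
    ----------
    n_factors : int
        Number of principal components (syndrome factors) to retain.
    threshold_sd : float, default 1.5
        A syndrome indicator is positive when the standardized factor score
        exceeds this many standard deviations above the training mean.  At
        1.5 SD on approximately normal scores the per-indicator positive rate
        is about 1 - Phi(1.5) ~ 6.7%.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_scales, n_factors)
        Varimax-rotated principal-component loadings.
    weights_ : ndarray of shape (n_scales, n_factors)
        Projection from standardized scales to standardized factor scores.
    """

    def __init__(self, n_factors: int = 6, threshold_sd: float = 1.5):
        self.n_factors = n_factors
        self.threshold_sd = threshold_sd

    def _validate(self, X, fitting: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"scale_{i}" for i in range(X.shape[1])]
        if X.ndim != 2:
            raise ValueError("scale matrix must be 2-dimensional")
        if fitting:
            n, p = X.shape
            if self.n_factors > p:
                raise ValueError(
                    f"n_factors={self.n_factors} exceeds the {p} available scales"
                )
            if n <= p:
                raise ValueError("need more subjects than scales to fit")
            if n < 10 * p:
                warnings.warn(
                    "fewer than 10 subjects per scale; factor solution may be "
                    "unstable",
                    stacklevel=3,
                )
            sd = X.std(axis=0, ddof=1)
            zero = np.flatnonzero(sd == 0)
            if zero.size:
                raise ValueError(
                    f"zero-variance scale(s): {', '.join(names[i] for i in zero)}"
                )
        return X, names

    def fit(self, X, y=None):
        X, names = self._validate(X, fitting=True)
        n = X.shape[0]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.scale_names_ = names
        z = (X - self.mean_) / self.scale_
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        k = self.n_factors
        v = vt[:k].T
        s = s[:k]
        loadings = v * s / np.sqrt(n - 1)  # variable-component correlations
        self.rotation_ = varimax(loadings)
        self.loadings_ = loadings @ self.rotation_
        # Standardized factor scores: F = Z V diag(sqrt(n-1)/s) Q
        self.weights_ = v @ np.diag(np.sqrt(n - 1) / s) @ self.rotation_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Standardized factor scores, shape (n_subjects, n_factors)."""
        check_is_fitted(self, "weights_")
        X, _ = self._validate(X, fitting=False)
        return (X - self.mean_) / self.scale_ @ self.weights_

    def indicators(self, X) -> np.ndarray:
        """Boolean syndrome indicators: score > mean + threshold_sd * SD."""
        return self.transform(X) > self.threshold_sd

    def predict(self, X) -> np.ndarray:
        """Overall case flag: positive on any syndrome indicator."""
        return self.indicators(X).any(axis=1)


def two_stage_factor_definition(scale_matrix, n_factors: int, threshold_sd: float = 1.5):
    """Fit on ``scale_matrix`` and return (indicator matrix, overall flag)."""
    est = TwoStageFactorDefinition(n_factors=n_factors, threshold_sd=threshold_sd)
    est.fit(scale_matrix)
    ind = est.indicators(scale_matrix)
    return ind, ind.any(axis=1)
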