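"""Feature standardisation and PCA reduction.

Features are z-score normalised (population convention, 1/N) and projected
onto the smallest leading set of principal components whose cumulative
explained variance reaches 99.9%.  Both steps are fitted on the training
portion by default; fitting on the whole dataset (the reduction uses no
label information) is available through the pipeline's ``fit_scope``
switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

VARIANCE_THRESHOLD = 0.999


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature z-score parameters.

    Zero-spread features carry ``std = 1`` (so they transform to 0) and are
    flagged in ``zero_variance``.
    """

    means: np.ndarray
    stds: np.ndarray
    zero_variance: np.ndarray  # boolean flags

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.means.shape[0]:
            raise ValueError(
                f"feature width {X.shape[1]} does not match fitted width "
                f"{self.means.shape[0]}"
            )
        return (X - self.means) / self.stds


@dataclass(frozen=True)
class PCAModel:
    """Orthonormal component basis with per-component variance ratios."""

    components: np.ndarray               # (n_retained, n_features)
    explained_variance_ratios: np.ndarray  # all ratios, non-increasing
    n_retained: int

    def transform(self, X_standardized: np.ndarray) -> np.ndarray:
        X = np.asarray(X_standardized, dtype=float)
        if X.shape[1] != self.components.shape[1]:
            raise ValueError(
                f"feature width {X.shape[1]} does not match component width "
                f"{self.components.shape[1]}"
            )
        return X @ self.components.T


class StandardizedPCA(TransformerMixin, BaseEstimator):
    """z-score standardisation followed by variance-thresholded PCA.

    ``n_components_`` is the smallest m whose cumulative explained variance
    ratio reaches ``variance_threshold`` (0.999 by default).
    """

    def __init__(self, variance_threshold: float = VARIANCE_THRESHOLD):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        if not 0 < self.variance_threshold <= 1:
            raise ValueError(
                f"variance_threshold must be in (0, 1], got {self.variance_threshold}"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D table with at least 2 rows")
        scaler = StandardScaler()  # population (1/N) variance convention
        Z = scaler.fit_transform(X)
        self.means_ = scaler.mean_
        self.stds_ = scaler.scale_  # zero-variance columns get scale 1
        self.zero_variance_mask_ = scaler.var_ == 0

        pca = PCA(svd_solver="full")
        pca.fit(Z)
        ratios = pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        # smallest m with cumulative ratio >= threshold (tolerant at 1.0)
        m = int(np.searchsorted(cum, self.variance_threshold - 1e-12) + 1)
        m = min(m, len(ratios))
        self.explained_variance_ratio_ = ratios
        self.explained_variance_ = pca.explained_variance_
        self.components_ = pca.components_[:m]
        self.n_components_ = m
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        return self.standardization_params_.transform(X) @ self.components_.T

    @property
    def standardization_params_(self) -> StandardizationParams:
        check_is_fitted(self, "components_")
        return StandardizationParams(self.means_, self.stds_, self.zero_variance_mask_)

    @property
    def pca_model_(self) -> PCAModel:
        check_is_fitted(self, "components_")
        return PCAModel(
            self.components_, self.explained_variance_ratio_, self.n_components_
        )


def zscore_fit(X: np.ndarray) -> StandardizationParams:
    """Per-column mean and population standard deviation of a feature table."""
    X = np.asarray(X, dtype=float)
    if X.size == 0 or X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a non-empty 2-D table with at least 2 rows")
    means = X.mean(axis=0)
    stds = X.std(axis=0)  # population (1/N)
    zero = stds == 0
    stds = np.where(zero, 1.0, stds)
    return StandardizationParams(means, stds, zero)


def pca_fit(
    X_standardized: np.ndarray, variance_threshold: float = VARIANCE_THRESHOLD
) -> PCAModel:
    """PCA of standardised data keeping ``variance_threshold`` cumulative variance."""
    est = StandardizedPCA(variance_threshold)
    # data is already standardised; fitting re-centres but leaves scale intact
    est.fit(X_standardized)
    return est.pca_model_


def transform(
    X: np.ndarray, params: StandardizationParams, model: PCAModel
) -> np.ndarray:
    """Standardise ``X`` and project it onto the retained components."""
    return model.transform(params.transform(X))
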