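"""Training-set-only z-score normalization.

Location and scale are estimated from training rows exclusively and then
applied to any row set, so validation and test rows never influence the fit.
Constant features get scale 1 (and transform to exactly 0) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["ZScoreNormalizer"]

_SCALE_TOL = 1e-12


class ZScoreNormalizer:
    """Per-feature z-scoring fitted on training rows only.

    Attributes
    ----------
    location_ : ndarray of shape (n_features,)
        Per-feature training mean.
    scale_ : ndarray of shape (n_features,)
        Per-feature training sample standard deviation (ddof=1); constant
        features get scale 1.
    """

    def fit(self, X: np.ndarray) -> "ZScoreNormalizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("expected a non-empty 2-d training matrix")
        self.location_ = X.mean(axis=0)
        if X.shape[0] > 1:
            sd = X.std(axis=0, ddof=1)
        else:
            sd = np.zeros(X.shape[1])
        constant = sd <= _SCALE_TOL
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature(s); scale set to 1",
                UserWarning,
                stacklevel=2,
            )
        self.scale_ = np.where(constant, 1.0, sd)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}"
            )
        return (X - self.location_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
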