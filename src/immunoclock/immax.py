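"""IMMAX immune-age index by principal component regression on five biomarkers.

The index approximates a comprehensive immune-age score on the [0, 1] scale from
flow-cytometry-derived cell-frequency biomarkers: the four ratios enter on the
log scale, the CD28neg fraction of CD8 T cells on the logit scale; predictors
are z-scored, projected onto the leading principal axes, and the target is
regressed on the scores by ordinary least squares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.base import BaseEstimator, RegressorMixin

from .cohort import BIOMARKER_COLUMNS

__all__ = ["ImmaxPCR", "fit_immax_pcr", "predict_immax"]

#: transform applied to each biomarker before standardization
TRANSFORMS = {name: ("logit" if name == "cd28neg_cd8_freq" else "log") for name in BIOMARKER_COLUMNS}


class DomainError(ValueError):
    """A biomarker value lies outside the domain of its transform."""


def _as_matrix(biomarkers) -> np.ndarray:
    if isinstance(biomarkers, pd.DataFrame):
        missing = [c for c in BIOMARKER_COLUMNS if c not in biomarkers.columns]
        if missing:
            raise ValueError(f"missing biomarker columns: {missing}")
        X = biomarkers[BIOMARKER_COLUMNS].to_numpy(dtype=float)
    else:
        X = np.asarray(biomarkers, dtype=float)
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValueError("biomarkers must be an n x 5 table")
    if np.isnan(X).any():
        raise ValueError("biomarkers contain missing values")
    return X


class ImmaxPCR(RegressorMixin, BaseEstimator):
    """Principal-component regression estimator of the IMMAX index.

    Parameters
    ----------
    n_components : int, default 1
        Number of retained principal axes (1..5).
    logit_eps : float, default 1e-4
        Clipping bound for the logit transform of the CD28neg fraction.

    Attributes
    ----------
    center_, scale_ : arrays of 5 floats on the transformed scale.
    loadings_ : (5, k) orthonormal principal axes; the first axis is sign-
        aligned to correlate positively with the CD8 memory:naive ratio.
    coef_, intercept_ : least-squares regression of the target on the scores.
    """

    def __init__(self, n_components: int = 1, logit_eps: float = 1e-4):
        self.n_components = n_components
        self.logit_eps = logit_eps

    # -- transform ---------------------------------------------------------
    def _transform_raw(self, X: np.ndarray, *, strict: bool = True) -> np.ndarray:
        T = np.empty_like(X)
        for j, name in enumerate(BIOMARKER_COLUMNS):
            col = X[:, j]
            if TRANSFORMS[name] == "log":
                if strict and np.any(col <= 0):
                    raise DomainError(f"column {name}: ratio must be strictly positive")
                T[:, j] = np.log(col)
            else:
                if strict and np.any((col < 0) | (col > 1)):
                    raise DomainError(f"column {name}: fraction must lie in [0, 1]")
                T[:, j] = logit(np.clip(col, self.logit_eps, 1 - self.logit_eps))
        return T

    def fit(self, X, y) -> "ImmaxPCR":
        k = int(self.n_components)
        if not 1 <= k <= 5:
            raise ValueError("n_components must be between 1 and 5")
        Xm = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != Xm.shape[0]:
            raise ValueError("target length does not match the biomarker table")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("target values must lie in [0, 1]")

        T = self._transform_raw(Xm)
        self.center_ = T.mean(axis=0)
        self.scale_ = T.std(axis=0, ddof=1)
        if np.any(self.scale_ <= 0):
            j = int(np.argmin(self.scale_))
            raise ValueError(f"column {BIOMARKER_COLUMNS[j]}: constant (zero scale)")
        Z = (T - self.center_) / self.scale_

        # principal axes via SVD of the standardized design
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        V = Vt[:k].T  # 5 x k, orthonormal columns
        # align PC1 so higher scores mean older immune age (positive loading
        # on the CD8 memory:naive ratio, the strongest senescence marker)
        j_anchor = BIOMARKER_COLUMNS.index("cd8_mem_naive_ratio")
        if V[j_anchor, 0] < 0:
            V[:, 0] = -V[:, 0]
        self.loadings_ = V

        S = Z @ V
        design = np.column_stack([np.ones(len(S)), S])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.fitted_raw_ = design @ beta
        return self

    def _raw_predict(self, X) -> np.ndarray:
        Xm = _as_matrix(X)
        Z = (self._transform_raw(Xm) - self.center_) / self.scale_
        return self.intercept_ + (Z @ self.loadings_) @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Predicted IMMAX, clipped to [0, 1]."""
        if not hasattr(self, "loadings_"):
            raise ValueError("ImmaxPCR instance is not fitted yet")
        return np.clip(self._raw_predict(X), 0.0, 1.0)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "immax_pcr",
            "n_components": int(self.n_components),
            "logit_eps": float(self.logit_eps),
            "transform_spec": TRANSFORMS,
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "loadings": self.loadings_.tolist(),
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImmaxPCR":
        model = cls(n_components=d["n_components"], logit_eps=d["logit_eps"])
        model.center_ = np.asarray(d["center"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.loadings_ = np.asarray(d["loadings"], dtype=float)
        model.intercept_ = float(d["intercept"])
        model.coef_ = np.asarray(d["coef"], dtype=float)
        return model


def fit_immax_pcr(biomarkers, target, k: int = 1) -> ImmaxPCR:
    """Fit the PCR index with ``k`` retained components."""
    return ImmaxPCR(n_components=k).fit(biomarkers, target)


def predict_immax(model: ImmaxPCR, biomarkers) -> np.ndarray:
    return model.predict(biomarkers)
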