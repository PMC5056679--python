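"""Standardized 2-D principal-component geometry fitted on complete cases.

All imputation errors in this package are Euclidean distances between the
true and the imputed observation after projection into a low-dimensional
(default 2-D) principal-component space.  The space is fitted once, on the
complete cases only, so the geometry never rotates when incomplete cases are
added — sidestepping the Procrustes-alignment problem that arises when a PCA
is refitted on imputed data.

Features are z-scored by the complete-case mean and standard deviation before
the eigendecomposition; real tables mix units (mm, mmHg, cell counts) and an
unscaled PCA would be dominated by whichever feature has the largest variance.
Every error, kernel and threshold in the package lives in this standardized
geometry.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import DataError


class PCAGeometry(BaseEstimator):
    """Complete-case standardization plus top-``n_components`` principal axes.

    Parameters
    ----------
    n_components : int, default=2
        Dimension of the error space.  Two suffices for the error measure and
        is the package default throughout.

    Attributes
    ----------
    mean_ : ndarray of shape (D,)
        Complete-case feature means.
    scale_ : ndarray of shape (D,)
        Complete-case standard deviations (ddof=1).  Zero-variance features
        get scale 1 (their z-scores are identically 0) and a warning.
    components_ : ndarray of shape (n_components, D)
        Orthonormal principal axes of the standardized complete cases; the
        largest-magnitude loading of each axis is made positive.
    eigenvalues_ : ndarray of shape (n_components,)
        Corresponding eigenvalues, in decreasing order.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("X must be 2-D")
        n, d = X.shape
        if n < 3:
            raise DataError(f"need at least 3 complete cases, got {n}")
        if d < 2:
            raise DataError("need at least 2 features")
        if np.isnan(X).any():
            raise DataError("geometry must be fitted on complete cases only")

        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero_var = sd <= 0
        if zero_var.any():
            warnings.warn(
                f"{int(zero_var.sum())} feature(s) with zero complete-case "
                "variance carry no information and get zero loadings",
                UserWarning,
                stacklevel=2,
            )
        if (~zero_var).sum() < 2:
            raise DataError("fewer than 2 features have positive variance")
        self.scale_ = np.where(zero_var, 1.0, sd)

        Z = (X - self.mean_) / self.scale_
        cov = (Z.T @ Z) / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][: self.n_components]
        axes = evecs[:, order].T  # (q, D)
        evals = np.clip(evals[order], 0.0, None)
        # deterministic sign: largest-magnitude loading of each axis positive
        for i in range(axes.shape[0]):
            j = int(np.argmax(np.abs(axes[i])))
            if axes[i, j] < 0:
                axes[i] = -axes[i]
        self.components_ = axes
        self.eigenvalues_ = evals
        return self

    # -- coordinate transforms -------------------------------------------

    def standardize(self, X) -> np.ndarray:
        """Map raw coordinates to z-scores (missing cells pass through as NaN)."""
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def unstandardize(self, Z) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_

    def project_std(self, Z) -> np.ndarray:
        """Project standardized coordinates onto the principal axes."""
        return np.asarray(Z, dtype=float) @ self.components_.T

    def transform(self, X) -> np.ndarray:
        """Project raw coordinates into the principal-component space."""
        return self.project_std(self.standardize(X))

    # -- the error measure -----------------------------------------------

    def error_std(self, z_true, z_imputed) -> float:
        """Euclidean distance in PC space between two standardized vectors."""
        d = self.project_std(np.atleast_2d(z_true)) - self.project_std(
            np.atleast_2d(z_imputed)
        )
        out = np.sqrt((d**2).sum(axis=1))
        return float(out[0]) if out.size == 1 else out

    def error(self, x_true, x_imputed) -> float:
        """Euclidean distance in PC space between two raw, fully observed vectors."""
        return self.error_std(self.standardize(x_true), self.standardize(x_imputed))

    def loadings_frame(self) -> pd.DataFrame:
        """Loadings table (one row per feature) for export/plotting."""
        q = self.components_.shape[0]
        return pd.DataFrame(
            self.components_.T,
            columns=[f"axis{i + 1}" for i in range(q)],
        )


def fit_space(complete: np.ndarray, n_components: int = 2) -> PCAGeometry:
    """Fit the standardized PCA geometry on a complete-case matrix."""
    return PCAGeometry(n_components=n_components).fit(complete)


def project2(x, geometry: PCAGeometry) -> np.ndarray:
    """Project one fully observed raw vector into the PC plane."""
    return geometry.transform(np.atleast_2d(x))[0]


def error2(x_true, x_imputed, geometry: PCAGeometry) -> float:
    """Imputation error: PC-plane distance between true and imputed vectors."""
    return geometry.error(np.atleast_2d(x_true), np.atleast_2d(x_imputed))
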