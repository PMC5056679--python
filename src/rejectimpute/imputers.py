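"""Single-imputation algorithms with a common fit/transform interface.

Every imputer is fitted on *complete cases only* and fills the missing cells
of partially observed rows without ever altering an observed entry.  The
reject-option wrapper treats the imputer as a black box, so any estimator
with this interface can be plugged in.

All imputers here operate in standardized coordinates (the same geometry the
errors are measured in); the wrapper standardizes before calling them.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .data import DataError


class CompleteCaseImputer(BaseEstimator, TransformerMixin):
    """Base class: fit on a complete matrix, fill NaNs on transform."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("X must be 2-D")
        if np.isnan(X).any():
            raise DataError(f"{type(self).__name__} must be fitted on complete cases")
        self._fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Return a copy of ``X`` with every NaN replaced by an estimate."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = X.copy()
        nan_rows = np.isnan(X).any(axis=1)
        if not nan_rows.any():
            return out
        if np.isnan(X).all(axis=1).any():
            raise DataError("cannot impute a row with no observed features")
        # group rows by missingness pattern so each pattern is filled in one shot
        masks = ~np.isnan(X[nan_rows])
        idx = np.flatnonzero(nan_rows)
        seen: dict[tuple, list[int]] = {}
        for i, m in zip(idx, masks):
            seen.setdefault(tuple(m), []).append(i)
        for key, rows in seen.items():
            mask = np.array(key, dtype=bool)
            out[rows] = self._fill(X[rows], mask)
        return out

    def _fit(self, X: np.ndarray) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _fill(self, rows: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Fill a batch of rows sharing one observation mask."""
        raise NotImplementedError


class MeanImputer(CompleteCaseImputer):
    """Missing entries are replaced by the complete-case feature mean."""

    def _fit(self, X):
        self.mean_ = X.mean(axis=0)

    def _fill(self, rows, mask):
        out = rows.copy()
        out[:, ~mask] = self.mean_[~mask]
        return out


class NearestNeighbourImputer(CompleteCaseImputer):
    """Mean of the k nearest complete cases' values at the missing features.

    Neighbour distance is the Euclidean distance over the query's *observed*
    features only.  Distance ties are broken by lower training-row index.
    If fewer than ``k`` complete cases are available all of them are used
    (``k = N_com`` reduces to mean imputation at the filled features).

    Parameters
    ----------
    k : int, default=3
        Number of neighbours averaged.
    """

    def __init__(self, k: int = 3):
        self.k = k

    def _fit(self, X):
        self.X_ = X.copy()

    def _fill(self, rows, mask):
        k = min(self.k, self.X_.shape[0])
        dist = cdist(rows[:, mask], self.X_[:, mask])
        # stable sort => equal distances resolve to the lower row index
        nn = np.argsort(dist, axis=1, kind="stable")[:, :k]
        out = rows.copy()
        out[:, ~mask] = self.X_[:, ~mask][nn].mean(axis=1)
        return out


class PPCAImputer(CompleteCaseImputer):
    """Probabilistic PCA imputation (latent-variable Gaussian model).

    The model is ``x = W z + mu + eps`` with ``z ~ N(0, I_q)`` and isotropic
    noise ``eps ~ N(0, sigma^2 I_D)``, fitted to the complete cases by EM.
    A missing block is completed by its conditional mean given the observed
    block: the posterior mean of ``z`` given the observed coordinates is
    mapped back through ``W`` (single imputation; no posterior draw).

    Parameters
    ----------
    n_components : int, default=2
        Latent dimension q.
    tol : float, default=1e-6
        Relative log-likelihood change declaring EM convergence.
    max_iter : int, default=500

    Attributes
    ----------
    W_ : ndarray of shape (D, q)
        Factor loadings.
    sigma2_ : float
        Isotropic noise variance (floored at 1e-12 with a warning if the EM
        drives it lower, as happens on exactly low-rank data).
    mean_ : ndarray of shape (D,)
    loglik_trace_ : ndarray
        Per-iteration log-likelihood; nondecreasing up to round-off.
    n_iter_ : int
    converged_ : bool
    """

    SIGMA2_FLOOR = 1e-12

    def __init__(self, n_components: int = 2, tol: float = 1e-6, max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def _fit(self, X):
        n, d = X.shape
        q = self.n_components
        if n <= q:
            raise DataError(f"PPCA needs more complete cases ({n}) than components ({q})")
        if q >= d:
            raise DataError("latent dimension must be smaller than the feature count")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        S = (Xc.T @ Xc) / n  # ML covariance

        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        sigma2 = max(float(evals[q:].mean()), 1e-6)
        W = evecs[:, :q] * np.sqrt(np.clip(evals[:q], 1e-12, None))

        Iq = np.eye(q)
        trace = []
        prev = -np.inf
        converged = False
        for it in range(self.max_iter):
            M = W.T @ W + sigma2 * Iq
            Minv = np.linalg.inv(M)
            SW = S @ W
            W_new = SW @ np.linalg.inv(sigma2 * Iq + Minv @ W.T @ SW)
            sigma2_new = float(np.trace(S - SW @ Minv @ W_new.T)) / d
            if sigma2_new < self.SIGMA2_FLOOR:
                warnings.warn(
                    "PPCA noise variance collapsed; flooring at "
                    f"{self.SIGMA2_FLOOR:g} (data may be exactly low-rank)",
                    UserWarning,
                    stacklevel=3,
                )
                sigma2_new = self.SIGMA2_FLOOR
            W, sigma2 = W_new, sigma2_new
            ll = self._loglik(S, W, sigma2, n)
            trace.append(ll)
            if prev > -np.inf and abs(ll - prev) <= self.tol * abs(prev):
                converged = True
                break
            prev = ll

        if not converged:
            warnings.warn(
                f"PPCA EM did not converge in {self.max_iter} iterations "
                f"(last relative change {abs(ll - prev) / abs(prev):.2e})",
                UserWarning,
                stacklevel=3,
            )
        self.W_ = W
        self.sigma2_ = sigma2
        self.loglik_trace_ = np.array(trace)
        self.n_iter_ = len(trace)
        self.converged_ = converged

    @staticmethod
    def _loglik(S, W, sigma2, n) -> float:
        d = S.shape[0]
        C = W @ W.T + sigma2 * np.eye(d)
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            return -np.inf
        return -0.5 * n * (
            d * np.log(2 * np.pi) + logdet + float(np.trace(np.linalg.solve(C, S)))
        )

    def _fill(self, rows, mask):
        Wo = self.W_[mask]
        M = Wo.T @ Wo + self.sigma2_ * np.eye(self.W_.shape[1])
        try:
            # E[z | x_obs] for the whole batch: (r, q)
            Ez = np.linalg.solve(M, Wo.T @ (rows[:, mask] - self.mean_[mask]).T).T
        except np.linalg.LinAlgError as exc:
            raise DataError(
                "observed-coordinate covariance block is numerically singular"
            ) from exc
        out = rows.copy()
        out[:, ~mask] = Ez @ self.W_[~mask].T + self.mean_[~mask]
        return out


IMPUTERS = {
    "ppca": PPCAImputer,
    "mean": MeanImputer,
    "knn": NearestNeighbourImputer,
}


def make_imputer(name_or_estimator, **kwargs) -> CompleteCaseImputer:
    """Resolve an imputer spec ('ppca' | 'mean' | 'knn' | estimator instance)."""
    if isinstance(name_or_estimator, str):
        try:
            return IMPUTERS[name_or_estimator](**kwargs)
        except KeyError:
            raise DataError(
                f"unknown imputer {name_or_estimator!r}; choose from {sorted(IMPUTERS)}"
            ) from None
    return name_or_estimator


# -- thin functional wrappers -------------------------------------------------

def impute_mean(case, mask, complete_means) -> np.ndarray:
    """Fill one row's missing entries with the complete-case feature means."""
    case = np.asarray(case, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = case.copy()
    out[~mask] = np.asarray(complete_means, dtype=float)[~mask]
    return out


def impute_knn(case, mask, complete, k: int = 3) -> np.ndarray:
    """Fill one row by the mean of its k nearest complete cases."""
    imp = NearestNeighbourImputer(k=k).fit(complete)
    row = np.where(np.asarray(mask, dtype=bool), case, np.nan)
    return imp.transform(row[None, :])[0]


def fit_ppca(complete, n_components: int = 2, tol: float = 1e-6,
             max_iter: int = 500) -> PPCAImputer:
    """Fit the probabilistic PCA model on a complete-case matrix."""
    return PPCAImputer(n_components=n_components, tol=tol, max_iter=max_iter).fit(
        complete
    )


def impute_ppca(case, mask, model: PPCAImputer) -> np.ndarray:
    """Fill one row by the PPCA conditional mean given its observed entries."""
    row = np.where(np.asarray(mask, dtype=bool), case, np.nan)
    return model.transform(row[None, :])[0]
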