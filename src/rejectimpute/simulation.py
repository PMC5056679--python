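"""Leave-one-out simulation of every missingness pattern in every complete case.

Each complete case is masked by each of the M observed missingness patterns,
imputed by an imputer fitted on the other ``N_com - 1`` complete cases, and
the distance between the imputed and the true point in the shared PC plane is
recorded.  The result is the ``N_com x M`` matrix of *true* imputation errors
that the kernel-weighted estimator averages over.

The imputer fit inside a leave-one-out split depends only on which case is
held out, not on the pattern being simulated, so each split is fitted once
and fills all M masked copies of its held-out case in one call.  The PC
geometry is fitted once on all complete cases and shared by every cell:
refitting it per split would change the error metric between cells and
reintroduce the rotation problem the fixed space avoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .data import CasePartition, DataError, DataMatrix
from .geometry import PCAGeometry
from .imputers import CompleteCaseImputer


@dataclass
class ErrorMatrix:
    """``N_com x M`` true imputation errors from simulated missingness.

    ``err[n, m]`` is the PC-plane error of complete case ``n`` imputed under
    pattern ``m``.  Cells where the imputer failed (or the pattern left no
    observed feature) hold NaN and are excluded, with renormalization, from
    every downstream weighted average.
    """

    err: np.ndarray
    imputer_id: str = ""
    complete_ids: list[str] = field(default_factory=list)
    pattern_signatures: list[str] = field(default_factory=list)
    n_failed: int = 0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.err)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.err, index=self.complete_ids, columns=self.pattern_signatures
        )


def rmse(values) -> float:
    """Root mean square of a nonempty vector (NaNs are the caller's problem)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("rmse of an empty vector is undefined")
    return float(np.sqrt(np.mean(v**2)))


def simulate_error_matrix(
    data: DataMatrix,
    partition: CasePartition,
    imputer: CompleteCaseImputer,
    geometry: PCAGeometry,
    patterns: np.ndarray | None = None,
    fitted_loo: list | None = None,
    return_fitted: bool = False,
):
    """Build the true-error matrix by simulating every pattern in every complete case.

    Parameters
    ----------
    data, partition : the dataset and its complete/incomplete split.
    imputer : unfitted imputer prototype; cloned and fitted per LOO split.
    geometry : fitted :class:`PCAGeometry` shared by all cells.
    patterns : optional ``(M, D)`` 0/1 array overriding ``partition.patterns``
        (used when scoring a new, previously unseen pattern).
    fitted_loo : optional list of already-fitted per-split imputers to reuse.
    return_fitted : also return the per-split fitted imputers.

    Returns
    -------
    ErrorMatrix, or ``(ErrorMatrix, fitted_loo)`` if ``return_fitted``.
    """
    if patterns is None:
        patterns = partition.patterns
    patterns = np.asarray(patterns, dtype=int)
    n_com = partition.n_complete
    m = patterns.shape[0]
    if n_com < 3:
        raise DataError(
            f"leave-one-out simulation needs at least 3 complete cases, got {n_com}"
        )
    if m < 1:
        raise DataError("no missingness patterns to simulate")

    X_std = geometry.standardize(data.values[partition.complete_rows])
    proj_true = geometry.project_std(X_std)

    err = np.full((n_com, m), np.nan)
    n_failed = 0
    fitted: list = [] if fitted_loo is None else fitted_loo
    empty = ~patterns.any(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} all-missing pattern(s) skipped (no observed "
            "feature to impute from)",
            UserWarning,
            stacklevel=2,
        )

    for i in range(n_com):
        rest = np.delete(np.arange(n_com), i)
        if fitted_loo is None:
            fit_i = clone(imputer).fit(X_std[rest])
            fitted.append(fit_i)
        else:
            fit_i = fitted_loo[i]
        # all M masked copies of the held-out case, filled in one call
        masked = np.where(patterns[~empty].astype(bool), X_std[i], np.nan)
        try:
            filled = fit_i.transform(masked)
            d = geometry.project_std(filled) - proj_true[i]
            err[i, ~empty] = np.sqrt((d**2).sum(axis=1))
        except Exception as exc:  # record, don't abort the whole matrix
            n_failed += int((~empty).sum())
            warnings.warn(
                f"imputer failed for complete case {i}: {exc}",
                UserWarning,
                stacklevel=2,
            )
    n_failed += int(empty.sum()) * n_com

    result = ErrorMatrix(
        err=err,
        imputer_id=type(imputer).__name__,
        complete_ids=[data.row_ids[r] for r in partition.complete_rows],
        pattern_signatures=["".join(map(str, p)) for p in patterns],
        n_failed=n_failed,
    )
    if return_fitted:
        return result, fitted
    return result
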