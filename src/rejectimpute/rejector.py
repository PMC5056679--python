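"""Imputation with a reject option: the end-to-end estimator and diagnostics.

:class:`RejectingImputer` wraps any complete-case imputer: it fits the PC
geometry on the complete cases, simulates every observed missingness pattern
in every complete case to obtain the true-error matrix, grid-searches the
kernel scales, estimates the imputation error of every genuinely incomplete
case, and accepts (imputes) only the cases whose estimated error is strictly
below the threshold.  Rejected cases are left to the analyst rather than
silently filled.

The module also provides the surrounding diagnostics: threshold sweeps over
the simulated complete-case errors, learning curves over the number of
complete cases, and scoring of newly arriving observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CasePartition, DataError, DataMatrix, partition_cases
from .estimation import (
    EstimateReport,
    KernelParams,
    estimate_error,
    estimate_errors_for_complete,
    grid_search,
)
from .geometry import PCAGeometry
from .imputers import make_imputer
from .simulation import ErrorMatrix, rmse, simulate_error_matrix


@dataclass
class RejectDecision:
    """Accept/reject outcome for one incomplete case."""

    case_id: str
    estimated_error: float
    threshold: float
    accepted: bool
    imputed_values: np.ndarray | None = None


def apply_threshold(
    estimates: list[EstimateReport],
    threshold: float,
    imputed: dict[str, np.ndarray] | None = None,
) -> list[RejectDecision]:
    """Strict accept rule: a case is accepted iff estimated_error < threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = []
    for est in estimates:
        accepted = est.estimated_error < threshold
        filled = None
        if accepted and imputed is not None:
            filled = imputed.get(est.case_id)
        out.append(
            RejectDecision(
                case_id=est.case_id,
                estimated_error=est.estimated_error,
                threshold=threshold,
                accepted=accepted,
                imputed_values=filled,
            )
        )
    return out


def threshold_sweep(
    estimated: np.ndarray,
    actual: ErrorMatrix | np.ndarray,
    thresholds,
) -> pd.DataFrame:
    """RMSE of actual errors among would-be included vs excluded cells.

    ``estimated`` and ``actual`` are aligned cell-for-cell (the complete-case
    simulated errors and their leave-one-out estimates).  Per threshold tau,
    cells with estimate < tau form the included group.  Empty groups yield
    NaN, never 0.
    """
    A = actual.err if isinstance(actual, ErrorMatrix) else np.asarray(actual, float)
    E = np.asarray(estimated, dtype=float)
    if A.shape != E.shape:
        raise ValueError("estimated and actual matrices must be aligned")
    cells = np.isfinite(A) & np.isfinite(E)
    a, e = A[cells], E[cells]
    rows = []
    for tau in np.asarray(thresholds, dtype=float):
        inc = e < tau
        rows.append(
            {
                "threshold": tau,
                "rmse_included": rmse(a[inc]) if inc.any() else np.nan,
                "rmse_excluded": rmse(a[~inc]) if (~inc).any() else np.nan,
                "n_included": int(inc.sum()),
                "n_excluded": int((~inc).sum()),
            }
        )
    return pd.DataFrame(rows)


def default_curve_sizes(n_complete: int, n_points: int = 10) -> np.ndarray:
    """Evenly spaced subsample sizes from max(5, 10% of N_com) up to N_com."""
    lo = max(5, math.ceil(0.1 * n_complete))
    sizes = np.unique(np.linspace(lo, n_complete, n_points).round().astype(int))
    return sizes[sizes >= 3]


def learning_curve(
    data: DataMatrix,
    partition: CasePartition,
    imputer,
    params: KernelParams,
    sizes=None,
    replications: int = 100,
    seed: int = 0,
    n_components: int = 2,
    self_exclusion: bool = True,
) -> pd.DataFrame:
    """RMSE of estimated and actual errors vs number of complete cases used.

    For each size s and replication, s complete cases are drawn without
    replacement (seeded), the full pipeline (geometry, error simulation,
    estimates at the supplied kernel scales) is rerun on the subsample, and
    the RMSE of the estimated and of the actual simulated errors recorded.
    Per-size means over replications are returned.  A flat curve near its
    final value indicates the complete-case sample is large enough.
    """
    if replications < 1:
        raise ValueError("need at least one replication")
    prototype = make_imputer(imputer)
    n_com = partition.n_complete
    if sizes is None:
        sizes = default_curve_sizes(n_com)
    sizes = np.asarray(sizes, dtype=int)
    if (sizes < 3).any() or (sizes > n_com).any():
        raise ValueError("sizes must lie in [3, N_com]")
    complete_vals = data.values[partition.complete_rows]
    patterns = partition.patterns

    rows = []
    for si, s in enumerate(sizes):
        r_est, r_act = [], []
        for rep in range(replications):
            rng = np.random.default_rng([seed, si, rep])
            sub = np.sort(rng.choice(n_com, size=s, replace=False))
            vals = complete_vals[sub]
            if (vals.std(axis=0, ddof=1) <= 0).sum() > vals.shape[1] - 2:
                warnings.warn(
                    f"degenerate subsample (size {s}, rep {rep}) skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            geom = PCAGeometry(n_components=n_components).fit(vals)
            sub_data = DataMatrix(values=vals, mask=np.ones_like(vals, dtype=bool))
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message="only .* complete case")
                sub_part = partition_cases(sub_data)
            err = simulate_error_matrix(
                sub_data, sub_part, prototype, geom, patterns=patterns
            )
            est = estimate_errors_for_complete(
                err,
                params,
                complete_std=geom.standardize(vals),
                patterns=patterns,
                self_exclusion=self_exclusion,
            )
            cells = np.isfinite(err.err) & np.isfinite(est)
            r_est.append(rmse(est[cells]))
            r_act.append(rmse(err.err[cells]))
        def _mean(v):
            if not v:
                return np.nan
            # identical replications (e.g. s = N_com) average to themselves
            return v[0] if len(set(v)) == 1 else float(np.mean(v))

        rows.append(
            {
                "subsample_size": int(s),
                "rmse_estimated": _mean(r_est),
                "rmse_actual": _mean(r_act),
                "replications": len(r_est),
            }
        )
    return pd.DataFrame(rows)


def check_plateau(curve: pd.DataFrame, rel_tol: float = 0.10) -> bool:
    """True if the actual-error curve has flattened (final vs ~80%-size RMSE)."""
    c = curve.sort_values("subsample_size")
    final = c.iloc[-1]
    target = 0.8 * final["subsample_size"]
    ref = c.iloc[(c["subsample_size"] - target).abs().argsort().iloc[0]]
    if ref["subsample_size"] == final["subsample_size"] and len(c) > 1:
        ref = c.iloc[-2]
    if not np.isfinite(final["rmse_actual"]) or final["rmse_actual"] == 0:
        return True
    rel = abs(final["rmse_actual"] - ref["rmse_actual"]) / final["rmse_actual"]
    return bool(rel <= rel_tol)


class RejectingImputer(BaseEstimator, TransformerMixin):
    """Single imputation with a data-driven reject option.

    Parameters
    ----------
    imputer : {'ppca', 'mean', 'knn'} or estimator, default='ppca'
        The underlying single-imputation algorithm (any object with the
        complete-case fit / NaN-filling transform interface).
    n_components : int, default=2
        Dimension of the PC error space (and of the PPCA latent space).
    gamma, delta : float or 'grid', default='grid'
        Kernel scale parameters; 'grid' selects them by grid search on the
        simulated complete-case errors.
    grid_gamma, grid_delta : array-like or None
        Grid values (default 21 points on [0, 10]).
    threshold : float, default=0.03
        Accept a case iff its estimated error (PC-plane distance in
        standardized coordinates) is strictly below this value.
    threshold_pct : float or None
        If set, overrides ``threshold`` with ``threshold_pct/100`` times the
        RMS of all valid simulated errors (a scale-free alternative).
    knn_k : int, default=3
        Neighbour count when ``imputer='knn'``.
    ppca_tol, ppca_max_iter : EM convergence controls when ``imputer='ppca'``.
    self_exclusion : bool, default=True
        Withhold each complete case's own simulated errors from its estimate
        during grid search and diagnostics.

    Attributes
    ----------
    partition_ : CasePartition
    geometry_ : PCAGeometry fitted on the complete cases.
    err_matrix_ : ErrorMatrix of simulated true errors (None if no patterns).
    kernel_params_ : KernelParams actually used.
    grid_result_ : GridSearchResult when the grid search ran, else None.
    complete_estimates_ : ndarray, leave-one-out estimates of the simulated cells.
    estimates_ : list of EstimateReport for the incomplete rows.
    decisions_ : list of RejectDecision for the incomplete rows.
    threshold_ : float, the resolved absolute threshold.
    """

    def __init__(
        self,
        imputer="ppca",
        n_components: int = 2,
        gamma="grid",
        delta="grid",
        grid_gamma=None,
        grid_delta=None,
        threshold: float = 0.03,
        threshold_pct: float | None = None,
        knn_k: int = 3,
        ppca_tol: float = 1e-6,
        ppca_max_iter: int = 500,
        self_exclusion: bool = True,
    ):
        self.imputer = imputer
        self.n_components = n_components
        self.gamma = gamma
        self.delta = delta
        self.grid_gamma = grid_gamma
        self.grid_delta = grid_delta
        self.threshold = threshold
        self.threshold_pct = threshold_pct
        self.knn_k = knn_k
        self.ppca_tol = ppca_tol
        self.ppca_max_iter = ppca_max_iter
        self.self_exclusion = self_exclusion

    # ------------------------------------------------------------------

    def _make_prototype(self):
        if isinstance(self.imputer, str):
            kwargs = {}
            if self.imputer == "knn":
                kwargs = {"k": self.knn_k}
            elif self.imputer == "ppca":
                kwargs = {
                    "n_components": self.n_components,
                    "tol": self.ppca_tol,
                    "max_iter": self.ppca_max_iter,
                }
            return make_imputer(self.imputer, **kwargs)
        return make_imputer(self.imputer)

    def _as_data(self, X) -> DataMatrix:
        if isinstance(X, DataMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return DataMatrix.from_dataframe(X)
        X = np.asarray(X, dtype=float)
        return DataMatrix(values=X, mask=~np.isnan(X))

    def fit(self, X, y=None):
        """Run the full pipeline on a matrix with NaN-marked missing cells."""
        data = self._as_data(X)
        partition = partition_cases(data)
        if partition.n_complete < 3:
            raise DataError(
                f"pipeline needs at least 3 complete cases, got {partition.n_complete}"
            )
        self.data_ = data
        self.partition_ = partition
        self.geometry_ = PCAGeometry(n_components=self.n_components).fit(
            data.values[partition.complete_rows]
        )
        self._complete_std_ = self.geometry_.standardize(
            data.values[partition.complete_rows]
        )
        prototype = self._make_prototype()
        self.imputer_ = self._make_prototype().fit(self._complete_std_)

        if partition.n_patterns >= 1:
            self.err_matrix_, self._loo_imputers_ = simulate_error_matrix(
                data, partition, prototype, self.geometry_, return_fitted=True
            )
        else:  # all rows complete: estimation stage is a no-op
            self.err_matrix_ = None
            self._loo_imputers_ = None

        self.grid_result_ = None
        if self.err_matrix_ is not None and (
            self.gamma == "grid" or self.delta == "grid"
        ):
            self.grid_result_ = grid_search(
                self.err_matrix_,
                self._complete_std_,
                partition.patterns,
                grid_gamma=self.grid_gamma,
                grid_delta=self.grid_delta,
                self_exclusion=self.self_exclusion,
            )
            gamma = (
                self.grid_result_.params.gamma
                if self.gamma == "grid"
                else float(self.gamma)
            )
            delta = (
                self.grid_result_.params.delta
                if self.delta == "grid"
                else float(self.delta)
            )
            self.kernel_params_ = KernelParams(gamma, delta)
        else:
            g = 0.0 if self.gamma == "grid" else float(self.gamma)
            d = 0.0 if self.delta == "grid" else float(self.delta)
            self.kernel_params_ = KernelParams(g, d)

        if self.threshold_pct is not None and self.err_matrix_ is not None:
            scale = rmse(self.err_matrix_.err[self.err_matrix_.valid])
            self.threshold_ = float(self.threshold_pct) / 100.0 * scale
        else:
            self.threshold_ = float(self.threshold)

        if self.err_matrix_ is not None:
            self.complete_estimates_ = estimate_errors_for_complete(
                self.err_matrix_,
                self.kernel_params_,
                complete_std=self._complete_std_,
                patterns=partition.patterns,
                self_exclusion=self.self_exclusion,
            )
        else:
            self.complete_estimates_ = None

        self.estimates_ = []
        imputed = {}
        for i in partition.incomplete_rows:
            x_std = self.geometry_.standardize(data.values[i])
            mu = data.mask[i].astype(int)
            rep = estimate_error(
                x_std,
                mu,
                self.err_matrix_,
                self._complete_std_,
                partition.patterns,
                self.kernel_params_,
                case_id=data.row_ids[i],
            )
            self.estimates_.append(rep)
            filled_std = self.imputer_.transform(x_std[None, :])[0]
            imputed[data.row_ids[i]] = self.geometry_.unstandardize(filled_std)
        self._imputed_ = imputed
        self.decisions_ = apply_threshold(self.estimates_, self.threshold_, imputed)
        self.n_accepted_ = sum(d.accepted for d in self.decisions_)
        self.n_rejected_ = len(self.decisions_) - self.n_accepted_
        self.n_features_in_ = data.d
        return self

    # ------------------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Estimated imputation error per row (0 for complete rows)."""
        data = self._as_data(X)
        out = np.zeros(data.n)
        for i in range(data.n):
            if data.mask[i].all():
                continue
            rep, _ = self.score_new_observation(
                data.values[i], data.mask[i].astype(int), _store=False
            )
            out[i] = rep.estimated_error
        return out

    def transform(self, X) -> np.ndarray:
        """Fill every missing cell (raw coordinates); observed cells unchanged.

        Rejection is reported through :meth:`decisions` / ``decisions_``, not
        by mutating the output shape.
        """
        data = self._as_data(X)
        filled_std = self.imputer_.transform(self.geometry_.standardize(data.values))
        out = self.geometry_.unstandardize(filled_std)
        return np.where(data.mask, data.values, out)

    def score_new_observation(self, x_new, mask_new=None, _store: bool = True):
        """Estimate and threshold a newly arriving observation.

        If its missingness pattern was never seen, the pattern is simulated
        across all complete cases (reusing the fitted leave-one-out imputers)
        and the error matrix gains exactly one column.  Complete observations
        are accepted with estimate 0 by convention.
        """
        x_new = np.asarray(x_new, dtype=float)
        if mask_new is None:
            mask_new = (~np.isnan(x_new)).astype(int)
        mask_new = np.asarray(mask_new, dtype=int)
        if not mask_new.any():
            raise DataError("cannot score an observation with all features missing")
        if mask_new.all():
            rep = EstimateReport("new", 0.0, 0.0, 0)
            dec = RejectDecision("new", 0.0, self.threshold_, True, x_new.copy())
            return rep, dec

        patterns = self.partition_.patterns
        err = self.err_matrix_
        known = (
            (patterns == mask_new).all(axis=1).any() if patterns.size else False
        )
        if not known:
            new_col = simulate_error_matrix(
                self.data_,
                self.partition_,
                self._make_prototype(),
                self.geometry_,
                patterns=mask_new[None, :],
                fitted_loo=self._loo_imputers_,
            )
            patterns = (
                np.vstack([patterns, mask_new[None, :]])
                if patterns.size
                else mask_new[None, :]
            )
            joined = (
                np.hstack([err.err, new_col.err]) if err is not None else new_col.err
            )
            err = ErrorMatrix(
                err=joined,
                imputer_id=new_col.imputer_id,
                complete_ids=new_col.complete_ids,
                pattern_signatures=(
                    (err.pattern_signatures if err else [])
                    + new_col.pattern_signatures
                ),
                n_failed=(err.n_failed if err else 0) + new_col.n_failed,
            )
            if _store:
                self.err_matrix_ = err
                self.partition_.patterns = patterns

        x_std = self.geometry_.standardize(
            np.where(mask_new.astype(bool), x_new, np.nan)
        )
        rep = estimate_error(
            x_std,
            mask_new,
            err,
            self._complete_std_,
            patterns,
            self.kernel_params_,
            case_id="new",
        )
        filled = self.geometry_.unstandardize(self.imputer_.transform(x_std[None, :])[0])
        accepted = rep.estimated_error < self.threshold_
        dec = RejectDecision(
            "new", rep.estimated_error, self.threshold_, accepted,
            filled if accepted else None,
        )
        return rep, dec

    def threshold_sweep(self, thresholds=None) -> pd.DataFrame:
        """Sweep the threshold over the simulated complete-case errors."""
        if self.err_matrix_ is None:
            raise DataError("no missingness patterns were simulated")
        if thresholds is None:
            top = float(np.nanmax(self.err_matrix_.err))
            thresholds = np.linspace(0.0, top * 1.05, 50)
        return threshold_sweep(self.complete_estimates_, self.err_matrix_, thresholds)

    def learning_curve(
        self, sizes=None, replications: int = 100, seed: int = 0
    ) -> pd.DataFrame:
        """Learning curve at the fitted kernel parameters."""
        return learning_curve(
            self.data_,
            self.partition_,
            self._make_prototype(),
            self.kernel_params_,
            sizes=sizes,
            replications=replications,
            seed=seed,
            n_components=self.n_components,
            self_exclusion=self.self_exclusion,
        )

    def decisions_frame(self) -> pd.DataFrame:
        """Per-case decisions as a table (imputed values in raw coordinates)."""
        rows = []
        for dec in self.decisions_:
            row = {
                "case_id": dec.case_id,
                "estimated_error": dec.estimated_error,
                "threshold": dec.threshold,
                "accepted": dec.accepted,
            }
            if dec.imputed_values is not None:
                for name, v in zip(self.data_.feature_names, dec.imputed_values):
                    row[name] = v
            rows.append(row)
        return pd.DataFrame(rows)
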