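"""Kernel-weighted estimation of per-case imputation error.

The error of an incomplete case x with missingness pattern mu_x is estimated
as a double weighted average over the simulated true errors Err[n, m]:

    EstimatedErr(x) = sum_m p1(m) * sum_n p2(n) * Err[n, m]

where p1 is the pattern-similarity kernel  exp(-gamma * ||mu_x - mu_m||),
normalized over the M patterns, and p2 is the value-similarity kernel
exp(-delta * ||mu_x . (x - x_n)||), normalized over the N_com complete
cases; the elementwise product with mu_x restricts the distance to the
query's *present* features.  Both kernels operate in the standardized
coordinates the errors are measured in.  gamma = delta = 0 gives uniform
weights, i.e. the grand mean of the error matrix; large scales concentrate
the weight on the query's own pattern and nearest complete cases.

The scale parameters are chosen by grid search on [0, 10] x [0, 10]: the
objective is the RMSE between estimated and actual errors over the complete
cases with simulated missingness (each case's own simulated error withheld
from its estimate, so the estimator cannot memorize).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import DataError
from .simulation import ErrorMatrix

DEFAULT_GRID = np.linspace(0.0, 10.0, 21)


@dataclass
class KernelParams:
    """Scale parameters of the two similarity kernels (both >= 0)."""

    gamma: float
    delta: float

    def __post_init__(self):
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValueError("gamma must be finite and >= 0")
        if not (np.isfinite(self.delta) and self.delta >= 0):
            raise ValueError("delta must be finite and >= 0")


@dataclass
class EstimateReport:
    """One case's estimated imputation error plus weighting diagnostics."""

    case_id: str
    estimated_error: float
    pattern_weight_entropy: float
    n_valid_cells: int


def pattern_similarity(mu_a, mu_b, gamma: float) -> float:
    """Similarity of two missingness patterns: exp(-gamma * ||mu_a - mu_b||)."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    if mu_a.shape != mu_b.shape:
        raise ValueError("patterns must have equal length")
    return float(np.exp(-gamma * np.linalg.norm(mu_a - mu_b)))


def value_similarity(x, mu_x, x_n, delta: float) -> float:
    """Similarity of feature values over the query's present features.

    ``exp(-delta * ||mu_x . (x - x_n)||)``: coordinates missing in the query
    are zeroed before the Euclidean norm, so only present features count.
    """
    mu = np.asarray(mu_x, dtype=float)
    if not mu.any():
        raise DataError("value similarity undefined for an all-missing pattern")
    diff = np.nan_to_num(np.asarray(x, dtype=float) - np.asarray(x_n, dtype=float))
    return float(np.exp(-delta * np.linalg.norm(mu * diff)))


def _normalize(w: np.ndarray) -> np.ndarray:
    s = w.sum()
    if s <= 0:
        raise DataError("all kernel weights vanished (numerical underflow)")
    return w / s


def estimation_weights(
    x_std,
    mu_x,
    complete_std: np.ndarray,
    patterns: np.ndarray,
    params: KernelParams,
    exclude: int | None = None,
) -> np.ndarray:
    """The ``(N_com, M)`` weight matrix of the double weighted average.

    Pattern weights are normalized over the M patterns, case weights over the
    complete cases (minus ``exclude``, if given); the returned outer product
    sums to 1.  Validity renormalization over failed error cells happens at
    estimation time, not here.
    """
    mu = np.asarray(mu_x, dtype=float)
    if not mu.any():
        raise DataError("cannot estimate error for an all-missing pattern")
    pat_dist = np.linalg.norm(patterns - mu, axis=1)
    p1 = _normalize(np.exp(-params.gamma * pat_dist))

    diff = np.nan_to_num(np.asarray(x_std, dtype=float) - complete_std) * mu
    val_dist = np.sqrt((diff**2).sum(axis=1))
    s2 = np.exp(-params.delta * val_dist)
    if exclude is not None:
        s2 = s2.copy()
        s2[exclude] = 0.0
    p2 = _normalize(s2)
    return np.outer(p2, p1)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def estimate_error(
    x_std,
    mu_x,
    err: ErrorMatrix | np.ndarray,
    complete_std: np.ndarray,
    patterns: np.ndarray,
    params: KernelParams,
    case_id: str = "",
    exclude: int | None = None,
) -> EstimateReport:
    """Estimate one case's imputation error (weighted average of true errors).

    Invalid (NaN) cells of the error matrix are excluded and the remaining
    weights renormalized.  The estimate is a convex combination, so it always
    lies within [min, max] of the valid cells.
    """
    E = err.err if isinstance(err, ErrorMatrix) else np.asarray(err, dtype=float)
    W = estimation_weights(x_std, mu_x, complete_std, patterns, params, exclude)
    valid = np.isfinite(E)
    if not valid.any():
        raise DataError("error matrix has no valid cells")
    dead_cols = ~valid.any(axis=0)
    if dead_cols.any():
        import warnings

        warnings.warn(
            f"{int(dead_cols.sum())} pattern column(s) have no valid simulated "
            "errors and contribute nothing to the estimate",
            UserWarning,
            stacklevel=2,
        )
    wsum = W[valid].sum()
    if wsum <= 0:
        raise DataError("all weight fell on invalid error cells")
    value = float((W[valid] * E[valid]).sum() / wsum)
    p1 = W.sum(axis=0)
    return EstimateReport(
        case_id=case_id,
        estimated_error=value,
        pattern_weight_entropy=_entropy(p1),
        n_valid_cells=int(valid.sum()),
    )


# -- vectorized complete-case estimates and the grid search ------------------

def precompute_distances(complete_std: np.ndarray, patterns: np.ndarray):
    """Distance arrays reused across every (gamma, delta) evaluation.

    Returns ``(pat_dist, val_dist)`` with ``pat_dist[m, m']`` the distance
    between patterns and ``val_dist[m, n, n']`` the present-feature distance
    between complete cases n and n' under pattern m.
    """
    P = np.asarray(patterns, dtype=float)
    pat_dist = cdist(P, P)
    n = complete_std.shape[0]
    m = P.shape[0]
    val_dist = np.empty((m, n, n))
    diff2 = (complete_std[:, None, :] - complete_std[None, :, :]) ** 2
    for k in range(m):
        val_dist[k] = np.sqrt(diff2 @ P[k])
    return pat_dist, val_dist


def estimate_errors_for_complete(
    err: ErrorMatrix | np.ndarray,
    params: KernelParams,
    complete_std: np.ndarray | None = None,
    patterns: np.ndarray | None = None,
    precomputed=None,
    self_exclusion: bool = True,
) -> np.ndarray:
    """Estimated error of every (complete case, pattern) simulated cell.

    Cell (n, m) is estimated by treating case n masked by pattern m as the
    query.  With ``self_exclusion`` (default) case n's own simulated errors
    are withheld from its estimate and the case weights renormalized over the
    other complete cases — the leave-one-out spirit of the simulation.
    """
    E = err.err if isinstance(err, ErrorMatrix) else np.asarray(err, dtype=float)
    if precomputed is None:
        precomputed = precompute_distances(complete_std, patterns)
    pat_dist, val_dist = precomputed
    n, m = E.shape

    P1 = np.exp(-params.gamma * pat_dist)
    P1 /= P1.sum(axis=1, keepdims=True)
    valid = np.isfinite(E)
    A = np.where(valid, E, 0.0) @ P1.T  # (n, m): pattern-averaged errors
    B = valid.astype(float) @ P1.T      # (n, m): pattern-averaged validity

    est = np.empty((n, m))
    for k in range(m):
        S2 = np.exp(-params.delta * val_dist[k])
        if self_exclusion:
            np.fill_diagonal(S2, 0.0)
        S2 /= S2.sum(axis=1, keepdims=True)
        num = S2 @ A[:, k]
        den = S2 @ B[:, k]
        with np.errstate(invalid="ignore", divide="ignore"):
            est[:, k] = np.where(den > 0, num / den, np.nan)
    return est


@dataclass
class GridSearchResult:
    params: KernelParams
    objective: float
    surface: pd.DataFrame  # columns: gamma, delta, objective


def grid_search(
    err: ErrorMatrix | np.ndarray,
    complete_std: np.ndarray,
    patterns: np.ndarray,
    grid_gamma=None,
    grid_delta=None,
    self_exclusion: bool = True,
) -> GridSearchResult:
    """Choose (gamma, delta) minimizing estimated-vs-actual error RMSE.

    The objective at each grid point is the RMSE of (estimated - actual)
    over all valid simulated cells.  Ties are broken by smaller gamma, then
    smaller delta.  The full surface is returned for inspection/plotting.
    """
    grid_gamma = DEFAULT_GRID if grid_gamma is None else np.asarray(grid_gamma, float)
    grid_delta = DEFAULT_GRID if grid_delta is None else np.asarray(grid_delta, float)
    if grid_gamma.size == 0 or grid_delta.size == 0:
        raise ValueError("grids must be nonempty")
    E = err.err if isinstance(err, ErrorMatrix) else np.asarray(err, dtype=float)
    valid = np.isfinite(E)
    if not valid.any():
        raise DataError("error matrix has no valid cells")

    pre = precompute_distances(complete_std, patterns)
    obj = np.empty((grid_gamma.size, grid_delta.size))
    for di, delta in enumerate(grid_delta):  # delta outer: reuse nothing heavy
        for gi, gamma in enumerate(grid_gamma):
            est = estimate_errors_for_complete(
                E,
                KernelParams(gamma=float(gamma), delta=float(delta)),
                precomputed=pre,
                self_exclusion=self_exclusion,
            )
            cells = valid & np.isfinite(est)
            obj[gi, di] = float(np.sqrt(np.mean((est[cells] - E[cells]) ** 2)))

    best = np.inf
    best_gi = best_di = 0
    for gi in range(grid_gamma.size):  # gamma-major scan: ties favour small gamma
        for di in range(grid_delta.size):
            if obj[gi, di] < best:
                best = obj[gi, di]
                best_gi, best_di = gi, di

    gg, dd = np.meshgrid(grid_gamma, grid_delta, indexing="ij")
    surface = pd.DataFrame(
        {"gamma": gg.ravel(), "delta": dd.ravel(), "objective": obj.ravel()}
    )
    return GridSearchResult(
        params=KernelParams(float(grid_gamma[best_gi]), float(grid_delta[best_di])),
        objective=float(best),
        surface=surface,
    )
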