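"""Synthetic datasets with the structure the reject-option method assumes.

The generators produce low-rank continuous data (a latent Gaussian factor
model, the regime where a 2-D PC error space and PPCA are sensible) and three
missingness mechanisms: MCAR, block-structured feature bias (entire
contiguous blocks of related measurements absent, as when a part of a
specimen is damaged — "anatomical bias"), and row-group bias (higher
missingness rates in rarer groups — "species bias").  Every generator is a
pure function of its arguments including the seed, and the fully observed
truth is never destroyed: masking returns a new object, so the true value of
every hidden cell remains available for exact error evaluation.

The study-condition helper :func:`make_study_split` reproduces the
60% complete / 40% incomplete row split used to evaluate the pipeline
(ceil(0.4 * 226) = 91 incomplete rows at the reference size).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data import DataError, DataMatrix

#: Realized missing fraction must land within this of the target (resample if not).
FRACTION_TOL = 0.03


@dataclass
class SyntheticSpec:
    """Low-rank Gaussian data spec: x = W z + mu + eps, z ~ N(0, I_rank)."""

    n_rows: int
    n_features: int
    latent_rank: int = 2
    noise_sd: float = 0.1
    loading_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.latent_rank >= self.n_features:
            raise ValueError("latent_rank must be smaller than n_features")
        if self.noise_sd < 0 or self.loading_scale <= 0:
            raise ValueError("noise_sd must be >= 0 and loading_scale > 0")
        if self.n_rows <= self.n_features:
            warnings.warn(
                "fewer rows than features; downstream estimates will be weak",
                UserWarning,
                stacklevel=2,
            )


def generate_lowrank(spec: SyntheticSpec, return_params: bool = False):
    """Fully observed low-rank data; optionally also the true (W, mu)."""
    rng = np.random.default_rng(spec.seed)
    W = spec.loading_scale * rng.standard_normal((spec.n_features, spec.latent_rank))
    mu = rng.standard_normal(spec.n_features)
    Z = rng.standard_normal((spec.n_rows, spec.latent_rank))
    X = Z @ W.T + mu
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng.standard_normal(X.shape)
    data = DataMatrix(values=X, mask=np.ones_like(X, dtype=bool))
    if return_params:
        return data, W, mu
    return data


def _fix_all_missing_rows(mask: np.ndarray, rng) -> np.ndarray:
    """Re-observe one random cell in any row left fully missing."""
    for i in np.flatnonzero(~mask.any(axis=1)):
        mask[i, rng.integers(mask.shape[1])] = True
    return mask


def _masked(data: DataMatrix, mask: np.ndarray) -> DataMatrix:
    return DataMatrix(
        values=np.where(mask, data.values, np.nan),
        mask=mask,
        feature_names=list(data.feature_names),
        row_ids=list(data.row_ids),
    )


def apply_mcar(data: DataMatrix, missing_fraction: float, seed: int = 0) -> DataMatrix:
    """Remove an exact uniformly random fraction of cells (MCAR)."""
    if not 0 < missing_fraction < 1:
        raise ValueError("missing_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n, d = data.values.shape
    n_cells = round(missing_fraction * n * d)
    flat = rng.choice(n * d, size=n_cells, replace=False)
    mask = np.ones(n * d, dtype=bool)
    mask[flat] = False
    mask = _fix_all_missing_rows(mask.reshape(n, d), rng)
    return _masked(data, mask)


def apply_block_bias(
    data: DataMatrix,
    missing_fraction: float,
    block_features=None,
    max_block_frac: float = 0.5,
    seed: int = 0,
) -> DataMatrix:
    """Concentrate missingness in contiguous feature blocks (anatomical bias).

    Random rows repeatedly receive a randomly placed contiguous sub-block of
    ``block_features`` (length up to ``max_block_frac`` of the block) until
    the overall missing fraction reaches the target.  All missing cells lie
    inside ``block_features``.
    """
    if not 0 < missing_fraction < 1:
        raise ValueError("missing_fraction must be in (0, 1)")
    n, d = data.values.shape
    block = np.arange(d) if block_features is None else np.asarray(block_features, int)
    if block.size == 0:
        raise ValueError("block_features must be nonempty")
    rng = np.random.default_rng(seed)
    mask = np.ones((n, d), dtype=bool)
    target = missing_fraction * n * d
    max_len = max(1, int(math.floor(max_block_frac * block.size)))
    tries = 0
    while (~mask).sum() < target and tries < 50 * n:
        tries += 1
        row = rng.integers(n)
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, block.size - length + 1))
        cols = block[start : start + length]
        new = mask[row].copy()
        new[cols] = False
        if not new.any():  # never leave a row fully missing
            continue
        mask[row] = new
    realized = (~mask).mean()
    if abs(realized - missing_fraction) > FRACTION_TOL:
        warnings.warn(
            f"realized missing fraction {realized:.3f} misses target "
            f"{missing_fraction:.3f} by more than {FRACTION_TOL:.0%}",
            UserWarning,
            stacklevel=2,
        )
    return _masked(data, mask)


def apply_group_bias(
    data: DataMatrix,
    missing_fraction: float,
    group_assignment,
    group_rates=None,
    seed: int = 0,
    max_resample: int = 100,
) -> DataMatrix:
    """Per-cell missingness with group-specific rates (species bias).

    ``group_rates`` are *relative* rates per group label (default: inversely
    proportional to group size, so rarer groups lose more cells); they are
    scaled so the expected overall fraction equals the target, and the draw
    is repeated until the realized fraction lands within tolerance.
    """
    if not 0 < missing_fraction < 1:
        raise ValueError("missing_fraction must be in (0, 1)")
    groups = np.asarray(group_assignment)
    n, d = data.values.shape
    if groups.shape != (n,):
        raise ValueError("group_assignment must have one label per row")
    labels, counts = np.unique(groups, return_counts=True)
    if group_rates is None:
        group_rates = {lab: 1.0 / c for lab, c in zip(labels, counts)}
    rel = np.array([float(group_rates[g]) for g in groups])
    if (rel < 0).any() or rel.sum() <= 0:
        raise ValueError("group rates must be nonnegative with a positive sum")
    rates = np.clip(rel * missing_fraction * n / rel.sum(), 0.0, 0.95)

    rng = np.random.default_rng(seed)
    for _ in range(max_resample):
        mask = rng.random((n, d)) >= rates[:, None]
        mask = _fix_all_missing_rows(mask, rng)
        if abs((~mask).mean() - missing_fraction) <= FRACTION_TOL:
            return _masked(data, mask)
    warnings.warn(
        "could not realize the target missing fraction within tolerance; "
        "returning the last draw",
        UserWarning,
        stacklevel=2,
    )
    return _masked(data, mask)


def make_study_split(
    truth: DataMatrix,
    masked: DataMatrix,
    frac_missing_rows: float = 0.4,
    seed: int = 0,
) -> DataMatrix:
    """Keep masks on a random ceil(frac * N) rows; restore the rest to complete.

    This is the study design for evaluating the pipeline on data where every
    row was damaged by the missingness mechanism: a random 40% of rows stay
    incomplete and the remaining 60% are restored to their true values, so a
    substantial complete-case set exists (226 rows -> 91 incomplete).
    """
    if not 0 <= frac_missing_rows < 1:
        raise ValueError("frac_missing_rows must be in [0, 1)")
    if truth.values.shape != masked.values.shape:
        raise DataError("truth and masked data must have identical shape")
    n = truth.n
    n_incomplete = math.ceil(frac_missing_rows * n)
    candidates = np.flatnonzero(~masked.mask.all(axis=1))
    rng = np.random.default_rng(seed)
    if candidates.size < n_incomplete:
        warnings.warn(
            f"only {candidates.size} rows have missing cells; requested "
            f"{n_incomplete} incomplete rows",
            UserWarning,
            stacklevel=2,
        )
        chosen = candidates
    else:
        chosen = rng.choice(candidates, size=n_incomplete, replace=False)
    mask = np.ones_like(truth.mask)
    mask[chosen] = masked.mask[chosen]
    return _masked(truth, mask)
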