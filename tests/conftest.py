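import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rejectimpute import (
    DataMatrix,
    SyntheticSpec,
    apply_block_bias,
    apply_mcar,
    generate_lowrank,
    make_study_split,
)
from rejectimpute.imputers import CompleteCaseImputer

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


class OracleImputer(CompleteCaseImputer):
    """Perfect imputer for testing: fills from a known ground-truth matrix.

    Each masked row is matched to the truth row agreeing with it on the
    observed coordinates (exact for simulated missingness in known cases).
    """

    def __init__(self, truth):
        self.truth = np.asarray(truth, dtype=float)

    def _fit(self, X):
        pass

    def _fill(self, rows, mask):
        out = rows.copy()
        for i, r in enumerate(rows):
            d = ((self.truth[:, mask] - r[mask]) ** 2).sum(axis=1)
            out[i, ~mask] = self.truth[int(np.argmin(d)), ~mask]
        return out


def make_study(
    n_rows=80,
    n_features=8,
    noise_sd=0.1,
    missing_fraction=0.4,
    frac_missing_rows=0.4,
    mechanism="mcar",
    seed=0,
):
    """Low-rank truth plus a study-split dataset with simulated missingness."""
    spec = SyntheticSpec(
        n_rows=n_rows, n_features=n_features, latent_rank=2,
        noise_sd=noise_sd, seed=seed,
    )
    truth = generate_lowrank(spec)
    if mechanism == "mcar":
        masked = apply_mcar(truth, missing_fraction, seed=seed + 1)
    else:
        masked = apply_block_bias(truth, missing_fraction, seed=seed + 1)
    study = make_study_split(truth, masked, frac_missing_rows, seed=seed + 2)
    return truth, study


@pytest.fixture(scope="session")
def study():
    """A medium synthetic dataset shared by pipeline-level tests."""
    return make_study(n_rows=80, n_features=8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_data():
    """5 rows, 2 complete, 3 incomplete with 2 distinct patterns."""
    values = np.array(
        [
            [1.0, 2.0, 3.0],
            [2.0, 1.0, 0.0],
            [np.nan, 4.0, 1.0],
            [0.5, np.nan, 2.0],
            [np.nan, 3.0, 0.5],
        ]
    )
    return DataMatrix(values=values, mask=~np.isnan(values))
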