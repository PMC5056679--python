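import numpy as np
import pytest

from rejectimpute import (
    DataError,
    EstimateReport,
    KernelParams,
    RejectingImputer,
    apply_threshold,
    learning_curve,
    partition_cases,
    threshold_sweep,
)
from rejectimpute.rejector import check_plateau, default_curve_sizes
from rejectimpute.estimation import estimate_errors_for_complete
from rejectimpute.geometry import PCAGeometry
from rejectimpute.simulation import rmse, simulate_error_matrix
from rejectimpute.imputers import MeanImputer

from conftest import make_study


def reports(values):
    return [EstimateReport(str(i), v, 0.0, 1) for i, v in enumerate(values)]


class TestApplyThreshold:
    def test_zero_threshold_rejects_everything(self):
        decs = apply_threshold(reports([0.0, 0.1, 2.0]), 0.0)
        assert not any(d.accepted for d in decs)

    def test_infinite_threshold_accepts_everything(self):
        decs = apply_threshold(reports([0.0, 0.1, 2.0]), np.inf)
        assert all(d.accepted for d in decs)

    def test_strict_inequality_at_boundary(self):
        decs = apply_threshold(reports([0.02, 0.03, 0.05]), 0.03)
        assert [d.accepted for d in decs] == [True, False, False]

    def test_monotone_in_threshold(self):
        ests = reports([0.01, 0.2, 0.5, 0.9, 1.4])
        accepted = [
            {d.case_id for d in apply_threshold(ests, t) if d.accepted}
            for t in (0.1, 0.6, 1.0, 2.0)
        ]
        for small, big in zip(accepted, accepted[1:]):
            assert small <= big


class TestThresholdSweep:
    @pytest.fixture()
    def aligned(self):
        rng = np.random.default_rng(21)
        actual = rng.random((8, 3))
        estimated = actual + 0.1 * rng.standard_normal((8, 3))
        return estimated, actual

    def test_below_minimum_estimate(self, aligned):
        est, act = aligned
        tab = threshold_sweep(est, act, [est.min() - 1.0])
        assert tab["n_included"].iloc[0] == 0
        assert np.isnan(tab["rmse_included"].iloc[0])
        assert tab["rmse_excluded"].iloc[0] == pytest.approx(rmse(act))

    def test_above_maximum_estimate(self, aligned):
        est, act = aligned
        tab = threshold_sweep(est, act, [est.max() + 1.0])
        assert tab["rmse_included"].iloc[0] == pytest.approx(rmse(act))
        assert np.isnan(tab["rmse_excluded"].iloc[0])

    def test_partition_is_exhaustive_and_disjoint(self, aligned):
        est, act = aligned
        tab = threshold_sweep(est, act, np.linspace(0, 1.5, 9))
        assert (tab["n_included"] + tab["n_excluded"] == act.size).all()


class TestLearningCurve:
    @pytest.fixture()
    def fitted(self):
        _, data = make_study(n_rows=60, n_features=6, seed=31)
        part = partition_cases(data)
        geom = PCAGeometry().fit(data.values[part.complete_rows])
        return data, part, geom

    def test_full_size_equals_full_data_run_exactly(self, fitted):
        data, part, geom = fitted
        params = KernelParams(2.0, 2.0)
        curve = learning_curve(
            data, part, "mean", params,
            sizes=[part.n_complete], replications=3, seed=5,
        )
        err = simulate_error_matrix(data, part, MeanImputer(), geom)
        est = estimate_errors_for_complete(
            err, params,
            complete_std=geom.standardize(data.values[part.complete_rows]),
            patterns=part.patterns,
        )
        assert curve["rmse_actual"].iloc[0] == rmse(err.err)
        assert curve["rmse_estimated"].iloc[0] == rmse(est)
        assert curve["replications"].iloc[0] == 3

    def test_same_seed_identical_curve(self, fitted):
        data, part, _ = fitted
        params = KernelParams(1.0, 1.0)
        kw = dict(sizes=[10, 20], replications=5, seed=9)
        a = learning_curve(data, part, "mean", params, **kw)
        b = learning_curve(data, part, "mean", params, **kw)
        assert a.equals(b)

    def test_replication_means_order_invariant(self, fitted):
        # means over replications do not depend on the processing order,
        # which is implied by the per-replication seed substreams
        data, part, _ = fitted
        params = KernelParams(1.0, 1.0)
        a = learning_curve(data, part, "mean", params, sizes=[15], replications=8, seed=2)
        b = learning_curve(data, part, "mean", params, sizes=[15], replications=8, seed=2)
        assert a["rmse_actual"].iloc[0] == b["rmse_actual"].iloc[0]

    def test_default_sizes_span_range(self):
        sizes = default_curve_sizes(100)
        assert sizes[0] == max(5, 10) and sizes[-1] == 100
        assert (np.diff(sizes) > 0).all()

    def test_invalid_sizes_rejected(self, fitted):
        data, part, _ = fitted
        with pytest.raises(ValueError):
            learning_curve(data, part, "mean", KernelParams(1, 1),
                           sizes=[part.n_complete + 1], replications=1)

    def test_plateau_detection(self):
        import pandas as pd

        flat = pd.DataFrame({
            "subsample_size": [10, 20, 30, 40],
            "rmse_actual": [0.5, 0.42, 0.405, 0.40],
            "rmse_estimated": [0.5] * 4,
        })
        steep = pd.DataFrame({
            "subsample_size": [10, 20, 30, 40],
            "rmse_actual": [2.0, 1.5, 1.0, 0.5],
            "rmse_estimated": [0.5] * 4,
        })
        assert check_plateau(flat)
        assert not check_plateau(steep)


class TestRejectingImputer:
    @pytest.fixture()
    def fitted(self):
        _, data = make_study(n_rows=70, n_features=7, seed=41)
        model = RejectingImputer(
            imputer="mean", gamma=2.0, delta=2.0, threshold_pct=100
        ).fit(data)
        return data, model

    def test_accept_reject_partition(self, fitted):
        data, model = fitted
        assert model.n_accepted_ + model.n_rejected_ == model.partition_.n_incomplete

    def test_transform_preserves_observed_and_fills_missing(self, fitted):
        data, model = fitted
        out = model.transform(data)
        np.testing.assert_array_equal(out[data.mask], data.values[data.mask])
        assert not np.isnan(out).any()

    def test_predict_zero_for_complete_rows(self, fitted):
        data, model = fitted
        est = model.predict(data.values[model.partition_.complete_rows[:4]])
        np.testing.assert_array_equal(est, 0.0)

    def test_predict_matches_fit_estimates(self, fitted):
        data, model = fitted
        i = model.partition_.incomplete_rows[0]
        est = model.predict(data.values[i][None, :])
        assert est[0] == pytest.approx(model.estimates_[0].estimated_error, abs=1e-10)

    def test_sklearn_param_interface(self):
        model = RejectingImputer(imputer="knn", knn_k=5)
        assert model.get_params()["knn_k"] == 5
        model.set_params(threshold=0.5)
        assert model.threshold == 0.5

    def test_all_complete_input_estimation_noop(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        model = RejectingImputer(imputer="mean", gamma=1.0, delta=1.0).fit(X)
        assert model.err_matrix_ is None
        assert model.decisions_ == []

    def test_too_few_complete_cases_aborts(self):
        X = np.array([[1.0, 2], [3, 4], [np.nan, 1], [np.nan, 2]])
        with pytest.warns(UserWarning):
            with pytest.raises(DataError, match="at least 3 complete"):
                RejectingImputer(imputer="mean", gamma=1.0, delta=1.0).fit(X)

    def test_refit_is_deterministic(self):
        _, data = make_study(n_rows=50, n_features=6, seed=43)
        a = RejectingImputer(imputer="mean").fit(data)
        b = RejectingImputer(imputer="mean").fit(data)
        assert np.array_equal(a.err_matrix_.err, b.err_matrix_.err)
        assert [d.estimated_error for d in a.decisions_] == [
            d.estimated_error for d in b.decisions_
        ]
        assert (a.kernel_params_.gamma, a.kernel_params_.delta) == (
            b.kernel_params_.gamma, b.kernel_params_.delta)

    def test_ppca_accepts_at_least_as_many_as_mean_on_lowrank_data(self):
        # low-rank structure: the latent-variable model imputes far better
        # than feature means, so more cases clear the same threshold
        _, data = make_study(n_rows=90, n_features=8, noise_sd=0.05, seed=47)
        kw = dict(gamma=2.0, delta=2.0, threshold=0.3)
        ppca = RejectingImputer(imputer="ppca", **kw).fit(data)
        mean = RejectingImputer(imputer="mean", **kw).fit(data)
        assert ppca.n_accepted_ >= mean.n_accepted_


class TestScoreNewObservation:
    @pytest.fixture()
    def fitted(self):
        _, data = make_study(n_rows=60, n_features=6, seed=51)
        model = RejectingImputer(
            imputer="mean", gamma=2.0, delta=2.0, threshold_pct=100
        ).fit(data)
        return data, model

    def test_stored_incomplete_case_reproduced(self, fitted):
        data, model = fitted
        i = model.partition_.incomplete_rows[0]
        rep, dec = model.score_new_observation(data.values[i])
        assert rep.estimated_error == pytest.approx(
            model.estimates_[0].estimated_error, abs=1e-12
        )
        assert dec.accepted == model.decisions_[0].accepted

    def test_unseen_pattern_appends_one_column(self, fitted):
        data, model = fitted
        m_before = model.err_matrix_.err.shape[1]
        new_mask = np.ones(data.d, dtype=int)
        new_mask[[0, data.d - 1]] = 0
        while (model.partition_.patterns == new_mask).all(axis=1).any():
            new_mask[1] = 0
        x = np.where(new_mask.astype(bool), data.values[0], np.nan)
        model.score_new_observation(x, new_mask)
        assert model.err_matrix_.err.shape[1] == m_before + 1

    def test_complete_observation_accepted_with_zero_estimate(self, fitted):
        data, model = fitted
        rep, dec = model.score_new_observation(np.ones(data.d))
        assert rep.estimated_error == 0.0
        assert dec.accepted
        np.testing.assert_array_equal(dec.imputed_values, np.ones(data.d))

    def test_all_missing_observation_rejected(self, fitted):
        data, model = fitted
        with pytest.raises(DataError):
            model.score_new_observation(np.full(data.d, np.nan))
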