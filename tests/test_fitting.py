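"""Objective, R², the global fit and the estimator front end."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from mosskinetics import (
    MossBioreactorModel,
    ObservedDataset,
    fit,
    objective,
    r_squared,
    simulate,
)
from mosskinetics.fitting import VARIABLE_COLUMNS, default_bounds
from mosskinetics.reactor import Trajectory
from mosskinetics.synthetic_data import NoiseModel, generate, get_fixture

FX = get_fixture("lineB-batch")


def noiseless_dataset(seed=0):
    return generate(FX, NoiseModel(cv=0.0, replicates=1, seed=seed))


class TestObjective:
    def test_self_consistency_on_noiseless_data(self):
        ds = noiseless_dataset()
        assert objective(FX.params, ds) < 1e-10

    def test_perturbed_parameters_increase_the_objective(self):
        ds = noiseless_dataset()
        at_truth = objective(FX.params, ds)
        perturbed = FX.params.replace(r_x_max=FX.params.r_x_max * 1.1)
        assert objective(perturbed, ds) > at_truth

    def test_noise_floor_matches_direct_residual_recomputation(self):
        """objective(truth) on noisy data equals the scaled noise sum of
        squares recomputed outside the fitting code."""
        noise = NoiseModel(cv=0.05, replicates=2, seed=42)
        ds = generate(FX, noise)
        # independent recomputation from the exact trajectory
        traj = simulate(
            FX.params, FX.optics, FX.schedule,
            output_times=np.asarray(FX.sampling_times),
        )
        scales = ds.scales()
        direct = 0.0
        for v in ds.observed_variables:
            sub = ds.data[ds.data["variable"] == v]
            exact = traj.values_at(VARIABLE_COLUMNS[v], sub["time_d"].to_numpy())
            direct += float(np.sum(((sub["value"].to_numpy() - exact) / scales[v]) ** 2))
        assert objective(FX.params, ds) == pytest.approx(direct, rel=0.2)

    def test_unknown_variable_rejected(self):
        df = pd.DataFrame(
            {"time_d": [0.0, 1.0], "variable": ["glucose", "glucose"], "value": [1, 2]}
        )
        with pytest.raises(ValueError, match="biomass"):
            ObservedDataset(data=df, schedule=FX.schedule, optics=FX.optics)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ObservedDataset(
                data=pd.DataFrame(columns=["time_d", "variable", "value"]),
                schedule=FX.schedule,
                optics=FX.optics,
            )


class TestRSquared:
    @staticmethod
    def _fake_trajectory(times, biomass):
        frame = pd.DataFrame({"time_d": times, "biomass_gDW_per_L": biomass})
        return Trajectory(frame=frame)

    @staticmethod
    def _dataset(times, values):
        df = pd.DataFrame(
            {"time_d": times, "variable": "biomass", "value": values}
        )
        return ObservedDataset(data=df, schedule=FX.schedule, optics=FX.optics)

    def test_perfect_prediction_scores_one(self):
        y = [1.0, 2.0, 3.0, 4.0]
        t = [0.0, 1.0, 2.0, 3.0]
        r2 = r_squared(self._fake_trajectory(t, y), self._dataset(t, y))
        assert r2["biomass"] == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = [1.0, 2.0, 3.0, 4.0]
        t = [0.0, 1.0, 2.0, 3.0]
        r2 = r_squared(self._fake_trajectory(t, [2.5] * 4), self._dataset(t, y))
        assert r2["biomass"] == pytest.approx(0.0)

    def test_four_point_hand_computation(self):
        # y = 1,2,3,4; yhat = 1.1,1.9,3.2,3.9: SS_res = 0.07, SS_tot = 5
        y = [1.0, 2.0, 3.0, 4.0]
        yhat = [1.1, 1.9, 3.2, 3.9]
        t = [0.0, 1.0, 2.0, 3.0]
        r2 = r_squared(self._fake_trajectory(t, yhat), self._dataset(t, y))
        assert r2["biomass"] == pytest.approx(1.0 - 0.07 / 5.0)

    def test_zero_variance_reported_missing(self):
        t = [0.0, 1.0, 2.0]
        r2 = r_squared(
            self._fake_trajectory(t, [2.0, 2.0, 2.0]), self._dataset(t, [2.0, 2.0, 2.0])
        )
        assert r2["biomass"] is None


class TestFit:
    def test_requires_free_parameters_and_a_seed(self):
        ds = noiseless_dataset()
        with pytest.raises(ValueError):
            fit(ds, {}, fixed_params=FX.params, seed=1)
        with pytest.raises(ValueError):
            fit(ds, {"r_x_max": (0.1, 1.0)}, fixed_params=FX.params, seed=None)
        with pytest.raises(ValueError):
            fit(ds, {"bogus": (0.1, 1.0)}, fixed_params=FX.params, seed=1)
        with pytest.raises(ValueError):
            fit(ds, {"r_x_max": (1.0, 0.1)}, fixed_params=FX.params, seed=1)

    def test_collapsed_bounds_return_the_pinned_point(self):
        ds = generate(FX, NoiseModel(cv=0.05, replicates=2, seed=9))
        truth = FX.params
        bounds = {
            "r_x_max": (truth.r_x_max, truth.r_x_max),
            "y_x_n": (truth.y_x_n, truth.y_x_n),
        }
        res = fit(ds, bounds, fixed_params=truth, seed=2)
        assert res.params.r_x_max == truth.r_x_max
        assert res.params.y_x_n == truth.y_x_n
        assert res.objective == pytest.approx(objective(truth, ds), rel=1e-12)

    def test_same_seed_gives_bit_identical_results(self):
        settings = {"maxiter": 25}
        bounds = default_bounds(FX.params, ["r_x_max", "y_x_n"])
        runs = []
        for _ in range(2):
            ds = generate(FX, NoiseModel(cv=0.05, replicates=2, seed=13))
            runs.append(
                fit(ds, bounds, fixed_params=FX.params, seed=13,
                    optimizer_settings=settings).to_json()
            )
        assert runs[0] == runs[1]

    def test_noiseless_recovery_within_one_percent(self, noiseless_batch_fit):
        _, res = noiseless_batch_fit
        assert res.params.r_x_max == pytest.approx(0.699, rel=0.01)
        assert res.objective < 1e-4

    def test_optimizer_admissibility_on_noisy_data(self, batch_recovery_fits):
        """The recovered optimum is never worse than the generating truth
        on the same noisy data."""
        for ds, res in batch_recovery_fits:
            assert res.objective <= objective(FX.params, ds) * (1 + 1e-9)

    def test_fit_reports_r_squared_for_observed_variables_only(self, batch_recovery_fits):
        _, res = batch_recovery_fits[0]
        assert set(res.r_squared) == {"biomass", "nitrate", "product"}
        assert all(v is not None and v <= 1 for v in res.r_squared.values())


class TestEstimator:
    @staticmethod
    def _xy(dataset):
        X = dataset.data[["time_d", "variable", "replicate_id"]]
        y = dataset.data["value"].to_numpy()
        return X, y

    def make_model(self, **kw):
        return MossBioreactorModel(
            schedule=FX.schedule,
            optics=FX.optics,
            fixed_params=FX.params,
            bounds=default_bounds(FX.params, ["r_x_max", "y_x_n"]),
            seed=4,
            optimizer_settings={"maxiter": 25},
            **kw,
        )

    def test_sklearn_param_interface_and_clone(self):
        model = self.make_model()
        params = model.get_params()
        assert params["seed"] == 4
        cloned = clone(model)
        assert cloned.get_params()["bounds"] == model.get_params()["bounds"]

    def test_fit_predict_score_roundtrip(self):
        ds = generate(FX, NoiseModel(cv=0.03, replicates=2, seed=21))
        X, y = self._xy(ds)
        model = self.make_model().fit(X, y)
        assert hasattr(model, "params_")
        yhat = model.predict(X)
        assert yhat.shape == y.shape
        # same (time, variable) pair always maps to the same prediction
        df = X.copy()
        df["pred"] = yhat
        assert df.groupby(["time_d", "variable"])["pred"].nunique().max() == 1
        assert model.score(X, y) > 0.9
        assert model.r_squared_["biomass"] > 0.9

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        model = self.make_model()
        with pytest.raises(NotFittedError):
            model.predict(pd.DataFrame({"time_d": [0.0], "variable": ["biomass"]}))


def test_joint_fit_over_two_datasets_runs(line_b_batch_fixture):
    """Joint fitting with shared parameters across schedules."""
    fx_b = line_b_batch_fixture
    fx_s = get_fixture("lineB-semicontinuous-D0.4")
    # share the batch truth so a common optimum exists
    fx_s = dataclasses.replace(fx_s, params=fx_b.params)
    ds_b = generate(fx_b, NoiseModel(cv=0.0, replicates=1, seed=1))
    ds_s = generate(fx_s, NoiseModel(cv=0.0, replicates=1, seed=1))
    bounds = default_bounds(fx_b.params, ["r_x_max"])
    res = fit([ds_b, ds_s], bounds, fixed_params=fx_b.params, seed=6,
              optimizer_settings={"maxiter": 20})
    assert res.params.r_x_max == pytest.approx(0.699, rel=0.02)
    assert set(res.r_squared) == {
        "lineB-batch:biomass", "lineB-batch:nitrate", "lineB-batch:product",
        "lineB-semicontinuous-D0.4:biomass", "lineB-semicontinuous-D0.4:nitrate",
        "lineB-semicontinuous-D0.4:product",
    }
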