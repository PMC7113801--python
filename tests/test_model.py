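"""The recurrent estimator: parameter count, masking contract, gradients,
training behaviour, and the patient-level cross-validation protocol."""

import numpy as np
import pandas as pd
import pytest

from wtte_icu import _gru, model, preprocess, weibull
from wtte_icu._exceptions import ConfigError, DataError


def tiny_estimator(**kw):
    defaults = dict(gru_units=4, dense_units=3, epochs=5, batch_size=8,
                    learning_rate=0.01, dtype="float64", random_state=0)
    defaults.update(kw)
    return model.WeibullGRURegressor(**defaults)


def random_problem(rng, n=24, T=5, V=3):
    X = rng.normal(size=(n, T, V))
    y = np.column_stack([rng.uniform(1, 20, n), rng.integers(0, 2, n)])
    return X, y


class TestArchitecture:
    def test_parameter_count_default_architecture(self):
        """3(45+50+1)50 + (50+1)20 + (20+1)2 learnable scalars."""
        assert _gru.param_count(45, 50, 20) == 15_462

    def test_parameter_count_matches_actual_arrays(self):
        rng = np.random.default_rng(0)
        params = _gru.init_params(45, 50, 20, rng)
        assert sum(v.size for v in params.values()) == _gru.param_count(45, 50, 20)

    def test_config_validation(self):
        with pytest.raises(ConfigError, match="gru_units"):
            model.ModelConfig(gru_units=0).validate()
        with pytest.raises(ConfigError, match="learning_rate"):
            model.ModelConfig(learning_rate=0).validate()


class TestNetworkGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic BPTT gradients agree with central differences, masked steps included."""
        rng = np.random.default_rng(3)
        B, T, V, H, D = 3, 4, 3, 4, 3
        X = rng.normal(size=(B, T, V))
        step_ok = np.ones((B, T))
        step_ok[0, 0] = 0.0  # leading padding
        step_ok[1, 2] = 0.0  # interior gap
        t = rng.uniform(1, 10, B)
        u = np.array([1.0, 0.0, 1.0])
        params = _gru.init_params(V, H, D, rng)

        def loss_of(p):
            raw, _ = _gru.forward(p, X, step_ok)
            loss, _, _ = weibull.nll_grad_raw(t, u, raw[:, 0], raw[:, 1])
            return loss.mean()

        raw, cache = _gru.forward(params, X, step_ok, keep_cache=True)
        _, gs, gl = weibull.nll_grad_raw(t, u, raw[:, 0], raw[:, 1])
        draw = np.stack([gs, gl], axis=1) / B
        grads = _gru.backward(params, X, step_ok, cache, draw)

        h = 1e-6
        for name, g in grads.items():
            flat = params[name].ravel()
            for idx in np.random.default_rng(1).choice(flat.size,
                                                       size=min(6, flat.size),
                                                       replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss_of(params)
                flat[idx] = orig - h
                down = loss_of(params)
                flat[idx] = orig
                fd = (up - down) / (2 * h)
                assert g.ravel()[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8), name


class TestMaskingContract:
    def test_prepending_masked_steps_preserves_predictions(self):
        rng = np.random.default_rng(5)
        X, y = random_problem(rng)
        est = tiny_estimator().fit(X, y)
        pad = np.full((X.shape[0], 2, X.shape[2]), np.nan)
        X_padded = np.concatenate([pad, X], axis=1)
        np.testing.assert_allclose(est.predict(X_padded), est.predict(X), atol=1e-6)

    def test_padding_values_are_ignored(self):
        rng = np.random.default_rng(6)
        X, y = random_problem(rng)
        mask = np.zeros(X.shape[:2], dtype=bool)
        mask[:, 0] = True
        est = tiny_estimator().fit(X, y, mask=mask)
        X2 = X.copy()
        X2[:, 0, :] = rng.normal(size=(X.shape[0], X.shape[2])) * 100
        np.testing.assert_allclose(est.predict(X2, mask=mask), est.predict(X, mask=mask),
                                   atol=1e-8)

    def test_all_masked_observation_refused(self):
        rng = np.random.default_rng(7)
        X, y = random_problem(rng)
        est = tiny_estimator().fit(X, y)
        X_bad = np.full_like(X, np.nan)
        with pytest.raises(DataError, match="masked"):
            est.predict(X_bad)

    def test_n_vars_mismatch_refused(self):
        rng = np.random.default_rng(8)
        X, y = random_problem(rng)
        est = tiny_estimator().fit(X, y)
        with pytest.raises(ConfigError, match="n_vars"):
            est.predict(rng.normal(size=(4, 5, 7)))


class TestTraining:
    def test_zero_epochs_returns_initialised_model(self):
        rng = np.random.default_rng(9)
        X, y = random_problem(rng)
        est = tiny_estimator(epochs=0).fit(X, y)
        assert len(est.history_) == 0
        p = est.predict(X)
        assert np.all(p > 0)

    def test_training_reduces_cost(self):
        rng = np.random.default_rng(10)
        X, y = random_problem(rng, n=64)
        est = tiny_estimator(epochs=30, restore_best=False).fit(X, y)
        hist = est.history_["train_cost"].to_numpy()
        assert len(hist) == 30
        assert np.all(np.isfinite(hist))
        assert hist[-5:].mean() <= hist[:5].mean()

    def test_reproducible_history_with_fixed_seed(self):
        rng = np.random.default_rng(11)
        X, y = random_problem(rng, n=32)
        h1 = tiny_estimator(epochs=5).fit(X, y).history_
        h2 = tiny_estimator(epochs=5).fit(X, y).history_
        pd.testing.assert_frame_equal(h1, h2)

    def test_validation_checkpoint_never_worse_than_marginal_fit(self):
        """With best-validation restore, the kept weights beat (or match) the
        covariate-free censored-Weibull fit on validation NLL."""
        rng = np.random.default_rng(12)
        X, y = random_problem(rng, n=64)
        Xv, yv = random_problem(rng, n=32)
        est = tiny_estimator(epochs=10).fit(X, y, validation_data=(Xv, yv))
        raw = model._marginal_raw_fit(y[:, 0], y[:, 1])
        k0 = max(weibull.link_shape(raw[0]), weibull.PARAM_FLOOR)
        lam0 = max(weibull.link_scale(raw[1]), weibull.PARAM_FLOOR)
        marginal_val = weibull.nll(yv[:, 0], yv[:, 1], k0, lam0).mean()
        assert -est.score(Xv, yv) <= marginal_val + 1e-9

    def test_label_validation(self):
        rng = np.random.default_rng(13)
        X, _ = random_problem(rng)
        with pytest.raises(DataError):
            tiny_estimator().fit(X, np.zeros((X.shape[0], 2)))  # zero times
        bad_u = np.column_stack([np.ones(X.shape[0]), np.full(X.shape[0], 2.0)])
        with pytest.raises(DataError):
            tiny_estimator().fit(X, bad_u)


class TestKfoldSplit:
    def patients(self, n_event, n_censored):
        n = n_event + n_censored
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "event": [1] * n_event + [0] * n_censored,
            "outcome_time": np.linspace(5, 100, n),
        })

    def test_published_cohort_fold_sizes(self):
        """759 patients, 5 folds: validation folds of 151 or 152 patients,
        7 or 8 event patients each (759 = 5*151 + 4, 37 = 5*7 + 2)."""
        pts = self.patients(37, 722)
        folds = model.kfold_split(pts, n_folds=5, seed=0)
        sizes = folds["fold"].value_counts()
        assert set(sizes) <= {151, 152}
        assert sizes.sum() == 759
        merged = folds.merge(pts, on="patient_id")
        per_fold_events = merged.groupby("fold")["event"].sum()
        assert set(per_fold_events) <= {7, 8}
        assert per_fold_events.sum() == 37

    def test_partition_disjoint_exhaustive(self):
        pts = self.patients(10, 40)
        folds = model.kfold_split(pts, n_folds=5, seed=1)
        assert len(folds) == 50
        assert folds["patient_id"].is_unique
        assert set(folds["fold"]) == {1, 2, 3, 4, 5}

    def test_seeded_determinism(self):
        pts = self.patients(10, 40)
        a = model.kfold_split(pts, 5, seed=3)
        b = model.kfold_split(pts, 5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_events(self):
        with pytest.raises(DataError, match="event patients"):
            model.kfold_split(self.patients(3, 40), n_folds=5)


class TestRunCv:
    @pytest.fixture(scope="class")
    def cv_result(self, small_windows):
        ws, patients = small_windows
        config = model.ModelConfig(epochs=3, batch_size=128, learning_rate=0.003,
                                   dtype="float32", seed=2)
        return ws, model.run_cv(ws, patients, config)

    def test_every_observation_predicted_exactly_once(self, cv_result):
        ws, (models, pooled, folds, scalers) = cv_result
        assert len(pooled) == ws.n_observations
        assert pooled["obs_id"].is_unique

    def test_five_models_with_histories(self, cv_result):
        ws, (models, pooled, folds, scalers) = cv_result
        assert len(models) == 5
        for est in models:
            assert len(est.history_) == 3
            assert est.history_["val_cost"].notna().all()

    def test_no_patient_straddles_folds(self, cv_result):
        ws, (models, pooled, folds, scalers) = cv_result
        per_patient = pooled.groupby("patient_id")["fold"].nunique()
        assert (per_patient == 1).all()

    def test_standardization_from_training_fold_only(self, cv_result):
        """Fold-1 scaler statistics equal a recomputation over the fold-1
        training observations, so validation data leaks nowhere."""
        ws, (models, pooled, folds, scalers) = cv_result
        val_p = set(folds.loc[folds["fold"] == 1, "patient_id"])
        train_idx = ~ws.labels["patient_id"].astype(str).isin(val_p)
        ref = preprocess.WindowStandardizer().fit(ws.values[train_idx.to_numpy()])
        np.testing.assert_allclose(scalers[0].mean_, ref.mean_, rtol=1e-12)
        np.testing.assert_allclose(scalers[0].scale_, ref.scale_, rtol=1e-12)


class TestNoSignalNull:
    def test_null_cohort_auc_near_half(self):
        """With zero hazard weights and no drift, the trained model cannot
        rank events above censored patients: AUC at the 1 h horizon sits in
        [0.45, 0.55] and the group risk medians coincide."""
        import warnings

        from wtte_icu import cohort, evaluate
        from wtte_icu.experiments import _cohort_to_windows

        def null_spec(n_event, n_censored, seed):
            return cohort.CohortSpec(
                n_event=n_event, n_censored=n_censored, hazard_weights=0.0,
                drift_amplitude=0.0, drift_n_vars=0, horizon_steps=4,
                min_outcome_hours=5.0, missing_rate_hourly=0.0,
                missing_rate_daily=0.0, daily_var_fraction=0.0,
                max_stay_hours=120.0, seed=seed,
            )

        # train on one null cohort, score a fresh one: any apparent
        # discrimination on held-out noise is a bug
        tr, _ = _cohort_to_windows(null_spec(200, 400, seed=31), 4, missing=False)
        ws, _ = _cohort_to_windows(null_spec(400, 800, seed=32), 4, missing=False)
        std, scaler = preprocess.standardize(tr)
        est = model.WeibullGRURegressor(epochs=5, learning_rate=0.003, batch_size=512,
                                        dtype="float32", random_state=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(std.values, tr.labels[["remaining_time", "u"]].to_numpy(float),
                    mask=std.mask)
        pooled = ws.labels.copy()
        pred = est.predict(scaler.transform(ws.values), mask=ws.mask)
        pooled["shape"], pooled["scale"] = pred[:, 0], pred[:, 1]
        tab = evaluate.tauc_table(pooled, horizons=(1,))
        assert 0.45 < tab["auc"].iloc[0] < 0.55

        traj = evaluate.risk_trajectories(pooled, horizon_for_risk=4.0)
        ev = traj[(traj["group"] == "event") & (traj["remaining"] == 1)]
        cen = traj[(traj["group"] == "censored") & (traj["remaining"] == 1)]
        spread = ev["q75"].iloc[0] - ev["q25"].iloc[0]
        assert abs(ev["median"].iloc[0] - cen["median"].iloc[0]) < max(spread, 1e-3)


class TestSaveLoad:
    def test_round_trip_predictions(self, tmp_path):
        rng = np.random.default_rng(20)
        X, y = random_problem(rng)
        est = tiny_estimator().fit(X, y)
        scaler = preprocess.WindowStandardizer().fit(X)
        model.save_model(est, scaler, tmp_path)
        loaded, loaded_scaler = model.load_model(tmp_path)
        np.testing.assert_allclose(loaded.predict(X), est.predict(X), rtol=1e-12)
        np.testing.assert_allclose(loaded_scaler.mean_, scaler.mean_)
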