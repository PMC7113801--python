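"""Feature selection, missingness filtering, window construction, standardisation."""

import numpy as np
import pandas as pd
import pytest

from wtte_icu import preprocess
from wtte_icu._exceptions import ConfigError
from conftest import make_wide

VARS3 = ["v0", "v1", "v2"]


def long_series(rows):
    return pd.DataFrame(rows, columns=["patient_id", "hour", "variable", "value"])


class TestSelectCommonFeatures:
    def test_pivot_is_lossless(self):
        series = long_series([("a", 0, "v0", 1.0), ("a", 1, "v0", 2.0),
                              ("a", 0, "v1", 3.0), ("b", 0, "v0", 4.0)])
        wide, flagged = preprocess.select_common_features(series, ["v0", "v1"])
        assert wide.notna().sum().sum() == 4
        assert list(wide.columns) == ["v0", "v1"]
        assert flagged == {"b": ["v1"]}

    def test_full_variable_set_gives_45_columns(self, small_windows):
        ws, _ = small_windows
        assert len(ws.var_names) == 45

    def test_empty_required_vars_rejected(self):
        with pytest.raises(ConfigError):
            preprocess.select_common_features(long_series([("a", 0, "v0", 1.0)]), [])

    def test_grid_extends_to_outcome(self):
        series = long_series([("a", 0, "v0", 1.0)])
        patients = pd.DataFrame({"patient_id": ["a"], "event": [0], "outcome_time": [5.0]})
        wide, _ = preprocess.select_common_features(series, ["v0"], patients)
        assert len(wide.loc["a"]) == 5  # hours 0..4


class TestComputeMissingness:
    def test_direct_count_oracle(self):
        """216 empty cells on a 48 h x 45 var grid: p_id 216, p_ir 216/2160 = 0.1."""
        variables = [f"v{i}" for i in range(45)]
        cells = {(h, v): 1.0 for h in range(48) for v in variables}
        empties = [(h, variables[j]) for h in range(48) for j in range(45)][:216]
        for key in empties:
            del cells[key]
        wide = make_wide(cells, 48, variables)
        stats = preprocess.compute_missingness(wide)
        assert stats.loc[0, "p_id"] == 216
        assert stats.loc[0, "p_ir"] == pytest.approx(0.1)

    def test_fully_observed_and_fully_missing(self):
        variables = [f"v{i}" for i in range(45)]
        full = make_wide({(h, v): 1.0 for h in range(10) for v in variables}, 10, variables)
        stats = preprocess.compute_missingness(full)
        assert stats.loc[0, "p_id"] == 0 and stats.loc[0, "p_ir"] == 0.0
        empty = make_wide({}, 10, variables)
        stats = preprocess.compute_missingness(empty)
        assert stats.loc[0, "p_id"] == 450 and stats.loc[0, "p_ir"] == 1.0


class TestFilterPatients:
    def test_thresholds(self):
        stats = pd.DataFrame({
            "patient_id": ["hi_pid", "hi_pir", "clean"],
            "p_id": [1500, 100, 0],
            "p_ir": [0.05, 0.25, 0.0],
        })
        assert preprocess.filter_patients(stats) == ["clean"]

    def test_boundary_values_retained(self):
        stats = pd.DataFrame({"patient_id": ["edge"], "p_id": [1000], "p_ir": [0.20]})
        assert preprocess.filter_patients(stats) == ["edge"]

    def test_empty_result_warns(self):
        stats = pd.DataFrame({"patient_id": ["x"], "p_id": [9999], "p_ir": [0.9]})
        with pytest.warns(UserWarning, match="excluded every patient"):
            assert preprocess.filter_patients(stats) == []

    def test_conservation(self, small_windows):
        ws, patients = small_windows
        variables = [f"v{i}" for i in range(3)]
        stats = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(10)],
            "p_id": [0, 1, 2000, 3, 4, 5000, 6, 7, 8, 9],
            "p_ir": [0.0, 0.5, 0.1, 0.0, 0.0, 0.1, 0.0, 0.0, 0.0, 0.0],
        })
        retained = preprocess.filter_patients(stats)
        excluded = set(stats["patient_id"]) - set(retained)
        assert len(retained) + len(excluded) == len(stats)
        assert not set(retained) & excluded


class TestCapCensoredTte:
    @pytest.mark.parametrize("remaining,u,expected",
                             [(100.0, 0, 72.0), (100.0, 1, 100.0), (10.0, 0, 10.0)])
    def test_cap(self, remaining, u, expected):
        assert preprocess.cap_censored_tte(remaining, u, tau=72.0) == expected

    def test_invalid_tau(self):
        with pytest.raises(ConfigError):
            preprocess.cap_censored_tte(10.0, 0, tau=0.0)


def naive_windows(grid: np.ndarray, outcome: float, u: int, T: int, tau: float):
    """Independent brute-force enumeration of right-aligned windows with
    within-window carry-forward; grid is (hours, vars) with NaN for missing."""
    H, V = grid.shape
    t_max = int(np.floor(outcome - 1.0)) if u else int(np.ceil(outcome)) - 1
    t_max = min(t_max, H - 1)
    out = []
    for t in range(0, t_max + 1):
        vals = np.full((T, V), np.nan)
        mask = np.ones(T, dtype=bool)
        start = t - T + 1
        carried = np.full(V, np.nan)
        carried_from = np.full(V, -1)
        for step, hour in enumerate(range(start, t + 1)):
            if hour < 0:
                continue
            for v in range(V):
                if not np.isnan(grid[hour, v]):
                    carried[v] = grid[hour, v]
                    carried_from[v] = hour
            ok = carried_from >= max(start, 0)
            vals[step] = np.where(ok, carried, np.nan)
            mask[step] = not ok.any()
        remaining = outcome - t
        if u == 0:
            remaining = min(remaining, tau)
        out.append((t, vals, mask, remaining))
    return [w for w in out if not w[2].all()]


class TestBuildWindows:
    def make_set(self, grid, outcome, u, T, tau=72.0, max_windows=None):
        H, V = grid.shape
        variables = [f"v{i}" for i in range(V)]
        idx = pd.MultiIndex.from_product([["p0"], range(H)], names=["patient_id", "hour"])
        wide = pd.DataFrame(grid, index=idx, columns=variables)
        patients = pd.DataFrame({"patient_id": ["p0"], "event": [u], "outcome_time": [outcome]})
        return preprocess.build_windows(wide, patients, horizon_steps=T, tau=tau,
                                        max_windows=max_windows)

    def test_three_hour_patient_padding(self):
        """Hours 0..2, horizon 3: three windows with 2, 1, 0 masked leading steps."""
        grid = np.arange(6, dtype=float).reshape(3, 2)
        ws = self.make_set(grid, outcome=3.0, u=0, T=3)
        assert ws.n_observations == 3
        np.testing.assert_array_equal(ws.mask.sum(axis=1), [2, 1, 0])
        # right alignment: last step of every window is the prediction hour
        np.testing.assert_allclose(ws.values[0, 2], grid[0])
        np.testing.assert_allclose(ws.values[1, 1:], grid[:2])
        np.testing.assert_allclose(ws.values[2], grid)

    def test_last_unmasked_step_is_prediction_hour(self, small_windows):
        ws, _ = small_windows
        last_unmasked = ws.mask.shape[1] - 1 - np.argmax(~ws.mask[:, ::-1], axis=1)
        assert (last_unmasked == ws.mask.shape[1] - 1).all()

    def test_censored_remaining_never_exceeds_tau(self, small_windows):
        ws, _ = small_windows
        censored = ws.labels[ws.labels["u"] == 0]
        assert (censored["remaining_time"] <= preprocess.DEFAULT_TAU).all()
        assert (ws.labels["remaining_time"] > 0).all()

    def test_event_remaining_at_least_one_hour(self, small_windows):
        ws, _ = small_windows
        events = ws.labels[ws.labels["u"] == 1]
        assert (events["remaining_time"] >= 1.0).all()

    def test_event_in_first_hour_excluded_with_warning(self):
        grid = np.ones((2, 2))
        with pytest.warns(UserWarning, match="first hour"):
            ws = self.make_set(grid, outcome=0.5, u=1, T=3)
        assert ws.n_observations == 0

    def test_tau_cap_applied_to_censored_labels(self):
        grid = np.ones((100, 2))
        ws = self.make_set(grid, outcome=100.0, u=0, T=4, tau=72.0)
        first = ws.labels.iloc[0]  # earliest kept prediction hour
        assert first["remaining_time"] <= 72.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("u", [0, 1])
    def test_matches_bruteforce_enumeration(self, seed, u):
        """Exact agreement with a hand-rolled sliding-window oracle on tiny grids."""
        rng = np.random.default_rng(seed)
        H, V, T = 6, 3, 4
        grid = rng.normal(size=(H, V))
        grid[rng.random((H, V)) < 0.4] = np.nan
        grid[-1, 0] = 1.0  # keep the final hour observable
        outcome = float(H) if u == 0 else H - 0.5 + 1  # event slightly past the grid
        ws = self.make_set(grid, outcome=outcome, u=u, T=T, tau=5.0, max_windows=H)
        ref = naive_windows(grid, outcome, u, T, tau=5.0)
        assert ws.n_observations == len(ref)
        for i, (t, vals, mask, remaining) in enumerate(ref):
            assert ws.labels.loc[i, "prediction_hour"] == t
            assert ws.labels.loc[i, "remaining_time"] == pytest.approx(remaining)
            np.testing.assert_array_equal(ws.mask[i], mask)
            np.testing.assert_allclose(ws.values[i], vals.astype(np.float32),
                                       equal_nan=True, rtol=1e-6)


class TestStandardizer:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(20, 6, 4))
        sc = preprocess.WindowStandardizer().fit(X)
        back = sc.inverse_transform(sc.transform(X))
        np.testing.assert_allclose(back, X, atol=1e-10)

    def test_training_fold_centred_validation_not(self):
        rng = np.random.default_rng(1)
        Xtr = rng.normal(0, 1, size=(50, 4, 3))
        Xval = rng.normal(2, 1, size=(50, 4, 3))
        sc = preprocess.WindowStandardizer().fit(Xtr)
        assert np.nanmean(sc.transform(Xtr)) == pytest.approx(0.0, abs=1e-12)
        assert abs(np.nanmean(sc.transform(Xval))) > 0.5

    def test_constant_variable_centred_not_nan(self):
        X = np.ones((10, 3, 2))
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = preprocess.WindowStandardizer().fit(X)
        out = sc.transform(X)
        assert np.all(out == 0.0)

    def test_nan_passthrough(self):
        X = np.array([[[1.0, np.nan], [3.0, 4.0]]])
        sc = preprocess.WindowStandardizer().fit(X)
        assert np.isnan(sc.transform(X)[0, 0, 1])


class TestWindowSetIO:
    def test_save_load_roundtrip(self, small_windows, tmp_path):
        ws, _ = small_windows
        ws.save(tmp_path)
        back = preprocess.LabeledWindowSet.load(tmp_path)
        np.testing.assert_allclose(back.values, ws.values, equal_nan=True)
        np.testing.assert_array_equal(back.mask, ws.mask)
        assert back.var_names == ws.var_names
        pd.testing.assert_frame_equal(back.labels, ws.labels)
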