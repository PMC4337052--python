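"""Network contracts: feature assembly, analytic gradients against finite
differences, training determinism, and monotone-map recovery."""

import numpy as np
import pytest

from doaindex import ann
from doaindex.io_formats import IndexSeries
from doaindex.sampen import EntropyTrack


def _track(values, spacing=5.0):
    values = np.asarray(values, dtype=float)
    times = spacing * (1 + np.arange(values.size))
    return EntropyTrack(times, values)


def _eacl_from(values, spacing=5.0):
    values = np.asarray(values, dtype=float)
    times = spacing * (1 + np.arange(values.size))
    return IndexSeries(times, np.clip(values, 0, 100))


class TestBuildFeatures:
    def test_row_count(self):
        track = _track(np.linspace(0.5, 2.5, 10))
        eacl = _eacl_from(np.linspace(90, 50, 10))
        fm = ann.build_features(track, eacl, lag=6)
        assert fm.X.shape == (5, 6)

    def test_lag_one_is_identity(self):
        vals = np.linspace(0.5, 2.5, 8)
        fm = ann.build_features(_track(vals), _eacl_from(np.linspace(90, 50, 8)), lag=1)
        np.testing.assert_allclose(fm.X[:, 0], vals)

    def test_all_missing_rejected(self):
        track = _track(np.full(10, np.nan))
        with pytest.raises(ValueError, match="no valid"):
            ann.build_features(track, _eacl_from(np.full(10, 50.0)), lag=2)

    def test_imputation_forward_fills_interior_gaps(self):
        vals = np.array([1.0, np.nan, 1.5, np.nan, np.nan, 2.0])
        fm = ann.build_features(_track(vals), _eacl_from(np.full(6, 50.0)), lag=1)
        np.testing.assert_allclose(fm.X[:, 0], [1.0, 1.0, 1.5, 1.5, 1.5, 2.0])

    def test_leading_missing_rows_dropped(self):
        vals = np.array([np.nan, np.nan, 1.0, 1.2, 1.4, 1.6])
        fm = ann.build_features(_track(vals), _eacl_from(np.full(6, 50.0)), lag=2)
        assert fm.X.shape[0] == 3  # rows whose window touches a leading NaN drop


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        """Backprop gradient vs central finite differences on a toy batch."""
        Xs = rng.standard_normal((5, 3))
        t01 = rng.uniform(0.2, 0.8, size=5)
        params = {
            "W1": rng.uniform(-0.5, 0.5, size=(3, 4)),
            "b1": rng.uniform(-0.5, 0.5, size=4),
            "w2": rng.uniform(-0.5, 0.5, size=4),
            "b2": 0.1,
        }
        _, grads = ann.loss_and_grads(params, Xs, t01)
        eps = 1e-6
        for key in params:
            arr = np.atleast_1d(np.asarray(params[key], dtype=float))
            g_analytic = np.atleast_1d(np.asarray(grads[key], dtype=float))
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                p_hi = {k: (np.array(v, dtype=float) if isinstance(v, np.ndarray) else v)
                        for k, v in params.items()}
                p_lo = {k: (np.array(v, dtype=float) if isinstance(v, np.ndarray) else v)
                        for k, v in params.items()}
                if isinstance(params[key], np.ndarray):
                    p_hi[key][idx] += eps
                    p_lo[key][idx] -= eps
                else:
                    p_hi[key] = params[key] + eps
                    p_lo[key] = params[key] - eps
                l_hi, _ = ann.loss_and_grads(p_hi, Xs, t01)
                l_lo, _ = ann.loss_and_grads(p_lo, Xs, t01)
                g_num = (l_hi - l_lo) / (2 * eps)
                denom = max(abs(g_num), abs(float(g_analytic[idx])), 1e-8)
                assert abs(float(g_analytic[idx]) - g_num) / denom < 1e-6


def _monotone_cohort(n_sessions, seed, n_epochs=80):
    """Sessions where EACL is a fixed monotone function of smoothed SampEn."""
    rng = np.random.default_rng(seed)
    feats = []
    for s in range(n_sessions):
        c = 50 + 45 * np.cos(np.linspace(0, 2 * np.pi, n_epochs))  # down and back up
        se = 0.2 + 2.5 * (c / 100.0) ** 1.5 + rng.normal(0, 0.03, size=n_epochs)
        track = _track(se)
        eacl = _eacl_from(c)
        fm = ann.build_features(track, eacl, lag=6)
        fm.session_id = f"m{s}"
        feats.append(fm)
    return feats


class TestTrain:
    def test_monotone_map_recovery(self):
        feats = _monotone_cohort(10, seed=1)
        model = ann.train(feats[:8], feats[8:], ann.TrainConfig(seed=1))
        held_out = _monotone_cohort(2, seed=99)
        for fm in held_out:
            pred = model.predict_values(fm.X)
            r = np.corrcoef(pred, fm.y)[0, 1]
            assert r >= 0.8

    def test_rank_preservation_on_noise_free_map(self):
        from scipy.stats import spearmanr

        feats = _monotone_cohort(6, seed=2)
        model = ann.train(feats[:5], feats[5:], ann.TrainConfig(seed=0))
        fm = _monotone_cohort(1, seed=77)[0]
        rho = spearmanr(model.predict_values(fm.X), fm.y).statistic
        assert rho >= 0.95

    def test_constant_target_converges_to_constant(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 3))
        fm = ann.FeatureMatrix(X=X, y=np.full(60, 50.0), times=np.arange(60.0))
        model = ann.train([fm], [fm], ann.TrainConfig(seed=3, lr=0.3))
        pred = model.predict_values(X)
        assert np.all(np.abs(pred - 50.0) < 1.0)

    def test_training_determinism(self):
        feats = _monotone_cohort(4, seed=5)
        a = ann.train(feats[:3], feats[3:], ann.TrainConfig(seed=11))
        b = ann.train(feats[:3], feats[3:], ann.TrainConfig(seed=11))
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.w2, b.w2)
        assert a.b2 == b.b2

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="validation"):
            ann.train([], [], ann.TrainConfig())


class TestPredict:
    def test_outputs_bounded(self):
        feats = _monotone_cohort(3, seed=6)
        model = ann.train(feats[:2], feats[2:], ann.TrainConfig(seed=0, max_epochs=50))
        track = _track(np.linspace(-5, 8, 40))  # deliberately extreme inputs
        series = ann.predict(model, track)
        assert np.all((series.values >= 0) & (series.values <= 100))

    def test_constant_input_constant_output(self):
        feats = _monotone_cohort(3, seed=6)
        model = ann.train(feats[:2], feats[2:], ann.TrainConfig(seed=0, max_epochs=50))
        series = ann.predict(model, _track(np.full(20, 1.3)))
        assert np.ptp(series.values) < 1e-9

    def test_times_start_at_lag(self):
        feats = _monotone_cohort(3, seed=6)
        model = ann.train(feats[:2], feats[2:], ann.TrainConfig(seed=0, max_epochs=10))
        track = _track(np.linspace(0.5, 2.0, 12))
        series = ann.predict(model, track)
        assert series.times[0] == track.times[model.lag - 1]
        assert len(series) == 12 - model.lag + 1


class TestSplit:
    def test_proportional_split_twelve_sessions(self):
        ids = [f"s{i}" for i in range(12)]
        split = ann.proportional_split(ids, (30, 10, 24))
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 4)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            ann.SplitSpec(train=["a"], validation=["a"], test=["b"])

    def test_serialization_roundtrip(self):
        feats = _monotone_cohort(3, seed=8)
        model = ann.train(feats[:2], feats[2:], ann.TrainConfig(seed=0, max_epochs=10))
        back = ann.MLPModel.from_json(model.to_json())
        X = feats[0].X
        np.testing.assert_allclose(back.predict_values(X), model.predict_values(X), rtol=1e-12)
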