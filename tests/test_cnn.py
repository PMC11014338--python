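"""1D-CNN localizer: structures, loss, training, prediction, depth sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiovib import cnn


class TestStructures:
    def test_structure7_channel_chain(self):
        spec = cnn.StructureSpec.from_id(7)
        assert spec.channels == (
            (1, 2), (2, 4), (4, 8), (8, 16), (16, 32), (32, 32)
        )

    @pytest.mark.parametrize("sid", range(1, 8))
    def test_all_structures_chain_and_flatten_1024(self, sid):
        spec = cnn.StructureSpec.from_id(sid)
        spec.validate()
        assert spec.n_conv_layers == 6
        assert spec.flatten_dim(2048) == 1024

    def test_flatten_formula(self):
        spec = cnn.StructureSpec.from_id(6)
        assert spec.flatten_dim(2048) == 32 * 2048 // 2**6

    def test_broken_chain_rejected(self):
        spec = cnn.StructureSpec(structure_id=0, channels=((1, 4), (8, 16)))
        with pytest.raises(ValueError, match="chain broken"):
            spec.validate()

    def test_non_divisible_length_rejected(self):
        spec = cnn.StructureSpec.from_id(6)
        with pytest.raises(ValueError, match="not divisible"):
            spec.flatten_dim(2050)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="valid: 1..7"):
            cnn.StructureSpec.from_id(8)

    def test_depth_sweep_flatten_sizes(self):
        expected = {3: 8192, 4: 4096, 5: 2048, 6: 1024, 7: 512, 8: 256,
                    9: 128, 10: 64}
        for depth, flat in expected.items():
            spec = cnn.structure_for_depth(depth)
            assert spec.n_conv_layers == depth
            assert spec.flatten_dim(2048) == flat

    def test_depth6_is_canonical(self):
        assert cnn.structure_for_depth(6).channels == \
            cnn.StructureSpec.from_id(6).channels
        assert cnn.DEFAULT_DEPTH == 6


class TestSmoothL1:
    def test_zero(self):
        assert cnn.smooth_l1(0.0) == 0.0

    def test_knee_continuity(self):
        # both branches give 0.5 at |x| = 1
        assert cnn.smooth_l1(1.0) == pytest.approx(0.5)
        assert cnn.smooth_l1(1.0 - 1e-9) == pytest.approx(0.5, abs=1e-8)

    def test_linear_branch(self):
        assert cnn.smooth_l1(-3.0) == pytest.approx(2.5)

    def test_mean_reduction(self):
        assert cnn.smooth_l1(np.array([0.0, 1.0, -3.0])) == pytest.approx(
            (0.0 + 0.5 + 2.5) / 3
        )

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_nonnegative(self, x):
        assert cnn.smooth_l1(x) >= 0.0

    def test_monotone_in_abs(self):
        grid = np.linspace(0.0, 5.0, 2001)
        vals = np.array([cnn.smooth_l1(g) for g in grid])
        assert np.all(np.diff(vals) >= 0.0)

    def test_continuity_on_grid(self):
        grid = np.linspace(-3.0, 3.0, 6001)
        vals = np.array([cnn.smooth_l1(g) for g in grid])
        assert np.max(np.abs(np.diff(vals))) < 3e-3  # Lipschitz bound * step


def _toy_problem(n=24, L=256, seed=0):
    """Single Gabor atom per segment; label = its center."""
    rng = np.random.default_rng(seed)
    centers = rng.integers(L // 4, 3 * L // 4, size=n)
    t = np.arange(L)
    X = np.stack([
        np.exp(-0.5 * ((t - c) / 10.0) ** 2) * np.cos(0.4 * (t - c))
        for c in centers
    ]).astype(np.float32)
    return X, centers.astype(np.float32)


class TestBuildAndPredict:
    def test_scalar_output_per_segment(self):
        model = cnn.build_localizer(7, input_length=256)
        X, _ = _toy_problem(8)
        out = model.forward(X)
        assert out.shape == (8,)

    def test_predict_deterministic(self):
        model = cnn.build_localizer(6, input_length=256)
        X, _ = _toy_problem(4)
        a = cnn.predict(model, X)
        b = cnn.predict(model, X)
        assert np.array_equal(a["coordinate"], b["coordinate"])

    def test_predict_clipping_and_flag(self):
        model = cnn.build_localizer(6, input_length=256)
        model.params["Wf2"][:] = 0.0
        model.params["bf2"][:] = 100.0  # raw output 100 * label_scale >> L-1
        X, _ = _toy_problem(3)
        res = cnn.predict(model, X)
        assert np.all(res["index"] == 255)
        assert np.all(res["out_of_range"])

    def test_length_mismatch_rejected(self):
        model = cnn.build_localizer(6, input_length=512)
        with pytest.raises(ValueError, match="length"):
            model.forward(np.zeros((2, 256), dtype=np.float32))

    def test_single_segment_accepted(self):
        model = cnn.build_localizer(6, input_length=256)
        res = cnn.predict(model, np.zeros(256, dtype=np.float32))
        assert res["coordinate"].shape == (1,)


class TestTraining:
    def test_no_improvement_early_stop(self):
        # zero learning rate: no improvement is possible after the first epoch
        X, y = _toy_problem(16)
        config = cnn.TrainConfig(learning_rate=0.0, max_epochs=200, patience=30,
                                 seed=0)
        model = cnn.train_localizer(X, y, 6, config)
        assert len(model.history) == 31  # best at epoch 0 + 30 stale epochs
        assert model.best_epoch == 0

    def test_best_so_far_non_increasing(self):
        X, y = _toy_problem(24)
        config = cnn.TrainConfig(learning_rate=1e-3, max_epochs=30, patience=29,
                                 seed=0)
        model = cnn.train_localizer(X, y, 6, config)
        best = np.minimum.accumulate(model.history)
        assert np.all(np.diff(best) <= 0.0)

    def test_determinism(self):
        X, y = _toy_problem(16)
        config = cnn.TrainConfig(learning_rate=1e-3, max_epochs=10, patience=5,
                                 seed=42)
        m1 = cnn.train_localizer(X, y, 6, config)
        m2 = cnn.train_localizer(X, y, 6, config)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k]), k
        assert m1.history == m2.history

    def test_memorization_oracle(self):
        X, y = _toy_problem(10, seed=1)
        config = cnn.TrainConfig(learning_rate=3e-3, max_epochs=500,
                                 patience=100, seed=0)
        model = cnn.train_localizer(X, y, 6, config)
        pred = cnn.predict(model, X)["coordinate"]
        assert np.mean(np.abs(pred - y)) < 2.0

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cnn.train_localizer(
                np.zeros((0, 256), dtype=np.float32), np.zeros(0), 6
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="patience"):
            cnn.TrainConfig(patience=1000, max_epochs=1000).validate()
        with pytest.raises(ValueError, match="batch_size"):
            cnn.TrainConfig(batch_size=0).validate()

    def test_checkpoint_round_trip(self, tmp_path):
        X, y = _toy_problem(8)
        config = cnn.TrainConfig(learning_rate=1e-3, max_epochs=3, patience=2,
                                 seed=0)
        model = cnn.train_localizer(X, y, 3, config, feature="AO")
        path = tmp_path / "ao.npz"
        model.save(path)
        loaded = cnn.LocalizerModel.load(path)
        assert loaded.feature == "AO"
        a = cnn.predict(model, X)["coordinate"]
        b = cnn.predict(loaded, X)["coordinate"]
        assert np.allclose(a, b)


class TestLearnability:
    def test_toy_learnability_oracle(self, corpus_builder):
        """Held-out MAE < 10 samples on noise-free synthetic cycles.

        Threshold fixed after a pilot run (observed ~4 samples at 150
        epochs on this configuration).
        """
        ds = corpus_builder(150, seed=0, noise_sd=0.0)
        X, y = ds.arrays("AO")
        n_train = int(0.7 * len(y))
        config = cnn.TrainConfig(learning_rate=1e-3, max_epochs=150,
                                 patience=30, seed=0)
        model = cnn.train_localizer(X[:n_train], y[:n_train], 6, config,
                                    feature="AO")
        pred = cnn.predict(model, X[n_train:])["coordinate"]
        assert np.mean(np.abs(pred - y[n_train:])) < 10.0


class TestDepthSweep:
    def test_sweep_runs_and_reports(self):
        X, y = _toy_problem(40, L=256, seed=2)
        config = cnn.TrainConfig(learning_rate=3e-3, max_epochs=15,
                                 patience=10, seed=0)
        out = cnn.depth_sweep(X[:30], y[:30], X[30:], y[30:],
                              depths=(3, 6), config=config)
        assert set(out) == {3, 6}
        for depth, res in out.items():
            assert "r2" in res, res
            assert res["flatten_dim"] == 32 * 256 // 2**depth

    def test_per_depth_failure_isolated(self):
        X, y = _toy_problem(10, L=256)
        config = cnn.TrainConfig(learning_rate=1e-3, max_epochs=3, patience=2,
                                 seed=0)
        out = cnn.depth_sweep(X[:8], y[:8], X[8:], y[8:],
                              depths=(6, 9), config=config)
        assert "r2" in out[6]
        assert "error" in out[9]  # 256 not divisible by 2**9
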