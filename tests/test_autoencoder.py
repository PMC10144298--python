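"""Shallow autoencoder: forward maps, loss, gradients, SCG training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from seizae import (AEModel, TrainConfig, decode, encode,
                    fit_feature_extractor, reconstruction_mae, satlin,
                    train_scg)
from seizae.autoencoder import _loss_grad, _pack, init_model, loss


def tiny_model(W_E, b_E, W_D, b_D):
    return AEModel(np.asarray(W_E, float), np.asarray(b_E, float),
                   np.asarray(W_D, float), np.asarray(b_D, float))


class TestSatlin:
    @pytest.mark.parametrize("x,expected", [
        (1.7, 1.0), (-5.0, -1.0), (0.0, 0.0), (0.25, 0.25), (-1.0, -1.0),
    ])
    def test_pointwise(self, x, expected):
        assert satlin(x) == expected

    @given(arrays(float, st.integers(1, 30),
                  elements=st.floats(-50, 50)))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_range_and_identity_segment(self, v):
        out = satlin(v)
        assert np.all(out >= -1) and np.all(out <= 1)
        inside = np.abs(v) <= 1
        np.testing.assert_array_equal(out[inside], v[inside])


class TestEncodeDecode:
    def test_encode_hand_example(self):
        model = tiny_model([[1.0], [-1.0], [0.5]], [0.2],
                           [[0.0, 0.0, 0.0]], [0.0, 0.0, 0.0])
        y = encode(model, [2.0, 1.0, -2.0])
        np.testing.assert_allclose(y, [0.2])

    def test_encode_zero_model(self):
        model = tiny_model(np.zeros((3, 1)), [0.0], np.zeros((1, 3)), np.zeros(3))
        np.testing.assert_array_equal(encode(model, [5.0, -2.0, 7.0]), [0.0])

    def test_encode_saturates(self):
        model = tiny_model([[10.0], [0.0], [0.0]], [0.0],
                           np.zeros((1, 3)), np.zeros(3))
        assert encode(model, [1.0, 3.0, -4.0])[0] == 1.0

    def test_encode_range_invariant(self):
        rng = np.random.default_rng(0)
        model = init_model(16, 4, seed=1)
        Y = encode(model, rng.uniform(-100, 100, (30, 16)))
        assert np.all(Y >= -1) and np.all(Y <= 1)

    def test_decode_hand_example(self):
        model = tiny_model(np.zeros((2, 1)), [0.0],
                           [[0.5, -1.0]], [0.1, 0.1])
        np.testing.assert_allclose(decode(model, [2.0]), [1.1, -1.9])

    def test_decode_zero_code_gives_bias(self):
        model = tiny_model(np.zeros((2, 1)), [0.0],
                           [[0.5, -1.0]], [0.3, -0.4])
        np.testing.assert_allclose(decode(model, [0.0]), [0.3, -0.4])

    def test_decoder_bias_flag(self):
        model = tiny_model(np.zeros((2, 1)), [0.0], [[0.5, -1.0]], [0.3, -0.4])
        model.use_decoder_bias = False
        np.testing.assert_allclose(decode(model, [1.0]), [0.5, -1.0])

    def test_dimension_errors(self):
        model = init_model(8, 2, seed=0)
        with pytest.raises(ValueError, match="length"):
            encode(model, np.zeros(5))
        with pytest.raises(ValueError, match="code"):
            decode(model, np.zeros(3))

    def test_shape_invariants_enforced(self):
        with pytest.raises(ValueError, match="hidden size"):
            AEModel(np.zeros((4, 4)), np.zeros(4), np.zeros((4, 4)), np.zeros(4))
        with pytest.raises(ValueError, match="shapes"):
            AEModel(np.zeros((4, 2)), np.zeros(3), np.zeros((2, 4)), np.zeros(4))


class TestLoss:
    def test_perfect_reconstruction_zero_loss(self):
        # identity-like model on codes within the linear segment
        model = tiny_model([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]], [0.0, 0.0],
                           [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], [0.0, 0.0, 0.0])
        X = np.array([[0.3, -0.2, 0.0], [0.5, 0.5, 0.0]])
        assert loss(model, X, l2_coeff=0.0) == pytest.approx(0.0)

    def test_mean_of_squares(self):
        model = tiny_model(np.zeros((2, 1)), [0.0], np.zeros((1, 2)), np.zeros(2))
        assert loss(model, np.array([[1.0, 1.0]]), 0.0) == pytest.approx(1.0)

    def test_l2_penalty_arithmetic(self):
        model = tiny_model([[1.0], [-1.0]], [0.0], [[1.0, -1.0]], [0.0, 0.0])
        X = np.zeros((1, 2))  # zero input, zero code -> zero reconstruction error
        assert loss(model, X, l2_coeff=0.5) == pytest.approx(2.0)

    def test_empty_batch_rejected(self):
        model = init_model(4, 2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            loss(model, np.zeros((0, 4)), 0.0)


class TestGradient:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        n, m, N = rng.integers(4, 9), rng.integers(1, 4), 5
        X = rng.uniform(-2, 2, (N, n))
        mod = init_model(n, m, seed=seed + 10)
        w = (_pack(mod.W_E, mod.b_E, mod.W_D, mod.b_D)
             + rng.normal(0, 0.1, n * m + m + m * n + n))
        _, g = _loss_grad(w, X, n, m, 1e-4, True)
        eps = 1e-6
        g_fd = np.empty_like(w)
        for i in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            g_fd[i] = (_loss_grad(wp, X, n, m, 1e-4, True)[0]
                       - _loss_grad(wm, X, n, m, 1e-4, True)[0]) / (2 * eps)
        rel = np.max(np.abs(g - g_fd)) / max(np.max(np.abs(g_fd)), 1e-12)
        assert rel < 1e-5


class TestTrainSCG:
    def test_identical_epochs_memorized(self):
        rng = np.random.default_rng(0)
        x0 = rng.uniform(-1, 1, 16)
        X = np.tile(x0, (20, 1))
        model, trace = train_scg(X, 4, TrainConfig(l2_coeff=0.0, max_iter=500, seed=1))
        mse = np.mean((x0 - decode(model, encode(model, x0))) ** 2)
        assert mse < 1e-6 * np.var(x0)
        assert trace.n_iter <= 500

    def test_trace_monotone_on_accepted_steps(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, (40, 16))
        _, trace = train_scg(X, 4, TrainConfig(max_iter=100, seed=2))
        diffs = np.diff(trace.losses)
        assert np.all(diffs <= 1e-15)
        assert trace.losses[-1] <= trace.losses[0]

    def test_linear_subspace_recovered(self):
        rng = np.random.default_rng(11)
        B = rng.normal(size=(4, 32))
        X = rng.normal(size=(200, 4)) @ B
        X = 0.9 * X / np.max(np.abs(X))
        model, _ = train_scg(X, 8, TrainConfig(l2_coeff=0.0, max_iter=1000, seed=2))
        Xhat = decode(model, encode(model, X))
        assert np.mean((X - Xhat) ** 2) < 0.01 * np.var(X)
        # sanity bound: cannot beat the best rank-8 linear reconstruction
        s = np.linalg.svd(X - X.mean(0), compute_uv=False)
        svd_floor = np.sum(s[8:] ** 2) / X.size
        assert np.mean((X - Xhat) ** 2) >= svd_floor - 1e-12

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (30, 16))
        cfg = TrainConfig(max_iter=60, seed=9)
        m1, _ = train_scg(X, 4, cfg)
        m2, _ = train_scg(X, 4, cfg)
        np.testing.assert_array_equal(m1.W_E, m2.W_E)
        np.testing.assert_array_equal(m1.W_D, m2.W_D)

    def test_hidden_size_bounds(self):
        X = np.zeros((5, 8))
        with pytest.raises(ValueError, match="hidden"):
            train_scg(X, 8, TrainConfig())
        with pytest.raises(ValueError, match="hidden"):
            train_scg(X, 0, TrainConfig())


class TestFitFeatureExtractor:
    def test_fold_arithmetic(self, fast_ae_cfg):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (100, 16))
        model, fold_mse = fit_feature_extractor(X, 4, fast_ae_cfg, folds=5)
        assert fold_mse.shape == (5,)
        assert model.m == 4
        assert np.all(fold_mse >= 0)

    def test_identical_epochs_near_zero_cv_error(self):
        X = np.tile(np.linspace(-0.8, 0.8, 16), (12, 1))
        _, fold_mse = fit_feature_extractor(
            X, 4, TrainConfig(l2_coeff=0.0, max_iter=500, seed=0), folds=2)
        assert np.all(fold_mse < 1e-8)

    def test_refit_determinism(self, fast_ae_cfg):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (40, 16))
        m1, e1 = fit_feature_extractor(X, 4, fast_ae_cfg, folds=4)
        m2, e2 = fit_feature_extractor(X, 4, fast_ae_cfg, folds=4)
        np.testing.assert_array_equal(m1.W_E, m2.W_E)
        np.testing.assert_array_equal(e1, e2)

    def test_fold_bounds(self, fast_ae_cfg):
        X = np.zeros((3, 8))
        with pytest.raises(ValueError, match="folds"):
            fit_feature_extractor(X, 2, fast_ae_cfg, folds=1)
        with pytest.raises(ValueError, match="at least"):
            fit_feature_extractor(X, 2, fast_ae_cfg, folds=5)


class TestReconstructionMAE:
    def test_perfect_and_hand_values(self):
        model = tiny_model(np.zeros((2, 1)), [0.0], np.zeros((1, 2)), np.zeros(2))
        per, mean = reconstruction_mae(model, np.array([[1.0, -1.0]]))
        np.testing.assert_allclose(per, [1.0])
        assert mean == pytest.approx(1.0)

    def test_batch_mean_is_mean_of_per_epoch(self):
        rng = np.random.default_rng(6)
        model = init_model(8, 2, seed=0)
        X = rng.uniform(-1, 1, (7, 8))
        per, mean = reconstruction_mae(model, X)
        assert mean == pytest.approx(per.mean())


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        model = init_model(12, 3, seed=8)
        model.save(tmp_path / "m.json")
        back = AEModel.load(tmp_path / "m.json")
        np.testing.assert_array_equal(back.W_E, model.W_E)
        np.testing.assert_array_equal(back.b_D, model.b_D)
        assert back.m == 3 and back.n == 12

    def test_wrong_format_rejected(self, tmp_path):
        (tmp_path / "x.json").write_text('{"format": "other"}')
        with pytest.raises(ValueError, match="model file"):
            AEModel.load(tmp_path / "x.json")
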