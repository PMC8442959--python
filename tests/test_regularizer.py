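"""Losses, MLP mechanics, and the regularizer Model/Results objects."""

import numpy as np
import pytest

from cardioreg.patches import extract_patches
from cardioreg.regularizer import (MLP, DisplacementRegularizer,
                                   RegularizerResults, TrainConfig,
                                   LAMBDA_PRESETS, biomech_loss, logcosh_loss,
                                   train_semisupervised, train_supervised)
from cardioreg.regularizer.losses import (biomech_grad, logcosh_grad,
                                          patch_divergence)

PATCH_SHAPE = (3, 3, 3, 4, 3)
D = int(np.prod(PATCH_SHAPE))
SPACING = (1.0, 1.0, 1.0)


class TestLogCosh:
    def test_zero_residual(self, rng):
        x = rng.normal(size=(4, 10))
        assert logcosh_loss(x, x) == 0.0

    def test_unit_residual_value(self):
        # log cosh(1) evaluated directly
        expected = float(np.log(np.cosh(1.0)))
        assert logcosh_loss(np.zeros((1, 1)), np.ones((1, 1))) == \
            pytest.approx(expected, abs=1e-12)

    def test_large_residual_l1_asymptote(self):
        r = 100.0
        val = logcosh_loss(np.zeros((1, 1)), np.full((1, 1), r))
        assert abs(val - (r - np.log(2.0))) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            logcosh_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.normal(size=(2, 6))
        true = rng.normal(size=(2, 6))
        g = logcosh_grad(pred, true)
        eps = 1e-6
        for i in range(2):
            for j in range(6):
                p = pred.copy()
                p[i, j] += eps
                m = pred.copy()
                m[i, j] -= eps
                fd = (logcosh_loss(p, true) - logcosh_loss(m, true)) / (2 * eps)
                assert abs(g[i, j] - fd) < 1e-6


class TestBiomechLoss:
    def test_perfect_adherence_static_divfree_is_zero(self):
        # constant-in-time, spatially constant patches: div = 0, dt = 0
        patch = np.ones((2, D))
        total, terms = biomech_loss(patch, patch, 1.0, 1.0, PATCH_SHAPE, SPACING)
        assert total == 0.0 and terms["div"] == 0.0 and terms["loop"] == 0.0

    def test_zero_lambdas_reduce_to_data_term(self, rng):
        pred = rng.normal(size=(3, D))
        noise = rng.normal(size=(3, D))
        total, _ = biomech_loss(pred, noise, 0.0, 0.0, PATCH_SHAPE, SPACING)
        assert total == pytest.approx(((noise - pred) ** 2).sum(), rel=1e-12)

    def test_matches_explicit_loop_oracle(self, rng):
        pred = rng.normal(size=(2, D))
        noise = rng.normal(size=(2, D))
        ld, ll = 0.7, 0.3
        total, terms = biomech_loss(pred, noise, ld, ll, PATCH_SHAPE, SPACING)
        data_o, div_o, loop_o = _biomech_oracle(pred, noise, PATCH_SHAPE, SPACING)
        assert abs(terms["data"] - data_o) < 1e-8
        assert abs(terms["div"] - div_o) < 1e-8
        assert abs(terms["loop"] - loop_o) < 1e-8
        assert abs(total - (data_o + ld * div_o + ll * loop_o)) < 1e-8

    def test_decomposition_exact_for_any_lambdas(self, rng):
        pred = rng.normal(size=(2, D))
        noise = rng.normal(size=(2, D))
        _, terms = biomech_loss(pred, noise, 1.0, 1.0, PATCH_SHAPE, SPACING)
        for ld, ll in [(0.0, 0.0), (0.5, 0.5), (2.0, 0.1), (3.7, 9.9)]:
            total, _ = biomech_loss(pred, noise, ld, ll, PATCH_SHAPE, SPACING)
            assert total == pytest.approx(
                terms["data"] + ld * terms["div"] + ll * terms["loop"], rel=1e-12)

    def test_small_patch_rejected(self):
        shape = (2, 2, 2, 3, 3)
        d = int(np.prod(shape))
        with pytest.raises(ValueError, match="spatial extent"):
            biomech_loss(np.zeros((1, d)), np.zeros((1, d)), 1.0, 1.0, shape,
                         SPACING)

    def test_gradient_matches_finite_differences(self, rng):
        shape = (3, 3, 3, 3, 3)
        d = int(np.prod(shape))
        pred = rng.normal(size=(1, d))
        noise = rng.normal(size=(1, d))
        g = biomech_grad(pred, noise, 0.4, 0.6, shape, SPACING)
        eps = 1e-6
        idx = rng.choice(d, size=30, replace=False)
        for j in idx:
            p = pred.copy()
            p[0, j] += eps
            m = pred.copy()
            m[0, j] -= eps
            fd = (biomech_loss(p, noise, 0.4, 0.6, shape, SPACING)[0]
                  - biomech_loss(m, noise, 0.4, 0.6, shape, SPACING)[0]) / (2 * eps)
            assert abs(g[0, j] - fd) < 1e-5


def _biomech_oracle(pred, noise, patch_shape, spacing):
    """Explicit loops over patches / voxels / frames."""
    px, py, pz, T, _ = patch_shape
    yp = pred.reshape((-1,) + tuple(patch_shape))
    yn = noise.reshape((-1,) + tuple(patch_shape))
    data = div = loop = 0.0
    for n in range(len(yp)):
        data += ((yn[n] - yp[n]) ** 2).sum()
        for t in range(T):
            for i in range(1, px - 1):
                for j in range(1, py - 1):
                    for k in range(1, pz - 1):
                        d = ((yp[n, i + 1, j, k, t, 0] - yp[n, i - 1, j, k, t, 0])
                             / (2 * spacing[0])
                             + (yp[n, i, j + 1, k, t, 1] - yp[n, i, j - 1, k, t, 1])
                             / (2 * spacing[1])
                             + (yp[n, i, j, k + 1, t, 2] - yp[n, i, j, k - 1, t, 2])
                             / (2 * spacing[2]))
                        div += d ** 2
            loop += ((yp[n, ..., (t + 1) % T, :] - yp[n, ..., t, :]) ** 2).sum()
    return data, div, loop


class TestMLPMechanics:
    def test_manual_forward_oracle(self, rng):
        net = MLP([4, 5, 3], dropout_p=0.0, seed=0)
        X = rng.normal(size=(2, 4)).astype(np.float32)
        out = net.predict(X)
        h = np.maximum(X @ net.W[0] + net.b[0], 0.0)
        manual = h @ net.W[1] + net.b[1]
        assert np.allclose(out, manual, atol=1e-6)
        assert np.allclose(net.hidden_activations(X), h, atol=1e-6)

    def test_prediction_bitwise_deterministic(self, rng):
        net = MLP([6, 8, 8, 6], dropout_p=0.5, seed=1)
        X = rng.normal(size=(3, 6)).astype(np.float32)
        assert np.array_equal(net.predict(X), net.predict(X))

    def test_zero_weight_model_gives_zero_embedding(self, rng):
        net = MLP([4, 7, 4], dropout_p=0.0, seed=0)
        net.W = [np.zeros_like(w) for w in net.W]
        X = rng.normal(size=(2, 4)).astype(np.float32)
        assert np.all(net.hidden_activations(X) == 0.0)

    def test_backward_matches_finite_differences(self, rng):
        net = MLP([3, 4, 2], dropout_p=0.0, seed=2, dtype=np.float64)
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 2))

        def loss():
            return 0.5 * ((net.predict(X) - Y) ** 2).sum()

        out, cache = net.forward(X)
        dW, db = net.backward(cache, out - Y)
        eps = 1e-7
        for pi, (p, gp) in enumerate(zip(net.W + net.b, dW + db)):
            flat = p.ravel()
            for j in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss()
                flat[j] = orig - eps
                lm = loss()
                flat[j] = orig
                assert abs(gp.ravel()[j] - (lp - lm) / (2 * eps)) < 1e-5


class TestConfig:
    def test_reference_training_defaults(self):
        cfg = TrainConfig()
        assert cfg.epochs == 100
        assert cfg.learning_rate == 1e-5
        assert cfg.hidden_width == 1000
        assert cfg.hidden_layers == 3 and cfg.dropout == 0.2

    def test_semisupervised_defaults(self):
        cfg = TrainConfig.semisupervised_default("fnt_like")
        assert cfg.hidden_layers == 7 and cfg.dropout == 0.5
        assert cfg.lambda_super == 1.0
        assert (cfg.lambda_div, cfg.lambda_loop) == (0.0, 1.0)

    def test_lambda_presets_per_tracking_method(self):
        assert LAMBDA_PRESETS["rfbm_like"] == (0.5, 0.5)
        assert LAMBDA_PRESETS["fnt_like"] == (0.0, 1.0)
        assert LAMBDA_PRESETS["ffd_like"] == (0.5, 0.5)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lambda_div=-1.0)


def _toy_patch_problem(rng, n=300, bias=0.8):
    """Tiny supervised problem: noise = truth + constant bias."""
    true = rng.normal(0.0, 0.5, size=(n, D))
    noise = true + bias
    return noise, true


class TestTraining:
    CFG = dict(hidden_layers=2, hidden_width=32, dropout=0.0,
               learning_rate=1e-3, epochs=30, batch_size=64, seed=7)

    def test_supervised_training_removes_constant_bias(self, rng):
        noise, true = _toy_patch_problem(rng)
        res = train_supervised(noise[:240], true[:240],
                               TrainConfig(**self.CFG),
                               patch_shape=PATCH_SHAPE, spacing_mm=SPACING)
        pred = res.predict(noise[240:])
        err_in = np.abs(noise[240:] - true[240:]).mean()
        err_out = np.abs(pred - true[240:]).mean()
        assert err_out < err_in

    def test_identity_augmentation_protects_clean_patches(self, rng):
        noise, true = _toy_patch_problem(rng)
        res = train_supervised(noise, true, TrainConfig(**self.CFG),
                               patch_shape=PATCH_SHAPE, spacing_mm=SPACING)
        clean_dev = np.abs(res.predict(true) - true).mean()
        noisy_dev = np.abs(res.predict(noise) - noise).mean()
        assert clean_dev < noisy_dev

    def test_semisupervised_without_target_equals_supervised(self, rng):
        noise, true = _toy_patch_problem(rng, n=150)
        cfg = TrainConfig(**{**self.CFG, "epochs": 5})
        r1 = train_supervised(noise, true, cfg, patch_shape=PATCH_SHAPE,
                              spacing_mm=SPACING)
        r2 = train_semisupervised(noise, true, None, cfg,
                                  patch_shape=PATCH_SHAPE, spacing_mm=SPACING)
        assert np.allclose(r1.history["train_loss"], r2.history["train_loss"])

    def test_divergence_weight_weakly_reduces_predicted_divergence(self, rng):
        """Mean |div| of target-domain predictions is weakly decreasing in
        lambda_div across a 3-point grid."""
        noise, true = _toy_patch_problem(rng, n=150)
        tgt = rng.normal(0.0, 0.7, size=(120, D))
        means = []
        for ld in (0.0, 1.0, 5.0):
            cfg = TrainConfig(**{**self.CFG, "epochs": 15},
                              lambda_div=ld, lambda_loop=0.0,
                              identity_augmentation=False)
            res = train_semisupervised(noise, true, tgt, cfg,
                                       patch_shape=PATCH_SHAPE,
                                       spacing_mm=SPACING)
            pred = res.predict(tgt).reshape((-1,) + PATCH_SHAPE)
            means.append(np.abs(patch_divergence(pred, SPACING)).mean())
        assert means[1] <= means[0] * 1.02 and means[2] <= means[1] * 1.02

    def test_divergent_training_aborts_with_diagnostic(self, rng):
        noise, true = _toy_patch_problem(rng, n=80)
        cfg = TrainConfig(**{**self.CFG, "epochs": 3, "learning_rate": 1e12})
        with pytest.raises(RuntimeError, match="diverged"):
            train_supervised(noise * 1e6, true * 1e6, cfg,
                             patch_shape=PATCH_SHAPE, spacing_mm=SPACING)

    def test_results_summary_and_persistence(self, rng, tmp_path):
        noise, true = _toy_patch_problem(rng, n=100)
        cfg = TrainConfig(**{**self.CFG, "epochs": 3})
        res = train_supervised(noise, true, cfg, patch_shape=PATCH_SHAPE,
                               spacing_mm=SPACING)
        text = res.summary()
        assert "best epoch" in text and "supervised" in text
        path = str(tmp_path / "model.npz")
        res.save(path)
        back = RegularizerResults.load(path)
        assert np.allclose(back.predict(noise[:5]), res.predict(noise[:5]))


class TestMultiView:
    def test_two_identical_views_equal_weight_surgery_single_view(self, rng):
        """f_multi([x; x]) must equal a single-view network whose first-layer
        weights are the sum of the two view blocks."""
        noise, true = _toy_patch_problem(rng, n=120)
        cfg = TrainConfig(hidden_layers=2, hidden_width=16, dropout=0.0,
                          learning_rate=1e-3, epochs=3, batch_size=64, seed=3)
        res = train_supervised(noise, true, cfg, patch_shape=PATCH_SHAPE,
                               spacing_mm=SPACING, second_view=noise.copy())
        X = rng.normal(size=(4, D))
        out_multi = res.predict(X, second=X)

        surgery = res.net.clone()
        W0 = res.net.W[0]
        surgery.W = [W0[:D] + W0[D:]] + [w.copy() for w in res.net.W[1:]]
        surgery.layer_sizes = [D] + res.net.layer_sizes[1:]
        mean, std = res.standardization
        Xs = DisplacementRegularizer._standardize(X, mean, std).astype(np.float32)
        out_single = DisplacementRegularizer._destandardize(
            surgery.predict(Xs), mean, std)
        assert np.allclose(out_multi, out_single, atol=1e-4)

    def test_multi_view_model_demands_second_input(self, rng):
        noise, true = _toy_patch_problem(rng, n=60)
        cfg = TrainConfig(hidden_layers=2, hidden_width=8, dropout=0.0,
                          epochs=2, batch_size=32, learning_rate=1e-3, seed=0)
        res = train_supervised(noise, true, cfg, patch_shape=PATCH_SHAPE,
                               spacing_mm=SPACING, second_view=noise.copy())
        with pytest.raises(ValueError, match="second"):
            res.predict(noise)


class TestEmbedding:
    def test_embedding_width_and_manual_forward(self, rng):
        noise, true = _toy_patch_problem(rng, n=80)
        cfg = TrainConfig(hidden_layers=2, hidden_width=24, dropout=0.0,
                          epochs=2, batch_size=32, learning_rate=1e-3, seed=0)
        res = train_supervised(noise, true, cfg, patch_shape=PATCH_SHAPE,
                               spacing_mm=SPACING)
        emb, _ = res.hidden_embedding(noise[:6])
        assert emb.shape == (6, 24)
        # manual layer-by-layer forward of the first patch
        mean, std = res.standardization
        x = DisplacementRegularizer._standardize(noise[:1], mean, std
                                                 ).astype(np.float32)
        h = x
        for W, b in zip(res.net.W[:-1], res.net.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        assert np.allclose(emb[0], h[0], atol=1e-5)

    def test_domain_labelled_embedding(self, rng):
        noise, true = _toy_patch_problem(rng, n=60)
        cfg = TrainConfig(hidden_layers=2, hidden_width=8, dropout=0.0,
                          epochs=2, batch_size=32, learning_rate=1e-3, seed=0)
        res = train_supervised(noise, true, cfg, patch_shape=PATCH_SHAPE,
                               spacing_mm=SPACING)
        emb, labels = res.hidden_embedding({"synthetic": noise[:10],
                                            "in_vivo": noise[10:25]})
        assert emb.shape[0] == 25
        assert list(labels[:10]) == ["synthetic"] * 10
        assert list(labels[10:]) == ["in_vivo"] * 15


class TestFieldLevel:
    def test_regularize_field_fingerprint_mismatch(self, small_truth, rng):
        ps = extract_patches(small_truth, stride=(2, 2, 2))
        cfg = TrainConfig(hidden_layers=2, hidden_width=8, dropout=0.0,
                          epochs=2, batch_size=64, learning_rate=1e-3, seed=0)
        res = train_supervised(ps, ps, cfg)
        from cardioreg.fields import DisplacementField4D
        wrong = DisplacementField4D(
            np.zeros(small_truth.grid_shape + (small_truth.n_frames + 2, 3)),
            small_truth.spacing_mm, small_truth.mask)
        with pytest.raises(ValueError, match="frames"):
            res.regularize_field(wrong)

    def test_regularize_field_round_trip_shape(self, small_truth):
        ps = extract_patches(small_truth, stride=(2, 2, 2))
        cfg = TrainConfig(hidden_layers=2, hidden_width=8, dropout=0.0,
                          epochs=2, batch_size=64, learning_rate=1e-3, seed=0)
        res = train_supervised(ps, ps, cfg)
        out = res.regularize_field(small_truth)
        assert out.values.shape == small_truth.values.shape
        assert out.reference == "lagrangian"
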