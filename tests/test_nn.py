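"""U-Net construction, autodiff gradients, Wasserstein Dice loss, training
mechanics on tiny problems."""

import numpy as np
import pytest

from dixonfat.nn import (
    TrainConfig,
    UNetConfig,
    WassersteinLossConfig,
    build_unet,
    gwd_loss,
    gwd_pixel_errors,
    load_checkpoint,
    predict,
    save_checkpoint,
    train_model,
)
from dixonfat.nn.loss import gwd_loss_and_grad, uniform_distance_matrix
from dixonfat.nn.unet import softmax


def brute_force_gwd(probs, target, m, eps, bg=0):
    """Independent per-pixel double-loop evaluation of the loss."""
    c, h, w = probs.shape
    total_w = 0.0
    tp = 0.0
    for i in range(h):
        for j in range(w):
            t = int(target[i, j])
            wij = sum(m[t, l] * probs[l, i, j] for l in range(c))
            total_w += wij
            if t != bg:
                tp += m[t, bg] - wij
    return 1.0 - (2 * tp + eps) / (2 * tp + total_w + eps)


class TestUNetConstruction:
    def test_probabilities_sum_to_one(self, rng):
        model = build_unet(UNetConfig(depth=2, base_channels=4, input_size=32), seed=0)
        p = model.predict_proba(rng.random((2, 1, 32, 32)).astype(np.float32))
        assert p.shape == (2, 3, 32, 32)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_init_identical(self):
        cfg = UNetConfig(depth=3, base_channels=4, input_size=64)
        a = build_unet(cfg, seed=5)
        b = build_unet(UNetConfig(depth=3, base_channels=4, input_size=64), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_bottleneck_size_depth4(self):
        cfg = UNetConfig(depth=4, input_size=384)
        assert cfg.bottleneck_size == 24

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(depth=4, input_size=100).validate()

    def test_parameter_count_deterministic(self):
        cfg = UNetConfig(depth=2, base_channels=4, input_size=16)
        assert build_unet(cfg, seed=0).n_parameters() == build_unet(cfg, seed=9).n_parameters()


class TestGwdLoss:
    def test_perfect_onehot_is_zero(self):
        target = np.array([[0, 1], [2, 1]])
        probs = np.zeros((3, 2, 2))
        for i in range(2):
            for j in range(2):
                probs[target[i, j], i, j] = 1.0
        assert gwd_loss(probs, target) == 0.0

    def test_two_class_error_is_wrong_mass(self, rng):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        cfg = WassersteinLossConfig(distance_matrix=m)
        probs = rng.random((2, 4, 4))
        probs /= probs.sum(axis=0)
        target = rng.integers(0, 2, (4, 4))
        errs = gwd_pixel_errors(probs, target, cfg)
        for i in range(4):
            for j in range(4):
                wrong = 1 - target[i, j]
                assert errs[i, j] == pytest.approx(probs[wrong, i, j], abs=1e-12)

    def test_matches_brute_force_random(self, rng):
        for _ in range(50):
            c = int(rng.integers(2, 5))
            m = rng.random((c, c))
            m = (m + m.T) / 2 + 0.1
            np.fill_diagonal(m, 0.0)
            cfg = WassersteinLossConfig(distance_matrix=m, eps=1e-5)
            probs = rng.random((c, 4, 4))
            probs /= probs.sum(axis=0)
            target = rng.integers(0, c, (4, 4))
            expect = brute_force_gwd(probs, target, m, cfg.eps)
            assert gwd_loss(probs, target, cfg) == pytest.approx(expect, abs=1e-10)

    def test_pixel_errors_scale_linearly_with_matrix(self, rng):
        m = uniform_distance_matrix(3)
        probs = rng.random((3, 4, 4))
        probs /= probs.sum(axis=0)
        target = rng.integers(0, 3, (4, 4))
        e1 = gwd_pixel_errors(probs, target, WassersteinLossConfig(distance_matrix=m))
        e3 = gwd_pixel_errors(probs, target,
                              WassersteinLossConfig(distance_matrix=3.0 * m))
        assert np.allclose(e3, 3.0 * e1, atol=1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            WassersteinLossConfig(distance_matrix=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            WassersteinLossConfig(distance_matrix=np.array([[1, 1], [1, 1]]))

    def test_gradient_matches_finite_differences(self, rng):
        cfg = WassersteinLossConfig(eps=1e-5)
        probs = rng.random((3, 3, 3))
        probs /= probs.sum(axis=0)
        target = rng.integers(0, 3, (3, 3))
        _, grad = gwd_loss_and_grad(probs, target, cfg)
        eps = 1e-7
        for _ in range(10):
            l_ = rng.integers(0, 3)
            i, j = rng.integers(0, 3, 2)
            pp = probs.copy()
            pp[l_, i, j] += eps
            pm = probs.copy()
            pm[l_, i, j] -= eps
            num = (gwd_loss(pp, target, cfg) - gwd_loss(pm, target, cfg)) / (2 * eps)
            assert grad[l_, i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestAutodiffGradients:
    def test_model_directional_derivative(self, rng):
        # one directional finite-difference through the whole net + loss
        model = build_unet(UNetConfig(depth=2, base_channels=4, input_size=16), seed=0)
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        y = rng.integers(0, 3, (2, 16, 16))
        cfg = WassersteinLossConfig()

        logits = model.forward(x)
        probs = softmax(logits.data, axis=-1)
        _, dprob = gwd_loss_and_grad(probs.transpose(0, 3, 1, 2), y, cfg)
        dprob = dprob.transpose(0, 2, 3, 1)
        inner = np.sum(dprob * probs, axis=-1, keepdims=True)
        logits.backward((probs * (dprob - inner)).astype(np.float32))

        params = model.parameters()
        d = [rng.normal(size=p.data.shape).astype(np.float32) for p in params]
        eps = 1e-2
        for p, dd in zip(params, d):
            p.data += eps * dd
        lp = gwd_loss(model.predict_proba(x), y, cfg)
        for p, dd in zip(params, d):
            p.data -= 2 * eps * dd
        lm = gwd_loss(model.predict_proba(x), y, cfg)
        num = (lp - lm) / (2 * eps)
        ana = sum(float(np.sum(p.grad * dd)) for p, dd in zip(params, d))
        assert ana == pytest.approx(num, rel=0.15, abs=1e-4)


@pytest.fixture(scope="module")
def tiny_cohort():
    from dixonfat import phantom

    return phantom.generate_cohort(
        n_subjects=5, visit_count_rule=1, seed=21, image_size=32,
        noise_sd=0.0, bias_amplitude=0.0, levels=("L23",))


class TestTraining:
    def test_loss_descends_on_easy_phantoms(self, tiny_cohort):
        manifest, data = tiny_cohort
        ucfg = UNetConfig(depth=2, base_channels=4, input_size=32)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=5, batch_size=4,
                           val_fraction=0.0, seed=0)
        _, hist = train_model(manifest, "region", ucfg, tcfg, data=data)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_deterministic_histories(self, tiny_cohort):
        manifest, data = tiny_cohort
        ucfg = UNetConfig(depth=2, base_channels=4, input_size=32)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=4,
                           val_fraction=0.0, seed=3)
        _, h1 = train_model(manifest, "fat", ucfg, tcfg, data=data)
        _, h2 = train_model(manifest, "fat", ucfg, tcfg, data=data)
        assert h1 == h2

    def test_empty_manifest_rejected(self, tiny_cohort):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            train_model(pd.DataFrame(columns=["subject_id", "visit", "level"]),
                        "region")

    def test_predict_maps_back_to_original_frame(self, tiny_cohort, rng):
        from dixonfat.core import DixonSlice

        model = build_unet(UNetConfig(depth=2, base_channels=4, input_size=32), seed=1)
        slc = DixonSlice(rng.random((24, 24)) * 100)  # smaller than input_size
        probs, labels = predict(model, slc)
        assert probs.shape == (3, 24, 24)
        assert labels.shape == (24, 24)
        assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_uniform_probabilities_argmax_background(self):
        flat = np.full((3, 5, 5), 1 / 3)
        assert np.all(np.argmax(flat, axis=0) == 0)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_unet(UNetConfig(depth=2, base_channels=4, input_size=32), seed=4)
        p = tmp_path / "m.npz"
        save_checkpoint(p, model, history=[{"epoch": 0}], task="region")
        back, meta = load_checkpoint(p)
        assert meta["task"] == "region"
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        assert np.allclose(back.predict_proba(x), model.predict_proba(x), atol=1e-7)
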