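"""Capsule network tests: closed forms, shape arithmetic, routing against a
loop-literal oracle, losses, gradients and the trained-model behaviour."""

import numpy as np
import pytest

from capsdecode.autodiff import Tensor, squash
from capsdecode.capsnet import (
    CapsNetConfig,
    CapsNetModel,
    MarginLossConfig,
    dynamic_routing,
    margin_loss,
    overall_loss,
    scaled_config,
    train_capsnet,
)
from capsdecode.encoding import longer_capsule_features
from capsdecode.pipeline import ssim_metric
from capsdecode.synthetic import generate_digits, images_to_array
from conftest import finite_difference


# ---------------------------------------------------------------------------
# Squash
# ---------------------------------------------------------------------------

class TestSquash:
    @pytest.mark.parametrize("norm,expected", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.9)])
    def test_closed_form_norms(self, norm, expected):
        s = np.zeros(8)
        s[2] = norm
        out = squash(Tensor(s)).data
        assert np.linalg.norm(out) == pytest.approx(expected, abs=1e-8)

    def test_direction_preserved(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=16)
        out = squash(Tensor(s)).data
        cos = s @ out / (np.linalg.norm(s) * np.linalg.norm(out))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_norm_bound_and_monotonicity(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=8)
        direction /= np.linalg.norm(direction)
        norms = np.logspace(-6, 3, 200)
        out_norms = [
            np.linalg.norm(squash(Tensor(direction * n)).data) for n in norms
        ]
        out_norms = np.array(out_norms)
        assert np.all(out_norms < 1.0)
        assert np.all(np.diff(out_norms) > 0)
        assert out_norms[-1] > 0.999

    def test_zero_vector(self):
        assert np.array_equal(squash(Tensor(np.zeros(8))).data, np.zeros(8))


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

class TestArchitectureShapes:
    def test_reference_arithmetic(self):
        cfg = CapsNetConfig()
        assert cfg.conv1_size == 20
        assert cfg.primary_size == 6
        assert cfg.n_primary == 1152

    def test_forward_shapes_full_config(self):
        model = CapsNetModel(CapsNetConfig(), seed=0)
        img = images_to_array(generate_digits(1, seed=0))[0]
        h = model.forward_conv1(img)
        assert h.shape == (1, 256, 20, 20)
        u = model.forward_primary(img)
        assert u.shape == (1, 1152, 8)
        v, c, _ = model.forward(img)
        assert v.shape == (1, 2, 16)
        assert c.shape == (1, 1152, 2)

    def test_wrong_input_extent(self):
        model = CapsNetModel(scaled_config(), seed=0)
        with pytest.raises(ValueError, match="28x28"):
            model.forward(np.zeros((27, 27)))

    def test_zero_image_zero_bias_gives_zero_capsules(self):
        model = CapsNetModel(scaled_config(), seed=0)
        u = model.forward_primary(np.zeros((28, 28)))
        assert np.allclose(u.data, 0.0)

    def test_primary_capsules_squashed(self):
        model = CapsNetModel(scaled_config(), seed=0)
        img = images_to_array(generate_digits(1, seed=1))[0]
        u = model.forward_primary(img)
        assert np.linalg.norm(u.data, axis=-1).max() < 1.0


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def routing_oracle(u_hat: np.ndarray, iterations: int):
    """Loop-literal transcription of the routing equations, scalars only."""
    B, N, J, D = u_hat.shape
    states = []
    b = np.zeros((B, N, J))
    for _ in range(iterations):
        c = np.empty_like(b)
        for bi in range(B):
            for i in range(N):
                e = np.exp(b[bi, i] - b[bi, i].max())
                c[bi, i] = e / e.sum()
        s = np.zeros((B, J, D))
        for bi in range(B):
            for j in range(J):
                for i in range(N):
                    s[bi, j] += c[bi, i, j] * u_hat[bi, i, j]
        v = np.zeros_like(s)
        for bi in range(B):
            for j in range(J):
                n2 = s[bi, j] @ s[bi, j]
                if n2 > 0:
                    v[bi, j] = (n2 / (1 + n2)) * s[bi, j] / np.sqrt(n2)
        states.append((b.copy(), c.copy(), v.copy()))
        bn = b.copy()
        for bi in range(B):
            for i in range(N):
                for j in range(J):
                    bn[bi, i, j] += u_hat[bi, i, j] @ v[bi, j]
        b = bn
    return v, c, states


class TestRouting:
    def test_first_iteration_uniform_couplings(self):
        u_hat = np.random.default_rng(0).normal(size=(1, 4, 2, 16))
        _, c = dynamic_routing(u_hat, iterations=1)
        assert np.allclose(c.data, 0.5)

    def test_single_upper_capsule(self):
        u_hat = np.random.default_rng(0).normal(size=(1, 5, 1, 8))
        for iters in (1, 2, 3):
            _, c = dynamic_routing(u_hat, iterations=iters)
            assert np.allclose(c.data, 1.0)

    def test_agreement_toy_instance(self):
        # 3 lower capsules: two agree on upper capsule A, one points opposite
        d = np.zeros(4)
        d[0] = 1.0
        u_hat = np.zeros((1, 3, 2, 4))
        u_hat[0, 0, 0] = 2 * d
        u_hat[0, 1, 0] = 2 * d
        u_hat[0, 2, 0] = -2 * d
        u_hat[0, :, 1] = 0.1 * d          # B barely sees anything
        trace = []
        v, c = dynamic_routing(u_hat, iterations=3, trace=trace)
        ov, oc, ostates = routing_oracle(u_hat, 3)
        for (b1, c1, v1), (b2, c2, v2) in zip(trace, ostates):
            assert np.allclose(b1, b2, atol=1e-12)
            assert np.allclose(c1, c2, atol=1e-12)
            assert np.allclose(v1, v2, atol=1e-12)
        # agreeing capsules couple to A more strongly than the dissenter
        assert c.data[0, 0, 0] > c.data[0, 2, 0]
        assert c.data[0, 1, 0] > c.data[0, 2, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        B, N, J, D = 2, int(rng.integers(1, 6)), int(rng.integers(1, 4)), 4
        u_hat = rng.normal(size=(B, N, J, D))
        iters = int(rng.integers(1, 5))
        v, c = dynamic_routing(u_hat, iterations=iters)
        ov, oc, _ = routing_oracle(u_hat, iters)
        assert np.allclose(v.data, ov, atol=1e-10)
        assert np.allclose(c.data, oc, atol=1e-10)

    def test_coupling_rows_sum_to_one_every_iteration(self):
        u_hat = np.random.default_rng(3).normal(size=(2, 6, 3, 8))
        trace = []
        dynamic_routing(u_hat, iterations=4, trace=trace)
        for _, c, _ in trace:
            assert np.allclose(c.sum(axis=2), 1.0, atol=1e-14)
            assert np.all(c >= 0)

    def test_nonfinite_predictions_rejected(self):
        u_hat = np.zeros((1, 2, 2, 4))
        u_hat[0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            dynamic_routing(u_hat)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((1, 2, 2, 4)), iterations=0)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

class TestLosses:
    @pytest.mark.parametrize("lengths,expected", [
        ((0.9, 0.1), 0.0),
        ((0.0, 0.0), 0.81),
        ((0.5, 0.5), 0.24),
    ])
    def test_margin_loss_worked_values(self, lengths, expected):
        loss = margin_loss(np.array(lengths), np.array([1.0, 0.0]))
        assert float(loss.data) == pytest.approx(expected, abs=1e-12)

    def test_margin_loss_batch_mean(self):
        L = np.array([[0.9, 0.1], [0.5, 0.5]])
        T = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert float(margin_loss(L, T).data) == pytest.approx(0.12)

    def test_margin_loss_rejects_non_onehot(self):
        with pytest.raises(ValueError, match="one-hot"):
            margin_loss(np.array([0.5, 0.5]), np.array([1.0, 1.0]))

    def test_margin_config_validation(self):
        with pytest.raises(ValueError):
            MarginLossConfig(m_plus=0.1, m_minus=0.9)

    def test_overall_loss_substitution(self):
        img = np.zeros((28, 28))
        rec = np.full((28, 28), 0.1)       # MSE = 0.01
        out = overall_loss(0.24, img, rec, mu=4.0)
        assert float(out.data) == pytest.approx(0.28)

    def test_overall_loss_zero_mse(self):
        img = np.random.default_rng(0).uniform(size=(28, 28))
        out = overall_loss(0.17, img, img.copy(), mu=4.0)
        assert float(out.data) == pytest.approx(0.17)

    def test_overall_loss_shape_check(self):
        with pytest.raises(ValueError):
            overall_loss(0.1, np.zeros((28, 28)), np.zeros((27, 28)))


# ---------------------------------------------------------------------------
# Decoder
# ---------------------------------------------------------------------------

class TestDecoder:
    def test_deterministic(self):
        model = CapsNetModel(scaled_config(), seed=0)
        z = np.random.default_rng(0).normal(size=16) * 0.3
        a = model.decode(z).data
        b = model.decode(z).data
        assert np.array_equal(a, b)

    def test_zero_capsule_zero_weights_uniform_sigmoid_bias(self):
        model = CapsNetModel(scaled_config(), seed=0)
        for w in (model.dec1_w, model.dec2_w, model.dec3_w,
                  model.dec1_b, model.dec2_b):
            w.data[...] = 0.0
        model.dec3_b.data[...] = 0.3
        img = model.decode(np.zeros(16)).data
        assert np.allclose(img, 1.0 / (1.0 + np.exp(-0.3)))

    def test_wrong_dimension_error(self):
        model = CapsNetModel(scaled_config(), seed=0)
        with pytest.raises(ValueError, match="16"):
            model.decode(np.zeros(8))

    def test_output_in_open_interval(self):
        model = CapsNetModel(scaled_config(), seed=1)
        img = model.decode(np.random.default_rng(1).normal(size=16)).data
        assert np.all(img > 0) and np.all(img < 1)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

class TestGradients:
    def test_overall_loss_gradient_matches_fd(self):
        """Backprop vs central differences at 10 random decoder weights."""
        model = CapsNetModel(scaled_config(), seed=2)
        img = images_to_array(generate_digits(2, seed=2))[0]
        target = np.array([[1.0, 0.0], [0.0, 1.0]])

        def compute():
            v, _, _ = model.forward(img)
            lengths = v.norm(axis=-1, eps=1e-12)
            m = margin_loss(lengths, target)
            vk = (v * Tensor(target[:, :, None])).sum(axis=1)
            rec = model.decode(vk)
            return overall_loss(m, Tensor(img), rec, mu=4.0)

        loss = compute()
        loss.backward()
        params = [model.dec1_w, model.dec2_w, model.dec3_w, model.dec3_b]
        grads = [p.grad.copy() for p in params]
        rng = np.random.default_rng(7)
        for ti, ci, fd in finite_difference(
            lambda: compute().data, params, rng=rng, n_coords=10, h=1e-5
        ):
            ana = grads[ti].reshape(-1)[ci]
            assert ana == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_single_step_descends(self):
        """One small gradient step on a batch of 10 reduces that batch's loss."""
        model = CapsNetModel(scaled_config(), seed=3)
        px, lab = images_to_array(generate_digits(10, seed=3))
        target = np.eye(2)[(lab == 9).astype(int)]

        def compute():
            v, _, _ = model.forward(px)
            lengths = v.norm(axis=-1, eps=1e-12)
            m = margin_loss(lengths, target)
            vk = (v * Tensor(target[:, :, None])).sum(axis=1)
            return overall_loss(m, Tensor(px), model.decode(vk), mu=4.0)

        loss = compute()
        loss.backward()
        before = float(loss.data)
        lr = 1e-4
        for p in model.parameters():
            p.data -= lr * p.grad
        after = float(compute().data)
        assert after < before


# ---------------------------------------------------------------------------
# Training (session-scoped fixture; scaled config, 500 glyphs, 20 epochs)
# ---------------------------------------------------------------------------

class TestTrainedModel:
    def test_training_accuracy(self, trained_capsnet):
        _, trace = trained_capsnet
        assert trace.epoch_accuracy[-1] >= 0.95

    def test_loss_trend_decreasing(self, trained_capsnet):
        _, trace = trained_capsnet
        losses = np.array(trace.epoch_loss)
        assert losses[-1] < losses[0]
        # non-increasing in trend: second-half mean below first-half mean
        assert losses[len(losses) // 2:].mean() < losses[: len(losses) // 2].mean()

    def test_classification_rule_is_argmax_norm(self, trained_capsnet, glyphs500):
        model, _ = trained_capsnet
        px, lab = glyphs500
        v, _, _ = model.forward(px[:20])
        norms = np.linalg.norm(v.data, axis=2)
        assert np.array_equal(model.classify(px[:20]), norms.argmax(axis=1))

    def test_reconstruction_ssim_on_training_items(self, trained_capsnet, glyphs500):
        model, _ = trained_capsnet
        px, _ = glyphs500
        v, _, _ = model.forward(px[:50])
        feats, _ = longer_capsule_features(v.data)
        rec = model.decode(feats).data
        ssims = [ssim_metric(px[i], rec[i]) for i in range(50)]
        assert np.mean(ssims) >= 0.6

    def test_translation_equivariance_surrogate(self, trained_capsnet):
        """Shifting a glyph 2 px changes the capsule vector but rarely the
        predicted class on held-out items."""
        model, _ = trained_capsnet
        images = generate_digits(
            100, seed=999, param_ranges={"translation": (-0.5, 0.5)}
        )
        px, lab = images_to_array(images)
        shifted = np.roll(px, 2, axis=2)
        v0, _, _ = model.forward(px)
        v1, _, _ = model.forward(shifted)
        assert not np.allclose(v0.data, v1.data)
        cls0 = np.linalg.norm(v0.data, axis=2).argmax(axis=1)
        cls1 = np.linalg.norm(v1.data, axis=2).argmax(axis=1)
        assert (cls0 == cls1).mean() >= 0.9

    def test_single_class_rejected(self):
        px, _ = images_to_array(generate_digits(10, class_mix=1.0, seed=0))
        with pytest.raises(ValueError, match="two classes"):
            train_capsnet(px, np.full(10, 6), scaled_config(), epochs=1, seed=0)
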