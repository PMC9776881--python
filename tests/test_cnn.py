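"""Tests for the depthwise-separable CNN stack and Adam optimizer."""

import numpy as np
import pytest

import _reference as ref
from histofuzz import cnn


def make_layer(rng, kh, c_in, c_out, mode="standard", stride=1, padding=0,
               activation="relu"):
    if mode == "depthwise":
        w = rng.normal(size=(kh, kh, c_in))
        b = rng.normal(size=c_in)
    else:
        w = rng.normal(size=(kh, kh, c_in, c_out))
        b = rng.normal(size=c_out)
    return cnn.ConvLayerSpec(w, b, activation, stride, padding, mode)


class TestConvForward:
    def test_scalar_substitution(self):
        layer = cnn.ConvLayerSpec(np.full((1, 1, 1, 1), 3.0), np.array([1.0]),
                                  "relu", mode="pointwise")
        assert cnn.conv_forward(np.full((1, 1, 1), 2.0), layer)[0, 0, 0] == 7.0
        assert cnn.conv_forward(np.full((1, 1, 1), -2.0), layer)[0, 0, 0] == 0.0

    @pytest.mark.parametrize("stride,padding", [(1, 0), (1, 1), (2, 1)])
    def test_matches_loop_oracle(self, stride, padding):
        rng = np.random.default_rng(10 * stride + padding)
        layer = make_layer(rng, 3, 3, 4, stride=stride, padding=padding)
        x = rng.normal(size=(8, 8, 3))
        got = cnn.conv_forward(x, layer)
        want = ref.conv_loops(x, layer.weights, layer.bias, stride, padding)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_shape_mismatch_raises(self):
        layer = make_layer(np.random.default_rng(0), 3, 3, 4)
        with pytest.raises(ValueError):
            cnn.conv_forward(np.zeros((8, 8, 2)), layer)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            cnn.ConvLayerSpec(np.zeros((2, 2, 1, 1)), np.zeros(1))


class TestDepthwiseSeparable:
    def test_parameter_factorization_arithmetic(self):
        k, c_in, c_out = 3, 8, 16
        separable = k * k * c_in + c_in * c_out
        standard = k * k * c_in * c_out
        assert separable == 200
        assert standard == 1152
        assert separable < standard  # holds since c_out > k^2/(1 + k^2/c_in)

    def test_identity_composition(self):
        c = 3
        dw_w = np.zeros((3, 3, c))
        dw_w[1, 1, :] = 1.0  # center tap
        dw = cnn.ConvLayerSpec(dw_w, np.zeros(c), "linear", padding=1,
                               mode="depthwise")
        pw = cnn.ConvLayerSpec(np.eye(c)[None, None], np.zeros(c), "linear",
                               mode="pointwise")
        x = np.random.default_rng(1).normal(size=(6, 6, c))
        np.testing.assert_allclose(
            cnn.depthwise_separable_forward(x, dw, pw), x, atol=1e-12)

    def test_matches_two_stage_loop_oracle(self):
        rng = np.random.default_rng(2)
        dw = make_layer(rng, 3, 4, None, mode="depthwise", stride=2, padding=1)
        pw = make_layer(rng, 1, 4, 6, mode="pointwise")
        x = rng.normal(size=(7, 7, 4))
        got = cnn.depthwise_separable_forward(x, dw, pw)
        mid = ref.depthwise_loops(x, dw.weights, dw.bias, 2, 1)
        want = ref.conv_loops(mid, pw.weights, pw.bias, 1, 0)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_non_pointwise_second_stage_rejected(self):
        rng = np.random.default_rng(3)
        dw = make_layer(rng, 3, 4, None, mode="depthwise")
        not_pw = make_layer(rng, 3, 4, 6)
        with pytest.raises(ValueError):
            cnn.depthwise_separable_forward(np.zeros((6, 6, 4)), dw, not_pw)


class TestMaxPool:
    def test_simple_maximum(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert cnn.max_pool(x, 2)[0, 0, 0] == 4.0

    def test_constant_input(self):
        out = cnn.max_pool(np.full((6, 6, 2), 3.3), 2)
        assert np.all(out == 3.3)

    @pytest.mark.parametrize("window,stride", [(2, 2), (3, 1), (2, 1)])
    def test_matches_loop_oracle(self, window, stride):
        rng = np.random.default_rng(window * 10 + stride)
        x = rng.normal(size=(8, 8, 4))
        got = cnn.max_pool(x, window, stride)
        want = ref.max_pool_loops(x, window, stride)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestAdam:
    def test_first_step_magnitude_is_learning_rate(self):
        for g in [2.0, -0.5, 1e-4, 300.0]:
            state = cnn.AdamState.zeros_like(np.zeros(1), learning_rate=0.01)
            w, _ = cnn.adam_step(state, np.array([g]), np.array([0.0]))
            expected = 0.01 * abs(g) / (abs(g) + state.epsilon)
            assert abs(w[0]) == pytest.approx(expected, abs=1e-12)
            assert abs(w[0]) == pytest.approx(0.01, abs=1e-6)
            assert np.sign(w[0]) == -np.sign(g)

    def test_zero_gradient_noop(self):
        state = cnn.AdamState.zeros_like(np.zeros(3))
        w0 = np.array([1.0, -2.0, 0.5])
        w, _ = cnn.adam_step(state, np.zeros(3), w0)
        np.testing.assert_array_equal(w, w0)

    def test_descent_on_quadratic(self):
        """50 steps on f(w) = w^2 from w = 1 with lr 0.1 reach |w| < 0.1.

        Adam's momentum overshoots the minimum (|w| rebounds briefly), so
        only the damped envelope is asserted, not stepwise monotonicity.
        """
        state = cnn.AdamState.zeros_like(np.zeros(1), learning_rate=0.1)
        w = np.array([1.0])
        traj = [abs(w[0])]
        for _ in range(50):
            w, _ = cnn.adam_step(state, 2 * w, w)
            traj.append(abs(w[0]))
        assert traj[-1] < 0.1
        assert max(traj[1:]) < traj[0]  # never leaves the initial bracket
        assert max(traj[25:]) < max(traj[:25])  # oscillation is damped

    def test_betas_zero_reduce_to_sign_sgd(self):
        state = cnn.AdamState.zeros_like(np.zeros(2), beta1=0.0, beta2=0.0,
                                         learning_rate=0.05)
        g = np.array([3.0, -0.2])
        w, _ = cnn.adam_step(state, g, np.zeros(2))
        expected = -0.05 * g / (np.abs(g) + state.epsilon)
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_literal_variant_matches_printed_form(self):
        """The no-square-root variant: w <- w - lr * m_hat / (v_hat + eps)."""
        state = cnn.AdamState.zeros_like(np.zeros(1), learning_rate=0.01,
                                         literal_eq6=True)
        g = np.array([2.0])
        w, _ = cnn.adam_step(state, g, np.array([0.0]))
        m_hat, v_hat = 2.0, 4.0
        assert w[0] == pytest.approx(-0.01 * m_hat / (v_hat + state.epsilon))

    def test_nonfinite_gradient_aborts(self):
        state = cnn.AdamState.zeros_like(np.zeros(1))
        with pytest.raises(FloatingPointError):
            cnn.adam_step(state, np.array([np.inf]), np.array([0.0]))


class TestBackwardPasses:
    """Analytic gradients against central finite differences."""

    @pytest.mark.parametrize("mode,stride", [("standard", 1), ("standard", 2),
                                             ("depthwise", 1), ("pointwise", 1)])
    def test_conv_layer_gradients(self, mode, stride):
        rng = np.random.default_rng(5)
        kh = 1 if mode == "pointwise" else 3
        layer = cnn.ConvLayer(make_layer(rng, kh, 2, 3, mode=mode, stride=stride,
                                         padding=0 if mode == "pointwise" else 1,
                                         activation="linear"))
        x = rng.normal(size=(2, 5, 5, 2))
        dout = rng.normal(size=layer.forward(x, False).shape)
        dx = layer.backward(dout)
        eps = 1e-6
        for idx in [(0, 1, 2, 0), (1, 4, 0, 1)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (np.sum(layer.forward(xp, False) * dout)
                   - np.sum(layer.forward(xm, False) * dout)) / (2 * eps)
            assert dx[idx] == pytest.approx(num, abs=1e-5)
        w = layer.spec.weights
        widx = (0, 0) + ((1,) if mode == "depthwise" else (1, 2))
        orig = w[widx]
        w[widx] = orig + eps
        up = np.sum(layer.forward(x, False) * dout)
        w[widx] = orig - eps
        down = np.sum(layer.forward(x, False) * dout)
        w[widx] = orig
        layer.forward(x, False)
        layer.backward(dout)
        assert layer.dw[widx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)

    def test_maxpool_gradients(self):
        rng = np.random.default_rng(6)
        layer = cnn.MaxPoolLayer(2, 2)
        x = rng.normal(size=(2, 4, 4, 3))
        out = layer.forward(x, False)
        dout = rng.normal(size=out.shape)
        dx = layer.backward(dout)
        eps = 1e-6
        idx = (0, 1, 1, 0)
        xp = x.copy()
        xp[idx] += eps
        num = (np.sum(layer.forward(xp, False) * dout)
               - np.sum(out * dout)) / eps
        layer.forward(x, False)
        assert dx[idx] == pytest.approx(num, abs=1e-4)


class TestNetwork:
    def test_presets_constructible(self):
        desk = cnn.NetworkSpec.desk()
        assert desk.stem_filters == 8 and len(desk.bottlenecks) == 4
        net = desk.build(0)
        out = net.forward(np.zeros((1, 64, 64, 3)))
        assert out.shape == (1, 3)
        full = cnn.NetworkSpec.full_scale()
        assert full.stem_filters == 32 and len(full.bottlenecks) == 19
        full.build(0)  # construct only; full-scale training is out of scope here

    def test_separable_classes_learned_quickly(self):
        """Dark vs bright tiles reach perfect training accuracy."""
        rng = np.random.default_rng(7)
        dark = rng.random((20, 64, 64, 3)) * 0.2
        bright = rng.random((20, 64, 64, 3)) * 0.2 + 0.8
        images = np.concatenate([dark, bright])
        labels = np.repeat([0, 1], 20)
        spec = cnn.NetworkSpec.desk(n_classes=2, dropout=0.1)
        net, history = cnn.train_feature_extractor(
            images, labels, spec, epochs=10, batch_size=8,
            learning_rate=0.002, seed=0)
        preds = np.argmax(net.forward(images), axis=1)
        assert np.mean(preds == labels) == 1.0
        assert history[-1] < history[0]

    def test_training_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        images = rng.random((24, 64, 64, 3))
        labels = np.tile([0, 1, 2], 8)
        spec = cnn.NetworkSpec.desk(dropout=0.25)
        _, h1 = cnn.train_feature_extractor(images, labels, spec, epochs=2,
                                            batch_size=8, seed=3)
        _, h2 = cnn.train_feature_extractor(images, labels, spec, epochs=2,
                                            batch_size=8, seed=3)
        assert h1 == h2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cnn.train_feature_extractor(np.zeros((4, 64, 64, 3)), np.zeros(4, int),
                                        cnn.NetworkSpec.desk())


@pytest.fixture(scope="module")
def net():
    return cnn.NetworkSpec.desk().build(seed=1)


class TestExtractFeatures:

    def test_identical_images_identical_vectors(self, net):
        img = np.random.default_rng(9).random((64, 64, 3))
        feats = cnn.extract_features(net, np.stack([img, img]))
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_dimension_and_determinism(self, net):
        imgs = np.random.default_rng(10).random((5, 64, 64, 3))
        f1 = cnn.extract_features(net, imgs)
        f2 = cnn.extract_features(net, imgs)
        assert f1.shape == (5, net.spec.feature_dim)
        np.testing.assert_array_equal(f1, f2)

    def test_wrong_size_rejected(self, net):
        with pytest.raises(ValueError):
            cnn.extract_features(net, np.zeros((2, 32, 32, 3)))

    def test_feature_vector_wrapper(self, net):
        imgs = np.random.default_rng(11).random((2, 64, 64, 3))
        fvs = cnn.extract_features(net, imgs, image_ids=["a", "b"])
        assert [fv.image_id for fv in fvs] == ["a", "b"]

    def test_separable_features_linearly_separable(self):
        """Features of dark vs bright tiles admit a perfect perceptron."""
        from sklearn.linear_model import Perceptron

        rng = np.random.default_rng(12)
        dark = rng.random((15, 64, 64, 3)) * 0.2
        bright = rng.random((15, 64, 64, 3)) * 0.2 + 0.8
        images = np.concatenate([dark, bright])
        labels = np.repeat([0, 1], 15)
        net, _ = cnn.train_feature_extractor(
            images, labels, cnn.NetworkSpec.desk(n_classes=2, dropout=0.1),
            epochs=5, batch_size=8, learning_rate=0.002, seed=1)
        feats = cnn.extract_features(net, images)
        clf = Perceptron(max_iter=200, random_state=0).fit(feats, labels)
        assert clf.score(feats, labels) == 1.0


def test_network_serialization_roundtrip(tmp_path):
    net = cnn.NetworkSpec.desk().build(seed=4)
    x = np.random.default_rng(13).random((2, 64, 64, 3))
    before = net.forward(x)
    path = tmp_path / "net.npz"
    net.save(path)
    loaded = cnn.Network.load(path)
    np.testing.assert_allclose(loaded.forward(x), before, atol=1e-12)
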