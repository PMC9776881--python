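"""Depthwise-separable CNN feature extractor with a from-scratch Adam optimizer.

The network follows the MobileNetV2 recipe: a stem convolution, a stack of
inverted residual bottlenecks (pointwise expansion -> depthwise spatial
convolution -> linear pointwise projection, with a skip connection when the
block preserves shape), global average pooling, and a small fully connected
head.  The penultimate FC layer is the feature tap: after training with
softmax cross-entropy, ``extract_features`` returns its activations (with
dropout disabled) as fixed-length per-image descriptors.

A depthwise-separable convolution factorizes a standard k x k convolution
into a per-channel spatial convolution followed by a 1x1 cross-channel
convolution, cutting the parameter count from ``k*k*Cin*Cout`` to
``k*k*Cin + Cin*Cout``.

Everything is plain numpy: forward passes are vectorized with sliding
windows, backward passes accumulate gradients with the transposed window
scheme, and weights are updated by the Adam rule

    m <- b1*m + (1-b1)*g          v <- b2*v + (1-b2)*g^2
    m_hat = m / (1 - b1^(t+1))    v_hat = v / (1 - b2^(t+1))
    w <- w - lr * m_hat / (sqrt(v_hat) + eps)

with the step counter ``t`` starting at 0.  ``literal_eq6=True`` switches
the denominator to ``v_hat + eps`` (no square root), a non-standard variant
kept selectable for comparison.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "ConvLayerSpec",
    "AdamState",
    "NetworkSpec",
    "Network",
    "FeatureVector",
    "conv_forward",
    "depthwise_separable_forward",
    "max_pool",
    "adam_step",
    "train_feature_extractor",
    "extract_features",
]


# ---------------------------------------------------------------------------
# functional ops


@dataclasses.dataclass
class ConvLayerSpec:
    """One convolution layer: weights, bias, activation, stride, padding, mode.

    Weight shapes: ``(kh, kw, c_in, c_out)`` for standard/pointwise mode,
    ``(kh, kw, c)`` for depthwise mode (one filter per input channel).
    """

    weights: np.ndarray
    bias: np.ndarray
    activation: str = "relu"  # relu | linear
    stride: int = 1
    padding: int = 0
    mode: str = "standard"  # standard | depthwise | pointwise

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.mode not in ("standard", "depthwise", "pointwise"):
            raise ValueError(f"unknown conv mode {self.mode!r}")
        if self.activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        expected_ndim = 3 if self.mode == "depthwise" else 4
        if self.weights.ndim != expected_ndim:
            raise ValueError(
                f"{self.mode} conv expects {expected_ndim}-D weights, "
                f"got shape {self.weights.shape}"
            )
        kh, kw = self.weights.shape[:2]
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel spatial dims must be odd")
        if self.mode == "pointwise" and (kh, kw) != (1, 1):
            raise ValueError("pointwise conv kernel must be 1x1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        n_out = self.weights.shape[2] if self.mode == "depthwise" else self.weights.shape[3]
        if self.bias.shape != (n_out,):
            raise ValueError(f"bias must have shape ({n_out},), got {self.bias.shape}")


def _activate(x: np.ndarray, activation: str) -> np.ndarray:
    return np.maximum(x, 0.0) if activation == "relu" else x


def _pad_spatial(x: np.ndarray, padding: int) -> np.ndarray:
    if padding == 0:
        return x
    return np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))


def _window_view(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, Ho, Wo, C, kh, kw) strided view over padded input (N, H, W, C)."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    return win[:, ::stride, ::stride]


def _conv_batch(x: np.ndarray, layer: ConvLayerSpec) -> np.ndarray:
    xp = _pad_spatial(x, layer.padding)
    kh, kw = layer.weights.shape[:2]
    if xp.shape[1] < kh or xp.shape[2] < kw:
        raise ValueError(
            f"padded input spatial dims {xp.shape[1:3]} smaller than kernel ({kh}, {kw})"
        )
    win = _window_view(xp, kh, kw, layer.stride)
    if layer.mode == "depthwise":
        if x.shape[3] != layer.weights.shape[2]:
            raise ValueError(
                f"depthwise conv expects {layer.weights.shape[2]} input channels, "
                f"got {x.shape[3]}"
            )
        pre = np.einsum("nhwcij,ijc->nhwc", win, layer.weights) + layer.bias
    else:
        if x.shape[3] != layer.weights.shape[2]:
            raise ValueError(
                f"conv expects {layer.weights.shape[2]} input channels, got {x.shape[3]}"
            )
        pre = np.einsum("nhwcij,ijco->nhwo", win, layer.weights) + layer.bias
    return _activate(pre, layer.activation)


def conv_forward(input: np.ndarray, layer: ConvLayerSpec) -> np.ndarray:
    """Forward pass of one convolution layer on a single (H, W, C) tensor.

    Computes, per output position and output channel s,
    ``T = f(sum_{x,y,z} C[x,y,z] * w[x,y,z,s] + b[s])`` where f is the
    layer activation; depthwise mode restricts the sum to one channel per
    filter.
    """
    x = np.asarray(input, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected (H, W, C) input, got shape {x.shape}")
    return _conv_batch(x[None], layer)[0]


def depthwise_separable_forward(
    input: np.ndarray, depthwise: ConvLayerSpec, pointwise: ConvLayerSpec
) -> np.ndarray:
    """Channelwise spatial convolution followed by a 1x1 cross-channel mix."""
    if depthwise.mode != "depthwise":
        raise ValueError("first layer must have mode='depthwise'")
    if pointwise.weights.shape[:2] != (1, 1):
        raise ValueError("pointwise kernel must be 1x1")
    return conv_forward(conv_forward(input, depthwise), pointwise)


def max_pool(input: np.ndarray, window: int, stride: int | None = None) -> np.ndarray:
    """Channelwise max pooling on a single (H, W, C) tensor."""
    x = np.asarray(input, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected (H, W, C) input, got shape {x.shape}")
    if stride is None:
        stride = window
    if window > min(x.shape[:2]):
        raise ValueError("pooling window larger than spatial dims")
    win = _window_view(x[None], window, window, stride)
    return win.max(axis=(-2, -1))[0]


# ---------------------------------------------------------------------------
# Adam


@dataclasses.dataclass
class AdamState:
    """First/second moment estimates and hyperparameters for one weight array."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    learning_rate: float = 0.01
    epsilon: float = 1e-8
    literal_eq6: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ValueError("beta1 and beta2 must be in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def zeros_like(cls, weights: np.ndarray, **hyper) -> "AdamState":
        return cls(m=np.zeros_like(weights, dtype=float),
                   v=np.zeros_like(weights, dtype=float), **hyper)


def adam_step(
    state: AdamState, gradient: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, AdamState]:
    """One Adam update; returns the new weights and the advanced state.

    The state is updated in place (and also returned).  Bias-correction
    exponents are ``t+1`` with ``t`` starting at 0, so the first step from
    a zero state has magnitude ``lr * |g| / (|g| + eps)``.
    """
    g = np.asarray(gradient, dtype=float)
    if g.shape != state.m.shape:
        raise ValueError(f"gradient shape {g.shape} != state shape {state.m.shape}")
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient passed to adam_step")
    state.m *= state.beta1
    state.m += (1.0 - state.beta1) * g
    state.v *= state.beta2
    state.v += (1.0 - state.beta2) * g * g
    m_hat = state.m / (1.0 - state.beta1 ** (state.t + 1))
    v_hat = state.v / (1.0 - state.beta2 ** (state.t + 1))
    denom = (v_hat + state.epsilon) if state.literal_eq6 else (np.sqrt(v_hat) + state.epsilon)
    new_weights = weights - state.learning_rate * m_hat / denom
    state.t += 1
    return new_weights, state


# ---------------------------------------------------------------------------
# trainable layers (forward caches what backward needs)


class _Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(weight, gradient) pairs; gradients are filled by backward."""
        return []


class ConvLayer(_Layer):
    def __init__(self, spec: ConvLayerSpec):
        self.spec = spec
        self.dw = np.zeros_like(spec.weights)
        self.db = np.zeros_like(spec.bias)
        self._xp: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = self.spec
        self._xp = _pad_spatial(x, s.padding)
        out = _conv_batch(x, s)
        self._mask = out > 0 if s.activation == "relu" else None
        self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.spec
        if self._mask is not None:
            dout = dout * self._mask
        kh, kw = s.weights.shape[:2]
        stride = s.stride
        xp = self._xp
        n, ho, wo = dout.shape[:3]
        dxp = np.zeros_like(xp)
        self.db[...] = dout.sum(axis=(0, 1, 2))
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i : i + ho * stride : stride, j : j + wo * stride : stride]
                if s.mode == "depthwise":
                    self.dw[i, j] = np.einsum("nhwc,nhwc->c", patch, dout)
                    dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        dout * s.weights[i, j]
                    )
                else:
                    self.dw[i, j] = np.einsum("nhwc,nhwo->co", patch, dout)
                    dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        np.einsum("nhwo,co->nhwc", dout, s.weights[i, j])
                    )
        p = s.padding
        if p:
            return dxp[:, p:-p, p:-p]
        return dxp

    def params(self):
        return [(self.spec.weights, self.dw), (self.spec.bias, self.db)]


class MaxPoolLayer(_Layer):
    def __init__(self, window: int, stride: int | None = None):
        self.window = window
        self.stride = stride if stride is not None else window

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        k, s = self.window, self.stride
        win = _window_view(x, k, k, s)  # (N,Ho,Wo,C,k,k)
        n, ho, wo, c = win.shape[:4]
        flat = win.reshape(n, ho, wo, c, k * k)
        self._arg = flat.argmax(axis=-1)
        self._dims = (n, ho, wo, c)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, ho, wo, c = self._dims
        k, s = self.window, self.stride
        dx = np.zeros(self._x_shape)
        ni, hi, wi, ci = np.indices((n, ho, wo, c))
        rows = hi * s + self._arg // k
        cols = wi * s + self._arg % k
        np.add.at(dx, (ni, rows, cols, ci), dout)
        return dx


class GlobalAvgPool(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)


class DenseLayer(_Layer):
    def __init__(self, weights: np.ndarray, bias: np.ndarray, activation: str = "linear"):
        self.w = weights
        self.b = bias
        self.activation = activation
        self.dw = np.zeros_like(weights)
        self.db = np.zeros_like(bias)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        out = x @ self.w + self.b
        out = _activate(out, self.activation)
        self._mask = out > 0 if self.activation == "relu" else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is not None:
            dout = dout * self._mask
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class DropoutLayer(_Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout layer used in training mode without an RNG")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class InvertedResidual(_Layer):
    """Pointwise expand -> depthwise (stride) -> linear pointwise project.

    Skip connection when stride is 1 and the channel count is preserved.
    """

    def __init__(self, expand: ConvLayer, depthwise: ConvLayer, project: ConvLayer,
                 use_residual: bool):
        self.layers = [expand, depthwise, project]
        self.use_residual = use_residual

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        if self.use_residual:
            out = out + x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        if self.use_residual:
            dx = dx + dout
        return dx

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


# ---------------------------------------------------------------------------
# network construction


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``bottlenecks`` is a list of ``(expansion, out_channels, stride)``
    tuples applied after the stem convolution.  ``feature_dim`` is the
    width of the penultimate FC layer whose activations are the extracted
    features.
    """

    input_size: int
    stem_filters: int
    bottlenecks: tuple
    feature_dim: int
    n_classes: int
    dropout: float = 0.5
    stem_pool: bool = True

    @classmethod
    def desk(cls, n_classes: int = 3, dropout: float = 0.5) -> "NetworkSpec":
        """Small preset trainable in minutes on a CPU: 64x64 input, 8-filter
        stem, 4 bottlenecks, 16-dim features."""
        return cls(
            input_size=64,
            stem_filters=8,
            bottlenecks=((4, 16, 2), (4, 16, 1), (4, 24, 2), (4, 24, 1)),
            feature_dim=16,
            n_classes=n_classes,
            dropout=dropout,
        )

    @classmethod
    def full_scale(cls, n_classes: int = 3, dropout: float = 0.5) -> "NetworkSpec":
        """Full-scale preset: 32-filter stem followed by 19 inverted residual
        bottlenecks (MobileNetV2-shaped).  Constructible and runnable, but not
        intended for CPU training."""
        table = [(1, 16, 1, 1), (6, 24, 3, 2), (6, 32, 4, 2), (6, 64, 4, 2),
                 (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
        blocks = []
        for t, c, n, s in table:
            for k in range(n):
                blocks.append((t, c, s if k == 0 else 1))
        assert len(blocks) == 19
        return cls(
            input_size=224,
            stem_filters=32,
            bottlenecks=tuple(blocks),
            feature_dim=256,
            n_classes=n_classes,
            dropout=dropout,
            stem_pool=False,
        )

    def build(self, seed: int = 0) -> "Network":
        return Network(self, seed)


def _he_conv(rng, kh, kw, c_in, c_out):
    std = np.sqrt(2.0 / (kh * kw * c_in))
    return rng.normal(0.0, std, size=(kh, kw, c_in, c_out))


class Network:
    """Sequential network built from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[_Layer] = []
        c_in = 3
        layers.append(ConvLayer(ConvLayerSpec(
            _he_conv(rng, 3, 3, c_in, spec.stem_filters),
            np.zeros(spec.stem_filters), "relu", stride=2, padding=1)))
        c_in = spec.stem_filters
        if spec.stem_pool:
            layers.append(MaxPoolLayer(2, 2))
        for expansion, c_out, stride in spec.bottlenecks:
            hidden = expansion * c_in
            expand = ConvLayer(ConvLayerSpec(
                _he_conv(rng, 1, 1, c_in, hidden), np.zeros(hidden),
                "relu", mode="pointwise"))
            dw_std = np.sqrt(2.0 / 9.0)
            depthwise = ConvLayer(ConvLayerSpec(
                rng.normal(0.0, dw_std, size=(3, 3, hidden)), np.zeros(hidden),
                "relu", stride=stride, padding=1, mode="depthwise"))
            project = ConvLayer(ConvLayerSpec(
                _he_conv(rng, 1, 1, hidden, c_out), np.zeros(c_out),
                "linear", mode="pointwise"))
            layers.append(InvertedResidual(
                expand, depthwise, project,
                use_residual=(stride == 1 and c_in == c_out)))
            c_in = c_out
        layers.append(GlobalAvgPool())
        feat = DenseLayer(
            rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, spec.feature_dim)),
            np.zeros(spec.feature_dim), "relu")
        layers.append(feat)
        layers.append(DropoutLayer(spec.dropout))
        layers.append(DenseLayer(
            rng.normal(0.0, np.sqrt(1.0 / spec.feature_dim),
                       size=(spec.feature_dim, spec.n_classes)),
            np.zeros(spec.n_classes), "linear"))
        self.layers = layers
        self._feature_index = len(layers) - 3  # penultimate FC (before dropout)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        dx = dlogits
        for layer in reversed(self.layers):
            dx = layer.backward(dx)

    def features(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for layer in self.layers[: self._feature_index + 1]:
            out = layer.forward(out, train=False)
        return out

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for layer in self.layers for p in layer.params()]

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, DropoutLayer):
                layer.rng = rng

    # -- serialization (single .npz archive) --------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": w for i, (w, _) in enumerate(self.params())}
        arrays["spec"] = np.frombuffer(
            repr(dataclasses.asdict(self.spec)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        import ast

        with np.load(path) as data:
            spec = NetworkSpec(**ast.literal_eval(bytes(data["spec"]).decode()))
            net = cls(spec, seed=0)
            for i, (w, _) in enumerate(net.params()):
                w[...] = data[f"p{i}"]
        return net


# ---------------------------------------------------------------------------
# training and feature extraction


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    vector: np.ndarray
    image_id: str


def _softmax_ce(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    shifted = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    probs = expd / expd.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


def train_feature_extractor(
    images: np.ndarray,
    labels: np.ndarray,
    spec: NetworkSpec,
    epochs: int = 10,
    batch_size: int = 32,
    learning_rate: float = 0.01,
    seed: int = 0,
    adam_kwargs: dict | None = None,
) -> tuple[Network, list[float]]:
    """Train the CNN on ``images`` (N, H, W, 3) in [0, 1] with int ``labels``.

    Softmax cross-entropy, Adam updates, seeded shuffling and dropout, so a
    fixed seed yields an identical loss history.  Returns the trained
    network and the per-epoch mean training loss.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least 2 classes")
    rng = np.random.default_rng(seed)
    net = spec.build(seed=int(rng.integers(2**31)))
    net.set_dropout_rng(np.random.default_rng(int(rng.integers(2**31))))
    adam_kwargs = dict(adam_kwargs or {})
    adam_kwargs.setdefault("learning_rate", learning_rate)
    states = [AdamState.zeros_like(w, **adam_kwargs) for w, _ in net.params()]

    n = images.shape[0]
    history: list[float] = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(images[idx], train=True)
            loss, dlogits = _softmax_ce(logits, labels[idx])
            net.backward(dlogits)
            for (w, g), state in zip(net.params(), states):
                w[...], _ = adam_step(state, g, w)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return net, history


def extract_features(
    network: Network,
    images: np.ndarray,
    image_ids: Sequence[str] | None = None,
    batch_size: int = 64,
) -> np.ndarray | list[FeatureVector]:
    """Penultimate-layer activations, dropout disabled (deterministic).

    Returns an (N, feature_dim) array, or a list of :class:`FeatureVector`
    when ``image_ids`` is given.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1] != network.spec.input_size:
        raise ValueError(
            f"network expects {network.spec.input_size}x{network.spec.input_size} "
            f"tiles, got {images.shape[1]}x{images.shape[2]}"
        )
    chunks = [
        network.features(images[i : i + batch_size])
        for i in range(0, images.shape[0], batch_size)
    ]
    feats = np.concatenate(chunks, axis=0)
    if not np.all(np.isfinite(feats)):
        raise FloatingPointError("non-finite feature values")
    if image_ids is None:
        return feats
    if len(image_ids) != feats.shape[0]:
        raise ValueError("image_ids length mismatch")
    return [FeatureVector(v, str(i)) for v, i in zip(feats, image_ids)]
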