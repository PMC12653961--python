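"""A small six-layer convolutional network ("CNN6") implemented on NumPy.

The architecture is four convolution+ReLU stages, each followed by 2x2
max-pooling, then two fully connected layers ending in two class logits.
Forward pass, backpropagation and the Adam optimizer are implemented directly
on NumPy arrays: the network is small enough to train on a CPU in minutes,
and a self-contained implementation keeps every run bit-reproducible under a
fixed seed.

Convolutions use 'same' zero padding and stride 1 via an im2col lowering to a
single matrix multiply per layer.  Data layout is NHWC throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

N_CONV_STAGES = 4
N_FC_STAGES = 2


@dataclass(frozen=True)
class Cnn6Spec:
    """Hyperparameters of the six-layer network.

    ``input_side_px`` must be divisible by ``pool_px ** 4`` so the four
    pooling stages divide the spatial grid evenly.
    """

    input_side_px: int = 32
    conv_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    kernel_px: int = 3
    pool_px: int = 2
    fc_hidden: int = 64
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_channels) != N_CONV_STAGES:
            raise ValueError(
                f"exactly {N_CONV_STAGES} convolutional stages are required "
                f"(got {len(self.conv_channels)} channel counts); together with "
                f"{N_FC_STAGES} fully connected stages they make the six layers"
            )
        divisor = self.pool_px**N_CONV_STAGES
        if self.input_side_px % divisor != 0:
            raise ValueError(
                f"input_side_px={self.input_side_px} must be divisible by "
                f"pool_px**{N_CONV_STAGES} = {divisor}"
            )
        if self.kernel_px % 2 != 1:
            raise ValueError("kernel_px must be odd for 'same' padding")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")

    @property
    def feature_side(self) -> int:
        """Spatial side after the four pooling stages."""
        return self.input_side_px // self.pool_px**N_CONV_STAGES

    @property
    def flat_features(self) -> int:
        return self.feature_side**2 * self.conv_channels[-1]


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int):
    """'Same' conv, stride 1.  x: (N,H,W,C); w: (k*k*C, F); returns (out, cols)."""
    n, h, wd, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    patches = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    cols = patches.transpose(0, 1, 2, 4, 5, 3).reshape(n, h, wd, k * k * c)
    out = cols @ w + b
    return out, cols


def _conv_backward(dout, cols, x_shape, w, k: int):
    n, h, wd, c = x_shape
    f = w.shape[1]
    dw = cols.reshape(-1, w.shape[0]).T @ dout.reshape(-1, f)
    db = dout.sum(axis=(0, 1, 2))
    dcols = (dout @ w.T).reshape(n, h, wd, k, k, c)
    pad = k // 2
    dxp = np.zeros((n, h + 2 * pad, wd + 2 * pad, c), dtype=dout.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + wd, :] += dcols[:, :, :, i, j, :]
    dx = dxp[:, pad : pad + h, pad : pad + wd, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray, p: int):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // p, p, w // p, p, c).transpose(0, 1, 3, 2, 4, 5)
    flat = xr.reshape(n, h // p, w // p, p * p, c)
    idx = flat.argmax(axis=3)
    out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def _pool_backward(dout, idx, x_shape, p: int):
    n, h, w, c = x_shape
    dflat = np.zeros((n, h // p, w // p, p * p, c), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = (
        dflat.reshape(n, h // p, w // p, p, p, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h, w, c)
    )
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Cnn6:
    """The six-layer classifier: weights, forward pass and backpropagation."""

    def __init__(self, spec: Cnn6Spec | None = None, seed: int = 0):
        self.spec = spec or Cnn6Spec()
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        k = self.spec.kernel_px
        c_in = 3
        for i, c_out in enumerate(self.spec.conv_channels):
            fan_in = k * k * c_in
            self.params[f"conv{i}_w"] = (
                rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float64)
            self.params[f"conv{i}_b"] = np.zeros(c_out)
            c_in = c_out
        nf = self.spec.flat_features
        self.params["fc1_w"] = (
            rng.standard_normal((nf, self.spec.fc_hidden)) * np.sqrt(2.0 / nf)
        ).astype(np.float64)
        self.params["fc1_b"] = np.zeros(self.spec.fc_hidden)
        self.params["fc2_w"] = (
            rng.standard_normal((self.spec.fc_hidden, self.spec.n_classes))
            * np.sqrt(2.0 / self.spec.fc_hidden)
        ).astype(np.float64)
        self.params["fc2_b"] = np.zeros(self.spec.n_classes)

    # -- inference ---------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        s = self.spec.input_side_px
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != s or x.shape[2] != s or x.shape[3] != 3:
            raise ValueError(
                f"input must be (N, {s}, {s}, 3) to match the model input side, "
                f"got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, want_cache: bool = False):
        x = self._check_input(x)
        k, p = self.spec.kernel_px, self.spec.pool_px
        cache: list = []
        h = x
        for i in range(N_CONV_STAGES):
            w, b = self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]
            z, cols = _conv_forward(h, w, b, k)
            a = np.maximum(z, 0.0)
            pooled, idx = _pool_forward(a, p)
            if want_cache:
                cache.append((h.shape, cols, z, a.shape, idx))
            h = pooled
        n = h.shape[0]
        flat = h.reshape(n, -1)
        z1 = flat @ self.params["fc1_w"] + self.params["fc1_b"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ self.params["fc2_w"] + self.params["fc2_b"]
        if want_cache:
            return logits, (cache, h.shape, flat, z1, a1)
        return logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._check_input(x)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    # -- training ----------------------------------------------------------

    def loss_and_gradients(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy over the batch plus gradients for every weight."""
        logits, (cache, h_shape, flat, z1, a1) = self.forward(x, want_cache=True)
        n = logits.shape[0]
        probs = softmax(logits)
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads["fc2_w"] = a1.T @ dlogits
        grads["fc2_b"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.params["fc2_w"].T
        dz1 = da1 * (z1 > 0)
        grads["fc1_w"] = flat.T @ dz1
        grads["fc1_b"] = dz1.sum(axis=0)
        dflat = dz1 @ self.params["fc1_w"].T
        dh = dflat.reshape(h_shape)
        k, p = self.spec.kernel_px, self.spec.pool_px
        for i in reversed(range(N_CONV_STAGES)):
            x_shape, cols, z, a_shape, idx = cache[i]
            da = _pool_backward(dh, idx, a_shape, p)
            dz = da * (z > 0)
            dh, dw, db = _conv_backward(dz, cols, x_shape, self.params[f"conv{i}_w"], k)
            grads[f"conv{i}_w"] = dw
            grads[f"conv{i}_b"] = db
        return loss, grads

    # -- bookkeeping -------------------------------------------------------

    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            if k not in weights:
                raise KeyError(f"missing weight {k!r}")
            if weights[k].shape != self.params[k].shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k] = weights[k].copy()


@dataclass
class Adam:
    """Adam optimizer over a named parameter dict."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        for k, g in grads.items():
            if k not in self._m:
                self._m[k] = np.zeros_like(g)
                self._v[k] = np.zeros_like(g)
            self._m[k] = self.beta1 * self._m[k] + (1 - self.beta1) * g
            self._v[k] = self.beta2 * self._v[k] + (1 - self.beta2) * g * g
            mhat = self._m[k] / (1 - self.beta1**self._t)
            vhat = self._v[k] / (1 - self.beta2**self._t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_cnn6(spec: Cnn6Spec | None = None, seed: int = 0) -> Cnn6:
    """Construct a CNN6 with seeded He-normal weights."""
    return Cnn6(spec=spec, seed=seed)
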