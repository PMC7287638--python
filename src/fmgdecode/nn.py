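"""Compact NumPy neural-network engine for the dual-output models.

Implements exactly the layers the decoding models need — 2-D convolution
(3x3, same padding), 2x2 max pooling, dense layers, and a gated recurrent
unit (GRU) — together with reverse-mode gradients, the RMSprop optimizer and
the weighted joint loss (cross-entropy for the gesture head, mean squared
error for the angle head). Everything is float32 and fully seeded: weight
initialization (Glorot uniform), minibatch shuffling and dropout masks all
draw from one generator, so training is bit-reproducible on a given machine.

Layers follow a minimal protocol: ``forward(x, train)`` caches what the
backward pass needs, ``backward(dy)`` returns the input gradient and fills
``grads`` aligned with ``params``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "softmax",
    "mse_loss",
    "cross_entropy_loss",
    "total_loss",
    "Dense",
    "Conv2D",
    "MaxPool2",
    "Flatten",
    "GRU",
    "RMSprop",
    "DualHeadNet",
    "EPSILON",
]

#: clipping floor for probabilities inside the log of the cross entropy
EPSILON = 1e-7


# ---------------------------------------------------------------------------
# losses (Eq.-level primitives, usable standalone as oracles)
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax: exp(z_i - max z) / sum_j exp(z_j - max z)."""
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error (1/n) * sum (y_i - y_hat_i)^2."""
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - y_hat) ** 2))


def cross_entropy_loss(one_hot: np.ndarray, p: np.ndarray, eps: float = EPSILON) -> float:
    """Categorical cross entropy -(1/n) * sum_i sum_j y_ij log p_ij.

    Probabilities are clipped to [eps, 1 - eps] before the log.
    """
    one_hot = np.asarray(one_hot, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if one_hot.shape != p.shape or one_hot.ndim != 2:
        raise ValueError(f"shape mismatch: {one_hot.shape} vs {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(one_hot * np.log(p)).sum() / one_hot.shape[0])


def total_loss(loss_c: float, loss_r: float, w_c: float, w_r: float) -> float:
    """Weighted joint loss w_c * loss_c + w_r * loss_r."""
    if w_c < 0 or w_r < 0:
        raise ValueError("loss weights must be non-negative")
    return w_c * loss_c + w_r * loss_r


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense:
    """Fully connected layer, optional rectifier activation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = False):
        self.w = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x = None
        self._pre = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        out = x @ self.w + self.b
        if self.relu:
            self._pre = out
            out = np.maximum(out, 0.0)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._pre > 0)
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Conv2D:
    """3x3 convolution with same padding and rectifier activation.

    Input/output layout is channels-last: [batch, H, W, C]. Implemented with
    im2col so both passes are single matrix products; the input gradient is
    the full correlation with the spatially flipped kernel.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3,
                 input_grad: bool = True):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        #: first-layer convolutions can skip the (unused) input gradient
        self.input_grad = input_grad
        self.c_in, self.c_out = c_in, c_out
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.w = _glorot(rng, fan_in, fan_out, (k, k, c_in, c_out))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols = None
        self._pre = None
        self._shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """Gather k x k patches as [B*H*W, k*k*C] via k^2 slab copies
        (much faster than a strided 6-D gather)."""
        k = self.k
        p = k // 2
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((b, h, w, k * k, c), dtype=x.dtype)
        for u in range(k):
            for v in range(k):
                cols[:, :, :, u * k + v, :] = xp[:, u : u + h, v : v + w, :]
        return cols.reshape(b * h * w, k * k * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, _ = x.shape
        self._shape = x.shape
        cols = self._im2col(x)
        self._cols = cols if train else None
        pre = cols @ self.w.reshape(-1, self.c_out) + self.b
        pre = pre.reshape(b, h, w, self.c_out)
        self._pre = pre if train else None
        return np.maximum(pre, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, _ = self._shape
        k = self.k
        dy = dy * (self._pre > 0)
        dy_flat = dy.reshape(b * h * w, self.c_out)
        self.grads[0][...] = (self._cols.T @ dy_flat).reshape(self.w.shape)
        self.grads[1][...] = dy_flat.sum(axis=0)
        if not self.input_grad:
            return None
        # input gradient: correlate padded dy with the flipped kernel
        p = k // 2
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((b, h, w, k * k, self.c_out), dtype=dy.dtype)
        for u in range(k):
            for v in range(k):
                cols[:, :, :, u * k + v, :] = dyp[:, u : u + h, v : v + w, :]
        cols = cols.reshape(b * h * w, k * k * self.c_out)
        # rows (u, v, c_out) -> columns c_in of the spatially flipped kernel
        w_back = np.flip(self.w, axis=(0, 1)).transpose(0, 1, 3, 2).reshape(-1, self.c_in)
        dx = (cols @ w_back).reshape(b, h, w, self.c_in)
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2, floor division on odd spatial dims.

    Degenerate inputs with both spatial dims below 2 pass through unchanged
    (needed for very small movement images in channel-ablation runs).
    """

    params: list = []
    grads: list = []

    def __init__(self):
        self._mask = None
        self._shape = None
        self._skip = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        if h < 2 or w < 2:
            self._skip = True
            return x
        self._skip = False
        h2, w2 = h // 2, w // 2
        self._shape = x.shape
        x4 = (
            x[:, : 2 * h2, : 2 * w2, :]
            .reshape(b, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h2, w2, 4, c)
        )
        idx = x4.argmax(axis=3)
        out = np.take_along_axis(x4, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._mask = idx
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._skip:
            return dy
        b, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        dx4 = np.zeros((b, h2, w2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dx4, self._mask[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = np.zeros((b, h, w, c), dtype=dy.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dx4.reshape(b, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(
                b, 2 * h2, 2 * w2, c
            )
        )
        return dx


class Flatten:
    params: list = []
    grads: list = []

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GRU:
    """Single gated-recurrent-unit layer returning the final hidden state.

    Input is [batch, timesteps, features]. Gates follow the classic
    formulation (update gate z, reset gate r, candidate with the reset gate
    applied to the recurrent term). ``dropout`` masks layer inputs and
    ``recurrent_dropout`` masks the hidden state entering the gates; both are
    inverted-dropout masks drawn once per batch and shared across timesteps,
    active only during training.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 dropout: float = 0.0, recurrent_dropout: float = 0.0):
        self.n_in, self.units = n_in, units
        self.dropout, self.recurrent_dropout = dropout, recurrent_dropout
        self.rng = rng
        self.wx = _glorot(rng, n_in, 3 * units, (n_in, 3 * units))
        # orthogonal-ish recurrent init keeps early dynamics stable
        a = rng.standard_normal((units, 3 * units)).astype(np.float32)
        self.wh = (a / math.sqrt(units)).astype(np.float32)
        self.b = np.zeros(3 * units, dtype=np.float32)
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        u = self.units
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mx = (self.rng.random((b, self.n_in)) < keep) / keep
        else:
            mx = None
        if train and self.recurrent_dropout > 0:
            keep = 1.0 - self.recurrent_dropout
            mh = (self.rng.random((b, u)) < keep) / keep
        else:
            mh = None
        h = np.zeros((b, u), dtype=np.float32)
        steps = []
        for i in range(t):
            xi = x[:, i, :] * mx if mx is not None else x[:, i, :]
            hd = h * mh if mh is not None else h
            gx = xi @ self.wx + self.b
            gh = hd @ self.wh
            z = _sigmoid(gx[:, :u] + gh[:, :u])
            r = _sigmoid(gx[:, u : 2 * u] + gh[:, u : 2 * u])
            c = np.tanh(gx[:, 2 * u :] + r * gh[:, 2 * u :])
            h_new = z * h + (1.0 - z) * c
            steps.append((xi, hd, h, z, r, c, gh[:, 2 * u :]))
            h = h_new
        if train:
            self._cache = (x, mx, mh, steps)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        x, mx, mh, steps = self._cache
        b, t, _ = x.shape
        u = self.units
        for g in self.grads:
            g[...] = 0.0
        dx = np.zeros_like(x)
        dwx, dwh, db = self.grads
        for i in range(t - 1, -1, -1):
            xi, hd, h_prev, z, r, c, ghc = steps[i]
            dz = dh * (h_prev - c) * z * (1.0 - z)
            dc = dh * (1.0 - z) * (1.0 - c * c)
            dr = dc * ghc * r * (1.0 - r)
            dgx = np.concatenate([dz, dr, dc], axis=1)
            dgh = np.concatenate([dz, dr, dc * r], axis=1)
            dwx += xi.T @ dgx
            dwh += hd.T @ dgh
            db += dgx.sum(axis=0)
            dxi = dgx @ self.wx.T
            dhd = dgh @ self.wh.T
            dx[:, i, :] = dxi * mx if mx is not None else dxi
            dh = dh * z + (dhd * mh if mh is not None else dhd)
        return dx


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class RMSprop:
    """RMSprop: cache = rho*cache + (1-rho)*g^2; p -= lr * g / (sqrt(cache)+eps)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# shared trunk + two heads
# ---------------------------------------------------------------------------

class DualHeadNet:
    """A trunk (list of layers) feeding two parallel dense heads: a K-way
    softmax gesture classifier and a single-unit linear angle regressor.

    The joint training objective is w_c * cross-entropy + w_r * MSE; both head
    gradients flow back through the shared trunk.
    """

    def __init__(self, trunk: list, feature_dim: int, n_classes: int,
                 rng: np.random.Generator):
        self.trunk = trunk
        self.n_classes = n_classes
        self.head_c = Dense(feature_dim, n_classes, rng)
        self.head_r = Dense(feature_dim, 1, rng)
        self.layers = trunk + [self.head_c, self.head_r]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        h = x
        for layer in self.trunk:
            h = layer.forward(h, train=train)
        logits = self.head_c.forward(h, train=train)
        angle = self.head_r.forward(h, train=train)[:, 0]
        return logits, angle

    def backward(self, dlogits: np.ndarray, dangle: np.ndarray) -> None:
        dh = self.head_c.backward(dlogits) + self.head_r.backward(dangle[:, None])
        for layer in reversed(self.trunk):
            dh = layer.backward(dh)

    def loss_and_grads(
        self, x: np.ndarray, labels: np.ndarray, angles: np.ndarray,
        w_c: float, w_r: float,
    ) -> tuple[float, float, float]:
        """One forward/backward pass; fills ``grads``; returns
        (total, cross-entropy, mse) for the batch."""
        n = x.shape[0]
        logits, angle_pred = self.forward(x, train=True)
        p = softmax(logits)
        one_hot = np.zeros_like(p)
        one_hot[np.arange(n), labels] = 1.0
        ce = cross_entropy_loss(one_hot, p)
        mse = mse_loss(angles, angle_pred)
        resid = angle_pred - angles
        dlogits = (w_c * (p - one_hot) / n).astype(np.float32)
        dangle = (w_r * 2.0 * resid / n).astype(np.float32)
        self.backward(dlogits, dangle)
        return total_loss(ce, mse, w_c, w_r), ce, mse

    def predict(self, x: np.ndarray, batch_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
        """(class probabilities [n x K], angles [n]) in inference mode."""
        probs, angles = [], []
        for i in range(0, x.shape[0], batch_size):
            logits, ang = self.forward(x[i : i + batch_size], train=False)
            probs.append(softmax(logits))
            angles.append(ang)
        return np.concatenate(probs, axis=0), np.concatenate(angles)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w
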