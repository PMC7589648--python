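"""Compact NumPy neural-network layers used by the two classifiers.

Implements exactly what the classifiers need — valid-mode 3D convolution,
3x3x3 max pooling, dense layers, ReLU, inverted dropout, an LSTM with
backpropagation through time, softmax cross-entropy and Adam — on float32
arrays with explicit forward/backward passes.  Everything is driven by a
``numpy.random.Generator``, so training is bit-reproducible for a fixed
seed on a fixed NumPy build.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class AdamState:
    """Adam optimizer state over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class SGDState:
    """Plain SGD, available as a config alternative to Adam."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3):
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            p -= (self.lr * g).astype(p.dtype)


# ---------------------------------------------------------------------------
# Layers


class Conv3D:
    """Single-input-channel valid 3D convolution (cross-correlation),
    stride 1, ``n_filters`` output channels."""

    def __init__(self, rng: np.random.Generator, n_filters: int, kernel: int,
                 input_layer: bool = False):
        k = kernel
        fan_in = k * k * k
        self.W = glorot_uniform(rng, (n_filters, k, k, k), fan_in, n_filters)
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.kernel = k
        # the gradient w.r.t. the input is never consumed when this is the
        # first layer; skipping it saves the most expensive backward step
        self.input_layer = input_layer
        self._patches: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (B, D, H, W) -> (B, D-k+1, H-k+1, W-k+1, F)
        k = self.kernel
        patches = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
        self._patches = patches if train else None
        self._in_shape = x.shape
        out = np.tensordot(patches, self.W, axes=([4, 5, 6], [1, 2, 3]))
        out += self.b
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        patches = self._patches
        self.dW = np.tensordot(dout, patches, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.db = dout.sum(axis=(0, 1, 2, 3))
        if self.input_layer:
            return None
        B, Do, Ho, Wo, _ = dout.shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for kz in range(k):
            for ky in range(k):
                for kx in range(k):
                    w_k = self.W[:, kz, ky, kx]  # (F,)
                    dx[:, kz:kz + Do, ky:ky + Ho, kx:kx + Wo] += dout @ w_k
        return dx

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class MaxPool3D:
    """Non-overlapping 3D max pooling (kernel == stride), valid mode: the
    trailing remainder of each spatial axis is cropped."""

    def __init__(self, kernel: int):
        self.k = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        B, D, H, W, F = x.shape
        Do, Ho, Wo = D // k, H // k, W // k
        xc = x[:, : Do * k, : Ho * k, : Wo * k, :]
        win = xc.reshape(B, Do, k, Ho, k, Wo, k, F)
        win = win.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(B, Do, Ho, Wo, F, k * k * k)
        self._arg = np.argmax(win, axis=-1)
        self._in_shape = x.shape
        out = np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        B, D, H, W, F = self._in_shape
        Do, Ho, Wo = D // k, H // k, W // k
        dwin = np.zeros((B, Do, Ho, Wo, F, k * k * k), dtype=np.float32)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dxc = dwin.reshape(B, Do, Ho, Wo, F, k, k, k).transpose(0, 1, 5, 2, 6, 3, 7, 4)
        dxc = dxc.reshape(B, Do * k, Ho * k, Wo * k, F)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : Do * k, : Ho * k, : Wo * k, :] = dxc
        return dx

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rng: np.random.Generator, p: float):
        self.rng = rng
        self.p = p

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []


class Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


# ---------------------------------------------------------------------------
# LSTM


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM:
    """Single-layer LSTM over (B, T, n_in) sequences; emits the final
    hidden state.  Gate order in the stacked weight matrices: i, f, g, o.
    Forget-gate bias initialized to 1 (standard recipe for trainability).
    """

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        H = hidden
        self.Wx = glorot_uniform(rng, (n_in, 4 * H), n_in, H)
        self.Wh = glorot_uniform(rng, (H, 4 * H), H, H)
        self.b = np.zeros(4 * H, dtype=np.float32)
        self.b[H: 2 * H] = 1.0
        self.H = H

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        self._cache = []
        self._x = x
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H: 2 * H])
            g = np.tanh(z[:, 2 * H: 3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        B, T, n_in = self._x.shape
        H = self.H
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(self._x)
        dh = dh_last.astype(np.float32)
        dc = np.zeros((B, H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new = self._cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ],
                axis=1,
            ).astype(np.float32)
            dWx += self._x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        self.dWx, self.dWh, self.db_ = dWx, dWh, db
        return dx

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dWx, self.dWh, self.db_]


# ---------------------------------------------------------------------------
# Generic training loop


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)


def train_network(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    lr: float = 1e-3,
    max_epochs: int = 100,
    batch_size: int = 32,
    optimizer: str = "adam",
) -> list[float]:
    """Minibatch training with softmax cross-entropy; returns the per-epoch
    mean loss curve."""
    n = X.shape[0]
    params = net.params
    if optimizer == "adam":
        opt = AdamState(params, lr=lr)
    elif optimizer == "sgd":
        opt = SGDState(params, lr=lr)
    else:
        raise ValueError("optimizer must be 'adam' or 'sgd'")
    losses: list[float] = []
    for _ in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start: start + batch_size]
            logits = net.forward(X[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step(net.params, net.grads)
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    return losses
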