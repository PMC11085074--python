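"""Minimal seeded convolutional-network engine.

A small, self-contained implementation of the handful of layer types the
pair-image classifier needs: 3x3 same-padding convolutions, 2x2 max
pooling, dense layers, rectifier activations and a sigmoid
cross-entropy head, trained with Adam. Everything is plain numpy with a
single ``numpy.random.Generator``, so training is bit-reproducible for a
fixed seed, and gradients are exact (verified against finite differences
in the test suite).

Shapes follow the NCHW convention; images enter as (n, rows, cols) and are
given a singleton channel axis internally.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float64


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution with 'same' zero padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        # He initialisation, appropriate for rectifier activations
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.params = [w.astype(_DTYPE), np.zeros(out_ch, dtype=_DTYPE)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        out = cols @ self.params[0].T + self.params[1]
        self._cache = (x.shape, cols)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, w), cols = self._cache
        k, p = self.k, self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.grads[0][...] = dmat.T @ cols
        self.grads[1][...] = dmat.sum(axis=0)
        dcols = (dmat @ self.params[0]).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing odd rows/cols are dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        h2, w2 = h // s, w // s
        xt = x[:, :, : h2 * s, : w2 * s].reshape(n, c, h2, s, w2, s)
        patches = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, s * s)
        arg = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, w), arg = self._cache
        s = self.size
        h2, w2 = h // s, w // s
        dpatches = np.zeros((n, c, h2, w2, s * s), dtype=_DTYPE)
        np.put_along_axis(dpatches, arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=_DTYPE)
        dx[:, :, : h2 * s, : w2 * s] = (
            dpatches.reshape(n, c, h2, w2, s, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * s, w2 * s)
        )
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w.astype(_DTYPE), np.zeros(n_out, dtype=_DTYPE)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Network:
    """A plain layer sequence ending in a 1-unit linear head (logit)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        dout = dlogits[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty(x.shape[0], dtype=_DTYPE)
        for lo in range(0, x.shape[0], batch_size):
            out[lo : lo + batch_size] = _sigmoid(
                self.forward(x[lo : lo + batch_size])
            )
        return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    # softplus(z) - y*z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    dlogits = (_sigmoid(logits) - y) / n
    return loss, dlogits


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
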