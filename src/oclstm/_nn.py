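"""Minimal feed-forward layer primitives with hand-written gradients.

Shapes follow the window-encoder convention: activations are
``(batch, width, channels)`` until flattened.  Convolutions slide along the
window axis only with same-padding; pooling is ceil-mode along the same
axis (a trailing partial window is pooled as-is), so spatial width never
drops below 1.  Every layer caches what its backward pass needs; ``params``
and ``grads`` are parallel dicts so a single optimizer can walk them.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base: parameterized layers fill ``params``/``grads`` with same keys."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv1dSame(Layer):
    """1-D convolution along the window axis, same-padding, He init.

    Weight ``W`` has shape ``(k, in_ch, out_ch)``; output position ``t``
    sums ``x[t - left + j] @ W[j]`` over kernel offsets ``j``.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.params["W"] = rng.normal(0.0, scale, size=(kernel, in_ch, out_ch))
        self.params["b"] = np.zeros(out_ch)
        self._cache = None

    def forward(self, x, train=False):
        B, W, C = x.shape
        k = self.kernel
        left = (k - 1) // 2
        xp = np.zeros((B, W + k - 1, C), dtype=x.dtype)
        xp[:, left:left + W] = x
        out = np.broadcast_to(self.params["b"], (B, W, self.out_ch)).copy()
        Wk = self.params["W"]
        for j in range(k):
            out += xp[:, j:j + W] @ Wk[j]
        self._cache = (xp, W)
        return out

    def backward(self, dout):
        xp, W = self._cache
        B = xp.shape[0]
        k = self.kernel
        left = (k - 1) // 2
        Wk = self.params["W"]
        dW = np.zeros_like(Wk)
        dxp = np.zeros_like(xp)
        flat_dout = dout.reshape(-1, self.out_ch)
        for j in range(k):
            seg = xp[:, j:j + W].reshape(-1, self.in_ch)
            dW[j] = seg.T @ flat_dout
            dxp[:, j:j + W] += dout @ Wk[j].T
        self.grads["W"] = dW
        self.grads["b"] = flat_dout.sum(axis=0)
        return dxp[:, left:left + W]

    def out_shape(self, in_shape):
        B, W, _ = in_shape
        return (B, W, self.out_ch)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Pool1d(Layer):
    """Ceil-mode max or average pooling of stride = size along the window axis."""

    def __init__(self, size: int = 2, mode: str = "max"):
        super().__init__()
        if mode not in ("max", "average"):
            raise ValueError(f"pooling mode must be 'max' or 'average', got {mode!r}")
        self.size, self.mode = size, mode

    @staticmethod
    def out_width(width: int, size: int) -> int:
        return -(-width // size)  # ceil division

    def forward(self, x, train=False):
        B, W, C = x.shape
        s = self.size
        Wo = self.out_width(W, s)
        pad = Wo * s - W
        if self.mode == "max":
            xp = np.concatenate([x, np.full((B, pad, C), -np.inf, dtype=x.dtype)], axis=1) if pad else x
            blocks = xp.reshape(B, Wo, s, C)
            idx = blocks.argmax(axis=2)
            out = np.take_along_axis(blocks, idx[:, :, None, :], axis=2)[:, :, 0, :]
            self._cache = (idx, W, pad)
        else:
            xp = np.concatenate([x, np.zeros((B, pad, C), dtype=x.dtype)], axis=1) if pad else x
            blocks = xp.reshape(B, Wo, s, C)
            # average over the *actual* members of each window
            counts = np.full(Wo, s, dtype=x.dtype)
            if pad:
                counts[-1] = s - pad
            out = blocks.sum(axis=2) / counts[None, :, None]
            self._cache = (counts, W, pad)
        return out

    def backward(self, dout):
        B, Wo, C = dout.shape
        s = self.size
        if self.mode == "max":
            idx, W, pad = self._cache
            dxp = np.zeros((B, Wo, s, C), dtype=dout.dtype)
            np.put_along_axis(dxp, idx[:, :, None, :], dout[:, :, None, :], axis=2)
            return dxp.reshape(B, Wo * s, C)[:, :W]
        counts, W, pad = self._cache
        dxp = np.repeat(dout / counts[None, :, None], s, axis=1)
        return dxp[:, :W]

    def out_shape(self, in_shape):
        B, W, C = in_shape
        return (B, self.out_width(W, self.size), C)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def out_shape(self, in_shape):
        B = in_shape[0]
        return (B, int(np.prod(in_shape[1:])))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        if zero_init:
            self.params["W"] = np.zeros((n_in, n_out))
        else:
            self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def out_shape(self, in_shape):
        return (in_shape[0], self.n_out)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    picked = probs[np.arange(n), labels]
    if weights is None:
        loss = float(-np.mean(np.log(picked + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
    else:
        w = weights[labels]
        wsum = w.sum()
        loss = float(-(w * np.log(picked + eps)).sum() / wsum)
        dlogits = probs * w[:, None]
        dlogits[np.arange(n), labels] -= w
        dlogits /= wsum
    return loss, dlogits


class SGDMomentum:
    """SGD with classical momentum and L2 weight decay (decay on W, not biases)."""

    def __init__(self, lr: float, momentum: float = 0.9, l2: float = 0.0):
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self._vel: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers) -> None:
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            vel = self._vel.setdefault(li, {k: np.zeros_like(v) for k, v in layer.params.items()})
            for key, param in layer.params.items():
                g = layer.grads[key]
                if self.l2 and key != "b":
                    g = g + self.l2 * param
                vel[key] = self.momentum * vel[key] - self.lr * g
                param += vel[key]


class Adam:
    """Adam over flat param/grad dict pairs (used by the recurrent stage)."""

    def __init__(self, lr: float = 1e-2, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for key, param in params.items():
            g = grads[key]
            m = self._m.setdefault(key, np.zeros_like(param))
            v = self._v.setdefault(key, np.zeros_like(param))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


def numerical_gradient(f, param: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar ``f()`` w.r.t. ``param`` in place."""
    grad = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    while not it.finished:
        ix = it.multi_index
        orig = param[ix]
        param[ix] = orig + eps
        fp = f()
        param[ix] = orig - eps
        fm = f()
        param[ix] = orig
        grad[ix] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
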