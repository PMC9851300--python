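"""A small, seeded, CPU-only neural-network engine on numpy.

Implements exactly the layer set the package's three networks need:
1-D convolution, max pooling, ReLU, flatten, dense (with optional l1 kernel
and l2 bias penalties), batch normalisation and dropout; SGD-with-momentum
and Adam optimisers; sigmoid/binary-cross-entropy and
softmax/categorical-cross-entropy heads.

Conventions: convolution/pooling tensors are (batch, channels, length);
dense tensors are (batch, features).  All floating state is float32.  Every
source of randomness (weight init, epoch shuffling, dropout masks) flows
from the single generator owned by :class:`Model`, so identical seed +
data + config reproduces identical weights.
"""

from __future__ import annotations

import json

import numpy as np

_EPS = 1e-7


# ---------------------------------------------------------------- layers


class Layer:
    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def forward(self, x, train: bool, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def param_items(self):
        """Yield (value, grad, l1, l2) tuples; grads are set by backward."""
        return []

    def spec(self) -> dict:
        raise NotImplementedError

    def get_state(self) -> list[np.ndarray]:
        return []

    def set_state(self, arrays: list[np.ndarray]) -> None:
        pass


class Conv1D(Layer):
    """Valid cross-correlation along the length axis."""

    def __init__(self, c_in: int, c_out: int, kernel: int):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.w = np.zeros((c_out, c_in, kernel), dtype=np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def init(self, rng):
        fan_in = self.c_in * self.kernel
        # He init: suits the all-ReLU stacks used here
        self.w = (rng.standard_normal(self.w.shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(self.c_out, dtype=np.float32)

    _SAMPLE_CHUNK = 8  # samples per im2col block, bounds peak memory

    def _patches(self, x):
        # (b, P, c_in * kernel) contiguous patch matrix
        sl = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        return np.ascontiguousarray(sl.transpose(0, 2, 1, 3)).reshape(
            x.shape[0], -1, self.c_in * self.kernel
        )

    def forward(self, x, train, rng=None):
        self._x = x
        B, _, L = x.shape
        P = L - self.kernel + 1
        w2 = self.w.reshape(self.c_out, -1)
        y = np.empty((B, self.c_out, P), dtype=np.float32)
        for lo in range(0, B, self._SAMPLE_CHUNK):
            hi = min(lo + self._SAMPLE_CHUNK, B)
            y[lo:hi] = (self._patches(x[lo:hi]) @ w2.T).transpose(0, 2, 1)
        y += self.b[None, :, None]
        return y

    def backward(self, dy, need_dx: bool = True):
        x = self._x
        B, _, L = x.shape
        P = L - self.kernel + 1
        w2 = self.w.reshape(self.c_out, -1)
        self.db = dy.sum(axis=(0, 2))
        dw2 = np.zeros_like(w2)
        dx = np.zeros_like(x) if need_dx else None
        for lo in range(0, B, self._SAMPLE_CHUNK):
            hi = min(lo + self._SAMPLE_CHUNK, B)
            dyt = np.ascontiguousarray(dy[lo:hi].transpose(0, 2, 1))  # (b, P, C_out)
            pat = self._patches(x[lo:hi])
            dw2 += np.tensordot(dyt, pat, axes=([0, 1], [0, 1]))
            if need_dx:
                dpat = dyt @ w2  # (b, P, c_in * kernel)
                dpat = dpat.reshape(hi - lo, P, self.c_in, self.kernel)
                for j in range(self.kernel):
                    dx[lo:hi, :, j : j + P] += dpat[:, :, :, j].transpose(0, 2, 1)
        self.dw = dw2.reshape(self.w.shape)
        self._x = None
        return dx

    def param_items(self):
        return [(self.w, self.dw, 0.0, 0.0), (self.b, self.db, 0.0, 0.0)]

    def spec(self):
        return {"type": "conv1d", "c_in": self.c_in, "c_out": self.c_out, "kernel": self.kernel}

    def get_state(self):
        return [self.w, self.b]

    def set_state(self, arrays):
        self.w, self.b = (a.astype(np.float32) for a in arrays)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing fragment shorter than the
    pool width is dropped."""

    def __init__(self, width: int):
        self.width = width

    def forward(self, x, train, rng=None):
        B, C, L = x.shape
        P = L // self.width
        xr = x[:, :, : P * self.width].reshape(B, C, P, self.width)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, L = self._shape
        P = L // self.width
        dx = np.zeros((B, C, P, self.width), dtype=np.float32)
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        out = np.zeros((B, C, L), dtype=np.float32)
        out[:, :, : P * self.width] = dx.reshape(B, C, P * self.width)
        return out

    def spec(self):
        return {"type": "maxpool1d", "width": self.width}


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def spec(self):
        return {"type": "relu"}


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def spec(self):
        return {"type": "flatten"}


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, l1: float = 0.0, l2_bias: float = 0.0):
        self.n_in, self.n_out = n_in, n_out
        self.l1, self.l2_bias = l1, l2_bias
        self.w = np.zeros((n_in, n_out), dtype=np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def init(self, rng):
        limit = np.sqrt(6.0 / (self.n_in + self.n_out))
        self.w = rng.uniform(-limit, limit, size=self.w.shape).astype(np.float32)
        self.b = np.zeros(self.n_out, dtype=np.float32)

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx

    def param_items(self):
        return [(self.w, self.dw, self.l1, 0.0), (self.b, self.db, 0.0, self.l2_bias)]

    def spec(self):
        return {
            "type": "dense", "n_in": self.n_in, "n_out": self.n_out,
            "l1": self.l1, "l2_bias": self.l2_bias,
        }

    def get_state(self):
        return [self.w, self.b]

    def set_state(self, arrays):
        self.w, self.b = (a.astype(np.float32) for a in arrays)


class BatchNorm(Layer):
    """Batch normalisation over the batch axis of (B, D) activations."""

    def __init__(self, dim: int, momentum: float = 0.99):
        self.dim, self.momentum = dim, momentum
        self.gamma = np.ones(dim, dtype=np.float32)
        self.beta = np.zeros(dim, dtype=np.float32)
        self.run_mean = np.zeros(dim, dtype=np.float32)
        self.run_var = np.ones(dim, dtype=np.float32)

    def forward(self, x, train, rng=None):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.run_mean = (m * self.run_mean + (1 - m) * mu).astype(np.float32)
            self.run_var = (m * self.run_var + (1 - m) * var).astype(np.float32)
        else:
            mu, var = self.run_mean, self.run_var
        self._inv_std = 1.0 / np.sqrt(var + _EPS)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        B = dy.shape[0]
        xhat = self._xhat
        self.dgamma = (dy * xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        dx = (
            self._inv_std / B
            * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )
        self._xhat = None
        return dx.astype(np.float32)

    def param_items(self):
        return [(self.gamma, self.dgamma, 0.0, 0.0), (self.beta, self.dbeta, 0.0, 0.0)]

    def spec(self):
        return {"type": "batchnorm", "dim": self.dim, "momentum": self.momentum}

    def get_state(self):
        return [self.gamma, self.beta, self.run_mean, self.run_var]

    def set_state(self, arrays):
        self.gamma, self.beta, self.run_mean, self.run_var = (
            a.astype(np.float32) for a in arrays
        )


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)

    def spec(self):
        return {"type": "dropout", "rate": self.rate}


_LAYER_TYPES = {
    "conv1d": lambda s: Conv1D(s["c_in"], s["c_out"], s["kernel"]),
    "maxpool1d": lambda s: MaxPool1D(s["width"]),
    "relu": lambda s: ReLU(),
    "flatten": lambda s: Flatten(),
    "dense": lambda s: Dense(s["n_in"], s["n_out"], s["l1"], s["l2_bias"]),
    "batchnorm": lambda s: BatchNorm(s["dim"], s["momentum"]),
    "dropout": lambda s: Dropout(s["rate"]),
}


# ------------------------------------------------------------ optimisers


class SGD:
    """Stochastic gradient descent with classical momentum.

    Gradients are rescaled when their global norm exceeds ``clipnorm``;
    without this, one oversized early step through the deep ReLU stack can
    silence the network for good (dead units, zero gradient thereafter).
    """

    def __init__(self, lr: float = 0.01, momentum: float = 0.9, clipnorm: float = 5.0):
        self.lr, self.momentum, self.clipnorm = lr, momentum, clipnorm
        self._vel: dict[int, np.ndarray] = {}

    def step(self, items):
        scale = 1.0
        if self.clipnorm:
            total = np.sqrt(sum(float(np.sum(g * g)) for _, g, _, _ in items))
            if total > self.clipnorm:
                scale = self.clipnorm / total
        for value, grad, l1, l2 in items:
            g = grad * scale
            if l1:
                g = g + l1 * np.sign(value)
            if l2:
                g = g + 2.0 * l2 * value
            v = self._vel.setdefault(id(value), np.zeros_like(value))
            v *= self.momentum
            v -= self.lr * g
            value += v


class Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999):
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, items):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for value, grad, l1, l2 in items:
            g = grad
            if l1:
                g = g + l1 * np.sign(value)
            if l2:
                g = g + 2.0 * l2 * value
            m = self._m.setdefault(id(value), np.zeros_like(value))
            v = self._v.setdefault(id(value), np.zeros_like(value))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            value -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


# ----------------------------------------------------------------- model


class Model:
    """A sequential network with a sigmoid/BCE or softmax/CE head.

    ``loss`` is ``"bce"`` (final layer emits one logit per sample) or
    ``"softmax_ce"`` (final layer emits one logit per class).
    """

    def __init__(self, layers: list[Layer], loss: str, seed: int = 0):
        if loss not in ("bce", "softmax_ce"):
            raise ValueError(f"unknown loss {loss!r}")
        self.layers = layers
        self.loss = loss
        self._rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(self._rng)

    # -- forward / loss

    def _forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train, rng=self._rng)
        return x

    def predict_proba(self, X, batch_size: int = 32) -> np.ndarray:
        """Probabilities: shape (n,) for BCE, (n, n_classes) for softmax."""
        outs = []
        for lo in range(0, len(X), batch_size):
            z = self._forward(np.asarray(X[lo : lo + batch_size], dtype=np.float32), train=False)
            if self.loss == "bce":
                outs.append(1.0 / (1.0 + np.exp(-z[:, 0])))
            else:
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs, axis=0)

    def _loss_and_grad(self, z, y):
        B = z.shape[0]
        if self.loss == "bce":
            p = 1.0 / (1.0 + np.exp(-z[:, 0]))
            loss = -np.mean(y * np.log(p + _EPS) + (1 - y) * np.log(1 - p + _EPS))
            dz = ((p - y) / B).astype(np.float32)[:, None]
        else:
            zs = z - z.max(axis=1, keepdims=True)
            e = np.exp(zs)
            p = e / e.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(p[np.arange(B), y] + _EPS))
            dz = p
            dz[np.arange(B), y] -= 1.0
            dz = (dz / B).astype(np.float32)
        return float(loss), dz

    # -- training

    def fit(self, X, y, epochs: int, batch_size: int, optimizer) -> dict:
        """Mini-batch training; returns ``{"loss": [per-epoch mean]}``."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        n = len(X)
        history: dict[str, list[float]] = {"loss": []}
        for _ in range(epochs):
            order = self._rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                z = self._forward(X[idx], train=True)
                loss, dz = self._loss_and_grad(z, y[idx])
                grad = dz
                for li in range(len(self.layers) - 1, -1, -1):
                    layer = self.layers[li]
                    if li == 0 and isinstance(layer, Conv1D):
                        layer.backward(grad, need_dx=False)  # input needs no gradient
                    else:
                        grad = layer.backward(grad)
                items = [it for layer in self.layers for it in layer.param_items()]
                optimizer.step(items)
                epoch_loss += loss * len(idx)
                seen += len(idx)
            history["loss"].append(epoch_loss / seen)
        return history

    # -- persistence

    def save(self, path) -> None:
        arch = json.dumps({"loss": self.loss, "layers": [l.spec() for l in self.layers]})
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, a in enumerate(layer.get_state()):
                arrays[f"l{i}_{j}"] = a
        np.savez(path, arch=np.frombuffer(arch.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as data:
            arch = json.loads(bytes(data["arch"]).decode())
            model = cls.__new__(cls)
            model.loss = arch["loss"]
            model._rng = np.random.default_rng(0)
            model.layers = [_LAYER_TYPES[s["type"]](s) for s in arch["layers"]]
            for i, layer in enumerate(model.layers):
                n_state = len(layer.get_state())
                if n_state:
                    layer.set_state([data[f"l{i}_{j}"] for j in range(n_state)])
        return model
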