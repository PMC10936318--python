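"""Minimal NumPy neural-network engine for the angle estimators.

Implements exactly the layer vocabulary the estimators need — LSTM, time-axis
convolution, max-pooling over time, dense, dropout, flatten — with manual
backpropagation and an Adam optimizer.  Tensors are time-major:
``(batch, timesteps, channels)``.  All stochastic behaviour (initialisation,
dropout masks, shuffling) flows from explicit NumPy generators, so training
is reproducible on a single device.

This is deliberately a small engine, not a framework: layers expose
``forward``/``backward`` and a flat parameter dict, and ``Sequential`` wires
them together.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ModelShapeError


def _glorot(rng, shape, fan_in, fan_out, kind="glorot_uniform"):
    if kind == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)
    if kind == "glorot_normal":
        sd = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, sd, size=shape)
    raise ModelShapeError(f"unknown initializer {kind!r}")


def _activate(z, kind):
    if kind is None or kind == "linear":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "leaky_relu":
        return np.where(z > 0, z, 0.2 * z)
    if kind == "tanh":
        return np.tanh(z)
    raise ModelShapeError(f"unknown activation {kind!r}")


def _activate_grad(z, kind):
    if kind is None or kind == "linear":
        return np.ones_like(z)
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "leaky_relu":
        return np.where(z > 0, 1.0, 0.2)
    if kind == "tanh":
        t = np.tanh(z)
        return 1.0 - t * t
    raise ModelShapeError(f"unknown activation {kind!r}")


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, rng, in_shape):  # returns out_shape
        raise NotImplementedError

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer on (B, D) inputs."""

    def __init__(self, units, activation=None, init="glorot_uniform", name="dense"):
        super().__init__()
        self.units = units
        self.activation = activation
        self.init = init
        self.name = name

    def build(self, rng, in_shape):
        if len(in_shape) != 1:
            raise ModelShapeError(f"{self.name}: expected flat input, got {in_shape}")
        d = in_shape[0]
        self.params = {
            "W": _glorot(rng, (d, self.units), d, self.units, self.init),
            "b": np.zeros(self.units),
        }
        return (self.units,)

    def forward(self, x, train=False, rng=None):
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        return _activate(self._z, self.activation)

    def backward(self, dy):
        dz = dy * _activate_grad(self._z, self.activation)
        self.grads = {"W": self._x.T @ dz, "b": dz.sum(axis=0)}
        return dz @ self.params["W"].T


class Flatten(Layer):
    name = "flatten"

    def build(self, rng, in_shape):
        self._in_shape = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, name="dropout"):
        super().__init__()
        self.rate = float(rate)
        self.name = name

    def build(self, rng, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ConvTime(Layer):
    """1-D convolution along the time axis ((k, 1) kernels, valid padding)."""

    def __init__(self, filters, kernel, activation="relu", init="glorot_uniform",
                 name="conv"):
        super().__init__()
        self.filters = filters
        self.kernel = int(kernel)
        self.activation = activation
        self.init = init
        self.name = name

    def build(self, rng, in_shape):
        if len(in_shape) != 2:
            raise ModelShapeError(f"{self.name}: expected (T, C) input, got {in_shape}")
        T, C = in_shape
        if self.kernel > T:
            raise ModelShapeError(
                f"{self.name}: kernel {self.kernel} exceeds time dimension {T}"
            )
        fan_in = self.kernel * C
        self.params = {
            "W": _glorot(rng, (fan_in, self.filters), fan_in, self.filters, self.init),
            "b": np.zeros(self.filters),
        }
        self._C = C
        return (T - self.kernel + 1, self.filters)

    def forward(self, x, train=False, rng=None):
        B, T, C = x.shape
        k = self.kernel
        patches = sliding_window_view(x, k, axis=1)          # (B, T', C, k)
        patches = np.swapaxes(patches, 2, 3).reshape(B, T - k + 1, k * C)
        self._patches = patches
        self._z = patches @ self.params["W"] + self.params["b"]
        return _activate(self._z, self.activation)

    def backward(self, dy):
        dz = dy * _activate_grad(self._z, self.activation)
        B, Tp, F = dz.shape
        k, C = self.kernel, self._C
        p2 = self._patches.reshape(-1, k * C)
        dz2 = dz.reshape(-1, F)
        self.grads = {"W": p2.T @ dz2, "b": dz2.sum(axis=0)}
        W = self.params["W"].reshape(k, C, F)
        dx = np.zeros((B, Tp + k - 1, C))
        for j in range(k):
            dx[:, j:j + Tp, :] += dz @ W[j].T
        return dx


class MaxPoolTime(Layer):
    """Max pooling over non-overlapping time pairs ((2, 1) pool)."""

    def __init__(self, pool=2, name="maxpool"):
        super().__init__()
        self.pool = int(pool)
        self.name = name

    def build(self, rng, in_shape):
        T, C = in_shape
        if T < self.pool:
            raise ModelShapeError(f"{self.name}: pool {self.pool} exceeds time {T}")
        return (T // self.pool, C)

    def forward(self, x, train=False, rng=None):
        B, T, C = x.shape
        p = self.pool
        T2 = T // p
        xr = x[:, :T2 * p].reshape(B, T2, p, C)
        self._arg = xr.argmax(axis=2)
        self._in_T = T
        return xr.max(axis=2)

    def backward(self, dy):
        B, T2, C = dy.shape
        p = self.pool
        dxr = np.zeros((B, T2, p, C))
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, self._in_T, C))
        dx[:, :T2 * p] = dxr.reshape(B, T2 * p, C)
        return dx


class LSTM(Layer):
    """Standard LSTM (input/forget/cell/output gates, forget bias 1)."""

    def __init__(self, units, return_sequences=False, init="glorot_uniform",
                 name="lstm"):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.init = init
        self.name = name

    def build(self, rng, in_shape):
        if len(in_shape) != 2:
            raise ModelShapeError(f"{self.name}: expected (T, C) input, got {in_shape}")
        T, D = in_shape
        H = self.units
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.params = {
            "Wx": _glorot(rng, (D, 4 * H), D, 4 * H, self.init),
            "Wh": _glorot(rng, (H, 4 * H), H, 4 * H, self.init),
            "b": b,
        }
        return (T, H) if self.return_sequences else (H,)

    def forward(self, x, train=False, rng=None):
        B, T, D = x.shape
        H = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xp = x.reshape(B * T, D) @ Wx
        xp = xp.reshape(B, T, 4 * H)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = xp[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            hc = np.tanh(c)
            h = o * hc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, h_prev, hc))
        self._x = x
        self._cache = cache
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, D = x.shape
        H = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWh = np.zeros_like(Wh)
        dzs = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            i, f, g, o, c_prev, h_prev, hc = self._cache[t]
            if self.return_sequences:
                dh = dh_next + dy[:, t]
            else:
                dh = dh_next + (dy if t == T - 1 else 0.0)
            do = dh * hc
            dc = dc_next + dh * o * (1.0 - hc * hc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dzs[:, t] = dz
            dWh += h_prev.T @ dz
            dh_next = dz @ Wh.T
        dz2 = dzs.reshape(B * T, 4 * H)
        self.grads = {
            "Wx": x.reshape(B * T, D).T @ dz2,
            "Wh": dWh,
            "b": dz2.sum(axis=0),
        }
        return (dz2 @ Wx.T).reshape(B, T, D)


class Sequential:
    """Ordered layer stack with shape inference at construction."""

    def __init__(self, layers, input_shape, seed=0):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        self.rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.build(self.rng, shape)
        self.output_shape = shape

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=self.rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [
            (li, k, layer.params[k])
            for li, layer in enumerate(self.layers)
            for k in sorted(layer.params)
        ]

    def num_params(self) -> int:
        return int(sum(p.size for _, _, p in self.parameters()))

    def get_weights(self):
        return [p.copy() for _, _, p in self.parameters()]

    def set_weights(self, weights):
        own = self.parameters()
        if len(own) != len(weights):
            raise ModelShapeError("weight list does not match model")
        for (li, k, _), w in zip(own, weights):
            self.layers[li].params[k] = w.copy()


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(self, model, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, _, p in model.parameters()]
        self.v = [np.zeros_like(p) for _, _, p in model.parameters()]

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, (li, k, p) in enumerate(self.model.parameters()):
            g = self.model.layers[li].grads[k]
            self.m[idx] = b1 * self.m[idx] + (1 - b1) * g
            self.v[idx] = b2 * self.v[idx] + (1 - b2) * g * g
            mhat = self.m[idx] / (1 - b1 ** self.t)
            vhat = self.v[idx] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
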