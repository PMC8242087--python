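"""Minimal dense/convolutional/recurrent network stack with exact backprop.

Implements precisely the layer set the blood-pressure network needs — 1-D
valid convolution, batch normalization over channels, (bidirectional) LSTM
returning full sequences, global average pooling over time, dense layers,
ReLU — each with an analytic backward pass, plus the legacy Adam optimizer
with per-update learning-rate decay lr_t = lr / (1 + decay * t).

Everything is float64 numpy and fully deterministic given a seed. Gradient
correctness is established by central finite differences in the test suite;
parameter counts follow the standard conventions (LSTM: 4*(u*(c_in+u)+u);
batch norm: 4 per channel, of which the 2 moving statistics are
non-trainable).

Array layout: inputs are (batch, time, channels).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1D", "BatchNorm", "ReLU", "LSTM", "Bidirectional",
    "GlobalAveragePooling1D", "Dense", "Adam",
    "glorot_uniform", "orthogonal",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random n x n orthogonal matrix (QR with sign fix)."""
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


# ---------------------------------------------------------------------------
# LSTM time-loop kernels. The hot loops are JIT-compiled with numba when it
# is available; the numpy fallback is identical arithmetic.
# ---------------------------------------------------------------------------

def _lstm_forward_kernel(z0, U, u):
    """z0: (T, B, 4u) input contribution x@W+b; returns gate/state stacks."""
    T, B = z0.shape[0], z0.shape[1]
    i = np.empty((T, B, u)); f = np.empty((T, B, u))
    g = np.empty((T, B, u)); o = np.empty((T, B, u))
    c = np.empty((T, B, u)); hc = np.empty((T, B, u))
    h = np.empty((T, B, u))
    h_prev = np.zeros((B, u)); c_prev = np.zeros((B, u))
    for t in range(T):
        z = z0[t] + np.dot(h_prev, U)
        i[t] = 1.0 / (1.0 + np.exp(-z[:, :u]))
        f[t] = 1.0 / (1.0 + np.exp(-z[:, u:2 * u]))
        g[t] = np.tanh(z[:, 2 * u:3 * u])
        o[t] = 1.0 / (1.0 + np.exp(-z[:, 3 * u:]))
        c[t] = f[t] * c_prev + i[t] * g[t]
        hc[t] = np.tanh(c[t])
        h[t] = o[t] * hc[t]
        h_prev = h[t]
        c_prev = c[t]
    return i, f, g, o, c, hc, h


def _lstm_backward_kernel(dY, i, f, g, o, c, hc, UT, u):
    """dY: (T, B, u) upstream; returns dZ (T, B, 4u) pre-activation grads."""
    T, B = dY.shape[0], dY.shape[1]
    dZ = np.empty((T, B, 4 * u))
    dh_next = np.zeros((B, u)); dc_next = np.zeros((B, u))
    for t in range(T - 1, -1, -1):
        dh = dY[t] + dh_next
        do = dh * hc[t]
        dc = dc_next + dh * o[t] * (1.0 - hc[t] ** 2)
        di = dc * g[t]
        dg = dc * i[t]
        if t > 0:
            df = dc * c[t - 1]
        else:
            df = np.zeros((B, u))
        dc_next = dc * f[t]
        dZ[t, :, :u] = di * i[t] * (1.0 - i[t])
        dZ[t, :, u:2 * u] = df * f[t] * (1.0 - f[t])
        dZ[t, :, 2 * u:3 * u] = dg * (1.0 - g[t] ** 2)
        dZ[t, :, 3 * u:] = do * o[t] * (1.0 - o[t])
        dh_next = np.dot(dZ[t], UT)
    return dZ


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit as _njit

    _lstm_forward_kernel = _njit(cache=False)(_lstm_forward_kernel)
    _lstm_backward_kernel = _njit(cache=False)(_lstm_backward_kernel)
except ImportError:  # pragma: no cover
    pass


class Layer:
    """Base: trainable ``params``, matching ``grads``, optional buffers."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return sum(p.size for p in self.params.values())

    def n_non_trainable(self) -> int:
        return sum(b.size for b in self.buffers.values())


class Conv1D(Layer):
    """Valid 1-D convolution (cross-correlation), kernel (k, c_in, filters)."""

    def __init__(self, c_in: int, filters: int, kernel: int,
                 rng: np.random.Generator, l2: float = 0.0):
        super().__init__()
        self.kernel, self.l2 = kernel, l2
        fan_in, fan_out = kernel * c_in, kernel * filters
        self.params["W"] = glorot_uniform(rng, (kernel, c_in, filters), fan_in, fan_out)
        self.params["b"] = np.zeros(filters)

    def forward(self, x, training):
        self._x = x
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (B, T', c_in, k); flatten the (c_in, k) taps for one BLAS call
        B, Tp, c_in, k = win.shape
        self._win2 = np.ascontiguousarray(win).reshape(B * Tp, c_in * k)
        Wf = self.params["W"].transpose(1, 0, 2).reshape(c_in * k, -1)  # (c*k, f)
        y = (self._win2 @ Wf).reshape(B, Tp, -1)
        self._shape = (B, Tp)
        return y + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        k, c_in, f = W.shape
        B, Tp = self._shape
        dy2 = dy.reshape(B * Tp, f)
        gW = (self._win2.T @ dy2).reshape(c_in, k, f).transpose(1, 0, 2)
        if self.l2:
            gW = gW + 2.0 * self.l2 * W
        self.grads["W"] = gW
        self.grads["b"] = dy.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        for j in range(k):
            dx[:, j:j + Tp, :] += dy @ W[j].T
        return dx

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(self.params["W"] ** 2)) if self.l2 else 0.0


class BatchNorm(Layer):
    """Batch normalization over (batch, time) per channel; eps/momentum follow
    the common deep-learning defaults (1e-3, 0.99)."""

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.buffers["moving_mean"] = np.zeros(channels)
        self.buffers["moving_var"] = np.ones(channels)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.buffers["moving_mean"] = m * self.buffers["moving_mean"] + (1 - m) * mean
            self.buffers["moving_var"] = m * self.buffers["moving_var"] + (1 - m) * var
        else:
            mean = self.buffers["moving_mean"]
            var = self.buffers["moving_var"]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat = self._xhat
        self.grads["gamma"] = np.sum(dy * xhat, axis=(0, 1))
        self.grads["beta"] = np.sum(dy, axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not self._training:
            return dxhat * self._inv_std
        N = xhat.shape[0] * xhat.shape[1]
        return (self._inv_std / N) * (
            N * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * np.sum(dxhat * xhat, axis=(0, 1))
        )


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class LSTM(Layer):
    """Standard LSTM returning the full hidden sequence.

    Gate order i, f, g(candidate), o; sigmoid gates, tanh candidate/output;
    forget-gate bias initialized to 1. Kernel is glorot-uniform, the
    recurrent matrix is block-orthogonal per gate.
    """

    def __init__(self, c_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.units = units
        self.params["W"] = glorot_uniform(rng, (c_in, 4 * units), c_in, 4 * units)
        self.params["U"] = np.concatenate(
            [orthogonal(rng, units) for _ in range(4)], axis=1)
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0  # forget gate
        self.params["b"] = b

    def forward(self, x, training):
        u = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        z0 = np.ascontiguousarray((x @ W + b).transpose(1, 0, 2))  # (T, B, 4u)
        i, f, g, o, c, hc, h = _lstm_forward_kernel(z0, U, u)
        self._cache = (x, i, f, g, o, c, hc, h)
        return np.ascontiguousarray(h.transpose(1, 0, 2))          # (B, T, u)

    def backward(self, dy):
        x, i, f, g, o, c, hc, h = self._cache
        u = self.units
        UT = np.ascontiguousarray(self.params["U"].T)
        dY = np.ascontiguousarray(dy.transpose(1, 0, 2))           # (T, B, u)
        dZ = _lstm_backward_kernel(dY, i, f, g, o, c, hc, UT, u)
        # recurrent grad: sum_t h_{t-1}^T dz_t (initial state is zero)
        self.grads["U"] = (h[:-1].reshape(-1, u).T
                           @ dZ[1:].reshape(-1, 4 * u))
        dZb = np.ascontiguousarray(dZ.transpose(1, 0, 2))          # (B, T, 4u)
        B, T, c_in = x.shape
        self.grads["W"] = (x.reshape(B * T, c_in).T
                           @ dZb.reshape(B * T, 4 * u))
        self.grads["b"] = dZ.sum(axis=(0, 1))
        return dZb @ self.params["W"].T


class Bidirectional(Layer):
    """Wraps two LSTMs over opposite time directions, concatenating outputs."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(c_in, units, rng)
        self.bwd = LSTM(c_in, units, rng)

    def forward(self, x, training):
        yf = self.fwd.forward(x, training)
        yb = self.bwd.forward(x[:, ::-1, :], training)[:, ::-1, :]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy):
        u = self.fwd.units
        dxf = self.fwd.backward(dy[:, :, :u])
        dxb = self.bwd.backward(dy[:, ::-1, u:])[:, ::-1, :]
        return dxf + dxb

    def n_trainable(self):
        return self.fwd.n_trainable() + self.bwd.n_trainable()

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]


class GlobalAveragePooling1D(Layer):
    def forward(self, x, training):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._T, axis=1) / self._T


class Dense(Layer):
    def __init__(self, c_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (c_in, units), c_in, units)
        self.params["b"] = np.zeros(units)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def iter_param_layers(layers) -> list[Layer]:
    """Flatten Bidirectional wrappers into their constituent LSTMs."""
    out = []
    for lay in layers:
        if isinstance(lay, Bidirectional):
            out.extend(lay.sublayers)
        else:
            out.append(lay)
    return out


class Adam:
    """Adam with the legacy per-update learning-rate decay.

    lr_t = lr / (1 + decay * t), then the usual bias-corrected moment update
    (beta1=0.9, beta2=0.999, eps=1e-7); t counts updates starting at 1.
    """

    def __init__(self, layers, lr: float = 0.01, decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.layers = iter_param_layers(layers)
        self.lr, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]

    def step(self) -> None:
        self.t += 1
        lr = self.lr / (1.0 + self.decay * self.t)
        corr = np.sqrt(1.0 - self.beta2 ** self.t) / (1.0 - self.beta1 ** self.t)
        for lay, m, v in zip(self.layers, self._m, self._v):
            for k, p in lay.params.items():
                gk = lay.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * gk
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * gk ** 2
                p -= lr * corr * m[k] / (np.sqrt(v[k]) + self.eps)
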