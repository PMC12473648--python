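"""Minimal NumPy layer zoo with hand-written backprop.

Only what the window classifiers need: width-only 2-D convolutions over
6 x T inputs, batch norm, ReLU, time-axis max pooling, dense layers,
dropout, a bidirectional LSTM and a softmax cross-entropy head, trained
with Adam.  Everything is float64 and seeded, so training is exactly
reproducible run-to-run on one machine.

Tensor convention: feature maps are (B, H, T, C) with H the six motion
channels stacked as image height and T the time axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient and weight-decay eligibility."""

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool, name: str):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConvWidth(Layer):
    """2-D convolution with a 1 x k kernel ('same' padding along time).

    Kernel height 1 means each of the six motion rows is filtered with the
    same shared time-axis kernel, preserving the vertical structure of the
    window while mixing input channels.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, name: str):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd")
        fan_in = c_in * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.pad = kernel // 2
        self.W = Param(scale * rng.standard_normal((c_out, c_in, kernel)), True, f"{name}.W")
        self.b = Param(np.zeros(c_out), False, f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (0, 0)))
        win = sliding_window_view(xp, self.kernel, axis=2)  # (B,H,T,Cin,k)
        self._cache = win
        return np.einsum("bhtck,ock->bhto", win, self.W.value) + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win = self._cache
        self.W.grad = np.einsum("bhtck,bhto->ock", win, dout)
        self.b.grad = dout.sum(axis=(0, 1, 2))
        dp = np.pad(dout, ((0, 0), (0, 0), (self.pad, self.pad), (0, 0)))
        dwin = sliding_window_view(dp, self.kernel, axis=2)  # (B,H,T,Cout,k)
        w_rev = self.W.value[:, :, ::-1]
        return np.einsum("bhtok,ock->bhtc", dwin, w_rev)


class BatchNorm(Layer):
    """Per-feature-channel batch normalization over (B, H, T)."""

    def __init__(self, channels: int, name: str, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), False, f"{name}.gamma")
        self.beta = Param(np.zeros(channels), False, f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        n = np.prod([dout.shape[a] for a in axes])
        self.gamma.grad = (dout * xhat).sum(axis=axes)
        self.beta.grad = dout.sum(axis=axes)
        g = self.gamma.value * inv
        return g * (dout - dout.mean(axis=axes) - xhat * (dout * xhat).mean(axis=axes)) if n > 1 else g * dout


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPoolTime(Layer):
    """Max pooling along the time axis only (1 x width window, same stride)."""

    def __init__(self, width: int = 2):
        self.width = width

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, t, c = x.shape
        t_out = t // self.width
        if t_out < 1:
            raise ValueError("pooling exhausts the time axis")
        xt = x[:, :, : t_out * self.width].reshape(b, h, t_out, self.width, c)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, t_out, c = dout.shape
        dxt = np.zeros((b, h, t_out, self.width, c))
        bi, hi, ti, ci = np.ogrid[0:b, 0:h, 0:t_out, 0:c]
        dxt[bi, hi, ti, self._argmax, ci] = dout
        dx = np.zeros(self._in_shape)
        dx[:, :, : t_out * self.width] = dxt.reshape(b, h, t_out * self.width, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class TimeCollapse(Layer):
    """(B, H, T, C) -> (B, T, H*C): time-indexed feature vectors for an RNN."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        b, h, t, c = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * c)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, t, c = self._shape
        return dout.reshape(b, t, h, c).transpose(0, 2, 1, 3)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(scale * rng.standard_normal((d_in, d_out)), True, f"{name}.W")
        self.b = Param(np.zeros(d_out), False, f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad = self._x.T @ dout
        self.b.grad = dout.sum(axis=0)
        return dout @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMDirection:
    """One direction of an LSTM; returns the final hidden state."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, name: str):
        self.hidden = hidden
        sx = np.sqrt(1.0 / d_in)
        sh = np.sqrt(1.0 / hidden)
        self.Wx = Param(sx * rng.standard_normal((d_in, 4 * hidden)), True, f"{name}.Wx")
        self.Wh = Param(sh * rng.standard_normal((hidden, 4 * hidden)), True, f"{name}.Wh")
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b, False, f"{name}.b")

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        hdim = self.hidden
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        self._x = x
        self._steps = []
        for s in range(t):
            z = x[:, s] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._steps.append((h, c, i, f, g, o, tc))
            h = o * tc
            c = c_new
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        x = self._x
        hdim = self.hidden
        dx = np.zeros_like(x)
        dWx = np.zeros_like(self.Wx.value)
        dWh = np.zeros_like(self.Wh.value)
        db = np.zeros_like(self.b.value)
        dh = dh_last.copy()
        dc = np.zeros_like(dh_last)
        for s in range(x.shape[1] - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._steps[s]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, s].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, s] = dz @ self.Wx.value.T
            dh = dz @ self.Wh.value.T
            dc = dc * f
        self.Wx.grad = dWx
        self.Wh.grad = dWh
        self.b.grad = db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM over (B, T, D); outputs the concatenated final
    hidden states of the two directions, shape (B, 2*hidden)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, name: str):
        self.fwd = _LSTMDirection(d_in, hidden, rng, f"{name}.fwd")
        self.bwd = _LSTMDirection(d_in, hidden, rng, f"{name}.bwd")
        self.hidden = hidden

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h = self.hidden
        dxf = self.fwd.backward(dout[:, :h])
        dxb = self.bwd.backward(dout[:, h:])
        return dxf + dxb[:, ::-1]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = labels.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean())


def softmax_xent_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = labels.shape[0]
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return d / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 0.001, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.l2 = l2
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + (self.l2 * p.value if p.decay else 0.0)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential:
    """A plain layer stack with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)
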