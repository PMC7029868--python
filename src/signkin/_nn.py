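"""Minimal feed-forward/convolutional/recurrent network engine in numpy.

Implements exactly what the sequence classifiers need: dense, time-axis
convolution (kernels slide along time only, one-wide in the feature axis,
"same" padding), stacked LSTM layers, inverted dropout, softmax
cross-entropy, and Adam with staircase learning-rate decay.  Forward
passes cache what the analytic backward passes need; gradients are
verified against finite differences in the test suite.

Array conventions: dense layers take ``(B, D)``; convolutions take
``(B, T, F, C)`` (batch, time, feature column, channel); LSTMs take
``(B, T, D)``.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# activations


def _act_forward(name, z):
    if name is None or name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {name!r}")


def _act_backward(name, a, grad):
    if name is None or name == "linear":
        return grad
    if name == "relu":
        return grad * (a > 0)
    if name == "sigmoid":
        return grad * a * (1.0 - a)
    if name == "tanh":
        return grad * (1.0 - a * a)
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameters in ``params``, gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Dense(Layer):
    def __init__(self, n_in, n_out, activation=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.activation = activation
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._a = _act_forward(self.activation, z)
        return self._a

    def backward(self, grad):
        grad = _act_backward(self.activation, self._a, grad)
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class ExpandChannel(Layer):
    """(B, T, F) -> (B, T, F, 1)."""

    def forward(self, x, training=False, rng=None):
        return x[..., None]

    def backward(self, grad):
        return grad[..., 0]


class MergeChannels(Layer):
    """(B, T, F, C) -> (B, T, F*C) for feeding recurrent layers."""

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout with the given *keep* probability."""

    def __init__(self, keep_prob=0.8):
        super().__init__()
        self.keep_prob = float(keep_prob)

    def forward(self, x, training=False, rng=None):
        if not training or self.keep_prob >= 1.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        self._mask = (rng.random(x.shape) < self.keep_prob).astype(
            x.dtype
        ) / self.keep_prob
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class TimeConv(Layer):
    """Convolution along the time axis only ("same" padding, stride >= 1).

    Weights have shape (k, C_in, C_out); every feature column shares them.
    """

    def __init__(self, c_in, c_out, kernel, stride=1, activation="relu", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel, self.stride, self.activation = kernel, stride, activation
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.params["W"] = _glorot(rng, (kernel, c_in, c_out), fan_in, fan_out)
        self.params["b"] = np.zeros(c_out)

    @staticmethod
    def output_length(t_in: int, stride: int) -> int:
        return -(-t_in // stride)  # ceil division, "same" padding

    def _padding(self, t_in):
        t_out = self.output_length(t_in, self.stride)
        total = max((t_out - 1) * self.stride + self.kernel - t_in, 0)
        return total // 2, total - total // 2

    def forward(self, x, training=False, rng=None):
        B, T, F, C = x.shape
        k, s = self.kernel, self.stride
        pad_lo, pad_hi = self._padding(T)
        xp = np.pad(x, ((0, 0), (pad_lo, pad_hi), (0, 0), (0, 0)))
        # windows over time: (B, T_out, F, k, C)
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        win = win[:, ::s].transpose(0, 1, 2, 4, 3)
        self._cols = win.reshape(B, -1, F, k * C)
        W = self.params["W"].reshape(k * C, -1)
        z = self._cols @ W + self.params["b"]
        self._a = _act_forward(self.activation, z)
        self._in_shape, self._pads = x.shape, (pad_lo, pad_hi)
        return self._a  # (B, T_out, F, C_out)

    def backward(self, grad):
        grad = _act_backward(self.activation, self._a, grad)
        B, T, F, C = self._in_shape
        k, s = self.kernel, self.stride
        pad_lo, pad_hi = self._pads
        cols = self._cols.reshape(-1, k * C)
        g = grad.reshape(-1, grad.shape[-1])
        self.grads["W"] = (cols.T @ g).reshape(self.params["W"].shape)
        self.grads["b"] = g.sum(axis=0)
        gcols = (g @ self.params["W"].reshape(k * C, -1).T).reshape(
            B, -1, F, k, C
        )
        gx = np.zeros((B, T + pad_lo + pad_hi, F, C), dtype=grad.dtype)
        t_out = gcols.shape[1]
        for j in range(k):  # each tap hits a strided, duplicate-free slice
            gx[:, j : j + s * (t_out - 1) + 1 : s] += gcols[:, :, :, j, :]
        return gx[:, pad_lo : pad_lo + T]


class LSTM(Layer):
    """Single LSTM layer (input/forget/cell/output gates, forget bias 1).

    The input projection is computed for all time steps in one matrix
    product; only the recurrent projection runs in the per-step loop.
    """

    def __init__(self, n_in, n_units, return_sequences=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.n_units = n_units
        self.return_sequences = return_sequences
        self.params["Wx"] = _glorot(rng, (n_in, 4 * n_units), n_in, 4 * n_units)
        self.params["Wh"] = _glorot(rng, (n_units, 4 * n_units),
                                    n_units, 4 * n_units)
        b = np.zeros(4 * n_units)
        b[n_units : 2 * n_units] = 1.0  # forget-gate bias
        self.params["b"] = b

    def forward(self, x, training=False, rng=None):
        B, T, D = x.shape
        H = self.n_units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        zx = x.reshape(B * T, D) @ Wx
        zx = zx.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        outputs = np.empty((B, T, H), dtype=x.dtype)
        for t in range(T):
            gates = zx[:, t] + h @ Wh + b
            i = 1.0 / (1.0 + np.exp(-gates[:, :H]))
            f = 1.0 / (1.0 + np.exp(-gates[:, H : 2 * H]))
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-gates[:, 3 * H :]))
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            outputs[:, t] = h
            self._cache.append((i, f, g, o, c, tc))
        self._outputs = outputs
        return outputs if self.return_sequences else h

    def backward(self, grad):
        B, T, D = self._x.shape
        H = self.n_units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dtype = self._x.dtype
        if self.return_sequences:
            grad_seq = grad
        else:
            grad_seq = np.zeros((B, T, H), dtype=dtype)
            grad_seq[:, -1] = grad
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dgates_all = np.empty((B, T, 4 * H), dtype=dtype)
        dh_next = np.zeros((B, H), dtype=dtype)
        dc_next = np.zeros((B, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c, tc = self._cache[t]
            c_prev = self._cache[t - 1][4] if t > 0 else np.zeros((B, H),
                                                                  dtype=dtype)
            h_prev = self._outputs[:, t - 1] if t > 0 else np.zeros(
                (B, H), dtype=dtype)
            dh = grad_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dgates = np.concatenate(
                [
                    dc * g * i * (1 - i),
                    dc * c_prev * f * (1 - f),
                    dc * i * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dgates_all[:, t] = dgates
            dWh += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            dh_next = dgates @ Wh.T
            dc_next = dc * f
        flat = dgates_all.reshape(B * T, 4 * H)
        self.grads["Wx"] = self._x.reshape(B * T, D).T @ flat
        self.grads["Wh"] = dWh
        self.grads["b"] = db
        return (flat @ Wx.T).reshape(B, T, D)


class LastStep(Layer):
    """(B, T, H) -> (B, H): keep the final time step only."""

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x[:, -1]

    def backward(self, grad):
        out = np.zeros(self._shape)
        out[:, -1] = grad
        return out


# ---------------------------------------------------------------------------
# loss and network


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> float:
    """Mean softmax cross-entropy: -sum_i y_i log softmax(y'_i)."""
    p = softmax(logits)
    return float(-np.mean(np.sum(onehot * np.log(p + 1e-300), axis=1)))


class Network:
    """A plain layer stack with softmax cross-entropy on top."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def loss_and_grad(self, x, onehot, rng=None):
        logits = self.forward(x, training=True, rng=rng)
        p = softmax(logits)
        loss = float(-np.mean(np.sum(onehot * np.log(p + 1e-300), axis=1)))
        self.backward((p - onehot) / x.shape[0])
        return loss, logits

    def predict_logits(self, x, batch_size=512):
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers)

    def astype(self, dtype) -> "Network":
        """Cast all parameters in place (e.g. float32 for speed)."""
        for layer in self.layers:
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(dtype)
        return self

    def get_state(self):
        return [
            {k: v.copy() for k, v in layer.params.items()} for layer in self.layers
        ]

    def set_state(self, state):
        for layer, params in zip(self.layers, state):
            for k, v in params.items():
                layer.params[k] = v.copy()


class Adam:
    """Adam with a staircase learning-rate schedule (decay every N epochs)."""

    def __init__(self, network: Network, learning_rate=1e-3, decay=0.9,
                 decay_every=5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.network = network
        self.lr0 = learning_rate
        self.decay = decay
        self.decay_every = decay_every
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in network.layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in network.layers]

    def learning_rate(self, epoch: int) -> float:
        return self.lr0 * self.decay ** (epoch // self.decay_every)

    def step(self, epoch: int) -> None:
        self.t += 1
        lr = self.learning_rate(epoch)
        for li, layer in enumerate(self.network.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k] = self.beta1 * self.m[li][k] + (1 - self.beta1) * g
                v = self.v[li][k] = self.beta2 * self.v[li][k] + (1 - self.beta2) * g * g
                mhat = m / (1 - self.beta1 ** self.t)
                vhat = v / (1 - self.beta2 ** self.t)
                layer.params[k] = p - lr * mhat / (np.sqrt(vhat) + self.eps)
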