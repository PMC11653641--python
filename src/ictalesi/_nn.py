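"""Minimal NumPy neural-network core: layers, backprop and Adam.

Only what the spatiotemporal inverse model needs: per-time-step dense
layers with ReLU residual blocks, stacked LSTM layers, mean-squared-error
loss and the Adam optimizer (L2-coupled weight decay, as in common deep
learning frameworks).  Gradients are hand-derived and validated against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ResidualBlock", "LSTM", "Sequential", "Adam", "mse_loss"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Layer:
    """Base layer: parameter dict + cached forward state for backward."""

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    """Affine map applied to the last axis of a 2-D input (N, in) -> (N, out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params = {
            "W": rng.uniform(-limit, limit, (n_in, n_out)).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class ResidualBlock(Layer):
    """y = x + ReLU(Dense(x)); width-preserving."""

    def __init__(self, width: int, rng, dtype=np.float32):
        super().__init__()
        self.dense = Dense(width, width, rng, dtype)
        self.params = self.dense.params
        self.grads = self.dense.grads

    def zero_grad(self):
        self.dense.zero_grad()
        self.grads = self.dense.grads

    def forward(self, x):
        z = self.dense.forward(x)
        self._mask = z > 0
        return x + z * self._mask

    def backward(self, dy):
        dz = self.dense.backward(dy * self._mask)
        return dy + dz


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LSTM(Layer):
    """Single LSTM layer over (batch, time, features) with optional residual add.

    Gate order i, f, g, o; forget-gate bias initialized to +1.  The input
    projection for all time steps is computed in one matrix product; only
    the recurrent part runs step by step.
    """

    def __init__(self, n_in: int, hidden: int, rng, residual: bool = False,
                 dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        self.residual = residual and n_in == hidden
        s = 1.0 / np.sqrt(hidden)
        self.params = {
            "Wx": rng.uniform(-s, s, (n_in, 4 * hidden)).astype(dtype),
            "Wh": rng.uniform(-s, s, (hidden, 4 * hidden)).astype(dtype),
            "b": np.zeros(4 * hidden, dtype=dtype),
        }
        self.params["b"][hidden:2 * hidden] = 1.0
        self.zero_grad()

    def forward(self, x):
        B, T, _ = x.shape
        H = self.hidden
        pre = x.reshape(B * T, -1) @ self.params["Wx"] + self.params["b"]
        pre = pre.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        cache = []
        out = np.empty((B, T, H), dtype=x.dtype)
        Wh = self.params["Wh"]
        for t in range(T):
            z = pre[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        self._x, self._cache = x, cache
        return out + x if self.residual else out

    def backward(self, dy):
        x, cache = self._x, self._cache
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        dpre = np.empty((B, T, 4 * H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dy[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1,
            )
            dpre[:, t] = dz
            dh_next = dz @ Wh.T
            dc_next = dc * f
            self.grads["Wh"] += cache[t][0].T @ dz
        flat = dpre.reshape(B * T, 4 * H)
        self.grads["Wx"] += x.reshape(B * T, -1).T @ flat
        self.grads["b"] += flat.sum(axis=0)
        dx = (flat @ Wx.T).reshape(x.shape)
        return dx + dy if self.residual else dx


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        out = []
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"{li}.{name}", layer.params[name], layer.grads[name]))
        return out

    def state_dict(self):
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state):
        for name, p, _ in self.parameters():
            np.copyto(p, state[name])


class Adam:
    """Adam with L2 weight decay added to the gradient (framework convention)."""

    def __init__(self, model: Sequential, lr=3e-4, weight_decay=1e-6,
                 betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in model.parameters()}
        self.v = {name: np.zeros_like(p) for name, p, _ in model.parameters()}

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, p, g in self.model.parameters():
            if self.wd:
                g = g + self.wd * p
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mse_loss(pred, target):
    """Mean squared error and its gradient with respect to ``pred``.

    Overflow in the square (diverging training) yields an infinite loss
    rather than a warning; the training loop turns that into an error.
    """
    diff = pred - target
    with np.errstate(over="ignore"):
        loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff
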