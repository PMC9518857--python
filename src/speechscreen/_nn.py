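"""Minimal batch-first neural-network layers in NumPy with exact backprop.

Only what the sequence classifier needs: LSTM (optionally bidirectional via
a wrapper), additive temporal attention, dense, dropout, and a fused
softmax/cross-entropy head. Shapes are batch-first: sequences are
``(B, T, d)``. Every layer caches its forward pass and exposes
``backward(dY) -> dX`` filling ``self.grads`` (keyed like ``self.params``).

Gradients are verified against central finite differences in the test
suite; float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot",
    "Dense",
    "Dropout",
    "LSTM",
    "BiLSTM",
    "Attention",
    "softmax",
    "softmax_cross_entropy",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape or (fan_in, fan_out))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Dense(Layer):
    """Affine map with optional rectifier: Y = relu?(X W + b)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = False):
        super().__init__()
        self.relu = relu
        self.params = {"W": glorot(rng, n_in, n_out), "b": np.zeros(n_out)}

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        self._X = X
        Z = X @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = Z > 0
            Z = Z * self._mask
        return Z

    def backward(self, dY: np.ndarray) -> np.ndarray:
        if self.relu:
            dY = dY * self._mask
        self.grads = {"W": self._X.T @ dY, "b": dY.sum(axis=0)}
        return dY @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return X
        if rng is None:
            raise ValueError("training-mode dropout needs an explicit rng")
        self._mask = (rng.random(X.shape) >= self.rate) / (1.0 - self.rate)
        return X * self._mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return dY if self._mask is None else dY * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single-direction LSTM returning the full hidden sequence.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialised to one.
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_units = n_in, n_units
        u = n_units
        b = np.zeros(4 * u)
        b[u:2 * u] = 1.0
        self.params = {
            "Wx": glorot(rng, n_in, 4 * u, (n_in, 4 * u)),
            "Wh": glorot(rng, u, 4 * u, (u, 4 * u)),
            "b": b,
        }

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, _ = X.shape
        u = self.n_units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        H = np.zeros((B, T, u))
        self._I = np.zeros((B, T, u))
        self._F = np.zeros((B, T, u))
        self._G = np.zeros((B, T, u))
        self._O = np.zeros((B, T, u))
        self._C = np.zeros((B, T, u))
        self._TC = np.zeros((B, T, u))
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        XW = X @ Wx  # hoist the input projection out of the loop
        for t in range(T):
            z = XW[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            self._I[:, t], self._F[:, t], self._G[:, t], self._O[:, t] = i, f, g, o
            self._C[:, t], self._TC[:, t] = c, tc
            H[:, t] = h
        self._X, self._H = X, H
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X, H = self._X, self._H
        B, T, _ = X.shape
        u = self.n_units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            i, f, g, o = self._I[:, t], self._F[:, t], self._G[:, t], self._O[:, t]
            tc = self._TC[:, t]
            c_prev = self._C[:, t - 1] if t > 0 else np.zeros((B, u))
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, u))
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ Wh.T
            dX[:, t] = dz @ Wx.T
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dX


class BiLSTM(Layer):
    """Two LSTMs over opposite time directions, outputs concatenated."""

    def __init__(self, n_in: int, units_per_direction: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(n_in, units_per_direction, rng)
        self.bwd = LSTM(n_in, units_per_direction, rng)
        self.params = {
            **{f"fwd_{k}": v for k, v in self.fwd.params.items()},
            **{f"bwd_{k}": v for k, v in self.bwd.params.items()},
        }

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        Hf = self.fwd.forward(X, training)
        Hb = self.bwd.forward(X[:, ::-1], training)[:, ::-1]
        return np.concatenate([Hf, Hb], axis=2)

    def backward(self, dH: np.ndarray) -> np.ndarray:
        u = self.fwd.n_units
        dXf = self.fwd.backward(dH[:, :, :u])
        dXb = self.bwd.backward(dH[:, ::-1, u:])[:, ::-1]
        self.grads = {
            **{f"fwd_{k}": v for k, v in self.fwd.grads.items()},
            **{f"bwd_{k}": v for k, v in self.bwd.grads.items()},
        }
        return dXf + dXb

    def zero_grads(self) -> None:
        self.fwd.zero_grads()
        self.bwd.zero_grads()
        super().zero_grads()


class Attention(Layer):
    """Additive temporal attention pooling a sequence to one context vector.

    Scores ``e_t = v . tanh(W h_t + b)`` are softmax-normalised over time and
    the context is the weighted sum of the hidden states.
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": glorot(rng, n_in, n_units),
            "b": np.zeros(n_units),
            "v": glorot(rng, n_units, 1, (n_units,)),
        }

    def forward(self, H: np.ndarray, training: bool = False) -> np.ndarray:
        if H.ndim != 3 or H.shape[1] < 1:
            raise ValueError("attention expects a non-empty (B, T, d) sequence")
        W, b, v = self.params["W"], self.params["b"], self.params["v"]
        self._H = H
        self._S = np.tanh(H @ W + b)           # (B, T, a)
        E = self._S @ v                         # (B, T)
        self._A = softmax(E, axis=1)            # attention weights
        return np.einsum("bt,btd->bd", self._A, H)

    @property
    def last_weights(self) -> np.ndarray:
        """Attention weights from the most recent forward pass, (B, T)."""
        return self._A

    def backward(self, dCtx: np.ndarray) -> np.ndarray:
        H, S, A = self._H, self._S, self._A
        W, v = self.params["W"], self.params["v"]
        dA = np.einsum("bd,btd->bt", dCtx, H)
        dH = A[:, :, None] * dCtx[:, None, :]
        dE = A * (dA - (A * dA).sum(axis=1, keepdims=True))
        dv = (S * dE[:, :, None]).sum(axis=(0, 1))
        dZ = dE[:, :, None] * v * (1.0 - S * S)
        self.grads = {
            "W": np.einsum("btd,bta->da", H, dZ),
            "b": dZ.sum(axis=(0, 1)),
            "v": dv,
        }
        return dH + dZ @ W.T


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, probs, dlogits)."""
    probs = softmax(logits, axis=1)
    B = logits.shape[0]
    eps = 1e-300
    loss = -float(np.mean(np.log(probs[np.arange(B), labels] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return loss, probs, dlogits / B
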