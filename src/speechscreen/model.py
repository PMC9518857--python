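"""Bi-LSTM classifier with temporal attention.

Layer stack (in order): bidirectional LSTM (sequence output, directions
concatenated) -> LSTM (sequence output) -> additive attention pooling to a
single context vector -> dense (relu) -> dropout -> dense (relu) -> dense
softmax over the classes.

The bidirectional width is interpreted as the *total* output width by
default (units split evenly across the two directions); the alternative
per-direction reading is selectable via ``bidirectional_interpretation``.
With the default spec the total reading lands near 1.5M trainable
parameters, the per-direction reading above 3M.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import _nn

__all__ = [
    "ModelSpec",
    "BiLSTMAttentionModel",
    "build_model",
    "count_parameters",
    "attention_pool",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; defaults give the full-size network."""

    frames_per_segment: int = 100
    n_features: int = 13
    bilstm_units_total: int = 512
    lstm_units: int = 256
    attention_units: int = 512
    dense1_units: int = 128
    dropout_rate: float = 0.6
    dense2_units: int = 64
    n_classes: int = 2
    bidirectional_interpretation: str = "total"  # or "per_direction"

    def __post_init__(self) -> None:
        counts = (
            self.frames_per_segment, self.n_features, self.bilstm_units_total,
            self.lstm_units, self.attention_units, self.dense1_units,
            self.dense2_units, self.n_classes,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all unit counts must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.bidirectional_interpretation not in ("total", "per_direction"):
            raise ValueError("bidirectional_interpretation must be 'total' or 'per_direction'")
        if self.bidirectional_interpretation == "total" and self.bilstm_units_total % 2:
            raise ValueError("total bidirectional width must be even")

    @property
    def input_shape(self) -> tuple[int, int]:
        return (self.frames_per_segment, self.n_features)

    @property
    def units_per_direction(self) -> int:
        if self.bidirectional_interpretation == "total":
            return self.bilstm_units_total // 2
        return self.bilstm_units_total

    def scaled(self, factor: float) -> "ModelSpec":
        """Shrink (or grow) every unit count by ``factor`` for desk-scale runs."""
        shrink = lambda u: max(1, int(round(u * factor)))
        return replace(
            self,
            bilstm_units_total=max(2, 2 * shrink(self.bilstm_units_total / 2)),
            lstm_units=shrink(self.lstm_units),
            attention_units=shrink(self.attention_units),
            dense1_units=shrink(self.dense1_units),
            dense2_units=shrink(self.dense2_units),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter total from per-layer closed forms.

    LSTM with input i and u units: 4 * (u * (i + u) + u); dense i -> u:
    i * u + u; additive attention over d-wide states with a hidden units:
    d * a + a + a.
    """
    i = spec.n_features
    u = spec.units_per_direction
    lstm1 = 2 * 4 * (u * (i + u) + u)
    width = 2 * u
    v = spec.lstm_units
    lstm2 = 4 * (v * (width + v) + v)
    attn = v * spec.attention_units + spec.attention_units + spec.attention_units
    d1 = v * spec.dense1_units + spec.dense1_units
    d2 = spec.dense1_units * spec.dense2_units + spec.dense2_units
    out = spec.dense2_units * spec.n_classes + spec.n_classes
    return lstm1 + lstm2 + attn + d1 + d2 + out


class BiLSTMAttentionModel:
    """Model handle: the layer stack, its parameters, and the init seed.

    An optional per-feature normaliser (set by the trainer from
    training-partition statistics) is applied inside :meth:`forward` so that
    saved models carry their own preprocessing.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.rng_seed = seed
        rng = np.random.default_rng(seed)
        u = spec.units_per_direction
        self.bilstm = _nn.BiLSTM(spec.n_features, u, rng)
        self.lstm = _nn.LSTM(2 * u, spec.lstm_units, rng)
        self.attention = _nn.Attention(spec.lstm_units, spec.attention_units, rng)
        self.dense1 = _nn.Dense(spec.lstm_units, spec.dense1_units, rng, relu=True)
        self.dropout = _nn.Dropout(spec.dropout_rate)
        self.dense2 = _nn.Dense(spec.dense1_units, spec.dense2_units, rng, relu=True)
        self.head = _nn.Dense(spec.dense2_units, spec.n_classes, rng, relu=False)
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None

    # -- parameter plumbing -------------------------------------------------

    @property
    def _layers(self):
        return {
            "bilstm": self.bilstm,
            "lstm": self.lstm,
            "attention": self.attention,
            "dense1": self.dense1,
            "dense2": self.dense2,
            "head": self.head,
        }

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable tensor."""
        return {
            f"{lname}.{pname}": arr
            for lname, layer in self._layers.items()
            for pname, arr in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{lname}.{pname}": arr
            for lname, layer in self._layers.items()
            for pname, arr in layer.grads.items()
        }

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(weights) != set(params):
            raise ValueError("weight keys do not match this architecture")
        for k, arr in params.items():
            arr[...] = weights[k]

    def set_normalizer(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.norm_mean = np.asarray(mean, dtype=np.float64)
        self.norm_std = np.asarray(std, dtype=np.float64)

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # -- forward / backward -------------------------------------------------

    def _check_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"batch shape {X.shape[1:]} does not match input {self.spec.input_shape}"
            )
        if self.norm_mean is not None:
            X = (X - self.norm_mean) / self.norm_std
        return X

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Class-probability matrix, one row per segment on the simplex.

        Dropout is active only with ``training=True`` (which then requires
        an explicit ``rng``); inference is deterministic.
        """
        X = self._check_batch(X)
        H = self.bilstm.forward(X, training)
        H = self.lstm.forward(H, training)
        ctx = self.attention.forward(H, training)
        z = self.dense1.forward(ctx, training)
        z = self.dropout.forward(z, training, rng)
        z = self.dense2.forward(z, training)
        logits = self.head.forward(z, training)
        return _nn.softmax(logits, axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-timestep attention distribution for each segment in X."""
        self.forward(X, training=False)
        return self.attention.last_weights

    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator | None = None,
        training: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and gradients for every trainable tensor."""
        X = self._check_batch(X)
        y = np.asarray(y, dtype=np.int64)
        H = self.bilstm.forward(X, training)
        H = self.lstm.forward(H, training)
        ctx = self.attention.forward(H, training)
        z = self.dense1.forward(ctx, training)
        z = self.dropout.forward(z, training, rng)
        z = self.dense2.forward(z, training)
        logits = self.head.forward(z, training)
        loss, _, dlogits = _nn.softmax_cross_entropy(logits, y)
        d = self.head.backward(dlogits)
        d = self.dense2.backward(d)
        d = self.dropout.backward(d)
        d = self.dense1.backward(d)
        dH = self.attention.backward(d)
        dH = self.lstm.backward(dH)
        self.bilstm.backward(dH)
        return loss, self.gradients()

    def evaluate_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Inference-mode (dropout off) mean cross-entropy."""
        probs = self.forward(X, training=False)
        y = np.asarray(y, dtype=np.int64)
        return -float(np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300)))


def build_model(spec: ModelSpec, seed: int = 0) -> BiLSTMAttentionModel:
    """Construct the network with deterministic, seeded initialisation."""
    return BiLSTMAttentionModel(spec, seed)


def attention_pool(
    sequence: np.ndarray,
    attention_units: int,
    parameters: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Standalone additive attention over a single (T, d) sequence.

    Returns ``(context, weights)``; pass ``parameters`` (keys W, b, v) to pin
    the scoring function, otherwise it is randomly initialised from ``seed``.
    """
    sequence = np.asarray(sequence, dtype=np.float64)
    if sequence.ndim != 2 or sequence.shape[0] < 1:
        raise ValueError("sequence must be a non-empty (T, d) matrix")
    layer = _nn.Attention(sequence.shape[1], attention_units, np.random.default_rng(seed))
    if parameters is not None:
        for k in ("W", "b", "v"):
            layer.params[k][...] = parameters[k]
    context = layer.forward(sequence[None])[0]
    return context, layer.last_weights[0]


def save_model(model: BiLSTMAttentionModel, path: str | os.PathLike) -> Path:
    """NPZ checkpoint with the spec (and normaliser) embedded as metadata."""
    path = Path(path)
    arrays = {f"param:{k}": v for k, v in model.parameters().items()}
    if model.norm_mean is not None:
        arrays["norm_mean"] = model.norm_mean
        arrays["norm_std"] = model.norm_std
    meta = json.dumps({"spec": model.spec.to_dict(), "rng_seed": model.rng_seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    return path


def load_model(path: str | os.PathLike) -> BiLSTMAttentionModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = BiLSTMAttentionModel(ModelSpec.from_dict(meta["spec"]), meta["rng_seed"])
        model.set_weights(
            {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
        )
        if "norm_mean" in data.files:
            model.set_normalizer(data["norm_mean"], data["norm_std"])
    return model
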