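"""The 150-32-16-5 feedforward softmax classifier.

The model is deliberately hand-implemented in numpy (no autodiff framework):

    h1 = ReLU(W1 x + b1)        W1: 32x150
    h2 = ReLU(W2 h1 + b2)       W2: 16x32
    p  = softmax(W3 h2 + b3)    W3: 5x16

trained by minimising the mean cross-entropy ``L = -1/N sum_i sum_k
y_ik log p_ik`` over one-hot labels with full-batch Adam by default. Being
hand-written keeps the model tiny, fully deterministic under a seed, and —
importantly for trust in the gradients — checkable against central finite
differences (see :func:`backward`'s contract).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LAYER_SIZES",
    "NetworkParameters",
    "ForwardTrace",
    "TrainConfig",
    "LabeledBatch",
    "init_network",
    "forward",
    "forward_batch",
    "cross_entropy",
    "backward",
    "train",
    "predict",
    "save_model",
    "load_model",
]

#: (input, hidden 1, hidden 2, output) layer widths
LAYER_SIZES = (150, 32, 16, 5)
N_CLASSES = LAYER_SIZES[-1]

_PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3")


@dataclass
class NetworkParameters:
    """Weights and biases of the three dense layers, plus the class order."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d_in, h1, h2, d_out = LAYER_SIZES
        expected = {
            "W1": (h1, d_in), "b1": (h1,),
            "W2": (h2, h1), "b2": (h2,),
            "W3": (d_out, h2), "b3": (d_out,),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        labels = tuple(self.class_labels)
        if len(labels) != d_out or len(set(labels)) != d_out:
            raise ValueError(f"class_labels must be {d_out} unique ids")
        self.class_labels = labels

    def arrays(self) -> tuple[np.ndarray, ...]:
        return tuple(getattr(self, n) for n in _PARAM_NAMES)

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            *(a.copy() for a in self.arrays()), class_labels=self.class_labels
        )


@dataclass
class ForwardTrace:
    """Post-activation values of one forward pass (single input)."""

    h1: np.ndarray
    h2: np.ndarray
    probs: np.ndarray


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-2
    batch_size: int | None = None  # None = full batch
    optimizer: str = "adam"
    seed: int = 0
    early_stop_patience: int | None = None
    early_stop_min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or None for full batch")


@dataclass
class LabeledBatch:
    """Normalised 150-bin inputs with one-hot labels."""

    inputs: np.ndarray  # (N, 150)
    labels: np.ndarray  # (N, 5) one-hot

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.inputs.ndim != 2 or self.inputs.shape[1] != LAYER_SIZES[0]:
            raise ValueError(f"inputs must be (N, {LAYER_SIZES[0]})")
        if self.labels.shape != (self.inputs.shape[0], N_CLASSES):
            raise ValueError(f"labels must be (N, {N_CLASSES})")
        if len(self.inputs) < 1:
            raise ValueError("batch must be non-empty")
        row_sums = self.labels.sum(axis=1)
        if not np.allclose(row_sums, 1.0):
            raise ValueError("each label row must sum to 1 (one-hot)")

    def __len__(self) -> int:
        return len(self.inputs)


def init_network(seed: int, class_labels: tuple[str, ...] | list[str]) -> NetworkParameters:
    """He-uniform weight initialisation (limit sqrt(6/fan_in)), zero biases."""
    labels = tuple(class_labels)
    if len(labels) != N_CLASSES or len(set(labels)) != N_CLASSES:
        raise ValueError(f"exactly {N_CLASSES} unique class labels required")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    d_in, h1, h2, d_out = LAYER_SIZES
    weights = []
    for fan_out, fan_in in ((h1, d_in), (h2, h1), (d_out, h2)):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
    return NetworkParameters(
        W1=weights[0], b1=np.zeros(h1),
        W2=weights[1], b2=np.zeros(h2),
        W3=weights[2], b3=np.zeros(d_out),
        class_labels=labels,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)  # overflow-safe, mathematically identical
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_batch(params: NetworkParameters, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched forward pass; returns (h1, h2, probs) with rows per input."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != LAYER_SIZES[0]:
        raise ValueError(f"inputs must be (N, {LAYER_SIZES[0]}), got {X.shape}")
    h1 = np.maximum(X @ params.W1.T + params.b1, 0.0)
    h2 = np.maximum(h1 @ params.W2.T + params.b2, 0.0)
    probs = _softmax(h2 @ params.W3.T + params.b3)
    return h1, h2, probs


def forward(params: NetworkParameters, x: np.ndarray) -> ForwardTrace:
    """Single-input forward pass returning all post-activation values."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (LAYER_SIZES[0],):
        raise ValueError(f"input must be a {LAYER_SIZES[0]}-vector, got {x.shape}")
    h1, h2, probs = forward_batch(params, x[None, :])
    return ForwardTrace(h1=h1[0], h2=h2[0], probs=probs[0])


def cross_entropy(probs_batch: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class (one-hot labels)."""
    probs_batch = np.asarray(probs_batch, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs_batch.shape != labels.shape or probs_batch.ndim != 2:
        raise ValueError("probs and labels must share shape (N, n_classes)")
    if not np.allclose(probs_batch.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = (probs_batch * labels).sum(axis=1)
    return float(-np.mean(np.log(np.clip(p_true, 1e-300, None))))


def backward(params: NetworkParameters, batch: LabeledBatch) -> dict[str, np.ndarray]:
    """Analytic gradients of the mean cross-entropy w.r.t. every parameter.

    Standard backpropagation through softmax + cross-entropy (output delta
    ``(p - y)/N``) and the two ReLU layers. Agrees with central finite
    differences to < 1e-4 relative error — asserted by the test suite, which
    is the point of hand-writing the model.
    """
    X, Y = batch.inputs, batch.labels
    n = len(batch)
    h1, h2, probs = forward_batch(params, X)
    d3 = (probs - Y) / n  # (N, 5)
    grads = {
        "W3": d3.T @ h2,
        "b3": d3.sum(axis=0),
    }
    d2 = (d3 @ params.W3) * (h2 > 0)  # (N, 16)
    grads["W2"] = d2.T @ h1
    grads["b2"] = d2.sum(axis=0)
    d1 = (d2 @ params.W2) * (h1 > 0)  # (N, 32)
    grads["W1"] = d1.T @ X
    grads["b1"] = d1.sum(axis=0)
    return grads


def train(
    train_set: LabeledBatch, config: TrainConfig,
    class_labels: tuple[str, ...] | list[str] | None = None,
    params: NetworkParameters | None = None,
) -> tuple[NetworkParameters, list[float]]:
    """Fit the network by seeded gradient descent; returns (params, loss per epoch).

    Every class must appear in the training labels. ``params`` may carry a
    pre-initialised network (otherwise one is drawn from ``config.seed``);
    identical data and config reproduce an identical loss history.
    """
    present = train_set.labels.sum(axis=0) > 0
    if not present.all():
        missing = [i for i, p in enumerate(present) if not p]
        raise ValueError(f"classes {missing} absent from the training set")
    if params is None:
        if class_labels is None:
            raise ValueError("either params or class_labels must be given")
        params = init_network(config.seed, class_labels)
    else:
        params = params.copy()

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    arrays = {n: getattr(params, n) for n in _PARAM_NAMES}
    if config.optimizer == "adam":
        m = {n: np.zeros_like(a) for n, a in arrays.items()}
        v = {n: np.zeros_like(a) for n, a in arrays.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

    loss_history: list[float] = []
    best_loss = np.inf
    stale = 0
    n = len(train_set)
    batch_size = config.batch_size or n

    for _ in range(config.epochs):
        _, _, probs = forward_batch(params, train_set.inputs)
        loss = cross_entropy(probs, train_set.labels)
        loss_history.append(loss)

        order = rng.permutation(n) if batch_size < n else np.arange(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            sub = LabeledBatch(train_set.inputs[idx], train_set.labels[idx])
            grads = backward(params, sub)
            if config.optimizer == "adam":
                step += 1
                for name in _PARAM_NAMES:
                    g = grads[name]
                    m[name] = beta1 * m[name] + (1 - beta1) * g
                    v[name] = beta2 * v[name] + (1 - beta2) * g * g
                    m_hat = m[name] / (1 - beta1**step)
                    v_hat = v[name] / (1 - beta2**step)
                    arrays[name] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            else:
                for name in _PARAM_NAMES:
                    arrays[name] -= config.learning_rate * grads[name]

        if config.early_stop_patience is not None:
            if loss < best_loss - config.early_stop_min_delta:
                best_loss = loss
                stale = 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    break
    return params, loss_history


def predict(params: NetworkParameters, spectra: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Class-probability rows for a list/array of normalised spectra."""
    if isinstance(spectra, list) and not spectra:
        return np.empty((0, N_CLASSES))
    X = np.asarray(spectra, dtype=np.float64)
    if X.size == 0:
        return np.empty((0, N_CLASSES))
    _, _, probs = forward_batch(params, X)
    return probs


def save_model(params: NetworkParameters, path: str | Path, *, config: TrainConfig | None = None) -> None:
    """Write a portable, diffable JSON model file (shapes + flat arrays)."""
    payload = {
        "layer_sizes": list(LAYER_SIZES),
        "class_labels": list(params.class_labels),
        "parameters": {
            n: {"shape": list(a.shape), "data": a.ravel().tolist()}
            for n, a in zip(_PARAM_NAMES, params.arrays())
        },
    }
    if config is not None:
        payload["train_config"] = {
            "epochs": config.epochs,
            "learning_rate": config.learning_rate,
            "batch_size": config.batch_size,
            "optimizer": config.optimizer,
            "seed": config.seed,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> NetworkParameters:
    payload = json.loads(Path(path).read_text())
    if tuple(payload["layer_sizes"]) != LAYER_SIZES:
        raise ValueError(f"unsupported layer sizes {payload['layer_sizes']}")
    kwargs = {
        n: np.asarray(d["data"], dtype=np.float64).reshape(d["shape"])
        for n, d in payload["parameters"].items()
    }
    return NetworkParameters(**kwargs, class_labels=tuple(payload["class_labels"]))
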