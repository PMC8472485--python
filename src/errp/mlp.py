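"""Multi-layer perceptron with full-batch scaled-conjugate-gradient training.

The network is the 5-layer pattern-recognition architecture common in ERP
decoding: an input layer the size of the feature vector, three tanh hidden
layers (default 100-50-25), and a single sigmoid output unit.  Training
minimizes the mean binary cross-entropy over the whole training set with
``scg_minimize``; with validation_checks equal to max_iterations there is no
early stopping and no validation split.  Inputs are used as-is (microvolts),
without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ERRP, NONERRP
from .scg import ScgOptions, ScgRecord, scg_minimize

__all__ = ["MLPArchitecture", "MLPModel", "train_mlp", "predict_mlp"]


@dataclass(frozen=True)
class MLPArchitecture:
    input_size: int
    hidden_sizes: tuple[int, ...] = (100, 50, 25)
    hidden_activation: str = "tanh"
    max_iterations: int = 200
    validation_checks: int = 200  # equal to max_iterations => early stopping disabled
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size < 1:
            raise ValueError("input_size must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must all be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.hidden_activation not in ("tanh", "logistic"):
            raise ValueError("hidden_activation must be 'tanh' or 'logistic'")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_size, *self.hidden_sizes, 1)


@dataclass
class MLPModel:
    architecture: MLPArchitecture
    weights: list[np.ndarray]  # per layer, fan_in x fan_out
    biases: list[np.ndarray]
    training_record: ScgRecord = field(default_factory=ScgRecord)


def _shapes(arch: MLPArchitecture) -> list[tuple[int, int]]:
    sizes = arch.layer_sizes
    return [(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]


def _init_params(arch: MLPArchitecture) -> np.ndarray:
    """Seeded Glorot-uniform weights, zero biases, flattened."""
    rng = np.random.default_rng(arch.seed)
    chunks = []
    for fan_in, fan_out in _shapes(arch):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        chunks.append(rng.uniform(-limit, limit, size=fan_in * fan_out))
        chunks.append(np.zeros(fan_out))
    return np.concatenate(chunks)


def _unflatten(arch: MLPArchitecture, w: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    pos = 0
    for fan_in, fan_out in _shapes(arch):
        weights.append(w[pos:pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
        biases.append(w[pos:pos + fan_out])
        pos += fan_out
    return weights, biases


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - a * a
    return a * (1.0 - a)


def _forward_logits(arch: MLPArchitecture, weights, biases, X: np.ndarray):
    """Hidden activations and the pre-sigmoid output (logits)."""
    acts = [X]
    a = X
    for W, b in zip(weights[:-1], biases[:-1]):
        a = _act(a @ W + b, arch.hidden_activation)
        acts.append(a)
    z = (a @ weights[-1] + biases[-1]).ravel()
    return acts, z


def _loss_grad(arch: MLPArchitecture, w: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and its gradient, computed from logits.

    Using log(1+exp(z)) - y z keeps the loss finite for saturated outputs.
    """
    weights, biases = _unflatten(arch, w)
    acts, z = _forward_logits(arch, weights, biases, X)
    n = len(y)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    prob = 1.0 / (1.0 + np.exp(-z))
    dz = ((prob - y) / n)[:, None]

    grads = []
    delta = dz
    for i in range(len(weights) - 1, -1, -1):
        gW = acts[i].T @ delta
        gb = delta.sum(axis=0)
        grads.append((gW, gb))
        if i > 0:
            delta = (delta @ weights[i].T) * _act_grad(acts[i], arch.hidden_activation)
    grads.reverse()
    flat = np.concatenate([np.concatenate([gW.ravel(), gb]) for gW, gb in grads])
    return loss, flat


def train_mlp(X: np.ndarray, labels: np.ndarray, arch: MLPArchitecture,
              scg_opts: ScgOptions | None = None) -> MLPModel:
    """Fit the network by full-batch SCG on the mean cross-entropy.

    ``labels`` are class codes (ErrP=1 / NonErrP=0).  Deterministic given
    (X, labels, architecture).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.shape[1] != arch.input_size:
        raise ValueError(f"expected {arch.input_size} features, got {X.shape[1]}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")

    opts = scg_opts or ScgOptions(max_iterations=arch.max_iterations)
    w0 = _init_params(arch)
    w_star, record = scg_minimize(lambda w: _loss_grad(arch, w, X, y), w0, opts)
    weights, biases = _unflatten(arch, w_star)
    return MLPModel(arch, weights, biases, record)


def predict_mlp(model: MLPModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid output probability of ErrP and the thresholded labels.

    A trial is labelled ErrP when the output probability is >= 0.5.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.architecture.input_size:
        raise ValueError(
            f"expected n x {model.architecture.input_size} features, got {X.shape}"
        )
    _, z = _forward_logits(model.architecture, model.weights, model.biases, X)
    prob = 1.0 / (1.0 + np.exp(-z))
    labels = np.where(prob >= 0.5, ERRP, NONERRP)
    return prob, labels
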