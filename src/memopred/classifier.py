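"""Four-layer feed-forward neural network trained by online backpropagation.

The network uses logistic sigmoid activations throughout and a single output
neuron for the binary membrane / nonmembrane decision (membrane encoded as
target 1).  Training minimises the half sum-of-squared-errors

    E = 1/2 * sum_p (t_p - o_p)^2

by per-pattern (online) gradient descent with learning rate ``lambda``
(default 0.01).  Pre-activation sums ``s`` are stored on the forward pass and
reused for the weight update; per-neuron biases are treated as weights from a
constant-1 activation and can be disabled for a literal minimal network.

The default output delta is the exact gradient, -(t - o) * sigma'(s_out); a
``literal_output_delta`` flag drops the sigma' factor for the simplified
textbook update rule (no longer the gradient of E, kept for comparison).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import Scaler


class TrainingError(RuntimeError):
    """Training aborted (non-finite gradients or invalid configuration)."""


class ModelFormatError(ValueError):
    """Model archive is corrupt, incompatible, or fingerprint-mismatched."""


MODEL_FORMAT_VERSION = 1


def sigmoid(n):
    """Logistic function 1 / (1 + e^-n), clipped for numerical safety."""
    n = np.clip(n, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-n))


def sigmoid_derivative(n):
    """d/dn sigmoid(n) = sigma(n) (1 - sigma(n))."""
    s = sigmoid(n)
    return s * (1.0 - s)


@dataclass
class MLPModel:
    """Layer sizes plus per-connection weights and per-neuron biases."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]  # weights[l]: (sizes[l], sizes[l+1])
    biases: list[np.ndarray]  # biases[l]: (sizes[l+1],)
    use_bias: bool = True
    fingerprint: str = ""

    def copy(self) -> "MLPModel":
        return MLPModel(
            layer_sizes=self.layer_sizes,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            use_bias=self.use_bias,
            fingerprint=self.fingerprint,
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Backpropagation hyperparameters."""

    lam: float = 0.01  # learning rate lambda
    max_epochs: int = 1000
    error_tolerance: float = 1e-3  # stop when epoch E drops below this
    seed: int = 0
    init_scale: float = 0.5
    shuffle: bool = True
    use_bias: bool = True
    literal_output_delta: bool = False

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise TrainingError("learning rate lambda must be > 0")
        if self.max_epochs < 1:
            raise TrainingError("max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch error trace (half-SSE E and conventional RMSE)."""

    epoch_error: list[float] = field(default_factory=list)
    epoch_rmse: list[float] = field(default_factory=list)
    stopping_reason: str = ""


def init_model(
    layer_sizes: Sequence[int],
    seed: int = 0,
    init_scale: float = 0.5,
    use_bias: bool = True,
    fingerprint: str = "",
) -> MLPModel:
    """Random uniform weights in [-init_scale, +init_scale], seeded."""
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise TrainingError("layer_sizes needs >= 2 positive entries")
    rng = np.random.default_rng(seed)
    weights = [
        rng.uniform(-init_scale, init_scale, size=(a, b))
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    biases = [
        rng.uniform(-init_scale, init_scale, size=b) if use_bias else np.zeros(b)
        for b in sizes[1:]
    ]
    return MLPModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        use_bias=use_bias,
        fingerprint=fingerprint,
    )


def forward(model: MLPModel, x: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Forward pass; returns per-layer activations and stored sums s.

    ``activations[0]`` is the input; ``sums[l]`` holds the pre-activation sum
    of layer ``l + 1`` (kept for the backward pass).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.layer_sizes[0]:
        raise TrainingError(
            f"input length {x.size} != input layer size {model.layer_sizes[0]}"
        )
    activations = [x]
    sums = []
    a = x
    for w, b in zip(model.weights, model.biases):
        s = a @ w + b
        sums.append(s)
        a = sigmoid(s)
        activations.append(a)
    return activations, sums


def compute_error(targets, outputs) -> float:
    """E = 1/2 sum_p (t_p - o_p)^2, the training objective as printed."""
    t = np.asarray(targets, dtype=float).ravel()
    o = np.asarray(outputs, dtype=float).ravel()
    if t.size != o.size:
        raise TrainingError("targets and outputs differ in length")
    return float(0.5 * np.sum((t - o) ** 2))


def rmse(targets, outputs) -> float:
    """Conventional root-mean-squared error (logged alongside E)."""
    t = np.asarray(targets, dtype=float).ravel()
    o = np.asarray(outputs, dtype=float).ravel()
    return float(np.sqrt(np.mean((t - o) ** 2)))


def gradients(
    model: MLPModel, x, t, literal_output_delta: bool = False
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Backpropagated gradients of E for one pattern.

    Returns (weight grads, bias grads, output o).  delta_to = dE/ds_to;
    dE/dw_from,to = o_from * delta_to.
    """
    activations, sums = forward(model, x)
    o = activations[-1]
    t = np.asarray(t, dtype=float).ravel()
    delta = -(t - o)
    if not literal_output_delta:
        delta = delta * sigmoid_derivative(sums[-1])
    w_grads: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    b_grads: list[np.ndarray] = [None] * len(model.biases)  # type: ignore[list-item]
    for layer in range(len(model.weights) - 1, -1, -1):
        w_grads[layer] = np.outer(activations[layer], delta)
        b_grads[layer] = delta
        if layer > 0:
            delta = sigmoid_derivative(sums[layer - 1]) * (model.weights[layer] @ delta)
    return w_grads, b_grads, float(o[0]) if o.size == 1 else o


def backprop_update(
    model: MLPModel,
    x,
    t,
    lam: float = 0.01,
    literal_output_delta: bool = False,
) -> MLPModel:
    """One online gradient-descent step on a single pattern (in place)."""
    w_grads, b_grads, _ = gradients(model, x, t, literal_output_delta)
    for layer, (gw, gb) in enumerate(zip(w_grads, b_grads)):
        if not (np.all(np.isfinite(gw)) and np.all(np.isfinite(gb))):
            raise TrainingError(f"non-finite gradient in layer {layer}; training aborted")
        model.weights[layer] -= lam * gw
        if model.use_bias:
            model.biases[layer] -= lam * gb
    return model


def train(
    model: MLPModel,
    X: np.ndarray,
    T: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[MLPModel, TrainingHistory]:
    """Online backpropagation: every pattern is trained one at a time.

    An epoch presents all patterns (shuffled when configured, seeded); the
    epoch error E is computed from a fresh forward pass over the whole set.
    Stops at ``max_epochs`` or when E drops below ``error_tolerance``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.asarray(T, dtype=float).ravel()
    if X.shape[0] == 0:
        raise TrainingError("empty training set")
    if X.shape[0] != T.size:
        raise TrainingError("X and T are not aligned")
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    n = X.shape[0]
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        for idx in order:
            backprop_update(model, X[idx], T[idx], config.lam, config.literal_output_delta)
        outputs = predict_scores(model, X)
        e = compute_error(T, outputs)
        history.epoch_error.append(e)
        history.epoch_rmse.append(rmse(T, outputs))
        if e < config.error_tolerance:
            history.stopping_reason = f"error_tolerance reached at epoch {_epoch + 1}"
            break
    else:
        history.stopping_reason = f"max_epochs ({config.max_epochs}) reached"
    return model, history


def predict(model: MLPModel, x) -> float:
    """Sigmoid output score in (0, 1) for one feature vector."""
    activations, _ = forward(model, x)
    return float(activations[-1][0])


def predict_scores(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Vectorised scores for a feature matrix (rows are patterns)."""
    A = np.atleast_2d(np.asarray(X, dtype=float))
    for w, b in zip(model.weights, model.biases):
        A = sigmoid(A @ w + b)
    return A[:, 0]


def predict_label(model: MLPModel, x, threshold: float = 0.5) -> str:
    """'membrane' iff score >= threshold (ties go to the positive class)."""
    return "membrane" if predict(model, x) >= threshold else "nonmembrane"


# --- model archive ----------------------------------------------------------


def save_model(
    path: str | Path,
    model: MLPModel,
    scaler: Scaler | None = None,
    config: TrainingConfig | None = None,
) -> None:
    """Write a self-describing JSON archive (weights, biases, scaler, config)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "use_bias": model.use_bias,
        "fingerprint": model.fingerprint,
        "scaler": None
        if scaler is None
        else {
            "mean": scaler.mean.tolist(),
            "scale": scaler.scale.tolist(),
            "fingerprint": scaler.fingerprint,
        },
        "training_config": None if config is None else vars(config).copy(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[MLPModel, Scaler | None, TrainingConfig | None]:
    """Load a model archive; bit-exact round trip of weights and metadata."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(f"unsupported or corrupt model archive {path}")
    try:
        model = MLPModel(
            layer_sizes=tuple(payload["layer_sizes"]),
            weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
            biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
            use_bias=bool(payload["use_bias"]),
            fingerprint=payload.get("fingerprint", ""),
        )
        scaler = None
        if payload.get("scaler") is not None:
            s = payload["scaler"]
            scaler = Scaler(
                mean=np.asarray(s["mean"], dtype=float),
                scale=np.asarray(s["scale"], dtype=float),
                fingerprint=s.get("fingerprint", ""),
            )
        config = None
        if payload.get("training_config") is not None:
            config = TrainingConfig(**payload["training_config"])
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"corrupt model archive {path}: {exc}") from exc
    return model, scaler, config


def make_mlp_trainer(
    hidden: Sequence[int] = (32, 16),
    config: TrainingConfig = TrainingConfig(),
):
    """Trainer closure for cross-validation: fits a scaler and an MLP on each
    fold's training instances only, returning a score function for held-out
    rows.  Suitable for :func:`memopred.evaluation.jackknife` / ``kfold``."""
    from .features import apply_scaler, fit_scaler

    def trainer(X_train: np.ndarray, y_train, seed: int):
        t = np.array([1.0 if str(lbl) == "membrane" else 0.0 for lbl in y_train])
        scaler = fit_scaler(np.asarray(X_train, dtype=float))
        Xs = apply_scaler(scaler, X_train)
        sizes = (Xs.shape[1], *hidden, 1)
        fold_config = replace(config, seed=seed)
        model = init_model(sizes, seed=seed, init_scale=config.init_scale,
                           use_bias=config.use_bias)
        model, _ = train(model, Xs, t, fold_config)

        def score(X_test: np.ndarray) -> np.ndarray:
            return predict_scores(model, apply_scaler(scaler, X_test))

        return score

    return trainer


def check_fingerprint(model: MLPModel, fingerprint: str) -> None:
    """Refuse feature vectors extracted under a different layout."""
    if model.fingerprint and fingerprint and model.fingerprint != fingerprint:
        raise ModelFormatError(
            "model was trained under a different feature layout "
            f"({model.fingerprint} != {fingerprint})"
        )
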