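"""Feed-forward classifier trained with backpropagation.

A deliberately transparent numpy implementation: dense ReLU hidden layers
(default topology 12-24-12-24-12), a 3-unit softmax output, categorical
cross-entropy with optional L1/L2 weight penalties, inverted dropout on
hidden activations during training, and mini-batch optimization by Adam
(default), plain SGD, or SGD with momentum. Everything is seeded and
reproducible, and the exact loss/gradient pair is exposed so gradients
can be verified against finite differences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np


@dataclass
class MLPConfig:
    """Topology and training hyperparameters.

    ``hidden_layers`` is the neuron count per hidden layer. Dropout 0.5,
    64 epochs and batch size 10 are the study defaults; Adam runs with its
    canonical constants (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8).
    """

    hidden_layers: tuple[int, ...] = (12, 24, 12, 24, 12)
    activation: str = "relu"
    dropout_rate: float = 0.5
    epochs: int = 64
    batch_size: int = 10
    optimizer: str = "adam"  # adam | sgd | sgd_momentum
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    momentum: float = 0.9
    l1_lambda: float = 0.0
    l2_lambda: float = 0.0
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden_layers must be non-empty positive counts")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.activation != "relu":
            raise ValueError("only relu hidden activation is supported")
        if self.optimizer not in ("adam", "sgd", "sgd_momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainedMLP:
    """Layer parameters plus training history."""

    weights: list[np.ndarray]  # weights[i]: (fan_in, fan_out)
    biases: list[np.ndarray]
    config: MLPConfig
    input_dim: int
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"loss": [], "accuracy": []}
    )

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def layer_dims(self) -> list[int]:
        return [self.input_dim, *self.config.hidden_layers, self.config.n_classes]


def init_mlp(input_dim: int, cfg: MLPConfig | None = None) -> TrainedMLP:
    """He-initialised network keyed to ``cfg.seed``; biases start at zero."""
    cfg = cfg or MLPConfig()
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
    dims = [input_dim, *cfg.hidden_layers, cfg.n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    return TrainedMLP(weights=weights, biases=biases, config=cfg, input_dim=input_dim)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    model: TrainedMLP,
    x: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray | None], np.ndarray]:
    """Forward pass; inverted dropout applied only when a rng is given."""
    rate = model.config.dropout_rate if dropout_rng is not None else 0.0
    acts = [x]
    masks: list[np.ndarray | None] = []
    h = x
    n_hidden = len(model.config.hidden_layers)
    for i in range(n_hidden):
        h = np.maximum(h @ model.weights[i] + model.biases[i], 0.0)
        if rate > 0:
            mask = (dropout_rng.random(h.shape) >= rate) / (1.0 - rate)
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(h)
    logits = h @ model.weights[-1] + model.biases[-1]
    return acts, masks, logits


def _regularization(model: TrainedMLP) -> float:
    cfg = model.config
    if cfg.l1_lambda == 0 and cfg.l2_lambda == 0:
        return 0.0
    return float(
        cfg.l1_lambda * sum(np.abs(w).sum() for w in model.weights)
        + cfg.l2_lambda * sum((w ** 2).sum() for w in model.weights)
    )


def loss_and_grads(
    model: TrainedMLP,
    x: np.ndarray,
    y: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Cross-entropy (+ L1/L2 penalty) and its exact parameter gradients.

    ``y`` holds internal class indices. Without a dropout rng this is the
    deterministic training loss used by the finite-difference checks.
    """
    cfg = model.config
    n = x.shape[0]
    acts, masks, logits = _forward(model, x, dropout_rng)
    probs = _softmax(logits)
    ce = -np.log(np.clip(probs[np.arange(n), y], 1e-300, None)).mean()
    loss = ce + _regularization(model)

    delta = probs
    delta[np.arange(n), y] -= 1.0
    delta /= n
    gw = [np.empty_like(w) for w in model.weights]
    gb = [np.empty_like(b) for b in model.biases]
    for i in range(len(model.weights) - 1, -1, -1):
        gw[i] = acts[i].T @ delta
        gb[i] = delta.sum(axis=0)
        if cfg.l1_lambda:
            gw[i] += cfg.l1_lambda * np.sign(model.weights[i])
        if cfg.l2_lambda:
            gw[i] += 2.0 * cfg.l2_lambda * model.weights[i]
        if i > 0:
            delta = delta @ model.weights[i].T
            if masks[i - 1] is not None:
                delta = delta * masks[i - 1]
            delta[acts[i] <= 0] = 0.0
    return float(loss), gw, gb


class _Optimizer:
    def __init__(self, model: TrainedMLP):
        cfg = model.config
        self.cfg = cfg
        self.t = 0
        if cfg.optimizer == "adam":
            self.m = [np.zeros_like(w) for w in model.weights + model.biases]
            self.v = [np.zeros_like(w) for w in model.weights + model.biases]
        elif cfg.optimizer == "sgd_momentum":
            self.vel = [np.zeros_like(w) for w in model.weights + model.biases]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        cfg = self.cfg
        lr = cfg.learning_rate
        if cfg.optimizer == "sgd":
            for p, g in zip(params, grads):
                p -= lr * g
        elif cfg.optimizer == "sgd_momentum":
            for i, (p, g) in enumerate(zip(params, grads)):
                self.vel[i] = cfg.momentum * self.vel[i] - lr * g
                p += self.vel[i]
        else:  # adam, bias-corrected moments
            self.t += 1
            b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_epsilon
            for i, (p, g) in enumerate(zip(params, grads)):
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                m_hat = self.m[i] / (1 - b1 ** self.t)
                v_hat = self.v[i] / (1 - b2 ** self.t)
                p -= lr * m_hat / (np.sqrt(v_hat) + eps)


def train_mlp(
    model: TrainedMLP,
    features: np.ndarray,
    labels: np.ndarray,
    cfg: MLPConfig | None = None,
) -> TrainedMLP:
    """Mini-batch training; returns a new trained model.

    Rows are reshuffled every epoch from the seeded stream; dropout is
    active only here. History records the mean in-batch loss and the
    end-of-epoch (deterministic, dropout-free) training accuracy. A
    non-finite loss aborts with the epoch/batch in the message.
    """
    x = np.asarray(features, float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    cfg = cfg or model.config
    if np.any(y < 0) or np.any(y >= cfg.n_classes):
        raise ValueError(f"labels must be internal indices 0..{cfg.n_classes - 1}")
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} != model input dim {model.input_dim}"
        )
    model = copy.deepcopy(model)
    model.config = cfg
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    drop_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    opt = _Optimizer(model)
    n = x.shape[0]
    params = model.weights + model.biases
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            rng = drop_rng if cfg.dropout_rate > 0 else None
            loss, gw, gb = loss_and_grads(model, x[idx], y[idx], rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            opt.step(params, gw + gb)
            batch_losses.append(loss)
        model.history["loss"].append(float(np.mean(batch_losses)))
        model.history["accuracy"].append(
            float((predict(model, x) == y).mean())
        )
    return model


def predict_proba(model: TrainedMLP, features: np.ndarray) -> np.ndarray:
    """Class distribution per row; dropout inactive, rows sum to one."""
    x = np.asarray(features, float)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} != model input dim {model.input_dim}"
        )
    _, _, logits = _forward(model, x, dropout_rng=None)
    return _softmax(logits)


def predict(model: TrainedMLP, features: np.ndarray) -> np.ndarray:
    """Argmax class per row; ties break toward the lower class index."""
    return np.argmax(predict_proba(model, features), axis=1)
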