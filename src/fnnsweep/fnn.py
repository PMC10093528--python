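"""From-scratch fully connected feedforward network for binary outcomes.

Implements exactly the eleven tunable hyperparameters under study: output
activation (sigmoid / hard sigmoid), weight initializer (five schemes),
number of hidden layers, learning rate, momentum, iteration-based learning
rate decay, inverted dropout, epochs, batch size, and L1/L2 weight
penalties.  Hidden activations are ReLU; the single output unit is paired
with binary cross-entropy.  Training is plain mini-batch SGD with classical
momentum:

    lr_t = lr0 / (1 + decay * t)
    v   <- momentum * v - lr_t * grad
    w   <- w + v

where ``t`` counts completed mini-batch updates (a per-epoch counting mode
is available via ``decay_mode``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

EPS = 1e-7  # probability clipping floor for cross-entropy

OUTPUT_ACTIVATIONS = ("sigmoid", "hard_sigmoid")
INITIALIZERS = ("uniform", "normal", "glorot_uniform", "glorot_normal", "lecun_uniform")


class DimensionError(ValueError):
    """Array shapes do not match the network architecture."""


class DivergenceError(ArithmeticError):
    """Training produced a non-finite loss or gradient."""


@dataclass(frozen=True)
class HyperParams:
    """One complete setting of the 11 tunable hyperparameters.

    Defaults are the base values of the study protocol (the setting every
    non-swept hyperparameter assumes in fixed-base sweeps).
    """

    output_activation: str = "sigmoid"
    weight_initializer: str = "glorot_normal"
    n_hidden_layers: int = 2
    learning_rate: float = 0.005
    momentum: float = 0.9
    decay: float = 0.01
    dropout_rate: float = 0.5
    epochs: int = 100
    batch_size: int = 10
    l1: float = 0.0
    l2: float = 0.008
    hidden_width: int = 75
    decay_mode: str = "batch"  # "batch": t = updates done; "epoch": t = epoch index

    def __post_init__(self):
        if self.output_activation not in OUTPUT_ACTIVATIONS:
            raise ValueError(f"unknown output activation {self.output_activation!r}")
        if self.weight_initializer not in INITIALIZERS:
            raise ValueError(f"unknown initializer {self.weight_initializer!r}")
        if self.decay_mode not in ("batch", "epoch"):
            raise ValueError(f"unknown decay_mode {self.decay_mode!r}")
        if self.n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.decay < 0:
            raise ValueError("decay must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("l1 and l2 must be non-negative")

    def with_(self, **kwargs) -> "HyperParams":
        return replace(self, **kwargs)

    def layer_sizes(self, n_features: int) -> list[int]:
        """Size chain input -> hidden x n_hidden_layers -> 1 output."""
        return [n_features] + [self.hidden_width] * self.n_hidden_layers + [1]


@dataclass
class NetworkParams:
    """Per-layer weight matrices, bias vectors and momentum velocities."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    velocities_w: list[np.ndarray] = field(default_factory=list)
    velocities_b: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if not self.velocities_w:
            self.velocities_w = [np.zeros_like(w) for w in self.weights]
            self.velocities_b = [np.zeros_like(b) for b in self.biases]

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def sum_sq_weights(self) -> float:
        return float(sum(np.sum(w * w) for w in self.weights))

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            [v.copy() for v in self.velocities_w],
            [v.copy() for v in self.velocities_b],
        )


@dataclass
class TrainHistory:
    """Per-epoch mean training loss and effective learning-rate trace."""

    losses: list[float] = field(default_factory=list)
    effective_lr: list[float] = field(default_factory=list)
    iterations: int = 0


def init_params(layer_sizes, initializer: str, seed: int) -> NetworkParams:
    """Initialize weights per the named scheme; biases and velocities are zero.

    Schemes (fan_in x fan_out per layer):
      glorot_normal  N(0, sqrt(2/(fan_in+fan_out)))
      glorot_uniform U(+-sqrt(6/(fan_in+fan_out)))
      lecun_uniform  U(+-sqrt(3/fan_in))
      uniform        U(+-0.05)
      normal         N(0, 0.05)
    """
    if initializer not in INITIALIZERS:
        raise ValueError(f"unknown initializer {initializer!r}; choose from {INITIALIZERS}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        shape = (fan_in, fan_out)
        if initializer == "glorot_normal":
            w = rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), shape)
        elif initializer == "glorot_uniform":
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-lim, lim, shape)
        elif initializer == "lecun_uniform":
            lim = np.sqrt(3.0 / fan_in)
            w = rng.uniform(-lim, lim, shape)
        elif initializer == "uniform":
            w = rng.uniform(-0.05, 0.05, shape)
        else:  # normal
            w = rng.normal(0.0, 0.05, shape)
        weights.append(w)
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights, biases)


def activate(x, kind: str):
    """relu / sigmoid / hard_sigmoid, vectorized.

    hard_sigmoid is the piecewise-linear approximation clip(0.2x + 0.5, 0, 1).
    """
    x = np.asarray(x, dtype=float)
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "sigmoid":
        # split by sign for numerical stability at large |x|
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    if kind == "hard_sigmoid":
        return np.clip(0.2 * x + 0.5, 0.0, 1.0)
    raise ValueError(f"unknown activation {kind!r}")


def forward(params: NetworkParams, X: np.ndarray, hp: HyperParams,
            training: bool = False, rng: np.random.Generator | None = None):
    """Forward pass returning every intermediate needed by backprop.

    Returns a dict with pre-activations ``z`` per layer, post-dropout hidden
    outputs ``h`` (h[0] is the input), dropout ``masks`` (None in inference
    or when dropout_rate is 0) and output probabilities ``p``.  Inverted
    dropout scales kept units by 1/(1-rate) at train time so inference needs
    no rescaling.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.weights[0].shape[0]:
        raise DimensionError(
            f"input has {X.shape[1]} features but layer 0 expects {params.weights[0].shape[0]}")
    n_layers = len(params.weights)
    use_dropout = training and hp.dropout_rate > 0
    if use_dropout and rng is None:
        raise ValueError("training-mode forward with dropout requires an rng")
    keep = 1.0 - hp.dropout_rate

    h = [X]
    zs, masks = [], []
    a = X
    for l in range(n_layers - 1):  # hidden layers
        z = a @ params.weights[l] + params.biases[l]
        zs.append(z)
        a = np.maximum(z, 0.0)
        if use_dropout:
            mask = (rng.random(a.shape) < keep) / keep
            a = a * mask
            masks.append(mask)
        else:
            masks.append(None)
        h.append(a)
    z_out = a @ params.weights[-1] + params.biases[-1]
    zs.append(z_out)
    p = activate(z_out, hp.output_activation)
    return {"z": zs, "h": h, "masks": masks, "p": p}


def loss(y: np.ndarray, p: np.ndarray, hp: HyperParams, params: NetworkParams) -> float:
    """Mean binary cross-entropy plus l1*sum|W| + l2*sum(W^2) (biases exempt)."""
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if y.shape != p.shape:
        raise DimensionError(f"labels length {y.size} != predictions length {p.size}")
    pc = np.clip(p, EPS, 1.0 - EPS)
    bce = -float(np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    penalty = 0.0
    if hp.l1 > 0:
        penalty += hp.l1 * sum(float(np.sum(np.abs(w))) for w in params.weights)
    if hp.l2 > 0:
        penalty += hp.l2 * sum(float(np.sum(w * w)) for w in params.weights)
    return bce + penalty


def backward(params: NetworkParams, cache: dict, y: np.ndarray, hp: HyperParams):
    """Gradients of :func:`loss` w.r.t. every weight and bias.

    L1 contributes the subgradient ``l1*sign(W)``, L2 contributes ``2*l2*W``.
    Dropout masks from the forward pass are re-applied on the backward path.
    The clipping of probabilities in the loss is respected: cases whose raw
    output fell outside [eps, 1-eps] carry zero gradient through the clip.
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    p = cache["p"]
    if p.shape[0] != y.shape[0]:
        raise DimensionError(f"stale activations: {p.shape[0]} cases vs {y.shape[0]} labels")
    n = y.shape[0]
    pc = np.clip(p, EPS, 1.0 - EPS)
    # dL/dp through the clip (zero where clipped), then dp/dz per activation
    dL_dp = (pc - y) / (pc * (1.0 - pc)) / n
    inside = (p > EPS) & (p < 1.0 - EPS)
    dL_dp = dL_dp * inside
    if hp.output_activation == "sigmoid":
        dp_dz = p * (1.0 - p)
    else:  # hard_sigmoid: slope 0.2 strictly inside the ramp
        dp_dz = 0.2 * ((p > 0.0) & (p < 1.0))
    delta = dL_dp * dp_dz

    grads_w = [None] * len(params.weights)
    grads_b = [None] * len(params.biases)
    for l in range(len(params.weights) - 1, -1, -1):
        a_prev = cache["h"][l]
        grads_w[l] = a_prev.T @ delta
        grads_b[l] = delta.sum(axis=0)
        if hp.l1 > 0:
            grads_w[l] = grads_w[l] + hp.l1 * np.sign(params.weights[l])
        if hp.l2 > 0:
            grads_w[l] = grads_w[l] + 2.0 * hp.l2 * params.weights[l]
        if l > 0:
            g = delta @ params.weights[l].T
            mask = cache["masks"][l - 1]
            if mask is not None:
                g = g * mask
            delta = g * (cache["z"][l - 1] > 0)
    return grads_w, grads_b


def effective_lr(hp: HyperParams, iteration: int) -> float:
    """Iteration-based decay schedule lr_t = lr0 / (1 + decay * t)."""
    return hp.learning_rate / (1.0 + hp.decay * iteration)


def sgd_update(params: NetworkParams, grads_w, grads_b, hp: HyperParams,
               iteration: int) -> int:
    """In-place classical-momentum SGD step; returns the incremented iteration."""
    lr = effective_lr(hp, iteration)
    for l in range(len(params.weights)):
        if not (np.all(np.isfinite(grads_w[l])) and np.all(np.isfinite(grads_b[l]))):
            raise DivergenceError(f"non-finite gradient in layer {l} at iteration {iteration}")
        params.velocities_w[l] = hp.momentum * params.velocities_w[l] - lr * grads_w[l]
        params.velocities_b[l] = hp.momentum * params.velocities_b[l] - lr * grads_b[l]
        params.weights[l] = params.weights[l] + params.velocities_w[l]
        params.biases[l] = params.biases[l] + params.velocities_b[l]
    return iteration + 1


def train(X: np.ndarray, y: np.ndarray, hp: HyperParams, seed: int):
    """Train on (X, y) for ``hp.epochs`` full passes; returns (params, history).

    Each epoch the cases are reshuffled (seeded), partitioned into batches of
    ``hp.batch_size`` (last batch possibly smaller), and every batch applies
    forward / backward / SGD-with-momentum.  A batch size exceeding the
    training-set size is clamped with a warning.  Deterministic: identical
    (X, y, hp, seed) give bit-identical weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if y.shape[0] != n:
        raise DimensionError(f"{n} cases but {y.shape[0]} labels")
    batch_size = hp.batch_size
    if batch_size > n:
        logger.warning("batch_size %d exceeds training size %d; clamped", batch_size, n)
        batch_size = n

    rng = np.random.default_rng(seed)
    params = init_params(hp.layer_sizes(X.shape[1]), hp.weight_initializer, seed)
    history = TrainHistory()
    t = 0
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        history.effective_lr.append(
            effective_lr(hp, epoch if hp.decay_mode == "epoch" else t))
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            cache = forward(params, xb, hp, training=True, rng=rng)
            batch_loss = loss(yb, cache["p"], hp, params)
            if not np.isfinite(batch_loss):
                raise DivergenceError(f"non-finite loss in epoch {epoch}")
            epoch_losses.append(batch_loss)
            gw, gb = backward(params, cache, yb, hp)
            t_for_lr = epoch if hp.decay_mode == "epoch" else t
            try:
                sgd_update(params, gw, gb, hp, t_for_lr)
            except DivergenceError as e:
                raise DivergenceError(f"epoch {epoch}: {e}") from None
            t += 1
        history.losses.append(float(np.mean(epoch_losses)))
    history.iterations = t
    return params, history


def predict(params: NetworkParams, X: np.ndarray, hp: HyperParams) -> np.ndarray:
    """Inference-mode forward pass; probabilities in [0, 1], dropout ignored."""
    return forward(params, X, hp, training=False)["p"].ravel()


def save_checkpoint(params: NetworkParams, hp: HyperParams, path) -> None:
    """Write a JSON checkpoint with hex-encoded floats for exact round-trip."""
    blob = {
        "layer_sizes": params.layer_sizes,
        "hyperparams": {k: getattr(hp, k) for k in (
            "output_activation", "weight_initializer", "n_hidden_layers",
            "learning_rate", "momentum", "decay", "dropout_rate", "epochs",
            "batch_size", "l1", "l2", "hidden_width", "decay_mode")},
        "weights": [[f.hex() for f in w.ravel()] for w in params.weights],
        "biases": [[f.hex() for f in b] for b in params.biases],
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns (params, hyperparams)."""
    with open(path) as fh:
        blob = json.load(fh)
    sizes = blob["layer_sizes"]
    weights, biases = [], []
    for l, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:])):
        weights.append(np.array([float.fromhex(s) for s in blob["weights"][l]]).reshape(fi, fo))
        biases.append(np.array([float.fromhex(s) for s in blob["biases"][l]]))
    return NetworkParams(weights, biases), HyperParams(**blob["hyperparams"])
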