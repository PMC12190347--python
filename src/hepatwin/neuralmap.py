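"""Feed-forward maps between cluster expression and mechanistic state.

Two small regression networks connect the data and the model: a *forward*
map from a patient's K-cluster expression vector (optionally augmented with
the resection fraction) to the 10-component mechanistic state, and a
*reverse* map from simulated states back to cluster expression.  Both use
the same architecture — input -> 64 -> 128 -> output, a rectifier after
each hidden layer, dropout (p = 0.2) after each hidden layer during
training — trained with mean squared error and the Adam optimizer.

The implementation is plain numpy with analytic backpropagation, fully
seeded: the same seed and data reproduce weights bit-exactly, and inference
is deterministic (dropout disabled).  Inputs and targets are standardized
per feature with training-set statistics and de-standardized at prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class NetSpec:
    """Architecture and optimization settings of one map."""

    input_dim: int
    output_dim: int
    hidden_dims: tuple[int, ...] = (64, 128)
    dropout_p: float = 0.2
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: int | None = None  # None = full batch
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.output_dim <= 0:
            raise ValueError("dimensions must be positive")
        if any(h <= 0 for h in self.hidden_dims):
            raise ValueError("hidden dimensions must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")

    @property
    def layer_dims(self) -> tuple[tuple[int, int], ...]:
        dims = (self.input_dim, *self.hidden_dims, self.output_dim)
        return tuple(zip(dims[:-1], dims[1:]))


@dataclass
class TrainingSet:
    """Paired (input, target) rows with per-row provenance."""

    inputs: np.ndarray
    targets: np.ndarray
    provenance: tuple[tuple[str, str], ...] = ()  # (patient, time label)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.targets.ndim != 2:
            raise ValueError("inputs and targets must be 2-d")
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets row counts differ")

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass
class TrainedMap:
    """A trained map: weights, normalization statistics and loss log."""

    spec: NetSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    training_log: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    direction: str = "forward"


def parameter_count(spec: NetSpec) -> int:
    """Total trainable parameters: sum over layers of in*out + out."""
    return sum(i * o + o for i, o in spec.layer_dims)


def _init_layers(spec: NetSpec, rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in spec.layer_dims:
        scale = np.sqrt(2.0 / fan_in)  # He initialization for rectifiers
        weights.append(rng.standard_normal((fan_in, fan_out)) * scale)
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward_pass(x, weights, biases, drop_masks=None):
    """Return activations per layer; ``drop_masks`` applies inverted dropout."""
    acts = [x]
    h = x
    n_layers = len(weights)
    for li, (W, b) in enumerate(zip(weights, biases)):
        z = h @ W + b
        if li < n_layers - 1:
            h = np.maximum(z, 0.0)
            if drop_masks is not None:
                h = h * drop_masks[li]
        else:
            h = z
        acts.append(h)
    return acts


def _backward_pass(acts, targets, weights, drop_masks=None):
    """MSE gradients (mean over rows and output features)."""
    n = acts[0].shape[0]
    d = acts[-1].shape[1]
    grad_out = 2.0 * (acts[-1] - targets) / (n * d)
    gw = [None] * len(weights)
    gb = [None] * len(weights)
    delta = grad_out
    for li in range(len(weights) - 1, -1, -1):
        gw[li] = acts[li].T @ delta
        gb[li] = delta.sum(axis=0)
        if li > 0:
            delta = delta @ weights[li].T
            if drop_masks is not None:
                delta = delta * drop_masks[li - 1]
            delta = delta * (acts[li] > 0)
    return gw, gb


def train_map(
    training: TrainingSet,
    spec: NetSpec,
    direction: str = "forward",
) -> TrainedMap:
    """Fit the map by Adam on the mean squared error.

    Dropout (inverted scaling) is active during training only.  The run is
    fully determined by ``spec.seed`` and the data.  Raises on an empty
    training set or a non-finite loss.
    """
    if len(training) == 0:
        raise ValueError("empty training set")
    if training.inputs.shape[1] != spec.input_dim:
        raise ValueError("training input width does not match spec")
    if training.targets.shape[1] != spec.output_dim:
        raise ValueError("training target width does not match spec")

    X, Y = training.inputs, training.targets
    if spec.standardize:
        x_mean, x_std = X.mean(axis=0), X.std(axis=0)
        y_mean, y_std = Y.mean(axis=0), Y.std(axis=0)
        x_std = np.where(x_std > 0, x_std, 1.0)
        y_std = np.where(y_std > 0, y_std, 1.0)
    else:
        x_mean = np.zeros(X.shape[1]); x_std = np.ones(X.shape[1])
        y_mean = np.zeros(Y.shape[1]); y_std = np.ones(Y.shape[1])
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_mean) / y_std

    rng = np.random.default_rng(spec.seed)
    weights, biases = _init_layers(spec, rng)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate
    n = len(training)
    batch = n if spec.batch_size is None else min(spec.batch_size, n)
    keep = 1.0 - spec.dropout_p

    log = np.empty(spec.epochs)
    step = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb, yb = Xs[idx], Ys[idx]
            if spec.dropout_p > 0:
                masks = [
                    (rng.random((xb.shape[0], h)) < keep) / keep
                    for h in spec.hidden_dims
                ]
            else:
                masks = None
            acts = _forward_pass(xb, weights, biases, masks)
            loss = float(np.mean((acts[-1] - yb) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate"
                )
            epoch_loss += loss * len(idx)
            gw, gb = _backward_pass(acts, yb, weights, masks)
            step += 1
            bc1 = 1.0 - beta1 ** step
            bc2 = 1.0 - beta2 ** step
            for li in range(len(weights)):
                m_w[li] = beta1 * m_w[li] + (1 - beta1) * gw[li]
                v_w[li] = beta2 * v_w[li] + (1 - beta2) * gw[li] ** 2
                weights[li] -= lr * (m_w[li] / bc1) / (np.sqrt(v_w[li] / bc2) + eps)
                m_b[li] = beta1 * m_b[li] + (1 - beta1) * gb[li]
                v_b[li] = beta2 * v_b[li] + (1 - beta2) * gb[li] ** 2
                biases[li] -= lr * (m_b[li] / bc1) / (np.sqrt(v_b[li] / bc2) + eps)
        log[epoch] = epoch_loss / n

    return TrainedMap(
        spec=spec, weights=weights, biases=biases,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        training_log=log, direction=direction,
    )


def apply_map(trained: TrainedMap, x: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout off), de-standardized output."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    if x.shape[1] != trained.spec.input_dim:
        raise ValueError(
            f"input width {x.shape[1]} != spec input_dim {trained.spec.input_dim}"
        )
    xs = (x - trained.x_mean) / trained.x_std
    acts = _forward_pass(xs, trained.weights, trained.biases, None)
    y = acts[-1] * trained.y_std + trained.y_mean
    return y[0] if squeeze else y


def loss_and_grads(weights, biases, X, Y):
    """Standardization-free MSE loss and analytic gradients (for checks)."""
    acts = _forward_pass(X, weights, biases, None)
    loss = float(np.mean((acts[-1] - Y) ** 2))
    gw, gb = _backward_pass(acts, Y, weights, None)
    return loss, gw, gb


def build_training_pairs(
    traj,
    sims: dict[str, "np.ndarray"],
    direction: str,
    *,
    fractions: dict[str, float] | None = None,
    include_fraction: bool = True,
) -> TrainingSet:
    """Pair observed cluster vectors with simulated state vectors.

    ``traj`` is a :class:`~hepatwin.coexpress.ClusterTrajectory`; ``sims``
    maps patient id to a (T, S) array of simulated state vectors on the same
    grid.  Forward rows are (cluster vector [, f]) -> state vector; reverse
    rows swap the roles (without the fraction feature).  Only (patient,
    time) pairs with every cluster observed contribute.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if direction == "forward" and include_fraction and fractions is None:
        raise ValueError("fractions required when the f-feature is enabled")
    rows_x, rows_y, prov = [], [], []
    for pi, patient in enumerate(traj.patient_ids):
        if patient not in sims:
            continue
        states = np.asarray(sims[patient], dtype=float)
        for ti in range(traj.values.shape[2]):
            if not traj.mask[:, pi, ti].all():
                continue
            cvec = traj.values[:, pi, ti]
            svec = states[ti]
            if direction == "forward":
                xin = (np.concatenate([cvec, [fractions[patient]]])
                       if include_fraction else cvec)
                rows_x.append(xin)
                rows_y.append(svec)
            else:
                rows_x.append(svec)
                rows_y.append(cvec)
            prov.append((patient, str(ti)))
    if not rows_x:
        raise ValueError("no usable (patient, time) pairs")
    return TrainingSet(np.array(rows_x), np.array(rows_y), tuple(prov))
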