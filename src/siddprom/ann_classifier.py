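"""Cost-sensitive 250-2-1 feed-forward network for promoter prediction.

The network takes the 250 window energies (per-position z-scored with
training-set statistics), passes them through two sigmoid hidden units and
one sigmoid output unit, and classifies *promoter* when the output score
exceeds a fixed 0.5 cutoff.  Its precision-recall trade-off is steered not
by moving the cutoff but by *cost-sensitive training*: a cost matrix over
(TP, TN, FP, FN) outcomes maps to per-class example weights — each positive
weighs ``cost_fn − cost_tp`` and each negative ``cost_fp − cost_tn`` — in a
weighted cross-entropy loss.  For any fixed set of decisions the expected
cost differs from this weighted loss only by a constant, so their minimizers
coincide.  Training one network per cost setting and plotting each network's
test-set (precision, recall) traces the method's precision-recall curve.

Training is plain seeded mini-batch gradient descent with momentum, with a
stratified validation holdout for early stopping; the weights from the best
validation epoch are returned.  Everything is a pure function of
(data, costs, config seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import TrainingError
from .evaluation import ConfusionCounts, PRCurve, PRPoint
from .sidd_io import NON_PROMOTER, PROMOTER, WINDOW_LENGTH, WindowInstance

N_INPUT = WINDOW_LENGTH
N_HIDDEN = 2
N_OUTPUT = 1

_SCALE_EPS = 1e-8
_PROB_EPS = 1e-12

# rng stream tags
_VALSPLIT_STREAM = 11
_TRAIN_STREAM = 12


@dataclass(frozen=True)
class CostMatrix:
    """Outcome costs; misclassification must cost more than being correct.

    The implied per-class example weights, ``cost_fn − cost_tp`` for
    positives and ``cost_fp − cost_tn`` for negatives, must be non-negative
    with at least one strictly positive.
    """

    cost_tp: float = 0.0
    cost_tn: float = 0.0
    cost_fp: float = 1.0
    cost_fn: float = 1.0

    def __post_init__(self) -> None:
        if min(self.cost_tp, self.cost_tn, self.cost_fp, self.cost_fn) < 0:
            raise ValueError("costs must be non-negative")
        if self.positive_weight < 0 or self.negative_weight < 0:
            raise ValueError(
                "correct classification must not cost more than error"
            )
        if self.positive_weight == 0 and self.negative_weight == 0:
            raise ValueError(
                "at least one misclassification must cost more than the "
                "corresponding correct classification"
            )

    @property
    def positive_weight(self) -> float:
        return self.cost_fn - self.cost_tp

    @property
    def negative_weight(self) -> float:
        return self.cost_fp - self.cost_tn

    def describe(self) -> str:
        return (
            f"tp={self.cost_tp:g},tn={self.cost_tn:g},"
            f"fp={self.cost_fp:g},fn={self.cost_fn:g}"
        )


#: Cost settings spanning precision-heavy to recall-heavy operating points.
DEFAULT_COST_GRID = tuple(
    CostMatrix(0.0, 0.0, 1.0, fn) for fn in (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 500
    patience: int = 25
    validation_fraction: float = 0.15
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_epochs < 1 or self.patience < 1 or self.batch_size < 1:
            raise ValueError("epochs, patience and batch size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass
class MlpModel:
    """Weights, biases and preprocessing of one trained 250-2-1 network."""

    input_weights: np.ndarray  # (250, 2)
    hidden_biases: np.ndarray  # (2,)
    output_weights: np.ndarray  # (2,)
    output_bias: float
    input_center: np.ndarray  # (250,)
    input_scale: np.ndarray  # (250,)
    seed: int = 0
    costs: CostMatrix = field(default_factory=CostMatrix)
    decision_cutoff: float = 0.5

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=np.float64)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=np.float64)
        self.output_weights = np.asarray(self.output_weights, dtype=np.float64)
        self.input_center = np.asarray(self.input_center, dtype=np.float64)
        self.input_scale = np.asarray(self.input_scale, dtype=np.float64)
        if self.input_weights.shape != (N_INPUT, N_HIDDEN):
            raise ValueError(
                f"input weights must be {N_INPUT}x{N_HIDDEN}, "
                f"got {self.input_weights.shape}"
            )
        if self.hidden_biases.shape != (N_HIDDEN,):
            raise ValueError("hidden biases must have length 2")
        if self.output_weights.shape != (N_HIDDEN,):
            raise ValueError("output weights must have length 2")
        if self.input_center.shape != (N_INPUT,) or self.input_scale.shape != (
            N_INPUT,
        ):
            raise ValueError("standardization vectors must have length 250")
        if np.any(self.input_scale <= 0):
            raise ValueError("input_scale entries must be positive")
        if not 0.0 < self.decision_cutoff < 1.0:
            raise ValueError("decision_cutoff must lie in (0, 1)")

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Forward pass on raw (unstandardized) energy rows."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != N_INPUT:
            raise ValueError(f"expected {N_INPUT} energies, got {X.shape[1]}")
        Z = (X - self.input_center) / self.input_scale
        hidden = expit(Z @ self.input_weights + self.hidden_biases)
        return expit(hidden @ self.output_weights + self.output_bias)

    def predict(self, X: np.ndarray) -> list[str]:
        return [
            PROMOTER if s > self.decision_cutoff else NON_PROMOTER
            for s in self.scores(X)
        ]


def standardize_inputs(train_set, eps: float = _SCALE_EPS):
    """Per-relative-position mean and sd over a training set.

    The standard deviation is floored at ``eps`` so constant positions do
    not divide by zero.
    """
    X, _ = train_set.to_arrays()
    if X.shape[0] < 2:
        raise ValueError("standardization requires at least 2 instances")
    center = X.mean(axis=0)
    scale = np.maximum(X.std(axis=0), eps)
    return center, scale


def forward(model: MlpModel, window: WindowInstance) -> float:
    """Network score in (0, 1) for one window."""
    return float(model.scores(window.energies)[0])


def _example_weights(y: np.ndarray, costs: CostMatrix) -> np.ndarray:
    w = np.where(y, costs.positive_weight, costs.negative_weight)
    mean = w.mean()
    if mean <= 0:
        raise TrainingError("all example weights are zero under these costs")
    return w / mean  # normalize so the learning rate is cost-scale free


def _weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    losses = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(np.sum(w * losses) / np.sum(w))


def train_ann(
    train_set, costs: CostMatrix, config: TrainingConfig | None = None
) -> MlpModel:
    """Fit the 250-2-1 network by cost-weighted seeded gradient descent.

    A stratified ``validation_fraction`` holdout monitors the weighted
    validation loss; training stops after ``patience`` epochs without
    improvement and the best-validation-epoch weights are returned.
    Classes with fewer than 4 members cannot be held out, in which case the
    training subset doubles as the validation monitor.
    """
    config = config or TrainingConfig()
    X, y = train_set.to_arrays()
    if y.all() or not y.any():
        raise TrainingError("training set must contain both classes")
    center, scale = standardize_inputs(train_set)
    Z = (X - center) / scale
    yf = y.astype(np.float64)

    # stratified validation holdout
    rng_split = np.random.default_rng([config.seed, _VALSPLIT_STREAM])
    val_idx: list[int] = []
    for cls in (True, False):
        members = np.flatnonzero(y == cls)
        n_val = int(np.floor(config.validation_fraction * members.size))
        if members.size >= 4 and n_val >= 1:
            chosen = rng_split.permutation(members)[:n_val]
            val_idx.extend(chosen.tolist())
    val_idx = np.array(sorted(val_idx), dtype=np.int64)
    train_idx = np.setdiff1d(np.arange(y.size), val_idx)
    if val_idx.size == 0 or not (
        y[train_idx].any() and not y[train_idx].all()
    ):
        train_idx = np.arange(y.size)
        val_idx = train_idx

    w_all = _example_weights(y, costs)
    Zt, yt, wt = Z[train_idx], yf[train_idx], w_all[train_idx]
    Zv, yv, wv = Z[val_idx], yf[val_idx], w_all[val_idx]

    rng = np.random.default_rng([config.seed, _TRAIN_STREAM])
    w1 = rng.uniform(-0.5, 0.5, size=(N_INPUT, N_HIDDEN))
    b1 = np.zeros(N_HIDDEN)
    w2 = rng.uniform(-0.5, 0.5, size=N_HIDDEN)
    b2 = 0.0
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = 0.0

    def val_cost() -> float:
        hidden = expit(Zv @ w1 + b1)
        return _weighted_bce(expit(hidden @ w2 + b2), yv, wv)

    best = (val_cost(), copy.deepcopy((w1, b1, w2, b2)))
    epochs_since_best = 0
    n_train = Zt.shape[0]
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            batch = order[start : start + config.batch_size]
            Zb, yb, wb = Zt[batch], yt[batch], wt[batch]
            hidden = expit(Zb @ w1 + b1)
            p = expit(hidden @ w2 + b2)
            # gradient of the weighted mean BCE wrt pre-activations
            dz2 = wb * (p - yb) / np.sum(wb)
            g_w2 = hidden.T @ dz2
            g_b2 = float(np.sum(dz2))
            dh = np.outer(dz2, w2) * hidden * (1.0 - hidden)
            g_w1 = Zb.T @ dh
            g_b1 = dh.sum(axis=0)
            v_w1 = config.momentum * v_w1 - config.learning_rate * g_w1
            v_b1 = config.momentum * v_b1 - config.learning_rate * g_b1
            v_w2 = config.momentum * v_w2 - config.learning_rate * g_w2
            v_b2 = config.momentum * v_b2 - config.learning_rate * g_b2
            w1 += v_w1
            b1 += v_b1
            w2 += v_w2
            b2 += v_b2
        hidden = expit(Zt @ w1 + b1)
        train_loss = _weighted_bce(expit(hidden @ w2 + b2), yt, wt)
        if not np.isfinite(train_loss):
            raise TrainingError("training loss became non-finite")
        current = val_cost()
        if current < best[0] - 1e-12:
            best = (current, copy.deepcopy((w1, b1, w2, b2)))
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break
    w1, b1, w2, b2 = best[1]
    return MlpModel(
        input_weights=w1,
        hidden_biases=b1,
        output_weights=w2,
        output_bias=float(b2),
        input_center=center,
        input_scale=scale,
        seed=config.seed,
        costs=costs,
    )


def evaluate_model(model: MlpModel, test_set) -> PRPoint:
    """Test-set precision-recall point of one trained network."""
    X, y = test_set.to_arrays()
    predicted = np.array([lab == PROMOTER for lab in model.predict(X)])
    counts = ConfusionCounts(
        tp=int(np.sum(predicted & y)),
        fp=int(np.sum(predicted & ~y)),
        tn=int(np.sum(~predicted & ~y)),
        fn=int(np.sum(~predicted & y)),
    )
    return PRPoint.from_counts(counts, f"costs({model.costs.describe()})")


def trace_prc_by_costs(
    train_set,
    test_set,
    cost_grid=DEFAULT_COST_GRID,
    config: TrainingConfig | None = None,
):
    """One trained network and one test-set PR point per cost setting.

    Returns ``(curve, models)``; ``models`` follows the grid order and each
    curve point's operating parameter names its generating costs.  Unlike a
    threshold sweep, no monotonicity is guaranteed — cost settings land
    where they land on the recall axis.  Each network's initialization seed
    derives from (config.seed, grid index) so replicate networks differ
    while the whole trace stays a pure function of the config seed.
    """
    cost_grid = list(cost_grid)
    if not cost_grid:
        raise ValueError("empty cost grid")
    config = config or TrainingConfig()
    points = []
    models = []
    for i, costs in enumerate(cost_grid):
        member_cfg = TrainingConfig(
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            max_epochs=config.max_epochs,
            patience=config.patience,
            validation_fraction=config.validation_fraction,
            batch_size=config.batch_size,
            seed=int(np.random.default_rng([config.seed, 1000 + i]).integers(2**31)),
        )
        model = train_ann(train_set, costs, member_cfg)
        models.append(model)
        points.append(evaluate_model(model, test_set))
    return PRCurve(points, label="ANN"), models


# ---------------------------------------------------------------------------
# Flat-text model serialization
# ---------------------------------------------------------------------------


def save_model(model: MlpModel, path) -> None:
    def fmt(a) -> str:
        return " ".join(f"{v:.17g}" for v in np.atleast_1d(a).ravel())

    with open(path, "w") as handle:
        handle.write("siddprom-mlp 1\n")
        handle.write(f"dims {N_INPUT} {N_HIDDEN} {N_OUTPUT}\n")
        handle.write(f"seed {model.seed}\n")
        c = model.costs
        handle.write(
            f"costs {c.cost_tp:.17g} {c.cost_tn:.17g} "
            f"{c.cost_fp:.17g} {c.cost_fn:.17g}\n"
        )
        handle.write(f"cutoff {model.decision_cutoff:.17g}\n")
        handle.write(f"input_center {fmt(model.input_center)}\n")
        handle.write(f"input_scale {fmt(model.input_scale)}\n")
        handle.write(f"input_weights {fmt(model.input_weights)}\n")
        handle.write(f"hidden_biases {fmt(model.hidden_biases)}\n")
        handle.write(f"output_weights {fmt(model.output_weights)}\n")
        handle.write(f"output_bias {model.output_bias:.17g}\n")


def load_model(path) -> MlpModel:
    fields_: dict[str, list[str]] = {}
    with open(path) as handle:
        magic = handle.readline().split()
        if magic[:1] != ["siddprom-mlp"]:
            raise ValueError(f"{path}: not a siddprom MLP model file")
        for line in handle:
            parts = line.split()
            if parts:
                fields_[parts[0]] = parts[1:]
    dims = [int(v) for v in fields_["dims"]]
    if dims != [N_INPUT, N_HIDDEN, N_OUTPUT]:
        raise ValueError(f"{path}: unexpected architecture {dims}")
    arr = lambda key: np.asarray(fields_[key], dtype=np.float64)
    ct, cn, cf, cfn = (float(v) for v in fields_["costs"])
    return MlpModel(
        input_weights=arr("input_weights").reshape(N_INPUT, N_HIDDEN),
        hidden_biases=arr("hidden_biases"),
        output_weights=arr("output_weights"),
        output_bias=float(fields_["output_bias"][0]),
        input_center=arr("input_center"),
        input_scale=arr("input_scale"),
        seed=int(fields_["seed"][0]),
        costs=CostMatrix(ct, cn, cf, cfn),
        decision_cutoff=float(fields_["cutoff"][0]),
    )
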