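"""Trainable volume estimators on the 16-distance radial feature.

Two estimators share a fit/predict contract:

* **Multivariate quadratic regression** — ordinary least squares on the
  33-column design [d_i², d_i, 1]:

      V = c + Σ_i (a_i d_i² + b_i d_i),   i = 1..16.

* **Backpropagation network** — a fully connected feed-forward net with
  sigmoid hidden layers (default 4 layers of 16 units) and a single linear
  output, trained by full-batch gradient descent with classical momentum on
  mean-squared error (deterministic given the seed; plain fixed-step descent
  stalls well short of convergence on deep sigmoid stacks).
  Inputs are z-scored with statistics from the training split only;
  initialization is Glorot-uniform and seeded, so runs are deterministic.

The cohort splitter reproduces the benchmark protocol of training on a random
half of all frames (frame-level); a case-level mode that keeps whole cycles
together is provided because frame-level splitting leaks cases across the
train/test boundary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contour import RadialFeature, radial_distances
from .errors import (
    BorderValidationError,
    ConfigurationError,
    DivergenceError,
    SingularFitError,
)
from .function import CycleSeries

__all__ = [
    "QuadraticModel",
    "BPNetConfig",
    "BPNetModel",
    "SplitPlan",
    "TrainingReport",
    "fit_quadratic",
    "predict_quadratic",
    "fit_bpnet",
    "predict_bpnet",
    "split_cohort",
    "hidden_layer_sweep",
    "bpnet_loss_and_gradients",
]

N_FEATURES = 16


def _as_feature_matrix(features) -> np.ndarray:
    """Stack RadialFeatures (or raw 16-vectors) into an (n, 16) matrix."""
    rows = []
    for f in features:
        d = f.distances if isinstance(f, RadialFeature) else np.asarray(f, float)
        if len(d) != N_FEATURES:
            raise BorderValidationError(
                f"expected {N_FEATURES} distances, got {len(d)}"
            )
        rows.append(np.asarray(d, dtype=float))
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# quadratic regression
# ---------------------------------------------------------------------------

@dataclass
class QuadraticModel:
    """V = c + Σ a_i d_i² + b_i d_i (33 parameters, volumes in ml)."""

    a: np.ndarray  # (16,) quadratic coefficients
    b: np.ndarray  # (16,) linear coefficients
    c: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (N_FEATURES,) or self.b.shape != (N_FEATURES,):
            raise ConfigurationError("quadratic model needs 16 + 16 coefficients")


def _quadratic_design(x: np.ndarray) -> np.ndarray:
    return np.hstack([x**2, x, np.ones((len(x), 1))])


def fit_quadratic(features, volumes) -> QuadraticModel:
    """Ordinary-least-squares fit of the quadratic volume model."""
    x = _as_feature_matrix(features)
    y = np.asarray(volumes, dtype=float).ravel()
    if len(x) != len(y):
        raise ConfigurationError("features and volumes differ in length")
    n_params = 2 * N_FEATURES + 1
    if len(y) < n_params:
        raise SingularFitError(
            f"need >= {n_params} samples for {n_params} coefficients, got {len(y)}"
        )
    design = _quadratic_design(x)
    rank = np.linalg.matrix_rank(design)
    if rank < n_params:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(design, pivoting=True, mode="economic")
        names = ([f"d{i + 1:02d}^2" for i in range(N_FEATURES)]
                 + [f"d{i + 1:02d}" for i in range(N_FEATURES)] + ["1"])
        bad = sorted(names[j] for j in piv[rank:])
        raise SingularFitError(
            f"design matrix rank {rank} < {n_params}; dependent columns: {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return QuadraticModel(a=coef[:N_FEATURES], b=coef[N_FEATURES:2 * N_FEATURES],
                          c=float(coef[-1]))


def predict_quadratic(model: QuadraticModel, feature) -> float:
    """Evaluate the fitted quadratic form for one feature, in ml."""
    d = _as_feature_matrix([feature])[0]
    return float(model.c + np.dot(model.a, d**2) + np.dot(model.b, d))


# ---------------------------------------------------------------------------
# backpropagation network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BPNetConfig:
    """Architecture and optimizer settings of the backprop network."""

    n_hidden_layers: int = 4
    units_per_layer: int = 16
    learning_rate: float = 0.2
    momentum: float = 0.9
    max_epochs: int = 30000
    tolerance: float = 1e-12  # stop when the epoch loss decrease falls below
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_hidden_layers <= 8:
            raise ConfigurationError("n_hidden_layers must be between 1 and 8")
        if self.units_per_layer < 1:
            raise ConfigurationError("units_per_layer must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must be in [0, 1)")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass
class BPNetModel:
    """A trained network: layer weights/biases plus input standardization."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    config: BPNetConfig

    def save(self, path: str | Path) -> None:
        """Serialize to human-auditable JSON."""
        payload = {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BPNetModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
            biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            x_std=np.asarray(payload["x_std"], dtype=float),
            config=BPNetConfig(**payload["config"]),
        )


@dataclass
class TrainingReport:
    losses: np.ndarray  # training MSE per epoch
    n_train: int
    converged: bool
    holdout_mse: float | None = None


@dataclass(frozen=True)
class SplitPlan:
    """Random train/test partition of a cohort.

    ``mode="frame"`` samples frames independently (the benchmark protocol);
    ``mode="case"`` keeps all frames of a case on one side, avoiding case
    leakage across the boundary.
    """

    mode: str = "frame"
    fraction_train: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("frame", "case"):
            raise ConfigurationError("mode must be 'frame' or 'case'")
        if not 0.0 < self.fraction_train < 1.0:
            raise ConfigurationError("fraction_train must be in (0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_layers(sizes: list[int], rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(weights, biases, x: np.ndarray):
    """Forward pass; returns activations per layer (input first)."""
    acts = [x]
    h = x
    last = len(weights) - 1
    for i, (w, b) in enumerate(zip(weights, biases)):
        z = h @ w + b
        h = z if i == last else _sigmoid(z)  # linear output node
        acts.append(h)
    return acts


def bpnet_loss_and_gradients(weights, biases, x: np.ndarray, y: np.ndarray):
    """Mean-squared-error loss and its analytic gradients.

    Exposed separately so the backprop gradients can be checked against
    finite differences at any depth.
    """
    n = len(x)
    with np.errstate(over="ignore", invalid="ignore"):
        acts = _forward(weights, biases, x)
        pred = acts[-1].ravel()
        resid = pred - y
        loss = float(np.mean(resid**2))
    grad_w = [np.zeros_like(w) for w in weights]
    grad_b = [np.zeros_like(b) for b in biases]
    with np.errstate(over="ignore", invalid="ignore"):
        delta = (2.0 / n) * resid[:, None]  # linear output layer
        for i in range(len(weights) - 1, -1, -1):
            grad_w[i] = acts[i].T @ delta
            grad_b[i] = delta.sum(axis=0)
            if i > 0:
                a = acts[i]  # sigmoid activation of layer i
                delta = (delta @ weights[i].T) * a * (1.0 - a)
    return loss, grad_w, grad_b


def fit_bpnet(features, volumes, config: BPNetConfig | None = None,
              split: SplitPlan | None = None) -> tuple[BPNetModel, TrainingReport]:
    """Train the backprop network on (features, reference volumes in ml).

    When ``split`` is given, a random ``fraction_train`` of the provided
    samples is used for training and the rest reported as held-out MSE;
    standardization statistics always come from the training portion only.
    """
    config = config or BPNetConfig()
    x_all = _as_feature_matrix(features)
    y_all = np.asarray(volumes, dtype=float).ravel()
    if len(x_all) != len(y_all):
        raise ConfigurationError("features and volumes differ in length")
    if split is not None:
        rng = np.random.default_rng(split.seed)
        perm = rng.permutation(len(y_all))
        n_train = int(round(split.fraction_train * len(y_all)))
        if n_train == 0 or n_train == len(y_all):
            raise ConfigurationError("split leaves an empty train or test set")
        tr, te = perm[:n_train], perm[n_train:]
        x, y = x_all[tr], y_all[tr]
        x_hold, y_hold = x_all[te], y_all[te]
    else:
        x, y = x_all, y_all
        x_hold = y_hold = None
    if len(y) < 50:
        raise ConfigurationError(f"need >= 50 training samples, got {len(y)}")

    x_mean = x.mean(axis=0)
    x_std = x.std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    xs = (x - x_mean) / x_std

    sizes = ([x.shape[1]]
             + [config.units_per_layer] * config.n_hidden_layers + [1])
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_layers(sizes, rng)
    biases[-1][:] = y.mean()  # start the linear output at the target mean

    losses = np.empty(config.max_epochs)
    prev = np.inf
    converged = False
    n_epochs = 0
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    for epoch in range(config.max_epochs):
        loss, grad_w, grad_b = bpnet_loss_and_gradients(weights, biases, xs, y)
        if not np.isfinite(loss):
            raise DivergenceError(
                "training loss is non-finite; try a smaller learning_rate"
            )
        losses[epoch] = loss
        n_epochs = epoch + 1
        if abs(prev - loss) < config.tolerance:
            converged = True
            break
        prev = loss
        mu, lr = config.momentum, config.learning_rate
        for w, b, gw, gb, vw, vb in zip(weights, biases, grad_w, grad_b,
                                        vel_w, vel_b):
            vw *= mu
            vw -= lr * gw
            vb *= mu
            vb -= lr * gb
            w += vw
            b += vb

    model = BPNetModel(weights=weights, biases=biases,
                       x_mean=x_mean, x_std=x_std, config=config)
    holdout = None
    if x_hold is not None and len(x_hold):
        holdout = float(np.mean((predict_bpnet(model, x_hold) - y_hold) ** 2))
    return model, TrainingReport(losses=losses[:n_epochs], n_train=len(y),
                                 converged=converged, holdout_mse=holdout)


def predict_bpnet(model: BPNetModel, feature) -> float | np.ndarray:
    """Deterministic forward pass; accepts one feature or a batch."""
    arr = np.asarray(
        feature.distances if isinstance(feature, RadialFeature) else feature,
        dtype=float,
    )
    single = arr.ndim == 1
    x = _as_feature_matrix(arr[None, :] if single else arr)
    xs = (x - model.x_mean) / model.x_std
    pred = _forward(model.weights, model.biases, xs)[-1].ravel()
    return float(pred[0]) if single else pred


# ---------------------------------------------------------------------------
# cohort splitting and the depth sweep
# ---------------------------------------------------------------------------

def split_cohort(cohort: list[CycleSeries], split: SplitPlan
                 ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Disjoint, exhaustive train/test index sets of (case, frame) pairs."""
    if not cohort:
        raise ConfigurationError("empty cohort")
    rng = np.random.default_rng(split.seed)
    if split.mode == "frame":
        pairs = [(i, j) for i, cyc in enumerate(cohort) for j in range(len(cyc))]
        perm = rng.permutation(len(pairs))
        n_train = int(round(split.fraction_train * len(pairs)))
        if n_train == 0 or n_train == len(pairs):
            raise ConfigurationError("split leaves an empty train or test set")
        train = [pairs[k] for k in perm[:n_train]]
        test = [pairs[k] for k in perm[n_train:]]
        return train, test
    perm = rng.permutation(len(cohort))
    n_train = int(round(split.fraction_train * len(cohort)))
    if n_train == 0 or n_train == len(cohort):
        raise ConfigurationError("split leaves an empty train or test set")
    train_cases, test_cases = set(perm[:n_train]), set(perm[n_train:])
    train = [(i, j) for i in sorted(train_cases) for j in range(len(cohort[i]))]
    test = [(i, j) for i in sorted(test_cases) for j in range(len(cohort[i]))]
    return train, test


def _cohort_features(cohort: list[CycleSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Featurize every frame (using cached features where present)."""
    feats, vols = [], []
    for cyc in cohort:
        for fr in cyc.frames:
            if fr.feature is None:
                if fr.border is None:
                    raise ConfigurationError(
                        f"frame {cyc.case_id}/{fr.frame_id} has no border"
                    )
                fr.feature = radial_distances(fr.border)
            feats.append(fr.feature.distances)
            vols.append(fr.volume_ml)
    return np.vstack(feats), np.asarray(vols)


def hidden_layer_sweep(cohort: list[CycleSeries], layers, base_config: BPNetConfig,
                       split: SplitPlan) -> pd.DataFrame:
    """Train/test CCC and ICC as a function of network depth.

    One network is trained per requested depth on the same split; agreement
    is measured against the reference volumes on each side of the split.
    """
    from .agreement import ccc as _ccc, icc as _icc

    layers = list(layers)
    if not layers or any(not 1 <= d <= 8 for d in layers):
        raise ConfigurationError("layer depths must lie in 1..8")
    feats, vols = _cohort_features(cohort)
    flat_index = {(i, j): k for k, (i, j) in enumerate(
        (i, j) for i, cyc in enumerate(cohort) for j in range(len(cyc))
    )}
    train_ids, test_ids = split_cohort(cohort, split)
    tr = [flat_index[p] for p in train_ids]
    te = [flat_index[p] for p in test_ids]
    rows = []
    for depth in layers:
        config = dataclasses.replace(base_config, n_hidden_layers=depth)
        model, _ = fit_bpnet(feats[tr], vols[tr], config)
        pred_tr = predict_bpnet(model, feats[tr])
        pred_te = predict_bpnet(model, feats[te])
        rows.append({
            "n_hidden_layers": depth,
            "ccc_train": _ccc(pred_tr, vols[tr]).value,
            "ccc_test": _ccc(pred_te, vols[te]).value,
            "icc_train": _icc(pred_tr, vols[tr]).value,
            "icc_test": _icc(pred_te, vols[te]).value,
        })
    return pd.DataFrame(rows)
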