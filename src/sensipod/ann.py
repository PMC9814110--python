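"""Feed-forward neural-network defined approaches for EC3 prediction.

Two small fully connected networks integrate the nonanimal endpoints into a
murine LLNA EC3 estimate:

* ``D_hC`` — inputs Avg.Lys.Cys (DPRA) and MIT (h-CLAT);
* ``D_hC_KS`` — the same plus Imax (KeratinoSens).

Architecture: input -> 5 -> 2 -> 1 with logistic activations on both hidden
layers and the output. Inputs and the EC3 target are log10-transformed, then
min-max scaled onto [margin, 1 - margin] using training-set extremes so the
logistic output can represent every target. Training is full-batch gradient
descent on mean squared error with a momentum term, run for a fixed number
of iterations from uniform random initial weights.

Because the fit depends on the random initialization, a defined-approach
prediction is an ensemble statistic: the network is trained ``n_runs`` times
(default 100) from independent seeds, and the reported EC3 is the arithmetic
mean of the per-run predictions with a 95% interval from the 2.5th/97.5th
percentiles of the run distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EnsembleFailureError, InvalidInputError, SchemaError

VARIANT_FEATURES = {
    "D_hC": ("avg_lys_cys", "mit_ug_ml"),
    "D_hC_KS": ("avg_lys_cys", "mit_ug_ml", "imax"),
}
HIDDEN_SIZES = (5, 2)


@dataclass(frozen=True)
class ANNConfig:
    """Hyperparameters of one defined-approach network.

    The hidden topology (5 then 2 nodes) and logistic activations are fixed
    properties of the defined approach, not tunables. Learning rate 0.2 and
    momentum 0.5 give stable convergence at 10,000 full-batch iterations on
    the scaled data; weights start uniform on (-init_range, +init_range).
    """

    variant: str = "D_hC"
    iterations: int = 10_000
    learning_rate: float = 0.2
    momentum: float = 0.5
    init_range: float = 0.5
    seed: int = 0
    scaling_margin: float = 0.05

    def __post_init__(self):
        if self.variant not in VARIANT_FEATURES:
            raise InvalidInputError(f"unknown variant {self.variant!r}")
        if self.iterations < 1:
            raise InvalidInputError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise InvalidInputError("momentum must be in [0, 1)")
        if not (0.0 <= self.scaling_margin < 0.5):
            raise InvalidInputError("scaling margin must be in [0, 0.5)")

    @property
    def features(self) -> tuple:
        return VARIANT_FEATURES[self.variant]


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature log10 min/max from the training set, mapping onto
    [margin, 1 - margin]."""

    log_min: np.ndarray
    log_max: np.ndarray
    margin: float

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if (values <= 0).any():
            raise InvalidInputError("all inputs must be positive (log scale)")
        logs = np.log10(values)
        span = self.log_max - self.log_min
        span = np.where(span == 0, 1.0, span)
        unit = (logs - self.log_min) / span
        return self.margin + (1.0 - 2.0 * self.margin) * unit

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        unit = (np.asarray(scaled, dtype=float) - self.margin) / (1.0 - 2.0 * self.margin)
        span = self.log_max - self.log_min
        span = np.where(span == 0, 1.0, span)
        return 10.0 ** (self.log_min + unit * span)

    @classmethod
    def fit(cls, values: np.ndarray, margin: float) -> "ScalingParams":
        values = np.asarray(values, dtype=float)
        if (values <= 0).any():
            raise InvalidInputError("all training values must be positive")
        logs = np.log10(values)
        return cls(logs.min(axis=0), logs.max(axis=0), margin)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ANNModel:
    """A trained network: weights/biases for input->5->2->1 plus the frozen
    training-set scaling for inputs and target."""

    weights: list  # [W1, W2, W3]
    biases: list   # [b1, b2, b3]
    x_scaling: ScalingParams
    y_scaling: ScalingParams
    config: ANNConfig

    def forward(self, x_scaled: np.ndarray) -> np.ndarray:
        """Scaled output in (0, 1) for scaled input rows (n, n_features)."""
        x = np.atleast_2d(np.asarray(x_scaled, dtype=float))
        if x.shape[1] != self.weights[0].shape[0]:
            raise SchemaError(
                f"expected {self.weights[0].shape[0]} inputs, got {x.shape[1]}")
        a = x
        for W, b in zip(self.weights, self.biases):
            a = _logistic(a @ W + b)
        return a[:, 0]

    def predict_ec3(self, endpoints) -> float:
        """EC3 (%) for one endpoint vector (mapping or sequence ordered as the
        variant's features)."""
        x = endpoint_array(endpoints, self.config.variant)
        out = self.forward(self.x_scaling.transform(x))
        return float(self.y_scaling.inverse(out)[0])

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_scaling": {"log_min": self.x_scaling.log_min.tolist(),
                          "log_max": self.x_scaling.log_max.tolist(),
                          "margin": self.x_scaling.margin},
            "y_scaling": {"log_min": np.atleast_1d(self.y_scaling.log_min).tolist(),
                          "log_max": np.atleast_1d(self.y_scaling.log_max).tolist(),
                          "margin": self.y_scaling.margin},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANNModel":
        cfg = ANNConfig(**d["config"])
        xs = ScalingParams(np.asarray(d["x_scaling"]["log_min"]),
                           np.asarray(d["x_scaling"]["log_max"]),
                           d["x_scaling"]["margin"])
        ys = ScalingParams(np.asarray(d["y_scaling"]["log_min"]),
                           np.asarray(d["y_scaling"]["log_max"]),
                           d["y_scaling"]["margin"])
        return cls([np.asarray(w) for w in d["weights"]],
                   [np.asarray(b) for b in d["biases"]], xs, ys, cfg)


@dataclass(frozen=True)
class EnsemblePrediction:
    per_run_ec3: tuple
    mean_ec3: float
    ci_low: float
    ci_high: float

    @property
    def n_runs(self) -> int:
        return len(self.per_run_ec3)


@dataclass(frozen=True)
class BenchmarkResult:
    r_squared: float
    rmse_log10: float
    n: int


def endpoint_array(endpoints, variant: str) -> np.ndarray:
    """Validate and order an endpoint vector for a model variant.

    Accepts a mapping with the variant's feature names or a plain sequence in
    feature order; all values must be positive.
    """
    features = VARIANT_FEATURES[variant]
    if isinstance(endpoints, dict):
        missing = [f for f in features if endpoints.get(f) is None]
        if missing:
            raise InvalidInputError(
                f"variant {variant} requires endpoint(s) {missing}")
        values = [float(endpoints[f]) for f in features]
    else:
        values = [float(v) for v in endpoints]
        if len(values) != len(features):
            raise InvalidInputError(
                f"variant {variant} takes {len(features)} endpoints, got {len(values)}")
    if any(v <= 0 for v in values):
        raise InvalidInputError("endpoint values must be strictly positive")
    return np.asarray(values)


def validate_training_table(table: pd.DataFrame, variant: str) -> pd.DataFrame:
    """Check a training table for the columns a variant needs.

    Required: ``chemical``, the variant's feature columns, ``ec3_pct`` and
    (optionally) ``split`` in {train, test}; missing split defaults to train.
    """
    features = VARIANT_FEATURES[variant]
    required = {"chemical", "ec3_pct", *features}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"training table missing column(s) {sorted(missing)}")
    table = table.copy()
    if "split" not in table.columns:
        table["split"] = "train"
    bad = ~table["split"].isin(["train", "test"])
    if bad.any():
        raise SchemaError("split must be 'train' or 'test'")
    for split in ("train", "test"):
        sub = table[table["split"] == split]
        if sub["chemical"].duplicated().any():
            raise SchemaError(f"duplicate chemical keys within the {split} split")
    if (table["ec3_pct"] <= 0).any():
        raise SchemaError("EC3 values must be positive")
    for f in features:
        if (table[f] <= 0).any():
            raise SchemaError(f"endpoint column {f!r} must be strictly positive")
    return table


def _init_parameters(config: ANNConfig, rng: np.random.Generator):
    sizes = (len(config.features), *HIDDEN_SIZES, 1)
    r = config.init_range
    weights = [rng.uniform(-r, r, size=(sizes[i], sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    biases = [rng.uniform(-r, r, size=sizes[i + 1]) for i in range(len(sizes) - 1)]
    return weights, biases


def _forward_activations(weights, biases, x):
    acts = [x]
    a = x
    for W, b in zip(weights, biases):
        a = _logistic(a @ W + b)
        acts.append(a)
    return acts


def gradients(weights, biases, x, y):
    """Analytic MSE gradients w.r.t. every weight and bias (backpropagation).

    Loss = mean over samples of (out - y)^2; logistic derivative a(1 - a).
    """
    n = x.shape[0]
    acts = _forward_activations(weights, biases, x)
    out = acts[-1]
    delta = (2.0 / n) * (out - y.reshape(-1, 1)) * out * (1.0 - out)
    grads_w, grads_b = [], []
    for layer in range(len(weights) - 1, -1, -1):
        grads_w.insert(0, acts[layer].T @ delta)
        grads_b.insert(0, delta.sum(axis=0))
        if layer > 0:
            a_prev = acts[layer]
            delta = (delta @ weights[layer].T) * a_prev * (1.0 - a_prev)
    return grads_w, grads_b


def train(table: pd.DataFrame, config: ANNConfig) -> ANNModel:
    """Fit one network by full-batch gradient descent with momentum.

    Runs exactly ``config.iterations`` epochs; deterministic given
    ``config.seed``. Input/target scaling is frozen from the training split.
    A zero-variance target still trains (with a warning-free constant fit)
    but yields a degenerate scaling span of 1.
    """
    table = validate_training_table(table, config.variant)
    train_rows = table[table["split"] == "train"]
    if len(train_rows) < 2:
        raise SchemaError("need at least 2 training rows")
    X = train_rows[list(config.features)].to_numpy(dtype=float)
    y = train_rows["ec3_pct"].to_numpy(dtype=float)

    x_scaling = ScalingParams.fit(X, config.scaling_margin)
    y_scaling = ScalingParams.fit(y.reshape(-1, 1), config.scaling_margin)
    Xs = x_scaling.transform(X)
    ys = y_scaling.transform(y.reshape(-1, 1))[:, 0]

    rng = np.random.default_rng(config.seed)
    weights, biases = _init_parameters(config, rng)
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]

    lr, mom = config.learning_rate, config.momentum
    for _ in range(config.iterations):
        gw, gb = gradients(weights, biases, Xs, ys)
        for k in range(len(weights)):
            vel_w[k] = mom * vel_w[k] - lr * gw[k]
            vel_b[k] = mom * vel_b[k] - lr * gb[k]
            weights[k] = weights[k] + vel_w[k]
            biases[k] = biases[k] + vel_b[k]

    return ANNModel(weights, biases, x_scaling,
                    ScalingParams(y_scaling.log_min, y_scaling.log_max,
                                  y_scaling.margin), config)


def derive_run_seeds(master_seed: int, n_runs: int) -> np.ndarray:
    """Deterministic per-run seeds spawned from one master seed (< 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n_runs, dtype=np.uint32) % np.uint32(2**31)


class ANNEnsemble:
    """A bag of independently initialized trained networks.

    Training the same architecture ``n_runs`` times from different random
    weights and averaging the predictions is the defined approach's way of
    quantifying the uncertainty inherent in the learning algorithm.
    """

    def __init__(self, models: Sequence[ANNModel], config: ANNConfig):
        self.models = list(models)
        self.config = config

    @classmethod
    def fit(cls, table: pd.DataFrame, config: ANNConfig,
            n_runs: int = 100) -> "ANNEnsemble":
        if n_runs < 2:
            raise InvalidInputError("an ensemble needs at least 2 runs")
        seeds = derive_run_seeds(config.seed, n_runs)
        models, failures = [], []
        for s in seeds:
            cfg = ANNConfig(variant=config.variant, iterations=config.iterations,
                            learning_rate=config.learning_rate,
                            momentum=config.momentum,
                            init_range=config.init_range, seed=int(s),
                            scaling_margin=config.scaling_margin)
            try:
                model = train(table, cfg)
                if not all(np.isfinite(w).all() for w in model.weights):
                    raise FloatingPointError("non-finite weights after training")
                models.append(model)
            except (FloatingPointError, ValueError) as exc:  # run dropped
                failures.append((int(s), str(exc)))
        if len(models) < n_runs / 2:
            raise EnsembleFailureError(
                f"{len(failures)} of {n_runs} runs failed: {failures[:3]}")
        ens = cls(models, config)
        ens.failures = failures
        return ens

    def predict(self, endpoints) -> EnsemblePrediction:
        per_run = np.asarray([m.predict_ec3(endpoints) for m in self.models])
        mean = float(per_run.mean())
        lo, hi = np.percentile(per_run, [2.5, 97.5])
        return EnsemblePrediction(tuple(per_run.tolist()), mean,
                                  max(0.0, float(lo)), float(hi))


def ensemble_predict(table: pd.DataFrame, endpoints, config: ANNConfig,
                     n_runs: int = 100) -> EnsemblePrediction:
    """Train an ``n_runs`` ensemble on `table` and predict one endpoint vector."""
    return ANNEnsemble.fit(table, config, n_runs).predict(endpoints)


def predict_ec3(model: ANNModel, endpoints) -> float:
    """EC3 (%) from one trained network (scale -> forward -> inverse scale)."""
    return model.predict_ec3(endpoints)


def benchmark(model_or_ensemble, table: pd.DataFrame,
              split: str = "test") -> BenchmarkResult:
    """R^2 and RMSE between predicted and observed EC3 in log10 space.

    Accepts a single model or an ensemble (whose mean EC3 per chemical is
    used). ``split`` selects the rows of `table` to score.
    """
    config = model_or_ensemble.config
    table = validate_training_table(table, config.variant)
    rows = table[table["split"] == split]
    if rows.empty:
        raise SchemaError(f"split {split!r} is empty")
    X = rows[list(config.features)].to_numpy(dtype=float)
    obs = np.log10(rows["ec3_pct"].to_numpy(dtype=float))
    if isinstance(model_or_ensemble, ANNEnsemble):
        preds = np.asarray(
            [model_or_ensemble.predict(x).mean_ec3 for x in X])
    else:
        preds = np.asarray([model_or_ensemble.predict_ec3(x) for x in X])
    pred = np.log10(preds)
    resid = pred - obs
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt((resid ** 2).mean()))
    return BenchmarkResult(r2, rmse, len(rows))


def save_model(model: ANNModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path) -> ANNModel:
    with open(path) as fh:
        return ANNModel.from_dict(json.load(fh))
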