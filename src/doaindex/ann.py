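"""Backpropagation network mapping the entropy track to a 0-100 index.

A single-hidden-layer feedforward network (tanh hidden units, logistic
output scaled to [0, 100]) is trained by full-batch gradient descent with
momentum on mean squared error against the expert consciousness score,
with early stopping on a held-out validation set. Inputs are the current
windowed sample entropy plus the preceding ``lag - 1`` values, giving the
regressor 30 s of temporal context at the 5-s cadence; ``lag=1`` reduces to
a strictly pointwise entropy-to-score mapping.

The forward/backward pass is written out explicitly (no optimizer library):
the analytic gradient is part of the package's contract and is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_formats import IndexSeries
from .sampen import EntropyTrack

__all__ = [
    "FeatureMatrix",
    "TrainConfig",
    "MLPModel",
    "SplitSpec",
    "proportional_split",
    "build_features",
    "train",
    "predict",
    "loss_and_grads",
]


@dataclass
class SplitSpec:
    """Disjoint session-level train/validation/test assignment.

    Splitting is always by session, never by epoch: epochs within one
    session are strongly dependent, so an epoch-level split would leak the
    test sessions into training.
    """

    train: list[str]
    validation: list[str]
    test: list[str]

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("train/validation/test sessions must be disjoint")
        if not self.train or not self.validation:
            raise ValueError("need at least one training and one validation session")


def proportional_split(
    session_ids: list[str], proportions: tuple[int, int, int] = (30, 10, 24)
) -> SplitSpec:
    """Assign sessions to train/validation/test in the given proportions.

    Counts are allocated by largest remainder so they always sum to the
    cohort size; sessions are assigned in the order given (callers pass a
    deterministic ordering). The default 30:10:24 mirrors a 64-patient
    cohort split; 12 sessions yield 6/2/4.
    """
    n = len(session_ids)
    if n < 3:
        raise ValueError("need at least 3 sessions to split")
    total = sum(proportions)
    exact = [n * p / total for p in proportions]
    counts = [int(e) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    for k in sorted(range(3), key=lambda i: -remainders[i]):
        if sum(counts) == n:
            break
        counts[k] += 1
    counts = [max(1, c) for c in counts]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    i1, i2 = counts[0], counts[0] + counts[1]
    return SplitSpec(
        train=list(session_ids[:i1]),
        validation=list(session_ids[i1:i2]),
        test=list(session_ids[i2:]),
    )


@dataclass
class FeatureMatrix:
    """Lagged entropy features with aligned targets, one row per 5-s epoch."""

    X: np.ndarray  # (n_epochs, lag)
    y: np.ndarray  # EACL target, 0-100
    times: np.ndarray
    session_id: str = "session"

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, lag) with one target per row")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("features and targets must be finite")


@dataclass
class TrainConfig:
    hidden: int = 10
    lr: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 2000
    patience: int = 50
    seed: int = 0


@dataclass
class MLPModel:
    """Trained network: weights, input standardization, and lag."""

    W1: np.ndarray  # (lag, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    lag: int
    config: TrainConfig = field(default_factory=TrainConfig)

    def predict_values(self, X: np.ndarray) -> np.ndarray:
        """Predictions in [0, 100] for a raw (unstandardized) feature matrix."""
        Xs = (X - self.x_mean) / self.x_sd
        params = {"W1": self.W1, "b1": self.b1, "w2": self.w2, "b2": self.b2}
        return 100.0 * _forward(params, Xs)[0]

    def to_json(self) -> str:
        payload = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "lag": self.lag,
            "config": self.config.__dict__,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            W1=np.array(d["W1"]),
            b1=np.array(d["b1"]),
            w2=np.array(d["w2"]),
            b2=float(d["b2"]),
            x_mean=np.array(d["x_mean"]),
            x_sd=np.array(d["x_sd"]),
            lag=int(d["lag"]),
            config=TrainConfig(**d["config"]),
        )


# ---------------------------------------------------------------------------
# Feature construction


def _impute_forward(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Forward-fill NaNs; returns the filled array and the index of the
    first valid entry (rows touching leading NaNs must be dropped)."""
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("entropy track contains no valid values")
    first_valid = int(np.argmax(finite))
    filled = values.copy()
    last = np.nan
    for k in range(filled.size):
        if np.isfinite(filled[k]):
            last = filled[k]
        else:
            filled[k] = last
    return filled, first_valid


def _lag_matrix(values: np.ndarray, lag: int) -> np.ndarray:
    """Row k holds values[k-lag+1 .. k] for k = lag-1 .. n-1."""
    n = values.size
    if n < lag:
        raise ValueError(f"track of {n} epochs is shorter than lag {lag}")
    return np.column_stack([values[j : n - lag + 1 + j] for j in range(lag)])


def build_features(
    entropy_track: EntropyTrack, eacl: IndexSeries, lag: int = 6
) -> FeatureMatrix:
    """Assemble lagged entropy features aligned with the EACL target.

    Missing entropy values are imputed by the last valid value; epochs whose
    lag window reaches before the first valid value are dropped. The EACL
    track is linearly interpolated onto the entropy epoch times.
    """
    filled, first_valid = _impute_forward(entropy_track.values)
    X = _lag_matrix(filled, lag)
    times = entropy_track.times[lag - 1 :]
    # drop rows touching leading NaNs, and rows outside the EACL span
    keep = (np.arange(lag - 1, filled.size) - (lag - 1)) >= first_valid
    half_step = 2.5
    keep &= (times >= eacl.times[0] - half_step) & (times <= eacl.times[-1] + half_step)
    if not keep.any():
        raise ValueError("no overlap between entropy track and EACL track")
    y = np.interp(times[keep], eacl.times, eacl.values)
    return FeatureMatrix(X=X[keep], y=y, times=times[keep])


# ---------------------------------------------------------------------------
# Network forward / backward


def _forward(params: dict, Xs: np.ndarray):
    a = np.tanh(Xs @ params["W1"] + params["b1"])
    z2 = a @ params["w2"] + params["b2"]
    y01 = 1.0 / (1.0 + np.exp(-z2))
    return y01, a


def loss_and_grads(params: dict, Xs: np.ndarray, t01: np.ndarray):
    """Mean squared error on the [0, 1]-scaled target and its analytic
    gradient with respect to every parameter."""
    n = Xs.shape[0]
    y01, a = _forward(params, Xs)
    e = y01 - t01
    loss = float(np.mean(e**2))
    dz2 = (2.0 / n) * e * y01 * (1.0 - y01)
    grads = {
        "w2": a.T @ dz2,
        "b2": float(np.sum(dz2)),
    }
    da = np.outer(dz2, params["w2"])
    dz1 = da * (1.0 - a**2)
    grads["W1"] = Xs.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads


def _stack_features(mats: list[FeatureMatrix]):
    X = np.vstack([m.X for m in mats])
    y = np.concatenate([m.y for m in mats])
    return X, y


def train(
    train_features: list[FeatureMatrix],
    val_features: list[FeatureMatrix],
    config: TrainConfig | None = None,
) -> MLPModel:
    """Fit the network by full-batch gradient descent with momentum.

    Weights start from a seeded uniform(-0.5, 0.5) draw; the returned model
    carries the weights that achieved the best validation MSE (early
    stopping with the configured patience).
    """
    config = config or TrainConfig()
    if not train_features or not val_features:
        raise ValueError("need at least one training and one validation session")
    X_tr, y_tr = _stack_features(train_features)
    X_va, y_va = _stack_features(val_features)
    lag = X_tr.shape[1]

    x_mean = X_tr.mean(axis=0)
    x_sd = X_tr.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs_tr = (X_tr - x_mean) / x_sd
    Xs_va = (X_va - x_mean) / x_sd
    t_tr, t_va = y_tr / 100.0, y_va / 100.0

    rng = np.random.default_rng(config.seed)
    H = config.hidden
    params = {
        "W1": rng.uniform(-0.5, 0.5, size=(lag, H)),
        "b1": rng.uniform(-0.5, 0.5, size=H),
        "w2": rng.uniform(-0.5, 0.5, size=H),
        "b2": float(rng.uniform(-0.5, 0.5)),
    }
    velocity = {k: np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0
                for k, v in params.items()}

    def val_mse(p):
        y01, _ = _forward(p, Xs_va)
        return float(np.mean((y01 - t_va) ** 2))

    best = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in params.items()}
    best_val = val_mse(params)
    stall = 0
    for _epoch in range(config.max_epochs):
        loss, grads = loss_and_grads(params, Xs_tr, t_tr)
        if not np.isfinite(loss):
            raise RuntimeError("training diverged; lower the learning rate")
        for k in params:
            velocity[k] = config.momentum * velocity[k] - config.lr * grads[k]
            params[k] = params[k] + velocity[k]
        v = val_mse(params)
        if v < best_val - 1e-12:
            best_val = v
            best = {k: (p.copy() if isinstance(p, np.ndarray) else p)
                    for k, p in params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    return MLPModel(
        W1=np.asarray(best["W1"]),
        b1=np.asarray(best["b1"]),
        w2=np.asarray(best["w2"]),
        b2=float(best["b2"]),
        x_mean=x_mean,
        x_sd=x_sd,
        lag=lag,
        config=config,
    )


def predict(model: MLPModel, entropy_track: EntropyTrack) -> IndexSeries:
    """Predict the 0-100 index for each epoch from epoch ``lag`` onward."""
    filled, first_valid = _impute_forward(entropy_track.values)
    X = _lag_matrix(filled, model.lag)
    times = entropy_track.times[model.lag - 1 :]
    keep = (np.arange(model.lag - 1, filled.size) - (model.lag - 1)) >= first_valid
    values = model.predict_values(X[keep])
    return IndexSeries(times[keep], np.clip(values, 0.0, 100.0))
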