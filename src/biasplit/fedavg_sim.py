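"""Desk-scale federated-averaging demonstrator on toy regression tasks.

The point of this module is to exercise the *splits*, not to model any
particular network: clients hold subsets of a cohort produced by one of
the splitters, each trains a linear regressor on synthetic features, and
the server aggregates by size-weighted parameter averaging (federated
averaging).  Features are a seeded random linear map of the standardized
labels plus Gaussian noise, shared by all clients, so the learning task is
a noisy inverse problem: the best linear predictor of the labels from the
features regresses toward the label mean of the *training* distribution.
Clients with biased label distributions therefore learn genuinely
different local models, and the averaged global model inherits their
compromises — IID splits track the centralized model, hard median splits
collapse toward the pooled mean (shrunken prediction spread, inflated
errors at the label extremes), and realistically biased splits land in
between.

Training is deterministic full-batch gradient descent; every scenario is
exactly reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_synth import ConfigurationError

__all__ = [
    "ToyRegressionTask",
    "LinearModel",
    "FederationSchedule",
    "TrainingError",
    "make_task",
    "local_train",
    "fedavg_round",
    "run_federation",
    "binned_mae_report",
    "prediction_variance_ratio",
]

DEFAULT_NOISE_SD = 1.5  # on the standardized-label scale
DEFAULT_N_FEATURES = 4


class TrainingError(RuntimeError):
    """Raised when gradient descent diverges (non-finite loss)."""


@dataclass(frozen=True)
class ToyRegressionTask:
    """Shared feature transform: ``x = z @ transform + noise`` with z the
    labels standardized by the pooled moments recorded here."""

    transform: np.ndarray  # (d, p)
    noise_sd: float
    label_mean: np.ndarray  # (d,)
    label_sd: np.ndarray  # (d,)

    @property
    def n_features(self) -> int:
        return self.transform.shape[1]

    def features(self, labels: np.ndarray, seed: int) -> np.ndarray:
        """Deterministic noisy features for a block of labels."""
        labels = np.atleast_2d(labels)
        z = (labels - self.label_mean) / self.label_sd
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, self.noise_sd, size=(labels.shape[0], self.n_features))
        return z @ self.transform + noise


def make_task(
    pooled_labels: np.ndarray,
    seed: int,
    n_features: int = DEFAULT_N_FEATURES,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> ToyRegressionTask:
    """Build the shared random feature transform from pooled label moments."""
    labels = np.atleast_2d(pooled_labels)
    d = labels.shape[1]
    rng = np.random.default_rng(seed)
    transform = rng.normal(0.0, 1.0, size=(d, n_features)) / math.sqrt(d)
    return ToyRegressionTask(
        transform=transform,
        noise_sd=float(noise_sd),
        label_mean=labels.mean(axis=0),
        label_sd=labels.std(axis=0),
    )


@dataclass(frozen=True)
class LinearModel:
    """y_hat = x @ weights + bias."""

    weights: np.ndarray  # (p, d)
    bias: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        b = np.asarray(self.bias, dtype=float)
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise ValueError("model parameters must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", b)

    @classmethod
    def zeros(cls, n_features: int, n_outputs: int) -> "LinearModel":
        return cls(weights=np.zeros((n_features, n_outputs)), bias=np.zeros(n_outputs))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.weights + self.bias

    def mae(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-output mean absolute error."""
        return np.abs(self.predict(x) - np.atleast_2d(y)).mean(axis=0)


@dataclass(frozen=True)
class FederationSchedule:
    """Federation rounds x local epochs, with a shared GD learning rate.

    Defaults follow a 50-round, 20-epochs-per-round schedule; desk-scale
    runs typically shrink both.
    """

    rounds: int = 50
    local_epochs: int = 20
    learning_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.local_epochs < 1:
            raise ConfigurationError("rounds and local_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


def local_train(
    model: LinearModel,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    learning_rate: float,
) -> LinearModel:
    """Deterministic full-batch gradient descent on mean squared error."""
    if len(x) == 0:
        raise ConfigurationError("client dataset is empty")
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    w = model.weights.copy()
    b = model.bias.copy()
    n = x.shape[0]
    for _ in range(epochs):
        resid = x @ w + b - y
        grad_w = 2.0 / n * x.T @ resid
        grad_b = 2.0 / n * resid.sum(axis=0)
        w -= learning_rate * grad_w
        b -= learning_rate * grad_b
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise TrainingError(
                f"gradient descent diverged (lr={learning_rate}, n={n}); "
                f"reduce the learning rate"
            )
    return LinearModel(weights=w, bias=b)


def fedavg_round(models: Sequence[LinearModel], sizes: Sequence[int]) -> LinearModel:
    """Size-weighted parameter averaging of structurally identical models."""
    if len(models) != len(sizes) or not models:
        raise ValueError("one size per model required")
    if any(s <= 0 for s in sizes):
        raise ValueError("client sizes must be positive")
    shape = models[0].weights.shape
    if any(m.weights.shape != shape for m in models):
        raise ValueError("client models are structurally different")
    weights_arr = np.asarray(sizes, dtype=float)
    weights_arr /= weights_arr.sum()
    w = sum(a * m.weights for a, m in zip(weights_arr, models))
    b = sum(a * m.bias for a, m in zip(weights_arr, models))
    return LinearModel(weights=w, bias=b)


def run_federation(
    clients: Sequence[tuple[np.ndarray, np.ndarray]],
    schedule: FederationSchedule,
    test_data: tuple[np.ndarray, np.ndarray] | None = None,
    init: LinearModel | None = None,
) -> tuple[LinearModel, pd.DataFrame]:
    """Alternate local training and federated averaging.

    Each round starts every client from the current global model, trains
    ``local_epochs`` full-batch GD epochs locally, and averages the client
    models weighted by client size.  Records global-test MAE per round when
    test data is given.  A single client degenerates to centralized
    training with the same total epoch budget.
    """
    if not clients:
        raise ConfigurationError("at least one client required")
    sizes = [len(x) for x, _ in clients]
    if any(s == 0 for s in sizes):
        raise ConfigurationError("every client needs at least one sample")
    p = clients[0][0].shape[1]
    d = np.atleast_2d(clients[0][1]).shape[1]
    model = init if init is not None else LinearModel.zeros(p, d)
    history = []
    for rnd in range(1, schedule.rounds + 1):
        locals_ = [
            local_train(model, x, y, schedule.local_epochs, schedule.learning_rate)
            for x, y in clients
        ]
        model = fedavg_round(locals_, sizes)
        record: dict = {"round": rnd}
        if test_data is not None:
            mae = model.mae(*test_data)
            for j, v in enumerate(mae):
                record[f"test_mae_{j}"] = float(v)
        history.append(record)
    return model, pd.DataFrame(history)


def binned_mae_report(
    model: LinearModel,
    x: np.ndarray,
    y: np.ndarray,
    bin_edges: Sequence[np.ndarray],
) -> pd.DataFrame:
    """Per-label-bin mean absolute error table.

    One row per (label dimension, bin): bin bounds, sample count, MAE
    (``NaN`` for empty bins, which are reported but carry no error), plus a
    trailing ``overall`` row per dimension.  The overall MAE equals the
    count-weighted mean of the bin MAEs.
    """
    y = np.atleast_2d(y)
    if y.shape[0] == 0:
        raise ConfigurationError("test data is empty")
    errors = np.abs(model.predict(x) - y)
    rows = []
    for j, edges in enumerate(bin_edges):
        edges = np.asarray(edges, dtype=float)
        idx = np.clip(np.searchsorted(edges, y[:, j], side="right") - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            mask = idx == b
            rows.append(
                {
                    "dimension": j,
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "count": int(mask.sum()),
                    "mae": float(errors[mask, j].mean()) if mask.any() else math.nan,
                }
            )
        rows.append(
            {
                "dimension": j,
                "bin_low": -math.inf,
                "bin_high": math.inf,
                "count": y.shape[0],
                "mae": float(errors[:, j].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of one federated scenario on a fixed task and test set."""

    model: LinearModel
    history: pd.DataFrame
    test_mae: np.ndarray  # per label dimension
    variance_ratio: np.ndarray
    client_sizes: tuple[int, ...]
    client_val_mae: tuple[tuple[float, ...], ...]
    test_features: np.ndarray  # the features the test MAE was scored on


def run_scenario(
    train_cohort,
    assignment,
    task: ToyRegressionTask,
    schedule: FederationSchedule,
    seed: int,
    test_cohort,
    val_fraction: float = 0.2,
) -> ScenarioResult:
    """Run one federated scenario for a given partition of the train pool.

    Features are generated once per sample from the shared task transform
    (so competing splitters see identical data), each client keeps an
    80/20 local train/validation split with validation only logged, and
    the global model is scored on the common held-out test cohort.
    """
    rng = np.random.default_rng(seed)
    x_train = task.features(train_cohort.labels, seed=int(rng.integers(2**31 - 1)))
    x_test = task.features(test_cohort.labels, seed=int(rng.integers(2**31 - 1)))
    groups = assignment.groups(train_cohort)
    clients = []
    val_sets = []
    for idx in groups:
        if len(idx) == 0:
            raise ConfigurationError("a client received no samples")
        perm = rng.permutation(len(idx))
        n_val = int(np.rint(val_fraction * len(idx)))
        val_idx = idx[perm[:n_val]]
        fit_idx = idx[perm[n_val:]]
        clients.append((x_train[fit_idx], train_cohort.labels[fit_idx]))
        val_sets.append((x_train[val_idx], train_cohort.labels[val_idx]))
    test = (x_test, test_cohort.labels)
    model, history = run_federation(clients, schedule, test_data=test)
    val_mae = tuple(
        tuple(model.mae(xv, yv)) if len(xv) else ()
        for xv, yv in val_sets
    )
    return ScenarioResult(
        model=model,
        history=history,
        test_mae=model.mae(*test),
        variance_ratio=prediction_variance_ratio(model, *test),
        client_sizes=tuple(len(x) for x, _ in clients),
        client_val_mae=val_mae,
        test_features=x_test,
    )


def prediction_variance_ratio(model: LinearModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Var(predictions) / Var(labels) per output: values well below 1 flag
    mode collapse (the model compressing predictions toward the mean)."""
    pred = model.predict(x)
    y = np.atleast_2d(y)
    return pred.var(axis=0) / y.var(axis=0)
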