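"""Extreme learning machine regression.

A single-hidden-layer feedforward network whose hidden-layer weights and
biases are drawn at random (uniform on [−1, 1], seeded) and never trained;
only the output weights are learned, in closed form, as the minimum-norm
least-squares solution

    output_weights = pinv(P) · y,      P = activation(X·Wᵀ + b)

via the Moore–Penrose pseudoinverse of the hidden-layer output matrix P.
``optimize_elm`` follows the published protocol: shuffle the compounds,
split 4:1 into training and test sets, scan activation functions and
hidden-node counts 1..100, and keep the model with the lowest test RMSE
(ties broken by higher correlation coefficient, then fewer hidden nodes).

Shapes follow the standard ELM convention: input weights are
(n_hidden × n_inputs), one bias per hidden node, output weights
(n_hidden,).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .dataio import QsarDataset
from .preprocess import random_split
from .validation import pearson_r

__all__ = [
    "ACTIVATIONS",
    "ElmModel",
    "ElmMetrics",
    "elm_train",
    "elm_predict",
    "optimize_elm",
    "compute_metrics",
]

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "sine": np.sin,
    "hardlim": lambda z: (z >= 0).astype(float),
    "tribas": lambda z: np.maximum(0.0, 1.0 - np.abs(z)),
}


@dataclass
class ElmModel:
    input_weights: np.ndarray  # (n_hidden, n_inputs)
    biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden,)
    activation: str
    seed: int
    n_hidden: int

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise KeyError(
                f"unknown activation {self.activation!r}; "
                f"registered: {sorted(ACTIVATIONS)}"
            )
        if self.input_weights.shape[0] != self.n_hidden or self.biases.shape != (
            self.n_hidden,
        ):
            raise ValueError("inconsistent hidden-layer dimensions")

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return elm_predict(self, X)

    def to_json(self, path: str | Path) -> None:
        # (seed, n_hidden, activation, n_inputs) regenerate the hidden layer
        payload = {
            "seed": self.seed,
            "n_hidden": self.n_hidden,
            "activation": self.activation,
            "n_inputs": self.n_inputs,
            "output_weights": self.output_weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElmModel":
        payload = json.loads(Path(path).read_text())
        W, b = _hidden_layer(
            payload["seed"], payload["n_hidden"], payload["n_inputs"]
        )
        return cls(
            input_weights=W,
            biases=b,
            output_weights=np.asarray(payload["output_weights"], dtype=float),
            activation=payload["activation"],
            seed=payload["seed"],
            n_hidden=payload["n_hidden"],
        )


@dataclass
class ElmMetrics:
    mae: float
    rmse: float
    cc: float
    mapd: float

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "rmse": self.rmse, "cc": self.cc, "mapd": self.mapd}


def _hidden_layer(seed: int, n_hidden: int, n_inputs: int):
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_inputs))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    return W, b


def _hidden_output(model_or_parts, X: np.ndarray) -> np.ndarray:
    W, b, act = model_or_parts
    return ACTIVATIONS[act](X @ W.T + b)


def elm_train(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    activation: str = "sigmoid",
    seed: int = 0,
) -> ElmModel:
    """Train an ELM: random hidden layer, pseudoinverse output solve."""
    if activation not in ACTIVATIONS:
        raise KeyError(
            f"unknown activation {activation!r}; registered: {sorted(ACTIVATIONS)}"
        )
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training matrix")
    W, b = _hidden_layer(seed, n_hidden, X.shape[1])
    P = _hidden_output((W, b, activation), X)
    out = np.linalg.pinv(P) @ y  # minimum-norm least-squares solution
    return ElmModel(
        input_weights=W,
        biases=b,
        output_weights=out,
        activation=activation,
        seed=seed,
        n_hidden=n_hidden,
    )


def elm_predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns, model expects {model.n_inputs}"
        )
    P = _hidden_output((model.input_weights, model.biases, model.activation), X)
    return P @ model.output_weights


def compute_metrics(y_exp: np.ndarray, y_pred: np.ndarray) -> ElmMetrics:
    """MAE, RMSE, Pearson CC and MAPD (mean of 100·|err|/observed)."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.size < 2 or y_exp.shape != y_pred.shape:
        raise ValueError("need equal-length vectors of size >= 2")
    if np.any(y_exp == 0):
        raise ValueError("MAPD undefined: an observed activity is zero")
    err = y_exp - y_pred
    return ElmMetrics(
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        cc=pearson_r(y_exp, y_pred),
        mapd=float((100.0 * np.abs(err) / np.abs(y_exp)).mean()),
    )


def optimize_elm(
    dataset: QsarDataset,
    activations: Sequence[str] = ("sigmoid", "sine", "hardlim", "tribas"),
    hidden_range: tuple[int, int] = (1, 100),
    split_seed: int = 0,
    weight_seed: int = 0,
) -> tuple[ElmModel, ElmMetrics]:
    """Grid-search activation × hidden-node count on a seeded 4:1 split.

    Selection: lowest test-set RMSE, ties broken by higher CC, then by
    fewer hidden nodes.  Deterministic given ``(split_seed, weight_seed)``.
    """
    lo, hi = hidden_range
    if lo > hi or lo < 1:
        raise ValueError(f"empty or invalid hidden_range {hidden_range}")
    if dataset.table.n_compounds < 10:
        raise ValueError("need at least 10 compounds for the 4:1 protocol")
    for act in activations:
        if act not in ACTIVATIONS:
            raise KeyError(
                f"unknown activation {act!r}; registered: {sorted(ACTIVATIONS)}"
            )

    partition = random_split(dataset.table, 0.8, split_seed)
    work = dataset.with_partition(partition)
    train, test = work.subset("train"), work.subset("test")
    X_tr, y_tr = train.table.values, train.y
    X_te, y_te = test.table.values, test.y

    best: tuple[float, float, int, ElmModel, ElmMetrics] | None = None
    for act in activations:
        for n_hidden in range(lo, hi + 1):
            model = elm_train(X_tr, y_tr, n_hidden, act, weight_seed)
            pred = elm_predict(model, X_te)
            if np.ptp(pred) == 0:
                continue  # constant predictions: CC undefined, never optimal
            metrics = compute_metrics(y_te, pred)
            key = (metrics.rmse, -metrics.cc, n_hidden)
            if best is None or key < (best[0], best[1], best[2]):
                best = (metrics.rmse, -metrics.cc, n_hidden, model, metrics)
    if best is None:
        raise ValueError("every candidate produced constant test predictions")
    return best[3], best[4]
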