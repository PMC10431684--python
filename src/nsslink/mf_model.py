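"""Biased matrix factorization trained by SGD.

The bi-adjacency matrix is approximated by P (N×k) times Q (k×M) plus a
bias term mu + b_i + b_j.  Each epoch shuffles the training samples and
applies the four gradient updates per sample:

    e_ij = a_ij − (mu + b_i + b_j + p_i·q_j)
    b_i  += gamma (e_ij − lambda b_i)
    b_j  += gamma (e_ij − lambda b_j)
    p_i  += gamma (e_ij q_j − lambda p_i)
    q_j  += gamma (e_ij p_i − lambda q_j)

using the pre-update p_i, q_j on the right-hand sides.  The confidence
score of an unobserved pair is mu + b_i + b_j + p_i·q_j.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .network_io import BipartiteNetwork

__all__ = [
    "MFParams",
    "TrainingSet",
    "FactorModel",
    "init_model",
    "predict_score",
    "sgd_update",
    "objective",
    "train",
    "build_training_set",
    "score_all_unobserved",
    "save_model",
    "load_model",
]

_FORMAT = "nsslink-factor-model-v1"


@dataclass(frozen=True)
class MFParams:
    k: int = 16
    lam: float = 0.05
    gamma: float = 0.01
    max_iters: int = 30
    init_scale: float = 0.1
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class TrainingSet:
    """Samples (i, j, a_ij) over an N×M matrix; positives 1, negatives 0."""

    samples: list[tuple[int, int, float]]
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for i, j, a in self.samples:
            if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
                raise ValueError(f"sample index ({i}, {j}) out of range")
            if (i, j) in seen:
                raise ValueError(f"duplicate sample ({i}, {j})")
            seen.add((i, j))


@dataclass
class FactorModel:
    P: np.ndarray  # (N, k)
    Q: np.ndarray  # (k, M)
    b_row: np.ndarray  # (N,)
    b_col: np.ndarray  # (M,)
    mu: float
    params: MFParams
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.P.shape[0]

    @property
    def n_cols(self) -> int:
        return self.Q.shape[1]


def init_model(n_rows: int, n_cols: int, params: MFParams) -> FactorModel:
    """Factors i.i.d. normal(0, init_scale²); biases and mu zero; seeded."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rng = np.random.default_rng(params.seed)
    P = rng.normal(0.0, params.init_scale, size=(n_rows, params.k))
    Q = rng.normal(0.0, params.init_scale, size=(params.k, n_cols))
    return FactorModel(
        P=P,
        Q=Q,
        b_row=np.zeros(n_rows),
        b_col=np.zeros(n_cols),
        mu=0.0,
        params=params,
    )


def predict_score(model: FactorModel, i: int, j: int) -> float:
    """Confidence score mu + b_i + b_j + p_i·q_j."""
    if not (0 <= i < model.n_rows and 0 <= j < model.n_cols):
        raise IndexError(f"pair index ({i}, {j}) out of range")
    return float(
        model.mu + model.b_row[i] + model.b_col[j] + model.P[i] @ model.Q[:, j]
    )


def sgd_update(
    model: FactorModel, sample: tuple[int, int, float], params: MFParams
) -> None:
    """One gradient step on a single sample, in place."""
    i, j, a = sample
    pi = model.P[i].copy()
    qj = model.Q[:, j].copy()
    e = a - (model.mu + model.b_row[i] + model.b_col[j] + pi @ qj)
    if not np.isfinite(e):
        raise FloatingPointError(
            f"non-finite residual at sample ({i}, {j}); try a smaller gamma"
        )
    g, lam = params.gamma, params.lam
    model.b_row[i] += g * (e - lam * model.b_row[i])
    model.b_col[j] += g * (e - lam * model.b_col[j])
    model.P[i] = pi + g * (e * qj - lam * pi)
    model.Q[:, j] = qj + g * (e * pi - lam * qj)


def objective(model: FactorModel, ts: TrainingSet) -> float:
    """Regularized squared error over the training samples."""
    rows = np.fromiter((s[0] for s in ts.samples), dtype=np.intp)
    cols = np.fromiter((s[1] for s in ts.samples), dtype=np.intp)
    vals = np.fromiter((s[2] for s in ts.samples), dtype=float)
    pred = (
        model.mu
        + model.b_row[rows]
        + model.b_col[cols]
        + np.einsum("ik,ki->i", model.P[rows], model.Q[:, cols])
    )
    err = float(np.sum((vals - pred) ** 2))
    reg = float(
        np.sum(model.b_row[rows] ** 2)
        + np.sum(model.b_col[cols] ** 2)
        + np.sum(model.P[rows] ** 2)
        + np.sum(model.Q[:, cols] ** 2)
    )
    return err + model.params.lam * reg


def train(ts: TrainingSet, params: MFParams) -> FactorModel:
    """Fit the model: max_iters epochs of shuffled per-sample SGD.

    mu is set to the mean of the training values before the first epoch.
    The regularized objective is logged per epoch into
    ``model.objective_trace``.  Bit-identical per seed.
    """
    if not ts.samples:
        raise ValueError("training set is empty")
    model = init_model(ts.n_rows, ts.n_cols, params)
    model.mu = float(np.mean([a for _, _, a in ts.samples]))

    rows = np.array([s[0] for s in ts.samples], dtype=np.intp)
    cols = np.array([s[1] for s in ts.samples], dtype=np.intp)
    vals = np.array([s[2] for s in ts.samples], dtype=float)
    n = len(vals)

    rng = np.random.default_rng(params.seed + 1)
    P, Q = model.P, model.Q
    b_row, b_col = model.b_row, model.b_col
    mu, g, lam = model.mu, params.gamma, params.lam
    for _ in range(params.max_iters):
        order = rng.permutation(n)
        for idx in order:
            i = rows[idx]
            j = cols[idx]
            pi = P[i]
            qj = Q[:, j]
            e = vals[idx] - (mu + b_row[i] + b_col[j] + pi @ qj)
            b_row[i] += g * (e - lam * b_row[i])
            b_col[j] += g * (e - lam * b_col[j])
            new_pi = pi + g * (e * qj - lam * pi)
            Q[:, j] = qj + g * (e * pi - lam * qj)
            P[i] = new_pi
        epoch_obj = objective(model, ts)
        if not np.isfinite(epoch_obj):
            raise FloatingPointError(
                "training objective diverged; try a smaller gamma"
            )
        model.objective_trace.append(epoch_obj)
    return model


def build_training_set(
    net: BipartiteNetwork, negatives: Iterable[tuple[str, str]]
) -> TrainingSet:
    """Present edges as value-1 samples plus the given pairs as value-0.

    Raw-MF mode is obtained by passing every unobserved pair as a negative.
    """
    li = net.left_index()
    ri = net.right_index()
    samples = [(li[u], ri[v], 1.0) for u, v in sorted(net.present_edges)]
    for u, v in sorted(set(negatives)):
        if (u, v) in net.present_edges:
            raise ValueError(f"negative pair {(u, v)} is a present edge")
        samples.append((li[u], ri[v], 0.0))
    return TrainingSet(samples, net.n_left, net.n_right)


def score_all_unobserved(
    model: FactorModel,
    net: BipartiteNetwork,
    exclude: set[tuple[str, str]] | None = None,
) -> Iterator[tuple[tuple[str, str], float]]:
    """Scores for every pair that is neither present nor excluded."""
    if model.n_rows != net.n_left or model.n_cols != net.n_right:
        raise ValueError(
            f"model shape ({model.n_rows}, {model.n_cols}) does not match "
            f"network ({net.n_left}, {net.n_right})"
        )
    exclude = exclude or set()
    scores = model.mu + model.b_row[:, None] + model.b_col[None, :] + model.P @ model.Q
    for i, u in enumerate(net.left_nodes):
        for j, v in enumerate(net.right_nodes):
            pair = (u, v)
            if pair in net.present_edges or pair in exclude:
                continue
            yield pair, float(scores[i, j])


def save_model(model: FactorModel, path: str | Path) -> None:
    """Serialize to a single versioned JSON archive."""
    payload = {
        "format": _FORMAT,
        "mu": model.mu,
        "P": model.P.tolist(),
        "Q": model.Q.tolist(),
        "b_row": model.b_row.tolist(),
        "b_col": model.b_col.tolist(),
        "params": {
            "k": model.params.k,
            "lam": model.params.lam,
            "gamma": model.params.gamma,
            "max_iters": model.params.max_iters,
            "init_scale": model.params.init_scale,
            "seed": model.params.seed,
            "threshold": model.params.threshold,
        },
        "objective_trace": model.objective_trace,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> FactorModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a {_FORMAT} archive")
    return FactorModel(
        P=np.array(payload["P"], dtype=float),
        Q=np.array(payload["Q"], dtype=float),
        b_row=np.array(payload["b_row"], dtype=float),
        b_col=np.array(payload["b_col"], dtype=float),
        mu=float(payload["mu"]),
        params=MFParams(**payload["params"]),
        objective_trace=list(payload["objective_trace"]),
    )
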