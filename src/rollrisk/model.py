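"""Shallow regularized feed-forward risk network.

Architecture: input layer of predictor encodings, one densely connected
hidden layer of 32 logistic units with an L2 penalty of 1e-4 on both weight
matrices (not biases), and a single logistic output unit trained with binary
cross-entropy.  Training runs in two phases — small batches (2**7) with
early-stopping patience 2 on test loss, then large batches (2**14) with
patience 4 continuing from the phase-1 weights — restoring the best test-loss
weights at the end of each phase.  Optimization uses Adamax-style adaptive
gradient descent.  Implemented directly on numpy so training is exactly
reproducible from the configured seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    hidden_nodes: int = 32
    l2_penalty: float = 1e-4
    phase1_batch: int = 2**7
    phase1_patience: int = 2
    phase2_batch: int = 2**14
    phase2_patience: int = 4
    max_epochs_per_phase: int = 200
    learning_rate: float = 0.002  # conventional Adamax defaults
    beta1: float = 0.9
    beta2: float = 0.999
    train_seed: int = 0

    def __post_init__(self):
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")
        if min(self.phase1_batch, self.phase2_batch) < 1:
            raise ValueError("batch sizes must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class RiskNetwork:
    """Weight container; ``columns`` pins the expected input layout."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    columns: tuple = ()

    def copy_weights(self) -> dict:
        return {"W1": self.W1.copy(), "b1": self.b1.copy(), "W2": self.W2.copy(), "b2": self.b2.copy()}

    def load_weights(self, w: dict) -> None:
        self.W1, self.b1 = w["W1"].copy(), w["b1"].copy()
        self.W2, self.b2 = w["W2"].copy(), w["b2"].copy()

    @property
    def n_parameters(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def squared_weight_norm(self) -> float:
        return float(np.sum(self.W1**2) + np.sum(self.W2**2))

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = _sigmoid(X @ self.W1 + self.b1)
        return _sigmoid(h @ self.W2 + self.b2).ravel()


def build_network(input_width: int, cfg: ModelConfig | None = None, columns=()) -> RiskNetwork:
    """Glorot-uniform initialized network; deterministic given ``train_seed``."""
    cfg = cfg or ModelConfig()
    if input_width < 1:
        raise ValueError("input_width must be >= 1")
    rng = np.random.default_rng(cfg.train_seed)
    h = cfg.hidden_nodes
    lim1 = np.sqrt(6.0 / (input_width + h))
    lim2 = np.sqrt(6.0 / (h + 1))
    return RiskNetwork(
        W1=rng.uniform(-lim1, lim1, size=(input_width, h)),
        b1=np.zeros(h),
        W2=rng.uniform(-lim2, lim2, size=(h, 1)),
        b2=np.zeros(1),
        columns=tuple(columns),
    )


@dataclass
class TrainedRiskModel:
    network: RiskNetwork
    config: ModelConfig
    trace: pd.DataFrame  # phase, epoch, train_loss, test_loss, restored
    encoding_plan_json: str | None = None


def _loss(net: RiskNetwork, X: np.ndarray, y: np.ndarray, l2: float) -> float:
    p = np.clip(net.forward(X), _EPS, 1.0 - _EPS)
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(bce + l2 * net.squared_weight_norm())


class _Adamax:
    def __init__(self, shapes, lr, beta1, beta2):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m = [np.zeros(s) for s in shapes]
        self.u = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        correction = 1.0 - self.b1**self.t
        for p, g, m, u in zip(params, grads, self.m, self.u):
            m *= self.b1
            m += (1.0 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p -= (self.lr / correction) * m / (u + _EPS)


def _train_phase(net, X_tr, y_tr, X_te, y_te, cfg, batch_size, patience, rng, phase):
    opt = _Adamax(
        [net.W1.shape, net.b1.shape, net.W2.shape, net.b2.shape],
        cfg.learning_rate, cfg.beta1, cfg.beta2,
    )
    l2 = cfg.l2_penalty
    n = len(y_tr)
    best_loss = np.inf
    best_weights = net.copy_weights()
    best_epoch = -1
    bad = 0
    records = []
    for epoch in range(cfg.max_epochs_per_phase):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            h = _sigmoid(Xb @ net.W1 + net.b1)
            p = _sigmoid(h @ net.W2 + net.b2).ravel()
            m = len(yb)
            dz2 = ((p - yb) / m)[:, None]
            gW2 = h.T @ dz2 + 2.0 * l2 * net.W2
            gb2 = dz2.sum(axis=0)
            dh = dz2 @ net.W2.T * h * (1.0 - h)
            gW1 = Xb.T @ dh + 2.0 * l2 * net.W1
            gb1 = dh.sum(axis=0)
            opt.step([net.W1, net.b1, net.W2, net.b2], [gW1, gb1, gW2, gb2])
        train_loss = _loss(net, X_tr, y_tr, l2)
        test_loss = _loss(net, X_te, y_te, l2)
        records.append({"phase": phase, "epoch": epoch, "train_loss": train_loss, "test_loss": test_loss})
        if test_loss < best_loss:
            best_loss, best_epoch, bad = test_loss, epoch, 0
            best_weights = net.copy_weights()
        else:
            bad += 1
            if bad >= patience:
                break
    net.load_weights(best_weights)
    trace = pd.DataFrame(records)
    trace["restored"] = trace["epoch"] == best_epoch
    return trace


def train(
    net: RiskNetwork,
    X_train,
    y_train,
    X_test,
    y_test,
    cfg: ModelConfig | None = None,
) -> TrainedRiskModel:
    """Two-phase training protocol with early stopping on test loss."""
    cfg = cfg or ModelConfig()
    X_tr = _as_matrix(X_train, net.columns)
    X_te = _as_matrix(X_test, net.columns)
    y_tr = np.asarray(y_train, dtype=float)
    y_te = np.asarray(y_test, dtype=float)
    if len(y_te) == 0:
        raise ValueError("empty test set: early stopping is undefined")
    if len(np.unique(y_tr)) < 2:
        raise ValueError(
            f"degenerate training labels (all {y_tr[0] if len(y_tr) else 'absent'}); cannot train"
        )
    rng = np.random.default_rng(cfg.train_seed + 1)
    t1 = _train_phase(net, X_tr, y_tr, X_te, y_te, cfg, cfg.phase1_batch, cfg.phase1_patience, rng, 1)
    t2 = _train_phase(net, X_tr, y_tr, X_te, y_te, cfg, cfg.phase2_batch, cfg.phase2_patience, rng, 2)
    trace = pd.concat([t1, t2], ignore_index=True)
    return TrainedRiskModel(network=net, config=cfg, trace=trace)


def _as_matrix(X, columns) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if columns:
            missing = [c for c in columns if c not in X.columns]
            extra = [c for c in X.columns if c not in set(columns)]
            if missing or extra:
                raise ValueError(f"design-matrix column mismatch; missing={missing}, extra={extra}")
            X = X.loc[:, list(columns)]
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if columns and arr.shape[1] != len(columns):
        raise ValueError(f"expected {len(columns)} columns, got {arr.shape[1]}")
    return arr


def predict_risk(model: TrainedRiskModel | RiskNetwork, X) -> np.ndarray:
    """Endpoint probabilities for each row (logistic output)."""
    net = model.network if isinstance(model, TrainedRiskModel) else model
    return net.forward(_as_matrix(X, net.columns))
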