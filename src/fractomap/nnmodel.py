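"""Multilabel compartment-weight regression network.

The model maps a normalized F-fraction profile to a point on the
C-compartment simplex:

    input(F) -> dense(h, ReLU) -> dense(C, linear) -> clamp >= 0 -> / sum

The first hidden layer width h is a hyperparameter searched within
``C + 0.4*(F - C) .. C + 0.6*(F - C)`` (floored at C so the layer never
bottlenecks below the output size). Training minimizes the mean squared
error against weight targets, with an 80/20 train/validation split and
early stopping after five non-improving epochs. Hyperparameters (optimizer
among SGD / RMSprop / Adam, log-uniform learning rate in [1e-4, 1e-1],
hidden width) are selected by Hyperband-style successive halving.

Predictions are ensembled: each optimization round rebuilds the augmented
training set, re-tunes, and trains several independent runs; raw outputs
are averaged over rounds x runs x replicates per condition and
renormalized, with the spread kept for downstream statistics.

The network is small enough that the forward/backward passes are plain
NumPy matrix algebra; training a replicate model takes seconds on one CPU.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import TrainingSet, build_training_set
from .data_io import DataError, MarkerSet
from .preprocess import ProfileTensor

logger = logging.getLogger(__name__)

OPTIMIZERS = ("sgd", "rmsprop", "adam")
LR_BOUNDS = (1e-4, 1e-1)


def hidden_size_range(F: int, C: int) -> tuple[int, int]:
    """Admissible first-hidden-layer widths for F fractions, C compartments.

    low = max(C, round(C + 0.4*(F-C))), high = max(low, round(C + 0.6*(F-C))).
    """
    low = max(C, round(C + 0.4 * (F - C)))
    high = max(low, round(C + 0.6 * (F - C)))
    return low, high


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture + optimization hyperparameters of one model."""

    F: int
    C: int
    hidden1: int
    optimizer: str = "adam"
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise DataError(f"optimizer must be one of {OPTIMIZERS}")
        if not (LR_BOUNDS[0] <= self.learning_rate <= LR_BOUNDS[1]):
            raise DataError(f"learning rate outside {LR_BOUNDS}")
        if self.hidden1 < self.C:
            raise DataError("hidden layer must be at least C wide")


def default_spec(F: int, C: int) -> NetworkSpec:
    """Midpoint spec used when hyperparameter search is disabled."""
    low, high = hidden_size_range(F, C)
    return NetworkSpec(F=F, C=C, hidden1=round((low + high) / 2),
                       optimizer="adam", learning_rate=1e-3)


class CompartmentNet:
    """Dense(h, ReLU) -> Dense(C) -> nonnegativity clamp -> sum-normalize."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        F, h, C = spec.F, spec.hidden1, spec.C
        # He init for the ReLU layer, Glorot for the linear head
        self.W1 = rng.normal(0.0, math.sqrt(2.0 / F), size=(F, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, math.sqrt(1.0 / h), size=(h, C))
        # start inside the live region of the clamp -> normalize head
        self.b2 = np.full(C, 1.0 / C)

    # -- forward ---------------------------------------------------------
    def _forward(self, X):
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        Z = H @ self.W2 + self.b2
        A = np.maximum(Z, 0.0)
        S = A.sum(axis=1, keepdims=True)
        Y = np.where(S > 0, A / np.where(S > 0, S, 1.0), 1.0 / self.spec.C)
        return H, Z, A, S, Y

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Compartment weights on the C-simplex, one row per profile."""
        return self._forward(np.asarray(X, dtype=float))[-1]

    # -- backward --------------------------------------------------------
    def _gradients(self, X, T):
        n, C = X.shape[0], self.spec.C
        H, Z, A, S, Y = self._forward(X)
        dY = 2.0 * (Y - T) / (n * C)          # d(mean squared error)
        ok = (S[:, 0] > 0)
        # y_i = a_i / s  =>  dL/da_j = (dL/dy_j - sum_i dL/dy_i y_i) / s
        inner = (dY * Y).sum(axis=1, keepdims=True)
        dA = np.where(ok[:, None], (dY - inner) / np.where(S > 0, S, 1.0), 0.0)
        dZ = dA * (Z > 0)
        # rows with every activation clamped emit a constant and would get
        # zero gradient forever; push their raw activations toward the
        # target instead so they can re-enter the live region
        dead = ~ok
        if dead.any():
            dZ[dead] = dY[dead]
        dW2 = H.T @ dZ
        db2 = dZ.sum(axis=0)
        dH = dZ @ self.W2.T
        dH *= H > 0
        dW1 = X.T @ dH
        db1 = dH.sum(axis=0)
        loss = float(np.mean((Y - T) ** 2))
        return loss, (dW1, db1, dW2, db2)

    def mse(self, X, T) -> float:
        Y = self.predict(X)
        return float(np.mean((Y - np.asarray(T, dtype=float)) ** 2))

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        self.W1, self.b1, self.W2, self.b2 = [w.copy() for w in weights]


class _Optimizer:
    def __init__(self, kind: str, lr: float):
        self.kind, self.lr = kind, lr
        self.state: dict = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.kind == "sgd":
                p -= self.lr * g
            elif self.kind == "rmsprop":
                v = self.state.setdefault(i, np.zeros_like(p))
                v *= 0.9
                v += 0.1 * g * g
                p -= self.lr * g / (np.sqrt(v) + 1e-7)
            else:  # adam
                m = self.state.setdefault(("m", i), np.zeros_like(p))
                v = self.state.setdefault(("v", i), np.zeros_like(p))
                m *= 0.9
                m += 0.1 * g
                v *= 0.999
                v += 0.001 * g * g
                mh = m / (1 - 0.9 ** self.t)
                vh = v / (1 - 0.999 ** self.t)
                p -= self.lr * mh / (np.sqrt(vh) + 1e-8)


def build_network(spec: NetworkSpec, seed: int = 0) -> CompartmentNet:
    return CompartmentNet(spec, np.random.default_rng(seed))


def train_single(
    model: CompartmentNet,
    train_set: TrainingSet,
    seed: int,
    max_epochs: int = 100,
    patience: int = 5,
    batch_size: int = 32,
    val_fraction: float = 0.2,
) -> float:
    """Train in place on an 80/20 split with early stopping; returns the
    best validation MSE. Restores the best-epoch weights."""
    n = len(train_set)
    if n < 10:
        raise DataError(f"training set too small ({n} < 10 profiles)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ttr = train_set.X[tr_idx], train_set.Y[tr_idx]
    Xval, Tval = train_set.X[val_idx], train_set.Y[val_idx]

    opt = _Optimizer(model.spec.optimizer, model.spec.learning_rate)
    best_val, best_w, stale = math.inf, model.get_weights(), 0
    for _epoch in range(max_epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), batch_size):
            sl = order[start:start + batch_size]
            _, grads = model._gradients(Xtr[sl], Ttr[sl])
            opt.step(model.params, grads)
        val = model.mse(Xval, Tval)
        if val < best_val - 1e-12:
            best_val, best_w, stale = val, model.get_weights(), 0
        else:
            stale += 1
            if stale >= patience:
                break
    model.set_weights(best_w)
    return best_val


def _sample_spec(F: int, C: int, rng: np.random.Generator) -> NetworkSpec:
    low, high = hidden_size_range(F, C)
    lr = float(np.exp(rng.uniform(np.log(LR_BOUNDS[0]), np.log(LR_BOUNDS[1]))))
    return NetworkSpec(
        F=F, C=C,
        hidden1=int(rng.integers(low, high + 1)),
        optimizer=str(rng.choice(OPTIMIZERS)),
        learning_rate=lr,
    )


def tune_hyperparameters(
    train_set: TrainingSet,
    F: int,
    C: int,
    seed: int,
    max_epochs: int = 20,
    reduction_factor: int = 3,
    patience: int = 5,
) -> NetworkSpec:
    """Hyperband search over optimizer x learning rate x hidden width.

    Brackets of successive halving with budget ``max_epochs`` and the given
    reduction factor: candidate specs are trained for a small epoch budget,
    the best third survive to a tripled budget, until one candidate reaches
    the full budget. Returns the spec with the lowest validation MSE.
    """
    rng = np.random.default_rng(seed)
    eta = reduction_factor
    s_max = int(math.log(max_epochs, eta))
    best_spec, best_val = None, math.inf
    for s in range(s_max, -1, -1):
        n = math.ceil((s_max + 1) / (s + 1) * eta ** s)
        r0 = max_epochs * eta ** (-s)
        candidates = [_sample_spec(F, C, rng) for _ in range(n)]
        scores = None
        for i in range(s + 1):
            n_i = math.floor(n * eta ** (-i))
            r_i = min(max_epochs, int(round(r0 * eta ** i)))
            if scores is not None:
                keep = np.argsort(scores)[: max(1, n_i)]
                candidates = [candidates[k] for k in keep]
            scores = []
            for spec in candidates:
                mseed = int(rng.integers(0, 2 ** 31 - 1))
                model = build_network(spec, seed=mseed)
                val = train_single(model, train_set, seed=mseed,
                                   max_epochs=max(1, r_i), patience=patience)
                scores.append(val)
        k = int(np.argmin(scores))
        if scores[k] < best_val:
            best_val, best_spec = scores[k], candidates[k]
    logger.info("tuned spec: %s (val MSE %.3g)", best_spec, best_val)
    return best_spec


@dataclass
class EnsemblePrediction:
    """Raw per-run outputs and per-condition aggregates.

    ``raw`` holds one row per (species, condition, replicate, round, run)
    with one column per compartment. ``mean[g]`` is the renormalized mean
    weight vector per species, ``std[g]`` the elementwise s.d. over the
    same collection of raw vectors.
    """

    raw: pd.DataFrame
    mean: dict = field(default_factory=dict)    # condition -> DataFrame (S x C)
    std: dict = field(default_factory=dict)
    compartment_order: list = field(default_factory=list)
    specs: dict = field(default_factory=dict)   # (g, r, round) -> NetworkSpec


def aggregate_predictions(raw: pd.DataFrame, order) -> tuple[dict, dict]:
    mean, std = {}, {}
    for g, grp in raw.groupby("condition", sort=False):
        m = grp.groupby("species")[list(order)].mean()
        s = grp.groupby("species")[list(order)].std(ddof=1).fillna(0.0)
        m = m.div(m.sum(axis=1), axis=0)
        mean[g], std[g] = m, s
    return mean, std


def predict_ensemble(
    profiles: ProfileTensor,
    markers: MarkerSet,
    seed: int,
    rounds: int = 3,
    runs: int = 10,
    tune: bool = True,
    max_epochs: int = 100,
    tune_max_epochs: int = 20,
    reduction_factor: int = 3,
    patience: int = 5,
    mix_ratios=(0.25, 0.5, 0.75),
    mix_fraction: float = 0.05,
    noise_factor: float = 2.0,
) -> EnsemblePrediction:
    """Full ensemble: per (condition, replicate, round) rebuild the
    augmented training set, optionally re-tune, train ``runs`` independent
    models and predict every species of that replicate."""
    if rounds < 1 or runs < 1:
        raise DataError("rounds and runs must both be >= 1")
    order = markers.compartment_order
    C = len(order)
    rows = []
    specs = {}
    for g in profiles.conditions:
        for r in profiles.replicates(g):
            mat = profiles.profiles[(g, r)]
            F = mat.shape[1]
            X_all = mat.to_numpy(dtype=float)
            rep_tag = zlib.crc32(f"{g}|{r}".encode()) % 100000
            for rnd in range(rounds):
                # every round draws a fresh augmented set (and tuning)
                aug_seed = (seed + 1000 * rnd + 17 * rep_tag) % (2 ** 31 - 1)
                tset = build_training_set(
                    profiles, markers, g, r, seed=aug_seed,
                    mix_ratios=mix_ratios, mix_fraction=mix_fraction,
                    noise_factor=noise_factor,
                )
                if tune:
                    spec = tune_hyperparameters(
                        tset, F, C, seed=aug_seed,
                        max_epochs=tune_max_epochs,
                        reduction_factor=reduction_factor, patience=patience,
                    )
                else:
                    spec = default_spec(F, C)
                specs[(g, r, rnd)] = spec
                for run in range(runs):
                    run_seed = (aug_seed + 1000 * rnd + run) % (2 ** 31 - 1)
                    model = build_network(spec, seed=run_seed)
                    train_single(model, tset, seed=run_seed,
                                 max_epochs=max_epochs, patience=patience)
                    W = model.predict(X_all)
                    block = pd.DataFrame(W, columns=order, index=mat.index)
                    block.insert(0, "run", run)
                    block.insert(0, "round", rnd)
                    block.insert(0, "replicate", r)
                    block.insert(0, "condition", g)
                    rows.append(block.reset_index(names="species"))
    raw = pd.concat(rows, ignore_index=True)
    mean, std = aggregate_predictions(raw, order)
    return EnsemblePrediction(raw=raw, mean=mean, std=std,
                              compartment_order=list(order), specs=specs)
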