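"""The 4-2-1 feed-forward registration quality classifier.

A deliberately small network: four inputs (DO_trans, DO_rot, MS_trans,
MS_rot), two hidden tanh units, and one output unit whose tanh activation is
affinely mapped to [0, 1].  Scores above 0.5 (strictly) are classified as
unsuccessful registrations.  Training minimizes the mean squared error with
Moller's scaled conjugate gradient (SCG) — a conjugate-gradient method that
replaces the line search with a scaled Hessian-vector estimate and a
model-trust-region adaptation of the scaling parameter lambda — with early
stopping on a held-out validation split.

Inputs are standardized to zero mean / unit variance on the training split;
the standardization is stored in the model.  Targets: successful -> 0,
unsuccessful -> 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from regiq.mvd import SUCCESSFUL, UNSUCCESSFUL

__all__ = [
    "MlpModel",
    "TrainConfig",
    "TrainingTrace",
    "InvalidDatasetError",
    "scg_train",
    "predict",
    "classify",
]


class InvalidDatasetError(ValueError):
    """Training data does not contain both classes."""


@dataclass
class MlpModel:
    """4-2-1 network weights plus input standardization."""

    w1: np.ndarray  # (n_hidden, 4)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (1, n_hidden)
    b2: np.ndarray  # (1,)
    x_mean: np.ndarray  # (4,)
    x_sd: np.ndarray  # (4,)
    meta: dict = field(default_factory=dict)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Scores in [0, 1] for raw (unstandardized) feature rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.x_mean) / self.x_sd
        H = np.tanh(Z @ self.w1.T + self.b1)
        y = np.tanh(H @ self.w2.T + self.b2)
        return ((y + 1.0) / 2.0).ravel()

    def to_json(self) -> str:
        d = {k: np.asarray(getattr(self, k)).tolist()
             for k in ("w1", "b1", "w2", "b2", "x_mean", "x_sd")}
        d["meta"] = self.meta
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "MlpModel":
        d = json.loads(s)
        return cls(**{k: np.asarray(d[k]) for k in
                      ("w1", "b1", "w2", "b2", "x_mean", "x_sd")},
                   meta=d.get("meta", {}))


@dataclass(frozen=True)
class TrainConfig:
    train_fraction: float = 0.8
    n_hidden: int = 2
    max_iterations: int = 2000
    patience: int = 25  # validation checks without improvement before stopping
    sigma0: float = 1e-4  # SCG Hessian-vector step scale
    lambda0: float = 1e-6  # initial trust-region scale
    init_scale: float = 0.5  # uniform weight init half-width
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class TrainingTrace:
    train_mse: list
    val_mse: list
    best_val_mse: list  # best-so-far at each validation check (non-increasing)
    n_iterations: int
    stopped_early: bool


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1.ravel(), w2.ravel(), b2.ravel()])


def _unpack(w, n_hidden, n_in):
    i = 0
    w1 = w[i:i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = w[i:i + n_hidden]; i += n_hidden
    w2 = w[i:i + n_hidden].reshape(1, n_hidden); i += n_hidden
    b2 = w[i:i + 1]
    return w1, b1, w2, b2


def _loss_grad(w, Z, t, n_hidden):
    """Mean squared error and its analytic gradient (backprop)."""
    n_in = Z.shape[1]
    w1, b1, w2, b2 = _unpack(w, n_hidden, n_in)
    A1 = Z @ w1.T + b1
    H = np.tanh(A1)
    A2 = (H @ w2.T + b2).ravel()
    y = (np.tanh(A2) + 1.0) / 2.0
    e = y - t
    n = len(t)
    loss = float(np.mean(e ** 2))
    # dy/dA2 = 0.5 * (1 - tanh(A2)^2)
    dA2 = (2.0 / n) * e * 0.5 * (1.0 - np.tanh(A2) ** 2)
    gw2 = dA2 @ H
    gb2 = np.array([dA2.sum()])
    dH = np.outer(dA2, w2.ravel())
    dA1 = dH * (1.0 - H ** 2)
    gw1 = dA1.T @ Z
    gb1 = dA1.sum(axis=0)
    return loss, _pack(gw1, gb1, gw2.reshape(1, -1), gb2)


def _scg_minimize(fun_grad, w0, max_iterations, sigma0, lambda0, callback=None):
    """Moller's scaled conjugate gradient on a flat weight vector.

    ``fun_grad(w) -> (loss, grad)``.  ``callback(k, w)`` may return True to
    stop (early stopping hook)."""
    w = w0.copy()
    N = len(w)
    f, g = fun_grad(w)
    r = -g
    p = r.copy()
    lam, lam_bar = lambda0, 0.0
    success = True
    delta = 1.0
    for k in range(1, max_iterations + 1):
        p2 = float(p @ p)
        if p2 == 0.0:
            break
        if success:
            sigma = sigma0 / np.sqrt(p2)
            _, g_eps = fun_grad(w + sigma * p)
            s = (g_eps - g) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p2
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun_grad(w + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / mu ** 2
        if comparison >= 0:  # successful step
            w = w + alpha * p
            f, g = f_new, g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % N == 0:  # restart along steepest descent
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam *= 0.25
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p2
        if callback is not None and callback(k, w):
            break
        if float(r @ r) < 1e-18:
            break
    return w, k


def scg_train(X: np.ndarray, labels, config: TrainConfig = TrainConfig()):
    """Train the 4-2-1 classifier with SCG and early stopping.

    Parameters
    ----------
    X : (n, 4) array of feature rows (raw units).
    labels : length-n sequence of "successful"/"unsuccessful" strings, or
        binary targets (1 = unsuccessful).
    config : TrainConfig

    Returns
    -------
    (MlpModel, TrainingTrace)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    t = np.array([1.0 if (l == UNSUCCESSFUL or l == 1) else 0.0 for l in labels])
    if len(t) != len(X):
        raise ValueError("labels length mismatch")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(X))
    n_train = max(1, int(round(config.train_fraction * len(X))))
    if n_train == len(X):
        n_train = len(X) - 1 if len(X) > 1 else len(X)
    tr, va = order[:n_train], order[n_train:]
    if len(va) == 0:
        va = tr
    if len(np.unique(t[tr])) < 2 or min((t[tr] == 0).sum(), (t[tr] == 1).sum()) < 2:
        raise InvalidDatasetError("training split needs >= 2 examples of each class")

    mean = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    Ztr, ttr = Z[tr], t[tr]
    Zva, tva = Z[va], t[va]

    n_in = X.shape[1]
    n_w = config.n_hidden * n_in + config.n_hidden + config.n_hidden + 1
    w0 = rng.uniform(-config.init_scale, config.init_scale, size=n_w)

    trace = TrainingTrace([], [], [], 0, False)
    best = {"w": w0.copy(), "val": np.inf, "since": 0}

    def fun_grad(w):
        return _loss_grad(w, Ztr, ttr, config.n_hidden)

    def callback(k, w):
        loss_tr, _ = _loss_grad(w, Ztr, ttr, config.n_hidden)
        loss_va, _ = _loss_grad(w, Zva, tva, config.n_hidden)
        trace.train_mse.append(loss_tr)
        trace.val_mse.append(loss_va)
        if loss_va < best["val"]:
            best["val"] = loss_va
            best["w"] = w.copy()
            best["since"] = 0
        else:
            best["since"] += 1
        trace.best_val_mse.append(best["val"])
        if best["since"] >= config.patience:
            trace.stopped_early = True
            return True
        return False

    _, n_iter = _scg_minimize(fun_grad, w0, config.max_iterations,
                              config.sigma0, config.lambda0, callback)
    trace.n_iterations = n_iter
    w1, b1, w2, b2 = _unpack(best["w"], config.n_hidden, n_in)
    model = MlpModel(w1=w1, b1=b1, w2=w2, b2=b2, x_mean=mean, x_sd=sd,
                     meta={"seed": config.seed, "n_hidden": config.n_hidden,
                           "n_train": int(n_train), "n_val": int(len(va)),
                           "best_val_mse": best["val"]})
    return model, trace


def predict(model: MlpModel, fv) -> float:
    """Score in [0, 1] for one feature vector (higher = more likely failed)."""
    x = fv.as_array() if hasattr(fv, "as_array") else np.asarray(fv, dtype=float)
    return float(model.forward(x.reshape(1, -1))[0])


def classify(model: MlpModel, fv, threshold: float = 0.5) -> str:
    """"unsuccessful" iff the score is strictly greater than the threshold."""
    return UNSUCCESSFUL if predict(model, fv) > threshold else SUCCESSFUL
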