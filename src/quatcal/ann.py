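"""One-hidden-layer feed-forward networks trained by Levenberg-Marquardt.

Each analyte gets its own network with a single output neuron.  The hidden
transfer function is linear (purelin), hyperbolic tangent sigmoid (tansig)
or logistic (logsig); the output is always linear.  Inputs and targets are
min-max scaled to [-1, 1] from the training data.  Training follows the
damped Gauss-Newton scheme: the update is

    Δw = −(JᵀJ + μI)⁻¹ Jᵀe

with the damping μ multiplied by ``mu_dec`` after a successful step and by
``mu_inc`` after a rejected one.  Validation-based early stopping returns
the weights of the epoch with the lowest validation RMSE.

When the parameter count exceeds the sample count the update is computed
through the push-through identity Δw = −Jᵀ(JJᵀ + μI)⁻¹e, which solves an
n×n system instead of a p×p one; the two forms are algebraically equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ANNConfig", "ANNModel", "forward", "train_lm", "scan_hidden",
           "ANN_HIDDEN", "default_ann_config", "TRANSFER_PAIRS"]

#: Per-analyte default hidden-layer sizes.
ANN_HIDDEN = {"CAF": 10, "COD": 8, "PAR": 3, "PAP": 30}

TRANSFER_PAIRS = ("purelin-purelin", "tansig-purelin", "logsig-purelin")

_MU_MAX = 1e10
_MU_MIN = 1e-20


@dataclass(frozen=True)
class ANNConfig:
    hidden_neurons: int = 10
    transfer_pair: str = "purelin-purelin"
    mu: float = 0.001
    mu_dec: float = 0.001
    mu_inc: float = 100.0
    max_epochs: int = 300
    max_val_fail: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise ValueError("invalid-config: hidden_neurons must be >= 1")
        if not 0.0 < self.mu_dec < 1.0 < self.mu_inc:
            raise ValueError("invalid-config: need 0 < mu_dec < 1 < mu_inc")
        if self.transfer_pair not in TRANSFER_PAIRS:
            raise ValueError(f"invalid-config: unknown transfer pair {self.transfer_pair!r}")


def default_ann_config(analyte: str, seed: int = 0, **overrides) -> ANNConfig:
    kw = dict(hidden_neurons=ANN_HIDDEN[analyte], seed=seed)
    kw.update(overrides)
    return ANNConfig(**kw)


def _hidden_fns(pair: str):
    name = pair.split("-")[0]
    if name == "purelin":
        return (lambda z: z), (lambda z, a: np.ones_like(z))
    if name == "tansig":
        return np.tanh, (lambda z, a: 1.0 - a ** 2)
    # logsig
    return (lambda z: 1.0 / (1.0 + np.exp(-z))), (lambda z, a: a * (1.0 - a))


@dataclass(frozen=True)
class ANNModel:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    transfer_pair: str
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    best_epoch: int = 0
    history: dict = field(default_factory=dict, repr=False)
    config: ANNConfig | None = None


def _scale_x(model_or_stats, X):
    x_min, x_max = model_or_stats
    rng = np.where(x_max > x_min, x_max - x_min, 1.0)
    return 2.0 * (X - x_min) / rng - 1.0


def _scale_y(y, y_min, y_max):
    rng = (y_max - y_min) if y_max > y_min else 1.0
    return 2.0 * (y - y_min) / rng - 1.0


def _unscale_y(ys, y_min, y_max):
    rng = (y_max - y_min) if y_max > y_min else 1.0
    return (ys + 1.0) * rng / 2.0 + y_min


def _forward_scaled(W1, b1, W2, b2, Xs, f1):
    Z = Xs @ W1.T + b1
    A = f1(Z)
    return Z, A, A @ W2 + b2


def forward(model: ANNModel, X: np.ndarray) -> np.ndarray:
    """Network predictions in concentration units (µg/mL)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W1.shape[1]:
        raise ValueError("invalid-input: input width does not match the network")
    f1, _ = _hidden_fns(model.transfer_pair)
    Xs = _scale_x((model.x_min, model.x_max), X)
    _, _, ys = _forward_scaled(model.W1, model.b1, model.W2, model.b2, Xs, f1)
    return _unscale_y(ys, model.y_min, model.y_max)


def _jacobian(W1, b1, W2, b2, Xs, f1, df1):
    """Residual Jacobian w.r.t. [W1, b1, W2, b2], one row per sample."""
    Z, A, ys = _forward_scaled(W1, b1, W2, b2, Xs, f1)
    D = df1(Z, A) * W2[None, :]                    # n x h
    J_W1 = (D[:, :, None] * Xs[:, None, :]).reshape(len(Xs), -1)
    J = np.hstack([J_W1, D, A, np.ones((len(Xs), 1))])
    return J, ys


def _lm_step(J, e, mu):
    n, p = J.shape
    if p <= n:
        H = J.T @ J
        H[np.diag_indices_from(H)] += mu
        return -np.linalg.solve(H, J.T @ e)
    G = J @ J.T
    G[np.diag_indices_from(G)] += mu
    return -(J.T @ np.linalg.solve(G, e))


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2, [b2]])


def _unpack(w, h, p):
    W1 = w[: h * p].reshape(h, p)
    b1 = w[h * p: h * p + h]
    W2 = w[h * p + h: h * p + 2 * h]
    b2 = float(w[-1])
    return W1, b1, W2, b2


def train_lm(X_train, y_train, X_val, y_val, config: ANNConfig) -> ANNModel:
    """Levenberg-Marquardt training with validation-based early stopping.

    Training stops at ``max_epochs``, when μ can no longer be increased,
    or after ``max_val_fail`` consecutive epochs whose validation RMSE
    exceeds the best seen so far.  The returned weights are those of the
    best-validation epoch.
    """
    X_train = np.atleast_2d(np.asarray(X_train, float))
    y_train = np.asarray(y_train, float).ravel()
    X_val = np.atleast_2d(np.asarray(X_val, float))
    y_val = np.asarray(y_val, float).ravel()
    if X_train.size == 0 or X_val.size == 0:
        raise ValueError("invalid-input: train and validation sets must be non-empty")
    if X_train.shape[1] != X_val.shape[1]:
        raise ValueError("invalid-input: train/validation widths differ")

    p = X_train.shape[1]
    h = config.hidden_neurons
    x_min, x_max = X_train.min(axis=0), X_train.max(axis=0)
    y_min, y_max = float(y_train.min()), float(y_train.max())
    Xs = _scale_x((x_min, x_max), X_train)
    ys_t = _scale_y(y_train, y_min, y_max)
    Xvs = _scale_x((x_min, x_max), X_val)
    f1, df1 = _hidden_fns(config.transfer_pair)

    rng = np.random.default_rng(config.seed)
    w = rng.uniform(-0.5, 0.5, size=h * p + 2 * h + 1)

    def val_rmse(wvec):
        W1, b1, W2, b2 = _unpack(wvec, h, p)
        _, _, yv = _forward_scaled(W1, b1, W2, b2, Xvs, f1)
        return float(np.sqrt(np.mean((_unscale_y(yv, y_min, y_max) - y_val) ** 2)))

    def train_rmse_from_sse(sse):
        # residuals live in scaled space; report in concentration units
        scale = ((y_max - y_min) if y_max > y_min else 1.0) / 2.0
        return float(np.sqrt(sse / len(y_train)) * scale)

    mu = config.mu
    W1, b1, W2, b2 = _unpack(w, h, p)
    J, yhat = _jacobian(W1, b1, W2, b2, Xs, f1, df1)
    e = yhat - ys_t
    sse = float(e @ e)
    history = {"train_rmse": [], "val_rmse": [], "mu": []}
    best_w, best_val, best_epoch = w.copy(), val_rmse(w), 0
    val_fails = 0

    for epoch in range(1, config.max_epochs + 1):
        accepted = False
        while mu <= _MU_MAX:
            step = _lm_step(J, e, mu)
            w_try = w + step
            W1t, b1t, W2t, b2t = _unpack(w_try, h, p)
            _, _, yhat_try = _forward_scaled(W1t, b1t, W2t, b2t, Xs, f1)
            e_try = yhat_try - ys_t
            sse_try = float(e_try @ e_try)
            if np.isfinite(sse_try) and sse_try < sse:
                w, sse = w_try, sse_try
                mu = max(mu * config.mu_dec, _MU_MIN)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            break                           # μ exhausted: converged/stuck
        W1, b1, W2, b2 = _unpack(w, h, p)
        J, yhat = _jacobian(W1, b1, W2, b2, Xs, f1, df1)
        e = yhat - ys_t
        v = val_rmse(w)
        history["train_rmse"].append(train_rmse_from_sse(sse))
        history["val_rmse"].append(v)
        history["mu"].append(mu)
        if v < best_val:
            best_val, best_w, best_epoch = v, w.copy(), epoch
            val_fails = 0
        else:
            val_fails += 1
            if val_fails >= config.max_val_fail:
                break
        if sse < 1e-24:
            break

    W1, b1, W2, b2 = _unpack(best_w, h, p)
    return ANNModel(W1, b1, W2, b2, config.transfer_pair,
                    x_min, x_max, y_min, y_max,
                    best_epoch=best_epoch, history=history, config=config)


def scan_hidden(X_train, y_train, X_val, y_val, sizes, config: ANNConfig):
    """Train once per hidden-layer size; choose the lowest validation RMSE.

    Returns (table, chosen_size, best_model); the table has one row
    (size, val_rmse, best_epoch) per requested size, in the requested
    order.  Ties within 1e-12 go to the smaller network.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("invalid-input: no hidden sizes requested")
    rows = []
    models = {}
    for s in sizes:
        cfg = ANNConfig(hidden_neurons=int(s), transfer_pair=config.transfer_pair,
                        mu=config.mu, mu_dec=config.mu_dec, mu_inc=config.mu_inc,
                        max_epochs=config.max_epochs,
                        max_val_fail=config.max_val_fail, seed=config.seed)
        m = train_lm(X_train, y_train, X_val, y_val, cfg)
        pred = forward(m, X_val).ravel()
        v = float(np.sqrt(np.mean((pred - np.asarray(y_val, float).ravel()) ** 2)))
        rows.append({"hidden_neurons": int(s), "val_rmse": v, "best_epoch": m.best_epoch})
        models[int(s)] = m
    min_rmse = min(r["val_rmse"] for r in rows)
    chosen = min(r["hidden_neurons"] for r in rows if r["val_rmse"] <= min_rmse + 1e-12)
    return rows, chosen, models[chosen]
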