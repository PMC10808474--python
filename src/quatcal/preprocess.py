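"""Column preprocessing with stored calibration state, plus exploratory PCA.

Three modes are supported: ``raw`` (identity), ``mean_center`` (subtract
calibration column means) and ``autoscale`` (additionally divide by the
calibration column standard deviations, n-1 denominator).  The response is
transformed consistently with the spectra and predictions are
back-transformed.  Statistics are always those of the calibration data;
new samples are never used to refit them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PreprocModel", "fit_preproc", "apply_preproc", "inverse_y",
           "pca_decompose", "MODES"]

MODES = ("raw", "mean_center", "autoscale")


@dataclass(frozen=True)
class PreprocModel:
    mode: str
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    n_columns: int = 0


def fit_preproc(X: np.ndarray, y: np.ndarray | None, mode: str) -> PreprocModel:
    """Learn preprocessing statistics from calibration data only."""
    if mode not in MODES:
        raise ValueError(f"invalid-input: unknown preprocessing mode {mode!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("invalid-input: X must be 2-D with at least 2 samples")
    p = X.shape[1]
    if mode == "raw":
        return PreprocModel("raw", n_columns=p)
    x_mean = X.mean(axis=0)
    y_mean = float(np.mean(y)) if y is not None else 0.0
    if mode == "mean_center":
        return PreprocModel("mean_center", x_mean=x_mean, y_mean=y_mean, n_columns=p)
    x_sd = X.std(axis=0, ddof=1)
    if np.any(x_sd <= 0):
        raise ValueError("degenerate-column: zero-variance column under autoscale")
    y_sd = float(np.std(y, ddof=1)) if y is not None else 1.0
    if y is not None and y_sd <= 0:
        raise ValueError("degenerate-response: constant response under autoscale")
    return PreprocModel("autoscale", x_mean=x_mean, x_sd=x_sd,
                        y_mean=y_mean, y_sd=y_sd, n_columns=p)


def apply_preproc(model: PreprocModel, X: np.ndarray,
                  y: np.ndarray | None = None):
    """Transform new data with stored calibration statistics."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or (model.n_columns and X.shape[1] != model.n_columns):
        raise ValueError("invalid-input: column count does not match fitted state")
    if model.mode == "raw":
        Xt = X.copy()
    elif model.mode == "mean_center":
        Xt = X - model.x_mean
    else:
        Xt = (X - model.x_mean) / model.x_sd
    if y is None:
        return Xt
    y = np.asarray(y, dtype=float)
    if model.mode == "raw":
        yt = y.copy()
    elif model.mode == "mean_center":
        yt = y - model.y_mean
    else:
        yt = (y - model.y_mean) / model.y_sd
    return Xt, yt


def inverse_y(model: PreprocModel, y_proc: np.ndarray) -> np.ndarray:
    """Back-transform predictions to concentration units."""
    y_proc = np.asarray(y_proc, dtype=float)
    if model.mode == "raw":
        return y_proc.copy()
    if model.mode == "mean_center":
        return y_proc + model.y_mean
    return y_proc * model.y_sd + model.y_mean


def pca_decompose(X: np.ndarray, n_components: int):
    """PCA of the column-centered matrix via SVD.

    Returns (scores, loadings, explained_variance_fractions) with loadings
    of shape (p, n_components), orthonormal columns, and the sign fixed so
    each loading's largest-magnitude element is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError("invalid-input: n_components out of range")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s ** 2))
    k = n_components
    loadings = Vt[:k].T
    # deterministic sign: largest |loading| element positive per component
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            U[:, j] = -U[:, j]
    scores = U[:, :k] * s[:k]
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, loadings, evr
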