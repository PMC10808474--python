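"""PLS-1 regression by NIPALS with cross-validated latent-variable selection.

One model is fitted per analyte (single response).  The NIPALS loop
deflates both X and y; the regression vector for ``a`` components is
``b_a = W_a (P_aᵀ W_a)⁻¹ q_a`` where W holds the unit-norm weight vectors,
P the X-loadings and q the response loadings.  Regression vectors are kept
for every intermediate component count so cross-validation can score all
candidate LV counts from a single deflation pass per fold.

RMSEC, RMSECV and RMSEP all use the same plain 1/n root-mean-square
formula; cross-validation pools held-out residuals over folds (and over
repetitions for repeated k-fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocModel, apply_preproc, fit_preproc, inverse_y

__all__ = ["PLS1Model", "CVResult", "nipals_pls1", "fit_pls1", "predict",
           "rmse", "cross_validate", "select_lv", "loo", "kfold"]

_DEFLATION_TOL = 1e-12
_RESIDUAL_TOL = 1e-14


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_lv: int):
    """NIPALS PLS-1 on already-preprocessed data.

    Returns (W, P, q, B) where B[:, a-1] is the regression vector using the
    first ``a`` components, plus the number of components actually
    extracted (deflation stops early once the X residual is numerically
    exhausted).
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    extracted = 0
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _DEFLATION_TOL:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < _RESIDUAL_TOL:
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        extracted += 1
        if float(np.sum(X * X)) < _RESIDUAL_TOL:
            extracted = a + 1
            break
    B = np.zeros((p, n_lv))
    for a in range(1, extracted + 1):
        Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
        # PᵀW is upper triangular for PLS-1; small dense solve is fine
        B[:, a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    for a in range(extracted, n_lv):
        B[:, a] = B[:, extracted - 1] if extracted else 0.0
    return W, P, q, B, extracted


@dataclass(frozen=True)
class PLS1Model:
    analyte: str
    n_lv: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    b: np.ndarray
    preproc: PreprocModel
    n_lv_effective: int = 0
    fitted_values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int,
             preproc_mode: str = "mean_center", analyte: str = "") -> PLS1Model:
    """Fit a single-response PLS model with ``n_lv`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError("invalid-lv: n_lv must be in 1..min(samples-1, wavelengths)")
    if np.ptp(y) == 0:
        raise ValueError("degenerate-response: constant response")
    pre = fit_preproc(X, y, preproc_mode)
    Xt, yt = apply_preproc(pre, X, y)
    W, P, q, B, extracted = nipals_pls1(Xt, yt, n_lv)
    b = B[:, n_lv - 1]
    fitted = inverse_y(pre, Xt @ b)
    fitted.setflags(write=False)
    return PLS1Model(analyte, n_lv, W, P, q, b, pre, extracted, fitted)


def predict(model: PLS1Model, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations for new spectra (µg/mL)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xt = apply_preproc(model.preproc, X_new)
    return inverse_y(model.preproc, Xt @ model.b)


def rmse(y_true, y_pred) -> float:
    """Root mean squared error, plain 1/n denominator.

    The same formula serves RMSEC (calibration), RMSEP (prediction) and
    RMSECV (pooled cross-validation residuals).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("invalid-input: need equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def loo():
    """Leave-one-out cross-validation scheme."""
    return ("loo",)


def kfold(k: int, n_iter: int = 1, seed: int = 0):
    """Repeated random k-fold scheme."""
    return ("kfold", int(k), int(n_iter), int(seed))


def _partitions(scheme, n: int):
    """Yield lists of folds (index arrays) for each repetition."""
    if scheme[0] == "loo":
        yield [np.array([i]) for i in range(n)]
        return
    _, k, n_iter, seed = scheme
    if k > n:
        raise ValueError("invalid-scheme: more folds than samples")
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        perm = rng.permutation(n)
        yield [np.sort(perm[i::k]) for i in range(k)]


@dataclass(frozen=True)
class CVResult:
    rmsecv_by_lv: np.ndarray
    chosen_lv: int
    scheme: tuple
    lv_max: int


def cross_validate(X: np.ndarray, y: np.ndarray, scheme=("loo",),
                   lv_max: int = 10, preproc_mode: str = "mean_center") -> CVResult:
    """RMSECV per candidate LV count 1..lv_max.

    Preprocessing and the PLS fit are redone on each training fold alone;
    held-out residuals are pooled over folds and repetitions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    sq = np.zeros(lv_max)
    count = 0
    for folds in _partitions(scheme, n):
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            if len(train) < 2:
                raise ValueError("invalid-scheme: training fold with < 2 samples")
            lv_cap = min(lv_max, len(train) - 1, X.shape[1])
            if lv_cap < lv_max:
                raise ValueError("invalid-scheme: lv_max infeasible for smallest fold")
            pre = fit_preproc(X[train], y[train], preproc_mode)
            Xt, yt = apply_preproc(pre, X[train], y[train])
            _, _, _, B, _ = nipals_pls1(Xt, yt, lv_max)
            Xh = apply_preproc(pre, X[fold])
            preds = inverse_y(pre, Xh @ B)            # len(fold) x lv_max
            sq += np.sum((preds - y[fold, None]) ** 2, axis=0)
            count += len(fold)
    rmsecv = np.sqrt(sq / count)
    return CVResult(rmsecv, _argmin_lv(rmsecv), scheme, lv_max)


def _argmin_lv(rmsecv: np.ndarray, tol: float = 1e-12) -> int:
    best = float(np.min(rmsecv))
    for a, v in enumerate(rmsecv, start=1):
        if v <= best + tol:
            return a
    return int(np.argmin(rmsecv)) + 1


def select_lv(cv: CVResult) -> int:
    """LV count minimizing RMSECV; ties (within 1e-12) go to fewer LVs."""
    if cv.rmsecv_by_lv.size == 0:
        raise ValueError("invalid-input: empty RMSECV curve")
    return _argmin_lv(cv.rmsecv_by_lv)
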