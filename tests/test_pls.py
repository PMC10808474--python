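"""PLS-1: NIPALS correctness against independent oracles, CV, LV choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quatcal import design as dg
from quatcal import pls
from quatcal import spectra as sp


def textbook_pls1(X, y, n_lv):
    """Independent PLS-1 oracle: direct deflation, scores kept explicitly.

    Written from the classic algorithm statement (weights from the
    covariance vector, scores, loadings, rank-one deflation), with the
    regression vector assembled from the stored score/loading matrices.
    """
    X = X.copy().astype(float)
    y = y.copy().astype(float)
    p = X.shape[1]
    W = np.zeros((p, n_lv))
    T = np.zeros((X.shape[0], n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = X.T @ y
        w = w / np.sqrt(w @ w)
        t = X @ w
        pa = (X.T @ t) / (t @ t)
        qa = (y @ t) / (t @ t)
        X = X - np.outer(t, pa)
        y = y - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
    return W @ np.linalg.inv(P.T @ W) @ q


@pytest.fixture(scope="module")
def random_instances():
    rng = np.random.default_rng(11)
    out = []
    for _ in range(8):
        X = rng.normal(size=(10, 12))
        y = rng.normal(size=10)
        out.append((X - X.mean(0), y - y.mean()))
    return out


@pytest.mark.parametrize("n_lv", [1, 2, 4, 6])
def test_nipals_matches_textbook_oracle(random_instances, n_lv):
    for X, y in random_instances:
        _, _, _, B, _ = pls.nipals_pls1(X, y, n_lv)
        b_oracle = textbook_pls1(X, y, n_lv)
        np.testing.assert_allclose(B[:, n_lv - 1], b_oracle, atol=1e-8)


def test_nipals_matches_sklearn(random_instances):
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    for X, y in random_instances[:4]:
        for n_lv in (2, 5):
            model = sklearn.PLSRegression(n_components=n_lv, scale=False)
            model.fit(X, y)
            _, _, _, B, _ = pls.nipals_pls1(X, y, n_lv)
            np.testing.assert_allclose(
                X @ B[:, n_lv - 1], model.predict(X).ravel(), atol=1e-8)


def test_rank_one_exact_fit():
    # one informative column, the rest orthogonal to it: a single latent
    # variable must reproduce the response exactly
    rng = np.random.default_rng(2)
    Q, _ = np.linalg.qr(rng.normal(size=(15, 6)))
    X = Q * rng.uniform(1, 3, size=6)
    y = 3.0 * X[:, 2]
    model = pls.fit_pls1(X, y, 1, "raw")
    assert pls.rmse(y, model.fitted_values) < 1e-10


def test_noiseless_design_exact_at_four_lv(cal_window, default_design, library):
    """Rank-4 noiseless mixtures are fitted exactly with 4 LVs; predictions
    agree with the known-pure-spectra least-squares oracle."""
    X = cal_window.absorbance
    curves = np.vstack([
        np.interp(cal_window.wavelengths, s.grid.points, s.curve)
        for s in library
    ])
    for j, analyte in enumerate(dg.ANALYTES):
        y = default_design.concentrations[:, j]
        model = pls.fit_pls1(X, y, 4, "mean_center", analyte)
        assert pls.rmse(y, model.fitted_values) < 1e-6
        # oracle: solve Beer-Lambert directly from the pure curves
        conc_oracle = X @ np.linalg.pinv(curves)
        np.testing.assert_allclose(model.fitted_values, conc_oracle[:, j],
                                   atol=1e-6)


def test_max_lv_matches_pseudoinverse_oracle():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(8, 12))
    y = rng.normal(size=8)
    model = pls.fit_pls1(X, y, 7, "mean_center")
    Xc = X - X.mean(0)
    b_mn = np.linalg.pinv(Xc) @ (y - y.mean())
    np.testing.assert_allclose(model.fitted_values, Xc @ b_mn + y.mean(),
                               atol=1e-6)


def test_predict_consistency_and_rowwise(cal_window, default_design):
    X = cal_window.absorbance
    y = default_design.concentrations[:, 0]
    model = pls.fit_pls1(X, y, 4, "mean_center")
    np.testing.assert_allclose(pls.predict(model, X), model.fitted_values,
                               atol=1e-12)
    doubled = np.vstack([X[3], X[3]])
    pred = pls.predict(model, doubled)
    assert pred[0] == pred[1]


def test_centre_point_recovered_noiselessly(cal_window, default_design,
                                            noiseless_validation):
    val = sp.restrict(noiseless_validation, (210.0, 300.0))
    centre = val.absorbance[1:2]       # mixture 27, the all-centre run
    expected = [3.6, 8.0, 12.0, 4.5]
    for j in range(4):
        y = default_design.concentrations[:, j]
        model = pls.fit_pls1(cal_window.absorbance, y, 4, "mean_center")
        assert pls.predict(model, centre)[0] == pytest.approx(expected[j], abs=1e-4)


def test_rmse_closed_forms():
    assert pls.rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert pls.rmse([0, 0], [0.5, 0.5]) == pytest.approx(0.5)
    assert pls.rmse([0.3, -0.4], [0.0, 0.0]) == pytest.approx(0.3536, abs=1e-4)
    with pytest.raises(ValueError, match="invalid-input"):
        pls.rmse([], [])


@settings(max_examples=30, derandomize=True)
@given(d=st.floats(-5, 5))
def test_rmse_constant_offset(d):
    y = np.arange(6.0)
    assert pls.rmse(y, y + d) == pytest.approx(abs(d), abs=1e-12)


def test_kfold_with_k_equals_n_matches_loo():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 8))
    y = rng.normal(size=10)
    r_loo = pls.cross_validate(X, y, pls.loo(), lv_max=4)
    r_kf = pls.cross_validate(X, y, pls.kfold(10, 1, seed=0), lv_max=4)
    np.testing.assert_allclose(r_loo.rmsecv_by_lv, r_kf.rmsecv_by_lv, atol=1e-12)


def test_loo_is_order_invariant():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(12, 9))
    y = rng.normal(size=12)
    perm = rng.permutation(12)
    a = pls.cross_validate(X, y, pls.loo(), lv_max=5)
    b = pls.cross_validate(X[perm], y[perm], pls.loo(), lv_max=5)
    np.testing.assert_allclose(a.rmsecv_by_lv, b.rmsecv_by_lv, atol=1e-10)


def test_repeated_kfold_is_deterministic():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 9))
    y = rng.normal(size=12)
    a = pls.cross_validate(X, y, pls.kfold(4, 3, seed=5), lv_max=4)
    b = pls.cross_validate(X, y, pls.kfold(4, 3, seed=5), lv_max=4)
    np.testing.assert_array_equal(a.rmsecv_by_lv, b.rmsecv_by_lv)


def test_select_lv_tie_break_and_monotone():
    cv = pls.CVResult(np.array([0.5, 0.2, 0.2, 0.3]), 2, ("loo",), 4)
    assert pls.select_lv(cv) == 2
    cv2 = pls.CVResult(np.array([0.5, 0.4, 0.3, 0.2]), 4, ("loo",), 4)
    assert pls.select_lv(cv2) == 4


def test_noiseless_data_selects_four_lv(cal_window, default_design):
    X = cal_window.absorbance
    y = default_design.concentrations[:, 1]          # COD
    cv = pls.cross_validate(X, y, pls.loo(), lv_max=6)
    assert cv.rmsecv_by_lv[3] < 1e-6
    assert cv.chosen_lv == 4


def test_zero_column_leaves_predictions_unchanged():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(10, 6))
    y = rng.normal(size=10)
    m1 = pls.fit_pls1(X, y, 3, "mean_center")
    X_aug = np.hstack([X, np.zeros((10, 1))])
    m2 = pls.fit_pls1(X_aug, y, 3, "mean_center")
    np.testing.assert_allclose(m1.fitted_values, m2.fitted_values, atol=1e-10)


def test_invalid_lv_and_constant_response():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(5, 4))
    with pytest.raises(ValueError, match="invalid-lv"):
        pls.fit_pls1(X, rng.normal(size=5), 5, "raw")
    with pytest.raises(ValueError, match="degenerate-response"):
        pls.fit_pls1(X, np.full(5, 2.0), 2, "raw")
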