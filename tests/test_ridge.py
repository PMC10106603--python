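import numpy as np
import pytest
from sklearn.linear_model import Ridge as SkRidge

from yieldcast.ridge import (LambdaSearch, RidgeTraitCV, RidgeTraitRegressor,
                             bic_of, effective_df, fit_ridge, select_lambda_cv)


def _standardize_pop(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


def brute_force_ridge(X, y, alpha):
    """Independent normal-equation solve on the standardized system."""
    Z = _standardize_pop(X)
    p = X.shape[1]
    beta = np.linalg.solve(Z.T @ Z + alpha * np.eye(p), Z.T @ (y - y.mean()))
    coef = beta / X.std(axis=0)
    intercept = y.mean() - coef @ X.mean(axis=0)
    return coef, intercept


def random_instance(seed, n_max=30, p_max=4):
    rng = np.random.default_rng(seed)
    p = rng.integers(1, p_max + 1)
    n = rng.integers(p + 2, n_max + 1)
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 20, size=p)
    y = rng.normal(size=n)
    return X, y


def test_lambda_zero_equals_ols():
    X, y = random_instance(1)
    m = fit_ridge(X, y, 0.0)
    ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)
    assert m.intercept_ == pytest.approx(ols[0], abs=1e-8)
    assert np.allclose(m.coef_, ols[1:], atol=1e-8)


def test_huge_lambda_shrinks_to_mean():
    X, y = random_instance(2)
    m = fit_ridge(X, y, 1e12)
    assert np.all(np.abs(m.coef_) < 1e-6)
    assert m.intercept_ == pytest.approx(y.mean(), abs=1e-4)


def test_three_point_worked_fit_and_predict():
    X = np.array([[1.0], [2.0], [3.0]])
    y = np.array([1.0, 2.0, 3.0])
    m = fit_ridge(X, y, 1.0)
    coef, intercept = brute_force_ridge(X, y, 1.0)
    assert m.coef_ == pytest.approx(coef, abs=1e-12)
    assert m.intercept_ == pytest.approx(intercept, abs=1e-12)
    assert m.predict([[2.0]])[0] == pytest.approx(intercept + 2.0 * coef[0], abs=1e-12)


@pytest.mark.parametrize("seed", range(100))
def test_closed_form_matches_brute_force(seed):
    X, y = random_instance(seed)
    alpha = float(np.random.default_rng(seed + 1000).uniform(0, 10))
    m = fit_ridge(X, y, alpha)
    coef, intercept = brute_force_ridge(X, y, alpha)
    assert np.max(np.abs(m.coef_ - coef)) < 1e-8
    assert abs(m.intercept_ - intercept) < 1e-8


def test_matches_sklearn_ridge_on_standardized_design():
    """sklearn minimizes the identical penalized objective on pre-standardized Z."""
    X, y = random_instance(5)
    alpha = 3.7
    Z = _standardize_pop(X)
    sk = SkRidge(alpha=alpha, fit_intercept=True).fit(Z, y)
    m = fit_ridge(X, y, alpha)
    beta_std = m.coef_ * X.std(axis=0)
    assert np.allclose(beta_std, sk.coef_, atol=1e-8)


def test_coef_norm_nonincreasing_in_lambda():
    X, y = random_instance(7)
    norms = []
    for alpha in [0.0, 0.1, 1.0, 10.0, 100.0]:
        m = fit_ridge(X, y, alpha)
        norms.append(np.linalg.norm(m.coef_ * X.std(axis=0)))
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def test_fitted_values_invariant_to_column_affine_rescale():
    X, y = random_instance(8)
    m1 = fit_ridge(X, y, 2.0)
    X2 = X * 3.5 + 100.0
    m2 = fit_ridge(X2, y, 2.0)
    assert np.allclose(m1.predict(X), m2.predict(X2), atol=1e-8)


def test_zero_variance_column_rejected():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValueError, match="zero-variance"):
        fit_ridge(X, np.arange(10.0), 1.0)


def test_too_few_observations_rejected():
    with pytest.raises(ValueError, match="n >= p"):
        fit_ridge(np.random.default_rng(0).normal(size=(3, 2)), np.zeros(3), 1.0)


def test_predict_column_mismatch():
    X, y = random_instance(3)
    m = fit_ridge(X, y, 1.0)
    with pytest.raises(ValueError, match="mismatch"):
        m.predict(np.zeros((2, X.shape[1] + 1)))


def test_serialization_roundtrip():
    X, y = random_instance(4)
    m = fit_ridge(X, y, 1.5)
    m.feature_names_in_ = np.array([f"t{i}" for i in range(X.shape[1])], dtype=object)
    back = RidgeTraitRegressor.from_dict(m.to_dict())
    assert np.allclose(back.predict(X), m.predict(X))
    assert back.to_dict() == m.to_dict()


# -- effective degrees of freedom -----------------------------------------

def test_edf_limits():
    X, _ = random_instance(11, p_max=3)
    X = np.random.default_rng(11).normal(size=(20, 3))
    assert effective_df(X, 0.0) == pytest.approx(3.0)
    assert effective_df(X, 1e14) < 1e-6


def test_edf_matches_dense_hat_trace():
    rng = np.random.default_rng(12)
    for seed in range(20):
        X = np.random.default_rng(seed).normal(size=(20, 2)) * [3.0, 0.5]
        alpha = float(rng.uniform(0.1, 50))
        Z = _standardize_pop(X)
        hat = Z @ np.linalg.inv(Z.T @ Z + alpha * np.eye(2)) @ Z.T
        assert abs(effective_df(X, alpha) - np.trace(hat)) < 1e-10


def test_edf_strictly_decreasing_in_lambda():
    X = np.random.default_rng(13).normal(size=(25, 4))
    vals = [effective_df(X, a) for a in [0.0, 0.5, 2.0, 10.0, 50.0]]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# -- BIC -------------------------------------------------------------------

def test_bic_hand_value():
    m = RidgeTraitRegressor(alpha=0.0)
    m.rss_, m.edf_, m.n_train_ = 10.0, 2.0, 10
    m.bic_ = 10 * np.log(10.0 / 10) + 3 * np.log(10)
    assert bic_of(m) == pytest.approx(3 * np.log(10), abs=1e-10)
    assert bic_of(m) == pytest.approx(6.9077, abs=1e-4)


def test_bic_monotone_in_edf():
    a, b = RidgeTraitRegressor(0.0), RidgeTraitRegressor(0.0)
    for m, edf in ((a, 2.0), (b, 3.0)):
        m.rss_, m.edf_, m.n_train_ = 5.0, edf, 20
        m.bic_ = 20 * np.log(5.0 / 20) + (edf + 1) * np.log(20)
    assert bic_of(a) < bic_of(b)


def test_bic_zero_rss_is_error():
    m = RidgeTraitRegressor(0.0)
    m.rss_, m.edf_, m.n_train_, m.bic_ = 0.0, 2.0, 10, None
    with pytest.raises(ValueError, match="zero"):
        bic_of(m)


def test_noise_predictor_raises_mean_bic():
    """Adding a pure-noise column to a strong-signal fit worsens BIC on average."""
    deltas = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(scale=0.3, size=40)
        noise = rng.normal(size=40)
        m1 = fit_ridge(x[:, None], y, 0.01)
        m2 = fit_ridge(np.column_stack([x, noise]), y, 0.01)
        deltas.append(bic_of(m2) - bic_of(m1))
    assert np.mean(deltas) > 0


# -- cross-validated penalty selection ------------------------------------

def test_cv_deterministic_given_seed():
    X, y = random_instance(21)
    X, y = np.repeat(X, 3, axis=0), np.repeat(y, 3)  # n >= k
    l1, s1 = select_lambda_cv(X, y, LambdaSearch(seed=42))
    l2, s2 = select_lambda_cv(X, y, LambdaSearch(seed=42))
    assert l1 == l2
    assert np.array_equal(s1.cv_mse, s2.cv_mse)


def test_cv_noiseless_linear_picks_smallest_lambda():
    X = np.linspace(0, 1, 50).reshape(-1, 1)
    y = 2.0 * X[:, 0]
    lam, filled = select_lambda_cv(X, y, LambdaSearch(seed=0))
    assert lam == filled.grid[-1]  # grid descends; last entry is smallest


def test_cv_pure_noise_prefers_largest_lambda():
    wins = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        lam, filled = select_lambda_cv(X, y, LambdaSearch(seed=seed))
        wins += lam == filled.grid[0]
    assert wins > 100


def test_cv_rejects_empty_grid_and_small_n():
    with pytest.raises(ValueError, match="empty"):
        LambdaSearch(grid=np.array([]))
    X, y = random_instance(22)
    with pytest.raises(ValueError):
        select_lambda_cv(X[:5], y[:5], LambdaSearch(k_folds=10))


def test_ridge_cv_estimator_fits_and_exposes_alpha():
    rng = np.random.default_rng(30)
    X = rng.normal(size=(60, 2))
    y = X @ [1.0, -0.5] + rng.normal(scale=0.2, size=60)
    est = RidgeTraitCV(LambdaSearch(seed=3)).fit(X, y)
    assert est.alpha_ > 0
    assert est.cv_mse_.shape == est.alphas_.shape
    assert est.bic_ is not None
    # sklearn-style params survive get_params/set_params
    assert "search" in est.get_params()
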