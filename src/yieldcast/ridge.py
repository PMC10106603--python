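"""Penalized linear regression engine for yield models.

Ridge regression with an unpenalized intercept, fitted in closed form on
standardized predictors:

    minimize  ||y - b0 - Z b||^2 + alpha * ||b||^2

where Z has columns centered to zero mean and scaled to unit standard
deviation (population 1/n convention, pinned for reproducibility).
Coefficients are reported back on the original trait scale. Model
complexity is measured by the effective degrees of freedom of the ridge
hat matrix, edf = sum_i d_i^2 / (d_i^2 + alpha) over the singular values
of Z, and models are compared by a Gaussian-likelihood BIC

    BIC = n * ln(RSS / n) + (edf + 1) * ln(n)

with +1 for the unpenalized intercept (reduces to the textbook BIC at
alpha = 0). The penalty is chosen per fit by 10-fold cross validation over
a data-adaptive log-spaced grid, taking the alpha with lowest held-out
mean squared error (ties broken toward more regularization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


def _standardize(X):
    """Center/scale columns; population (1/n) standard deviation."""
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    scales = X.std(axis=0)  # ddof=0
    if np.any(scales == 0):
        j = int(np.flatnonzero(scales == 0)[0])
        raise ValueError(f"zero-variance predictor column {j}")
    return (X - centers) / scales, centers, scales


def _validate_design(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (n plots x p traits)")
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least one predictor")
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("design contains missing or non-finite values")
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 observations, got n={n}, p={p}")
    return X, y


class RidgeTraitRegressor(RegressorMixin, BaseEstimator):
    """Closed-form ridge regression with edf-based BIC.

    Parameters
    ----------
    alpha : float, default 1.0
        L2 penalty on standardized coefficients; ``alpha=0`` reproduces
        ordinary least squares.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) ndarray       -- slopes on the original trait scale
    intercept_ : float
    centers_, scales_ : (p,)   -- standardization constants
    n_train_ : int
    rss_ : float               -- residual sum of squares on training data
    edf_ : float               -- trace of the ridge hat matrix
    bic_ : float or None       -- None when RSS is exactly 0 (degenerate fit)
    feature_names_in_ : optional column names seen in fit
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X, y):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy()
        X, y = _validate_design(X, y)
        n, p = X.shape
        Z, centers, scales = _standardize(X)
        y_mean = y.mean()
        y_c = y - y_mean

        U, d, Vt = np.linalg.svd(Z, full_matrices=False)
        # shrinkage factors d/(d^2+alpha); 0/0 at alpha=0 with rank-deficient Z -> 0
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(d > 0, d / (d**2 + self.alpha), 0.0)
        beta_std = Vt.T @ (f * (U.T @ y_c))

        self.coef_ = beta_std / scales
        self.intercept_ = y_mean - float(self.coef_ @ centers)
        self.centers_, self.scales_ = centers, scales
        self.n_train_ = n
        resid = y_c - Z @ beta_std
        self.rss_ = float(resid @ resid)
        self.edf_ = float(np.sum(d**2 / (d**2 + self.alpha))) if self.alpha > 0 \
            else float(np.sum(d > 1e-12))
        self.bic_ = None if self.rss_ <= 0 else (
            n * np.log(self.rss_ / n) + (self.edf_ + 1.0) * np.log(n)
        )
        return self

    def predict(self, X):
        if hasattr(X, "columns"):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"predictor count mismatch: got {X.shape}, model has p={self.coef_.shape[0]}"
            )
        return self.intercept_ + X @ self.coef_

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        names = list(getattr(self, "feature_names_in_", range(len(self.coef_))))
        return {
            "combo": [str(c) for c in names],
            "coefficients": [float(c) for c in self.coef_],
            "intercept": float(self.intercept_),
            "lambda": float(self.alpha),
            "centers": [float(c) for c in self.centers_],
            "scales": [float(s) for s in self.scales_],
            "n_train": int(self.n_train_),
            "rss": float(self.rss_),
            "edf": float(self.edf_),
            "bic": None if self.bic_ is None else float(self.bic_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeTraitRegressor":
        m = cls(alpha=d["lambda"])
        m.feature_names_in_ = np.asarray(d["combo"], dtype=object)
        m.coef_ = np.asarray(d["coefficients"], dtype=float)
        m.intercept_ = float(d["intercept"])
        m.centers_ = np.asarray(d["centers"], dtype=float)
        m.scales_ = np.asarray(d["scales"], dtype=float)
        m.n_train_ = int(d["n_train"])
        m.rss_, m.edf_, m.bic_ = d["rss"], d["edf"], d["bic"]
        return m


@dataclass
class LambdaSearch:
    """Cross-validation settings for the ridge penalty.

    ``grid=None`` builds a data-adaptive grid at fit time: 100 log-spaced
    values descending over [1e-4 * lam_max, lam_max] with
    lam_max = max|Z^T y_centered| / n. ``cv_mse`` is filled by
    :func:`select_lambda_cv`.
    """

    grid: np.ndarray | None = None
    n_grid: int = 100
    k_folds: int = 10
    seed: int = 0
    cv_mse: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.size == 0:
                raise ValueError("lambda grid is empty")
            if np.any(g <= 0):
                raise ValueError("lambda grid must be strictly positive")
            if np.any(np.diff(g) >= 0):
                raise ValueError("lambda grid must be strictly descending")
            self.grid = g
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def resolve_grid(self, Z, y_c) -> np.ndarray:
        if self.grid is not None:
            return self.grid
        lam_max = float(np.max(np.abs(Z.T @ y_c))) / len(y_c)
        if lam_max <= 0:  # y exactly constant; any grid works
            lam_max = 1.0
        return np.geomspace(lam_max, 1e-4 * lam_max, self.n_grid)


def select_lambda_cv(X, y, search: LambdaSearch | None = None):
    """Pick the ridge penalty by k-fold cross validation.

    Folds come from a seeded permutation with sizes differing by at most
    one. For every grid value the mean over folds of the held-out MSE is
    recorded; the winner is the alpha with the lowest mean MSE, ties going
    to the larger alpha (the grid is descending, so the first minimum).

    Returns ``(lambda_star, search)`` with ``search.cv_mse`` filled.
    """
    search = search if search is not None else LambdaSearch()
    if hasattr(X, "columns"):
        X = X.to_numpy()
    X, y = _validate_design(X, y)
    n = len(y)
    k = search.k_folds
    if n < k:
        raise ValueError(f"need n >= k_folds, got n={n}, k={k}")
    Z_all, _, _ = _standardize(X)
    grid = search.resolve_grid(Z_all, y - y.mean())

    rng = np.random.default_rng(search.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a CV fold has fewer than 2 observations")

    fold_mse = np.empty((k, len(grid)))
    for fi, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        Ztr, centers, scales = _standardize(Xtr)
        y_mean = ytr.mean()
        U, d, Vt = np.linalg.svd(Ztr, full_matrices=False)
        w = U.T @ (ytr - y_mean)
        # beta for every grid alpha at once: (p, m)
        f = d[:, None] / (d[:, None] ** 2 + grid[None, :])
        beta = Vt.T @ (f * w[:, None])
        Zte = (X[test_idx] - centers) / scales
        pred = y_mean + Zte @ beta  # (n_test, m)
        fold_mse[fi] = np.mean((y[test_idx][:, None] - pred) ** 2, axis=0)

    cv_mse = fold_mse.mean(axis=0)
    lambda_star = float(grid[int(np.argmin(cv_mse))])
    return lambda_star, replace(search, grid=grid, cv_mse=cv_mse)


class RidgeTraitCV(RidgeTraitRegressor):
    """Ridge with the penalty selected by k-fold CV, then refit on all data.

    Extra fitted attributes: ``alpha_`` (selected penalty), ``alphas_``
    (the grid used) and ``cv_mse_`` (per-grid-point held-out MSE).
    """

    def __init__(self, search: LambdaSearch | None = None):
        self.search = search

    def fit(self, X, y):
        lam, filled = select_lambda_cv(X, y, self.search)
        self.alpha = self.alpha_ = lam
        self.alphas_ = filled.grid
        self.cv_mse_ = filled.cv_mse
        return super().fit(X, y)


# -- module-level functional surface --------------------------------------

def fit_ridge(X, y, alpha: float) -> RidgeTraitRegressor:
    """Fit a ridge model at a fixed penalty; returns the fitted estimator."""
    return RidgeTraitRegressor(alpha=alpha).fit(X, y)


def effective_df(X, alpha: float) -> float:
    """Effective degrees of freedom of the ridge hat matrix on standardized X.

    Equals ``trace(Z (Z'Z + alpha I)^-1 Z')`` = sum_i d_i^2/(d_i^2 + alpha).
    """
    X = np.asarray(X, dtype=float)
    Z, _, _ = _standardize(X)
    d = np.linalg.svd(Z, compute_uv=False)
    if alpha == 0:
        return float(np.sum(d > 1e-12))
    return float(np.sum(d**2 / (d**2 + alpha)))


def bic_of(model: RidgeTraitRegressor) -> float:
    """Gaussian-likelihood BIC of a fitted model; lower is better."""
    if model.rss_ <= 0 or model.bic_ is None:
        raise ValueError("BIC undefined: residual sum of squares is zero (perfect fit)")
    return float(model.bic_)
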