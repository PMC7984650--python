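"""Sparsity-constrained principal component regression (LASSO-PCR).

The single-channel estimator: features are centered and decomposed by an
economy SVD, ``X_c = U S Vᵀ``; the response is regressed on the component
scores ``Z = U S`` under an L1 penalty,

    β̂ = argmin_β  (1/2n) ‖y − Zβ‖² + α ‖β‖₁ ,

and the score-space coefficients are projected back to feature space as a
weight map ``ŵ = V β̂`` so that predictions read ``ŷ = (X − x̄) ŵ + b``. All
``min(n−1, p)`` components are retained — the L1 term does the selection, a
hard truncation would be an extra undocumented filter.

The penalty is selected on a log-spaced grid by inner k-fold cross-validation
minimizing mean squared error. The same inner pass doubles as the producer of
out-of-fold training-set predictions for stacking: each training row's
prediction comes from the fold model that excluded it, evaluated at the
grid point the CV selected.

The penalty is written on the per-sample (1/2n) objective scale used by
scikit-learn's coordinate descent; on this scale duplicating every row leaves
the solution unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = ["LassoPCR", "fit_lasso_pcr", "out_of_fold_predictions", "default_lambda_grid"]


def default_lambda_grid(
    Z: np.ndarray, y_centered: np.ndarray, n_lambdas: int = 30, min_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced penalty grid from the data-driven entry point downwards.

    ``α_max = max |Zᵀ y| / n`` is the smallest penalty at which every
    coefficient is zero; the grid descends to ``min_ratio · α_max``.
    """
    n = Z.shape[0]
    alpha_max = float(np.max(np.abs(Z.T @ y_centered)) / n)
    if not np.isfinite(alpha_max) or alpha_max <= 0:
        alpha_max = 1e-12
    return np.geomspace(alpha_max, alpha_max * min_ratio, n_lambdas)


@dataclass
class _PCABasis:
    """Centered SVD basis of one training matrix."""

    means: np.ndarray       # (p,)
    V: np.ndarray           # (p, c) principal axes, orthonormal columns
    Z: np.ndarray           # (n, c) component scores U S

    @classmethod
    def fit(cls, X: np.ndarray) -> "_PCABasis":
        means = X.mean(axis=0)
        Xc = X - means
        n = X.shape[0]
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # rank cannot exceed n-1 after centering; drop numerically-null axes
        c = min(n - 1, Xc.shape[1])
        tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
        c = min(c, int(np.sum(s > tol))) or 1
        return cls(means=means, V=Vt[:c].T, Z=U[:, :c] * s[:c])

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) @ self.V


def _path_coefs(Z: np.ndarray, yc: np.ndarray, alphas: np.ndarray,
                positive: bool = False) -> np.ndarray:
    """Coordinate-descent solution path; returns coefs of shape (c, n_alphas)."""
    order = np.argsort(alphas)[::-1]
    _, coefs, _ = lasso_path(Z, yc, alphas=alphas[order], positive=positive)
    out = np.empty_like(coefs)
    out[:, order] = coefs
    return out


class LassoPCR(RegressorMixin, BaseEstimator):
    """L1-penalized principal component regression with inner-CV penalty choice.

    Parameters
    ----------
    lambda_grid : array-like or None
        Explicit penalty grid (per-sample objective scale). ``None`` builds
        ``n_lambdas`` log-spaced values from the data-driven maximum.
    n_lambdas, lambda_min_ratio : int, float
        Grid size and lower bound ratio when the grid is data-driven.
    inner_folds : int
        Folds of the inner CV that selects the penalty.
    fixed_lambda : float or None
        Skip the inner CV and fit at this penalty (used for the shrinkage
        limits and in oracle comparisons).
    random_state : int or None
        Seeds the inner-fold shuffle.

    Attributes
    ----------
    column_means_ : (p,) centering vector
    principal_axes_ : (p, c) orthonormal columns V
    coef_components_ : (c,) β̂ on component scores
    weight_map_ : (p,) ŵ = V β̂ (this is also ``coef_`` for sklearn interop)
    intercept_ : float, the training mean of y
    lambda_ : float, selected penalty
    lambda_grid_ : the grid searched
    cv_mse_ : mean inner-CV MSE per grid point (None when fixed_lambda)
    oof_predictions_ : out-of-fold training predictions at ``lambda_``
        (None when fixed_lambda)
    """

    def __init__(
        self,
        lambda_grid=None,
        n_lambdas: int = 30,
        lambda_min_ratio: float = 1e-3,
        inner_folds: int = 5,
        fixed_lambda: float | None = None,
        random_state: int | None = None,
    ):
        self.lambda_grid = lambda_grid
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.inner_folds = inner_folds
        self.fixed_lambda = fixed_lambda
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.size:
            raise ValueError("X and y row counts differ")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in X or y")
        if self.lambda_grid is not None and len(np.atleast_1d(self.lambda_grid)) == 0:
            raise ValueError("empty lambda grid")
        n = X.shape[0]

        basis = _PCABasis.fit(X)
        ybar = float(y.mean())
        yc = y - ybar

        if self.fixed_lambda is not None:
            grid = np.asarray([float(self.fixed_lambda)])
            best = 0
            self.cv_mse_ = None
            self.oof_predictions_ = None
        else:
            if self.inner_folds < 2:
                raise ValueError("inner_folds must be at least 2")
            if n < self.inner_folds:
                raise ValueError(
                    f"{self.inner_folds}-fold inner CV needs at least that many rows, got {n}"
                )
            if self.lambda_grid is not None:
                grid = np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
            else:
                grid = default_lambda_grid(basis.Z, yc, self.n_lambdas, self.lambda_min_ratio)
            oof = np.empty((n, grid.size))
            folds = KFold(self.inner_folds, shuffle=True, random_state=self.random_state)
            for tr, te in folds.split(X):
                fb = _PCABasis.fit(X[tr])
                fyb = float(y[tr].mean())
                coefs = _path_coefs(fb.Z, y[tr] - fyb, grid)
                oof[te] = fb.transform(X[te]) @ coefs + fyb
            mse = np.mean((oof - y[:, None]) ** 2, axis=0)
            # ties resolved toward the larger (first, grid is descending) penalty
            best = int(np.argmin(mse))
            self.cv_mse_ = mse
            self.oof_predictions_ = oof[:, best].copy()

        coef = _path_coefs(basis.Z, yc, grid)[:, best]

        self.n_features_in_ = X.shape[1]
        self.column_means_ = basis.means
        self.principal_axes_ = basis.V
        self.singular_values_ = None  # kept implicit; Z = (X - means) V
        self.coef_components_ = coef
        self.weight_map_ = basis.V @ coef
        self.coef_ = self.weight_map_
        self.intercept_ = ybar
        self.lambda_ = float(grid[best])
        self.lambda_grid_ = grid
        return self

    # -------------------------------------------------------------- predict
    def predict(self, X):
        check_is_fitted(self, "weight_map_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        return (X - self.column_means_) @ self.weight_map_ + self.intercept_

    def predict_from_scores(self, X):
        """Dual-path prediction through score space, ``Z_new β̂ + b``.

        Identical to :meth:`predict` up to floating-point error; exposed so
        the back-projection identity ŵ = Vβ̂ is directly checkable.
        """
        check_is_fitted(self, "weight_map_")
        X = np.asarray(X, dtype=float)
        Z_new = (X - self.column_means_) @ self.principal_axes_
        return Z_new @ self.coef_components_ + self.intercept_


# ------------------------------------------------------------- thin wrappers

def fit_lasso_pcr(
    X,
    y,
    lambda_grid=None,
    inner_folds: int = 5,
    seed: int | None = None,
    **kwargs,
) -> LassoPCR:
    """Fit a :class:`LassoPCR` (functional spelling)."""
    return LassoPCR(
        lambda_grid=lambda_grid, inner_folds=inner_folds, random_state=seed, **kwargs
    ).fit(X, y)


def out_of_fold_predictions(
    X,
    y,
    k: int = 5,
    lambda_grid=None,
    seed: int | None = None,
) -> tuple[np.ndarray, LassoPCR]:
    """Out-of-fold training predictions plus the final refitted model.

    One k-fold pass simultaneously selects the penalty (minimum CV MSE over
    the grid) and yields, for every row, a prediction from the fold model
    that excluded it, at that selected penalty. The returned model is
    refitted on all rows at the same penalty.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available rows")
    model = LassoPCR(lambda_grid=lambda_grid, inner_folds=k, random_state=seed).fit(X, y)
    return model.oof_predictions_, model
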