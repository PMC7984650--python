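"""Level-2 learning: non-negative LASSO over stacked channel predictions.

Out-of-fold single-channel predictions form the meta-feature matrix (one
column per channel, rows are training subjects); a non-negative L1 model
selects and reweights channels, shrinking redundant ones exactly to zero.
Meta-features already share the response's units, so they enter uncentered
and unscaled; the intercept absorbs the response mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .containers import FeatureChannel
from .lasso_pcr import LassoPCR
from .preprocess import residualize_response

__all__ = [
    "MetaMatrix",
    "NonNegativeStackedLasso",
    "build_meta_matrix",
    "fit_stacked",
    "predict_stacked",
    "TwoLevelSettings",
    "TwoLevelResult",
    "run_two_level",
]


@dataclass
class MetaMatrix:
    """Subjects × channels matrix of per-channel predicted responses.

    Training rows hold out-of-fold predictions; test rows hold fitted-model
    predictions. Column order is fixed and recorded via ``channel_names``.
    """

    matrix: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("meta matrix must be 2-D")
        if len(self.channel_names) != self.matrix.shape[1]:
            raise ValueError("one name per meta column required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")


def build_meta_matrix(per_channel_predictions: list[np.ndarray],
                      channel_names: list[str]) -> MetaMatrix:
    """Stack per-channel prediction vectors as columns."""
    if len(per_channel_predictions) != len(channel_names):
        raise ValueError("one name per prediction vector required")
    cols = [np.asarray(v, dtype=float).ravel() for v in per_channel_predictions]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("prediction vectors have unequal lengths")
    return MetaMatrix(np.column_stack(cols), list(channel_names))


class NonNegativeStackedLasso(RegressorMixin, BaseEstimator):
    """Non-negative L1 meta-model over channel predictions.

    The penalty is selected on a log-spaced grid by inner k-fold CV
    (minimum mean squared error); coefficients of shrunk channels are
    exactly zero and all coefficients are ≥ 0 — the constraint keeps them
    interpretable as channel weights.

    Attributes
    ----------
    meta_coefficients_ : (n_channels,) non-negative weights (also ``coef_``)
    intercept_ : float
    lambda_ : selected penalty (per-sample objective scale)
    channel_names_ : column order the model was fitted with
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

    def _grid(self, M: np.ndarray, yc: np.ndarray) -> np.ndarray:
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0:
                raise ValueError("empty lambda grid")
            return np.sort(grid)[::-1]
        n = M.shape[0]
        Mc = M - M.mean(axis=0)
        # entry point for the positive-lasso: only positive correlations count
        alpha_max = float(np.max(Mc.T @ yc) / n)
        if not np.isfinite(alpha_max) or alpha_max <= 0:
            alpha_max = 1e-12
        return np.geomspace(alpha_max, alpha_max * self.lambda_min_ratio, self.n_lambdas)

    def fit(self, M, y, channel_names: list[str] | None = None):
        if isinstance(M, MetaMatrix):
            channel_names = list(M.channel_names)
            M = M.matrix
        M = np.asarray(M, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if M.ndim != 2 or M.shape[0] != y.size:
            raise ValueError("meta matrix / response shape mismatch")
        if not (np.isfinite(M).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in meta matrix or response")
        n = M.shape[0]
        ybar = float(y.mean())

        if self.fixed_lambda is not None:
            grid = np.asarray([float(self.fixed_lambda)])
            best = 0
            self.cv_mse_ = None
        else:
            if n < 2 * self.inner_folds:
                raise ValueError(
                    f"need at least {2 * self.inner_folds} rows for "
                    f"{self.inner_folds}-fold inner CV, got {n}"
                )
            grid = self._grid(M, y - ybar)
            folds = KFold(self.inner_folds, shuffle=True, random_state=self.random_state)
            oof = np.empty((n, grid.size))
            for tr, te in folds.split(M):
                mu = M[tr].mean(axis=0)
                fyb = float(y[tr].mean())
                _, coefs, _ = lasso_path(M[tr] - mu, y[tr] - fyb, alphas=grid, positive=True)
                oof[te] = (M[te] - mu) @ coefs + fyb
            self.cv_mse_ = np.mean((oof - y[:, None]) ** 2, axis=0)
            best = int(np.argmin(self.cv_mse_))

        final = Lasso(alpha=float(grid[best]), positive=True, fit_intercept=True,
                      max_iter=50_000)
        final.fit(M, y)
        self.n_features_in_ = M.shape[1]
        self.meta_coefficients_ = np.asarray(final.coef_, dtype=float)
        self.coef_ = self.meta_coefficients_
        self.intercept_ = float(final.intercept_)
        self.lambda_ = float(grid[best])
        self.lambda_grid_ = grid
        self.channel_names_ = (
            list(channel_names) if channel_names is not None
            else [f"channel_{j}" for j in range(M.shape[1])]
        )
        return self

    def predict(self, M, channel_names: list[str] | None = None):
        check_is_fitted(self, "meta_coefficients_")
        if isinstance(M, MetaMatrix):
            channel_names = list(M.channel_names)
            M = M.matrix
        M = np.asarray(M, dtype=float)
        if M.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} meta columns, got {M.shape[1]}")
        if channel_names is not None and channel_names != self.channel_names_:
            raise ValueError(
                f"channel order mismatch: model {self.channel_names_}, input {channel_names}"
            )
        return M @ self.meta_coefficients_ + self.intercept_


def fit_stacked(meta_train: MetaMatrix, y_train, lambda_grid=None,
                inner_folds: int = 5, seed: int | None = None) -> NonNegativeStackedLasso:
    """Fit the level-2 non-negative LASSO (functional spelling)."""
    return NonNegativeStackedLasso(
        lambda_grid=lambda_grid, inner_folds=inner_folds, random_state=seed
    ).fit(meta_train, y_train)


def predict_stacked(model: NonNegativeStackedLasso, meta_test: MetaMatrix) -> np.ndarray:
    return model.predict(meta_test)


# ------------------------------------------------------------ full protocol


@dataclass
class TwoLevelSettings:
    """Knobs of one two-level run (defaults follow the study protocol)."""

    inner_folds: int = 5
    n_lambdas: int = 30
    lambda_min_ratio: float = 1e-3
    seed: int | None = None
    #: per-subject neuroimaging confounder (e.g. intracranial volume) to be
    #: partialled out of the response with train-only coefficients; None skips
    icv: np.ndarray | None = None


@dataclass
class TwoLevelResult:
    channel_names: list[str]
    channel_models: dict[str, LassoPCR]
    stacked_model: NonNegativeStackedLasso
    meta_train: MetaMatrix
    meta_test: MetaMatrix
    per_channel_test_pred: dict[str, np.ndarray]
    stacked_test_pred: np.ndarray = field(default=None)  # type: ignore[assignment]
    y_train: np.ndarray = field(default=None)  # type: ignore[assignment]
    y_test: np.ndarray = field(default=None)  # type: ignore[assignment]


def run_two_level(
    channels: list[FeatureChannel],
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    settings: TwoLevelSettings | None = None,
) -> TwoLevelResult:
    """Execute the full two-level protocol on one train/test split.

    Per channel: inner-CV LASSO-PCR on the training rows yields out-of-fold
    training predictions and, after a full-train refit at the selected
    penalty, test predictions. The OOF columns train the non-negative L1
    stacker, which then produces the final test predictions. When an ICV
    vector is supplied, the response is first residualized on it with
    train-only coefficients.

    The inner fold assignment is derived from the settings seed alone, so it
    is shared by every channel of the split: an exact duplicate channel
    yields a bitwise-identical meta-column.
    """
    settings = settings or TwoLevelSettings()
    y = np.asarray(y, dtype=float).ravel()
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")

    y_tr, y_te = y[train_idx], y[test_idx]
    if settings.icv is not None:
        icv = np.asarray(settings.icv, dtype=float).ravel()
        y_tr, y_te = residualize_response(y_tr, y_te, icv[train_idx], icv[test_idx])

    names = [ch.name for ch in channels]
    if len(set(names)) != len(names):
        raise ValueError("channel names must be unique")

    models: dict[str, LassoPCR] = {}
    oof_cols, test_cols = [], []
    for ch in channels:
        model = LassoPCR(
            n_lambdas=settings.n_lambdas,
            lambda_min_ratio=settings.lambda_min_ratio,
            inner_folds=settings.inner_folds,
            random_state=settings.seed,
        ).fit(ch.values[train_idx], y_tr)
        models[ch.name] = model
        oof_cols.append(model.oof_predictions_)
        test_cols.append(model.predict(ch.values[test_idx]))

    meta_train = build_meta_matrix(oof_cols, names)
    meta_test = build_meta_matrix(test_cols, names)

    stacker = NonNegativeStackedLasso(
        n_lambdas=settings.n_lambdas,
        lambda_min_ratio=settings.lambda_min_ratio,
        inner_folds=settings.inner_folds,
        random_state=settings.seed,
    ).fit(meta_train, y_tr)

    return TwoLevelResult(
        channel_names=names,
        channel_models=models,
        stacked_model=stacker,
        meta_train=meta_train,
        meta_test=meta_test,
        per_channel_test_pred=dict(zip(names, test_cols)),
        stacked_test_pred=stacker.predict(meta_test),
        y_train=y_tr,
        y_test=y_te,
    )
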