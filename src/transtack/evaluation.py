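"""Performance protocol: family-aware Monte Carlo splits and summaries.

Repeated 70/30 train/test partitions keep every family (twin pair) wholly on
one side of the split — twins' correlated traits would otherwise leak across
the partition and inflate out-of-sample accuracy. Per-split metrics (R²,
MAE, the stacking bonus, level-2 channel weights) are summarized by the
median with a percentile-bootstrap confidence interval, and channels are
compared pairwise with a one-tailed Wilcoxon signed-rank test plus the
matched-pairs rank-biserial effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error as _sk_mae
from sklearn.metrics import r2_score as _sk_r2

from .containers import FeatureChannel
from .stacking import TwoLevelSettings, run_two_level

__all__ = [
    "SplitPlan",
    "monte_carlo_splits",
    "r_squared",
    "mean_absolute_error",
    "stacking_bonus",
    "bootstrap_median_ci",
    "compare_channels",
    "PerformanceReport",
    "evaluate_study",
]

STACKED = "stacked"  # model label for the level-2 predictions


# ------------------------------------------------------------------- splits


@dataclass
class SplitPlan:
    """Group-respecting Monte Carlo train/test partitions."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    test_fraction: float
    group_labels: np.ndarray
    seed: int | None

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)


def monte_carlo_splits(
    n: int,
    family_groups,
    strata=None,
    n_splits: int = 100,
    test_fraction: float = 0.3,
    seed: int | None = None,
) -> SplitPlan:
    """Repeated random train/test partitions that never split a family.

    Families are shuffled and whole families assigned to the test side until
    it holds ``round(test_fraction · n)`` subjects (overshoot bounded by one
    family). With ``strata`` (a per-subject continuous value, e.g. the
    response), families are first binned by quintiles of their group mean and
    the test quota is filled proportionally per bin.
    """
    groups = np.asarray(family_groups)
    if groups.size != n:
        raise ValueError("family_groups must label every subject")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    target = int(round(test_fraction * n))
    uniq, inverse = np.unique(groups, return_inverse=True)
    members: list[np.ndarray] = [np.flatnonzero(inverse == g) for g in range(uniq.size)]
    sizes = np.array([m.size for m in members])
    if sizes.max() > target:
        raise ValueError(
            f"a family of size {sizes.max()} cannot fit in a test set of {target}"
        )

    if strata is not None:
        values = np.asarray(strata, dtype=float)
        gmeans = np.array([values[m].mean() for m in members])
        n_bins = min(5, uniq.size)
        # quantile bins of the group-level mean
        edges = np.quantile(gmeans, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(edges, gmeans, side="right")
    else:
        bins = np.zeros(uniq.size, dtype=int)

    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        test_mask = np.zeros(n, dtype=bool)
        filled = 0
        for b in np.unique(bins):
            gidx = np.flatnonzero(bins == b)
            rng.shuffle(gidx)
            quota = int(round(test_fraction * sizes[gidx].sum()))
            got = 0
            for g in gidx:
                if got >= quota:
                    break
                test_mask[members[g]] = True
                got += sizes[g]
            filled += got
        # top up across bins if rounding left the overall target short
        if filled < target:
            remaining = [g for g in rng.permutation(uniq.size)
                         if not test_mask[members[g][0]]]
            for g in remaining:
                if filled >= target:
                    break
                test_mask[members[g]] = True
                filled += sizes[g]
        splits.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return SplitPlan(splits=splits, test_fraction=test_fraction,
                     group_labels=groups, seed=seed)


# ------------------------------------------------------------------ metrics


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot (may be negative)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("equal nonzero lengths required")
    if np.var(y_true) == 0:
        raise ValueError("R² undefined for a zero-variance response")
    return float(_sk_r2(y_true, y_pred))


def mean_absolute_error(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("equal nonzero lengths required")
    return float(_sk_mae(y_true, y_pred))


def stacking_bonus(r2_stacking: float, r2_singles, mode: str = "best") -> float:
    """Stacked-model gain over the single channels, per split.

    ``mode="mean"``: gain over the average single-channel R².
    ``mode="best"``: the conservative gain over the best single channel.
    """
    singles = np.asarray(list(r2_singles), dtype=float)
    if singles.size == 0:
        raise ValueError("r2_singles must be nonempty")
    if mode == "mean":
        return float(r2_stacking - singles.mean())
    if mode == "best":
        return float(r2_stacking - singles.max())
    raise ValueError(f"unknown mode {mode!r}")


def bootstrap_median_ci(
    values, n_boot: int = 1000, alpha: float = 0.05, seed: int | None = None
) -> tuple[float, float, float]:
    """Median with a percentile-bootstrap confidence interval."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(v, size=(n_boot, v.size), replace=True), axis=1)
    lo, hi = np.percentile(meds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(np.median(v)), float(lo), float(hi)


def compare_channels(scores_a, scores_b) -> tuple[float, float]:
    """Paired one-tailed comparison of two per-split metric vectors.

    Wilcoxon signed-rank test of ``a > b`` plus the matched-pairs
    rank-biserial correlation (positive minus negative rank sums over the
    total rank sum). Ties (zero differences) are dropped, the signed-rank
    convention; an all-tie comparison is degenerate and reported as p = 1,
    effect 0 with a warning.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.size != b.size or a.size < 5:
        raise ValueError("paired vectors of equal length >= 5 required")
    d = a - b
    nz = d != 0
    if not nz.any():
        warnings.warn("all paired differences are zero; Wilcoxon test degenerate",
                      stacklevel=2)
        return 1.0, 0.0
    res = stats.wilcoxon(a[nz], b[nz], alternative="greater",
                         method="exact" if nz.sum() <= 25 else "auto")
    ranks = stats.rankdata(np.abs(d[nz]))
    total = ranks.sum()
    r_pos = ranks[d[nz] > 0].sum()
    rank_biserial = float((r_pos - (total - r_pos)) / total)
    return float(res.pvalue), rank_biserial


# ------------------------------------------------------------- study runner


@dataclass
class PerformanceReport:
    """Per-split metrics plus bootstrap summaries of a Monte Carlo study."""

    metrics: pd.DataFrame           # split, model, r2, mae
    meta_coefficients: pd.DataFrame  # split, channel, beta
    bonus: pd.DataFrame             # split, b_mean, b_best
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    coef_summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    bonus_summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    n_boot: int = 1000
    alpha: float = 0.05

    def summarize(self, seed: int | None = 0) -> "PerformanceReport":
        """(Re)compute median + percentile-bootstrap CI summary tables."""
        rows = []
        for (model,), grp in self.metrics.groupby(["model"]):
            for metric in ("r2", "mae"):
                med, lo, hi = bootstrap_median_ci(
                    grp[metric], self.n_boot, self.alpha, seed
                )
                rows.append({"model": model, "metric": metric,
                             "median": med, "ci_low": lo, "ci_high": hi})
        self.summary = pd.DataFrame(rows)
        rows = []
        for (channel,), grp in self.meta_coefficients.groupby(["channel"]):
            med, lo, hi = bootstrap_median_ci(grp["beta"], self.n_boot, self.alpha, seed)
            rows.append({"channel": channel, "median": med,
                         "ci_low": lo, "ci_high": hi})
        self.coef_summary = pd.DataFrame(rows)
        rows = []
        for col in ("b_mean", "b_best"):
            med, lo, hi = bootstrap_median_ci(self.bonus[col], self.n_boot, self.alpha, seed)
            rows.append({"bonus": col, "median": med, "ci_low": lo, "ci_high": hi})
        self.bonus_summary = pd.DataFrame(rows)
        return self


def evaluate_study(
    channels: list[FeatureChannel],
    y: np.ndarray,
    family_groups,
    icv=None,
    strata=None,
    n_splits: int = 100,
    test_fraction: float = 0.3,
    inner_folds: int = 5,
    n_lambdas: int = 30,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PerformanceReport:
    """Run the full Monte Carlo protocol and summarize it.

    For each of ``n_splits`` family-respecting 70/30 partitions the two-level
    pipeline is fitted on the training side and scored on the test side; the
    report carries per-split R²/MAE for every single channel and the stacked
    model, the level-2 channel weights, both stacking-bonus variants, and
    bootstrap summaries of their medians.

    All randomness descends from ``seed`` through independent spawned
    streams, so adding splits never changes earlier splits' results.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    root = np.random.SeedSequence(seed)
    split_seed, per_split_seq, boot_seed = root.spawn(3)

    plan = monte_carlo_splits(
        n, family_groups, strata=strata, n_splits=n_splits,
        test_fraction=test_fraction,
        seed=int(split_seed.generate_state(1)[0] % (2**31)),
    )
    split_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in per_split_seq.spawn(n_splits)]

    names = [ch.name for ch in channels]
    metric_rows, coef_rows, bonus_rows = [], [], []
    for s, (train_idx, test_idx) in enumerate(plan):
        settings = TwoLevelSettings(
            inner_folds=inner_folds, n_lambdas=n_lambdas, seed=split_seeds[s],
            icv=None if icv is None else np.asarray(icv, dtype=float),
        )
        result = run_two_level(channels, y, train_idx, test_idx, settings)
        singles = {}
        for name in names:
            pred = result.per_channel_test_pred[name]
            singles[name] = r_squared(result.y_test, pred)
            metric_rows.append({"split": s, "model": name, "r2": singles[name],
                                "mae": mean_absolute_error(result.y_test, pred)})
        r2_stack = r_squared(result.y_test, result.stacked_test_pred)
        metric_rows.append({"split": s, "model": STACKED, "r2": r2_stack,
                            "mae": mean_absolute_error(result.y_test,
                                                       result.stacked_test_pred)})
        for name, beta in zip(names, result.stacked_model.meta_coefficients_):
            coef_rows.append({"split": s, "channel": name, "beta": float(beta)})
        r2_singles = list(singles.values())
        bonus_rows.append({
            "split": s,
            "b_mean": stacking_bonus(r2_stack, r2_singles, "mean"),
            "b_best": stacking_bonus(r2_stack, r2_singles, "best"),
        })

    report = PerformanceReport(
        metrics=pd.DataFrame(metric_rows),
        meta_coefficients=pd.DataFrame(coef_rows),
        bonus=pd.DataFrame(bonus_rows),
        n_boot=n_boot,
        alpha=alpha,
    )
    return report.summarize(seed=int(boot_seed.generate_state(1)[0] % (2**31)))
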