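"""Feature-relevance layer: encoding patterns and map post-processing.

Decoding weights of a backward model can be large purely to cancel noise;
multiplying by the feature covariance, ``A = Σ_X ŵ``, turns them into
encoding patterns interpretable as feature–response associations. The
response-variance factor is a scalar here (single response) and is omitted,
so patterns are meaningful up to a positive scale — which the max-abs
rescaling to [−1, 1] then fixes without breaking sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureChannel
from .lasso_pcr import LassoPCR
from .preprocess import devectorize_upper_triangle

__all__ = [
    "EncodingPattern",
    "encoding_pattern",
    "maxabs_rescale",
    "strength_map",
    "group_average_loadings",
    "refit_full",
]


@dataclass
class EncodingPattern:
    """Per-feature encoding loadings of one channel."""

    channel: str
    loadings: np.ndarray
    feature_labels: list[str] | None = None
    rescaled: bool = False
    ordering: str = "row-major strictly-upper-triangle"  # for link channels


def encoding_pattern(weight_map: np.ndarray, X: np.ndarray,
                     channel: str = "", feature_labels=None) -> EncodingPattern:
    """Transform decoding weights to an encoding pattern, A = Σ_X ŵ.

    The sample feature covariance (n−1 denominator) is never materialized:
    ``A = X_cᵀ (X_c ŵ) / (n−1)`` needs two matrix-vector products, so the
    transform stays cheap at connectome scale.
    """
    w = np.asarray(weight_map, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != w.size:
        raise ValueError(f"weight map of length {w.size} does not match X {X.shape}")
    Xc = X - X.mean(axis=0)
    A = Xc.T @ (Xc @ w) / (X.shape[0] - 1)
    return EncodingPattern(channel=channel, loadings=A, feature_labels=feature_labels)


def maxabs_rescale(loadings: np.ndarray) -> np.ndarray:
    """Rescale to [−1, 1] by the max absolute value; zeros stay exact zeros."""
    a = np.asarray(loadings, dtype=float)
    if a.size == 0:
        raise ValueError("empty loadings")
    m = np.max(np.abs(a))
    return a.copy() if m == 0 else a / m


def strength_map(link_loadings: np.ndarray, n_regions: int,
                 top_fraction: float = 0.01) -> np.ndarray:
    """Per-region strength of a link-loading vector.

    The vector over region pairs is devectorized to the symmetric matrix of
    absolute link weights, all but the ``top_fraction`` largest links are
    zeroed (ties at the cut are kept), and the strength is the row sum —
    concentrating each region's score on its strongest links.
    """
    v = np.abs(np.asarray(link_loadings, dtype=float).ravel())
    expected = n_regions * (n_regions - 1) // 2
    if v.size != expected:
        raise ValueError(f"expected {expected} links for {n_regions} regions, got {v.size}")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    k = max(1, int(round(top_fraction * v.size)))
    if k < v.size:
        cut = np.sort(v)[::-1][k - 1]
        v = np.where(v >= cut, v, 0.0)
    return devectorize_upper_triangle(v, n_regions).sum(axis=1)


def group_average_loadings(pattern: EncodingPattern, grouping: dict[str, str],
                           sign: str = "positive") -> pd.DataFrame:
    """Mean strictly-positive (or strictly-negative) loading per feature group.

    Groups without any loading of the requested sign appear with a missing
    mean (``NaN``) and a zero count; features absent from the grouping are
    ignored but tallied in the ``n_ungrouped`` attribute of the result.
    """
    if not grouping:
        raise ValueError("empty grouping")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    labels = pattern.feature_labels
    if labels is None:
        labels = [str(j) for j in range(pattern.loadings.size)]
    df = pd.DataFrame({"label": labels, "loading": pattern.loadings})
    df["group"] = df["label"].map(grouping)
    n_ungrouped = int(df["group"].isna().sum())
    df = df.dropna(subset=["group"])
    mask = df["loading"] > 0 if sign == "positive" else df["loading"] < 0
    kept = df[mask]
    out = (
        kept.groupby("group")["loading"]
        .agg(mean_loading="mean", n_features="count")
        .reindex(sorted(df["group"].unique()))
        .reset_index()
    )
    out["n_features"] = out["n_features"].fillna(0).astype(int)
    out.attrs["sign"] = sign
    out.attrs["n_ungrouped"] = n_ungrouped
    return out


def refit_full(
    channels: list[FeatureChannel],
    y: np.ndarray,
    coef_summary: pd.DataFrame,
    inner_folds: int = 5,
    n_lambdas: int = 30,
    seed: int | None = None,
) -> tuple[dict[str, tuple[LassoPCR, EncodingPattern]], list[str]]:
    """Full-data refit and encoding patterns for the contributing channels.

    A channel contributes when the bootstrap CI of its median level-2 weight
    excludes zero (``ci_low > 0``; weights are non-negative); the rest are
    reported back as non-contributing, with no map. Each surviving channel
    is refitted on *all* observations with the penalty re-optimized by inner
    CV, then its weight map is covariance-transformed and max-abs rescaled.
    """
    surviving = set(
        coef_summary.loc[coef_summary["ci_low"] > 0, "channel"].astype(str)
    )
    results: dict[str, tuple[LassoPCR, EncodingPattern]] = {}
    non_contributing = []
    for ch in channels:
        if ch.name not in surviving:
            non_contributing.append(ch.name)
            continue
        model = LassoPCR(inner_folds=inner_folds, n_lambdas=n_lambdas,
                         random_state=seed).fit(ch.values, y)
        pattern = encoding_pattern(model.weight_map_, ch.values,
                                   channel=ch.name, feature_labels=ch.feature_labels)
        pattern.loadings = maxabs_rescale(pattern.loadings)
        pattern.rescaled = True
        results[ch.name] = (model, pattern)
    return results, non_contributing
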