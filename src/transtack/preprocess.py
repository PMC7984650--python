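"""Feature-matrix plumbing around the two-level pipeline.

Vectorization of symmetric connectivity matrices, removal of zero-variance
features, train-only residualization of the response on a head-size
confounder, assembly of the demographic confounder channel, and channel
concatenation for the single-matrix baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import FeatureChannel

__all__ = [
    "vectorize_upper_triangle",
    "devectorize_upper_triangle",
    "drop_zero_variance",
    "residualize_response",
    "confounder_channel",
    "concatenate_channels",
]


def vectorize_upper_triangle(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Extract the strictly-upper-triangle of a symmetric matrix.

    Row-major order (``(0,1), (0,2), ..., (1,2), ...``), diagonal excluded —
    a ``p × p`` connectome yields ``p(p−1)/2`` features. The diagonal is
    dropped because the self-correlation of a Fisher z-transformed
    connectome is infinite.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize_upper_triangle(vec: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (zero diagonal)."""
    v = np.asarray(vec, dtype=float).ravel()
    if n_regions is None:
        # solve p(p-1)/2 = len(v)
        p = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    else:
        p = int(n_regions)
    if p * (p - 1) // 2 != v.size:
        raise ValueError(f"vector of length {v.size} is not an upper triangle of a {p}×{p} matrix")
    m = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    m[iu] = v
    return m + m.T


def drop_zero_variance(channel: FeatureChannel) -> tuple[FeatureChannel, list[str]]:
    """Remove constant feature columns, reporting the dropped labels.

    Constant features (whatever the constant) carry no predictive
    information and break variance-based steps downstream.
    """
    var = channel.values.var(axis=0)
    keep = var > 0
    if not keep.any():
        raise ValueError(f"channel {channel.name!r}: every column has zero variance")
    dropped = [l for l, k in zip(channel.feature_labels, keep) if not k]
    if not dropped:
        return channel, []
    kept_labels = [l for l, k in zip(channel.feature_labels, keep) if k]
    groups = None
    if channel.feature_groups is not None:
        groups = {l: g for l, g in channel.feature_groups.items() if l in set(kept_labels)}
    out = FeatureChannel(
        name=channel.name,
        values=channel.values[:, keep],
        feature_labels=kept_labels,
        subject_ids=channel.subject_ids,
        feature_groups=groups,
    )
    return out, dropped


def residualize_response(
    y_train: np.ndarray,
    y_test: np.ndarray,
    conf_train: np.ndarray,
    conf_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial a single confounder (e.g. intracranial volume) out of the response.

    A simple linear regression ``y ~ 1 + conf`` is fitted on the *training*
    rows only; both train and test responses are replaced by their residuals
    under those train-estimated coefficients, so no test information ever
    influences the adjustment.
    """
    y_tr = np.asarray(y_train, dtype=float).ravel()
    y_te = np.asarray(y_test, dtype=float).ravel()
    c_tr = np.asarray(conf_train, dtype=float).ravel()
    c_te = np.asarray(conf_test, dtype=float).ravel()
    if y_tr.size != c_tr.size or y_te.size != c_te.size:
        raise ValueError("response/confounder length mismatch")
    if y_tr.size < 3:
        raise ValueError("need at least 3 training rows to fit the adjustment")
    c_mean = c_tr.mean()
    y_mean = y_tr.mean()
    ss = np.sum((c_tr - c_mean) ** 2)
    if ss == 0.0:
        warnings.warn("confounder has zero variance in train; intercept-only adjustment",
                      stacklevel=2)
        slope = 0.0
    else:
        slope = float(np.sum((c_tr - c_mean) * (y_tr - y_mean)) / ss)
    intercept = y_mean - slope * c_mean
    return y_tr - (intercept + slope * c_tr), y_te - (intercept + slope * c_te)


def confounder_channel(meta: pd.DataFrame) -> FeatureChannel:
    """Assemble demographics (age, sex, education) as an extra channel.

    Mediating variables that are not imaging measures enter the stacker as
    their own modality: if they carry most of the response variance, the
    level-2 L1 fit shrinks the imaging channels away on its own. Sex is
    one-hot coded with one reference level dropped; education is treated as a
    numeric ordinal.
    """
    required = ["age", "sex", "education"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing confounder columns: {missing}")
    if meta[required].isna().any().any():
        raise ValueError("missing values in confounders; drop those subjects first")
    sex = pd.get_dummies(meta["sex"].astype(str), prefix="sex", drop_first=True, dtype=float)
    cols = pd.concat(
        [meta["age"].astype(float), sex, meta["education"].astype(float)], axis=1
    )
    cols.columns = ["age", *sex.columns, "education"]
    ids = meta["subject_id"].to_numpy(dtype=str) if "subject_id" in meta.columns else None
    return FeatureChannel(
        name="confounders",
        values=cols.to_numpy(dtype=float),
        feature_labels=list(cols.columns),
        subject_ids=ids,
    )


def concatenate_channels(channels: list[FeatureChannel], name: str = "concatenated") -> FeatureChannel:
    """Column-wise concatenation of channels (single-matrix baseline).

    Labels are prefixed with the source channel name; subject ordering must
    already agree (id-keyed alignment happens upstream).
    """
    if not channels:
        raise ValueError("no channels to concatenate")
    n = channels[0].n_subjects
    for ch in channels:
        if ch.n_subjects != n:
            raise ValueError(f"channel {ch.name!r} has {ch.n_subjects} rows, expected {n}")
    ids0 = channels[0].subject_ids
    for ch in channels[1:]:
        if ids0 is not None and ch.subject_ids is not None and not np.array_equal(ids0, ch.subject_ids):
            raise ValueError("subject ids differ across channels")
    values = np.concatenate([ch.values for ch in channels], axis=1)
    labels = [f"{ch.name}:{l}" for ch in channels for l in ch.feature_labels]
    return FeatureChannel(name=name, values=values, feature_labels=labels, subject_ids=ids0)
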