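"""Core in-memory containers shared across the pipeline.

A *channel* is one modality's subjects × features matrix (e.g. the vectorized
upper triangle of a functional connectome, regional cortical thickness, a
local-connectome fingerprint). All channels of a study share one subject
ordering; alignment is always id-keyed upstream, never positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureChannel", "ResponseVector", "validate_subject_meta"]

#: columns every subject-metadata table must carry
META_COLUMNS = ("subject_id", "family_group", "intracranial_volume", "age", "sex", "education")


@dataclass
class FeatureChannel:
    """One modality's feature matrix with labels and optional feature grouping.

    Parameters
    ----------
    name
        Short channel label (``"fc"``, ``"thickness"``, ...).
    values
        ``(n_subjects, n_features)`` float array, no missing values.
    feature_labels
        One label per column.
    subject_ids
        Optional per-row subject identifiers (kept as strings).
    feature_groups
        Optional mapping feature label -> group label (tract, region,
        network), used when summarizing loadings per anatomical group.
    """

    name: str
    values: np.ndarray
    feature_labels: list[str] = field(default=None)  # type: ignore[assignment]
    subject_ids: np.ndarray | None = None
    feature_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"channel {self.name!r}: values must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError(f"channel {self.name!r}: non-finite values present")
        if self.feature_labels is None:
            self.feature_labels = [f"{self.name}_{j}" for j in range(self.values.shape[1])]
        self.feature_labels = [str(l) for l in self.feature_labels]
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError(
                f"channel {self.name!r}: {len(self.feature_labels)} labels for "
                f"{self.values.shape[1]} columns"
            )
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids, dtype=str)
            if self.subject_ids.shape[0] != self.values.shape[0]:
                raise ValueError(f"channel {self.name!r}: subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureChannel":
        """Row-subset (copy) preserving labels and grouping."""
        ids = None if self.subject_ids is None else self.subject_ids[rows]
        return FeatureChannel(
            name=self.name,
            values=self.values[rows],
            feature_labels=list(self.feature_labels),
            subject_ids=ids,
            feature_groups=self.feature_groups,
        )

    def to_frame(self) -> pd.DataFrame:
        idx = self.subject_ids if self.subject_ids is not None else np.arange(self.n_subjects)
        return pd.DataFrame(self.values, index=pd.Index(idx, name="subject_id"),
                            columns=self.feature_labels)


@dataclass
class ResponseVector:
    """A continuous per-subject score (the regression response)."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError(f"response {self.name!r}: non-finite values present")

    def __len__(self) -> int:
        return self.values.size


def validate_subject_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a subject-metadata table (family group, ICV, demographics).

    Every subject must carry exactly one family-group label (twins share
    theirs), a positive intracranial volume, and complete age / sex /
    education entries; subjects with missing values are the caller's problem
    to drop *before* validation, mirroring cohort-assembly practice.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta[list(META_COLUMNS)].isna().any().any():
        raise ValueError("metadata contains missing values")
    if (meta["intracranial_volume"] <= 0).any():
        raise ValueError("intracranial_volume must be positive")
    if meta["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in metadata")
    return meta
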