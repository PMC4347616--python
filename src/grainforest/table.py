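"""Labeled feature tables with per-example grain identifiers.

A *grain* is the coarsest level of an implicit data hierarchy over which a
feature value is constant — for variant prioritization tables, typically the
gene. All examples sharing a grain identifier form one partition; partitions
are the unit of leakage control for both in-bag sampling and train/test
splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GrainTable", "Partitioning", "partition_by_grain"]


@dataclass
class GrainTable:
    """A labeled feature matrix where every example carries a grain identifier.

    Parameters
    ----------
    features : ndarray of shape (n, d)
        Real-valued feature matrix.
    labels : ndarray of shape (n,)
        Binary labels; 0 = control, 1 = positive.
    grain_ids : ndarray of shape (n,)
        Opaque identifier of the coarsest-grain partition each example
        belongs to (e.g. a gene symbol, or the value of a grain-defining
        feature column).
    feature_names : list of str
        Column names, length d.
    """

    features: np.ndarray
    labels: np.ndarray
    grain_ids: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features.reshape(-1, 1)
        self.labels = np.asarray(self.labels, dtype=int)
        self.grain_ids = np.asarray(self.grain_ids)
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError("table must have at least one example and one feature")
        if self.labels.shape != (n,):
            raise ValueError(f"labels must have shape ({n},), got {self.labels.shape}")
        if self.grain_ids.shape != (n,):
            raise ValueError(f"grain_ids must have shape ({n},), got {self.grain_ids.shape}")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal number of feature columns")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "GrainTable":
        """Row-subset (or multiset, if indices repeat) of the table."""
        idx = np.asarray(indices, dtype=np.intp)
        return GrainTable(
            features=self.features[idx],
            labels=self.labels[idx],
            grain_ids=self.grain_ids[idx],
            feature_names=list(self.feature_names),
        )

    def to_dataframe(self, label_col: str = "label", grain_col: str = "grain_id") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, grain_col, self.grain_ids)
        df.insert(0, label_col, self.labels)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        grain_col: str = "grain_id",
    ) -> "GrainTable":
        for col in (label_col, grain_col):
            if col not in df.columns:
                raise ValueError(f"required column {col!r} missing")
        feature_cols = [c for c in df.columns if c not in (label_col, grain_col)]
        return cls(
            features=df[feature_cols].to_numpy(dtype=float),
            labels=df[label_col].to_numpy(),
            grain_ids=df[grain_col].to_numpy(),
            feature_names=feature_cols,
        )


@dataclass
class Partitioning:
    """Grouping of example indices by distinct grain value.

    ``groups`` maps each grain value to the ordered array of example indices
    carrying it; groups are disjoint and jointly cover all n indices.
    """

    groups: dict
    n: int

    @property
    def p(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(v) for v in self.groups.values()], dtype=int)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("partitioning must contain at least one group")
        all_idx = np.concatenate([np.asarray(v) for v in self.groups.values()])
        if len(all_idx) != self.n or len(np.unique(all_idx)) != self.n:
            raise ValueError("groups must be disjoint and cover all indices")


def partition_by_grain(table: GrainTable) -> Partitioning:
    """Stratify example indices by the distinct values of the grain identifier.

    Groups are ordered by sorted grain value so the partitioning is
    deterministic for a given table.
    """
    values, inverse = np.unique(table.grain_ids, return_inverse=True)
    groups = {}
    for j, v in enumerate(values):
        groups[v.item() if hasattr(v, "item") else v] = np.flatnonzero(inverse == j)
    return Partitioning(groups=groups, n=table.n)
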