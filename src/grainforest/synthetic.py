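"""Synthetic benchmark generator for the grain-overfitting study.

The generated table has seven real-valued features and a balanced binary
label:

* ``u1..u3`` — non-informative, Uniform(0,1) independent of the class;
* ``g1..g3`` — informative, conditional Gaussians whose mean depends on the
  class and whose spread differs per feature, giving three levels of class
  overlap;
* ``grain``  — a non-informative auxiliary feature taking one of a small
  number of distinct Uniform(0,1) values. Each distinct value covers exactly
  ``partition_size`` examples of a single class (at zero noise), so the
  feature acts as a class-pure identifier of a group of examples — exactly
  the structure of a coarse-grained gene-level score.

A flexible learner trained carelessly on such a table memorises the grain
values instead of the informative features; controlling ``partition_size``
and the grain-level label noise isolates that effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import GrainTable

__all__ = [
    "SyntheticConfig",
    "BaseFeatures",
    "generate_base_features",
    "attach_grain_feature",
    "inject_grain_noise",
    "make_dataset",
    "DEFAULT_INFORMATIVE_PARAMS",
]

#: (mean_class0, mean_class1, sd) for each informative feature. The shared
#: mean shift with three spreads yields strong / medium / weak separation.
DEFAULT_INFORMATIVE_PARAMS: tuple[tuple[float, float, float], ...] = (
    (0.4, 0.6, 0.05),
    (0.4, 0.6, 0.10),
    (0.4, 0.6, 0.20),
)

FEATURE_NAMES = ["u1", "u2", "u3", "g1", "g2", "g3", "grain"]


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic benchmark table.

    ``partition_size`` (|P|) is the number of same-class examples sharing
    each distinct grain value and must divide ``n_per_class``;
    ``noise_level`` is the fraction of each partition whose grain value is
    swapped with a partition of the opposite class.
    """

    n_per_class: int = 2000
    partition_size: int = 1
    noise_level: float = 0.0
    informative_params: tuple = DEFAULT_INFORMATIVE_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.partition_size < 1 or self.n_per_class % self.partition_size != 0:
            raise ValueError(
                f"partition_size={self.partition_size} must divide n_per_class={self.n_per_class}"
            )
        if not 0.0 <= self.noise_level <= 0.5:
            raise ValueError("noise_level must lie in [0, 0.5]")

    def to_dict(self) -> dict:
        return {
            "n_per_class": self.n_per_class,
            "partition_size": self.partition_size,
            "noise_level": self.noise_level,
            "informative_params": [list(p) for p in self.informative_params],
            "seed": self.seed,
        }


@dataclass
class BaseFeatures:
    """The six grain-free columns (u1..u3, g1..g3) plus labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: FEATURE_NAMES[:6])


def generate_base_features(
    n_per_class: int,
    params: tuple = DEFAULT_INFORMATIVE_PARAMS,
    rng: np.random.Generator | None = None,
) -> BaseFeatures:
    """Generate the class-balanced table of 3 uniform + 3 conditional-Gaussian features."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    for m0, m1, sd in params:
        if sd <= 0:
            raise ValueError("informative feature sd must be positive")
    if rng is None:
        rng = np.random.default_rng()
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    X = np.empty((n, 3 + len(params)))
    X[:, :3] = rng.uniform(0.0, 1.0, size=(n, 3))
    for j, (m0, m1, sd) in enumerate(params):
        means = np.where(labels == 1, m1, m0)
        X[:, 3 + j] = rng.normal(means, sd)
    names = FEATURE_NAMES[:3] + [f"g{j + 1}" for j in range(len(params))]
    return BaseFeatures(features=X, labels=labels, feature_names=names)


def _distinct_uniform(n_values: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform(0,1) draws, redrawn on the (measure-zero) event of a collision."""
    vals = rng.uniform(0.0, 1.0, size=n_values)
    while len(np.unique(vals)) < n_values:  # pragma: no cover - collisions are astronomically rare
        vals = rng.uniform(0.0, 1.0, size=n_values)
    return vals


def attach_grain_feature(
    base: BaseFeatures,
    partition_size: int,
    rng: np.random.Generator,
) -> GrainTable:
    """Append the grain-defining auxiliary feature as a new last column.

    Per class, ``n_per_class / partition_size`` distinct Uniform(0,1) values
    are drawn and each assigned to exactly ``partition_size`` examples of
    that class; the value doubles as the example's grain identifier. At zero
    noise every grain value is therefore class-pure.
    """
    labels = base.labels
    n_per_class = int((labels == 0).sum())
    if (labels == 1).sum() != n_per_class:
        raise ValueError("base table must be class-balanced")
    if partition_size < 1 or n_per_class % partition_size != 0:
        raise ValueError(f"partition_size={partition_size} must divide n_per_class={n_per_class}")
    values_per_class = n_per_class // partition_size
    all_values = _distinct_uniform(2 * values_per_class, rng)
    grain = np.empty(len(labels))
    for c, vals in ((0, all_values[:values_per_class]), (1, all_values[values_per_class:])):
        idx = np.flatnonzero(labels == c)
        grain[idx] = np.repeat(vals, partition_size)
    features = np.column_stack([base.features, grain])
    return GrainTable(
        features=features,
        labels=labels.copy(),
        grain_ids=grain.copy(),
        feature_names=base.feature_names + ["grain"],
    )


def inject_grain_noise(
    table: GrainTable,
    noise_level: float,
    rng: np.random.Generator,
) -> GrainTable:
    """Swap grain values between class-paired partitions.

    Class-0 partitions are paired 1:1 at random with class-1 partitions;
    within each pair, ``k = round(noise_level * partition_size)`` examples on
    each side exchange grain-feature values (labels are untouched; the grain
    identifier follows the feature value). After injection each grain value
    covers a ``1 - noise_level`` majority of its original class.
    """
    if not 0.0 <= noise_level <= 0.5:
        raise ValueError("noise_level must lie in [0, 0.5]")
    if noise_level == 0.0:
        return GrainTable(
            features=table.features.copy(),
            labels=table.labels.copy(),
            grain_ids=table.grain_ids.copy(),
            feature_names=list(table.feature_names),
        )
    grain_col = table.feature_names.index("grain") if "grain" in table.feature_names else table.d - 1
    features = table.features.copy()
    grain_ids = table.grain_ids.copy()
    vals0 = np.unique(grain_ids[table.labels == 0])
    vals1 = np.unique(grain_ids[table.labels == 1])
    if len(vals0) != len(vals1):
        raise ValueError("partitions are not pairable 1:1 across classes")
    sizes = np.unique([np.sum(grain_ids == v) for v in np.concatenate([vals0, vals1])])
    if len(sizes) != 1:
        raise ValueError("noise injection requires equal-size partitions")
    partition_size = int(sizes[0])
    k = int(np.floor(noise_level * partition_size + 0.5))  # round half-up
    if k < 1:
        raise ValueError(
            f"noise_level={noise_level} with partition_size={partition_size} "
            "rounds to zero swaps; use a larger partition"
        )
    paired = rng.permutation(vals1)
    for v0, v1 in zip(vals0, paired):
        idx0 = np.flatnonzero(grain_ids == v0)
        idx1 = np.flatnonzero(grain_ids == v1)
        swap0 = rng.choice(idx0, size=k, replace=False)
        swap1 = rng.choice(idx1, size=k, replace=False)
        features[swap0, grain_col] = v1
        features[swap1, grain_col] = v0
        grain_ids[swap0] = v1
        grain_ids[swap1] = v0
    return GrainTable(
        features=features,
        labels=table.labels.copy(),
        grain_ids=grain_ids,
        feature_names=list(table.feature_names),
    )


def make_dataset(config: SyntheticConfig) -> GrainTable:
    """Generate a full 7-feature benchmark table from a config.

    Columns are ordered [u1, u2, u3, g1, g2, g3, grain]; the whole table is
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base = generate_base_features(config.n_per_class, config.informative_params, rng)
    table = attach_grain_feature(base, config.partition_size, rng)
    if config.noise_level > 0:
        table = inject_grain_noise(table, config.noise_level, rng)
    return table
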