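"""Grain-aware splitting and the two synthetic benchmark experiments.

Experiment 1 (bin size): sweep the grain partition size |P| and measure how
test performance of the three sampling schemes evolves; the standard
bootstrap degrades with growing |P| as trees overfit the grain feature,
hierarchical sampling stays flat. OOB permutation importance is harvested
from the standard-scheme forest to watch the grain feature displace the
informative ones.

Experiment 2 (label noise): at fixed partition sizes, swap a fraction of
grain values between class-paired partitions. Noise implicitly shrinks
partitions, so the standard scheme's bias declines as noise grows while the
hierarchical scheme is flat throughout.

Every repetition regenerates the grain feature on top of a fixed base table
and makes a fresh grain-aware train/test split; all randomness descends from
the grid's master seed, so the full record list is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import (
    METRIC_DISPLAY,
    METRIC_ORDER,
    MetricSet,
    confusion,
    metric_set,
    wilcoxon_bonferroni,
)
from .forest import ForestConfig, GrainForestModel
from .synthetic import DEFAULT_INFORMATIVE_PARAMS, BaseFeatures, attach_grain_feature, generate_base_features, inject_grain_noise
from .table import GrainTable, partition_by_grain

__all__ = [
    "ExperimentGrid",
    "RunRecord",
    "grain_split",
    "run_experiment_binsize",
    "run_experiment_noise",
    "compare_schemes",
    "records_to_dataframe",
    "FULL_GRID",
    "SCALED_GRID",
]

logger = logging.getLogger(__name__)

FULL_PARTITION_SIZES = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)
FULL_NOISE_LEVELS = tuple(round(0.05 * i, 2) for i in range(1, 11))
FULL_NOISE_SIZES = (20, 50, 100, 200, 500, 1000)


@dataclass
class ExperimentGrid:
    """Factorial design of a synthetic benchmark run."""

    partition_sizes: tuple = FULL_PARTITION_SIZES
    noise_levels: tuple = FULL_NOISE_LEVELS
    n_reps: int = 100
    schemes: tuple = ("standard", "stratified", "hierarchical")
    n_trees: int = 1000
    m_try: int | None = None
    n_per_class: int = 2000
    informative_params: tuple = DEFAULT_INFORMATIVE_PARAMS
    train_fraction: float = 0.5
    seed: int = 0
    harvest_importance: bool = True
    importance_schemes: tuple = ("standard",)

    def __post_init__(self) -> None:
        if not self.partition_sizes or not self.schemes:
            raise ValueError("partition_sizes and schemes must be non-empty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


#: Full-fidelity grid of the benchmark.
FULL_GRID = ExperimentGrid()

#: Scaled-down preset exercising the same trends in minutes.
SCALED_GRID = ExperimentGrid(
    partition_sizes=(1, 100, 500),
    noise_levels=(0.05, 0.25, 0.45),
    n_reps=10,
    n_trees=200,
)


@dataclass
class RunRecord:
    """Outcome of one scheme on one grid cell repetition."""

    scheme: str
    partition_size: int
    noise_level: float
    repetition: int
    metrics: MetricSet
    importance: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)


# ----------------------------------------------------------------- splitting

def grain_split(table: GrainTable, train_fraction: float, rng: np.random.Generator):
    """Split a table along distinct grain values; no value spans both sides.

    Grain values are stratified by the majority class of their partition
    (ties count as class 1) and, within each stratum, ``floor(fraction *
    count)`` values go to the training side. A guard moves one value when
    the floor would leave either side empty.

    Returns ``(train, test)`` GrainTables preserving row order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    part = partition_by_grain(table)
    if part.p < 2:
        raise ValueError("grain split needs at least two distinct grain values")
    values = list(part.groups.keys())
    cls = np.array([1 if table.labels[idx].mean() >= 0.5 else 0 for idx in part.groups.values()])
    train_values: list = []
    test_values: list = []
    for c in (0, 1):
        stratum = [v for v, k in zip(values, cls) if k == c]
        if not stratum:
            continue
        k_train = int(np.floor(train_fraction * len(stratum)))
        picked = rng.choice(len(stratum), size=k_train, replace=False)
        picked_set = set(picked.tolist())
        for i, v in enumerate(stratum):
            (train_values if i in picked_set else test_values).append(v)
    if not train_values:
        mover = test_values[int(rng.integers(len(test_values)))]
        test_values.remove(mover)
        train_values.append(mover)
    if not test_values:
        mover = train_values[int(rng.integers(len(train_values)))]
        train_values.remove(mover)
        test_values.append(mover)
    train_idx = np.sort(np.concatenate([part.groups[v] for v in train_values]))
    test_idx = np.sort(np.concatenate([part.groups[v] for v in test_values]))
    return table.subset(train_idx), table.subset(test_idx)


# ------------------------------------------------------------------- running

def _cell_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))


def _run_cell(
    train: GrainTable,
    test: GrainTable,
    grid: ExperimentGrid,
    scheme: str,
    forest_seed: int,
    imp_rng: np.random.Generator,
    partition_size: int,
    noise_level: float,
    rep: int,
) -> RunRecord:
    cfg = ForestConfig(n_trees=grid.n_trees, m_try=grid.m_try, scheme=scheme, seed=forest_seed)
    results = GrainForestModel(train, cfg).fit()
    scores = results.predict_scores(test.features)
    preds = (scores >= 0.5).astype(int)
    metrics = metric_set(confusion(test.labels, preds), scores, test.labels)
    importance = None
    if grid.harvest_importance and scheme in grid.importance_schemes:
        importance = results.oob_importance(rng=imp_rng)
    return RunRecord(
        scheme=scheme,
        partition_size=partition_size,
        noise_level=noise_level,
        repetition=rep,
        metrics=metrics,
        importance=importance,
        feature_names=list(train.feature_names),
    )


def _base_table(grid: ExperimentGrid) -> BaseFeatures:
    rng = np.random.default_rng(_cell_seed(grid.seed, 0))
    return generate_base_features(grid.n_per_class, grid.informative_params, rng)


def run_experiment_binsize(grid: ExperimentGrid) -> list[RunRecord]:
    """Partition-size sweep: fresh grain feature and split per repetition."""
    base = _base_table(grid)
    records: list[RunRecord] = []
    for si, size in enumerate(grid.partition_sizes):
        for rep in range(grid.n_reps):
            ss = _cell_seed(grid.seed, 1, si, rep)
            rng = np.random.default_rng(ss)
            table = attach_grain_feature(base, size, rng)
            train, test = grain_split(table, grid.train_fraction, rng)
            base_seed = int(ss.generate_state(4)[3] % (2**31 - 8))
            for ki, scheme in enumerate(grid.schemes):
                rec = _run_cell(
                    train, test, grid, scheme, base_seed + ki,
                    np.random.default_rng(ss.spawn(1)[0]), size, 0.0, rep,
                )
                records.append(rec)
            logger.info("binsize |P|=%d rep %d done", size, rep)
    return records


def run_experiment_noise(grid: ExperimentGrid) -> list[RunRecord]:
    """Noise x partition-size factorial; sizes below 20 are rejected."""
    if min(grid.partition_sizes) < 20:
        raise ValueError("noise experiment requires partition sizes >= 20")
    base = _base_table(grid)
    records: list[RunRecord] = []
    for si, size in enumerate(grid.partition_sizes):
        for ni, noise in enumerate(grid.noise_levels):
            for rep in range(grid.n_reps):
                ss = _cell_seed(grid.seed, 2, si, ni, rep)
                rng = np.random.default_rng(ss)
                table = attach_grain_feature(base, size, rng)
                table = inject_grain_noise(table, noise, rng)
                train, test = grain_split(table, grid.train_fraction, rng)
                base_seed = int(ss.generate_state(4)[3] % (2**31 - 8))
                for ki, scheme in enumerate(grid.schemes):
                    rec = _run_cell(
                        train, test, grid, scheme, base_seed + ki,
                        np.random.default_rng(ss.spawn(1)[0]), size, noise, rep,
                    )
                    records.append(rec)
                logger.info("noise |P|=%d x=%.2f rep %d done", size, noise, rep)
    return records


# ----------------------------------------------------------------- analysis

def records_to_dataframe(records: list[RunRecord]) -> pd.DataFrame:
    """One row per RunRecord: design cell, metrics, per-feature importance."""
    rows = []
    for r in records:
        row = {
            "scheme": r.scheme,
            "partition_size": r.partition_size,
            "noise_level": r.noise_level,
            "repetition": r.repetition,
        }
        row.update(r.metrics.as_dict())
        if r.importance is not None:
            for name, value in zip(r.feature_names, r.importance):
                row[f"imp_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def compare_schemes(
    records: list[RunRecord],
    scheme_a: str | None = None,
    scheme_b: str | None = None,
    metrics: list[str] = METRIC_ORDER,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired per-metric comparison of exactly two schemes.

    Records are paired on (partition_size, noise_level, repetition); each
    metric is tested with the Wilcoxon signed-rank test and Bonferroni
    correction with m = number of metrics. Returns a table listing, per
    metric, the two means, which scheme is larger, and the adjusted p.
    """
    schemes = sorted({r.scheme for r in records})
    if scheme_a is None or scheme_b is None:
        if len(schemes) != 2:
            raise ValueError(f"records contain schemes {schemes}; specify scheme_a/scheme_b")
        scheme_a, scheme_b = schemes
    by_cell: dict = {}
    for r in records:
        if r.scheme not in (scheme_a, scheme_b):
            continue
        by_cell.setdefault((r.partition_size, r.noise_level, r.repetition), {})[r.scheme] = r
    pairs = []
    for key, cell in sorted(by_cell.items()):
        if set(cell) != {scheme_a, scheme_b}:
            raise ValueError(f"unpaired repetition at cell {key}")
        pairs.append((cell[scheme_a], cell[scheme_b]))
    if not pairs:
        raise ValueError("no paired records")
    paired = {
        m: (
            np.array([getattr(a.metrics, m) for a, _ in pairs]),
            np.array([getattr(b.metrics, m) for _, b in pairs]),
        )
        for m in metrics
    }
    tests = wilcoxon_bonferroni(paired, n_comparisons=len(metrics), alpha=alpha)
    rows = []
    for m in metrics:
        a, b = paired[m]
        rows.append(
            {
                "metric": METRIC_DISPLAY.get(m, m),
                f"mean_{scheme_a}": a.mean(),
                f"mean_{scheme_b}": b.mean(),
                "larger": scheme_a if a.mean() > b.mean() else (scheme_b if b.mean() > a.mean() else "tie"),
                "statistic": tests[m]["statistic"],
                "p_raw": tests[m]["p_raw"],
                "p_adjusted": tests[m]["p_adjusted"],
                "significant": tests[m]["significant"],
            }
        )
    return pd.DataFrame(rows)


def scaled_grid(**overrides) -> ExperimentGrid:
    """The scaled-down preset with optional field overrides."""
    return replace(SCALED_GRID, **overrides)
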