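"""Random forest with grain-aware in-bag sampling.

Organised as a model / results pair: :class:`GrainForestModel` holds the
training table and configuration; its :meth:`~GrainForestModel.fit` returns a
:class:`GrainForestResults` carrying the trained trees, the per-tree in-bag
log, prediction, out-of-bag permutation importance and a ``summary()`` table.

Trees are unpruned CART learners (Gini impurity) examining ``m_try`` randomly
chosen candidate features per split, grown to purity; each tree is trained on
exactly the in-bag sample drawn by the configured scheme — the learner itself
never resamples. The ensemble scores an example as the fraction of trees that
vote class 1 (an unweighted hard vote), so scores are multiples of
``1/n_trees``; the default decision threshold is 0.5 with ties going to
class 1, which favours recall in a prioritization setting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .sampling import SCHEMES, draw_inbag
from .table import GrainTable, Partitioning, partition_by_grain

__all__ = [
    "ForestConfig",
    "GrainForestModel",
    "GrainForestResults",
    "train_forest",
    "predict_scores",
    "oob_permutation_importance",
    "load_forest",
]


@dataclass
class ForestConfig:
    """Forest hyper-parameters.

    Parameters
    ----------
    n_trees : int
        Ensemble size t; default 1000.
    m_try : int or None
        Number of candidate features examined at each split (M). ``None``
        resolves to ``floor(sqrt(d))`` at fit time, the customary
        classification default.
    scheme : {"standard", "stratified", "hierarchical"}
        In-bag sampling scheme.
    seed : int
        Master seed; spawns independent per-tree streams, so results do not
        depend on the order trees are built in.
    """

    n_trees: int = 1000
    m_try: int | None = None
    scheme: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.m_try is not None and self.m_try < 1:
            raise ValueError("m_try must be positive")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")

    def resolve_m_try(self, d: int) -> int:
        m = self.m_try if self.m_try is not None else max(1, math.floor(math.sqrt(d)))
        if m > d:
            raise ValueError(f"m_try={m} exceeds number of features d={d}")
        return m

    def to_dict(self) -> dict:
        return {"n_trees": self.n_trees, "m_try": self.m_try, "scheme": self.scheme, "seed": self.seed}


class _ArrayTree:
    """A decision tree deserialised to plain arrays; prediction only.

    Mirrors the CART routing rule (go left when x[feature] <= threshold).
    """

    def __init__(self, children_left, children_right, feature, threshold, pred):
        self.children_left = np.asarray(children_left, dtype=np.intp)
        self.children_right = np.asarray(children_right, dtype=np.intp)
        self.feature = np.asarray(feature, dtype=np.intp)
        self.threshold = np.asarray(threshold, dtype=float)
        self.pred = np.asarray(pred, dtype=int)

    @classmethod
    def from_sklearn(cls, est: DecisionTreeClassifier) -> "_ArrayTree":
        t = est.tree_
        node_pred = est.classes_[t.value[:, 0, :].argmax(axis=1)]
        return cls(t.children_left, t.children_right, t.feature, t.threshold, node_pred)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.intp)
        while True:
            inner = self.children_left[node] >= 0
            if not inner.any():
                break
            cur = node[inner]
            go_left = X[inner, self.feature[cur]] <= self.threshold[cur]
            node[inner] = np.where(go_left, self.children_left[cur], self.children_right[cur])
        return self.pred[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "pred": self.pred.tolist(),
        }


class GrainForestModel:
    """Random forest classifier specification bound to a training table.

    Parameters
    ----------
    table : GrainTable
        Training data; both classes must be present.
    config : ForestConfig
        Ensemble size, split width, sampling scheme and master seed.

    Examples
    --------
    >>> model = GrainForestModel(table, ForestConfig(scheme="hierarchical", seed=7))
    >>> results = model.fit()
    >>> scores = results.predict_scores(test.features)
    """

    def __init__(self, table: GrainTable, config: ForestConfig | None = None):
        self.table = table
        self.config = config if config is not None else ForestConfig()
        if len(np.unique(table.labels)) < 2:
            raise ValueError("training table must contain both classes")
        self.partitioning: Partitioning | None = None
        if self.config.scheme in ("stratified", "hierarchical"):
            self.partitioning = partition_by_grain(table)
            if self.config.scheme == "hierarchical" and self.partitioning.p < 2:
                raise ValueError("hierarchical sampling needs at least two grain partitions")

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label", grain_col: str = "grain_id", **config_kwargs):
        table = GrainTable.from_dataframe(df, label_col=label_col, grain_col=grain_col)
        return cls(table, ForestConfig(**config_kwargs))

    def fit(self) -> "GrainForestResults":
        """Train the ensemble: draw one fresh in-bag sample per tree, learn a tree on it."""
        cfg = self.config
        table = self.table
        m_try = cfg.resolve_m_try(table.d)
        master = np.random.SeedSequence(cfg.seed)
        trees: list = []
        inbag_log: list[np.ndarray] = []
        for child in master.spawn(cfg.n_trees):
            rng = np.random.default_rng(child)
            inbag = draw_inbag(cfg.scheme, table.n, self.partitioning, rng)
            est = DecisionTreeClassifier(
                criterion="gini",
                max_features=m_try,
                random_state=int(child.generate_state(1)[0] % (2**31)),
            )
            est.fit(table.features[inbag], table.labels[inbag])
            trees.append(est)
            inbag_log.append(np.sort(inbag))
        return GrainForestResults(model=self, trees=trees, inbag_log=inbag_log, m_try=m_try)


@dataclass
class GrainForestResults:
    """A fitted grain-aware random forest."""

    model: GrainForestModel
    trees: list
    inbag_log: list[np.ndarray]
    m_try: int
    _oob_cache: dict = field(default_factory=dict, repr=False)

    @property
    def config(self) -> ForestConfig:
        return self.model.config

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def feature_names(self) -> list[str]:
        return self.model.table.feature_names

    # ------------------------------------------------------------------ scoring
    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting class 1 for each row of X, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.model.table.d:
            raise ValueError(
                f"feature dimension mismatch: model trained on d={self.model.table.d}, got {X.shape[1]}"
            )
        votes = np.zeros(X.shape[0], dtype=float)
        for tree in self.trees:
            votes += tree.predict(X)
        return votes / self.n_trees

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Hard labels at the given score threshold; ties go to class 1."""
        return (self.predict_scores(X) >= threshold).astype(int)

    # ------------------------------------------------------------- out-of-bag
    def oob_masks(self) -> np.ndarray:
        """Boolean (n_trees, n) matrix; True where an example is out-of-bag."""
        n = self.model.table.n
        masks = np.ones((self.n_trees, n), dtype=bool)
        for i, inbag in enumerate(self.inbag_log):
            masks[i, inbag] = False
        return masks

    def oob_error(self) -> float:
        """Mean per-tree misclassification rate on out-of-bag examples."""
        table = self.model.table
        masks = self.oob_masks()
        errs = []
        for tree, mask in zip(self.trees, masks):
            if not mask.any():
                continue
            errs.append(np.mean(tree.predict(table.features[mask]) != table.labels[mask]))
        return float(np.mean(errs)) if errs else float("nan")

    def oob_importance(self, rng: np.random.Generator | None = None, n_perm: int = 1) -> np.ndarray:
        """Out-of-bag permutation importance for each feature.

        For every tree, the increase in out-of-bag misclassification error
        after shuffling a feature's values among that tree's OOB examples,
        averaged over ``n_perm`` permutations and then over trees. A feature
        the forest ignores scores ~0; a feature acting as an identifier of
        the training grains scores high while generalising features decline.
        """
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        table = self.model.table
        masks = self.oob_masks()
        never_oob = ~masks.any(axis=0)
        if never_oob.any():
            warnings.warn(
                f"{int(never_oob.sum())} example(s) never out-of-bag; they cannot "
                "contribute to the importance estimate",
                stacklevel=2,
            )
        deltas = np.zeros((self.n_trees, table.d))
        used = np.zeros(self.n_trees, dtype=bool)
        for i, (tree, mask) in enumerate(zip(self.trees, masks)):
            if not mask.any():
                continue
            used[i] = True
            Xo = table.features[mask]
            yo = table.labels[mask]
            base_err = np.mean(tree.predict(Xo) != yo)
            for f in range(table.d):
                perm_err = 0.0
                Xp = Xo.copy()
                for _ in range(n_perm):
                    Xp[:, f] = rng.permutation(Xo[:, f])
                    perm_err += np.mean(tree.predict(Xp) != yo)
                deltas[i, f] = perm_err / n_perm - base_err
        if not used.any():
            raise ValueError("no tree has out-of-bag examples; importance undefined")
        return deltas[used].mean(axis=0)

    # ---------------------------------------------------------------- reporting
    def summary(self) -> str:
        cfg = self.config
        table = self.model.table
        bag_sizes = np.array([len(b) for b in self.inbag_log])
        train_acc = np.mean(self.predict(table.features) == table.labels)
        lines = [
            "Grain-aware Random Forest Results",
            "=" * 41,
            f"sampling scheme:       {cfg.scheme}",
            f"trees:                 {self.n_trees}",
            f"m_try:                 {self.m_try}",
            f"seed:                  {cfg.seed}",
            f"training examples:     {table.n}  (d = {table.d})",
            f"grain partitions:      {self.model.partitioning.p if self.model.partitioning else table.n}",
            f"in-bag size:           {bag_sizes.min()}..{bag_sizes.max()}",
            f"training accuracy:     {train_acc:.4f}",
            f"out-of-bag error:      {self.oob_error():.4f}",
        ]
        return "\n".join(lines)

    # -------------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Serialise config, seed and tree structures to a single JSON file."""
        payload = {
            "format": "grainforest-model",
            "version": 1,
            "config": self.config.to_dict(),
            "m_try": self.m_try,
            "feature_names": self.feature_names,
            "trees": [
                (t if isinstance(t, _ArrayTree) else _ArrayTree.from_sklearn(t)).to_dict()
                for t in self.trees
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


class _LoadedModel:
    """Minimal stand-in for GrainForestModel behind a deserialised results object."""

    def __init__(self, config: ForestConfig, feature_names: list[str]):
        self.config = config
        self.partitioning = None
        self.table = _LoadedTableStub(feature_names)


class _LoadedTableStub:
    def __init__(self, feature_names: list[str]):
        self.feature_names = feature_names
        self.d = len(feature_names)


def load_forest(path) -> GrainForestResults:
    """Load a forest saved with :meth:`GrainForestResults.save`.

    The loaded object predicts and scores; operations needing the training
    table (OOB error/importance, summary) are unavailable.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "grainforest-model":
        raise ValueError(f"{path} is not a grainforest model file")
    config = ForestConfig(**payload["config"])
    trees = [_ArrayTree(**t) for t in payload["trees"]]
    model = _LoadedModel(config, payload["feature_names"])
    return GrainForestResults(model=model, trees=trees, inbag_log=[], m_try=payload["m_try"])


# --------------------------------------------------------------- functional API

def train_forest(table: GrainTable, config: ForestConfig) -> GrainForestResults:
    """Train a forest on ``table`` under ``config`` (model/results shorthand)."""
    return GrainForestModel(table, config).fit()


def predict_scores(forest: GrainForestResults, X: np.ndarray) -> np.ndarray:
    return forest.predict_scores(X)


def oob_permutation_importance(
    forest: GrainForestResults,
    table: GrainTable | None = None,
    rng: np.random.Generator | None = None,
    n_perm: int = 1,
) -> np.ndarray:
    """Out-of-bag permutation importance profile (see ``oob_importance``)."""
    if table is not None and table is not forest.model.table:
        raise ValueError("importance is defined on the forest's own training table")
    return forest.oob_importance(rng=rng, n_perm=n_perm)
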