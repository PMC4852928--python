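"""Phase-2 wrapper feature selection: a subsampled ensemble of Gini trees.

Each tree is grown on a uniform random two-thirds subsample *without
replacement*; the held-out third estimates misclassification (out-of-bag
accuracy by majority vote over the trees for which a patient was held out).
Splits are threshold tests ``count >= t`` chosen to maximise the weighted
Gini impurity decrease over a random feature subset, and a feature's
importance is its summed impurity decrease (weighted by the fraction of
training samples reaching the node), averaged over trees — the mean-decrease-
in-impurity ranking used to shortlist predictors before rule induction.

The trees are implemented natively so split enumeration, importance
accounting and tie-breaking are fully specified: candidate thresholds are
midpoints between consecutive distinct observed values, and ties in impurity
decrease break by (lower threshold, feature name).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError
from .events import FeatureMatrix


def gini_impurity(class_counts: tuple[int, int]) -> float:
    """Gini impurity 1 - p1^2 - p2^2 of a two-class node; in [0, 0.5]."""
    n1, n2 = class_counts
    if n1 < 0 or n2 < 0:
        raise ValueError("negative class counts")
    n = n1 + n2
    if n == 0:
        raise DegenerateInputError("Gini impurity of an empty node is undefined")
    p1, p2 = n1 / n, n2 / n
    return 1.0 - p1 * p1 - p2 * p2


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble hyper-parameters.

    ``train_fraction`` defaults to 2/3 (subsampling without replacement, with
    the remaining third held out per tree).  n_trees=500, sqrt feature
    subsets, unlimited depth and min_leaf=1 are this package's defaults where
    the procedure itself fixes no value.
    """

    n_trees: int = 500
    train_fraction: float = 2 / 3
    features_per_split: int | str = "sqrt"
    max_depth: int | None = None
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if isinstance(self.features_per_split, str) and self.features_per_split != "sqrt":
            raise ConfigurationError("features_per_split must be an integer or 'sqrt'")
        if self.min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")

    def mtry(self, n_features: int) -> int:
        if self.features_per_split == "sqrt":
            return max(1, int(math.isqrt(n_features)))
        m = int(self.features_per_split)
        if not 1 <= m <= n_features:
            raise ConfigurationError("features_per_split out of range")
        return m


@dataclass
class TreeNode:
    """Internal: threshold test x[feature] >= threshold; leaf: prediction."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None   # x < threshold
    right: "TreeNode | None" = None  # x >= threshold
    prediction: bool | None = None
    n_samples: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx: np.ndarray,
    feature_names: list[str],
    min_leaf: int,
):
    """Best (decrease, threshold, feature) over candidate features.

    Returns (feature, threshold, weighted_child_impurity) or None.  Impurity
    decrease here is within-node: I(parent) - sum w_i I(child_i).  Ties break
    by (lower threshold, feature name).
    """
    n = len(y)
    n_pos = int(y.sum())
    parent_imp = gini_impurity((n_pos, n - n_pos))
    # class-symmetric integer-based impurity so that exactly-tied candidates
    # come out bit-identical; near-ties within 1e-12 are treated as ties and
    # broken by (lower threshold, feature name)
    candidates = []  # (decrease, threshold, name, feature, child_imp)
    for f in feature_idx:
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = y[order]
        cum_pos = np.cumsum(ys)
        boundary = np.nonzero(xs[:-1] != xs[1:])[0]
        if boundary.size == 0:
            continue
        sizes = boundary + 1
        ok = (sizes >= min_leaf) & (n - sizes >= min_leaf)
        boundary = boundary[ok]
        if boundary.size == 0:
            continue
        nl = boundary + 1
        nr = n - nl
        pos_l = cum_pos[boundary].astype(np.int64)
        pos_r = n_pos - pos_l
        neg_l = nl - pos_l
        neg_r = nr - pos_r
        gini_l = 1.0 - (pos_l * pos_l + neg_l * neg_l) / (nl * nl)
        gini_r = 1.0 - (pos_r * pos_r + neg_r * neg_r) / (nr * nr)
        child_imp = (nl * gini_l + nr * gini_r) / n
        decrease = parent_imp - child_imp
        thresholds = (xs[boundary] + xs[boundary + 1]) / 2.0
        name = feature_names[f]
        for i in range(len(boundary)):
            candidates.append(
                (float(decrease[i]), float(thresholds[i]), name, int(f), float(child_imp[i]))
            )
    if not candidates:
        return None
    top = max(c[0] for c in candidates)
    if top <= 1e-15:
        return None
    best = min(
        (c for c in candidates if c[0] >= top - 1e-12), key=lambda c: (c[1], c[2])
    )
    return best[3], best[1], best[4]


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    feature_names: list[str],
    config: ForestConfig,
    rng: np.random.Generator,
    importances: np.ndarray,
    n_train: int,
    depth: int = 0,
    mtry: int | None = None,
) -> TreeNode:
    n = len(idx)
    yi = y[idx]
    n_pos = int(yi.sum())
    node = TreeNode(n_samples=n)
    majority = n_pos * 2 > n or (n_pos * 2 == n)  # ties predict positive
    if (
        n_pos in (0, n)
        or n < 2 * config.min_leaf
        or (config.max_depth is not None and depth >= config.max_depth)
    ):
        node.prediction = bool(majority)
        return node
    m = mtry if mtry is not None else X.shape[1]
    cand = np.sort(rng.choice(X.shape[1], size=m, replace=False))
    found = _best_split(X[idx], yi, cand, feature_names, config.min_leaf)
    if found is None:
        node.prediction = bool(majority)
        return node
    f, t, child_imp = found
    parent_imp = gini_impurity((n_pos, n - n_pos))
    importances[f] += (n / n_train) * (parent_imp - child_imp)
    mask = X[idx, f] >= t
    node.feature = f
    node.threshold = t
    node.right = _grow_tree(
        X, y, idx[mask], feature_names, config, rng, importances, n_train, depth + 1, mtry
    )
    node.left = _grow_tree(
        X, y, idx[~mask], feature_names, config, rng, importances, n_train, depth + 1, mtry
    )
    return node


def _predict_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X), dtype=bool)
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, rows = stack.pop()
        if rows.size == 0:
            continue
        if nd.is_leaf:
            out[rows] = nd.prediction
            continue
        mask = X[rows, nd.feature] >= nd.threshold
        stack.append((nd.right, rows[mask]))
        stack.append((nd.left, rows[~mask]))
    return out


@dataclass
class RandomForest:
    """A fitted ensemble: trees plus their training subsamples."""

    trees: list[TreeNode]
    train_indices: list[np.ndarray]
    feature_names: list[str]
    config: ForestConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(X), dtype=np.int64)
        for tree in self.trees:
            votes += _predict_tree(tree, X)
        return votes * 2 >= len(self.trees)


@dataclass
class ImportanceTable:
    """Mean-decrease-in-impurity importances with deterministic ranks."""

    importances: dict[str, float]
    ranks: dict[str, int] = field(default_factory=dict)
    oob_accuracy: float = float("nan")

    def __post_init__(self):
        if not self.ranks:
            ordered = sorted(self.importances, key=lambda f: (-self.importances[f], f))
            self.ranks = {f: i + 1 for i, f in enumerate(ordered)}

    def to_frame(self) -> pd.DataFrame:
        ordered = sorted(self.ranks, key=self.ranks.get)
        return pd.DataFrame(
            {
                "feature": ordered,
                "gini_importance": [self.importances[f] for f in ordered],
                "rank": [self.ranks[f] for f in ordered],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_forest(matrix: FeatureMatrix, config: ForestConfig | None = None):
    """Fit the subsampled Gini-tree ensemble; returns (forest, ImportanceTable).

    Fixed seed gives an identical forest; OOB accuracy is the majority-vote
    accuracy over each patient's held-out trees.
    """
    config = config or ForestConfig()
    X = matrix.values
    y = matrix.y
    if y.all() or not y.any():
        raise DegenerateInputError("forest requires both classes present")
    n, p = X.shape
    n_train = max(1, round(config.train_fraction * n))
    if n_train >= n:
        n_train = n - 1
    mtry = config.mtry(p)
    rng = np.random.default_rng(config.seed)
    total_importance = np.zeros(p)
    oob_votes = np.zeros(n, dtype=np.int64)
    oob_counts = np.zeros(n, dtype=np.int64)
    trees: list[TreeNode] = []
    train_sets: list[np.ndarray] = []
    for _ in range(config.n_trees):
        idx = np.sort(rng.choice(n, size=n_train, replace=False))
        imp = np.zeros(p)
        tree = _grow_tree(X, y, idx, matrix.feature_names, config, rng, imp, n_train, mtry=mtry)
        total_importance += imp
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=True)
        if oob.size:
            pred = _predict_tree(tree, X[oob])
            oob_votes[oob] += pred
            oob_counts[oob] += 1
        trees.append(tree)
        train_sets.append(idx)
    mean_imp = total_importance / config.n_trees
    voted = oob_counts > 0
    oob_pred = oob_votes[voted] * 2 >= oob_counts[voted]
    oob_acc = float((oob_pred == y[voted]).mean()) if voted.any() else float("nan")
    table = ImportanceTable(
        importances={matrix.feature_names[j]: float(mean_imp[j]) for j in range(p)},
        oob_accuracy=oob_acc,
    )
    forest = RandomForest(trees, train_sets, list(matrix.feature_names), config)
    return forest, table


def select_top(importances: ImportanceTable, k: int) -> list[str]:
    """Top-k features by importance, ties broken by feature name."""
    n = len(importances.importances)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    ordered = sorted(importances.ranks, key=importances.ranks.get)
    return ordered[:k]
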