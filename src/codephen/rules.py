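"""Phase-3 single-tree rule induction and the if-then rule engine.

A single binary decision tree over the aggregated predictor counts is grown
with the C4.5 family of conventions — gain-ratio splitting restricted to
splits with above-average information gain, and pessimistic post-pruning with
confidence factor ``cf`` — then flattened into transparent if-then rules: one
rule per leaf, conditions in root-to-leaf order, so the ruleset's decision
function is identical to the tree's.  A single interpretable ruleset, rather
than an ensemble, is the end product clinicians audit.

Pessimistic pruning estimates a node's true error rate by the one-sided
upper confidence bound of the binomial error count observed at training
(Clopper–Pearson upper limit at confidence ``cf``); a subtree collapses to a
leaf when the leaf's estimated errors do not exceed the subtree's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputFormatError
from .events import NON_RA, RA, FeatureMatrix

_EPS = 1e-12


def entropy(class_counts: Sequence[int]) -> float:
    """Shannon entropy in bits of a class-count vector."""
    n = sum(class_counts)
    if n == 0:
        raise DegenerateInputError("entropy of an empty node is undefined")
    h = 0.0
    for c in class_counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h


def information_gain_ratio(
    parent_counts: tuple[int, int],
    split_counts: tuple[tuple[int, int], tuple[int, int]],
) -> float:
    """Gain ratio of a two-way split: information gain / split information.

    Split information is the entropy of the branch-size distribution; by
    convention the ratio is 0 when split information is 0 (one empty branch).
    """
    n = sum(parent_counts)
    if n == 0:
        raise DegenerateInputError("empty parent node")
    (l1, l2), (r1, r2) = split_counts
    if l1 + r1 != parent_counts[0] or l2 + r2 != parent_counts[1]:
        raise ValueError("split counts do not partition parent counts")
    nl, nr = l1 + l2, r1 + r2
    if nl == 0 or nr == 0:
        return 0.0
    gain = entropy(parent_counts) - (nl / n) * entropy((l1, l2)) - (nr / n) * entropy((r1, r2))
    split_info = entropy((nl, nr))
    if split_info <= _EPS:
        return 0.0
    return gain / split_info


def pessimistic_upper_error(errors: int, n: int, cf: float = 0.25) -> float:
    """One-sided upper confidence bound on the true error rate of a leaf
    that misclassified ``errors`` of ``n`` training samples."""
    if n <= 0:
        raise DegenerateInputError("empty leaf")
    if errors >= n:
        return 1.0
    return float(stats.beta.ppf(1.0 - cf, errors + 1, n - errors))


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class TreeNode:
    """Binary node: test ``count(feature) >= threshold`` (right branch)."""

    n_ra: int
    n_nonra: int
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None   # feature count < threshold
    right: "TreeNode | None" = None  # feature count >= threshold

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return self.n_ra + self.n_nonra

    @property
    def prediction(self) -> str:
        # ties predict the negative class: flagging RA needs a majority
        return RA if self.n_ra > self.n_nonra else NON_RA

    @property
    def training_errors(self) -> int:
        return min(self.n_ra, self.n_nonra)

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class DecisionTree:
    root: TreeNode
    feature_names: list[str]

    def classify(self, record: Mapping[str, float]) -> str:
        node = self.root
        while not node.is_leaf:
            value = record.get(node.feature, 0)
            node = node.right if value >= node.threshold else node.left
        return node.prediction

    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def features_used(self) -> set[str]:
        used = set()

        def _walk(node):
            if not node.is_leaf:
                used.add(node.feature)
                _walk(node.left)
                _walk(node.right)

        _walk(self.root)
        return used


def _candidate_splits(X: np.ndarray, y: np.ndarray, names: list[str], min_leaf: int):
    """All admissible (feature, threshold) candidates with gain and ratio."""
    n = len(y)
    n_pos = int(y.sum())
    h_parent = entropy((n_pos, n - n_pos))
    out = []  # (name, threshold, gain, ratio, col)
    for j, name in enumerate(names):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        boundary = np.nonzero(xs[:-1] != xs[1:])[0]
        if boundary.size == 0:
            continue
        nl = boundary + 1
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        boundary, nl, nr = boundary[ok], nl[ok], nr[ok]
        if boundary.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        pos_l = cum_pos[boundary]
        pos_r = n_pos - pos_l

        def _h(a, b):
            tot = a + b
            with np.errstate(divide="ignore", invalid="ignore"):
                pa = np.where(a > 0, a / tot, 1.0)
                pb = np.where(b > 0, b / tot, 1.0)
                return -(np.where(a > 0, a / tot * np.log2(pa), 0.0)
                         + np.where(b > 0, b / tot * np.log2(pb), 0.0))

        gain = h_parent - (nl / n) * _h(pos_l, nl - pos_l) - (nr / n) * _h(pos_r, nr - pos_r)
        # threshold-choice penalty for continuous/count attributes (the MDL
        # correction of later C4.5 releases): charge log2(#candidate cuts)/n
        # so that a feature cannot buy gain merely by offering many cuts
        n_cuts = np.count_nonzero(xs[:-1] != xs[1:])
        gain = gain - math.log2(n_cuts) / n if n_cuts > 1 else gain
        split_info = _h(nl, nr)
        ratio = np.where(split_info > _EPS, gain / np.where(split_info > _EPS, split_info, 1.0), 0.0)
        thresholds = (xs[boundary] + xs[boundary + 1]) / 2.0
        for t, g, r in zip(thresholds, gain, ratio):
            if g > _EPS:
                out.append((name, float(t), float(g), float(r), j))
    return out


def _grow(X: np.ndarray, y: np.ndarray, names: list[str], min_leaf: int) -> TreeNode:
    n_pos = int(y.sum())
    node = TreeNode(n_ra=n_pos, n_nonra=len(y) - n_pos)
    if n_pos in (0, len(y)) or len(y) < 2 * min_leaf:
        return node
    cands = _candidate_splits(X, y, names, min_leaf)
    if not cands:
        return node
    avg_gain = sum(c[2] for c in cands) / len(cands)
    admissible = [c for c in cands if c[2] >= avg_gain - _EPS]
    # max gain ratio; ties (within float tolerance) by (feature name, lower threshold)
    rmax = max(c[3] for c in admissible)
    best = min((c for c in admissible if c[3] >= rmax - 1e-9), key=lambda c: (c[0], c[1]))
    name, t, _, _, j = best
    mask = X[:, j] >= t
    node.feature = name
    node.threshold = t
    node.right = _grow(X[mask], y[mask], names, min_leaf)
    node.left = _grow(X[~mask], y[~mask], names, min_leaf)
    return node


def _prune(node: TreeNode, cf: float) -> float:
    """Bottom-up pessimistic pruning; returns estimated subtree errors."""
    if node.is_leaf:
        return node.n * pessimistic_upper_error(node.training_errors, node.n, cf)
    subtree_err = _prune(node.left, cf) + _prune(node.right, cf)
    leaf_err = node.n * pessimistic_upper_error(node.training_errors, node.n, cf)
    if leaf_err <= subtree_err + _EPS:
        node.feature = node.threshold = node.left = node.right = None
        return leaf_err
    return subtree_err


def induce_tree(
    matrix: FeatureMatrix,
    min_leaf: int = 2,
    cf: float = 0.25,
    prune: bool = True,
) -> DecisionTree:
    """Grow and pessimistically prune a gain-ratio tree on ``matrix``.

    Deterministic given input.  Degenerate input (a single class, or no
    admissible split) yields a single majority-class leaf, not an error.
    ``cf`` in (0, 1): smaller values prune more aggressively.
    """
    if not 0.0 < cf < 1.0:
        raise ValueError("cf must be in (0, 1)")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    root = _grow(matrix.values, matrix.y, matrix.feature_names, min_leaf)
    if prune:
        _prune(root, cf)
    return DecisionTree(root=root, feature_names=list(matrix.feature_names))


# ---------------------------------------------------------------------------
# If-then rules


@dataclass(frozen=True)
class Condition:
    feature: str
    comparator: str  # one of >=, <, ==
    value: float

    def __post_init__(self):
        if self.comparator not in (">=", "<", "=="):
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def holds(self, record: Mapping[str, float]) -> bool:
        v = record.get(self.feature, 0)
        if self.comparator == ">=":
            return v >= self.value
        if self.comparator == "<":
            return v < self.value
        return v == self.value

    def __str__(self) -> str:
        value = int(self.value) if float(self.value).is_integer() else self.value
        return f"{self.feature} {self.comparator} {value}"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    conclusion: str
    confidence: float = 1.0

    def matches(self, record: Mapping[str, float]) -> bool:
        return all(c.holds(record) for c in self.conditions)

    def __str__(self) -> str:
        cond = " and ".join(str(c) for c in self.conditions) if self.conditions else "always"
        return f"if {cond} then {self.conclusion} [confidence={self.confidence:.4f}]"


@dataclass(frozen=True)
class RuleSet:
    """Ordered rules with first-match evaluation and a default conclusion."""

    rules: tuple[Rule, ...]
    default: str = NON_RA

    def classify(self, record: Mapping[str, float]) -> str:
        for rule in self.rules:
            if rule.matches(record):
                return rule.conclusion
        return self.default

    def features(self) -> set[str]:
        return {c.feature for r in self.rules for c in r.conditions}

    def serialise(self) -> str:
        lines = ["codephen-ruleset v1"]
        lines += [str(r) for r in self.rules]
        lines.append(f"default {self.default}")
        return "\n".join(lines) + "\n"

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.serialise())

    @classmethod
    def parse(cls, text: str) -> "RuleSet":
        lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
        if not lines or lines[0] != "codephen-ruleset v1":
            raise InputFormatError("not a codephen ruleset (missing header)")
        rules = []
        default = NON_RA
        for ln in lines[1:]:
            if ln.startswith("default "):
                default = ln.split(None, 1)[1]
                continue
            if not ln.startswith("if "):
                raise InputFormatError(f"unparseable rule line: {ln!r}")
            body, _, tail = ln[3:].partition(" then ")
            conclusion, _, conf = tail.partition(" [confidence=")
            confidence = float(conf.rstrip("]")) if conf else 1.0
            conditions = []
            if body.strip() != "always":
                for part in body.split(" and "):
                    feat, comp, value = part.split()
                    conditions.append(Condition(feat, comp, float(value)))
            rules.append(Rule(tuple(conditions), conclusion.strip(), confidence))
        return cls(tuple(rules), default)

    @classmethod
    def from_file(cls, path) -> "RuleSet":
        with open(path, encoding="utf-8") as fh:
            return cls.parse(fh.read())


def extract_rules(tree: DecisionTree) -> RuleSet:
    """Flatten a tree into one rule per leaf (root-to-leaf condition order).

    The rules are mutually exclusive and exhaustive, so the ruleset computes
    exactly the tree's decision function; leaf confidence is the majority
    fraction of its training samples.
    """
    rules: list[Rule] = []

    def _walk(node: TreeNode, conds: tuple[Condition, ...]):
        if node.is_leaf:
            conf = max(node.n_ra, node.n_nonra) / node.n if node.n else 1.0
            rules.append(Rule(conds, node.prediction, conf))
            return
        _walk(node.left, conds + (Condition(node.feature, "<", node.threshold),))
        _walk(node.right, conds + (Condition(node.feature, ">=", node.threshold),))

    _walk(tree.root, ())
    default = tree.root.prediction
    return RuleSet(tuple(rules), default)


def classify(ruleset: RuleSet, record: Mapping[str, float]) -> str:
    """Conclusion of the first matching rule, else the default.  Features
    missing from ``record`` are treated as count 0."""
    return ruleset.classify(record)
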