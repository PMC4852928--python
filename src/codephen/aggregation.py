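"""Phase-2 seed expansion and code grouping.

Screened codes act as *seeds*: each seed pulls in every code from the dataset
universe that shares its hierarchical prefix (dose/form variants of one drug,
sibling diagnoses) or its active ingredient, so that rarer-but-valid variants
of a selected predictor join the same variable.  Overlapping groups are then
unioned transitively until disjoint — the grouped feature is the sum of its
members' counts, and a code must contribute to exactly one variable.

The similarity notion is explicitly prefix + ingredient; no free-text
descriptions are consulted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, InputFormatError
from .events import CodeGroup, FeatureMatrix
from .forest import ForestConfig, fit_forest


def default_prefix_depth(code: str) -> int:
    """Chapter-aware default: medication chapters (lower-case first character)
    group at depth 3, diagnosis/procedure chapters at depth 4."""
    return 3 if code[:1].islower() else 4


@dataclass(frozen=True)
class IngredientMap:
    """Map code -> active-ingredient name (each code has exactly one)."""

    mapping: dict[str, str]

    def ingredient(self, code: str) -> str | None:
        return self.mapping.get(code)

    @classmethod
    def from_csv(cls, path) -> "IngredientMap":
        df = pd.read_csv(path, dtype=str)
        if list(df.columns) != ["code", "ingredient"]:
            raise InputFormatError(f"{path}: expected header code,ingredient")
        if df["code"].duplicated().any():
            dupes = sorted(df.loc[df["code"].duplicated(), "code"])
            raise ConfigurationError(f"codes mapped to multiple ingredients: {dupes}")
        return cls(dict(zip(df["code"], df["ingredient"])))


def expand_seeds(
    selected: list[str],
    universe: set[str] | list[str],
    prefix_depth: int | None = None,
    ingredients: IngredientMap | None = None,
) -> dict[str, set[str]]:
    """Expand each seed code into the set of universe codes similar to it.

    A universe code joins a seed's group if it shares the seed's prefix of
    length ``prefix_depth`` (chapter-aware default when None) or maps to the
    same active ingredient.  Expansion never removes a seed, and the output
    is independent of seed order (groups are keyed by seed).
    """
    if prefix_depth is not None and not 1 <= prefix_depth <= 5:
        raise ConfigurationError("prefix_depth must be in 1..5")
    universe = set(universe)
    groups: dict[str, set[str]] = {}
    for seed in sorted(set(selected)):
        depth = prefix_depth if prefix_depth is not None else default_prefix_depth(seed)
        prefix = seed[:depth]
        members = {seed}
        members.update(c for c in universe if c[:depth] == prefix)
        if ingredients is not None:
            ing = ingredients.ingredient(seed)
            if ing is not None:
                members.update(c for c in universe if ingredients.ingredient(c) == ing)
        groups[seed] = members
    return groups


def merge_groups(
    groups: dict[str, set[str]],
    ingredients: IngredientMap | None = None,
) -> list[CodeGroup]:
    """Union overlapping groups transitively until pairwise disjoint.

    Merged groups are the connected components of the code-sharing graph over
    the input groups (computed here by union-find).  Each output group is
    named for its lexicographically-smallest seed (prefixed by the shared
    ingredient name when one exists) and sorted by name.
    """
    seeds = sorted(groups)
    parent = {s: s for s in seeds}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lexicographically smaller seed as the root
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    owner: dict[str, str] = {}
    for s in seeds:
        for code in sorted(groups[s]):
            if code in owner:
                union(owner[code], s)
            else:
                owner[code] = s

    merged: dict[str, set[str]] = {}
    for s in seeds:
        merged.setdefault(find(s), set()).update(groups[s])

    out = []
    for root in sorted(merged):
        codes = merged[root]
        name = root
        if ingredients is not None:
            ings = {ingredients.ingredient(c) for c in codes} - {None}
            if len(ings) == 1:
                name = next(iter(ings))
        kind = "medication" if root[:1].islower() else "diagnosis"
        out.append(CodeGroup(name=name, codes=frozenset(codes), kind=kind))
    out.sort(key=lambda g: g.name)
    return out


@dataclass(frozen=True)
class ExpansionEvaluation:
    oob_before: float
    oob_after: float
    difference: float  # after - before
    accepted: bool


def evaluate_expansion(
    matrix_before: FeatureMatrix,
    matrix_after: FeatureMatrix,
    config: ForestConfig | None = None,
    tolerance: float = 0.0,
) -> ExpansionEvaluation:
    """Judge a candidate expansion by out-of-bag accuracy before vs after.

    The expansion is accepted iff OOB accuracy does not drop by more than
    ``tolerance`` (default: never accept any loss).  Both matrices must
    describe the same patients with the same labels.
    """
    if (
        matrix_before.patient_ids != matrix_after.patient_ids
        or matrix_before.labels != matrix_after.labels
    ):
        raise ConfigurationError("expansion evaluation requires matching patients and labels")
    config = config or ForestConfig(n_trees=50, seed=0)
    _, imp_before = fit_forest(matrix_before, config)
    _, imp_after = fit_forest(matrix_after, config)
    diff = imp_after.oob_accuracy - imp_before.oob_accuracy
    return ExpansionEvaluation(
        oob_before=imp_before.oob_accuracy,
        oob_after=imp_after.oob_accuracy,
        difference=diff,
        accepted=diff >= -tolerance,
    )
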