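"""Phase 3: induce a single transparent tree and flatten it to if-then rules.

A gain-ratio tree with pessimistic pruning is grown on the grouped
predictors; every root-to-leaf path becomes one rule, so the ruleset is
exactly the tree's decision function and can be audited line by line.
"""

from codephen import (
    SimulationConfig,
    build_feature_matrix,
    build_records,
    expand_seeds,
    extract_rules,
    induce_tree,
    merge_groups,
    screen,
    simulate,
)
from codephen.screening import selected_codes

events, labels, _ = simulate(SimulationConfig(seed=1))
records = build_records(events, labels)
matrix = build_feature_matrix(records)
groups = merge_groups(expand_seeds(selected_codes(screen(matrix)), set(matrix.feature_names)))
grouped = build_feature_matrix(records, groups)

tree = induce_tree(grouped, min_leaf=5, cf=0.25)
ruleset = extract_rules(tree)
print(f"tree: {tree.n_leaves()} leaves, depth {tree.depth()}, "
      f"{len(tree.features_used())} of {grouped.n_features} predictors used")
print(ruleset.serialise())
# Conditions are occurrence-count thresholds; confidence is the majority
# fraction of the leaf's training patients.  First-match evaluation.
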