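"""End-to-end orchestration of the three phenotyping phases.

simulate (or load) -> screen -> aggregate -> rank -> induce -> classify ->
validate, with every intermediate artifact serialised and a manifest
recording seeds and the code funnel (codes in -> screened -> groups ->
top-k -> rule features).  Each stage consumes only the serialised artifacts
of the previous one, so a run is resumable and two runs with the same config
are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .aggregation import IngredientMap, expand_seeds, merge_groups
from .errors import CodephenError, ConfigurationError
from .events import (
    CodeGroup,
    FeatureMatrix,
    build_feature_matrix,
    build_records,
    read_events,
    read_labels,
    write_code_groups,
    write_events,
    write_labels,
)
from .forest import ForestConfig, fit_forest, select_top
from .rules import DecisionTree, RuleSet, extract_rules, induce_tree
from .screening import screen, selected_codes, write_screening
from .simulate import SimulationConfig, simulate
from .validation import (
    LinkageTable,
    compare_algorithms,
    linkage_table_from_labels,
    scenario_analysis,
)


@dataclass
class PipelineConfig:
    """One config object driving all stages.

    Either ``sim`` (synthetic cohort) or both ``events_path``/``labels_path``
    must be given.  ``top_k`` caps how many ranked groups enter rule
    induction (40 by default — comfortably above the size of published code
    funnels — and clipped to the number of groups available).
    """

    outdir: str | Path = "pipeline_out"
    sim: SimulationConfig | None = field(default_factory=SimulationConfig)
    events_path: str | None = None
    labels_path: str | None = None
    denominator: str = "population"
    prefix_depth: int | None = None
    ingredient_map_path: str | None = None
    forest: ForestConfig = field(default_factory=lambda: ForestConfig(n_trees=100))
    top_k: int = 40
    min_leaf: int = 5
    cf: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            kwargs["sim"] = SimulationConfig(**kwargs["sim"])
        if "forest" in kwargs:
            kwargs["forest"] = ForestConfig(**kwargs["forest"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    manifest: dict
    screened: list
    groups: list[CodeGroup]
    importance_table: object
    tree: DecisionTree
    ruleset: RuleSet
    linkage_table: LinkageTable
    latent_table: LinkageTable | None


def _group_features(records, groups: list[CodeGroup]) -> dict[str, dict[str, int]]:
    return {
        r.patient_id: {
            g.name: sum(r.code_counts.get(c, 0) for c in g.codes) for g in groups
        }
        for r in records
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all phases, write artifacts under ``config.outdir`` and return
    the in-memory results with the manifest.

    Any stage failure aborts with the stage name and cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"codephen_version": __version__, "stages": {}, "artifacts": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise CodephenError(f"pipeline stage {name!r} failed: {exc}") from exc

        return deco

    # --- stage 0: data -----------------------------------------------------
    @stage("data")
    def _data():
        if config.sim is not None:
            events, labels, truth = simulate(config.sim)
            write_events(events, out / "events.csv")
            write_labels(labels, out / "labels.csv")
            manifest["stages"]["data"] = {
                "source": "synthetic",
                "seed": config.sim.seed,
                "n_patients": config.sim.n_patients,
                "n_events": len(events),
                "n_labelled": len(labels),
            }
            return events, labels, truth
        if not (config.events_path and config.labels_path):
            raise ConfigurationError("need either sim config or events+labels paths")
        events = read_events(config.events_path)
        labels = read_labels(config.labels_path)
        manifest["stages"]["data"] = {
            "source": config.events_path,
            "n_events": len(events),
            "n_labelled": len(labels),
        }
        return events, labels, None

    events, labels, truth = _data

    # --- phase 1: screening ------------------------------------------------
    @stage("screening")
    def _screen():
        records = build_records(events, labels)
        raw_matrix = build_feature_matrix(records)
        results = screen(raw_matrix, config.denominator)
        write_screening(results, out / "screened.csv")
        sel = selected_codes(results)
        manifest["stages"]["screening"] = {
            "n_codes": raw_matrix.n_features,
            "n_selected": len(sel),
            "denominator": config.denominator,
        }
        return records, raw_matrix, results, sel

    records, raw_matrix, screened, selected = _screen

    # --- phase 2a: aggregation --------------------------------------------
    @stage("aggregation")
    def _aggregate():
        ingredients = (
            IngredientMap.from_csv(config.ingredient_map_path)
            if config.ingredient_map_path
            else None
        )
        universe = set(raw_matrix.feature_names)
        expanded = expand_seeds(selected, universe, config.prefix_depth, ingredients)
        groups = merge_groups(expanded, ingredients)
        write_code_groups(groups, out / "groups.yaml")
        manifest["stages"]["aggregation"] = {"n_groups": len(groups)}
        return groups

    groups = _aggregate

    # --- phase 2b: forest ranking -------------------------------------------
    @stage("ranking")
    def _rank():
        grouped_matrix = build_feature_matrix(records, groups)
        _, table = fit_forest(grouped_matrix, config.forest)
        table.to_csv(out / "importance.csv")
        k = min(config.top_k, grouped_matrix.n_features)
        top = select_top(table, k)
        manifest["stages"]["ranking"] = {
            "n_trees": config.forest.n_trees,
            "seed": config.forest.seed,
            "oob_accuracy": round(table.oob_accuracy, 6),
            "top_k": k,
        }
        return grouped_matrix, table, top

    grouped_matrix, importance_table, top = _rank

    # --- phase 3: rule induction --------------------------------------------
    @stage("induction")
    def _induce():
        cols = [grouped_matrix.feature_names.index(f) for f in top]
        sub = FeatureMatrix(
            grouped_matrix.patient_ids,
            top,
            grouped_matrix.values[:, cols],
            grouped_matrix.labels,
        )
        tree = induce_tree(sub, min_leaf=config.min_leaf, cf=config.cf)
        ruleset = extract_rules(tree)
        ruleset.to_file(out / "ruleset.txt")
        manifest["stages"]["induction"] = {
            "min_leaf": config.min_leaf,
            "cf": config.cf,
            "n_rules": len(ruleset.rules),
            "n_rule_features": len(ruleset.features()),
        }
        return tree, ruleset

    tree, ruleset = _induce

    # --- validation ---------------------------------------------------------
    @stage("validation")
    def _validate():
        all_records = build_records(events, labels)
        feats = _group_features(all_records, groups)
        predicted = {pid: ruleset.classify(v) for pid, v in feats.items()}
        n_pop = truth.config.n_patients if truth is not None else len(all_records)
        table = linkage_table_from_labels(predicted, labels, population_size=n_pop)
        table.to_csv(out / "linkage_table.csv")
        latent = None
        if truth is not None:
            latent = linkage_table_from_labels(
                predicted, truth.latent_labels, population_size=n_pop
            )
        report = compare_algorithms({"induced": table})
        report.to_csv(out / "validation_report.csv", index=False)
        sm = scenario_analysis(table)
        manifest["stages"]["validation"] = {
            "flagged": table.n_flagged,
            "worst_ppv": None if sm.worst.ppv is None else round(sm.worst.ppv, 6),
            "best_ppv": None if sm.best.ppv is None else round(sm.best.ppv, 6),
        }
        return table, latent

    linkage_table, latent_table = _validate

    funnel = [
        manifest["stages"]["screening"]["n_codes"],
        manifest["stages"]["screening"]["n_selected"],
        manifest["stages"]["aggregation"]["n_groups"],
        manifest["stages"]["ranking"]["top_k"],
        manifest["stages"]["induction"]["n_rule_features"],
    ]
    manifest["funnel"] = funnel
    manifest["artifacts"] = {
        name: name + ext
        for name, ext in [
            ("events", ".csv"),
            ("labels", ".csv"),
            ("screened", ".csv"),
            ("groups", ".yaml"),
            ("importance", ".csv"),
            ("ruleset", ".txt"),
            ("linkage_table", ".csv"),
            ("validation_report", ".csv"),
        ]
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return PipelineResult(
        manifest=manifest,
        screened=screened,
        groups=groups,
        importance_table=importance_table,
        tree=tree,
        ruleset=ruleset,
        linkage_table=linkage_table,
        latent_table=latent_table,
    )
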