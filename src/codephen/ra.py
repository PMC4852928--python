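"""The published-style rheumatoid-arthritis phenotyping engine.

Eight predictors drive the classifier: seven code groups counted as
occurrences — QOF RA diagnosis codes (RARTH_COD), psoriatic-arthritis
exclusion codes (PSORIATIC_CD), alternative-arthropathy exclusion codes
(ALTERNATIVE_RA), and the prednisolone / methotrexate / sulphasalazine /
leflunomide medication groups — plus INTENSITY_RA, a categorical severity
variable with levels {1, 2, 3, 4, 9}: 1 sero-positive/erosive RA (most
severe), 2 RA classification codes, 3 RA-related conditions (e.g. rheumatoid
nodule), 4 sero-negative RA, 9 no RA history.  A patient's intensity is the
most severe (lowest-numbered) level whose code set their record intersects.

The default ruleset encodes the published decision logic: psoriatic
arthritis excludes RA outright; an alternative arthropathy without RA
evidence excludes RA; a QOF RA code or intensity 1-2 *plus* DMARD or
prednisolone evidence flags RA; anything else is not RA.  Exact split
thresholds belong to the fitted tree, not the method, so the engine is fully
configuration-driven: any induced or transcribed ruleset and any code lists
can be loaded in place of the defaults.  The code lists shipped here are
synthetic placeholders — real deployments supply their own terminology
lists through the group-configuration file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError
from .events import NON_RA, RA, CodeGroup, PatientRecord
from .rules import Condition, Rule, RuleSet

INTENSITY_LEVELS = (1, 2, 3, 4, 9)
NO_HISTORY = 9

COUNT_PREDICTORS = (
    "RARTH_COD",
    "PSORIATIC_CD",
    "ALTERNATIVE_RA",
    "PREDNISOLONE",
    "METHOTREXATE_CD",
    "SULPHASALAZINE_CD",
    "LEFLUNOMIDE_CD",
)
PREDICTOR_NAMES = COUNT_PREDICTORS + ("INTENSITY_RA",)
DMARD_PREDICTORS = ("PREDNISOLONE", "METHOTREXATE_CD", "SULPHASALAZINE_CD", "LEFLUNOMIDE_CD")


@dataclass(frozen=True)
class RAPredictorSet:
    """The eight predictors: seven count groups plus the intensity class map."""

    groups: Mapping[str, CodeGroup]
    intensity_map: Mapping[int, frozenset[str]]

    def __post_init__(self):
        missing = [n for n in COUNT_PREDICTORS if n not in self.groups]
        if missing:
            raise ConfigurationError(f"predictor configuration missing groups: {missing}")
        if not all(lvl in self.intensity_map for lvl in (1, 2, 3, 4)):
            raise ConfigurationError("intensity class map must cover levels 1-4")


def derive_intensity(record: PatientRecord, class_code_map: Mapping[int, Iterable[str]]) -> int:
    """Most severe (lowest-numbered) intensity level whose codes the record
    carries; 9 when the record has no RA history at all.  Adding codes can
    only keep or lower (worsen) the level."""
    for level in sorted(k for k in class_code_map if k != NO_HISTORY):
        if any(record.count(c) >= 1 for c in class_code_map[level]):
            return level
    return NO_HISTORY


def feature_vector(record: PatientRecord, predictors: RAPredictorSet) -> dict[str, int]:
    """The 8-dimensional predictor vector for one patient: group occurrence
    counts plus the derived intensity class."""
    features = {
        name: sum(record.count(c) for c in predictors.groups[name].codes)
        for name in COUNT_PREDICTORS
    }
    features["INTENSITY_RA"] = derive_intensity(record, predictors.intensity_map)
    return features


def default_ruleset() -> RuleSet:
    """The shipped decision rules (first-match).

    Exclusions dominate: any psoriatic-arthritis code forces notRA; an
    alternative arthropathy without RA evidence (no QOF code, intensity
    outside {1, 2}) forces notRA.  RA requires diagnostic evidence (QOF code
    or intensity 1-2) together with medication evidence (any DMARD group or
    prednisolone).  Default: notRA.
    """
    ge1 = lambda f: Condition(f, ">=", 1)
    rules: list[Rule] = [
        Rule((ge1("PSORIATIC_CD"),), NON_RA),
        Rule(
            (
                ge1("ALTERNATIVE_RA"),
                Condition("RARTH_COD", "<", 1),
                Condition("INTENSITY_RA", ">=", 3),
            ),
            NON_RA,
        ),
    ]
    for evidence in (ge1("RARTH_COD"), Condition("INTENSITY_RA", "<", 3)):
        for med in DMARD_PREDICTORS:
            rules.append(Rule((evidence, ge1(med)), RA))
    return RuleSet(tuple(rules), default=NON_RA)


def classify_ra(
    record: PatientRecord,
    predictors: RAPredictorSet,
    ruleset: RuleSet | None = None,
) -> str:
    """Classify one patient: build the 8-predictor vector and run the rules."""
    ruleset = ruleset or default_ruleset()
    unknown = ruleset.features() - set(PREDICTOR_NAMES)
    if unknown:
        raise ConfigurationError(f"ruleset references unknown predictors: {sorted(unknown)}")
    return ruleset.classify(feature_vector(record, predictors))


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_flagged: int

    @property
    def flagged_fraction(self) -> float | None:
        if self.n_patients == 0:
            return None
        return self.n_flagged / self.n_patients


def cohort_classify(
    records: Sequence[PatientRecord],
    predictors: RAPredictorSet,
    ruleset: RuleSet | None = None,
) -> tuple[dict[str, str], CohortSummary]:
    """Classify every record; returns per-patient labels and the flagged-count
    summary (order-invariant over the cohort)."""
    ruleset = ruleset or default_ruleset()
    labels = {r.patient_id: classify_ra(r, predictors, ruleset) for r in records}
    n_flagged = sum(1 for v in labels.values() if v == RA)
    return labels, CohortSummary(n_patients=len(records), n_flagged=n_flagged)


# ---------------------------------------------------------------------------
# Configuration IO


def default_predictors() -> RAPredictorSet:
    """Placeholder predictor configuration with synthetic code lists matching
    the synthetic-data generator's planted signal.  Real deployments replace
    every list with their own terminology codes."""
    groups = {
        "RARTH_COD": CodeGroup("RARTH_COD", frozenset({"N0400"}), "diagnosis"),
        "PSORIATIC_CD": CodeGroup("PSORIATIC_CD", frozenset({"N0452"}), "exclusion"),
        "ALTERNATIVE_RA": CodeGroup("ALTERNATIVE_RA", frozenset({"N0450", "N0451"}), "exclusion"),
        "PREDNISOLONE": CodeGroup("PREDNISOLONE", frozenset({"bd3z1", "bd3z2"}), "medication"),
        "METHOTREXATE_CD": CodeGroup(
            "METHOTREXATE_CD", frozenset({"h3311", "h3312", "h3313"}), "medication"
        ),
        "SULPHASALAZINE_CD": CodeGroup(
            "SULPHASALAZINE_CD", frozenset({"h2211", "h2212"}), "medication"
        ),
        "LEFLUNOMIDE_CD": CodeGroup("LEFLUNOMIDE_CD", frozenset({"h4411"}), "medication"),
    }
    intensity = {
        1: frozenset({"N0411"}),          # sero-positive / erosive RA
        2: frozenset({"N0400", "N0412"}),  # RA classification codes
        3: frozenset({"N0420"}),           # related conditions (rheumatoid nodule)
        4: frozenset({"N0413"}),           # sero-negative RA
    }
    return RAPredictorSet(groups=groups, intensity_map=intensity)


def read_predictors(path) -> RAPredictorSet:
    """Load a predictor configuration: YAML with ``groups`` (name -> {kind,
    codes}) and ``intensity`` (level -> codes)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        groups = {
            name: CodeGroup(name, frozenset(spec["codes"]), spec.get("kind", "other"))
            for name, spec in raw["groups"].items()
        }
        intensity = {int(level): frozenset(codes) for level, codes in raw["intensity"].items()}
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"{path}: malformed predictor configuration ({exc})") from exc
    return RAPredictorSet(groups=groups, intensity_map=intensity)


def write_predictors(predictors: RAPredictorSet, path) -> None:
    payload = {
        "groups": {
            name: {"kind": g.kind, "codes": sorted(g.codes)}
            for name, g in predictors.groups.items()
        },
        "intensity": {int(k): sorted(v) for k, v in predictors.intensity_map.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
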