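"""Synthetic linked primary/secondary-care EHR generator.

Emulates the population structure the pipeline is built for: a primary-care
coded-event stream for every patient, and a gold-standard diagnosis available
only for the subset of patients who also appear in a secondary-care specialist
system (partial record linkage).  The planted signal mirrors what makes
data-driven phenotyping work on real records:

* predictive code groups that are rare overall but far more prevalent in
  cases than controls (diagnosis codes, disease-modifying drugs);
* dose/form variants of one drug sharing a hierarchical code prefix, so
  prefix aggregation has real structure to recover;
* exclusion codes more prevalent in controls (differential diagnoses);
* noise codes drawn with equal probability in both classes.

Counts given presence are Poisson with a floor of 1 — the simplest model that
yields the count-valued features the downstream trees split on.  What this
generator does *not* emulate: longitudinal disease trajectories, calendar-time
coding drift, or correlated comorbidity structure; results on it bound what
the pipeline machinery can do, not how real records behave.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .events import NON_RA, RA, CodedEvent
from .rules import RuleSet

_DATE0 = _dt.date(2000, 1, 1)
_DATE_SPAN_DAYS = 4748  # through 2012


@dataclass(frozen=True)
class PlantedGroup:
    """A code group with a class-conditional presence differential.

    ``p_case``/``p_control`` are per-patient presence probabilities; for a
    predictive group p_case >= p_control, for an exclusion group the
    inequality may invert.  If present, the patient's total count for the
    group is Poisson(``mean_count_if_present``) floored at 1 and spread over
    the member codes uniformly at random (member codes of one drug share a
    prefix, so each variant individually carries signal).
    """

    name: str
    member_codes: tuple[str, ...]
    p_case: float
    p_control: float
    mean_count_if_present: float = 2.0
    kind: str = "diagnosis"

    def __post_init__(self):
        if not self.member_codes:
            raise ConfigurationError(f"planted group {self.name}: no member codes")
        for p in (self.p_case, self.p_control):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"planted group {self.name}: probability {p} out of range")
        if self.mean_count_if_present <= 0:
            raise ConfigurationError(f"planted group {self.name}: non-positive mean count")


def default_planted_groups() -> tuple[PlantedGroup, ...]:
    """The default planted RA signal: strong diagnosis/medication groups
    (10x+ more prevalent in cases), an exclusion group, and dose variants
    sharing 3-character medication prefixes."""
    return (
        PlantedGroup("qof_ra", ("N0400",), 0.60, 0.05, 2.5, "diagnosis"),
        PlantedGroup("seropositive_ra", ("N0411", "N0412"), 0.60, 0.05, 2.0, "diagnosis"),
        PlantedGroup("methotrexate", ("h3311", "h3312", "h3313"), 0.60, 0.05, 3.0, "medication"),
        PlantedGroup("prednisolone", ("bd3z1", "bd3z2"), 0.60, 0.05, 2.0, "medication"),
        PlantedGroup("sulphasalazine", ("h2211", "h2212"), 0.60, 0.05, 2.0, "medication"),
        PlantedGroup("psoriatic_arthritis", ("N0452",), 0.02, 0.08, 1.5, "exclusion"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic linked cohort.

    Defaults mirror a linked rheumatology-clinic stratum: 2,000 patients with
    17% RA prevalence, 80% of patients linked to the secondary-care system,
    100 uninformative noise codes, and the default planted signal above.
    """

    n_patients: int = 2000
    prevalence: float = 0.17
    linkage_rate: float = 0.8
    n_noise_codes: int = 100
    noise_presence: float = 0.10
    planted_groups: tuple[PlantedGroup, ...] = field(default_factory=default_planted_groups)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 10:
            raise ConfigurationError("n_patients must be at least 10")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not 0.0 < self.linkage_rate <= 1.0:
            raise ConfigurationError("linkage_rate must be in (0, 1]")
        if self.n_noise_codes < 0:
            raise ConfigurationError("n_noise_codes must be non-negative")


@dataclass
class SimulationTruth:
    """Echo of the generating process: the config plus per-patient latent state.

    Unlinked patients keep their latent diagnosis here, so best/worst-case
    scenario bounds can be compared against the latent reality they bracket.
    """

    config: SimulationConfig
    latent_labels: dict[str, str]
    linked: dict[str, bool]
    noise_codes: tuple[str, ...]


def noise_code_names(n: int) -> tuple[str, ...]:
    # Z-chapter style administrative codes; consecutive codes share a depth-4
    # prefix (Z0000..Z0009 -> Z000) so aggregation also has null structure.
    return tuple(f"Z{i:04d}" for i in range(n))


def simulate(config: SimulationConfig) -> tuple[list[CodedEvent], dict[str, str], SimulationTruth]:
    """Draw one synthetic linked cohort.

    Returns the primary-care event list, the observed gold-standard labels
    (linked patients only — unlinked patients form the "no reference data"
    stratum), and the truth echo with every patient's latent diagnosis.
    Identical config (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i:06d}" for i in range(n)]
    is_case = rng.random(n) < config.prevalence
    is_linked = rng.random(n) < config.linkage_rate
    noise_codes = noise_code_names(config.n_noise_codes)

    events: list[CodedEvent] = []

    def emit(pid: str, code: str, k: int) -> None:
        days = rng.integers(0, _DATE_SPAN_DAYS, size=k)
        for d in np.sort(days):
            events.append(CodedEvent(pid, code, _DATE0 + _dt.timedelta(days=int(d))))

    for i, pid in enumerate(pids):
        for g in config.planted_groups:
            p = g.p_case if is_case[i] else g.p_control
            if rng.random() < p:
                total = max(1, int(rng.poisson(g.mean_count_if_present)))
                members = rng.integers(0, len(g.member_codes), size=total)
                for j, k in zip(*np.unique(members, return_counts=True)):
                    emit(pid, g.member_codes[int(j)], int(k))
        for code in noise_codes:
            if rng.random() < config.noise_presence:
                emit(pid, code, max(1, int(rng.poisson(1.0))))

    labels = {
        pid: (RA if is_case[i] else NON_RA) for i, pid in enumerate(pids) if is_linked[i]
    }
    truth = SimulationTruth(
        config=config,
        latent_labels={pid: (RA if is_case[i] else NON_RA) for i, pid in enumerate(pids)},
        linked={pid: bool(is_linked[i]) for i, pid in enumerate(pids)},
        noise_codes=noise_codes,
    )
    return events, labels, truth


def null_config(**overrides) -> SimulationConfig:
    """Default config with the planted differentials removed (p_case = p_control):
    no code carries signal, the null case for screening calibration checks."""
    groups = tuple(
        replace(g, p_case=0.10, p_control=0.10) for g in default_planted_groups()
    )
    return SimulationConfig(planted_groups=groups, **overrides)


# ---------------------------------------------------------------------------
# Cohorts generated from a known ruleset (for rule-recovery experiments)


def simulate_ruleset_cohort(
    ruleset: RuleSet,
    feature_means: dict[str, float],
    n_patients: int,
    label_noise: float = 0.05,
    seed: int = 0,
):
    """Generate (features, labels) whose true decision function is ``ruleset``.

    Feature counts are independent Poissons with the given means; each
    patient's label is the ruleset's conclusion, flipped with probability
    ``label_noise``.  Returns (feature dict-of-arrays, label list).
    """
    rng = np.random.default_rng(seed)
    names = list(feature_means)
    X = {f: rng.poisson(feature_means[f], size=n_patients) for f in names}
    labels = []
    flip = rng.random(n_patients) < label_noise
    for i in range(n_patients):
        lab = ruleset.classify({f: int(X[f][i]) for f in names})
        if flip[i]:
            lab = NON_RA if lab == RA else RA
        labels.append(lab)
    return X, labels
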