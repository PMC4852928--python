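"""Diagnostic-accuracy evaluation under incomplete record linkage.

An EHR phenotyping algorithm is validated against a reference diagnosis that
exists only for the linked subset of patients.  The natural summary is a
3x3 linkage table: algorithm output (RA / not RA / no primary-care data) by
reference status (RA / not RA / no reference record).  With cells

    a = predicted RA,    reference RA      e = predicted RA,    no reference
    b = predicted RA,    reference not RA  f = predicted notRA, no reference
    c = predicted notRA, reference RA      g = no GP data,      reference RA
    d = predicted notRA, reference not RA  h = no GP data,      reference not RA

the unlinked predicted-RA patients (e) are the crux: the *worst case* counts
all of them as false positives (no reference record means not RA), the *best
case* counts all of them as true positives (RA treated elsewhere):

    worst: sens = a/(a+c)        ppv = a/(a+b+e)      spec = (d+f)/((d+f)+(b+e))
    best:  sens = (a+e)/(a+e+c)  ppv = (a+e)/(a+b+e)  spec = (d+f)/((d+f)+b)

The no-GP-data row (g, h) is reported but excluded from every metric
denominator.  The true performance, if the latent status of unlinked
patients were known, is bracketed by the two scenarios.  Worst-case
prevalence is (a+c)/population when a population size is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .errors import InputFormatError
from .events import NON_RA, RA, CodedEvent, PatientRecord, build_records

SCENARIOS = ("worst", "best")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Point metrics of a 2x2 table; a metric with a zero denominator is None."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    accuracy: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """sensitivity = tp/(tp+fn); specificity = tn/(tn+fp); ppv = tp/(tp+fp);
    accuracy = (tp+tn)/total.  Undefined metrics are returned as None rather
    than raising, so one empty margin does not void the rest."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("negative confusion-matrix cells")
    return ConfusionMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        accuracy=_ratio(tp + tn, tp + fp + fn + tn),
    )


@dataclass(frozen=True)
class LinkageTable:
    """The 3x3 predicted x reference table (no-GP-data x no-reference cell
    is structurally absent)."""

    a: int  # pred RA,    ref RA
    b: int  # pred RA,    ref notRA
    c: int  # pred notRA, ref RA
    d: int  # pred notRA, ref notRA
    e: int = 0  # pred RA,    no reference data
    f: int = 0  # pred notRA, no reference data
    g: int = 0  # no GP data, ref RA
    h: int = 0  # no GP data, ref notRA
    population_size: int | None = None

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d, self.e, self.f, self.g, self.h)
        if min(cells) < 0:
            raise ValueError("negative linkage-table cells")

    @property
    def n_flagged(self) -> int:
        """Patients the algorithm flags as RA (with or without a reference record)."""
        return self.a + self.b + self.e

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_RA": [self.a, self.c, self.g],
                "ref_notRA": [self.b, self.d, self.h],
                "no_ref_data": [self.e, self.f, None],
            },
            index=["pred_RA", "pred_notRA", "no_gp_data"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="gp_data")

    @classmethod
    def from_csv(cls, path, population_size: int | None = None) -> "LinkageTable":
        df = pd.read_csv(path, index_col=0)
        try:
            return cls(
                a=int(df.loc["pred_RA", "ref_RA"]),
                b=int(df.loc["pred_RA", "ref_notRA"]),
                e=int(df.loc["pred_RA", "no_ref_data"]),
                c=int(df.loc["pred_notRA", "ref_RA"]),
                d=int(df.loc["pred_notRA", "ref_notRA"]),
                f=int(df.loc["pred_notRA", "no_ref_data"]),
                g=int(df.loc["no_gp_data", "ref_RA"]),
                h=int(df.loc["no_gp_data", "ref_notRA"]),
                population_size=population_size,
            )
        except KeyError as exc:
            raise InputFormatError(f"{path}: missing linkage-table cell {exc}") from exc


@dataclass(frozen=True)
class ScenarioMetrics:
    worst: ConfusionMetrics
    best: ConfusionMetrics
    prevalence_worst: float | None = None


def scenario_analysis(table: LinkageTable) -> ScenarioMetrics:
    """Best/worst-case bounds on sensitivity, specificity and PPV (module
    docstring formulas); exact integer arithmetic, zero denominators yield
    None per metric."""
    a, b, c, d, e, f = table.a, table.b, table.c, table.d, table.e, table.f
    worst = ConfusionMetrics(
        sensitivity=_ratio(a, a + c),
        specificity=_ratio(d + f, d + f + b + e),
        ppv=_ratio(a, a + b + e),
        accuracy=_ratio(a + d + f, a + b + c + d + e + f),
    )
    best = ConfusionMetrics(
        sensitivity=_ratio(a + e, a + e + c),
        specificity=_ratio(d + f, d + f + b),
        ppv=_ratio(a + e, a + b + e),
        accuracy=_ratio(a + e + d + f, a + b + c + d + e + f),
    )
    prevalence = None
    if table.population_size:
        prevalence = (a + c) / table.population_size
    return ScenarioMetrics(worst=worst, best=best, prevalence_worst=prevalence)


@dataclass(frozen=True)
class CohortArithmetic:
    """Headline cohort fractions derivable from a linkage table plus the
    population size: how many were flagged, how many of those were linked,
    and how many of the linked were confirmed by the reference."""

    flagged: int
    flagged_fraction: float | None
    linked_fraction: float | None     # (a+b) / (a+b+e)
    confirmed_fraction: float | None  # a / (a+b)
    prevalence_worst: float | None    # (a+c) / population


def cohort_arithmetic(table: LinkageTable) -> CohortArithmetic:
    flagged = table.n_flagged
    pop = table.population_size
    return CohortArithmetic(
        flagged=flagged,
        flagged_fraction=_ratio(flagged, pop) if pop else None,
        linked_fraction=_ratio(table.a + table.b, flagged),
        confirmed_fraction=_ratio(table.a, table.a + table.b),
        prevalence_worst=_ratio(table.a + table.c, pop) if pop else None,
    )


def compare_algorithms(tables: Mapping[str, LinkageTable]) -> pd.DataFrame:
    """One row per algorithm per scenario, deterministic order (input order,
    worst before best); values agree exactly with scenario_analysis."""
    if not tables:
        raise ValueError("at least one linkage table required")
    rows = []
    for name, table in tables.items():
        sm = scenario_analysis(table)
        for scenario, m in (("worst", sm.worst), ("best", sm.best)):
            rows.append(
                {
                    "algorithm": name,
                    "scenario": scenario,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv,
                    "accuracy": m.accuracy,
                    "prevalence_worst": sm.prevalence_worst if scenario == "worst" else None,
                }
            )
    return pd.DataFrame(rows)


def linkage_table_from_labels(
    predicted: Mapping[str, str],
    reference: Mapping[str, str],
    population_size: int | None = None,
) -> LinkageTable:
    """Cross-tabulate predicted labels against reference labels.

    Patients absent from ``reference`` fall in the no-reference-data column;
    patients absent from ``predicted`` (no GP data) fall in the no-GP-data row.
    """
    cells = dict(a=0, b=0, c=0, d=0, e=0, f=0, g=0, h=0)
    for pid, pred in predicted.items():
        ref = reference.get(pid)
        if pred == RA:
            key = "a" if ref == RA else ("b" if ref == NON_RA else "e")
        else:
            key = "c" if ref == RA else ("d" if ref == NON_RA else "f")
        cells[key] += 1
    for pid, ref in reference.items():
        if pid not in predicted:
            cells["g" if ref == RA else "h"] += 1
    return LinkageTable(**cells, population_size=population_size)


def format_percent(value: float | None, decimals: int = 1) -> str:
    """Render a proportion as a percentage string at the requested precision."""
    if value is None:
        return "NA"
    return f"{100 * value:.{decimals}f}%"


def prevalence_by_year(
    events: Sequence[CodedEvent],
    classifier: Callable[[PatientRecord], str],
    years: Sequence[int],
    population: Sequence[str] | None = None,
) -> pd.Series:
    """Cumulative-code prevalence trajectory.

    For each calendar year, every patient's record is rebuilt from events
    dated up to 31 December of that year and re-classified; the value is the
    fraction of the cohort flagged RA.  The cohort is ``population`` if
    given, else all patients appearing anywhere in the event stream.  With a
    monotone classifier (adding codes never unflags) the series is
    non-decreasing.
    """
    pids = sorted(set(population) if population is not None else {e.patient_id for e in events})
    out = {}
    for year in years:
        sub = [e for e in events if e.date.year <= year]
        records = {r.patient_id: r for r in build_records(sub)}
        flagged = 0
        for pid in pids:
            rec = records.get(pid, PatientRecord(patient_id=pid))
            if classifier(rec) == RA:
                flagged += 1
        out[year] = flagged / len(pids) if pids else float("nan")
    return pd.Series(out, name="prevalence")
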