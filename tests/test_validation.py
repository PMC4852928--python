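import datetime as dt

import numpy as np
import pytest

from codephen.events import NON_RA, RA, CodedEvent
from codephen.published import (
    ABMU_POPULATION,
    DATA_DRIVEN_TABLE,
    PUBLISHED_TABLES,
    QOF_TABLE,
    THOMAS_TABLE,
)
from codephen.validation import (
    LinkageTable,
    cohort_arithmetic,
    compare_algorithms,
    confusion_metrics,
    format_percent,
    linkage_table_from_labels,
    prevalence_by_year,
    scenario_analysis,
)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(10, 0, 0, 10)
        assert (m.sensitivity, m.specificity, m.ppv, m.accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_reported_as_undefined_not_raised(self):
        m = confusion_metrics(0, 0, 5, 5)
        assert m.sensitivity == 0.0 and m.ppv is None
        assert m.specificity == 1.0

    def test_hand_arithmetic_on_2x2(self):
        m = confusion_metrics(tp=1588, fp=268, fn=254, tn=9967)
        assert m.sensitivity == pytest.approx(1588 / 1842)
        assert m.ppv == pytest.approx(1588 / 1856)
        assert m.accuracy == pytest.approx((1588 + 9967) / (1588 + 268 + 254 + 9967))

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 0)


class TestScenarioAnalysis:
    def test_qof_table_reproduces_reported_metrics(self):
        sm = scenario_analysis(QOF_TABLE)
        assert sm.worst.sensitivity == pytest.approx(1377 / 1588)  # 86.7%
        assert sm.worst.ppv == pytest.approx(1377 / 4741)          # 29.0%
        assert sm.best.sensitivity == pytest.approx(4228 / 4439)   # 95.2%
        assert sm.best.ppv == pytest.approx(4228 / 4741)           # 89.2%
        assert round(100 * sm.worst.specificity) == 99

    def test_no_unlinked_patients_collapses_to_plain_confusion_metrics(self):
        table = LinkageTable(a=10, b=2, c=3, d=85)
        sm = scenario_analysis(table)
        plain = confusion_metrics(tp=10, fp=2, fn=3, tn=85)
        for scenario in (sm.worst, sm.best):
            assert scenario.sensitivity == plain.sensitivity
            assert scenario.specificity == plain.specificity
            assert scenario.ppv == plain.ppv

    @pytest.mark.parametrize("seed", range(10))
    def test_bracketing_worst_below_best(self, seed):
        rng = np.random.default_rng(seed)
        table = LinkageTable(*(int(v) for v in rng.integers(1, 500, size=8)))
        sm = scenario_analysis(table)
        assert sm.worst.sensitivity <= sm.best.sensitivity
        assert sm.worst.ppv <= sm.best.ppv

    def test_worst_case_prevalence_uses_population(self):
        sm = scenario_analysis(DATA_DRIVEN_TABLE)
        assert sm.prevalence_worst == pytest.approx(1588 / ABMU_POPULATION)


class TestLatentBracketing:
    @pytest.mark.parametrize("seed", range(8))
    def test_latent_ppv_inside_bounds_and_sensitivity_below_best(self, seed):
        """With unlinked patients' latent status known, the latent PPV always
        falls inside the [worst, best] scenario band (a/(a+b+e) <= (a+e_RA)/
        (a+b+e) <= (a+e)/(a+b+e) cell-wise), and the latent sensitivity never
        exceeds the best-case bound.  The worst-case sensitivity is the
        linked-stratum sensitivity, so it bounds the latent value only on
        average, not seed by seed."""
        rng = np.random.default_rng(seed)
        n = 3000
        truth = rng.random(n) < 0.2
        # imperfect classifier, independent of linkage
        pred = np.where(truth, rng.random(n) < 0.85, rng.random(n) < 0.03)
        linked = rng.random(n) < 0.5
        predicted = {f"P{i}": (RA if pred[i] else NON_RA) for i in range(n)}
        reference = {f"P{i}": (RA if truth[i] else NON_RA) for i in range(n) if linked[i]}
        latent = {f"P{i}": (RA if truth[i] else NON_RA) for i in range(n)}
        observed = linkage_table_from_labels(predicted, reference)
        sm = scenario_analysis(observed)
        lt = linkage_table_from_labels(predicted, latent)
        latent_m = confusion_metrics(lt.a, lt.b, lt.c, lt.d)
        assert sm.worst.ppv <= latent_m.ppv <= sm.best.ppv
        assert latent_m.sensitivity <= sm.best.sensitivity


def test_cohort_arithmetic_matches_hand_counts():
    ca = cohort_arithmetic(DATA_DRIVEN_TABLE)
    assert ca.flagged == 4279
    assert ca.flagged_fraction == pytest.approx(4279 / 475580)
    assert ca.linked_fraction == pytest.approx(1719 / 4279)
    assert ca.confirmed_fraction == pytest.approx(1323 / 1719)
    assert ca.prevalence_worst == pytest.approx(1588 / 475580)


def test_compare_algorithms_structure_and_consistency():
    report = compare_algorithms(PUBLISHED_TABLES)
    assert len(report) == 6  # three algorithms x two scenarios
    row = report[(report.algorithm == "thomas") & (report.scenario == "worst")].iloc[0]
    assert row.sensitivity == pytest.approx(scenario_analysis(THOMAS_TABLE).worst.sensitivity)


def test_linkage_table_csv_round_trip(tmp_path):
    p = tmp_path / "t.csv"
    QOF_TABLE.to_csv(p)
    back = LinkageTable.from_csv(p, population_size=QOF_TABLE.population_size)
    assert back == QOF_TABLE


def test_linkage_table_from_labels_counts_every_stratum():
    predicted = {"A": RA, "B": RA, "C": NON_RA, "D": NON_RA, "E": RA}
    reference = {"A": RA, "C": RA, "D": NON_RA, "B": NON_RA, "Z": RA}
    t = linkage_table_from_labels(predicted, reference)
    assert (t.a, t.b, t.c, t.d, t.e, t.f, t.g, t.h) == (1, 1, 1, 1, 1, 0, 1, 0)


def test_format_percent_matches_published_rounding():
    assert format_percent(1377 / 1588) == "86.7%"
    assert format_percent(1377 / 4741, 0) == "29%"
    assert format_percent(None) == "NA"


class TestPrevalenceByYear:
    @staticmethod
    def _classifier(record):
        return RA if record.count("N0400") >= 1 else NON_RA

    def test_single_flag_jumps_and_stays(self):
        events = [
            CodedEvent("P1", "N0400", dt.date(2005, 3, 1)),
            CodedEvent("P2", "Z0001", dt.date(2001, 1, 1)),
        ]
        series = prevalence_by_year(events, self._classifier, range(2003, 2008))
        assert series.loc[2004] == 0.0
        assert (series.loc[2005:] == 0.5).all()
        assert series.is_monotonic_increasing

    def test_empty_cohort_gives_empty_report(self):
        series = prevalence_by_year([], self._classifier, [])
        assert series.empty

    @pytest.mark.parametrize("year", [2003, 2007, 2011])
    def test_agrees_with_bruteforce_reclassification(self, year, small_cohort):
        """Year-T prevalence equals classifying per-patient code bags rebuilt
        by hand from only the events dated <= T."""
        _, events, _, _ = small_cohort
        events = events[:2000]
        series = prevalence_by_year(events, self._classifier, [year])
        pids = sorted({e.patient_id for e in events})
        flagged = 0
        for pid in pids:
            n0400 = sum(
                1
                for e in events
                if e.patient_id == pid and e.code == "N0400" and e.date.year <= year
            )
            flagged += n0400 >= 1
        assert series.loc[year] == pytest.approx(flagged / len(pids))


from hypothesis import given, settings, strategies as st

_cell = st.integers(0, 10**6)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(a=_cell, b=_cell, c=_cell, d=_cell, e=_cell, f=_cell)
def test_scenario_bounds_ordered_for_any_table(a, b, c, d, e, f):
    """Whatever the cells, worst-case sensitivity and PPV never exceed the
    best case, with equality when no flagged patient is unlinked (e = 0)."""
    sm = scenario_analysis(LinkageTable(a=a, b=b, c=c, d=d, e=e, f=f))
    if sm.worst.sensitivity is not None and sm.best.sensitivity is not None:
        assert sm.worst.sensitivity <= sm.best.sensitivity
        if e == 0:
            assert sm.worst.sensitivity == sm.best.sensitivity
    if sm.worst.ppv is not None:
        assert sm.worst.ppv <= sm.best.ppv
        if e == 0:
            assert sm.worst.ppv == sm.best.ppv
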