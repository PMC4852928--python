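"""Core EHR data types and flat-file IO.

The substrate of the whole pipeline is a bag of coded clinical events: one row
per (patient, code, date, source).  Codes are treated as opaque 5-character
hierarchical strings (UK primary-care Read codes are the motivating
terminology: the code prefix encodes the chapter hierarchy, so related
diagnoses or dose variants of one drug share a prefix).  No external code
dictionary is consulted; hierarchy lives entirely in the prefixes.

Feature values downstream are occurrence *counts*, not presence flags; repeat
codes on the same date are counted as separate events (deduplication is a
recording-practice question this package deliberately does not decide for the
user).
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateInputError, InputFormatError

RA = "RA"
NON_RA = "nonRA"
UNLABELLED = "unlabelled"

SOURCES = ("primary", "secondary")
GROUP_KINDS = ("diagnosis", "medication", "exclusion", "other")

# 1-5 alphanumeric characters, optionally padded with trailing dots to width 5
_CODE_RE = re.compile(r"^[A-Za-z0-9]{1,5}\.{0,4}$")


def is_valid_code(code: str) -> bool:
    return bool(code) and len(code) <= 5 and bool(_CODE_RE.match(code))


@dataclass(frozen=True)
class CodedEvent:
    """One coded clinical event for one patient."""

    patient_id: str
    code: str
    date: _dt.date
    source: str = "primary"

    def __post_init__(self):
        if not is_valid_code(self.code):
            raise InputFormatError(f"invalid clinical code {self.code!r}")
        if self.source not in SOURCES:
            raise InputFormatError(f"unknown source {self.source!r}")


@dataclass
class PatientRecord:
    """Per-patient bag of codes with the gold-standard label, if linked.

    ``linked`` records whether the patient has a secondary-care record at all;
    a patient can be linked yet unlabelled only transiently — a definite label
    implies linkage.
    """

    patient_id: str
    code_counts: dict[str, int] = field(default_factory=dict)
    label: str = UNLABELLED
    linked: bool = False

    def __post_init__(self):
        if self.label not in (RA, NON_RA, UNLABELLED):
            raise ConfigurationError(f"unknown label {self.label!r}")
        if self.label != UNLABELLED and not self.linked:
            raise ConfigurationError(
                f"patient {self.patient_id}: labelled {self.label} but not linked"
            )
        if any(c < 0 for c in self.code_counts.values()):
            raise ConfigurationError(f"patient {self.patient_id}: negative code count")

    def count(self, code: str) -> int:
        return self.code_counts.get(code, 0)


@dataclass(frozen=True)
class CodeGroup:
    """A named set of clinical codes aggregated to one variable."""

    name: str
    codes: frozenset[str]
    kind: str = "other"

    def __post_init__(self):
        if not self.codes:
            raise ConfigurationError(f"code group {self.name!r} is empty")
        if self.kind not in GROUP_KINDS:
            raise ConfigurationError(f"code group {self.name!r}: unknown kind {self.kind!r}")


class FeatureMatrix:
    """Patients x features matrix of non-negative occurrence counts.

    Rows are labelled patients only; absence of a code is a count of 0 (there
    are no missing cells).  ``labels`` holds "RA"/"nonRA" per row.
    """

    def __init__(
        self,
        patient_ids: Sequence[str],
        feature_names: Sequence[str],
        values: np.ndarray,
        labels: Sequence[str],
    ):
        values = np.asarray(values, dtype=np.int64)
        if values.shape != (len(patient_ids), len(feature_names)):
            raise ConfigurationError(
                f"matrix shape {values.shape} does not match "
                f"{len(patient_ids)} patients x {len(feature_names)} features"
            )
        if (values < 0).any():
            raise ConfigurationError("negative counts in feature matrix")
        labels = list(labels)
        if len(labels) != len(patient_ids):
            raise ConfigurationError("labels length does not match patients")
        bad = set(labels) - {RA, NON_RA}
        if bad:
            raise ConfigurationError(f"feature-matrix labels must be RA/nonRA, got {bad}")
        self.patient_ids = list(patient_ids)
        self.feature_names = list(feature_names)
        self.values = values
        self.labels = labels

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def y(self) -> np.ndarray:
        """Boolean outcome vector: True where the gold standard says RA."""
        return np.array([lab == RA for lab in self.labels], dtype=bool)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "patient_id", self.patient_ids)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, dtype={"patient_id": str})
        if df.columns[0] != "patient_id" or df.columns[-1] != "label":
            raise InputFormatError(
                "feature-matrix file must have patient_id first and label last"
            )
        feats = list(df.columns[1:-1])
        return cls(df["patient_id"].tolist(), feats, df[feats].to_numpy(), df["label"].tolist())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureMatrix)
            and self.patient_ids == other.patient_ids
            and self.feature_names == other.feature_names
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# Event-file IO

_EVENT_HEADER = ["patient_id", "code", "date", "source"]


def read_events(path) -> list[CodedEvent]:
    """Read coded events from a comma-delimited file.

    Expected header: ``patient_id,code,date,source`` with ISO-8601 dates.
    Malformed rows are reported collectively with their line numbers.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InputFormatError(f"{path}: empty event file") from None
        if [h.strip() for h in header] != _EVENT_HEADER:
            raise InputFormatError(
                f"{path}: expected header {','.join(_EVENT_HEADER)}, got {','.join(header)}"
            )
        events: list[CodedEvent] = []
        bad: list[int] = []
        reasons: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                pid, code, date_s, source = (f.strip() for f in row)
                events.append(CodedEvent(pid, code, _dt.date.fromisoformat(date_s), source))
            except (ValueError, InputFormatError) as exc:
                bad.append(lineno)
                reasons.append(str(exc))
        if bad:
            raise InputFormatError(
                f"{path}: {len(bad)} malformed event row(s): {reasons[0]}", lines=bad
            )
    return events


def write_events(events: Iterable[CodedEvent], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_HEADER)
        for ev in events:
            writer.writerow([ev.patient_id, ev.code, ev.date.isoformat(), ev.source])


def read_labels(path) -> dict[str, str]:
    """Read a gold-standard label file with header ``patient_id,label``."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["patient_id", "label"]:
        raise InputFormatError(f"{path}: expected header patient_id,label")
    bad = set(df["label"]) - {RA, NON_RA}
    if bad:
        raise InputFormatError(f"{path}: unknown labels {sorted(bad)}")
    return dict(zip(df["patient_id"], df["label"]))


def write_labels(labels: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"patient_id": list(labels), "label": [labels[p] for p in labels]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Record construction and feature matrices


def build_records(
    events: Iterable[CodedEvent],
    labels: Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Aggregate events into per-patient code-count records.

    Patients present in ``labels`` are marked linked with that label; patients
    seen only in the events stream are unlabelled and unlinked.  Patients in
    ``labels`` with no events at all are retained with an empty bag, mirroring
    the "no primary-care data" stratum of linkage tables.
    """
    labels = dict(labels or {})
    counts: dict[str, dict[str, int]] = {}
    for ev in events:
        bag = counts.setdefault(ev.patient_id, {})
        bag[ev.code] = bag.get(ev.code, 0) + 1
    pids = sorted(set(counts) | set(labels))
    records = []
    for pid in pids:
        label = labels.get(pid, UNLABELLED)
        records.append(
            PatientRecord(
                patient_id=pid,
                code_counts=counts.get(pid, {}),
                label=label,
                linked=label != UNLABELLED,
            )
        )
    return records


def build_feature_matrix(
    records: Sequence[PatientRecord],
    groups: Sequence[CodeGroup] | None = None,
) -> FeatureMatrix:
    """Materialise labelled records as a counts matrix.

    With ``groups=None`` there is one column per distinct raw code; with
    groups, one column per group valued as the sum of member-code counts
    (additivity over members is the defining property of aggregation).
    """
    labelled = [r for r in records if r.label != UNLABELLED]
    if not labelled:
        raise DegenerateInputError("no labelled records to build a feature matrix from")
    if groups is not None:
        if not groups:
            raise ConfigurationError("empty group list")
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate group names")
        cols = names
        values = np.zeros((len(labelled), len(cols)), dtype=np.int64)
        for j, g in enumerate(groups):
            for i, rec in enumerate(labelled):
                values[i, j] = sum(rec.code_counts.get(c, 0) for c in g.codes)
    else:
        cols = sorted({c for r in labelled for c in r.code_counts})
        index = {c: j for j, c in enumerate(cols)}
        values = np.zeros((len(labelled), len(cols)), dtype=np.int64)
        for i, rec in enumerate(labelled):
            for c, n in rec.code_counts.items():
                values[i, index[c]] = n
    return FeatureMatrix(
        [r.patient_id for r in labelled], cols, values, [r.label for r in labelled]
    )


# ---------------------------------------------------------------------------
# Code-group configuration files


def read_code_groups(path) -> list[CodeGroup]:
    """Load a YAML mapping ``group name -> {kind, codes: [...]}``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputFormatError(f"{path}: expected a mapping of group name -> spec")
    groups = []
    for name in sorted(raw):
        spec = raw[name]
        groups.append(
            CodeGroup(
                name=name,
                codes=frozenset(spec["codes"]),
                kind=spec.get("kind", "other"),
            )
        )
    return groups


def write_code_groups(groups: Sequence[CodeGroup], path) -> None:
    payload = {
        g.name: {"kind": g.kind, "codes": sorted(g.codes)} for g in groups
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
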