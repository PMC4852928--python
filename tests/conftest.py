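import datetime as dt

import numpy as np
import pytest

from codephen.events import NON_RA, RA, CodedEvent, FeatureMatrix
from codephen.simulate import SimulationConfig, simulate


def make_matrix(columns: dict[str, list[int]], labels: list[str]) -> FeatureMatrix:
    """Hand-build a small feature matrix from column lists."""
    names = list(columns)
    values = np.array([columns[c] for c in names], dtype=np.int64).T
    pids = [f"P{i:03d}" for i in range(len(labels))]
    return FeatureMatrix(pids, names, values, labels)


@pytest.fixture
def screening_example():
    """10 labelled patients; code X carried by 3 of 4 cases and 1 of 6 controls."""
    labels = [RA] * 4 + [NON_RA] * 6
    return make_matrix({"X": [1, 2, 1, 0, 1, 0, 0, 0, 0, 0]}, labels)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic linked cohort reused across read-only tests."""
    config = SimulationConfig(n_patients=400, n_noise_codes=30, seed=11)
    events, labels, truth = simulate(config)
    return config, events, labels, truth


def random_event(rng, n_patients=10, n_codes=6) -> CodedEvent:
    return CodedEvent(
        patient_id=f"P{rng.integers(n_patients):03d}",
        code=f"C{rng.integers(n_codes):04d}",
        date=dt.date(2005, 1, 1) + dt.timedelta(days=int(rng.integers(1000))),
    )
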