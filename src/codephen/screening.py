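"""Phase-1 univariate predictor screening by relative code frequency.

For each code x with N_x1 carrier cases and N_x2 carrier controls among N
labelled patients, the screening statistic is the relative frequency
difference

    rFeq(x) = p(RA | x) - p(nonRA | x)

Two denominator conventions are provided behind a flag.  ``population``
divides both carrier counts by N (all labelled patients), i.e.
rFeq = (N_x1 - N_x2)/N; ``carriers`` divides by the carrier count
N_x1 + N_x2, the conditional prevalence difference among carriers.  The two
conventions provably select the same codes: both are positive exactly when
N_x1 > N_x2.  The statistic deliberately rewards codes that are rare overall
but concentrated in cases — the rare-but-predictive codes a frequency cutoff
would discard.  Presence means count >= 1; no multiple-testing correction is
applied (this is a deliberately permissive univariate pre-filter, not an
inference step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .events import FeatureMatrix

DENOMINATORS = ("population", "carriers")


@dataclass(frozen=True)
class ScreeningResult:
    code: str
    n_case: int
    n_control: int
    n_total: int
    rfeq: float
    selected: bool


def screen(matrix: FeatureMatrix, denominator: str = "population") -> list[ScreeningResult]:
    """Rank every feature of ``matrix`` by rFeq, descending.

    Selection is strict positivity (more frequent in cases than controls);
    ties in rfeq are broken by lexicographic code order so output is
    deterministic.  Codes carried by no patient get rfeq 0 and are emitted
    unselected, keeping downstream joins total.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    y = matrix.y
    if y.all() or not y.any():
        raise DegenerateInputError("screening requires at least one case and one control")
    present = matrix.values >= 1
    n_case = present[y].sum(axis=0).astype(int)
    n_control = present[~y].sum(axis=0).astype(int)
    n_total = matrix.n_patients
    diff = n_case - n_control
    if denominator == "population":
        rfeq = diff / n_total
    else:
        carriers = n_case + n_control
        with np.errstate(invalid="ignore"):
            rfeq = np.where(carriers > 0, diff / np.where(carriers > 0, carriers, 1), 0.0)
    results = [
        ScreeningResult(
            code=matrix.feature_names[j],
            n_case=int(n_case[j]),
            n_control=int(n_control[j]),
            n_total=n_total,
            rfeq=float(rfeq[j]),
            selected=bool(rfeq[j] > 0),
        )
        for j in range(matrix.n_features)
    ]
    results.sort(key=lambda r: (-r.rfeq, r.code))
    return results


def selected_codes(results: list[ScreeningResult]) -> list[str]:
    """Codes passing the screen, in rank order."""
    return [r.code for r in results if r.selected]


def to_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "code": [r.code for r in results],
            "n_case": [r.n_case for r in results],
            "n_control": [r.n_control for r in results],
            "rfeq": [r.rfeq for r in results],
            "selected": [r.selected for r in results],
        }
    )


def write_screening(results: list[ScreeningResult], path) -> None:
    to_frame(results).to_csv(path, index=False)
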