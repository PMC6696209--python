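"""Test–retest reliability: ICC(2,1), SEM and minimal detectable change.

* ICC(2,1): two-way random effects, absolute agreement, single measurement,
  from the two-way ANOVA decomposition of an n × 2 (test, retest) matrix.
* SEM = SD · sqrt(1 − ICC), with SD the pooled standard deviation of all
  test and retest observations.
* MDC = SEM · 1.96 · sqrt(2) — the smallest individual change that exceeds
  measurement error at 95% confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import MeasureTable

__all__ = ["icc_two_way", "sem", "mdc", "ReliabilityResult", "reliability_report"]


def icc_two_way(pairs: np.ndarray) -> float:
    """ICC(2,1) of an n × 2 matrix of (test, retest) values."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an n x 2 matrix")
    if np.isnan(pairs).any():
        raise ValueError("pairs must be complete; drop incomplete rows first")
    n, k = pairs.shape
    if n < 3:
        raise ValueError("need at least 3 complete pairs")

    grand = pairs.mean()
    row_means = pairs.mean(axis=1)
    col_means = pairs.mean(axis=0)
    ss_total = float(((pairs - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance; ICC undefined")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    )


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement, SD · sqrt(1 − ICC)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if icc > 1:
        raise ValueError("icc cannot exceed 1")
    return sd * math.sqrt(1.0 - icc)


def mdc(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence, SEM · 1.96 · sqrt(2)."""
    if sem_value < 0:
        raise ValueError("sem must be non-negative")
    return sem_value * 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class ReliabilityResult:
    measure_id: str
    icc: float
    sem: float
    mdc: float
    sd_retest_sample: float
    n_pairs: int


def reliability_report(
    test_table: MeasureTable,
    retest_table: MeasureTable,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-measure ICC/SEM/MDC from paired test and retest sessions.

    Only subjects present in both sessions contribute; rows with a missing
    value in either session are dropped per measure.  SD is pooled over all
    retained test and retest observations.
    """
    ids = list(ids) if ids is not None else test_table.measure_ids
    common = test_table.values.index.intersection(retest_table.values.index)
    if len(common) < 3:
        raise ValueError("need at least 3 subjects present in both sessions")
    rows = []
    for m in ids:
        both = pd.DataFrame(
            {
                "test": test_table.values.loc[common, m],
                "retest": retest_table.values.loc[common, m],
            }
        ).dropna()
        icc = icc_two_way(both.to_numpy())
        sd = float(np.std(both.to_numpy().ravel(), ddof=1))
        s = sem(sd, icc)
        rows.append(
            {
                "measure_id": m,
                "icc": icc,
                "sem": s,
                "mdc": mdc(s),
                "sd_retest_sample": sd,
                "n_pairs": len(both),
            }
        )
    return pd.DataFrame(rows).set_index("measure_id")
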