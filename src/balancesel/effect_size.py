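"""Standardized mean differences between PD and control groups.

The SMD of a measure is (mean_PD − mean_HC) / S.  Two denominators are
supported:

* ``"paper"`` (default): S = sqrt[(SD₁²/n₁ + SD₂²/n₂) · (n₁n₂/(n₁+n₂))],
  which reduces to the classical pooled SD when n₁ = n₂ and SD₁ = SD₂;
* ``"cohen_pooled"``: Cohen's pooled SD,
  S = sqrt[((n₁−1)SD₁² + (n₂−1)SD₂²)/(n₁+n₂−2)].

Effect magnitudes follow the conventional bands: |SMD| ≥ 0.20 small,
≥ 0.50 moderate, ≥ 0.80 large.  Measures with |SMD| above a sensitivity
threshold (default 0.50) are retained as disease-sensitive.  Because the
impairment direction varies by measure, thresholding uses the absolute
value; the signed SMD is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation import ImputedEnsemble, pool_over_ensemble
from .tables import MeasureTable

__all__ = [
    "smd",
    "classify_smd",
    "EffectSizeResult",
    "compute_effect_sizes",
    "compute_effect_sizes_pooled",
    "filter_by_smd",
]

_VARIANTS = ("paper", "cohen_pooled")


def smd(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "paper",
) -> float:
    """Standardized mean difference (group 1 minus group 2)."""
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if variant == "paper":
        s = math.sqrt((sd1**2 / n1 + sd2**2 / n2) * (n1 * n2 / (n1 + n2)))
    else:
        s = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s == 0:
        raise ValueError("degenerate denominator: both group SDs are zero")
    return (mean1 - mean2) / s


def classify_smd(value: float) -> str:
    """Magnitude band of an SMD: negligible / small / moderate / large."""
    a = abs(value)
    if a >= 0.80:
        return "large"
    if a >= 0.50:
        return "moderate"
    if a >= 0.20:
        return "small"
    return "negligible"


@dataclass(frozen=True)
class EffectSizeResult:
    measure_id: str
    mean_pd: float
    mean_hc: float
    sd_pd: float
    sd_hc: float
    n_pd: int
    n_hc: int
    smd: float
    abs_smd: float
    passes_threshold: bool


def _group_stats(table: MeasureTable) -> pd.DataFrame:
    pd_vals = table.values.loc[table.group == "PD"]
    hc_vals = table.values.loc[table.group == "HC"]
    return pd.DataFrame(
        {
            "mean_pd": pd_vals.mean(),
            "mean_hc": hc_vals.mean(),
            "sd_pd": pd_vals.std(ddof=1),
            "sd_hc": hc_vals.std(ddof=1),
            "n_pd": pd_vals.notna().sum(),
            "n_hc": hc_vals.notna().sum(),
        }
    )


def compute_effect_sizes(
    table: MeasureTable, threshold: float = 0.5, variant: str = "paper"
) -> pd.DataFrame:
    """Per-measure SMD table (one row per measure, indexed by measure_id)."""
    stats = _group_stats(table)
    smds = [
        smd(
            row.mean_pd, row.sd_pd, int(row.n_pd),
            row.mean_hc, row.sd_hc, int(row.n_hc),
            variant=variant,
        )
        for row in stats.itertuples()
    ]
    stats["smd"] = smds
    stats["abs_smd"] = np.abs(stats["smd"])
    stats["passes_threshold"] = stats["abs_smd"] > threshold
    stats.index.name = "measure_id"
    return stats


def compute_effect_sizes_pooled(
    ensemble: ImputedEnsemble, threshold: float = 0.5, variant: str = "paper"
) -> pd.DataFrame:
    """Effect sizes pooled over an imputed ensemble (element-wise mean).

    Numeric columns are averaged across the completed datasets; the
    pass flag is recomputed from the pooled |SMD|.
    """
    pooled = pool_over_ensemble(
        lambda t: compute_effect_sizes(t, threshold=threshold, variant=variant)[
            ["mean_pd", "mean_hc", "sd_pd", "sd_hc", "n_pd", "n_hc", "smd"]
        ],
        ensemble,
    )
    out = pooled.mean.copy()
    out["abs_smd"] = out["smd"].abs()
    out["passes_threshold"] = out["abs_smd"] > threshold
    out["smd_between_imputation_sd"] = pooled.sd["smd"]
    out.index.name = "measure_id"
    return out


def filter_by_smd(effects: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Measures with |SMD| > threshold, sorted by |SMD| descending.

    Ties are broken by measure_id for determinism.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    kept = effects[effects["abs_smd"] > threshold].copy()
    kept["passes_threshold"] = True
    order = kept.reset_index().sort_values(
        ["abs_smd", "measure_id"], ascending=[False, True]
    )["measure_id"]
    return kept.loc[order]


def results_from_frame(effects: pd.DataFrame) -> list[EffectSizeResult]:
    """Materialize EffectSizeResult records from an effect-size table."""
    return [
        EffectSizeResult(
            measure_id=str(mid),
            mean_pd=float(r["mean_pd"]),
            mean_hc=float(r["mean_hc"]),
            sd_pd=float(r["sd_pd"]),
            sd_hc=float(r["sd_hc"]),
            n_pd=int(r["n_pd"]),
            n_hc=int(r["n_hc"]),
            smd=float(r["smd"]),
            abs_smd=float(r["abs_smd"]),
            passes_threshold=bool(r["passes_threshold"]),
        )
        for mid, r in effects.iterrows()
    ]
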