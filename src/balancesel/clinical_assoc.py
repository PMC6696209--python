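"""Associations between selected measures and clinical scales.

Each selected objective measure is correlated (Spearman) with each clinical
scale.  Dynamic balance (Mini-BEST) and balance confidence (ABC) exist for
both groups, so those correlations use the pooled cohort; quality-of-life
(PDQ-39) and disease-severity (MDS-UPDRS) scales exist only for the PD
group and are tested in PD subjects only.  P-values are Benjamini–Hochberg
adjusted within each scale family (one family = one scale across all
selected measures) and flagged significant at adjusted p < alpha
(default 0.01).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imputation import ImputedEnsemble
from .tables import MeasureTable

__all__ = ["SCALE_COHORTS", "associate", "associate_ensemble", "polar_plot"]

#: clinical scale -> cohort in which the association is tested
SCALE_COHORTS: dict[str, str] = {
    "MiniBEST": "all",
    "ABC": "all",
    "PDQ39_total": "PD_only",
    "PDQ39_mobility": "PD_only",
    "UPDRS_total": "PD_only",
    "UPDRS_II": "PD_only",
    "UPDRS_III": "PD_only",
}


def associate(
    measures: MeasureTable,
    clinical: pd.DataFrame,
    selected_ids: list[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Spearman correlations of selected measures against clinical scales.

    Returns one row per (measure, scale) with rho, raw and BH-adjusted p,
    the significance flag (adjusted p < alpha) and the cohort used.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    missing = set(selected_ids) - set(measures.measure_ids)
    if missing:
        raise KeyError(f"unknown measure_id(s): {sorted(missing)}")
    common = measures.values.index.intersection(clinical.index)
    if len(common) == 0:
        raise ValueError("no shared subjects between measures and clinical table")

    group = measures.group.loc[common]
    rows = []
    for scale in clinical.columns:
        cohort = SCALE_COHORTS.get(scale, "PD_only")
        subjects = common if cohort == "all" else common[group == "PD"]
        scale_vals = clinical.loc[subjects, scale]
        ok = scale_vals.notna()
        if (ok & (group.loc[subjects] == "PD")).sum() < 3:
            raise ValueError(f"scale {scale!r}: fewer than 3 non-missing PD values")
        p_raws, rhos = [], []
        for m in selected_ids:
            x = measures.values.loc[subjects, m]
            keep = ok & x.notna()
            res = stats.spearmanr(x[keep], scale_vals[keep])
            rhos.append(float(res.statistic))
            p_raws.append(float(res.pvalue))
        _, p_adj, _, _ = multipletests(p_raws, method="fdr_bh")
        for m, rho, p_raw, padj in zip(selected_ids, rhos, p_raws, p_adj):
            rows.append(
                {
                    "measure_id": m,
                    "scale": scale,
                    "rho": rho,
                    "p_raw": p_raw,
                    "p_adjusted": float(padj),
                    "significant": bool(padj < alpha),
                    "cohort_used": cohort,
                }
            )
    report = pd.DataFrame(rows)
    # cohort-routing invariant
    routed = report["scale"].map(lambda s: SCALE_COHORTS.get(s, "PD_only"))
    assert (report["cohort_used"] == routed).all()
    return report


def associate_ensemble(
    ensemble: ImputedEnsemble,
    clinical: pd.DataFrame,
    selected_ids: list[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Association report pooled over an imputed ensemble.

    Rho and raw p are averaged element-wise across the completed datasets;
    the BH adjustment and significance flag are then applied to the pooled
    raw p-values, per scale family.
    """
    reports = [
        associate(ds, clinical, selected_ids, alpha=alpha) for ds in ensemble.datasets
    ]
    base = reports[0][["measure_id", "scale", "cohort_used"]].copy()
    base["rho"] = np.mean([r["rho"].to_numpy() for r in reports], axis=0)
    base["p_raw"] = np.mean([r["p_raw"].to_numpy() for r in reports], axis=0)
    adj = []
    for scale, sub in base.groupby("scale", sort=False):
        _, p_adj, _, _ = multipletests(sub["p_raw"].to_numpy(), method="fdr_bh")
        adj.append(pd.Series(p_adj, index=sub.index))
    base["p_adjusted"] = pd.concat(adj).sort_index()
    base["significant"] = base["p_adjusted"] < alpha
    return base[
        ["measure_id", "scale", "rho", "p_raw", "p_adjusted", "significant", "cohort_used"]
    ]


def polar_plot(report: pd.DataFrame, cat, path, alpha_rho: float | None = None) -> None:
    """Polar chart of |rho| per measure, one panel per scale.

    Measures are placed around the circle grouped by domain; an optional
    dashed circle marks a significance threshold on |rho|.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scales = list(report["scale"].unique())
    n = len(scales)
    ncol = min(n, 4)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(
        nrow, ncol, subplot_kw={"projection": "polar"}, figsize=(4 * ncol, 4 * nrow)
    )
    axes = np.atleast_1d(axes).ravel()
    order = sorted(
        report["measure_id"].unique(), key=lambda m: (cat.get(m).domain.value, m)
    )
    theta = np.linspace(0, 2 * np.pi, len(order), endpoint=False)
    for ax, scale in zip(axes, scales):
        sub = report[report["scale"] == scale].set_index("measure_id").loc[order]
        ax.bar(theta, sub["rho"].abs(), width=2 * np.pi / max(len(order), 1) * 0.8)
        if alpha_rho is not None:
            ax.plot(
                np.linspace(0, 2 * np.pi, 100),
                np.full(100, alpha_rho),
                "k--",
                linewidth=1,
            )
        ax.set_title(scale)
        ax.set_xticks(theta)
        ax.set_xticklabels([cat.get(m).domain.value for m in order], fontsize=5)
        ax.set_ylim(0, 1)
    for ax in axes[len(scales):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
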