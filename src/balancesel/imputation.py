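"""Two-track completion of a measure table with categorized missingness.

Cells missing because the subject fell (A) or showed no detectable
anticipatory adjustment (D) are not missing at random — they mark the most
impaired subjects.  Those cells get a single worst-case value: the worst
observed value of the measure, pushed a further 2 observed SDs in the
impaired direction.  Cells missing for administrative or technical reasons
(B skipped, C unusable sensor data, E noisy baseline) are treated as
recoverable and completed by multiple imputation: chained equations with
predictive-mean-matching donor draws, conditioning on group membership and
all other measures, producing ``m`` completed datasets (default 25).
Downstream statistics are averaged over the completed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .catalog import Catalogue, ImpairmentDirection
from .tables import MeasureTable, MissCode, WORST_CASE_CODES, MI_CODES

__all__ = [
    "MeasureTable",
    "MissCode",
    "ImputedEnsemble",
    "TaskRemoval",
    "drop_high_missing_tasks",
    "impute_worst_case",
    "impute_multiple",
    "impute_table",
    "pool_over_ensemble",
    "PooledStat",
]


@dataclass
class TaskRemoval:
    table: MeasureTable
    catalogue: Catalogue
    #: task value -> {"pooled": rate, "PD": rate, "HC": rate}
    removed_tasks: dict[str, dict[str, float]]


@dataclass
class ImputedEnsemble:
    """M completed copies of one measure table.

    Worst-case (A/D) cells are identical across members; multiply imputed
    (B/C/E) cells differ between members.
    """

    datasets: tuple[MeasureTable, ...]
    #: measure_id -> (anchor worst value, observed SD, imputed value)
    worst_case_anchors: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def provenance(self) -> pd.DataFrame:
        """Per-cell imputation track: '', 'worst_case' or 'mi'."""
        codes = self.datasets[0].miss_code
        out = pd.DataFrame("", index=codes.index, columns=codes.columns)
        arr = codes.to_numpy()
        out[:] = np.where(
            np.isin(arr, sorted(WORST_CASE_CODES)),
            "worst_case",
            np.where(np.isin(arr, sorted(MI_CODES)), "mi", ""),
        )
        return out


def drop_high_missing_tasks(
    table: MeasureTable,
    cat: Catalogue,
    threshold: float = 0.20,
    trigger: str = "pooled",
) -> TaskRemoval:
    """Remove every measure of any task whose missingness exceeds ``threshold``.

    ``trigger`` selects the rate that is compared against the threshold:
    ``"pooled"`` (default) uses the whole-cohort missing fraction of the
    task's cells; ``"pd_or_pooled"`` also removes a task whose PD-group rate
    alone exceeds the threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if trigger not in ("pooled", "pd_or_pooled"):
        raise ValueError(f"unknown trigger rule: {trigger!r}")

    rates = table.task_missing_fractions(cat)
    removed: dict[str, dict[str, float]] = {}
    keep_cat = cat
    for task_value, row in rates.iterrows():
        hit = row["pooled"] > threshold
        if trigger == "pd_or_pooled":
            hit = hit or row["PD"] > threshold
        if hit:
            removed[task_value] = {k: float(v) for k, v in row.items()}
            keep_cat = Catalogue(
                tuple(d for d in keep_cat.descriptors if d.task.value != task_value)
            )
    new_table = table.select_measures(keep_cat.ids) if removed else table.copy()
    return TaskRemoval(table=new_table, catalogue=keep_cat, removed_tasks=removed)


def _worst_case_value(
    observed: np.ndarray, direction: ImpairmentDirection
) -> tuple[float, float, float]:
    sd = float(np.std(observed, ddof=1))
    if direction is ImpairmentDirection.HIGHER_IS_WORSE:
        worst = float(np.max(observed))
        return worst, sd, worst + 2.0 * sd
    worst = float(np.min(observed))
    return worst, sd, worst - 2.0 * sd


def impute_worst_case(
    table: MeasureTable, cat: Catalogue
) -> tuple[MeasureTable, dict[str, tuple[float, float, float]]]:
    """Fill A/D cells with the worst observed value +/- 2 observed SD.

    The anchor (worst value), the observed SD and the imputed value are
    returned per measure for the audit trail.  Cells missing for other
    reasons are untouched.
    """
    values = table.values.copy()
    codes = table.miss_code
    anchors: dict[str, tuple[float, float, float]] = {}
    for m in table.measure_ids:
        col_codes = codes[m].to_numpy()
        target = np.isin(col_codes, sorted(WORST_CASE_CODES)) & values[m].isna().to_numpy()
        if not target.any():
            continue
        observed = values[m].dropna().to_numpy()
        if observed.size < 2:
            raise ValueError(
                f"measure {m!r} has fewer than 2 observed values; SD undefined"
            )
        direction = cat.get(m).impairment_direction
        worst, sd, imputed = _worst_case_value(observed, direction)
        values.loc[target, m] = imputed
        anchors[m] = (worst, sd, imputed)
    return MeasureTable(values, table.group.copy(), codes.copy()), anchors


def _pmm_chained_fill(
    values: np.ndarray,
    miss_mask: np.ndarray,
    group_ind: np.ndarray,
    rng: np.random.Generator,
    n_sweeps: int = 5,
    n_donors: int = 5,
    ridge: float = 1e-3,
) -> np.ndarray:
    """One completed dataset via chained ridge regressions with PMM draws.

    Each incomplete column is regressed (ridge-regularized least squares,
    observed rows bootstrap-resampled to propagate model uncertainty) on the
    group indicator and all other columns; each missing cell receives the
    observed value of a donor drawn among the ``n_donors`` rows whose
    predictions are closest to the cell's prediction.
    """
    n, p = values.shape
    X = values.copy()
    col_means = np.nanmean(values, axis=0)
    for j in range(p):
        X[miss_mask[:, j], j] = col_means[j]

    incomplete = [j for j in range(p) if miss_mask[:, j].any()]
    # fewest-missing first, a conventional visit order for chained equations
    incomplete.sort(key=lambda j: miss_mask[:, j].sum())

    for _ in range(n_sweeps):
        for j in incomplete:
            obs = ~miss_mask[:, j]
            mis = miss_mask[:, j]
            others = [k for k in range(p) if k != j]
            A = np.column_stack([np.ones(n), group_ind, X[:, others]])
            y = X[:, j]
            idx_obs = np.flatnonzero(obs)
            boot = rng.choice(idx_obs, size=idx_obs.size, replace=True)
            Ab, yb = A[boot], y[boot]
            gram = Ab.T @ Ab
            gram[np.diag_indices_from(gram)] += ridge * idx_obs.size
            beta = np.linalg.solve(gram, Ab.T @ yb)
            pred = A @ beta
            pred_obs = pred[idx_obs]
            y_obs = y[idx_obs]
            for i in np.flatnonzero(mis):
                d = np.abs(pred_obs - pred[i])
                k = min(n_donors, d.size)
                donors = np.argpartition(d, k - 1)[:k]
                X[i, j] = y_obs[donors[rng.integers(0, k)]]
    return X


def impute_multiple(
    table: MeasureTable, m: int = 25, seed: int = 0, n_sweeps: int = 5
) -> ImputedEnsemble:
    """Complete remaining (B/C/E) missing cells by multiple imputation.

    Requires the worst-case track to have been applied first (no NaN cell
    may carry an A or D code).  Reproducible from ``seed``; the ``m``
    completed datasets differ in their multiply imputed cells.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    codes = table.miss_code.to_numpy()
    nan_mask = table.values.isna().to_numpy()
    if (nan_mask & np.isin(codes, sorted(WORST_CASE_CODES))).any():
        raise ValueError(
            "worst-case (A/D) cells are still missing; run impute_worst_case first"
        )
    fully_missing = nan_mask.all(axis=0)
    if fully_missing.any():
        bad = [m_ for m_, f in zip(table.measure_ids, fully_missing) if f]
        raise ValueError(f"measure(s) entirely missing, cannot impute: {bad}")

    if not nan_mask.any():
        return ImputedEnsemble(datasets=tuple(table.copy() for _ in range(m)))

    group_ind = (table.group == "PD").to_numpy(dtype=float)
    values = table.values.to_numpy(dtype=float)
    children = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for k in range(m):
        rng = np.random.default_rng(children[k])
        filled = _pmm_chained_fill(values, nan_mask, group_ind, rng, n_sweeps=n_sweeps)
        df = pd.DataFrame(filled, index=table.values.index, columns=table.values.columns)
        datasets.append(MeasureTable(df, table.group.copy(), table.miss_code.copy()))
    return ImputedEnsemble(datasets=tuple(datasets))


def impute_table(
    table: MeasureTable, cat: Catalogue, m: int = 25, seed: int = 0
) -> ImputedEnsemble:
    """Full two-track imputation: worst case (A/D), then MI (B/C/E)."""
    wc_table, anchors = impute_worst_case(table, cat)
    ensemble = impute_multiple(wc_table, m=m, seed=seed)
    ensemble.worst_case_anchors = anchors
    return ensemble


@dataclass
class PooledStat:
    mean: pd.DataFrame | pd.Series
    sd: pd.DataFrame | pd.Series


def pool_over_ensemble(
    stat_fn: Callable[[MeasureTable], pd.DataFrame | pd.Series],
    ensemble: ImputedEnsemble,
) -> PooledStat:
    """Element-wise mean (and SD, for diagnostics) of a statistic over the
    completed datasets."""
    results = [stat_fn(ds) for ds in ensemble.datasets]
    first = results[0]
    for r in results[1:]:
        if isinstance(first, (pd.DataFrame, pd.Series)):
            if r.shape != first.shape or not r.index.equals(first.index):
                raise ValueError("stat_fn returned mismatched shapes across datasets")
        elif np.shape(r) != np.shape(first):
            raise ValueError("stat_fn returned mismatched shapes across datasets")
    stacked = np.stack([np.asarray(r, dtype=float) for r in results])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=0)
    if isinstance(first, pd.DataFrame):
        return PooledStat(
            mean=pd.DataFrame(mean, index=first.index, columns=first.columns),
            sd=pd.DataFrame(sd, index=first.index, columns=first.columns),
        )
    if isinstance(first, pd.Series):
        return PooledStat(
            mean=pd.Series(mean, index=first.index),
            sd=pd.Series(sd, index=first.index),
        )
    return PooledStat(mean=mean, sd=sd)
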