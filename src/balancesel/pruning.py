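"""Redundancy pruning of the SMD-passing measure set.

Pairs of retained measures whose Spearman correlation exceeds a threshold
(default |rho| > 0.70) are considered collinear.  Violating pairs are
processed in descending |rho| (ties broken lexicographically); for each
pair whose members both still survive, one member is removed:

* **dual-task rule** — if the pair is the single-task/dual-task
  instantiation of the same base measure, the dual-task member is removed
  (simpler test batteries are preferred), whatever its effect size;
* **smaller-SMD rule** — otherwise the member with the smaller |SMD| is
  removed (keep the measure more sensitive to disease).

A removal deactivates the removed measure's remaining pairs, so the
procedure terminates with no violating pair among survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalogue
from .imputation import ImputedEnsemble, pool_over_ensemble
from .tables import MeasureTable

__all__ = [
    "CorrelationMatrix",
    "RemovalRecord",
    "PruningAudit",
    "spearman_matrix",
    "spearman_matrix_pooled",
    "prune",
]


@dataclass
class CorrelationMatrix:
    measure_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        p = len(self.measure_ids)
        if self.rho.shape != (p, p):
            raise ValueError("rho must be square and match measure_ids")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if np.nanmax(np.abs(self.rho)) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-12):
            raise ValueError("rho must have unit diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.measure_ids, columns=self.measure_ids)

    def submatrix(self, ids: list[str]) -> "CorrelationMatrix":
        pos = [self.measure_ids.index(i) for i in ids]
        return CorrelationMatrix(ids, self.rho[np.ix_(pos, pos)])


def spearman_matrix(
    table: MeasureTable, ids: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman rho (average-rank tie handling) on complete data."""
    ids = list(ids) if ids is not None else table.measure_ids
    values = table.values[ids]
    if values.isna().any().any():
        raise ValueError("spearman_matrix requires complete data; impute first")
    constant = values.nunique() <= 1
    if constant.any():
        bad = list(values.columns[constant])
        raise ValueError(f"correlation undefined for constant measure(s): {bad}")
    if len(ids) == 1:
        return CorrelationMatrix(ids, np.ones((1, 1)))
    rho = stats.spearmanr(values.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape == (1, 1):  # spearmanr collapses the 2-column case to a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(ids, rho)


def spearman_matrix_pooled(
    ensemble: ImputedEnsemble, ids: list[str] | None = None
) -> CorrelationMatrix:
    """Element-wise mean Spearman matrix over an imputed ensemble."""
    use_ids = list(ids) if ids is not None else ensemble.datasets[0].measure_ids
    pooled = pool_over_ensemble(
        lambda t: pd.DataFrame(
            spearman_matrix(t, use_ids).rho, index=use_ids, columns=use_ids
        ),
        ensemble,
    )
    return CorrelationMatrix(use_ids, pooled.mean.to_numpy())


@dataclass(frozen=True)
class RemovalRecord:
    removed_id: str
    kept_id: str
    rho: float
    rule_applied: str  # "smaller_smd" | "dual_task"


@dataclass
class PruningAudit:
    removed: list[RemovalRecord]
    survivors: list[str]  # ordered by |SMD| descending

    def to_dict(self) -> dict:
        return {
            "removed": [vars(r) for r in self.removed],
            "survivors": self.survivors,
        }


def _violating_pairs(
    corr: CorrelationMatrix, threshold: float
) -> list[tuple[float, str, str]]:
    ids = corr.measure_ids
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = corr.rho[i, j]
            if abs(r) > threshold:
                a, b = sorted((ids[i], ids[j]))
                out.append((r, a, b))
    # descending |rho|, then lexicographic pair ids
    out.sort(key=lambda t: (-abs(t[0]), t[1], t[2]))
    return out


def prune(
    effects: pd.DataFrame,
    corr: CorrelationMatrix,
    cat: Catalogue,
    threshold: float = 0.70,
) -> PruningAudit:
    """Greedy collinearity pruning with the dual-task and smaller-SMD rules.

    ``effects`` must be an effect-size table (indexed by measure_id, with an
    ``abs_smd`` column) covering exactly the ids of ``corr``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    ids = list(corr.measure_ids)
    if set(ids) != set(effects.index):
        raise ValueError("effects and correlation matrix must cover the same measures")

    abs_smd = effects["abs_smd"]
    alive = set(ids)
    removed: list[RemovalRecord] = []

    for r, a, b in _violating_pairs(corr, threshold):
        if a not in alive or b not in alive:
            continue
        if cat.is_st_dt_pair(a, b):
            out = cat.dt_member(a, b)
            rule = "dual_task"
        else:
            # remove the less sensitive member; tie -> lexicographically later
            if abs_smd[a] < abs_smd[b] or (abs_smd[a] == abs_smd[b] and a > b):
                out = a
            else:
                out = b
            rule = "smaller_smd"
        kept = b if out == a else a
        alive.discard(out)
        removed.append(RemovalRecord(removed_id=out, kept_id=kept, rho=float(r), rule_applied=rule))

    survivors = sorted(alive, key=lambda m: (-abs_smd[m], m))
    # post-condition: no violating pair among survivors
    sub = corr.submatrix(survivors).rho
    off = np.abs(sub[np.triu_indices_from(sub, k=1)])
    if off.size and off.max() > threshold:
        raise AssertionError("pruning left a violating pair among survivors")
    return PruningAudit(removed=removed, survivors=survivors)
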