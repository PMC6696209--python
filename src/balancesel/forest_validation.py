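"""Random-forest validation of a selected measure set.

A forest of decision trees is trained to classify PD vs control from the
selected measures.  Feature relevance is the mean decrease in Gini impurity
(1 − Σ pⱼ² at each node), normalized to sum to one; generalization is
assessed both by the out-of-bag error of a single forest and by randomized
k-fold cross-validation (default 10 folds: train on 90%, evaluate accuracy
and precision on the held-out 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_score
from sklearn.model_selection import KFold, StratifiedKFold

from .imputation import ImputedEnsemble
from .tables import MeasureTable

__all__ = [
    "gini_impurity",
    "ForestFit",
    "ForestReport",
    "fit_forest",
    "cross_validate",
    "cross_validate_ensemble",
]


def gini_impurity(p) -> float:
    """Gini impurity 1 − Σ pⱼ² of a class-probability vector."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("p must be a 1-d probability vector of length >= 2")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


@dataclass
class ForestFit:
    model: RandomForestClassifier
    importances: pd.Series  # normalized mean decrease in impurity
    oob_error: float
    seed: int


@dataclass
class ForestReport:
    accuracy_mean: float  # percent
    accuracy_sd: float
    precision_mean: float
    precision_sd: float
    importances: dict[str, float]
    oob_error: float
    folds: int
    seed: int
    fold_accuracies: list[float] = field(default_factory=list)
    fold_precisions: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy_mean_pct": self.accuracy_mean,
            "accuracy_sd_pct": self.accuracy_sd,
            "precision_mean_pct": self.precision_mean,
            "precision_sd_pct": self.precision_sd,
            "oob_error": self.oob_error,
            "folds": self.folds,
            "seed": self.seed,
            "fold_accuracies_pct": self.fold_accuracies,
            "fold_precisions_pct": self.fold_precisions,
            "importances": self.importances,
        }


def _design(table: MeasureTable, ids: list[str] | None):
    ids = list(ids) if ids is not None else table.measure_ids
    X = table.values[ids]
    if X.isna().any().any():
        raise ValueError("forest requires complete data; impute first")
    y = (table.group == "PD").to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes (PD and HC) are required")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    return X.to_numpy(), y, ids


def fit_forest(
    table: MeasureTable,
    ids: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> ForestFit:
    """Train a forest on the full table; report OOB error and importances.

    Trees are grown on bootstrap samples with sqrt(p) feature subsetting and
    unlimited depth; importances are impurity-based (mean decrease in Gini),
    normalized to sum to one.
    """
    X, y, ids = _design(table, ids)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # small bootstrap samples can miss a few OOB predictions; fine here
        warnings.simplefilter("ignore", UserWarning)
        model.fit(X, y)
    importances = pd.Series(model.feature_importances_, index=ids)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return ForestFit(
        model=model,
        importances=importances,
        oob_error=float(1.0 - model.oob_score_),
        seed=seed,
    )


def cross_validate(
    table: MeasureTable,
    ids: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    stratified: bool = False,
) -> ForestReport:
    """Randomized k-fold cross-validation of the PD/HC forest classifier.

    Per-fold accuracy and precision (positive class = PD) are evaluated on
    the held-out fold and summarized as mean ± SD, in percent.  A fold where
    precision is undefined (no predicted or no true positives) is recorded
    as missing and excluded from the precision summary with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y, ids = _design(table, ids)
    splitter = (
        StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=folds, shuffle=True, random_state=seed)
    )
    split_iter = splitter.split(X, y) if stratified else splitter.split(X)

    accs: list[float] = []
    precs: list[float] = []
    for k, (train, test) in enumerate(split_iter):
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {k}: training split lacks one class")
        model = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            random_state=seed + k,
            n_jobs=1,
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        accs.append(100.0 * accuracy_score(y[test], pred))
        if pred.sum() == 0 or y[test].sum() == 0:
            warnings.warn(
                f"fold {k}: precision undefined (no positive predictions or "
                "no PD subjects in the fold); excluded from the summary"
            )
            precs.append(np.nan)
        else:
            precs.append(100.0 * precision_score(y[test], pred, zero_division=0))

    importances = fit_forest(table, ids, n_trees=n_trees, seed=seed)
    acc_arr = np.asarray(accs)
    prec_arr = np.asarray(precs)
    return ForestReport(
        accuracy_mean=float(acc_arr.mean()),
        accuracy_sd=float(acc_arr.std(ddof=1)),
        precision_mean=float(np.nanmean(prec_arr)),
        precision_sd=float(np.nanstd(prec_arr, ddof=1)),
        importances={m: float(v) for m, v in importances.importances.items()},
        oob_error=importances.oob_error,
        folds=folds,
        seed=seed,
        fold_accuracies=[float(a) for a in accs],
        fold_precisions=[float(p) for p in precs],
    )


def cross_validate_ensemble(
    ensemble: ImputedEnsemble,
    ids: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    stratified: bool = False,
    max_datasets: int | None = None,
) -> ForestReport:
    """Cross-validation averaged over the completed datasets of an ensemble.

    Each completed dataset is cross-validated independently; the reported
    metrics are the means of the per-dataset summaries.  ``max_datasets``
    caps how many ensemble members are used (None = all).
    """
    datasets = ensemble.datasets[: max_datasets or len(ensemble.datasets)]
    reports = [
        cross_validate(ds, ids, folds=folds, seed=seed + i, n_trees=n_trees,
                       stratified=stratified)
        for i, ds in enumerate(datasets)
    ]
    imp_keys = reports[0].importances.keys()
    return ForestReport(
        accuracy_mean=float(np.mean([r.accuracy_mean for r in reports])),
        accuracy_sd=float(np.mean([r.accuracy_sd for r in reports])),
        precision_mean=float(np.mean([r.precision_mean for r in reports])),
        precision_sd=float(np.mean([r.precision_sd for r in reports])),
        importances={
            m: float(np.mean([r.importances[m] for r in reports])) for m in imp_keys
        },
        oob_error=float(np.mean([r.oob_error for r in reports])),
        folds=folds,
        seed=seed,
    )
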