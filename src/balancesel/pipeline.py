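"""End-to-end measure-selection pipeline with a reproducible run manifest.

Stages, in order: catalogue → cohort (synthetic or user CSVs) → removal of
tasks with excess missingness → two-track imputation → SMD filter →
correlation-redundancy pruning → random-forest validation → test–retest
reliability → clinical associations.  Every stage writes a report file into
the output directory; the manifest records the configuration, the
stage-by-stage measure counts and the SHA-256 of every output, so identical
config + seed yields identical hashes.

The single run seed fans out into independent per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so the synthetic cohort, the
imputation draws and the forest stay independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import Catalogue, build_default_catalogue
from .clinical_assoc import associate_ensemble
from .effect_size import compute_effect_sizes_pooled, filter_by_smd
from .forest_validation import cross_validate_ensemble
from .imputation import drop_high_missing_tasks, impute_table
from .pruning import prune, spearman_matrix_pooled
from .reliability import reliability_report
from .synthgen import SynthConfig, default_study_config, generate
from .tables import MeasureTable

logger = logging.getLogger("balancesel")

__all__ = ["RunConfig", "RunManifest", "run"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int
    out_dir: str | Path = "balancesel_out"
    # input: either a synthetic config, or CSV paths
    synth: bool = True
    synth_config: SynthConfig | None = None
    values_csv: str | None = None
    codes_csv: str | None = None
    retest_values_csv: str | None = None
    clinical_csv: str | None = None
    # stage parameters
    missing_task_threshold: float = 0.20
    m_imputations: int = 25
    smd_threshold: float = 0.5
    smd_variant: str = "paper"
    corr_threshold: float = 0.70
    folds: int = 10
    n_trees: int = 500
    forest_max_datasets: int | None = None
    alpha: float = 0.01
    # which optional stages to run
    run_forest: bool = True
    run_reliability: bool = True
    run_clinical: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.missing_task_threshold < 1:
            raise ValueError("missing_task_threshold must be in (0, 1)")
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.smd_threshold <= 0:
            raise ValueError("smd_threshold must be positive")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        if not self.synth and self.values_csv is None:
            raise ValueError("either synth=True or values_csv must be given")


@dataclass
class RunManifest:
    config: dict
    stage_counts: dict[str, int]
    removed_tasks: dict
    output_hashes: dict[str, str]
    version: str
    timestamp: str
    notes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    sc = echo.pop("synth_config", None)
    if sc is not None:
        # the full synthetic config is large; record its scalar identity
        echo["synth_config"] = {
            "n_pd": sc["n_pd"],
            "n_hc": sc["n_hc"],
            "n_measures": len(sc["catalogue"]["descriptors"]),
            "seed": sc["seed"],
        }
    echo["out_dir"] = str(echo["out_dir"])
    return echo


def run(config: RunConfig) -> RunManifest:
    """Execute the full selection pipeline; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_synth, seed_mi, seed_forest, _ = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )

    stage_counts: dict[str, int] = {}
    outputs: dict[str, Path] = {}
    notes: list[str] = []

    # --- stage 1: catalogue + cohort --------------------------------------
    retest_table = None
    clinical = None
    truth = None
    if config.synth:
        synth_cfg = config.synth_config or default_study_config(seed=seed_synth)
        if config.synth_config is None:
            notes.append("synthetic cohort from default study configuration")
        cohort = generate(synth_cfg)
        cat = synth_cfg.catalogue
        table = cohort.table
        retest_table = cohort.retest_table
        clinical = cohort.clinical
        truth = cohort.truth
        table.to_csv(out / "cohort_values.csv", out / "cohort_miss_codes.csv")
        retest_table.to_csv(out / "retest_values.csv", out / "retest_miss_codes.csv")
        clinical.to_csv(out / "clinical.csv", index_label="subject_id")
        truth.to_json(out / "synth_truth.json")
        for name in ("cohort_values.csv", "cohort_miss_codes.csv", "retest_values.csv",
                     "retest_miss_codes.csv", "clinical.csv", "synth_truth.json"):
            outputs[name] = out / name
    else:
        cat = build_default_catalogue()
        table = MeasureTable.from_csv(config.values_csv, config.codes_csv)
        cat = cat.subset([m for m in cat.ids if m in table.measure_ids])
        if config.retest_values_csv:
            retest_table = MeasureTable.from_csv(config.retest_values_csv)
        if config.clinical_csv:
            clinical = pd.read_csv(config.clinical_csv, index_col="subject_id")
            clinical.index = clinical.index.astype(str)
    cat.to_csv(out / "catalogue.csv")
    outputs["catalogue.csv"] = out / "catalogue.csv"
    stage_counts["catalogue"] = len(cat)
    logger.info("catalogue: %d measures", len(cat))

    # --- stage 2: task removal --------------------------------------------
    removal = drop_high_missing_tasks(table, cat, threshold=config.missing_task_threshold)
    table, cat = removal.table, removal.catalogue
    stage_counts["after_task_removal"] = len(cat)
    logger.info(
        "task removal: %d measures remain (removed: %s)",
        len(cat),
        sorted(removal.removed_tasks) or "none",
    )

    # --- stage 3: imputation -----------------------------------------------
    ensemble = impute_table(table, cat, m=config.m_imputations, seed=seed_mi)
    stage_counts["imputed_datasets"] = ensemble.m

    # --- stage 4: SMD filter -----------------------------------------------
    effects = compute_effect_sizes_pooled(
        ensemble, threshold=config.smd_threshold, variant=config.smd_variant
    )
    effects.to_csv(out / "effect_sizes.csv")
    outputs["effect_sizes.csv"] = out / "effect_sizes.csv"
    passing = filter_by_smd(effects, threshold=config.smd_threshold)
    selected_ids = list(passing.index)
    stage_counts["after_smd_filter"] = len(selected_ids)
    logger.info("SMD filter: %d sensitive measures", len(selected_ids))

    survivors: list[str] = []
    if not selected_ids:
        notes.append("no measures retained by the SMD filter; downstream stages skipped")
        (out / "selection_report.json").write_text(
            json.dumps({"survivors": [], "note": "no measures retained"}, indent=1)
        )
        outputs["selection_report.json"] = out / "selection_report.json"
    else:
        # --- stage 5: redundancy pruning -----------------------------------
        corr = spearman_matrix_pooled(ensemble, selected_ids)
        corr.to_frame().to_csv(out / "correlation_matrix.csv")
        outputs["correlation_matrix.csv"] = out / "correlation_matrix.csv"
        audit = prune(passing, corr, cat, threshold=config.corr_threshold)
        survivors = audit.survivors
        (out / "pruning_audit.json").write_text(json.dumps(audit.to_dict(), indent=1))
        outputs["pruning_audit.json"] = out / "pruning_audit.json"
    stage_counts["after_pruning"] = len(survivors)
    logger.info("pruning: %d survivors", len(survivors))

    # --- stage 6: forest validation ----------------------------------------
    if config.run_forest and survivors:
        report_sel = cross_validate_ensemble(
            ensemble, survivors, folds=config.folds, seed=seed_forest,
            n_trees=config.n_trees, max_datasets=config.forest_max_datasets,
        )
        report_all = cross_validate_ensemble(
            ensemble, None, folds=config.folds, seed=seed_forest,
            n_trees=config.n_trees, max_datasets=config.forest_max_datasets,
        )
        forest_payload = {
            "selected_measures": report_sel.to_dict(),
            "all_measures": report_all.to_dict(),
        }
        (out / "forest_report.json").write_text(json.dumps(forest_payload, indent=1))
        outputs["forest_report.json"] = out / "forest_report.json"
        pd.Series(report_sel.importances, name="importance").rename_axis(
            "measure_id"
        ).to_csv(out / "importances.csv")
        outputs["importances.csv"] = out / "importances.csv"
        logger.info(
            "forest: CV accuracy %.1f%% (selected) vs %.1f%% (all)",
            report_sel.accuracy_mean,
            report_all.accuracy_mean,
        )

    # --- stage 7: reliability ----------------------------------------------
    if config.run_reliability and survivors and retest_table is not None:
        test_complete = ensemble.datasets[0]
        rel = reliability_report(
            test_complete.select_group("PD"), retest_table, survivors
        )
        rel.to_csv(out / "reliability.csv")
        outputs["reliability.csv"] = out / "reliability.csv"

    # --- stage 8: clinical associations -------------------------------------
    if config.run_clinical and survivors and clinical is not None:
        assoc = associate_ensemble(ensemble, clinical, survivors, alpha=config.alpha)
        assoc.to_csv(out / "associations.csv", index=False)
        outputs["associations.csv"] = out / "associations.csv"

    manifest = RunManifest(
        config=_config_echo(config),
        stage_counts=stage_counts,
        removed_tasks=removal.removed_tasks,
        output_hashes={k: _sha256(p) for k, p in sorted(outputs.items())},
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        notes=notes,
    )
    manifest.to_json(out / "manifest.json")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return manifest
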