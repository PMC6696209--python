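"""Synthetic PD / control cohorts with known ground truth.

The generator emulates the statistical structure the selection pipeline
assumes, so every downstream stage can be validated against planted truth:

* a latent impairment factor per subject (PD mean-shifted, controls at 0)
  that drives informative missingness and the clinical scales;
* per-measure group effect sizes: each measure is unit-variance Gaussian
  within group, with the PD mean shifted so the population standardized
  mean difference equals the configured target, oriented along the
  measure's impairment direction;
* a structured correlation matrix: a common factor shared by all measures
  (the cross-domain correlation), equicorrelated within-domain blocks on
  top of it, and explicitly planted high-correlation pairs that the
  redundancy-pruning stage is supposed to resolve;
* categorized missingness by task and group: fall / no-APA categories are
  informative (the most impaired subjects are masked first), the remaining
  categories are masked completely at random;
* a retest session for the PD group whose population test-retest ICC per
  measure equals the configured target;
* clinical scales generated as linear functions of the latent factor,
  truncated to their natural ranges.

Values are standardized (within-group SD 1); the pipeline consumes only
scale-free statistics (SMD, rank correlations, ICC), so physical units are
irrelevant here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    Catalogue,
    Domain,
    ImpairmentDirection,
    Task,
    build_default_catalogue,
)
from .tables import MeasureTable, MissCode

__all__ = [
    "MissingnessRule",
    "PlantedPair",
    "ClinicalScaleSpec",
    "SynthConfig",
    "SynthTruth",
    "SynthCohort",
    "generate",
    "default_study_config",
    "strong_separation_config",
    "CLINICAL_SCALES",
]


@dataclass(frozen=True)
class MissingnessRule:
    """Mask ``rate`` of one group's subjects on every measure of a task."""

    task: Task
    group: str  # "PD" | "HC"
    rate: float
    code: MissCode

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")
        if self.group not in ("PD", "HC"):
            raise ValueError(f"group must be PD or HC, got {self.group!r}")
        if self.code is MissCode.OBSERVED:
            raise ValueError("missingness rule cannot use the Observed code")


@dataclass(frozen=True)
class PlantedPair:
    """A deliberately redundant measure pair for the pruning stage.

    ``kept`` is the member the pruning rules should retain, ``removed`` the
    one they should discard (smaller planted SMD, or the dual-task variant).
    """

    kept: str
    removed: str
    rho: float = 0.85
    expected_rule: str = "smaller_smd"  # or "dual_task"


@dataclass(frozen=True)
class ClinicalScaleSpec:
    lo: float
    hi: float
    center: float
    spread: float
    pd_only: bool


#: Natural ranges and cohort routing of the clinical scales.
CLINICAL_SCALES: Mapping[str, ClinicalScaleSpec] = {
    "MiniBEST": ClinicalScaleSpec(0, 28, 24.0, 3.0, pd_only=False),
    "ABC": ClinicalScaleSpec(0, 100, 90.0, 8.0, pd_only=False),
    "PDQ39_total": ClinicalScaleSpec(0, 100, 15.0, 12.0, pd_only=True),
    "PDQ39_mobility": ClinicalScaleSpec(0, 100, 20.0, 15.0, pd_only=True),
    "UPDRS_total": ClinicalScaleSpec(0, 260, 45.0, 20.0, pd_only=True),
    "UPDRS_II": ClinicalScaleSpec(0, 52, 12.0, 6.0, pd_only=True),
    "UPDRS_III": ClinicalScaleSpec(0, 132, 35.0, 15.0, pd_only=True),
}


@dataclass
class SynthConfig:
    """Parameters of one synthetic cohort."""

    catalogue: Catalogue
    n_pd: int = 144
    n_hc: int = 79
    #: measure_id -> target |SMD| (oriented by impairment direction).
    smd_profile: dict[str, float] = field(default_factory=dict)
    #: domain -> within-domain correlation (on top of the common factor).
    block_correlation: dict[Domain, float] = field(default_factory=dict)
    #: correlation shared by all measure pairs (common-factor variance).
    cross_block_correlation: float = 0.2
    #: explicit pairwise correlations overriding the block structure.
    extra_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    missingness_spec: list[MissingnessRule] = field(default_factory=list)
    #: measure_id -> target test-retest ICC (PD group); default for the rest.
    retest_icc: dict[str, float] = field(default_factory=dict)
    default_retest_icc: float = 0.90
    #: scale name -> signed loading on the latent impairment factor.
    clinical_loading: dict[str, float] = field(default_factory=dict)
    #: latent impairment factor mean shift in the PD group.
    latent_shift: float = 1.5
    #: planted redundant pairs (informational; correlations must also be
    #: present in extra_correlations).
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = set(self.catalogue.ids)
        unknown = set(self.smd_profile) - ids
        if unknown:
            raise ValueError(f"smd_profile references unknown measures: {sorted(unknown)}")
        for (a, b), r in self.extra_correlations.items():
            if a not in ids or b not in ids:
                raise ValueError(f"extra correlation references unknown pair ({a}, {b})")
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation out of range for ({a}, {b}): {r}")
        for d, r in self.block_correlation.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"block correlation out of [0, 1) for {d}: {r}")
        if not 0.0 <= self.cross_block_correlation < 1.0:
            raise ValueError("cross_block_correlation must be in [0, 1)")
        for m, icc in self.retest_icc.items():
            if m not in ids:
                raise ValueError(f"retest_icc references unknown measure {m}")
            if not 0.0 < icc <= 1.0:
                raise ValueError(f"ICC must be in (0, 1], got {icc} for {m}")
        for rule in self.missingness_spec:
            if rule.task not in {d.task for d in self.catalogue}:
                raise ValueError(f"missingness rule for task absent from catalogue: {rule.task}")

    @property
    def n_total(self) -> int:
        return self.n_pd + self.n_hc


@dataclass
class SynthTruth:
    """Everything needed to recompute the planted quantities."""

    planted_smd: dict[str, float]
    planted_sensitive: list[str]
    planted_kept: list[str]
    planted_pairs: list[PlantedPair]
    retest_icc: dict[str, float]
    latent: pd.Series
    complete_values: pd.DataFrame
    correlation_target: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "planted_smd": self.planted_smd,
            "planted_sensitive": self.planted_sensitive,
            "planted_kept": self.planted_kept,
            "planted_pairs": [vars(p) for p in self.planted_pairs],
            "retest_icc": self.retest_icc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SynthCohort:
    table: MeasureTable
    retest_table: MeasureTable
    clinical: pd.DataFrame
    truth: SynthTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------


def build_target_correlation(cfg: SynthConfig) -> pd.DataFrame:
    ids = cfg.catalogue.ids
    p = len(ids)
    idx = {m: i for i, m in enumerate(ids)}
    c = cfg.cross_block_correlation
    rho = np.full((p, p), c)
    for domain in Domain:
        block = [idx[d.measure_id] for d in cfg.catalogue if d.domain is domain]
        r = cfg.block_correlation.get(domain, c)
        for i in block:
            rho[i, block] = r
    for (a, b), r in cfg.extra_correlations.items():
        rho[idx[a], idx[b]] = rho[idx[b], idx[a]] = r
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=ids, columns=ids)


def _residual_cholesky(rho: np.ndarray, c: float) -> np.ndarray:
    """Cholesky factor of the correlation left over after the common factor."""
    p = rho.shape[0]
    resid = (rho - c) / (1.0 - c)
    np.fill_diagonal(resid, 1.0)
    try:
        return np.linalg.cholesky(resid)
    except np.linalg.LinAlgError:
        raise ValueError(
            "implied block correlation structure is not positive definite; "
            "lower block/extra correlations or raise the cross-block level"
        ) from None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _direction_signs(cat: Catalogue) -> np.ndarray:
    return np.array(
        [
            1.0 if d.impairment_direction is ImpairmentDirection.HIGHER_IS_WORSE else -1.0
            for d in cat
        ]
    )


def generate(cfg: SynthConfig) -> SynthCohort:
    """Draw one cohort from the configured generative model.

    Fully reproducible from ``cfg.seed``: identical configs yield
    bit-identical cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    cat = cfg.catalogue
    ids = cat.ids
    p = len(ids)
    n = cfg.n_total

    subjects = [f"PD{i+1:03d}" for i in range(cfg.n_pd)] + [
        f"HC{i+1:03d}" for i in range(cfg.n_hc)
    ]
    group = pd.Series(
        ["PD"] * cfg.n_pd + ["HC"] * cfg.n_hc, index=subjects, name="group"
    )
    is_pd = (group == "PD").to_numpy(dtype=float)

    rho_df = build_target_correlation(cfg)
    c = cfg.cross_block_correlation
    chol = _residual_cholesky(rho_df.to_numpy(), c)

    # common factor = standardized latent impairment within group
    factor = rng.standard_normal(n)
    resid = rng.standard_normal((n, p)) @ chol.T
    noise = np.sqrt(c) * factor[:, None] + np.sqrt(1.0 - c) * resid

    d_target = np.array([cfg.smd_profile.get(m, 0.0) for m in ids])
    signs = _direction_signs(cat)
    raw = d_target[None, :] * is_pd[:, None] + noise
    values = signs[None, :] * raw

    latent = pd.Series(
        cfg.latent_shift * is_pd + factor, index=subjects, name="latent_impairment"
    )

    complete = pd.DataFrame(values, index=subjects, columns=ids)

    # --- retest session (PD subjects, complete) ---------------------------
    pd_rows = is_pd.astype(bool)
    icc_vec = np.array(
        [cfg.retest_icc.get(m, cfg.default_retest_icc) for m in ids]
    )
    eps = rng.standard_normal((int(pd_rows.sum()), p))
    retest_raw = (
        d_target[None, :]
        + icc_vec[None, :] * noise[pd_rows]
        + np.sqrt(1.0 - icc_vec**2)[None, :] * eps
    )
    retest_values = pd.DataFrame(
        signs[None, :] * retest_raw, index=np.array(subjects)[pd_rows], columns=ids
    )
    retest_table = MeasureTable(
        retest_values,
        group.loc[pd_rows].copy(),
        pd.DataFrame("O", index=retest_values.index, columns=ids),
    )

    # --- missingness -------------------------------------------------------
    masked_values = complete.copy()
    codes = pd.DataFrame("O", index=subjects, columns=ids)
    informative = {MissCode.A_FALL, MissCode.D_NO_APA}
    # informative rules first, so the worst subjects get the worst-case code
    rules = sorted(
        cfg.missingness_spec, key=lambda r: (r.code not in informative,)
    )
    taken: dict[tuple[Task, str], set[str]] = {}
    for rule in rules:
        members = [s for s, g in group.items() if g == rule.group]
        n_mask = int(round(rule.rate * len(members)))
        if n_mask == 0:
            continue
        already = taken.setdefault((rule.task, rule.group), set())
        available = [s for s in members if s not in already]
        if rule.code in informative:
            # mask the most impaired first
            available.sort(key=lambda s: -latent[s])
            chosen = available[:n_mask]
        else:
            chosen = list(rng.choice(available, size=n_mask, replace=False))
        already.update(chosen)
        task_ids = [d.measure_id for d in cat if d.task is rule.task]
        masked_values.loc[chosen, task_ids] = np.nan
        codes.loc[chosen, task_ids] = rule.code.value

    table = MeasureTable(masked_values, group, codes)

    # --- clinical scales ----------------------------------------------------
    clin = {}
    for scale, loading in cfg.clinical_loading.items():
        spec = CLINICAL_SCALES[scale]
        e = rng.standard_normal(n)
        s = loading * latent.to_numpy() + np.sqrt(max(0.0, 1 - loading**2)) * e
        vals = np.clip(spec.center + spec.spread * s, spec.lo, spec.hi)
        if spec.pd_only:
            vals = np.where(pd_rows, vals, np.nan)
        clin[scale] = vals
    clinical = pd.DataFrame(clin, index=subjects)

    planted_sensitive = sorted(
        m
        for m in ids
        if cfg.smd_profile.get(m, 0.0) > 0.5 and cat.get(m).task is not Task.ECFOAM
    )
    removed = {pr.removed for pr in cfg.planted_pairs}
    planted_kept = sorted(m for m in planted_sensitive if m not in removed)

    truth = SynthTruth(
        planted_smd={m: cfg.smd_profile.get(m, 0.0) for m in ids},
        planted_sensitive=planted_sensitive,
        planted_kept=planted_kept,
        planted_pairs=list(cfg.planted_pairs),
        retest_icc={m: cfg.retest_icc.get(m, cfg.default_retest_icc) for m in ids},
        latent=latent,
        complete_values=complete,
        correlation_target=rho_df,
    )
    return SynthCohort(
        table=table,
        retest_table=retest_table,
        clinical=clinical,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# default study configuration
# ---------------------------------------------------------------------------

#: id shorthand helpers for the default catalogue
def _mid(prefix: str, base: str, suffix: str | None) -> str:
    s = base.lower().replace(" ", "_")
    if s.startswith(prefix + "_"):
        s = s[len(prefix) + 1 :]
    return f"{prefix}_{s}_{suffix}" if suffix else f"{prefix}_{s}"


def _gid(base: str, suffix: str) -> str:
    return _mid("gait", base, suffix)


def _aid(base: str, suffix: str) -> str:
    return _mid("apa", base, suffix)


def _sid(base: str, suffix: str) -> str:
    return _mid("sway", base, suffix)


def _rid(base: str) -> str:
    return _mid("apr", base, None)


def default_study_config(seed: int = 0) -> SynthConfig:
    """Study-sized default: 144 PD / 79 HC, 93 measures, planted structure.

    44 measures are planted sensitive (population |SMD| 0.92-1.32, domain
    ordering Gait > APA > Sway > APR: 16 Gait, 10 APA, 11 Sway, 7 APR),
    20 of them redundant (paired at rho 0.85 with a more sensitive or
    single-task partner), 49 insensitive (|SMD| 0 except LOS at 0.05-0.12).  Missingness follows the reported
    task/group rates: eyes-closed-on-foam sway 38.9% PD / 11.4% HC (falls),
    eyes-open-on-foam 13.9% / 2.5% (falls), push-and-release 13.9% / 1.3%
    (falls and unusable data), dual-task step initiation 12.5% / 5.1%
    (no detectable APA and noisy baseline).
    """
    cat = build_default_catalogue()

    smd: dict[str, float] = {m: 0.0 for m in cat.ids}
    extra: dict[tuple[str, str], float] = {}
    pairs: list[PlantedPair] = []

    def plant_pair(kept: str, removed: str, kept_smd: float, removed_smd: float,
                   rule: str) -> None:
        smd[kept] = kept_smd
        smd[removed] = removed_smd
        extra[(kept, removed)] = 0.85
        pairs.append(PlantedPair(kept=kept, removed=removed, rho=0.85, expected_rule=rule))

    # --- Gait: 17 sensitive (7 kept, 10 removed) ---------------------------
    plant_pair(_gid("Turn velocity", "st"), _gid("Turn duration", "st"), 1.32, 1.00, "smaller_smd")
    plant_pair(_gid("Foot strike angle", "st"), _gid("Toe off angle", "st"), 1.30, 1.02, "smaller_smd")
    plant_pair(_gid("Gait speed", "st"), _gid("Stride length", "st"), 1.26, 0.98, "smaller_smd")
    plant_pair(_gid("Stance time", "st"), _gid("Double support time", "st"), 1.20, 0.96, "smaller_smd")
    plant_pair(_gid("Turn velocity", "st"), _gid("Turn velocity", "dt"), 1.32, 1.05, "dual_task")
    plant_pair(_gid("Foot strike angle", "st"), _gid("Foot strike angle", "dt"), 1.30, 1.04, "dual_task")
    plant_pair(_gid("Gait speed", "st"), _gid("Gait speed", "dt"), 1.26, 1.06, "dual_task")
    plant_pair(_gid("Arm ROM", "st"), _gid("Arm ROM", "dt"), 1.24, 1.03, "dual_task")
    plant_pair(_gid("Trunk ROM", "st"), _gid("Trunk ROM", "dt"), 1.18, 1.02, "dual_task")
    plant_pair(_gid("Stance time", "st"), _gid("Stance time", "dt"), 1.20, 1.00, "dual_task")

    # --- APA: 10 sensitive (5 kept, 5 removed; all removals are DT variants)
    plant_pair(_aid("First step ROM", "st"), _aid("First step ROM", "dt"), 1.28, 1.05, "dual_task")
    plant_pair(_aid("First step length", "st"), _aid("First step length", "dt"), 1.20, 1.03, "dual_task")
    plant_pair(_aid("APA amplitude ML", "st"), _aid("APA amplitude ML", "dt"), 1.16, 1.02, "dual_task")
    plant_pair(_aid("APA amplitude AP", "st"), _aid("APA amplitude AP", "dt"), 1.12, 1.01, "dual_task")
    plant_pair(_aid("APA duration", "st"), _aid("APA duration", "dt"), 1.10, 1.00, "dual_task")

    # --- Sway: 10 sensitive (7 kept, 3 removed) ----------------------------
    plant_pair(_sid("RMS ML", "eofoam"), _sid("RMS AP", "eofoam"), 1.20, 0.98, "smaller_smd")
    plant_pair(_sid("RMS ML", "isaw_st"), _sid("RMS ML", "isaw_dt"), 1.10, 1.00, "dual_task")
    plant_pair(_sid("RMS AP", "isaw_st"), _sid("RMS AP", "isaw_dt"), 1.08, 1.00, "dual_task")
    # every eyes-open-on-foam measure is sensitive: the task draws informative
    # fall-type missingness, whose worst-case imputation presumes a real deficit
    for base, d in [("Jerk ML", 1.02), ("Jerk AP", 1.04), ("Sway area", 1.06),
                    ("Mean velocity", 1.12), ("Centroid frequency", 1.00)]:
        smd[_sid(base, "eofoam")] = d

    # --- APR: 7 sensitive (5 kept, 2 removed) ------------------------------
    plant_pair(_rid("Step latency"), _rid("Time to stability"), 1.14, 0.92, "smaller_smd")
    plant_pair(_rid("Step length"), _rid("Step velocity"), 1.16, 0.94, "smaller_smd")
    for base, d in [("Number of steps", 0.96), ("Trunk lean", 0.98), ("First step duration", 1.00)]:
        smd[_rid(base)] = d

    # --- LOS: insensitive, small effects -----------------------------------
    smd["los_forward_range"] = 0.12
    smd["los_backward_range"] = 0.08
    smd["los_total_range"] = 0.05

    # ECFoam sway is sensitive but removed for excess missingness upstream of
    # the filter; plant realistic non-null effects there.
    for base in ("RMS ML", "RMS AP", "Jerk ML", "Jerk AP", "Sway area", "Mean velocity", "Centroid frequency"):
        smd[_sid(base, "ecfoam")] = 0.9

    # two removed measures sharing a kept partner must correlate like the
    # one-factor structure implies (0.85 * 0.85), or the matrix loses
    # positive definiteness
    by_kept: dict[str, list[str]] = {}
    for pr in pairs:
        by_kept.setdefault(pr.kept, []).append(pr.removed)
    for kept, removed_list in by_kept.items():
        for i in range(len(removed_list)):
            for j in range(i + 1, len(removed_list)):
                extra[(removed_list[i], removed_list[j])] = 0.85 * 0.85

    missingness = [
        MissingnessRule(Task.ECFOAM, "PD", 0.389, MissCode.A_FALL),
        MissingnessRule(Task.ECFOAM, "HC", 0.114, MissCode.A_FALL),
        MissingnessRule(Task.EOFOAM, "PD", 0.139, MissCode.A_FALL),
        MissingnessRule(Task.EOFOAM, "HC", 0.025, MissCode.A_FALL),
        MissingnessRule(Task.PUSH_RELEASE, "PD", 0.0695, MissCode.A_FALL),
        MissingnessRule(Task.PUSH_RELEASE, "PD", 0.0695, MissCode.C_NOT_USABLE),
        MissingnessRule(Task.PUSH_RELEASE, "HC", 0.0065, MissCode.A_FALL),
        MissingnessRule(Task.PUSH_RELEASE, "HC", 0.0065, MissCode.C_NOT_USABLE),
        MissingnessRule(Task.APA_DT, "PD", 0.0625, MissCode.D_NO_APA),
        MissingnessRule(Task.APA_DT, "PD", 0.0625, MissCode.E_NOISY),
        MissingnessRule(Task.APA_DT, "HC", 0.0255, MissCode.D_NO_APA),
        MissingnessRule(Task.APA_DT, "HC", 0.0255, MissCode.E_NOISY),
    ]

    retest_icc = {
        _gid("Turn velocity", "st"): 0.95,
        _gid("Foot strike angle", "st"): 0.97,
        _gid("Arm ROM", "st"): 0.96,
        _aid("First step ROM", "st"): 0.82,
    }

    clinical_loading = {
        "MiniBEST": -0.80,
        "ABC": -0.75,
        "PDQ39_total": 0.60,
        "PDQ39_mobility": 0.70,
        "UPDRS_total": 0.80,
        "UPDRS_II": 0.70,
        "UPDRS_III": 0.75,
    }

    return SynthConfig(
        catalogue=cat,
        n_pd=144,
        n_hc=79,
        smd_profile=smd,
        block_correlation={
            Domain.SWAY: 0.30,
            Domain.APA: 0.35,
            Domain.APR: 0.35,
            Domain.GAIT: 0.40,
            Domain.LOS: 0.50,
        },
        cross_block_correlation=0.20,
        extra_correlations=extra,
        missingness_spec=missingness,
        retest_icc=retest_icc,
        default_retest_icc=0.90,
        clinical_loading=clinical_loading,
        latent_shift=1.5,
        planted_pairs=pairs,
        seed=seed,
    )


def strong_separation_config(seed: int = 0) -> SynthConfig:
    """Clean, strongly separated cohort for classifier sanity checks.

    The 24 planted-independent sensitive measures of the default design all
    get |SMD| = 1.5, weak correlation and no missingness, so a classifier
    trained on them should separate the groups almost perfectly.
    """
    base = default_study_config(seed=seed)
    smd = {m: 0.0 for m in base.catalogue.ids}
    for m in generate_planted_kept(base):
        smd[m] = 1.5
    return SynthConfig(
        catalogue=base.catalogue,
        n_pd=144,
        n_hc=79,
        smd_profile=smd,
        block_correlation={d: 0.2 for d in Domain},
        cross_block_correlation=0.1,
        extra_correlations={},
        missingness_spec=[],
        retest_icc={},
        default_retest_icc=0.9,
        clinical_loading={},
        latent_shift=1.5,
        planted_pairs=[],
        seed=seed,
    )


def generate_planted_kept(cfg: SynthConfig) -> list[str]:
    """The planted-independent sensitive measure set implied by a config."""
    removed = {pr.removed for pr in cfg.planted_pairs}
    cat = cfg.catalogue
    return sorted(
        m
        for m, d in cfg.smd_profile.items()
        if d > 0.5 and m not in removed and cat.get(m).task is not Task.ECFOAM
    )
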