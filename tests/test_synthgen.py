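import numpy as np
import pandas as pd
import pytest

from balancesel.catalog import Domain, Task, build_default_catalogue
from balancesel.effect_size import compute_effect_sizes
from balancesel.reliability import icc_two_way
from balancesel.synthgen import (
    MissingnessRule,
    SynthConfig,
    default_study_config,
    generate,
    generate_planted_kept,
)
from balancesel.tables import MissCode
from conftest import complete_table


def _small_config(**overrides) -> SynthConfig:
    base = dict(
        catalogue=build_default_catalogue(),
        n_pd=144,
        n_hc=79,
        smd_profile={},
        block_correlation={},
        cross_block_correlation=0.2,
        missingness_spec=[],
        seed=0,
    )
    base.update(overrides)
    return SynthConfig(**base)


class TestDefaultStudyConfig:
    def test_cohort_sizes(self):
        cfg = default_study_config()
        assert cfg.n_pd == 144 and cfg.n_hc == 79

    def test_ecfoam_missingness_rates(self):
        cfg = default_study_config()
        rates = {
            (r.task, r.group): r.rate
            for r in cfg.missingness_spec
            if r.code is MissCode.A_FALL and r.task is Task.ECFOAM
        }
        assert rates[(Task.ECFOAM, "PD")] == pytest.approx(0.389)
        assert rates[(Task.ECFOAM, "HC")] == pytest.approx(0.114)

    def test_headline_retest_iccs(self):
        cfg = default_study_config()
        assert cfg.retest_icc["gait_turn_velocity_st"] == 0.95
        assert cfg.retest_icc["gait_foot_strike_angle_st"] == 0.97
        assert cfg.retest_icc["gait_arm_rom_st"] == 0.96
        assert cfg.retest_icc["apa_first_step_rom_st"] == 0.82

    def test_planted_structure_counts(self):
        cfg = default_study_config()
        cohort_kept = generate_planted_kept(cfg)
        sensitive = [
            m
            for m, d in cfg.smd_profile.items()
            if d > 0.5 and cfg.catalogue.get(m).task is not Task.ECFOAM
        ]
        assert len(sensitive) == 44
        assert len(cfg.planted_pairs) == 20
        assert len(cohort_kept) == 24

    def test_planted_domain_ordering(self):
        cfg = default_study_config()
        cat = cfg.catalogue
        means = {}
        for dom in (Domain.GAIT, Domain.APA, Domain.SWAY, Domain.APR):
            vals = [
                d
                for m, d in cfg.smd_profile.items()
                if d > 0.5 and cat.get(m).domain is dom and cat.get(m).task is not Task.ECFOAM
            ]
            means[dom] = np.mean(vals)
        assert means[Domain.GAIT] > means[Domain.APA] > means[Domain.SWAY] > means[Domain.APR]
        los = [cfg.smd_profile[m] for m in cat.ids if cat.get(m).domain is Domain.LOS]
        assert max(los) < 0.3


class TestGenerate:
    def test_seed_determinism(self):
        a = generate(default_study_config(seed=3))
        b = generate(default_study_config(seed=3))
        pd.testing.assert_frame_equal(a.table.values, b.table.values)
        pd.testing.assert_frame_equal(a.table.miss_code, b.table.miss_code)
        pd.testing.assert_frame_equal(a.retest_table.values, b.retest_table.values)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)

    def test_shapes_and_labels(self, study_cohort):
        cfg = study_cohort.config
        assert study_cohort.table.values.shape == (223, 93)
        assert study_cohort.retest_table.values.shape == (cfg.n_pd, 93)
        assert set(study_cohort.retest_table.group) == {"PD"}

    def test_null_profile_centered_at_zero(self):
        cfg = _small_config(seed=21, n_pd=3000, n_hc=3000)
        cohort = generate(cfg)
        effects = compute_effect_sizes(
            complete_table(cohort.truth.complete_values, cohort.table.group)
        )
        assert abs(effects["smd"].mean()) < 0.05

    def test_planted_smd_recovered_over_replicates(self):
        cat = build_default_catalogue()
        target = "gait_speed_st"
        estimates = []
        for s in range(200):
            cfg = _small_config(smd_profile={target: 1.0}, seed=5000 + s)
            cohort = generate(cfg)
            effects = compute_effect_sizes(
                complete_table(
                    cohort.truth.complete_values[[target]], cohort.table.group
                )
            )
            estimates.append(effects.loc[target, "smd"])
        # speed is lower-is-worse, so the signed SMD is negative
        assert np.mean(estimates) == pytest.approx(-1.0, abs=0.05)

    def test_large_n_parameter_recovery(self):
        """Planted SMD, block correlation and ICC at n = 10,000."""
        cfg = default_study_config(seed=77)
        big = SynthConfig(
            catalogue=cfg.catalogue,
            n_pd=6456,
            n_hc=3544,
            smd_profile=cfg.smd_profile,
            block_correlation=cfg.block_correlation,
            cross_block_correlation=cfg.cross_block_correlation,
            extra_correlations=cfg.extra_correlations,
            missingness_spec=[],
            retest_icc=cfg.retest_icc,
            planted_pairs=cfg.planted_pairs,
            seed=77,
        )
        cohort = generate(big)
        table = complete_table(cohort.truth.complete_values, cohort.table.group)

        effects = compute_effect_sizes(table)
        sens = cohort.truth.planted_sensitive
        errors = effects.loc[sens, "abs_smd"] - pd.Series(
            {m: cohort.truth.planted_smd[m] for m in sens}
        )
        assert abs(errors.mean()) < 0.02
        assert errors.abs().max() < 0.1

        # within-block correlation: gait block, planted 0.40.  Conditioned on
        # group, because the pooled-cohort correlation also carries the
        # planted between-group mean shifts.
        gait_ids = ["gait_cadence_st", "gait_trunk_rom_st", "gait_toe_off_angle_st"]
        sub = table.values.loc[table.group == "PD", gait_ids]
        corr = sub.corr().to_numpy()
        off = corr[np.triu_indices(3, k=1)]
        assert np.allclose(np.abs(off), 0.40, atol=0.02)

        # retest ICC at the planted target
        m = "gait_turn_velocity_st"
        pairs = np.column_stack(
            [
                cohort.truth.complete_values.loc[cohort.retest_table.values.index, m],
                cohort.retest_table.values[m],
            ]
        )
        assert icc_two_way(pairs) == pytest.approx(0.95, abs=0.02)

    def test_missingness_rates_respected(self, study_cohort):
        table = study_cohort.table
        cat = study_cohort.config.catalogue
        rates = table.task_missing_fractions(cat)
        assert rates.loc["ECFoam", "PD"] == pytest.approx(0.389, abs=1 / 144)
        assert rates.loc["ECFoam", "HC"] == pytest.approx(0.114, abs=1 / 79)
        assert rates.loc["EOFoam", "PD"] == pytest.approx(0.139, abs=1 / 144)
        assert rates.loc["Gait_ST", "pooled"] == 0.0

    def test_fall_missingness_targets_most_impaired(self, study_cohort):
        latent = study_cohort.truth.latent
        codes = study_cohort.table.miss_code["sway_rms_ml_ecfoam"]
        group = study_cohort.table.group
        pd_subjects = group[group == "PD"].index
        masked = [s for s in pd_subjects if codes[s] == "A"]
        unmasked = [s for s in pd_subjects if codes[s] == "O"]
        assert latent[masked].min() > latent[unmasked].max() - 1e-12

    def test_non_positive_definite_structure_rejected(self):
        # m1 highly correlated with both m2 and m3, which are anti-correlated
        extra = {
            ("gait_speed_st", "gait_speed_dt"): 0.95,
            ("gait_speed_st", "gait_stride_length_st"): 0.95,
            ("gait_speed_dt", "gait_stride_length_st"): -0.5,
        }
        cfg = _small_config(extra_correlations=extra)
        with pytest.raises(ValueError, match="positive definite"):
            generate(cfg)

    def test_clinical_scales_within_range_and_routed(self, study_cohort):
        clin = study_cohort.clinical
        group = study_cohort.table.group
        assert clin["MiniBEST"].between(0, 28).all()
        assert clin["ABC"].between(0, 100).all()
        # PD-only scales absent for controls, present for PD
        hc = group[group == "HC"].index
        pd_idx = group[group == "PD"].index
        assert clin.loc[hc, "UPDRS_III"].isna().all()
        assert clin.loc[pd_idx, "UPDRS_III"].notna().all()

    def test_clinical_scales_track_impairment(self, study_cohort):
        clin = study_cohort.clinical
        group = study_cohort.table.group
        mb_pd = clin.loc[group == "PD", "MiniBEST"].mean()
        mb_hc = clin.loc[group == "HC", "MiniBEST"].mean()
        assert mb_pd < mb_hc  # dynamic balance worse in PD

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            MissingnessRule(Task.ECFOAM, "PD", 1.5, MissCode.A_FALL)
        with pytest.raises(ValueError, match="ICC"):
            _small_config(retest_icc={"gait_speed_st": 1.5})
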