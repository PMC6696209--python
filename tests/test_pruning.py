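import numpy as np
import pandas as pd
import pytest

from balancesel.pruning import (
    CorrelationMatrix,
    prune,
    spearman_matrix,
    spearman_matrix_pooled,
)
from conftest import complete_table, toy_catalogue
from _oracles import prune_all_orders, prune_min_removal, spearman_oracle_no_ties


def _effects_frame(abs_smds: dict[str, float]) -> pd.DataFrame:
    df = pd.DataFrame({"abs_smd": pd.Series(abs_smds)})
    df.index.name = "measure_id"
    return df


def _toy_cat(ids):
    """Catalogue of unrelated single-task measures (no ST/DT pairs)."""
    return toy_catalogue(
        [(m, f"Base {m}", "APR", "PushRelease", "higher_is_worse") for m in ids]
    )


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(50)
        table = complete_table(
            pd.DataFrame({"x": x, "y": np.exp(x)}, index=[f"s{i}" for i in range(50)]),
            pd.Series(["PD"] * 25 + ["HC"] * 25, index=[f"s{i}" for i in range(50)]),
        )
        corr = spearman_matrix(table)
        assert corr.rho[0, 1] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self, rng):
        x = rng.standard_normal(30)
        idx = [f"s{i}" for i in range(30)]
        table = complete_table(
            pd.DataFrame({"x": x, "y": -x}, index=idx),
            pd.Series(["PD"] * 15 + ["HC"] * 15, index=idx),
        )
        assert spearman_matrix(table).rho[0, 1] == pytest.approx(-1.0)

    def test_five_point_vector_matches_rank_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [3, 1, 2, 5, 4]
        idx = [f"s{i}" for i in range(5)]
        table = complete_table(
            pd.DataFrame({"x": x, "y": y}, index=idx, dtype=float),
            pd.Series(["PD", "PD", "PD", "HC", "HC"], index=idx),
        )
        expected = spearman_oracle_no_ties(x, y)  # sum d^2 = 8 -> rho = 0.6
        assert expected == pytest.approx(0.6)
        assert spearman_matrix(table).rho[0, 1] == pytest.approx(expected)

    def test_constant_column_rejected_by_name(self, rng):
        idx = [f"s{i}" for i in range(10)]
        table = complete_table(
            pd.DataFrame(
                {"ok": rng.standard_normal(10), "flat": np.ones(10)}, index=idx
            ),
            pd.Series(["PD"] * 5 + ["HC"] * 5, index=idx),
        )
        with pytest.raises(ValueError, match="flat"):
            spearman_matrix(table)

    def test_incomplete_data_rejected(self, rng):
        idx = [f"s{i}" for i in range(10)]
        vals = pd.DataFrame(
            {"a": rng.standard_normal(10), "b": rng.standard_normal(10)}, index=idx
        )
        vals.loc["s0", "a"] = np.nan
        codes = pd.DataFrame("O", index=idx, columns=["a", "b"])
        codes.loc["s0", "a"] = "B"
        from balancesel.tables import MeasureTable

        table = MeasureTable(vals, pd.Series(["PD"] * 5 + ["HC"] * 5, index=idx), codes)
        with pytest.raises(ValueError, match="complete"):
            spearman_matrix(table)

    def test_pooled_matrix_is_mean_over_datasets(self, imputed_study):
        _, _, ensemble = imputed_study
        ids = ensemble.datasets[0].measure_ids[:10]
        pooled = spearman_matrix_pooled(ensemble, ids)
        per_ds = np.stack([spearman_matrix(ds, ids).rho for ds in ensemble.datasets])
        assert np.allclose(pooled.rho, per_ds.mean(axis=0))


class TestCorrelationMatrixType:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            CorrelationMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            CorrelationMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))


class TestPruneRules:
    def test_single_pair_removes_smaller_smd(self):
        ids = ["big", "small"]
        corr = CorrelationMatrix(ids, np.array([[1.0, 0.9], [0.9, 1.0]]))
        audit = prune(
            _effects_frame({"big": 1.0, "small": 0.6}), corr, _toy_cat(ids), 0.7
        )
        assert audit.survivors == ["big"]
        rec = audit.removed[0]
        assert (rec.removed_id, rec.kept_id, rec.rule_applied) == (
            "small",
            "big",
            "smaller_smd",
        )

    def test_dual_task_member_removed_despite_larger_smd(self):
        cat = toy_catalogue(
            [
                ("gait_speed_st", "Gait speed", "Gait", "Gait_ST", "lower_is_worse"),
                ("gait_speed_dt", "Gait speed", "Gait", "Gait_DT", "lower_is_worse"),
            ]
        )
        ids = ["gait_speed_st", "gait_speed_dt"]
        corr = CorrelationMatrix(ids, np.array([[1.0, 0.8], [0.8, 1.0]]))
        effects = _effects_frame({"gait_speed_st": 0.7, "gait_speed_dt": 1.1})
        audit = prune(effects, corr, cat, 0.7)
        assert audit.survivors == ["gait_speed_st"]
        assert audit.removed[0].rule_applied == "dual_task"

    def test_below_threshold_pair_untouched(self):
        ids = ["a", "b"]
        corr = CorrelationMatrix(ids, np.array([[1.0, 0.69], [0.69, 1.0]]))
        audit = prune(_effects_frame({"a": 1.0, "b": 0.6}), corr, _toy_cat(ids), 0.7)
        assert set(audit.survivors) == {"a", "b"}
        assert audit.removed == []

    def test_id_mismatch_rejected(self):
        corr = CorrelationMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="same measures"):
            prune(_effects_frame({"a": 1.0, "c": 0.5}), corr, _toy_cat(["a", "b", "c"]), 0.7)

    def test_deterministic(self, rng):
        ids, corr, effects, cat = _random_instance(rng, 6)
        a1 = prune(effects, corr, cat, 0.7)
        a2 = prune(effects, corr, cat, 0.7)
        assert a1.survivors == a2.survivors and a1.removed == a2.removed


def _random_instance(rng, n):
    """Random small instance with a valid (PSD) correlation matrix and a few
    planted violations."""
    ids = [f"m{i}" for i in range(n)]
    # random factor loadings give a PSD matrix with occasional |rho| > 0.7
    loadings = rng.uniform(0.3, 0.98, size=n) * rng.choice([-1, 1], size=n)
    rho = np.outer(loadings, loadings)
    np.fill_diagonal(rho, 1.0)
    effects = _effects_frame(
        {m: round(float(rng.uniform(0.5, 1.5)), 3) for m in ids}
    )
    return ids, CorrelationMatrix(ids, rho), effects, _toy_cat(ids)


class TestPruneAgainstExhaustiveOrders:
    """Brute-force enumeration of every rule-respecting removal order."""

    def _oracle_inputs(self, corr, effects, cat):
        ids = corr.measure_ids
        abs_rho = {}
        st_dt = {}
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                b = ids[j]
                key = tuple(sorted((a, b)))
                abs_rho[key] = abs(corr.rho[i, j])
                if cat.is_st_dt_pair(a, b):
                    st_dt[key] = cat.dt_member(a, b)
        return abs_rho, st_dt

    def test_greedy_output_is_reachable_and_violation_free(self, rng):
        for trial in range(150):
            n = int(rng.integers(3, 7))
            ids, corr, effects, cat = _random_instance(rng, n)
            audit = prune(effects, corr, cat, 0.7)
            abs_rho, st_dt = self._oracle_inputs(corr, effects, cat)
            terminals = prune_all_orders(
                ids, abs_rho, effects["abs_smd"].to_dict(), st_dt, 0.7
            )
            assert frozenset(audit.survivors) in terminals
            # and when every order converges, greedy matches the unique result
            if len(terminals) == 1:
                assert frozenset(audit.survivors) == next(iter(terminals))
            # no violating pair among survivors
            for i, a in enumerate(audit.survivors):
                for b in audit.survivors[i + 1 :]:
                    assert abs_rho[tuple(sorted((a, b)))] <= 0.7
            # every removal was justified by a then-violating pair and its rule
            for rec in audit.removed:
                key = tuple(sorted((rec.removed_id, rec.kept_id)))
                assert abs_rho[key] > 0.7
                if rec.rule_applied == "dual_task":
                    assert st_dt[key] == rec.removed_id
                else:
                    smds = effects["abs_smd"]
                    assert smds[rec.removed_id] <= smds[rec.kept_id]

    def test_planted_five_measure_instance_matches_minimum_removal(self):
        """Five measures, three violations: greedy finds the minimum-removal
        solution of the exhaustive search."""
        ids = ["m0", "m1", "m2", "m3", "m4"]
        rho = np.eye(5)
        # violations: (m0,m1)=0.9, (m0,m2)=0.8, (m3,m4)=0.75
        rho[0, 1] = rho[1, 0] = 0.9
        rho[0, 2] = rho[2, 0] = 0.8
        rho[3, 4] = rho[4, 3] = 0.75
        corr = CorrelationMatrix(ids, rho)
        effects = _effects_frame({"m0": 0.6, "m1": 1.2, "m2": 1.0, "m3": 0.9, "m4": 0.8})
        cat = _toy_cat(ids)
        audit = prune(effects, corr, cat, 0.7)
        abs_rho, st_dt = ({}, {})
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                abs_rho[tuple(sorted((a, ids[j])))] = abs(rho[i, j])
        minimal = prune_min_removal(ids, abs_rho, effects["abs_smd"].to_dict(), st_dt, 0.7)
        assert frozenset(audit.survivors) in minimal

    def test_study_survivor_matrix_has_no_violations(self, imputed_study):
        from balancesel.effect_size import compute_effect_sizes_pooled, filter_by_smd

        _, removal, ensemble = imputed_study
        passing = filter_by_smd(compute_effect_sizes_pooled(ensemble))
        corr = spearman_matrix_pooled(ensemble, list(passing.index))
        audit = prune(passing, corr, removal.catalogue, 0.7)
        sub = corr.submatrix(audit.survivors).rho
        off = np.abs(sub[np.triu_indices_from(sub, k=1)])
        assert off.max() <= 0.7
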