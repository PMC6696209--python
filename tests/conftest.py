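import numpy as np
import pandas as pd
import pytest

from balancesel.catalog import (
    Catalogue,
    Domain,
    ImpairmentDirection,
    MeasureDescriptor,
    Task,
    build_default_catalogue,
)
from balancesel.imputation import drop_high_missing_tasks, impute_table
from balancesel.synthgen import default_study_config, generate
from balancesel.tables import MeasureTable


def complete_table(values: pd.DataFrame, group: pd.Series) -> MeasureTable:
    """Wrap complete values in a MeasureTable with all-Observed codes."""
    codes = pd.DataFrame("O", index=values.index, columns=values.columns)
    return MeasureTable(values, group, codes)


def toy_catalogue(specs) -> Catalogue:
    """Catalogue from (measure_id, base_name, domain, task, direction) tuples."""
    return Catalogue(
        tuple(
            MeasureDescriptor(
                measure_id=mid,
                base_name=base,
                domain=Domain(dom),
                task=Task(task),
                is_dual_task=Task(task) in {Task.ISAW_STAND_DT, Task.GAIT_DT, Task.APA_DT},
                is_derived=Task(task) is Task.GAIT_DC,
                impairment_direction=ImpairmentDirection(direction),
            )
            for mid, base, dom, task, direction in specs
        )
    )


def two_group_table(rng, n_pd=30, n_hc=20, columns=("m1",), pd_shift=0.0):
    """Small complete Gaussian table, PD group optionally mean-shifted."""
    n = n_pd + n_hc
    subjects = [f"s{i}" for i in range(n)]
    group = pd.Series(["PD"] * n_pd + ["HC"] * n_hc, index=subjects)
    vals = pd.DataFrame(
        rng.standard_normal((n, len(columns))), index=subjects, columns=list(columns)
    )
    vals.iloc[:n_pd] += pd_shift
    return complete_table(vals, group)


@pytest.fixture(scope="session")
def catalogue() -> Catalogue:
    return build_default_catalogue()


@pytest.fixture(scope="session")
def study_cohort():
    return generate(default_study_config(seed=11))


@pytest.fixture(scope="session")
def imputed_study(study_cohort):
    """Task removal + two-track imputation of the session study cohort."""
    removal = drop_high_missing_tasks(
        study_cohort.table, study_cohort.config.catalogue
    )
    ensemble = impute_table(removal.table, removal.catalogue, m=10, seed=13)
    return study_cohort, removal, ensemble


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
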