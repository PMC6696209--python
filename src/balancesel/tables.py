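"""Subject x measure data container with per-cell missingness categories.

Missing cells are coded by *why* they are missing, because the imputation
policy depends on the reason:

===== ======================= ==============================================
code  category                imputation track
===== ======================= ==============================================
O     observed                --
A     fall during the task    worst case +/- 2 SD (single value)
B     task skipped            multiple imputation
C     sensor data not usable  multiple imputation
D     no detectable APA       worst case +/- 2 SD (single value)
E     baseline too noisy      multiple imputation
===== ======================= ==============================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalogue

__all__ = ["MissCode", "MeasureTable", "WORST_CASE_CODES", "MI_CODES"]


class MissCode(str, enum.Enum):
    OBSERVED = "O"
    A_FALL = "A"
    B_SKIP = "B"
    C_NOT_USABLE = "C"
    D_NO_APA = "D"
    E_NOISY = "E"


WORST_CASE_CODES = frozenset({MissCode.A_FALL.value, MissCode.D_NO_APA.value})
MI_CODES = frozenset(
    {MissCode.B_SKIP.value, MissCode.C_NOT_USABLE.value, MissCode.E_NOISY.value}
)


@dataclass
class MeasureTable:
    """Subjects x measures matrix with group labels and missingness codes.

    ``values`` and ``miss_code`` share index (subject_id) and columns
    (measure_id); ``group`` is a subject-indexed series of ``"PD"``/``"HC"``.
    A NaN cell must carry a non-Observed code.  An imputed cell keeps its
    original code as provenance, so a non-Observed code on a filled cell is
    legal.
    """

    values: pd.DataFrame
    group: pd.Series
    miss_code: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.validate()

    def validate(self) -> None:
        if not self.values.index.equals(self.miss_code.index) or not (
            self.values.columns.equals(self.miss_code.columns)
        ):
            raise ValueError("values and miss_code must share index and columns")
        if not self.values.index.equals(self.group.index):
            raise ValueError("group must be indexed by the same subjects as values")
        bad_groups = set(self.group.unique()) - {"PD", "HC"}
        if bad_groups:
            raise ValueError(f"unknown group label(s): {sorted(bad_groups)}")
        valid = {c.value for c in MissCode}
        codes = self.miss_code.to_numpy()
        if not np.isin(codes, sorted(valid)).all():
            raise ValueError("miss_code contains values outside {O,A,B,C,D,E}")
        if codes.size:
            nan_but_observed = self.values.isna().to_numpy() & (codes == "O")
            if nan_but_observed.any():
                raise ValueError("missing cells must carry a non-Observed miss code")

    # -- basic accessors ---------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def measure_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pd(self) -> int:
        return int((self.group == "PD").sum())

    @property
    def n_hc(self) -> int:
        return int((self.group == "HC").sum())

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def copy(self) -> "MeasureTable":
        return MeasureTable(self.values.copy(), self.group.copy(), self.miss_code.copy())

    def select_measures(self, measure_ids: Sequence[str]) -> "MeasureTable":
        missing = set(measure_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown measure_id(s): {sorted(missing)}")
        ids = list(measure_ids)
        return MeasureTable(
            self.values[ids].copy(), self.group.copy(), self.miss_code[ids].copy()
        )

    def select_group(self, group: str) -> "MeasureTable":
        mask = self.group == group
        return MeasureTable(
            self.values.loc[mask].copy(),
            self.group.loc[mask].copy(),
            self.miss_code.loc[mask].copy(),
        )

    # -- missingness summaries --------------------------------------------

    def missing_fraction(
        self, measure_ids: Iterable[str] | None = None, group: str | None = None
    ) -> float:
        """Fraction of NaN cells over the given measures (and group)."""
        vals = self.values if measure_ids is None else self.values[list(measure_ids)]
        if group is not None:
            vals = vals.loc[self.group == group]
        return float(vals.isna().to_numpy().mean())

    def task_missing_fractions(self, cat: Catalogue) -> pd.DataFrame:
        """Per-task missing fractions (pooled cohort, PD, HC)."""
        rows = []
        for task in {d.task for d in cat}:
            ids = [d.measure_id for d in cat if d.task is task and d.measure_id in self.values.columns]
            if not ids:
                continue
            rows.append(
                {
                    "task": task.value,
                    "pooled": self.missing_fraction(ids),
                    "PD": self.missing_fraction(ids, group="PD"),
                    "HC": self.missing_fraction(ids, group="HC"),
                }
            )
        return pd.DataFrame(rows).set_index("task").sort_index()

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, values_path, codes_path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.group)
        out.to_csv(values_path, index_label="subject_id")
        self.miss_code.to_csv(codes_path, index_label="subject_id")

    @classmethod
    def from_csv(cls, values_path, codes_path=None) -> "MeasureTable":
        vals = pd.read_csv(values_path, index_col="subject_id")
        vals.index = vals.index.astype(str).rename(None)
        group = vals.pop("group")
        if codes_path is not None:
            codes = pd.read_csv(codes_path, index_col="subject_id", dtype=str)
            codes.index = codes.index.astype(str).rename(None)
        else:
            codes = pd.DataFrame(
                np.where(vals.isna(), MissCode.B_SKIP.value, MissCode.OBSERVED.value),
                index=vals.index,
                columns=vals.columns,
            )
        return cls(vals, group, codes)
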