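"""Catalogue of objective balance measures from body-worn inertial sensors.

The battery covers five domains of postural control:

* **Sway** — quiet-stance acceleration statistics under six standing
  conditions (vision x surface, plus the standing phase of an instrumented
  stand-and-walk test with and without a concurrent cognitive task).
* **APA** — anticipatory postural adjustments before step initiation,
  single- and dual-task.
* **APR** — automatic postural responses to a push-and-release perturbation.
* **Gait** — spatiotemporal walking measures, single- and dual-task, plus
  derived dual-task-cost measures for five of them.
* **LOS** — functional limits of stability (maximal forward/backward lean).

The default catalogue instantiates 7 sway base measures under 6 standing
tasks (42), 12 gait base measures under single and dual task (24) plus 5
dual-task-cost measures, 6 APA base measures under single and dual task
(12), 7 APR measures and 3 LOS measures: 93 measures in total.

Each descriptor carries an impairment direction: whether parkinsonian
deficit pushes the measure up (e.g. sway amplitude, latencies, durations)
or down (e.g. speed, range of motion, step length).  Downstream worst-case
imputation and the synthetic-cohort generator both rely on it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "Domain",
    "Task",
    "ImpairmentDirection",
    "MeasureDescriptor",
    "Catalogue",
    "build_default_catalogue",
    "drop_task",
    "dual_task_cost",
    "DUAL_TASKS",
    "ST_DT_TASK_PAIRS",
]


class Domain(str, enum.Enum):
    SWAY = "Sway"
    APA = "APA"
    APR = "APR"
    GAIT = "Gait"
    LOS = "LOS"


class Task(str, enum.Enum):
    EOFIRM = "EOFirm"
    ECFIRM = "ECFirm"
    EOFOAM = "EOFoam"
    ECFOAM = "ECFoam"
    ISAW_STAND_ST = "ISAW_stand_ST"
    ISAW_STAND_DT = "ISAW_stand_DT"
    GAIT_ST = "Gait_ST"
    GAIT_DT = "Gait_DT"
    GAIT_DC = "Gait_DC"
    APA_ST = "APA_ST"
    APA_DT = "APA_DT"
    PUSH_RELEASE = "PushRelease"
    LOS = "LOS"


#: Tasks performed with a concurrent cognitive task.
DUAL_TASKS = frozenset({Task.ISAW_STAND_DT, Task.GAIT_DT, Task.APA_DT})

#: Dual-task variant -> single-task counterpart of the same base measure.
ST_DT_TASK_PAIRS: Mapping[Task, Task] = {
    Task.ISAW_STAND_DT: Task.ISAW_STAND_ST,
    Task.GAIT_DT: Task.GAIT_ST,
    Task.APA_DT: Task.APA_ST,
}


class ImpairmentDirection(str, enum.Enum):
    HIGHER_IS_WORSE = "higher_is_worse"
    LOWER_IS_WORSE = "lower_is_worse"


_HIGHER = ImpairmentDirection.HIGHER_IS_WORSE
_LOWER = ImpairmentDirection.LOWER_IS_WORSE


@dataclass(frozen=True)
class MeasureDescriptor:
    """Identity of one objective measure."""

    measure_id: str
    base_name: str
    domain: Domain
    task: Task
    is_dual_task: bool
    is_derived: bool
    impairment_direction: ImpairmentDirection

    def __post_init__(self) -> None:
        if self.is_derived and self.task is not Task.GAIT_DC:
            raise ValueError(
                f"{self.measure_id}: derived (dual-task-cost) measures must "
                f"have task {Task.GAIT_DC.value}, got {self.task.value}"
            )
        if self.is_dual_task != (self.task in DUAL_TASKS):
            raise ValueError(
                f"{self.measure_id}: is_dual_task must hold exactly for tasks "
                f"{sorted(t.value for t in DUAL_TASKS)}"
            )


# enum definition order is the canonical sort order
_DOMAIN_ORDER = {d: i for i, d in enumerate(Domain)}
_TASK_ORDER = {t: i for i, t in enumerate(Task)}


@dataclass(frozen=True)
class Catalogue:
    """Ordered, immutable collection of measure descriptors."""

    descriptors: tuple[MeasureDescriptor, ...]

    def __post_init__(self) -> None:
        ids = [d.measure_id for d in self.descriptors]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate measure_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self) -> Iterator[MeasureDescriptor]:
        return iter(self.descriptors)

    @property
    def ids(self) -> list[str]:
        return [d.measure_id for d in self.descriptors]

    def get(self, measure_id: str) -> MeasureDescriptor:
        for d in self.descriptors:
            if d.measure_id == measure_id:
                return d
        raise KeyError(measure_id)

    def __contains__(self, measure_id: str) -> bool:
        return any(d.measure_id == measure_id for d in self.descriptors)

    def domain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.descriptors:
            counts[d.domain.value] = counts.get(d.domain.value, 0) + 1
        return counts

    def task_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.descriptors:
            counts[d.task.value] = counts.get(d.task.value, 0) + 1
        return counts

    def subset(self, measure_ids: Iterable[str]) -> "Catalogue":
        wanted = set(measure_ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"unknown measure_id(s): {sorted(missing)}")
        return Catalogue(tuple(d for d in self.descriptors if d.measure_id in wanted))

    def is_st_dt_pair(self, id_a: str, id_b: str) -> bool:
        """True when the two measures are the ST/DT instantiation of one base."""
        a, b = self.get(id_a), self.get(id_b)
        if a.base_name != b.base_name or a.domain is not b.domain:
            return False
        pair = {a.task, b.task}
        return any({dt, st} == pair for dt, st in ST_DT_TASK_PAIRS.items())

    def dt_member(self, id_a: str, id_b: str) -> str:
        """Of an ST/DT pair, return the dual-task member's id."""
        if not self.is_st_dt_pair(id_a, id_b):
            raise ValueError(f"({id_a}, {id_b}) is not an ST/DT pair")
        return id_a if self.get(id_a).is_dual_task else id_b

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure_id": d.measure_id,
                    "base_name": d.base_name,
                    "domain": d.domain.value,
                    "task": d.task.value,
                    "is_dual_task": d.is_dual_task,
                    "is_derived": d.is_derived,
                    "impairment_direction": d.impairment_direction.value,
                }
                for d in self.descriptors
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_yaml(self, path) -> None:
        records = self.to_dataframe().to_dict(orient="records")
        with open(path, "w") as fh:
            yaml.safe_dump(records, fh, sort_keys=False)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "Catalogue":
        descriptors = tuple(
            MeasureDescriptor(
                measure_id=r["measure_id"],
                base_name=r["base_name"],
                domain=Domain(r["domain"]),
                task=Task(r["task"]),
                is_dual_task=bool(r["is_dual_task"]),
                is_derived=bool(r["is_derived"]),
                impairment_direction=ImpairmentDirection(r["impairment_direction"]),
            )
            for r in records
        )
        return cls(descriptors)

    @classmethod
    def from_yaml(cls, path) -> "Catalogue":
        with open(path) as fh:
            records = yaml.safe_load(fh)
        return cls.from_records(records)


# ---------------------------------------------------------------------------
# default base-measure lists (name -> impairment direction)
# ---------------------------------------------------------------------------

SWAY_BASES: Mapping[str, ImpairmentDirection] = {
    "RMS ML": _HIGHER,
    "RMS AP": _HIGHER,
    "Jerk ML": _HIGHER,
    "Jerk AP": _HIGHER,
    "Sway area": _HIGHER,
    "Mean velocity": _HIGHER,
    "Centroid frequency": _HIGHER,
}

GAIT_BASES: Mapping[str, ImpairmentDirection] = {
    "Gait speed": _LOWER,
    "Stride length": _LOWER,
    "Cadence": _LOWER,
    "Stance time": _HIGHER,
    "Double support time": _HIGHER,
    "Gait cycle duration SD": _HIGHER,
    "Arm ROM": _LOWER,
    "Trunk ROM": _LOWER,
    "Foot strike angle": _LOWER,
    "Turn velocity": _LOWER,
    "Turn duration": _HIGHER,
    "Toe off angle": _LOWER,
}

#: Gait bases that also get a derived dual-task-cost measure.
DC_BASES: tuple[str, ...] = (
    "Gait speed",
    "Stride length",
    "Stance time",
    "Double support time",
    "Gait cycle duration SD",
)

APA_BASES: Mapping[str, ImpairmentDirection] = {
    "First step ROM": _LOWER,
    "First step length": _LOWER,
    "First step duration": _HIGHER,
    "APA amplitude ML": _LOWER,
    "APA amplitude AP": _LOWER,
    "APA duration": _HIGHER,
}

APR_BASES: Mapping[str, ImpairmentDirection] = {
    "Step latency": _HIGHER,
    "Step length": _LOWER,
    "Step velocity": _LOWER,
    "Time to stability": _HIGHER,
    "Number of steps": _HIGHER,
    "Trunk lean": _HIGHER,
    "First step duration": _HIGHER,
}

LOS_BASES: Mapping[str, ImpairmentDirection] = {
    "Forward range": _LOWER,
    "Backward range": _LOWER,
    "Total range": _LOWER,
}

_STANDING_TASKS = (
    Task.EOFIRM,
    Task.ECFIRM,
    Task.EOFOAM,
    Task.ECFOAM,
    Task.ISAW_STAND_ST,
    Task.ISAW_STAND_DT,
)

_TASK_SLUG = {
    Task.EOFIRM: "eofirm",
    Task.ECFIRM: "ecfirm",
    Task.EOFOAM: "eofoam",
    Task.ECFOAM: "ecfoam",
    Task.ISAW_STAND_ST: "isaw_st",
    Task.ISAW_STAND_DT: "isaw_dt",
    Task.GAIT_ST: "st",
    Task.GAIT_DT: "dt",
    Task.GAIT_DC: "dc",
    Task.APA_ST: "st",
    Task.APA_DT: "dt",
    Task.PUSH_RELEASE: "pr",
    Task.LOS: "los",
}


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_")


def build_default_catalogue() -> Catalogue:
    """Construct the full 93-measure default catalogue.

    Deterministic ordering: (domain, task, base_name), with domain and task
    in enum definition order.
    """
    descriptors: list[MeasureDescriptor] = []

    def add(domain: Domain, base: str, task: Task, direction: ImpairmentDirection,
            derived: bool = False) -> None:
        prefix = domain.value.lower()
        slug = _slug(base)
        if slug.startswith(prefix + "_"):  # e.g. "gait_speed" under Gait
            slug = slug[len(prefix) + 1 :]
        mid = f"{prefix}_{slug}_{_TASK_SLUG[task]}"
        if task in (Task.PUSH_RELEASE, Task.LOS):
            mid = f"{prefix}_{slug}"
        descriptors.append(
            MeasureDescriptor(
                measure_id=mid,
                base_name=base,
                domain=domain,
                task=task,
                is_dual_task=task in DUAL_TASKS,
                is_derived=derived,
                impairment_direction=direction,
            )
        )

    for base, direction in SWAY_BASES.items():
        for task in _STANDING_TASKS:
            add(Domain.SWAY, base, task, direction)
    for base, direction in APA_BASES.items():
        for task in (Task.APA_ST, Task.APA_DT):
            add(Domain.APA, base, task, direction)
    for base, direction in APR_BASES.items():
        add(Domain.APR, base, Task.PUSH_RELEASE, direction)
    for base, direction in GAIT_BASES.items():
        for task in (Task.GAIT_ST, Task.GAIT_DT):
            add(Domain.GAIT, base, task, direction)
    for base in DC_BASES:
        add(Domain.GAIT, base, Task.GAIT_DC, GAIT_BASES[base], derived=True)
    for base, direction in LOS_BASES.items():
        add(Domain.LOS, base, Task.LOS, direction)

    descriptors.sort(
        key=lambda d: (_DOMAIN_ORDER[d.domain], _TASK_ORDER[d.task], d.base_name)
    )
    return Catalogue(tuple(descriptors))


def drop_task(cat: Catalogue, task: Task | str) -> Catalogue:
    """Return a catalogue without the descriptors of one task.

    The input catalogue is unchanged; dropping an absent (but valid) task is
    a no-op, so the operation is idempotent.
    """
    try:
        task = Task(task)
    except ValueError:
        raise ValueError(f"unknown task: {task!r}") from None
    return Catalogue(tuple(d for d in cat.descriptors if d.task is not task))


def dual_task_cost(st_value: float, dt_value: float) -> float:
    """Dual-task cost in percent: 100 * (DT - ST) / ST."""
    if st_value == 0:
        raise ValueError("undefined dual-task cost: single-task value is zero")
    return 100.0 * (dt_value - st_value) / st_value
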