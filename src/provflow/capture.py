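"""Experiment capture: frozen process copies, entity genealogy, measurements.

An :class:`Experiment` is an executable copy of one process version.  The
version is frozen at instantiation (with an automatic snapshot if the
process has unsaved edits) and never changes afterwards except through
:func:`amend_design`, which snapshots a new version mid-run and logs the
amendment while keeping the full version history.

Materials and equipment are tracked as :class:`EntityRecord` nodes.  Parent
links between entities (medium batch -> culture -> sample) form the
provenance graph — a DAG at all times — that the join engine later walks to
assemble statistical tables.  Entities may also be *used* by downstream
experiments (a culture sample flowing into an HPLC experiment), which is how
master-process links are realized in the data.

Measurements come in three shapes: scalars, time series (strictly
increasing timestamps, numeric values) and event series (ordered records of
named numeric/text fields).  Out-of-spec parameter values are stored and
flagged, never rejected.
"""

from __future__ import annotations

import csv
import io
import numbers
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from ._ids import Clock, IdGen, default_clock, default_idgen
from .errors import (CycleError, DomainError, StateError, ValidationError)
from .model import (Parameter, ProcessDefinition, ProcessVersion, Step)

MEASUREMENT_SHAPES = ("scalar", "timeseries", "eventseries")


class EntityRecord:
    """A material or equipment instance with genealogy links."""

    def __init__(self, id: str, label: str, kind: str, experiment_id: str,
                 step_id: str, slot_id: str):
        self.id = id
        self.label = label
        self.kind = kind
        self.experiment_id = experiment_id
        self.step_id = step_id
        self.slot_id = slot_id
        self.parents: list["EntityRecord"] = []
        self.children: list["EntityRecord"] = []
        #: (experiment_id, step_id, slot_id) places where this entity is
        #: consumed by other steps/experiments without creating a new entity
        self.uses: list[tuple[str, str, str]] = []

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<EntityRecord {self.label!r} ({self.kind})>"

    def to_dict(self) -> dict:
        return {
            "id": self.id, "label": self.label, "kind": self.kind,
            "experiment_id": self.experiment_id, "step_id": self.step_id,
            "slot_id": self.slot_id,
            "parents": [p.id for p in self.parents],
            "uses": [list(u) for u in self.uses],
        }


def add_parent(child: EntityRecord, parent: EntityRecord) -> None:
    """Attach a parent link, rejecting self-parentage and cycles."""
    if parent is child or parent.id == child.id:
        raise CycleError(f"entity {child.label!r} cannot be its own parent")
    if child in ancestors_of(parent):
        raise CycleError(
            f"link {parent.label!r} -> {child.label!r} would create a "
            "genealogy cycle")
    if any(p.id == parent.id for p in child.parents):
        return
    child.parents.append(parent)
    parent.children.append(child)


def ancestors_of(entity: EntityRecord) -> set[EntityRecord]:
    """Transitive closure over parent links, excluding the entity itself."""
    seen: set[str] = set()
    out: set[EntityRecord] = set()
    stack = list(entity.parents)
    while stack:
        e = stack.pop()
        if e.id in seen:
            continue
        seen.add(e.id)
        out.add(e)
        stack.extend(e.parents)
    return out


def descendants_of(entity: EntityRecord) -> set[EntityRecord]:
    """Transitive closure over child links, excluding the entity itself."""
    seen: set[str] = set()
    out: set[EntityRecord] = set()
    stack = list(entity.children)
    while stack:
        e = stack.pop()
        if e.id in seen:
            continue
        seen.add(e.id)
        out.add(e)
        stack.extend(e.children)
    return out


# spec-facing aliases
ancestors = ancestors_of
descendants = descendants_of


@dataclass
class ParameterValue:
    experiment_id: str
    step_id: str
    parameter_id: str
    name: str
    value: float
    unit: str
    in_spec: bool

    def to_dict(self) -> dict:
        return {"experiment_id": self.experiment_id, "step_id": self.step_id,
                "parameter_id": self.parameter_id, "name": self.name,
                "value": self.value, "unit": self.unit,
                "in_spec": self.in_spec}


@dataclass
class Measurement:
    id: str
    experiment_id: str
    step_id: str
    entity: EntityRecord
    variable: str
    unit: str
    shape: str
    value: object
    recorded_at: str

    def to_dict(self) -> dict:
        if self.shape == "timeseries":
            value = [[t, v] for t, v in self.value]
        elif self.shape == "eventseries":
            value = [dict(rec) for rec in self.value]
        else:
            value = self.value
        return {"id": self.id, "experiment_id": self.experiment_id,
                "step_id": self.step_id, "entity_id": self.entity.id,
                "variable": self.variable, "unit": self.unit,
                "shape": self.shape, "value": value,
                "recorded_at": self.recorded_at}


def _classify_payload(payload) -> tuple[str, object]:
    """Infer the measurement shape and normalize the payload."""
    if isinstance(payload, numbers.Real) and not isinstance(payload, bool):
        return "scalar", float(payload)
    if isinstance(payload, Sequence) and not isinstance(payload, (str, bytes)):
        items = list(payload)
        if not items:
            raise ValidationError("empty series payload")
        if all(isinstance(x, dict) for x in items):
            for rec in items:
                for k, v in rec.items():
                    if not isinstance(k, str):
                        raise ValidationError("event fields must be named")
                    if not isinstance(v, (numbers.Real, str)):
                        raise ValidationError(
                            "event field values must be numeric or text")
            return "eventseries", [dict(rec) for rec in items]
        pairs = []
        for x in items:
            if (not isinstance(x, Sequence) or isinstance(x, (str, bytes))
                    or len(x) != 2):
                raise ValidationError(
                    "timeseries payload must be (timestamp, value) pairs")
            t, v = x
            if not isinstance(t, numbers.Real) or not isinstance(
                    v, numbers.Real):
                raise ValidationError("timeseries entries must be numeric")
            pairs.append((float(t), float(v)))
        for (t0, _), (t1, _) in zip(pairs, pairs[1:]):
            if t1 <= t0:
                raise ValidationError(
                    f"timeseries timestamps must be strictly increasing "
                    f"({t0} -> {t1})")
        return "timeseries", pairs
    raise ValidationError(f"unsupported measurement payload: {payload!r}")


class Experiment:
    """A frozen copy of one process version plus everything recorded on it."""

    def __init__(self, process: ProcessDefinition, name: str, *,
                 idgen: IdGen | None = None, clock: Clock | None = None):
        if not process.steps:
            raise ValidationError(
                "cannot instantiate an experiment from an empty process")
        self._idgen = idgen or default_idgen
        self._clock = clock or default_clock
        process.snapshot_version()              # auto-snapshot if dirty
        self.id: str = self._idgen()
        self.name = name
        self.process = process
        self.version_number: int = process.current_version
        self.status = "running"
        self.created: str = self._clock()
        self.amendments: list[dict] = []
        self.entities: dict[str, EntityRecord] = {}
        self.used: list[EntityRecord] = []
        self.parameter_values: list[ParameterValue] = []
        self.measurements: list[Measurement] = []
        self.step_times: dict[str, dict] = {}

    # -- frozen-version helpers -------------------------------------------

    @property
    def frozen(self) -> ProcessVersion:
        return self.process.version(self.version_number)

    def _resolve_step(self, step: str | Step) -> Step:
        return self.frozen.find_step(step)

    def _resolve_slot(self, step: Step, slot: str):
        return step.slot(slot) if isinstance(slot, str) else slot

    # -- entity registration ----------------------------------------------

    def register_entity(self, step: str | Step, slot: str, label: str,
                        parents: Iterable[EntityRecord] = ()) -> EntityRecord:
        step = self._resolve_step(step)
        slot = self._resolve_slot(step, slot)
        if slot.kind not in ("material", "equipment"):
            raise ValidationError(
                f"entities live on material/equipment slots, not "
                f"{slot.kind!r}")
        entity = EntityRecord(self._idgen(), label, slot.kind, self.id,
                              step.id, slot.id)
        for parent in parents:
            if not isinstance(parent, EntityRecord):
                raise DomainError(f"unknown parent entity: {parent!r}")
            if parent.kind == "equipment":
                raise ValidationError(
                    "equipment entities never parent material entities")
            add_parent(entity, parent)
        self.entities[entity.id] = entity
        return entity

    def split_entity(self, step: str | Step, entity: EntityRecord,
                     n: int, labels: Sequence[str] | None = None,
                     slot: str | None = None) -> list[EntityRecord]:
        """Derive ``n`` child entities (e.g. timepoint samples) from one."""
        if n < 1:
            raise ValidationError(f"split count must be >= 1, got {n}")
        step_obj = self._resolve_step(step)
        if slot is None:
            outs = [s for s in step_obj.slots
                    if s.kind == "material" and s.direction == "output"]
            if len(outs) != 1:
                raise DomainError(
                    f"step {step_obj.name!r} needs exactly one material "
                    "output slot (or pass slot= explicitly)")
            slot = outs[0].name
        if labels is None:
            labels = [f"{entity.label}#{i + 1}" for i in range(n)]
        if len(labels) != n:
            raise ValidationError("labels length must equal n")
        return [self.register_entity(step_obj, slot, lab, parents=[entity])
                for lab in labels]

    def use_entity(self, step: str | Step, slot: str,
                   entity: EntityRecord) -> EntityRecord:
        """Record that an existing entity flows into an input slot here.

        No new entity is created; measurements recorded in this experiment
        may then target the shared entity, and the join engine places its
        label in this step's column as well.
        """
        step = self._resolve_step(step)
        slot = self._resolve_slot(step, slot)
        if slot.direction != "input":
            raise ValidationError(
                f"entities are used on input slots, {slot.name!r} is an "
                f"{slot.direction} slot")
        if slot.kind != entity.kind:
            raise ValidationError(
                f"cannot use a {entity.kind} entity on a {slot.kind} slot")
        use = (self.id, step.id, slot.id)
        if use not in entity.uses:
            entity.uses.append(use)
        if entity not in self.used:
            self.used.append(entity)
        return entity

    def _known_entity(self, entity: EntityRecord) -> bool:
        return entity.id in self.entities or entity in self.used

    # -- recording ---------------------------------------------------------

    def record_parameter(self, step: str | Step, parameter: str | Parameter,
                         value: float) -> ParameterValue:
        step = self._resolve_step(step)
        param = (step.parameter(parameter) if isinstance(parameter, str)
                 else parameter)
        lo, hi = param.lower_spec, param.upper_spec
        in_spec = True
        if lo is not None and value < lo:
            in_spec = False
        if hi is not None and value > hi:
            in_spec = False
        pv = ParameterValue(self.id, step.id, param.id, param.name,
                            float(value), param.unit, in_spec)
        self.parameter_values.append(pv)
        return pv

    def record_measurement(self, step: str | Step, entity: EntityRecord,
                           variable: str, unit: str,
                           payload) -> Measurement:
        step = self._resolve_step(step)
        if not self._known_entity(entity):
            raise DomainError(
                f"entity {entity.label!r} is not registered or used in "
                f"experiment {self.name!r}")
        shape, value = _classify_payload(payload)
        m = Measurement(self._idgen(), self.id, step.id, entity, variable,
                        unit, shape, value, self._clock())
        self.measurements.append(m)
        return m

    def record_step_time(self, step: str | Step, start: str | None = None,
                         stop: str | None = None) -> None:
        step = self._resolve_step(step)
        rec = self.step_times.setdefault(step.id, {})
        if start is not None:
            rec["start"] = start
        if stop is not None:
            rec["stop"] = stop

    # -- lifecycle ---------------------------------------------------------

    def amend_design(self, edit: Callable[[ProcessDefinition], None]
                     ) -> ProcessVersion:
        """Apply a design change mid-run and re-freeze to the new version."""
        if self.status != "running":
            raise StateError(
                f"cannot amend a {self.status!r} experiment")
        edit(self.process)
        version = self.process.snapshot_version()
        self.amendments.append({
            "at": self._clock(),
            "from_version": self.version_number,
            "to_version": version.number,
        })
        self.version_number = version.number
        return version

    def close(self) -> None:
        self.status = "closed"

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id, "name": self.name, "process_id": self.process.id,
            "version_number": self.version_number, "status": self.status,
            "created": self.created, "amendments": list(self.amendments),
            "entities": [e.to_dict() for e in self.entities.values()],
            "used": [e.id for e in self.used],
            "parameter_values": [p.to_dict() for p in self.parameter_values],
            "measurements": [m.to_dict() for m in self.measurements],
            "step_times": self.step_times,
        }


# -- module-level operation aliases -----------------------------------------

def instantiate_experiment(process: ProcessDefinition, name: str,
                           **kw) -> Experiment:
    return Experiment(process, name, **kw)


def register_entity(experiment: Experiment, step, slot, label,
                    parents=()) -> EntityRecord:
    return experiment.register_entity(step, slot, label, parents)


def split_entity(experiment: Experiment, step, entity, n,
                 labels=None, slot=None) -> list[EntityRecord]:
    return experiment.split_entity(step, entity, n, labels, slot)


def use_entity(experiment: Experiment, step, slot, entity) -> EntityRecord:
    return experiment.use_entity(step, slot, entity)


def record_parameter(experiment: Experiment, step, parameter,
                     value) -> ParameterValue:
    return experiment.record_parameter(step, parameter, value)


def record_measurement(experiment: Experiment, step, entity, variable,
                       unit, payload) -> Measurement:
    return experiment.record_measurement(step, entity, variable, unit, payload)


def amend_design(experiment: Experiment, edit) -> tuple:
    version = experiment.amend_design(edit)
    return version, experiment


def import_measurements_csv(experiment: Experiment, step,
                            source) -> list[Measurement]:
    """Bulk-import measurements from CSV.

    Expected columns: ``entity_label, variable, unit, timestamp, value``
    (``timestamp`` optional/empty for scalars).  Rows sharing an entity,
    variable and unit with timestamps are collected into one time series in
    file order; timestamp-less rows each become a scalar measurement.
    """
    if hasattr(source, "read"):
        reader = csv.DictReader(source)
    else:
        with open(source, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(io.StringIO(fh.read()))
    by_label: dict[str, EntityRecord] = {}
    for e in list(experiment.entities.values()) + experiment.used:
        by_label.setdefault(e.label, e)
    series: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    out: list[Measurement] = []
    for row in reader:
        label = row["entity_label"]
        if label not in by_label:
            raise DomainError(f"unknown entity label {label!r} in CSV")
        variable, unit = row["variable"], row.get("unit", "")
        ts = (row.get("timestamp") or "").strip()
        if ts:
            series.setdefault((label, variable, unit), []).append(
                (float(ts), float(row["value"])))
        else:
            out.append(experiment.record_measurement(
                step, by_label[label], variable, unit, float(row["value"])))
    for (label, variable, unit), pairs in series.items():
        out.append(experiment.record_measurement(
            step, by_label[label], variable, unit, pairs))
    return out
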