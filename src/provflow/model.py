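"""Versioned process definitions.

An experimental procedure is modelled as a *process*: a directed acyclic
graph of named steps.  Each step carries free-text instructions, references
to media files (stored as paths/URLs, never ingested), typed input/output
*slots* through which materials, equipment and data flow, and *parameters*
with a unit, a target value and lower/upper spec limits.  Flow edges connect
an output slot of one step to an input slot of another step of the same
kind, and the step graph must stay acyclic.

Processes are versioned: a snapshot freezes a deep, canonical copy of the
current steps and edges as an immutable :class:`ProcessVersion`.  Two
versions of the same process can be diffed into a :class:`ChangeSet`, and a
ChangeSet applied to the older version reproduces the newer one exactly.

Several processes can be composed into a :class:`MasterProcess` by linking
material output slots to material input slots across processes; the join
engine uses these links to assemble cross-process data tables.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from ._ids import Clock, IdGen, default_clock, default_idgen
from .errors import ConflictError, CycleError, DomainError, ValidationError

SLOT_KINDS = ("material", "equipment", "data")
SLOT_DIRECTIONS = ("input", "output")


@dataclass
class Slot:
    id: str
    name: str
    kind: str
    direction: str

    def to_dict(self) -> dict:
        return {"id": self.id, "name": self.name, "kind": self.kind,
                "direction": self.direction}

    @classmethod
    def from_dict(cls, d: dict) -> "Slot":
        return cls(id=d["id"], name=d["name"], kind=d["kind"],
                   direction=d["direction"])


@dataclass
class Parameter:
    id: str
    name: str
    unit: str = ""
    target: float | None = None
    lower_spec: float | None = None
    upper_spec: float | None = None

    def validate(self) -> None:
        lo, hi, tgt = self.lower_spec, self.upper_spec, self.target
        if lo is not None and hi is not None and lo > hi:
            raise ValidationError(
                f"parameter {self.name!r}: lower_spec {lo} > upper_spec {hi}")
        if lo is not None and hi is not None and tgt is not None:
            if not (lo <= tgt <= hi):
                raise ValidationError(
                    f"parameter {self.name!r}: target {tgt} outside "
                    f"spec limits [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {"id": self.id, "name": self.name, "unit": self.unit,
                "target": self.target, "lower_spec": self.lower_spec,
                "upper_spec": self.upper_spec}

    @classmethod
    def from_dict(cls, d: dict) -> "Parameter":
        return cls(id=d["id"], name=d["name"], unit=d["unit"],
                   target=d["target"], lower_spec=d["lower_spec"],
                   upper_spec=d["upper_spec"])


@dataclass
class Step:
    id: str
    name: str
    instructions: str = ""
    media_refs: list[str] = field(default_factory=list)
    slots: list[Slot] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)

    def slot(self, name: str) -> Slot:
        for s in self.slots:
            if s.name == name:
                return s
        raise DomainError(f"step {self.name!r} has no slot {name!r}")

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise DomainError(f"step {self.name!r} has no parameter {name!r}")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "instructions": self.instructions,
            "media_refs": list(self.media_refs),
            "slots": [s.to_dict() for s in self.slots],
            "parameters": [p.to_dict() for p in self.parameters],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Step":
        return cls(
            id=d["id"], name=d["name"], instructions=d["instructions"],
            media_refs=list(d["media_refs"]),
            slots=[Slot.from_dict(s) for s in d["slots"]],
            parameters=[Parameter.from_dict(p) for p in d["parameters"]],
        )


@dataclass(frozen=True)
class FlowEdge:
    """Directed connection (output slot) -> (input slot) between two steps."""

    from_step: str
    from_slot: str
    to_step: str
    to_slot: str

    def key(self) -> tuple[str, str, str, str]:
        return (self.from_step, self.from_slot, self.to_step, self.to_slot)

    def to_dict(self) -> dict:
        return {"from_step": self.from_step, "from_slot": self.from_slot,
                "to_step": self.to_step, "to_slot": self.to_slot}

    @classmethod
    def from_dict(cls, d: dict) -> "FlowEdge":
        return cls(**d)


@dataclass(frozen=True)
class ProcessLink:
    """Material handoff between two processes of a master process."""

    upstream_process: str
    upstream_step: str
    upstream_slot: str
    downstream_process: str
    downstream_step: str
    downstream_slot: str

    def to_dict(self) -> dict:
        return {
            "upstream_process": self.upstream_process,
            "upstream_step": self.upstream_step,
            "upstream_slot": self.upstream_slot,
            "downstream_process": self.downstream_process,
            "downstream_step": self.downstream_step,
            "downstream_slot": self.downstream_slot,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessLink":
        return cls(**d)


class ProcessVersion:
    """Immutable frozen copy of a process's steps and edges.

    The structure is held as a canonical plain-dict document (`data`), which
    makes immutability, byte-stable serialization and structural diffing
    straightforward.  :meth:`materialize` rebuilds Step/FlowEdge objects on
    demand; mutating those does not touch the stored document.
    """

    def __init__(self, process_id: str, number: int, data: dict, created: str):
        self._process_id = process_id
        self._number = number
        self._data = copy.deepcopy(data)
        self._created = created

    process_id = property(lambda self: self._process_id)
    number = property(lambda self: self._number)
    created = property(lambda self: self._created)

    @property
    def data(self) -> dict:
        return copy.deepcopy(self._data)

    def materialize(self) -> tuple[list[Step], list[FlowEdge]]:
        return ([Step.from_dict(s) for s in self._data["steps"]],
                [FlowEdge.from_dict(e) for e in self._data["edges"]])

    def find_step(self, ref: "str | Step") -> Step:
        name_or_id = ref.name if isinstance(ref, Step) else ref
        for s in self._data["steps"]:
            if s["name"] == name_or_id or s["id"] == name_or_id:
                return Step.from_dict(s)
        raise DomainError(f"version {self._number}: no step {name_or_id!r}")

    def to_dict(self) -> dict:
        return {"process_id": self._process_id, "number": self._number,
                "created": self._created, "data": copy.deepcopy(self._data)}

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessVersion":
        return cls(d["process_id"], d["number"], d["data"], d["created"])


class ProcessDefinition:
    """A named, versioned DAG of steps.

    Creation snapshots an empty version 1.  Structural edits mark the
    process *dirty*; the next snapshot (explicit, or implicit at experiment
    instantiation) freezes a new version.
    """

    def __init__(self, name: str, description: str = "", *,
                 idgen: IdGen | None = None, clock: Clock | None = None):
        if not name or not name.strip():
            raise ValidationError("process name must be non-empty")
        self._idgen = idgen or default_idgen
        self._clock = clock or default_clock
        self.id: str = self._idgen()
        self.name = name
        self.description = description
        self.steps: list[Step] = []
        self.edges: list[FlowEdge] = []
        self.versions: list[ProcessVersion] = []
        self._dirty = False
        self._snapshot(force=True)          # version 1: the empty template

    # -- introspection -----------------------------------------------------

    @property
    def current_version(self) -> int:
        return self.versions[-1].number

    @property
    def dirty(self) -> bool:
        return self._dirty

    def step(self, ref: str | Step) -> Step:
        if isinstance(ref, Step):
            return ref
        for s in self.steps:
            if s.name == ref or s.id == ref:
                return s
        raise DomainError(f"process {self.name!r} has no step {ref!r}")

    def version(self, number: int) -> ProcessVersion:
        for v in self.versions:
            if v.number == number:
                return v
        raise DomainError(f"process {self.name!r} has no version {number}")

    # -- edits -------------------------------------------------------------

    def add_step(self, name: str, instructions: str = "",
                 media_refs: Sequence[str] = ()) -> Step:
        if not name or not name.strip():
            raise ValidationError("step name must be non-empty")
        if any(s.name == name for s in self.steps):
            raise ConflictError(f"step name {name!r} already used")
        step = Step(id=self._idgen(), name=name, instructions=instructions,
                    media_refs=list(media_refs))
        self.steps.append(step)
        self._dirty = True
        return step

    def add_slot(self, step: str | Step, name: str, kind: str,
                 direction: str) -> Slot:
        step = self.step(step)
        if kind not in SLOT_KINDS:
            raise ValidationError(f"unknown slot kind {kind!r}")
        if direction not in SLOT_DIRECTIONS:
            raise ValidationError(f"unknown slot direction {direction!r}")
        if any(s.name == name for s in step.slots):
            raise ConflictError(
                f"slot name {name!r} already used on step {step.name!r}")
        slot = Slot(id=self._idgen(), name=name, kind=kind, direction=direction)
        step.slots.append(slot)
        self._dirty = True
        return slot

    def add_parameter(self, step: str | Step, name: str, unit: str = "",
                      target: float | None = None,
                      lower_spec: float | None = None,
                      upper_spec: float | None = None) -> Parameter:
        step = self.step(step)
        if any(p.name == name for p in step.parameters):
            raise ConflictError(
                f"parameter name {name!r} already used on step {step.name!r}")
        param = Parameter(id=self._idgen(), name=name, unit=unit,
                          target=target, lower_spec=lower_spec,
                          upper_spec=upper_spec)
        param.validate()
        step.parameters.append(param)
        self._dirty = True
        return param

    def connect(self, from_: tuple[str | Step, str],
                to: tuple[str | Step, str]) -> FlowEdge:
        """Connect ``(step, output slot)`` to ``(step, input slot)``.

        Slot kinds must match exactly, and the edge must keep the step
        graph acyclic.
        """
        from_step = self.step(from_[0])
        to_step = self.step(to[0])
        from_slot = from_step.slot(from_[1])
        to_slot = to_step.slot(to[1])
        if from_slot.direction != "output":
            raise ValidationError(
                f"slot {from_slot.name!r} is not an output slot")
        if to_slot.direction != "input":
            raise ValidationError(f"slot {to_slot.name!r} is not an input slot")
        if from_slot.kind != to_slot.kind:
            raise ValidationError(
                f"slot kind mismatch: {from_slot.kind} -> {to_slot.kind}")
        edge = FlowEdge(from_step.id, from_slot.id, to_step.id, to_slot.id)
        if any(e.key() == edge.key() for e in self.edges):
            raise ConflictError("edge already exists")
        g = self._step_graph()
        g.add_edge(from_step.id, to_step.id)
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError(
                f"edge {from_step.name!r} -> {to_step.name!r} would create "
                "a cycle")
        self.edges.append(edge)
        self._dirty = True
        return edge

    # -- versioning --------------------------------------------------------

    def snapshot_version(self) -> ProcessVersion:
        """Freeze the current structure; no-op when nothing changed."""
        return self._snapshot(force=False)

    def _snapshot(self, force: bool) -> ProcessVersion:
        if self.versions and not self._dirty and not force:
            return self.versions[-1]
        number = self.versions[-1].number + 1 if self.versions else 1
        data = {"steps": [s.to_dict() for s in self.steps],
                "edges": [e.to_dict() for e in self.edges]}
        version = ProcessVersion(self.id, number, data, self._clock())
        self.versions.append(version)
        self._dirty = False
        return version

    # -- helpers -----------------------------------------------------------

    def _step_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(s.id for s in self.steps)
        g.add_edges_from((e.from_step, e.to_step) for e in self.edges)
        return g

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "description": self.description,
            "steps": [s.to_dict() for s in self.steps],
            "edges": [e.to_dict() for e in self.edges],
            "versions": [v.to_dict() for v in self.versions],
            "dirty": self._dirty,
        }

    @classmethod
    def from_dict(cls, d: dict, *, idgen: IdGen | None = None,
                  clock: Clock | None = None) -> "ProcessDefinition":
        obj = cls.__new__(cls)
        obj._idgen = idgen or default_idgen
        obj._clock = clock or default_clock
        obj.id = d["id"]
        obj.name = d["name"]
        obj.description = d["description"]
        obj.steps = [Step.from_dict(s) for s in d["steps"]]
        obj.edges = [FlowEdge.from_dict(e) for e in d["edges"]]
        obj.versions = [ProcessVersion.from_dict(v) for v in d["versions"]]
        obj._dirty = d["dirty"]
        return obj


def steps_topological(steps: Sequence[Step],
                      edges: Sequence[FlowEdge]) -> list[Step]:
    """Steps in topological order; ties broken by declaration order."""
    order = {s.id: i for i, s in enumerate(steps)}
    by_id = {s.id: s for s in steps}
    g = nx.DiGraph()
    g.add_nodes_from(order)
    g.add_edges_from((e.from_step, e.to_step) for e in edges
                     if e.from_step in by_id and e.to_step in by_id)
    return [by_id[n] for n in
            nx.lexicographical_topological_sort(g, key=lambda n: order[n])]


# ---------------------------------------------------------------------------
# ChangeSet: structural diff between two versions of one process
# ---------------------------------------------------------------------------

_STEP_SCALARS = ("name", "instructions", "media_refs")


@dataclass
class ChangeSet:
    """Difference between two versions; applying it to the older version's
    document reproduces the newer one exactly."""

    added_steps: list[dict] = field(default_factory=list)
    removed_steps: list[str] = field(default_factory=list)
    modified_steps: dict[str, dict] = field(default_factory=dict)
    added_slots: list[dict] = field(default_factory=list)      # {step, slot}
    removed_slots: list[dict] = field(default_factory=list)    # {step, slot_id}
    modified_slots: list[dict] = field(default_factory=list)   # {step, slot}
    added_parameters: list[dict] = field(default_factory=list)
    removed_parameters: list[dict] = field(default_factory=list)
    modified_parameters: list[dict] = field(default_factory=list)
    added_edges: list[dict] = field(default_factory=list)
    removed_edges: list[dict] = field(default_factory=list)
    order: dict | None = None

    def is_empty(self) -> bool:
        return not any((
            self.added_steps, self.removed_steps, self.modified_steps,
            self.added_slots, self.removed_slots, self.modified_slots,
            self.added_parameters, self.removed_parameters,
            self.modified_parameters, self.added_edges, self.removed_edges))

    def summary(self) -> str:
        parts = []
        for label, seq in (
                ("steps added", self.added_steps),
                ("steps removed", self.removed_steps),
                ("steps modified", self.modified_steps),
                ("slots added", self.added_slots),
                ("slots removed", self.removed_slots),
                ("parameters added", self.added_parameters),
                ("parameters removed", self.removed_parameters),
                ("edges added", self.added_edges),
                ("edges removed", self.removed_edges)):
            if seq:
                parts.append(f"{label}: {len(seq)}")
        return "; ".join(parts) if parts else "no changes"


def _index(items: Iterable[dict]) -> dict[str, dict]:
    return {d["id"]: d for d in items}


def diff_versions(v_old: ProcessVersion, v_new: ProcessVersion) -> ChangeSet:
    """Structural diff between two versions of the same process."""
    if v_old.process_id != v_new.process_id:
        raise DomainError("versions belong to different processes")
    old, new = v_old.data, v_new.data
    cs = ChangeSet()
    old_steps, new_steps = _index(old["steps"]), _index(new["steps"])

    for sid, sd in new_steps.items():
        if sid not in old_steps:
            cs.added_steps.append(copy.deepcopy(sd))
    for sid in old_steps:
        if sid not in new_steps:
            cs.removed_steps.append(sid)

    for sid, new_sd in new_steps.items():
        old_sd = old_steps.get(sid)
        if old_sd is None:
            continue
        scal_old = {k: old_sd[k] for k in _STEP_SCALARS}
        scal_new = {k: new_sd[k] for k in _STEP_SCALARS}
        if scal_old != scal_new:
            cs.modified_steps[sid] = copy.deepcopy(scal_new)
        for kind, added, removed, modified in (
                ("slots", cs.added_slots, cs.removed_slots, cs.modified_slots),
                ("parameters", cs.added_parameters, cs.removed_parameters,
                 cs.modified_parameters)):
            old_items, new_items = _index(old_sd[kind]), _index(new_sd[kind])
            for oid, od in new_items.items():
                if oid not in old_items:
                    added.append({"step": sid, kind[:-1]: copy.deepcopy(od)})
                elif old_items[oid] != od:
                    modified.append({"step": sid, kind[:-1]: copy.deepcopy(od)})
            for oid in old_items:
                if oid not in new_items:
                    removed.append({"step": sid, f"{kind[:-1]}_id": oid})

    old_edges = {tuple(sorted(e.items())): e for e in old["edges"]}
    new_edges = {tuple(sorted(e.items())): e for e in new["edges"]}
    for k, e in new_edges.items():
        if k not in old_edges:
            cs.added_edges.append(copy.deepcopy(e))
    for k, e in old_edges.items():
        if k not in new_edges:
            cs.removed_edges.append(copy.deepcopy(e))

    if not cs.is_empty():
        cs.order = {
            "steps": [s["id"] for s in new["steps"]],
            "slots": {s["id"]: [x["id"] for x in s["slots"]]
                      for s in new["steps"]},
            "parameters": {s["id"]: [x["id"] for x in s["parameters"]]
                           for s in new["steps"]},
            "edges": [[e["from_step"], e["from_slot"], e["to_step"],
                       e["to_slot"]] for e in new["edges"]],
        }
    return cs


def apply_changeset(data_old: dict, cs: ChangeSet) -> dict:
    """Apply a ChangeSet to a version document, returning the new document."""
    data = copy.deepcopy(data_old)
    if cs.is_empty():
        return data

    steps = [s for s in data["steps"] if s["id"] not in set(cs.removed_steps)]
    by_id = {s["id"]: s for s in steps}
    for sid, scalars in cs.modified_steps.items():
        by_id[sid].update(copy.deepcopy(scalars))

    for kind, added, removed, modified in (
            ("slots", cs.added_slots, cs.removed_slots, cs.modified_slots),
            ("parameters", cs.added_parameters, cs.removed_parameters,
             cs.modified_parameters)):
        single = kind[:-1]
        for rec in removed:
            step = by_id[rec["step"]]
            step[kind] = [x for x in step[kind]
                          if x["id"] != rec[f"{single}_id"]]
        for rec in modified:
            step = by_id[rec["step"]]
            step[kind] = [copy.deepcopy(rec[single])
                          if x["id"] == rec[single]["id"] else x
                          for x in step[kind]]
        for rec in added:
            by_id[rec["step"]][kind].append(copy.deepcopy(rec[single]))

    steps.extend(copy.deepcopy(s) for s in cs.added_steps)
    by_id = {s["id"]: s for s in steps}

    removed_keys = {tuple(sorted(e.items())) for e in cs.removed_edges}
    edges = [e for e in data["edges"]
             if tuple(sorted(e.items())) not in removed_keys]
    edges.extend(copy.deepcopy(e) for e in cs.added_edges)

    if cs.order is not None:
        step_rank = {sid: i for i, sid in enumerate(cs.order["steps"])}
        steps.sort(key=lambda s: step_rank.get(s["id"], len(step_rank)))
        for s in steps:
            for kind in ("slots", "parameters"):
                ranks = {oid: i for i, oid in
                         enumerate(cs.order[kind].get(s["id"], []))}
                s[kind].sort(key=lambda x: ranks.get(x["id"], len(ranks)))
        edge_rank = {tuple(k): i for i, k in enumerate(cs.order["edges"])}
        edges.sort(key=lambda e: edge_rank.get(
            (e["from_step"], e["from_slot"], e["to_step"], e["to_slot"]),
            len(edge_rank)))

    return {"steps": steps, "edges": edges}


# ---------------------------------------------------------------------------
# Master process composition
# ---------------------------------------------------------------------------

class MasterProcess:
    """A set of processes linked by material handoffs, joined as one table."""

    def __init__(self, processes: Sequence[ProcessDefinition],
                 links: Sequence[ProcessLink], *, name: str = "master",
                 idgen: IdGen | None = None):
        self.id = (idgen or default_idgen)()
        self.name = name
        self.processes = list(processes)
        self.links = list(links)

    def process(self, pid: str) -> ProcessDefinition:
        for p in self.processes:
            if p.id == pid or p.name == pid:
                return p
        raise DomainError(f"master has no process {pid!r}")

    def to_dict(self) -> dict:
        return {"id": self.id, "name": self.name,
                "processes": [p.id for p in self.processes],
                "links": [l.to_dict() for l in self.links]}


def make_link(upstream: ProcessDefinition, up_step: str, up_slot: str,
              downstream: ProcessDefinition, down_step: str,
              down_slot: str) -> ProcessLink:
    """Resolve step/slot names into a :class:`ProcessLink`."""
    us, ds = upstream.step(up_step), downstream.step(down_step)
    return ProcessLink(upstream.id, us.id, us.slot(up_slot).id,
                       downstream.id, ds.id, ds.slot(down_slot).id)


def compose_master(processes: Sequence[ProcessDefinition],
                   links: Sequence[ProcessLink], *,
                   name: str = "master") -> MasterProcess:
    """Validate and build a master process from members and material links."""
    by_id = {p.id: p for p in processes}
    for link in links:
        for pid, sid, slot_id, direction in (
                (link.upstream_process, link.upstream_step,
                 link.upstream_slot, "output"),
                (link.downstream_process, link.downstream_step,
                 link.downstream_slot, "input")):
            if pid not in by_id:
                raise DomainError(f"link references unknown process {pid!r}")
            step = by_id[pid].step(sid)
            slot = next((s for s in step.slots if s.id == slot_id), None)
            if slot is None:
                raise DomainError(f"link references unknown slot {slot_id!r}")
            if slot.kind != "material":
                raise ValidationError(
                    f"process links must join material slots, got "
                    f"{slot.kind!r} ({slot.name!r})")
            if slot.direction != direction:
                raise ValidationError(
                    f"slot {slot.name!r} must be an {direction} slot")
    g = nx.DiGraph()
    g.add_nodes_from(by_id)
    g.add_edges_from((l.upstream_process, l.downstream_process) for l in links)
    if not nx.is_directed_acyclic_graph(g):
        raise CycleError("process links form a cycle")
    return MasterProcess(processes, links, name=name)


# -- module-level operation aliases (functional surface) --------------------

def create_process(name: str, description: str = "", **kw) -> ProcessDefinition:
    return ProcessDefinition(name, description, **kw)


def add_step(process: ProcessDefinition, name: str, instructions: str = "",
             media_refs: Sequence[str] = ()) -> Step:
    return process.add_step(name, instructions, media_refs)


def add_slot(process: ProcessDefinition, step: str | Step, name: str,
             kind: str, direction: str) -> Slot:
    return process.add_slot(step, name, kind, direction)


def add_parameter(process: ProcessDefinition, step: str | Step, name: str,
                  unit: str = "", target: float | None = None,
                  lower_spec: float | None = None,
                  upper_spec: float | None = None) -> Parameter:
    return process.add_parameter(step, name, unit, target, lower_spec,
                                 upper_spec)


def connect(process: ProcessDefinition, from_: tuple[str | Step, str],
            to: tuple[str | Step, str]) -> FlowEdge:
    return process.connect(from_, to)


def snapshot_version(process: ProcessDefinition) -> ProcessVersion:
    return process.snapshot_version()
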