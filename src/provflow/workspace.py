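"""Workspace: the unit of persistence.

A workspace holds processes (with their versions), master processes,
experiments, entities and measurements, and serializes to a single UTF-8
JSON document with stable key order, so that save -> load -> save is
byte-identical and workspace files diff cleanly under version control.
"""

from __future__ import annotations

import json

from ._ids import Clock, IdGen, default_clock, default_idgen
from .capture import (EntityRecord, Experiment, Measurement, ParameterValue)
from .errors import DomainError
from .model import MasterProcess, ProcessDefinition, ProcessLink

SCHEMA_VERSION = 1


class Workspace:
    def __init__(self, *, idgen: IdGen | None = None,
                 clock: Clock | None = None):
        self.idgen = idgen or default_idgen
        self.clock = clock or default_clock
        self.processes: dict[str, ProcessDefinition] = {}
        self.masters: dict[str, MasterProcess] = {}
        self.experiments: dict[str, Experiment] = {}

    # -- creation helpers (share the workspace id/clock providers) ---------

    def create_process(self, name: str, description: str = ""
                       ) -> ProcessDefinition:
        p = ProcessDefinition(name, description, idgen=self.idgen,
                              clock=self.clock)
        self.processes[p.id] = p
        return p

    def instantiate_experiment(self, process: ProcessDefinition,
                               name: str) -> Experiment:
        if process.id not in self.processes:
            self.processes[process.id] = process
        e = Experiment(process, name, idgen=self.idgen, clock=self.clock)
        self.experiments[e.id] = e
        return e

    def add_process(self, process: ProcessDefinition) -> ProcessDefinition:
        self.processes[process.id] = process
        return process

    def add_master(self, master: MasterProcess) -> MasterProcess:
        self.masters[master.id] = master
        return master

    def add_experiment(self, experiment: Experiment) -> Experiment:
        self.experiments[experiment.id] = experiment
        return experiment

    # -- lookup ------------------------------------------------------------

    def process(self, ref: str) -> ProcessDefinition:
        for p in self.processes.values():
            if p.id == ref or p.name == ref:
                return p
        raise DomainError(f"no process {ref!r} in workspace")

    def master(self, ref: str) -> MasterProcess:
        for m in self.masters.values():
            if m.id == ref or m.name == ref:
                return m
        raise DomainError(f"no master process {ref!r} in workspace")

    def experiment(self, ref: str) -> Experiment:
        for e in self.experiments.values():
            if e.id == ref or e.name == ref:
                return e
        raise DomainError(f"no experiment {ref!r} in workspace")

    def experiments_of(self, process: ProcessDefinition | str
                       ) -> list[Experiment]:
        pid = process if isinstance(process, str) else process.id
        return [e for e in self.experiments.values()
                if e.process.id == pid]

    def master_experiment_map(self, master: MasterProcess
                              ) -> dict[str, list[Experiment]]:
        """Mapping process id -> experiments, as join_master expects."""
        return {p.id: self.experiments_of(p) for p in master.processes}

    # -- persistence -------------------------------------------------------

    def to_json_text(self) -> str:
        doc = {
            "schema": SCHEMA_VERSION,
            "processes": [p.to_dict() for p in self.processes.values()],
            "masters": [m.to_dict() for m in self.masters.values()],
            "experiments": [e.to_dict() for e in self.experiments.values()],
        }
        return json.dumps(doc, ensure_ascii=False, indent=1) + "\n"

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.to_json_text())

    @classmethod
    def from_json_text(cls, text: str, *, idgen: IdGen | None = None,
                       clock: Clock | None = None) -> "Workspace":
        doc = json.loads(text)
        ws = cls(idgen=idgen, clock=clock)
        for pd in doc["processes"]:
            p = ProcessDefinition.from_dict(pd, idgen=ws.idgen,
                                            clock=ws.clock)
            ws.processes[p.id] = p
        for md in doc["masters"]:
            m = MasterProcess.__new__(MasterProcess)
            m.id = md["id"]
            m.name = md["name"]
            m.processes = [ws.processes[pid] for pid in md["processes"]]
            m.links = [ProcessLink.from_dict(l) for l in md["links"]]
            ws.masters[m.id] = m

        entity_pool: dict[str, EntityRecord] = {}
        parent_ids: dict[str, list[str]] = {}
        for ed in doc["experiments"]:
            exp = Experiment.__new__(Experiment)
            exp._idgen = ws.idgen
            exp._clock = ws.clock
            exp.id = ed["id"]
            exp.name = ed["name"]
            exp.process = ws.processes[ed["process_id"]]
            exp.version_number = ed["version_number"]
            exp.status = ed["status"]
            exp.created = ed["created"]
            exp.amendments = list(ed["amendments"])
            exp.entities = {}
            exp.used = []
            exp.parameter_values = []
            exp.measurements = []
            exp.step_times = dict(ed["step_times"])
            for rec in ed["entities"]:
                ent = EntityRecord(rec["id"], rec["label"], rec["kind"],
                                   rec["experiment_id"], rec["step_id"],
                                   rec["slot_id"])
                ent.uses = [tuple(u) for u in rec["uses"]]
                parent_ids[ent.id] = list(rec["parents"])
                exp.entities[ent.id] = ent
                entity_pool[ent.id] = ent
            for pv in ed["parameter_values"]:
                exp.parameter_values.append(ParameterValue(**pv))
            ws.experiments[exp.id] = exp

        # second pass: wire parents, uses and measurement entity refs
        for cid, pids in parent_ids.items():
            child = entity_pool[cid]
            for pid in pids:
                parent = entity_pool[pid]
                child.parents.append(parent)
                parent.children.append(child)
        for ed in doc["experiments"]:
            exp = ws.experiments[ed["id"]]
            exp.used = [entity_pool[eid] for eid in ed["used"]]
            for md in ed["measurements"]:
                if md["shape"] == "timeseries":
                    value = [(t, v) for t, v in md["value"]]
                elif md["shape"] == "eventseries":
                    value = [dict(rec) for rec in md["value"]]
                else:
                    value = md["value"]
                exp.measurements.append(Measurement(
                    md["id"], md["experiment_id"], md["step_id"],
                    entity_pool[md["entity_id"]], md["variable"],
                    md["unit"], md["shape"], value, md["recorded_at"]))
        return ws

    @classmethod
    def load(cls, path, *, idgen: IdGen | None = None,
             clock: Clock | None = None) -> "Workspace":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_text(fh.read(), idgen=idgen, clock=clock)
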