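"""Join engine: flatten captured experiments into tidy statistical tables.

Three joins are supported:

* **horizontal** (:func:`flatten_experiment`): one experiment becomes a
  table with one row per *terminal* material entity (a childless material
  entity within the table's scope).  Each row carries, grouped by step, the
  entity labels, recorded parameter values, step start/stop times and
  scalar measurements of every entity on the root-to-terminal lineage
  paths; measurements of shared ancestors repeat on every descendant row.
* **vertical** (:func:`concat_experiments`): experiments on the same
  process (any version) are stacked into common columns, with an
  ``experiment_id`` column prepended.  Where versions diverge, cells are
  null for experiments whose frozen version lacks the variable.
* **master** (:func:`join_master`): lineage paths traverse the material
  links of a :class:`~provflow.model.MasterProcess`, so rows span all
  member processes.

Deterministic layout: columns follow master/member order, then topological
step order of each frozen version, then declaration/recording order within
a step; rows follow entity-registration order.  Step labels are plain step
names, prefixed with the process name only when a step name collides
across the members of a master.

Equipment entities are step-level annotations: their labels (and any
measurements recorded on them) appear on every row whose lineage touches
the experiment in which the equipment occurs.  In the uncommon case that
several values land in one cell (e.g. two scalar measurements of the same
variable on one entity) the values are joined with ``|`` in recording
order.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

from .capture import Experiment, EntityRecord, ancestors_of
from .errors import DomainError
from .model import MasterProcess, ProcessDefinition, steps_topological
from .tables import Column, TidyTable

__all__ = ["flatten_experiment", "concat_experiments", "join_master",
           "eventseries_long"]


def _join_cell(values: list) -> object:
    if not values:
        return None
    if len(values) == 1:
        return values[0]
    return "|".join(_cell_str(v) for v in values)


def _cell_str(v) -> str:
    return repr(v) if isinstance(v, float) else str(v)


class _ScopeProcess:
    """One member process with its in-scope experiments."""

    def __init__(self, process: ProcessDefinition,
                 experiments: Sequence[Experiment], label: str):
        self.process = process
        self.experiments = list(experiments)
        self.label = label          # step-label prefix ("" = bare step names)

    def step_label(self, step_name: str) -> str:
        return f"{self.label}.{step_name}" if self.label else step_name


class _TableBuilder:
    def __init__(self, members: Sequence[_ScopeProcess],
                 include_experiment_id: bool):
        self.members = members
        self.include_experiment_id = include_experiment_id
        self.scope_exp_ids = {e.id for m in members for e in m.experiments}
        # per-experiment lookup maps built from the frozen versions
        self.step_name: dict[tuple[str, str], str] = {}    # (exp, step_id)
        self.slot_name: dict[tuple[str, str, str], str] = {}
        self.member_of_exp: dict[str, _ScopeProcess] = {}
        for m in members:
            for exp in m.experiments:
                self.member_of_exp[exp.id] = m
                steps, _ = exp.frozen.materialize()
                for s in steps:
                    self.step_name[(exp.id, s.id)] = s.name
                    for sl in s.slots:
                        self.slot_name[(exp.id, s.id, sl.id)] = sl.name

    # -- scope entities and terminals -------------------------------------

    def scope_entities(self) -> list[EntityRecord]:
        seen: set[str] = set()
        out: list[EntityRecord] = []
        for m in self.members:
            for exp in m.experiments:
                for e in exp.entities.values():
                    if e.id not in seen:
                        seen.add(e.id)
                        out.append(e)
                for e in exp.used:
                    if e.id not in seen:
                        seen.add(e.id)
                        out.append(e)
        return out

    def terminals(self, entities: list[EntityRecord]) -> list[EntityRecord]:
        ids = {e.id for e in entities}
        return [e for e in entities if e.kind == "material"
                and not any(c.id in ids for c in e.children)]

    # -- column construction ----------------------------------------------

    def build_columns(self) -> list[Column]:
        cols: list[Column] = []
        keys: set[tuple] = set()

        def add(col: Column):
            key = (col.step, col.variable, col.role)
            if key not in keys:
                keys.add(key)
                cols.append(col)

        if self.include_experiment_id:
            add(Column("", "experiment_id", "", "entity_id"))

        for m in self.members:
            for exp in m.experiments:
                steps, edges = exp.frozen.materialize()
                occupied = self._occupied_slots(m, exp)
                measured = self._scalar_columns(m, exp)
                for step in steps_topological(steps, edges):
                    label = m.step_label(step.name)
                    if step.id in exp.step_times:
                        rec = exp.step_times[step.id]
                        if "start" in rec:
                            add(Column(label, "start", "", "start_time"))
                        if "stop" in rec:
                            add(Column(label, "stop", "", "stop_time"))
                    for slot in step.slots:
                        if (step.id, slot.id) in occupied:
                            add(Column(label, slot.name, "", "entity_id"))
                    for p in step.parameters:
                        add(Column(label, p.name, p.unit, "parameter"))
                    for variable, unit in measured.get(step.id, []):
                        add(Column(label, variable, unit, "measurement"))
        return cols

    def _occupied_slots(self, m: _ScopeProcess,
                        exp: Experiment) -> set[tuple[str, str]]:
        occ: set[tuple[str, str]] = set()
        for e in exp.entities.values():
            occ.add((e.step_id, e.slot_id))
        for e in list(exp.entities.values()) + exp.used:
            for (xid, sid, slid) in e.uses:
                if xid == exp.id:
                    occ.add((sid, slid))
        return occ

    def _scalar_columns(self, m: _ScopeProcess, exp: Experiment
                        ) -> dict[str, list[tuple[str, str]]]:
        out: dict[str, list[tuple[str, str]]] = {}
        for meas in exp.measurements:
            if meas.shape != "scalar":
                continue
            pairs = out.setdefault(meas.step_id, [])
            if not any(v == meas.variable for v, _ in pairs):
                pairs.append((meas.variable, meas.unit))
        return out

    # -- row assembly ------------------------------------------------------

    def build_rows(self, cols: list[Column],
                   expand_timeseries: bool) -> list[list]:
        entities = self.scope_entities()
        ids_in_scope = {e.id for e in entities}
        col_index = {(c.step, c.variable, c.role): i
                     for i, c in enumerate(cols)}
        rows: list[list] = []
        for terminal in self.terminals(entities):
            ctx = [e for e in entities
                   if e.id == terminal.id
                   or e in ancestors_of(terminal)]
            ctx_ids = {e.id for e in ctx}
            ctx_exps = self._context_experiments(ctx)
            base = self._fill_row(cols, col_index, terminal, ctx, ctx_ids,
                                  ctx_exps, ids_in_scope)
            if expand_timeseries:
                rows.extend(self._expand(cols, col_index, base, ctx_ids,
                                         ctx_exps))
            else:
                rows.append(base)
        return rows

    def _context_experiments(self, ctx: list[EntityRecord]) -> list[str]:
        out: list[str] = []
        for e in ctx:
            if e.experiment_id in self.scope_exp_ids \
                    and e.experiment_id not in out:
                out.append(e.experiment_id)
            for (xid, _, _) in e.uses:
                if xid in self.scope_exp_ids and xid not in out:
                    out.append(xid)
        return out

    def _fill_row(self, cols, col_index, terminal, ctx, ctx_ids, ctx_exps,
                  ids_in_scope) -> list:
        cells: list[list] = [[] for _ in cols]

        def put(step_label, variable, role, value):
            i = col_index.get((step_label, variable, role))
            if i is not None:
                cells[i].append(value)

        if self.include_experiment_id:
            put("", "experiment_id", "entity_id", terminal.experiment_id)

        # entity labels: originations and uses of lineage-context materials
        for e in ctx:
            if e.experiment_id in self.scope_exp_ids:
                m = self.member_of_exp[e.experiment_id]
                sname = self.step_name.get((e.experiment_id, e.step_id))
                slname = self.slot_name.get(
                    (e.experiment_id, e.step_id, e.slot_id))
                if sname and slname:
                    put(m.step_label(sname), slname, "entity_id", e.label)
            for (xid, sid, slid) in e.uses:
                if xid in self.scope_exp_ids:
                    m = self.member_of_exp[xid]
                    sname = self.step_name.get((xid, sid))
                    slname = self.slot_name.get((xid, sid, slid))
                    if sname and slname:
                        put(m.step_label(sname), slname, "entity_id", e.label)

        # equipment annotations from context experiments
        for xid in ctx_exps:
            exp = self._experiment(xid)
            m = self.member_of_exp[xid]
            for e in list(exp.entities.values()) + exp.used:
                if e.kind != "equipment":
                    continue
                if e.experiment_id == xid:
                    sname = self.step_name.get((xid, e.step_id))
                    slname = self.slot_name.get((xid, e.step_id, e.slot_id))
                    if sname and slname:
                        put(m.step_label(sname), slname, "entity_id", e.label)
                for (uxid, sid, slid) in e.uses:
                    if uxid == xid:
                        sname = self.step_name.get((xid, sid))
                        slname = self.slot_name.get((xid, sid, slid))
                        if sname and slname:
                            put(m.step_label(sname), slname, "entity_id",
                                e.label)

        # parameter values and step times from context experiments
        for xid in ctx_exps:
            exp = self._experiment(xid)
            m = self.member_of_exp[xid]
            latest: dict[tuple[str, str], float] = {}
            for pv in exp.parameter_values:
                sname = self.step_name.get((xid, pv.step_id))
                if sname:
                    latest[(m.step_label(sname), pv.name)] = pv.value
            for (label, name), value in latest.items():
                put(label, name, "parameter", value)
            for sid, rec in exp.step_times.items():
                sname = self.step_name.get((xid, sid))
                if not sname:
                    continue
                label = m.step_label(sname)
                if "start" in rec:
                    put(label, "start", "start_time", rec["start"])
                if "stop" in rec:
                    put(label, "stop", "stop_time", rec["stop"])

        # scalar measurements on lineage-context or equipment entities
        for xid in ctx_exps:
            exp = self._experiment(xid)
            m = self.member_of_exp[xid]
            for meas in exp.measurements:
                if meas.shape != "scalar":
                    continue
                ent = meas.entity
                applies = (ent.id in ctx_ids
                           or (ent.kind == "equipment"
                               and ent.id in ids_in_scope))
                if not applies:
                    continue
                sname = self.step_name.get((xid, meas.step_id))
                if sname:
                    put(m.step_label(sname), meas.variable, "measurement",
                        meas.value)

        return [_join_cell(c) for c in cells]

    def _expand(self, cols, col_index, base, ctx_ids, ctx_exps) -> list[list]:
        points: dict[float, dict[int, float]] = {}
        for xid in ctx_exps:
            exp = self._experiment(xid)
            m = self.member_of_exp[xid]
            for meas in exp.measurements:
                if meas.shape != "timeseries" or meas.entity.id not in ctx_ids:
                    continue
                sname = self.step_name.get((xid, meas.step_id))
                if not sname:
                    continue
                i = col_index.get((m.step_label(sname), meas.variable,
                                   "measurement"))
                if i is None:
                    continue
                for t, v in meas.value:
                    points.setdefault(t, {})[i] = v
        t_index = col_index.get(("", "timestamp", "timestamp"))
        if not points:
            return [base]
        out = []
        for t in sorted(points):
            row = list(base)
            if t_index is not None:
                row[t_index] = t
            for i, v in points[t].items():
                row[i] = v
            out.append(row)
        return out

    def timeseries_columns(self) -> list[Column]:
        cols: list[Column] = [Column("", "timestamp", "h", "timestamp")]
        seen: set[tuple] = set()
        for m in self.members:
            for exp in m.experiments:
                for meas in exp.measurements:
                    if meas.shape != "timeseries":
                        continue
                    sname = self.step_name.get((exp.id, meas.step_id))
                    if not sname:
                        continue
                    key = (m.step_label(sname), meas.variable, "measurement")
                    if key not in seen:
                        seen.add(key)
                        cols.append(Column(key[0], meas.variable, meas.unit,
                                           "measurement"))
        return cols

    def _experiment(self, exp_id: str) -> Experiment:
        for m in self.members:
            for exp in m.experiments:
                if exp.id == exp_id:
                    return exp
        raise DomainError(f"experiment {exp_id!r} not in scope")

    def build(self, expand_timeseries: bool = False) -> TidyTable:
        cols = self.build_columns()
        if expand_timeseries:
            cols = cols + self.timeseries_columns()
        rows = self.build_rows(cols, expand_timeseries)
        provenance = [e.id for m in self.members for e in m.experiments]
        return TidyTable(columns=cols, rows=rows, provenance=provenance)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def flatten_experiment(experiment: Experiment, *,
                       expand_timeseries: bool = False) -> TidyTable:
    """Horizontal join: one experiment, one row per terminal material."""
    member = _ScopeProcess(experiment.process, [experiment], "")
    return _TableBuilder([member], include_experiment_id=False
                         ).build(expand_timeseries)


def concat_experiments(experiments: Sequence[Experiment], *,
                       expand_timeseries: bool = False) -> TidyTable:
    """Vertical join: stack experiments on one process into common columns."""
    if not experiments:
        raise DomainError("concat needs at least one experiment")
    pid = experiments[0].process.id
    for exp in experiments:
        if exp.process.id != pid:
            raise DomainError(
                "experiments must all instantiate the same process")
    member = _ScopeProcess(experiments[0].process, experiments, "")
    return _TableBuilder([member], include_experiment_id=True
                         ).build(expand_timeseries)


def join_master(master: MasterProcess,
                experiments: Mapping[str, Sequence[Experiment]], *,
                expand_timeseries: bool = False) -> TidyTable:
    """Cross-process join: lineage paths traverse master-process links.

    *experiments* maps process id (or name) to the experiments run on that
    process.  A link whose upstream output has no entity connected to the
    downstream process raises a warning and leaves the corresponding
    upstream columns null.
    """
    resolved: dict[str, list[Experiment]] = {}
    for key, exps in experiments.items():
        proc = master.process(key)
        resolved[proc.id] = list(exps)
        for exp in exps:
            if exp.process.id != proc.id:
                raise DomainError(
                    f"experiment {exp.name!r} does not instantiate process "
                    f"{proc.name!r}")
    name_counts: dict[str, int] = {}
    for p in master.processes:
        for s in p.steps:
            name_counts[s.name] = name_counts.get(s.name, 0) + 1
    collides = {n for n, c in name_counts.items() if c > 1}
    members = []
    for p in master.processes:
        needs_prefix = any(s.name in collides for s in p.steps) \
            and len(master.processes) > 1
        members.append(_ScopeProcess(p, resolved.get(p.id, []),
                                     p.name if needs_prefix else ""))
    _warn_unmatched_links(master, members)
    return _TableBuilder(members, include_experiment_id=True
                         ).build(expand_timeseries)


def _warn_unmatched_links(master: MasterProcess,
                          members: Sequence[_ScopeProcess]) -> None:
    by_pid = {m.process.id: m for m in members}
    for link in master.links:
        up = by_pid.get(link.upstream_process)
        down = by_pid.get(link.downstream_process)
        if up is None or down is None or not down.experiments:
            continue
        matched = False
        for exp in up.experiments:
            for e in exp.entities.values():
                if (e.step_id, e.slot_id) != (link.upstream_step,
                                              link.upstream_slot):
                    continue
                down_ids = {x.id for dexp in down.experiments
                            for x in dexp.entities.values()}
                if any(c.id in down_ids for c in e.children):
                    matched = True
                if any(xid in {d.id for d in down.experiments}
                       for (xid, _, _) in e.uses):
                    matched = True
        if not matched and any(exp.entities for exp in up.experiments):
            warnings.warn(
                f"master link {link.upstream_process} -> "
                f"{link.downstream_process} has no shared entity; upstream "
                "columns will be null", stacklevel=3)


def eventseries_long(experiment: Experiment) -> TidyTable:
    """Companion long-format table for event-series measurements."""
    field_names: list[str] = []
    for meas in experiment.measurements:
        if meas.shape != "eventseries":
            continue
        for rec in meas.value:
            for k in rec:
                if k not in field_names:
                    field_names.append(k)
    cols = [Column("", "experiment_id", "", "entity_id"),
            Column("", "entity", "", "entity_id"),
            Column("", "step", "", "entity_id"),
            Column("", "variable", "", "measurement"),
            Column("", "event_index", "", "measurement")]
    cols += [Column("", f, "", "measurement") for f in field_names]
    rows = []
    steps, _ = experiment.frozen.materialize()
    step_names = {s.id: s.name for s in steps}
    for meas in experiment.measurements:
        if meas.shape != "eventseries":
            continue
        for i, rec in enumerate(meas.value):
            row = [experiment.id, meas.entity.label,
                   step_names.get(meas.step_id, ""), meas.variable, i]
            row += [rec.get(f) for f in field_names]
            rows.append(row)
    return TidyTable(columns=cols, rows=rows, provenance=[experiment.id])
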