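"""Independent brute-force reference for the join engine.

This is a from-scratch, naive implementation of the documented flattening
semantics: it enumerates all root-to-terminal genealogy paths explicitly
(recursive DFS over parent links), unions the path nodes per terminal, and
assembles each row as a plain dict keyed by (step label, variable, role).
It shares no code with :mod:`provflow.join`; topological step ordering is
done with a hand-rolled Kahn's algorithm instead of networkx.
"""

from __future__ import annotations

import heapq


def kahn_topological(steps, edges):
    """Steps in topological order, declaration order breaking ties."""
    rank = {s.id: i for i, s in enumerate(steps)}
    by_id = {s.id: s for s in steps}
    succ = {s.id: set() for s in steps}
    indeg = {s.id: 0 for s in steps}
    for e in edges:
        if e.to_step not in succ.get(e.from_step, set()):
            if e.from_step in by_id and e.to_step in by_id:
                succ[e.from_step].add(e.to_step)
                indeg[e.to_step] += 1
    heap = [rank[sid] for sid, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    ordered_ids = {i: sid for sid, i in rank.items()}
    out = []
    while heap:
        sid = ordered_ids[heapq.heappop(heap)]
        out.append(by_id[sid])
        for nxt in sorted(succ[sid], key=lambda x: rank[x]):
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                heapq.heappush(heap, rank[nxt])
    assert len(out) == len(steps), "cycle in step graph"
    return out


def all_ancestor_paths(entity):
    """Every path root -> ... -> entity over parent links (full graph)."""
    if not entity.parents:
        return [[entity]]
    paths = []
    for parent in entity.parents:
        for p in all_ancestor_paths(parent):
            paths.append(p + [entity])
    return paths


def _fmt(v):
    return repr(v) if isinstance(v, float) else str(v)


class OracleBuilder:
    """Assemble the expected table for a scope of (process, experiments,
    label prefix) members."""

    def __init__(self, members, include_experiment_id):
        self.members = members
        self.include_eid = include_experiment_id
        self.scope_exp_ids = [e.id for (_, exps, _) in members for e in exps]
        self.exp_by_id = {e.id: e for (_, exps, _) in members for e in exps}
        self.prefix_of_exp = {e.id: label
                              for (_, exps, label) in members for e in exps}
        # naming maps straight off the frozen versions
        self.names = {}
        for (_, exps, label) in members:
            for exp in exps:
                steps, _ = exp.frozen.materialize()
                for s in steps:
                    sl = f"{label}.{s.name}" if label else s.name
                    self.names[(exp.id, s.id)] = sl
                    for slot in s.slots:
                        self.names[(exp.id, s.id, slot.id)] = slot.name

    def step_label(self, exp_id, step_id):
        return self.names.get((exp_id, step_id))

    def scope_entities(self):
        seen, out = set(), []
        for (_, exps, _) in self.members:
            for exp in exps:
                for e in exp.entities.values():
                    if e.id not in seen:
                        seen.add(e.id)
                        out.append(e)
                for e in exp.used:
                    if e.id not in seen:
                        seen.add(e.id)
                        out.append(e)
        return out

    def columns(self):
        cols = []
        seen = set()

        def add(key, unit):
            if key not in seen:
                seen.add(key)
                cols.append((key, unit))

        if self.include_eid:
            add(("", "experiment_id", "entity_id"), "")
        for (_, exps, label) in self.members:
            for exp in exps:
                steps, edges = exp.frozen.materialize()
                occupied = set()
                for e in exp.entities.values():
                    occupied.add((e.step_id, e.slot_id))
                for e in list(exp.entities.values()) + exp.used:
                    for (xid, sid, slid) in e.uses:
                        if xid == exp.id:
                            occupied.add((sid, slid))
                meas_by_step = {}
                for m in exp.measurements:
                    if m.shape == "scalar":
                        lst = meas_by_step.setdefault(m.step_id, [])
                        if not any(v == m.variable for v, _ in lst):
                            lst.append((m.variable, m.unit))
                for step in kahn_topological(steps, edges):
                    sl = f"{label}.{step.name}" if label else step.name
                    times = exp.step_times.get(step.id, {})
                    if "start" in times:
                        add((sl, "start", "start_time"), "")
                    if "stop" in times:
                        add((sl, "stop", "stop_time"), "")
                    for slot in step.slots:
                        if (step.id, slot.id) in occupied:
                            add((sl, slot.name, "entity_id"), "")
                    for p in step.parameters:
                        add((sl, p.name, "parameter"), p.unit)
                    for variable, unit in meas_by_step.get(step.id, []):
                        add((sl, variable, "measurement"), unit)
        return cols

    def rows(self, cols):
        keys = [k for k, _ in cols]
        entities = self.scope_entities()
        scope_ids = {e.id for e in entities}
        out = []
        for terminal in entities:
            if terminal.kind != "material":
                continue
            if any(c.id in scope_ids for c in terminal.children):
                continue
            # brute-force: enumerate every root->terminal path, union nodes
            on_paths = {e.id for path in all_ancestor_paths(terminal)
                        for e in path}
            ctx = [e for e in entities if e.id in on_paths]
            ctx_ids = {e.id for e in ctx}
            ctx_exps = []
            for e in ctx:
                if e.experiment_id in self.exp_by_id \
                        and e.experiment_id not in ctx_exps:
                    ctx_exps.append(e.experiment_id)
                for (xid, _, _) in e.uses:
                    if xid in self.exp_by_id and xid not in ctx_exps:
                        ctx_exps.append(xid)
            cells = {k: [] for k in keys}

            def put(key, value):
                if key in cells:
                    cells[key].append(value)

            if self.include_eid:
                put(("", "experiment_id", "entity_id"),
                    terminal.experiment_id)
            for e in ctx:
                lbl = self.step_label(e.experiment_id, e.step_id)
                if lbl is not None:
                    slot = self.names.get(
                        (e.experiment_id, e.step_id, e.slot_id))
                    put((lbl, slot, "entity_id"), e.label)
                for (xid, sid, slid) in e.uses:
                    lbl = self.step_label(xid, sid)
                    if lbl is not None:
                        put((lbl, self.names.get((xid, sid, slid)),
                             "entity_id"), e.label)
            for xid in ctx_exps:
                exp = self.exp_by_id[xid]
                for e in list(exp.entities.values()) + exp.used:
                    if e.kind != "equipment":
                        continue
                    if e.experiment_id == xid:
                        lbl = self.step_label(xid, e.step_id)
                        if lbl is not None:
                            put((lbl, self.names.get(
                                (xid, e.step_id, e.slot_id)), "entity_id"),
                                e.label)
                    for (uxid, sid, slid) in e.uses:
                        if uxid == xid:
                            lbl = self.step_label(xid, sid)
                            if lbl is not None:
                                put((lbl, self.names.get((xid, sid, slid)),
                                     "entity_id"), e.label)
            for xid in ctx_exps:
                exp = self.exp_by_id[xid]
                latest = {}
                for pv in exp.parameter_values:
                    lbl = self.step_label(xid, pv.step_id)
                    if lbl is not None:
                        latest[(lbl, pv.name)] = pv.value
                for (lbl, name), value in latest.items():
                    put((lbl, name, "parameter"), value)
                for sid, rec in exp.step_times.items():
                    lbl = self.step_label(xid, sid)
                    if lbl is None:
                        continue
                    if "start" in rec:
                        put((lbl, "start", "start_time"), rec["start"])
                    if "stop" in rec:
                        put((lbl, "stop", "stop_time"), rec["stop"])
            for xid in ctx_exps:
                exp = self.exp_by_id[xid]
                for m in exp.measurements:
                    if m.shape != "scalar":
                        continue
                    applies = (m.entity.id in ctx_ids
                               or (m.entity.kind == "equipment"
                                   and m.entity.id in scope_ids))
                    if not applies:
                        continue
                    lbl = self.step_label(xid, m.step_id)
                    if lbl is not None:
                        put((lbl, m.variable, "measurement"), m.value)
            row = []
            for k in keys:
                vals = cells[k]
                if not vals:
                    row.append(None)
                elif len(vals) == 1:
                    row.append(vals[0])
                else:
                    row.append("|".join(_fmt(v) for v in vals))
            out.append(row)
        return out

    def headers(self, cols):
        out = []
        for (step, variable, _), unit in cols:
            base = f"{step}.{variable}" if step else variable
            out.append(f"{base} [{unit}]" if unit else base)
        return out

    def build(self):
        cols = self.columns()
        return self.headers(cols), self.rows(cols)


def oracle_flatten(experiment):
    return OracleBuilder([(experiment.process, [experiment], "")],
                         include_experiment_id=False).build()


def oracle_concat(experiments):
    return OracleBuilder([(experiments[0].process, list(experiments), "")],
                         include_experiment_id=True).build()


def oracle_master(master, mapping):
    counts = {}
    for p in master.processes:
        for s in p.steps:
            counts[s.name] = counts.get(s.name, 0) + 1
    collides = {n for n, c in counts.items() if c > 1}
    members = []
    for p in master.processes:
        needs = (any(s.name in collides for s in p.steps)
                 and len(master.processes) > 1)
        members.append((p, list(mapping.get(p.id, [])),
                        p.name if needs else ""))
    return OracleBuilder(members, include_experiment_id=True).build()
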