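"""Join engine: horizontal/vertical/master flattening semantics."""

import numpy as np
import pytest

import provflow as pf

from _oracle import oracle_concat, oracle_flatten, oracle_master
from conftest import populate_experiment, random_experiment, random_process


def assert_matches_oracle(table, expected):
    headers, rows = expected
    assert table.header_labels() == headers
    assert table.rows == rows


class TestFlatten:
    def test_linear_single_path_single_row(self):
        p = pf.create_process("P")
        for i, name in enumerate(["A", "B", "C"]):
            s = p.add_step(name)
            p.add_slot(s, "in", "material", "input")
            p.add_slot(s, "out", "material", "output")
        p.connect(("A", "out"), ("B", "in"))
        p.connect(("B", "out"), ("C", "in"))
        e = pf.instantiate_experiment(p, "run")
        a = e.register_entity("A", "out", "mat-a")
        b = e.register_entity("B", "out", "mat-b", parents=[a])
        c = e.register_entity("C", "out", "mat-c", parents=[b])
        for step, ent in (("A", a), ("B", b), ("C", c)):
            e.record_measurement(step, ent, "mass", "g", 1.0)
        t = pf.flatten_experiment(e)
        assert t.shape[0] == 1
        assert None not in t.rows[0]
        assert_matches_oracle(t, oracle_flatten(e))

    def test_split_multiplies_rows(self, simple_experiment):
        t = pf.flatten_experiment(simple_experiment)
        assert t.shape[0] == 3
        # culture-level parameters identical across sample rows
        i = t.column_index("Cultivation.temperature [°C]")
        assert {row[i] for row in t.rows} == {40.1}
        dw = t.column_index("Analysis.dry weight [g L^-1]")
        assert sorted(row[dw] for row in t.rows) == [1.0, 1.5, 2.0]
        assert_matches_oracle(t, oracle_flatten(simple_experiment))

    def test_diamond_merge_keeps_both_branches(self, simple_process):
        e = pf.instantiate_experiment(simple_process, "run")
        medium = e.register_entity("Medium preparation", "medium", "medium")
        inoc = e.register_entity("Cultivation", "medium", "inoculum")
        culture = e.register_entity("Cultivation", "sample", "culture",
                                    parents=[medium, inoc])
        e.split_entity("Cultivation", culture, 2, slot="sample")
        t = pf.flatten_experiment(e)
        assert t.shape[0] == 2
        med = t.column_index("Medium preparation.medium")
        ino = t.column_index("Cultivation.medium")
        for row in t.rows:
            assert row[med] == "medium"
            assert row[ino] == "inoculum"
        assert_matches_oracle(t, oracle_flatten(e))

    def test_empty_experiment_full_header_zero_rows(self, simple_process):
        e = pf.instantiate_experiment(simple_process, "run")
        t = pf.flatten_experiment(e)
        assert t.shape[0] == 0

    def test_completeness_every_scalar_measurement_lands(self):
        """Each scalar measurement on lineage or equipment appears in at
        least one cell whenever the table has rows."""
        rng = np.random.default_rng(5)
        for k in range(25):
            e = random_experiment(rng, tag=f"c{k}")
            t = pf.flatten_experiment(e)
            if t.shape[0] == 0:
                continue
            rendered = set()
            for row in t.rows:
                for cell in row:
                    if cell is None:
                        continue
                    rendered.add(cell)
                    if isinstance(cell, str) and "|" in cell:
                        rendered.update(cell.split("|"))
            terminals = [x for x in e.entities.values()
                         if x.kind == "material" and not x.children]
            lineage = set()
            for term in terminals:
                lineage.add(term.id)
                lineage.update(a.id for a in pf.ancestors(term))
            for m in e.measurements:
                if m.shape != "scalar":
                    continue
                if m.entity.id in lineage or m.entity.kind == "equipment":
                    assert (m.value in rendered
                            or repr(m.value) in rendered)

    def test_determinism(self, simple_experiment):
        a = pf.flatten_experiment(simple_experiment)
        b = pf.flatten_experiment(simple_experiment)
        assert a.equals(b) and a.to_csv_text() == b.to_csv_text()

    def test_monotonicity_new_variable_preserves_cells(self,
                                                       simple_experiment):
        before = pf.flatten_experiment(simple_experiment)
        ent = next(iter(simple_experiment.entities.values()))
        simple_experiment.record_measurement("Analysis", ent, "protein",
                                             "g L^-1", 0.2)
        after = pf.flatten_experiment(simple_experiment)
        for col in before.columns:
            i = before.column_index(col.header())
            j = after.column_index(col.header())
            assert [r[i] for r in before.rows] == [r[j] for r in after.rows]


class TestConcat:
    def test_same_version_no_new_nulls(self, simple_process):
        exps = []
        for name in ("run 1", "run 2"):
            e = pf.instantiate_experiment(simple_process, name)
            m = e.register_entity("Medium preparation", "medium", "b")
            e.record_parameter("Medium preparation", "glucose", 7.5)
            e.record_parameter("Cultivation", "temperature", 40.0)
            exps.append(e)
        singles = [pf.flatten_experiment(e) for e in exps]
        t = pf.concat_experiments(exps)
        assert t.shape[0] == sum(s.shape[0] for s in singles)
        assert all(None not in row for row in t.rows)
        assert_matches_oracle(t, oracle_concat(exps))

    def test_version_gap_leaves_nulls(self, simple_process):
        e1 = pf.instantiate_experiment(simple_process, "v-old run")
        e1.register_entity("Medium preparation", "medium", "b1")
        simple_process.add_parameter("Cultivation", "antifoam type", "")
        e2 = pf.instantiate_experiment(simple_process, "v-new run")
        e2.register_entity("Medium preparation", "medium", "b2")
        e2.record_parameter("Cultivation", "antifoam type", 1.0)
        t = pf.concat_experiments([e1, e2])
        i = t.column_index("Cultivation.antifoam type")
        eid = t.column_index("experiment_id")
        for row in t.rows:
            if row[eid] == e1.id:
                assert row[i] is None          # version gap
            else:
                assert row[i] == 1.0
        assert_matches_oracle(t, oracle_concat([e1, e2]))

    def test_single_experiment_identity(self, simple_experiment):
        t = pf.concat_experiments([simple_experiment])
        f = pf.flatten_experiment(simple_experiment)
        assert t.header_labels() == ["experiment_id"] + f.header_labels()
        assert [row[1:] for row in t.rows] == f.rows
        assert {row[0] for row in t.rows} == {simple_experiment.id}

    def test_mixed_processes_rejected(self, simple_process):
        e1 = pf.instantiate_experiment(simple_process, "a")
        other = pf.create_process("Other")
        other.add_step("S")
        e2 = pf.instantiate_experiment(other, "b")
        with pytest.raises(pf.DomainError):
            pf.concat_experiments([e1, e2])


def _chain_master():
    """medium prep -> cultivation -> dry weight, 1 batch / 1 culture /
    3 samples."""
    med = pf.create_process("Medium prep")
    s = med.add_step("Mix")
    med.add_slot(s, "medium", "material", "output")
    cult = pf.create_process("Cultivation")
    s = cult.add_step("Grow")
    cult.add_slot(s, "medium in", "material", "input")
    cult.add_slot(s, "sample", "material", "output")
    dw = pf.create_process("Dry weight")
    s = dw.add_step("Weigh")
    dw.add_slot(s, "sample in", "material", "input")
    links = [pf.make_link(med, "Mix", "medium", cult, "Grow", "medium in"),
             pf.make_link(cult, "Grow", "sample", dw, "Weigh", "sample in")]
    master = pf.compose_master([med, cult, dw], links)
    e_med = pf.instantiate_experiment(med, "medium")
    batch = e_med.register_entity("Mix", "medium", "batch 1")
    e_cult = pf.instantiate_experiment(cult, "culture")
    culture = e_cult.register_entity("Grow", "medium in", "culture 1",
                                     parents=[batch])
    samples = e_cult.split_entity("Grow", culture, 3, slot="sample")
    e_dw = pf.instantiate_experiment(dw, "weights")
    for i, s_ in enumerate(samples):
        e_dw.use_entity("Weigh", "sample in", s_)
        e_dw.record_measurement("Weigh", s_, "dry weight", "g L^-1",
                                1.0 + i)
    mapping = {med.id: [e_med], cult.id: [e_cult], dw.id: [e_dw]}
    return master, mapping, (e_med, e_cult, e_dw)


class TestMasterJoin:
    def test_rows_span_all_processes(self):
        master, mapping, _ = _chain_master()
        t = pf.join_master(master, mapping)
        assert t.shape[0] == 3
        med = t.column_index("Mix.medium")
        dw = t.column_index("Weigh.dry weight [g L^-1]")
        assert all(row[med] == "batch 1" for row in t.rows)
        assert sorted(row[dw] for row in t.rows) == [1.0, 2.0, 3.0]
        assert_matches_oracle(t, oracle_master(master, mapping))

    def test_single_process_master_equals_concat(self, simple_process):
        exps = []
        for name in ("r1", "r2"):
            e = pf.instantiate_experiment(simple_process, name)
            c = e.register_entity("Cultivation", "sample", f"culture {name}")
            e.record_measurement("Cultivation", c, "OD660", "", 1.5)
            exps.append(e)
        master = pf.compose_master([simple_process], [])
        t = pf.join_master(master, {simple_process.id: exps})
        assert t.equals(pf.concat_experiments(exps))

    def test_sample_shared_by_two_analyses_one_row(self):
        master, mapping, (e_med, e_cult, e_dw) = _chain_master()
        hplc = pf.create_process("HPLC")
        s = hplc.add_step("Inject")
        hplc.add_slot(s, "sample in", "material", "input")
        cult = master.processes[1]
        links = master.links + [pf.make_link(cult, "Grow", "sample",
                                             hplc, "Inject", "sample in")]
        master2 = pf.compose_master(master.processes + [hplc], links)
        e_hplc = pf.instantiate_experiment(hplc, "metabolites")
        for s_ in list(e_cult.entities.values()):
            if not s_.children and s_.label != "culture 1":
                e_hplc.use_entity("Inject", "sample in", s_)
                e_hplc.record_measurement("Inject", s_, "glucose", "g L^-1",
                                          0.5)
        mapping2 = dict(mapping)
        mapping2[hplc.id] = [e_hplc]
        t = pf.join_master(master2, mapping2)
        assert t.shape[0] == 3                  # still one row per sample
        dw = t.column_index("Weigh.dry weight [g L^-1]")
        gl = t.column_index("Inject.glucose [g L^-1]")
        for row in t.rows:
            assert row[dw] is not None and row[gl] == 0.5
        assert_matches_oracle(t, oracle_master(master2, mapping2))

    def test_unmatched_link_warns_and_leaves_nulls(self):
        master, mapping, (e_med, e_cult, e_dw) = _chain_master()
        # fresh cultivation experiment without upstream parentage
        cult = master.processes[1]
        e_orphan = pf.instantiate_experiment(cult, "orphan culture")
        c = e_orphan.register_entity("Grow", "medium in", "orphan")
        e_orphan.split_entity("Grow", c, 1, slot="sample")
        mapping2 = {master.processes[0].id: [e_med],
                    cult.id: [e_orphan],
                    master.processes[2].id: []}
        with pytest.warns(UserWarning, match="no shared entity"):
            t = pf.join_master(master, mapping2)
        med = t.column_index("Mix.medium")
        orphan_rows = [r for r in t.rows if r[0] == e_orphan.id]
        assert orphan_rows and all(r[med] is None for r in orphan_rows)

    def test_step_name_collision_gets_process_prefix(self):
        a = pf.create_process("Prep A")
        s = a.add_step("Analysis")
        a.add_slot(s, "out", "material", "output")
        b = pf.create_process("Prep B")
        s = b.add_step("Analysis")
        b.add_slot(s, "in", "material", "input")
        master = pf.compose_master(
            [a, b], [pf.make_link(a, "Analysis", "out",
                                  b, "Analysis", "in")])
        ea = pf.instantiate_experiment(a, "ea")
        ea.register_entity("Analysis", "out", "x")
        t = pf.join_master(master, {a.id: [ea], b.id: []})
        assert "Prep A.Analysis.out" in t.header_labels()


class TestOracleEquivalence:
    def test_random_experiments_flatten(self):
        rng = np.random.default_rng(101)
        for k in range(60):
            e = random_experiment(rng, tag=f"f{k}")
            assert_matches_oracle(pf.flatten_experiment(e),
                                  oracle_flatten(e))

    def test_random_version_diverged_concat(self):
        rng = np.random.default_rng(202)
        for k in range(25):
            p = random_process(rng, tag=f"k{k}", max_steps=5)
            if not any(sl.kind == "material" for s in p.steps
                       for sl in s.slots):
                s = p.steps[0]
                p.add_slot(s, "extra", "material", "output")
                p.snapshot_version()
            exps = []
            for j in range(int(rng.integers(1, 4))):
                if j and rng.random() < 0.6:     # diverge the version
                    step = p.steps[int(rng.integers(len(p.steps)))]
                    p.add_parameter(step, f"new{j}", "u", 1.0)
                e = pf.instantiate_experiment(p, f"e{k}-{j}")
                populate_experiment(rng, e, f"{k}{j}", max_entities=8,
                                    max_measurements=15)
                exps.append(e)
            assert_matches_oracle(pf.concat_experiments(exps),
                                  oracle_concat(exps))

    def test_random_master_joins(self):
        rng = np.random.default_rng(303)
        for k in range(20):
            chain = []
            for i in range(int(rng.integers(2, 4))):
                chain.append(random_process(rng, tag=f"m{k}p{i}",
                                            max_steps=4))
            links = []
            for up, down in zip(chain, chain[1:]):
                ups = [(s, sl) for s in up.steps for sl in s.slots
                       if sl.kind == "material" and sl.direction == "output"]
                downs = [(s, sl) for s in down.steps for sl in s.slots
                         if sl.kind == "material" and sl.direction == "input"]
                if ups and downs:
                    (us, usl) = ups[int(rng.integers(len(ups)))]
                    (ds, dsl) = downs[int(rng.integers(len(downs)))]
                    links.append(pf.make_link(up, us.name, usl.name,
                                              down, ds.name, dsl.name))
            master = pf.compose_master(chain, links)
            mapping = {}
            upstream: list = []
            for i, proc in enumerate(chain):
                exp = pf.instantiate_experiment(proc, f"e{k}-{i}")
                populate_experiment(rng, exp, f"{k}m{i}", max_entities=7,
                                    max_measurements=10, upstream=upstream)
                mapping[proc.id] = [exp]
                upstream = [x for x in exp.entities.values()
                            if x.kind == "material"]
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = pf.join_master(master, mapping)
            assert_matches_oracle(t, oracle_master(master, mapping))


class TestTimeAndEventSeries:
    def test_expand_timeseries_rows(self, simple_process):
        e = pf.instantiate_experiment(simple_process, "run")
        culture = e.register_entity("Cultivation", "sample", "culture")
        e.record_measurement("Cultivation", culture, "CO2 offgas", "%",
                             [(0.0, 0.04), (1.0, 0.09), (2.0, 0.31)])
        t = pf.flatten_experiment(e, expand_timeseries=True)
        assert t.shape[0] == 3
        ts = t.column_index("timestamp [h]")
        co2 = t.column_index("Cultivation.CO2 offgas [%]")
        assert [row[ts] for row in t.rows] == [0.0, 1.0, 2.0]
        assert [row[co2] for row in t.rows] == [0.04, 0.09, 0.31]

    def test_eventseries_long_table(self, simple_process):
        e = pf.instantiate_experiment(simple_process, "run")
        culture = e.register_entity("Cultivation", "sample", "culture")
        e.record_measurement(
            "Cultivation", culture, "chromatogram", "",
            [{"peak": "glucose", "area": 5.2},
             {"peak": "glycerol", "area": 0.3}])
        t = pf.eventseries_long(e)
        assert t.shape[0] == 2
        peak = t.column_index("peak")
        assert [row[peak] for row in t.rows] == ["glucose", "glycerol"]
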