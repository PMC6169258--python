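"""Process definition, versioning, diffing and master composition."""

import numpy as np
import pytest

import provflow as pf
from provflow.model import apply_changeset, diff_versions

from _oracle import kahn_topological


class TestCreateProcess:
    def test_empty_template_at_version_1(self):
        p = pf.create_process("Chemostat cultivation", "continuous culture")
        assert p.current_version == 1
        assert p.steps == []

    def test_empty_name_rejected(self):
        with pytest.raises(pf.ValidationError):
            pf.create_process("")
        with pytest.raises(pf.ValidationError):
            pf.create_process("   ")

    def test_names_are_labels_ids_are_unique(self):
        a = pf.create_process("Cultivation")
        b = pf.create_process("Cultivation")
        assert a.id != b.id


class TestSteps:
    def test_insertion_order_preserved(self):
        p = pf.create_process("P")
        p.add_step("Medium preparation")
        p.add_step("Bioreactor preparation")
        assert [s.name for s in p.steps] == ["Medium preparation",
                                             "Bioreactor preparation"]

    def test_duplicate_step_name_conflicts(self):
        p = pf.create_process("P")
        p.add_step("Medium preparation")
        with pytest.raises(pf.ConflictError):
            p.add_step("Medium preparation")

    def test_media_reference_stored_verbatim(self):
        p = pf.create_process("P")
        s = p.add_step("Connect reservoir", "couple aseptically",
                       media_refs=["connector_video.mp4"])
        assert s.media_refs == ["connector_video.mp4"]


class TestSlotsAndParameters:
    def test_slot_kinds_and_conflicts(self):
        p = pf.create_process("P")
        s = p.add_step("Cultivation")
        p.add_slot(s, "culture broth", "material", "output")
        p.add_slot(s, "pH probe", "equipment", "input")
        with pytest.raises(pf.ConflictError):
            p.add_slot(s, "culture broth", "material", "output")
        with pytest.raises(pf.ValidationError):
            p.add_slot(s, "x", "liquid", "output")
        with pytest.raises(pf.ValidationError):
            p.add_slot(s, "x", "material", "sideways")

    def test_parameter_specs(self):
        p = pf.create_process("P")
        s = p.add_step("Cultivation")
        t = p.add_parameter(s, "temperature", "°C", 40, 39.5, 40.5)
        assert (t.target, t.lower_spec, t.upper_spec) == (40, 39.5, 40.5)
        ph = p.add_parameter(s, "pH", "", 5, 4.9, 5.1)
        assert ph.unit == ""
        with pytest.raises(pf.ValidationError):
            p.add_parameter(s, "stirrer", "rpm", 800, 900, 100)
        with pytest.raises(pf.ValidationError):
            p.add_parameter(s, "feed", "g", 50, 0, 10)   # target above upper


class TestConnect:
    @pytest.fixture
    def two_steps(self):
        p = pf.create_process("P")
        a = p.add_step("A")
        b = p.add_step("B")
        p.add_slot(a, "out", "material", "output")
        p.add_slot(a, "din", "material", "input")
        p.add_slot(a, "dout", "data", "output")
        p.add_slot(b, "in", "material", "input")
        p.add_slot(b, "back", "material", "output")
        return p

    def test_material_edge(self, two_steps):
        e = two_steps.connect(("A", "out"), ("B", "in"))
        assert e in two_steps.edges

    def test_kind_mismatch(self, two_steps):
        with pytest.raises(pf.ValidationError):
            two_steps.connect(("A", "dout"), ("B", "in"))

    def test_direction_enforced(self, two_steps):
        with pytest.raises(pf.ValidationError):
            two_steps.connect(("A", "din"), ("B", "in"))

    def test_cycle_rejected(self, two_steps):
        two_steps.connect(("A", "out"), ("B", "in"))
        with pytest.raises(pf.CycleError):
            two_steps.connect(("B", "back"), ("A", "din"))


class TestVersioning:
    def test_snapshot_increments_only_on_change(self):
        p = pf.create_process("P")
        p.add_step("A")
        v2 = p.snapshot_version()
        assert v2.number == 2
        assert p.snapshot_version().number == 2    # idempotent
        p.add_step("B")
        assert p.snapshot_version().number == 3

    def test_snapshot_immutable_under_later_edits(self):
        p = pf.create_process("P")
        s = p.add_step("A")
        p.add_slot(s, "out", "material", "output")
        v2 = p.snapshot_version()
        frozen = v2.data
        p.add_step("B")
        p.add_parameter("A", "temperature", "°C", 30)
        p.snapshot_version()
        assert v2.data == frozen

    def test_diff_identical_versions_is_empty(self):
        p = pf.create_process("P")
        p.add_step("A")
        v = p.snapshot_version()
        assert diff_versions(v, v).is_empty()

    def test_diff_lists_parameter_addition(self):
        p = pf.create_process("P")
        p.add_step("Cultivation")
        v2 = p.snapshot_version()
        p.add_parameter("Cultivation", "antifoam type", "")
        v3 = p.snapshot_version()
        cs = diff_versions(v2, v3)
        added = [rec["parameter"]["name"] for rec in cs.added_parameters]
        assert added == ["antifoam type"]
        assert not cs.added_steps and not cs.added_slots

    def test_diff_between_processes_rejected(self):
        a, b = pf.create_process("A"), pf.create_process("B")
        with pytest.raises(pf.DomainError):
            diff_versions(a.versions[0], b.versions[0])


def _random_edit(rng, p):
    """One structurally valid random edit on process *p*."""
    choice = rng.integers(0, 4)
    if choice == 0 or not p.steps:
        p.add_step(f"step{len(p.steps)}-{rng.integers(1e6)}")
    elif choice == 1:
        s = p.steps[int(rng.integers(len(p.steps)))]
        direction = "output" if rng.random() < 0.5 else "input"
        name = f"slot{len(s.slots)}"
        if not any(x.name == name for x in s.slots):
            p.add_slot(s, name, "material", direction)
    elif choice == 2:
        s = p.steps[int(rng.integers(len(p.steps)))]
        name = f"par{len(s.parameters)}"
        if not any(x.name == name for x in s.parameters):
            p.add_parameter(s, name, "u", float(rng.integers(10)))
    else:
        pairs = [((si, so), (ti, to))
                 for si, ss in enumerate(p.steps)
                 for so in ss.slots if so.direction == "output"
                 for ti, ts in enumerate(p.steps)
                 for to in ts.slots
                 if to.direction == "input" and si < ti
                 and so.kind == to.kind]
        if pairs:
            (si, so), (ti, to) = pairs[int(rng.integers(len(pairs)))]
            try:
                p.connect((p.steps[si], so.name), (p.steps[ti], to.name))
            except pf.ConflictError:
                pass


class TestDiffApplyRoundTrip:
    def test_apply_diff_reproduces_new_version(self):
        """apply(v_old, diff(v_old, v_new)) == v_new on 100 random edit
        sequences."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            p = pf.create_process(f"P{trial}")
            versions = [p.versions[0]]
            for _ in range(int(rng.integers(1, 4))):
                for _ in range(int(rng.integers(1, 6))):
                    _random_edit(rng, p)
                versions.append(p.snapshot_version())
            i = int(rng.integers(len(versions)))
            j = int(rng.integers(i, len(versions)))
            v_old, v_new = versions[i], versions[j]
            cs = diff_versions(v_old, v_new)
            assert apply_changeset(v_old.data, cs) == v_new.data


class TestAcyclicity:
    def test_topological_order_exists_after_random_connects(self):
        """Any sequence of successful connect calls leaves a DAG
        (exhaustively checked via explicit topological sorting, <= 10
        steps)."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            p = pf.create_process(f"G{trial}")
            n = int(rng.integers(2, 11))
            for i in range(n):
                s = p.add_step(f"s{i}")
                p.add_slot(s, "o", "material", "output")
                p.add_slot(s, "i", "material", "input")
            for _ in range(2 * n):
                a, b = rng.integers(n), rng.integers(n)
                if a == b:
                    continue
                try:
                    p.connect((f"s{a}", "o"), (f"s{b}", "i"))
                except (pf.CycleError, pf.ConflictError):
                    pass
            ordered = kahn_topological(p.steps, p.edges)
            rank = {s.id: k for k, s in enumerate(ordered)}
            assert all(rank[e.from_step] < rank[e.to_step] for e in p.edges)


class TestMasterComposition:
    @pytest.fixture
    def pair(self):
        a = pf.create_process("Medium prep")
        s = a.add_step("Mix")
        a.add_slot(s, "medium", "material", "output")
        a.add_slot(s, "log", "data", "output")
        b = pf.create_process("Cultivation")
        s = b.add_step("Grow")
        b.add_slot(s, "medium", "material", "input")
        return a, b

    def test_material_link(self, pair):
        a, b = pair
        link = pf.make_link(a, "Mix", "medium", b, "Grow", "medium")
        m = pf.compose_master([a, b], [link])
        assert len(m.processes) == 2

    def test_data_slot_link_rejected(self, pair):
        a, b = pair
        s = a.step("Mix")
        bad = pf.ProcessLink(a.id, s.id, s.slot("log").id,
                             b.id, b.step("Grow").id,
                             b.step("Grow").slot("medium").id)
        with pytest.raises(pf.ValidationError):
            pf.compose_master([a, b], [bad])

    def test_cross_process_cycle_rejected(self, pair):
        a, b = pair
        b.add_slot("Grow", "broth", "material", "output")
        a.add_slot("Mix", "recycle", "material", "input")
        links = [pf.make_link(a, "Mix", "medium", b, "Grow", "medium"),
                 pf.make_link(b, "Grow", "broth", a, "Mix", "recycle")]
        with pytest.raises(pf.CycleError):
            pf.compose_master([a, b], links)

    def test_single_process_master(self, pair):
        a, _ = pair
        m = pf.compose_master([a], [])
        assert [p.id for p in m.processes] == [a.id]

    def test_demo_master_has_six_members(self):
        ws = pf.build_demo_workspace(seed=0, replicates=1)
        master = next(iter(ws.masters.values()))
        assert len(master.processes) == 6
        assert len(master.links) == 5
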