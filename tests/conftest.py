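"""Shared fixtures and randomized builders for the test suite.

Random experiments are generated programmatically (no fixture files) with
seeded NumPy generators, so every run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import provflow as pf


@pytest.fixture
def simple_process():
    """Three-step linear process: medium prep -> cultivation -> analysis."""
    p = pf.create_process("Batch cultivation", "aerobic growth on glucose")
    prep = p.add_step("Medium preparation", "dissolve and sterilize")
    p.add_slot(prep, "medium", "material", "output")
    p.add_parameter(prep, "glucose", "g L^-1", 7.5)
    cult = p.add_step("Cultivation", "inoculate and grow")
    p.add_slot(cult, "medium", "material", "input")
    p.add_slot(cult, "sample", "material", "output")
    p.add_parameter(cult, "temperature", "°C", 40, 39.5, 40.5)
    ana = p.add_step("Analysis", "measure dry weight")
    p.add_slot(ana, "sample", "material", "input")
    p.connect(("Medium preparation", "medium"), ("Cultivation", "medium"))
    p.connect(("Cultivation", "sample"), ("Analysis", "sample"))
    p.snapshot_version()
    return p


@pytest.fixture
def simple_experiment(simple_process):
    """Experiment on the simple process: 1 medium batch -> culture -> 3
    samples with dry weights."""
    e = pf.instantiate_experiment(simple_process, "run 1")
    medium = e.register_entity("Medium preparation", "medium", "batch 1")
    e.record_parameter("Medium preparation", "glucose", 7.5)
    culture = e.register_entity("Cultivation", "medium", "culture 1",
                                parents=[medium])
    e.record_parameter("Cultivation", "temperature", 40.1)
    samples = e.split_entity("Cultivation", culture, 3, slot="sample")
    for i, s in enumerate(samples):
        e.use_entity("Analysis", "sample", s)
        e.record_measurement("Analysis", s, "dry weight", "g L^-1",
                             1.0 + 0.5 * i)
    return e


# ---------------------------------------------------------------------------
# randomized experiment builders (used by oracle-equivalence tests)
# ---------------------------------------------------------------------------

def random_process(rng: np.random.Generator, tag: str,
                   max_steps: int = 8) -> pf.ProcessDefinition:
    p = pf.create_process(f"proc-{tag}")
    n_steps = int(rng.integers(1, max_steps + 1))
    steps = []
    for i in range(n_steps):
        s = p.add_step(f"s{tag}{i}")
        steps.append(s)
        for j in range(int(rng.integers(1, 4))):
            kind = "equipment" if rng.random() < 0.15 else "material"
            direction = "output" if rng.random() < 0.5 else "input"
            p.add_slot(s, f"slot{j}{direction[0]}", kind, direction)
        for j in range(int(rng.integers(0, 3))):
            p.add_parameter(s, f"p{j}", "u", float(rng.integers(1, 100)))
    # random forward edges between kind-compatible slots
    for _ in range(int(rng.integers(0, n_steps))):
        i, j = sorted(rng.choice(n_steps, size=2, replace=False)) \
            if n_steps > 1 else (0, 0)
        if i == j:
            continue
        outs = [sl for sl in steps[i].slots if sl.direction == "output"]
        ins = [sl for sl in steps[j].slots if sl.direction == "input"]
        pairs = [(o, k) for o in outs for k in ins if o.kind == k.kind]
        if pairs:
            o, k = pairs[int(rng.integers(len(pairs)))]
            try:
                p.connect((steps[i], o.name), (steps[j], k.name))
            except pf.ConflictError:
                pass
    p.snapshot_version()
    return p


def populate_experiment(rng: np.random.Generator, exp: pf.Experiment,
                        tag: str, max_entities: int = 20,
                        max_measurements: int = 40,
                        upstream: list | None = None) -> None:
    """Register a random genealogy and random recordings on *exp*."""
    steps, _ = exp.frozen.materialize()
    mat_slots = [(s, sl) for s in steps for sl in s.slots
                 if sl.kind == "material"]
    eq_slots = [(s, sl) for s in steps for sl in s.slots
                if sl.kind == "equipment"]
    if not mat_slots:
        return
    n_entities = int(rng.integers(1, max_entities + 1))
    materials: list[pf.EntityRecord] = []
    for i in range(n_entities):
        if eq_slots and rng.random() < 0.1:
            s, sl = eq_slots[int(rng.integers(len(eq_slots)))]
            exp.register_entity(s, sl.name, f"eq-{tag}-{i}")
            continue
        s, sl = mat_slots[int(rng.integers(len(mat_slots)))]
        parents = []
        pool = list(materials)
        if upstream and rng.random() < 0.5:
            pool = pool + upstream
        if pool and rng.random() < 0.7:
            k = min(len(pool), int(rng.integers(1, 3)))
            idx = rng.choice(len(pool), size=k, replace=False)
            parents = [pool[int(x)] for x in idx]
        ent = exp.register_entity(s, sl.name, f"m-{tag}-{i}", parents)
        materials.append(ent)
    # use some upstream entities on input slots
    in_slots = [(s, sl) for (s, sl) in mat_slots if sl.direction == "input"]
    if upstream and in_slots:
        for ent in upstream:
            if rng.random() < 0.4:
                s, sl = in_slots[int(rng.integers(len(in_slots)))]
                exp.use_entity(s, sl.name, ent)
    # record a random subset of parameters
    for s in steps:
        for prm in s.parameters:
            if rng.random() < 0.8:
                exp.record_parameter(s, prm.name, float(rng.integers(0, 50)))
        if rng.random() < 0.2:
            exp.record_step_time(s, start=f"t{int(rng.integers(100))}")
    # scalar (and a few ignored timeseries) measurements
    everything = list(exp.entities.values()) + exp.used
    for i in range(int(rng.integers(0, max_measurements + 1))):
        ent = everything[int(rng.integers(len(everything)))]
        s = steps[int(rng.integers(len(steps)))]
        var = f"m{int(rng.integers(0, 5))}"
        if rng.random() < 0.15:
            ts = [(float(t), float(rng.random()))
                  for t in range(int(rng.integers(2, 5)))]
            exp.record_measurement(s, ent, f"ts{var}", "u", ts)
        else:
            exp.record_measurement(s, ent, var, "u",
                                   float(rng.integers(0, 1000)) / 10.0)


def random_experiment(rng: np.random.Generator,
                      tag: str = "x") -> pf.Experiment:
    p = random_process(rng, tag)
    if not p.steps:
        p.add_step(f"s{tag}0")
        p.add_slot(f"s{tag}0", "slot0o", "material", "output")
    exp = pf.instantiate_experiment(p, f"exp-{tag}")
    populate_experiment(rng, exp, tag)
    return exp
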