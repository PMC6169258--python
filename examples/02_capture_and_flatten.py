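"""Run an experiment on a process and flatten it to a tidy table.

The experiment freezes the process version; materials are registered with
parent links (medium batch -> culture -> samples) and every measurement
attaches to an entity at a step.  Flattening produces one row per terminal
sample carrying the full lineage context.
"""

import provflow as pf

p = pf.create_process("Batch cultivation")
prep = p.add_step("Medium preparation")
p.add_slot(prep, "medium", "material", "output")
p.add_parameter(prep, "glucose", "g L^-1", 7.5)
cult = p.add_step("Cultivation")
p.add_slot(cult, "medium", "material", "input")
p.add_slot(cult, "sample", "material", "output")
p.connect(("Medium preparation", "medium"), ("Cultivation", "medium"))

exp = pf.instantiate_experiment(p, "run 1")
medium = exp.register_entity("Medium preparation", "medium", "batch 1")
exp.record_parameter("Medium preparation", "glucose", 7.5)
culture = exp.register_entity("Cultivation", "medium", "culture 1",
                              parents=[medium])
for hour, sample in zip((2, 4, 6),
                        exp.split_entity("Cultivation", culture, 3,
                                         slot="sample")):
    exp.record_measurement("Cultivation", sample, "dry weight", "g L^-1",
                           0.1 * 2.718 ** (0.45 * hour))

table = pf.flatten_experiment(exp)
print(table.to_csv_text())
# Three rows (one per sample); the medium batch, its glucose parameter and
# the culture label repeat on every descendant row — shared ancestry is
# denormalized into each observation.
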