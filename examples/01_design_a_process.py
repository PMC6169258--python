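"""Define a versioned process, edit it, and diff the versions.

A process is the reusable template of an experimental procedure: steps
with instructions, typed material/equipment/data slots, and parameters
with target values and spec limits.
"""

import provflow as pf

p = pf.create_process("Batch cultivation", "Aerobic growth on glucose")
prep = p.add_step("Medium preparation", "Dissolve components, sterilize")
p.add_slot(prep, "medium", "material", "output")
p.add_parameter(prep, "glucose", "g L^-1", target=7.5)
p.add_parameter(prep, "pH", "", target=5.0, lower_spec=4.9, upper_spec=5.1)

cult = p.add_step("Cultivation", "Inoculate, control temperature, sample")
p.add_slot(cult, "medium", "material", "input")
p.add_slot(cult, "sample", "material", "output")
p.add_parameter(cult, "temperature", "°C", 40, 39.5, 40.5)
p.connect(("Medium preparation", "medium"), ("Cultivation", "medium"))

v2 = p.snapshot_version()
print(f"process {p.name!r}: version {v2.number}, {len(p.steps)} steps")

# a later refinement: document which antifoam was used
p.add_parameter("Cultivation", "antifoam type", "")
v3 = p.snapshot_version()
changes = pf.diff_versions(v2, v3)
print(f"version {v3.number} vs {v2.number}: {changes.summary()}")
# The diff pinpoints exactly what changed between protocol versions, so an
# outcome shift can later be correlated with, say, a new antifoam.
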