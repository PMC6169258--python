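# provflow

Structured experiment capture and quantitative microbial physiology in one
library: versioned process flow diagrams, material-genealogy provenance,
tidy-table joins, and growth-curve analytics, plus a Monod-kinetics
fermentation simulator that exercises the whole stack with known ground
truth.

## Who this is for

Labs running controlled cultivations (shake flasks, batch bioreactors,
chemostats) that want their procedures, sample genealogy and measurements
in one computable structure — and their physiology numbers (μ_max, yields,
uptake rates) computed objectively from that structure instead of from
hand-curated spreadsheets and visually chosen "exponential" points.

## The model

**Processes and experiments.** A *process* is a reusable template: a
directed acyclic graph of steps, each with instructions, typed
material/equipment/data slots, and parameters with target values and
lower/upper spec limits. Processes are versioned; snapshots are immutable
and diffable (`diff_versions` / `apply_changeset` round-trip exactly). An
*experiment* freezes one process version and collects parameter values
(stored and flagged when out of spec, never rejected) and measurements —
scalars, time series, or event series — each attached to a material or
equipment *entity*. Entities form a provenance DAG through parent links
(medium batch → culture → timepoint samples), which may cross experiments
along the material links of a *master process*.

**Joins.** Three flattening operations turn captured data into statistical
tables (variables as columns grouped by step, observations as rows):
`flatten_experiment` (one row per terminal material entity, carrying the
whole lineage context), `concat_experiments` (experiments on any version
of one process stacked into common columns, nulls where a version lacks a
variable), and `join_master` (rows span all linked processes). Tables
export to RFC-4180 CSV or JSON; export → import → export is
byte-identical.

**Physiology.** For a biomass signal X(t) (OD660 or dry weight), the
exponential phase is detected algorithmically and

- μ_max [h⁻¹] is the slope of ln X vs t over that window,
- Y_X/S [g g⁻¹] is the slope of X against consumed glucose,
- q_glucose = −(μ / Y_X/S) · 1000 / 180.156 [mmol (g biomass)⁻¹ h⁻¹],
- a chemostat at dilution rate D = F_out/V_L grows at μ = D once at
  steady state, asserted from biomass-sample drift,
- replicates are summarized as mean ± MAD with a pooled standard error
  (log-transformed for rate-like quantities).

## Worked example

`examples/04_batch_physiology.py` simulates an aerobic glucose batch
culture (7.5 g/L initial glucose) and recovers its parameters:

```
mu_max    = 0.4500 1/h        (true 0.45)
Y_X/S     = 0.5100 g/g         (true 0.51)
q_glucose = -4.90 mmol/(g h)  (negative = consumption)
```

`examples/06_demo_master_process.py` runs the full stack — six linked
processes, two strains × two temperatures × duplicate cultures, 2%
observation noise — and summarizes the joined master table:

```
master join: 40 sample rows x 18 columns from 13 experiments
CBS4732 at 30 °C: mu_max = 0.44±0.00  Y_X/S = 0.51±0.00  (mean±MAD over 2 cultures)
CBS4732 at 40 °C: mu_max = 0.67±0.01  Y_X/S = 0.48±0.00  (mean±MAD over 2 cultures)
CBS11895 at 30 °C: mu_max = 0.35±0.00  Y_X/S = 0.53±0.02  (mean±MAD over 2 cultures)
CBS11895 at 40 °C: mu_max = 0.62±0.00  Y_X/S = 0.49±0.01  (mean±MAD over 2 cultures)
```

Each μ_max is the log-linear slope over the detected exponential phase of
one culture's dry-weight samples; every row of the table is traceable to
one medium batch through the material genealogy. The other examples cover
process design/diffing, capture and flattening, shake-flask curves, and
chemostat operation.

A thin CLI mirrors the library
(`provflow process|experiment|record|flatten|concat|master-join|analyze|simulate|demo`),
with all state in a workspace JSON file.

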