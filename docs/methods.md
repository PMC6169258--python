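# Methods

This note documents the models, algorithms, numerical choices and open
design decisions behind provflow, and states what the synthetic data does
and does not emulate.

## Process model and versioning

A process is a DAG of steps; edges connect output slots to input slots of
the same kind (material↔material, equipment↔equipment, data↔data — the
model never shows cross-kind flow, so compatibility is strict equality).
Acyclicity is enforced at edge insertion (networkx), both inside a process
and across the processes of a master; master-process links join material
slots only.

Versioning is explicit: a snapshot freezes a canonical plain-document copy
of steps and edges. Creating a process snapshots an empty version 1;
snapshotting with no pending edits is a no-op returning the latest version
(this avoids version inflation from empty diffs and gives deterministic,
testable version boundaries — an interactive system would autosave
instead, which is out of scope for a library). Instantiating an experiment
auto-snapshots a dirty process first, so an experiment always references a
well-defined frozen version.

`ChangeSet` records added/removed/modified steps, slots, parameters and
edges between two versions plus the target ordering; `apply_changeset`
reproduces the newer version document exactly (property-tested over random
edit sequences). Parameters attach to steps (not slots); slot-scoped
parameters would be a compatible extension.

Identifiers are UUIDv4 strings; names are human labels, unique only where
stated (step names within a process, slot/parameter names within a step).
Media files are stored as path/URL references and never ingested.
Timestamps are ISO-8601 with explicit offset; elapsed-time variables are
plain numbers in hours.

## Capture semantics

Out-of-spec parameter values are stored with `in_spec=False`, never
rejected — spec limits document intent, they are not gates. Time series
must have strictly increasing timestamps and numeric values; event series
are ordered records of named numeric/text fields (e.g. HPLC peak name +
area). Equipment entities participate as annotations and measurement
targets but never parent material entities; cross-experiment parentage is
how master-process links are realized in the data. An entity can also be
*used* by a downstream experiment's input slot without creating a new
entity — this models the same physical sample flowing into an analysis
step, and is what lets one sample carry measurements from several
analysis experiments on a single row.

## Flattening semantics

Row key: a *terminal* entity — a childless material entity within the
table's scope. Rows therefore multiply on splits (timepoint samples) and
merge on joins (medium + inoculum → culture contributes one row per
downstream sample, carrying both ancestor branches). Where a terminal has
several ancestor paths to the same root, the row holds the union of path
nodes — the alternative (one row per distinct path) is documented here as
the rejected option, since a one-row-per-sample table is the analysis
target.

Column order is deterministic: member process order, topological step
order of each frozen version (declaration order breaking ties), and
within a step: start/stop times, occupied slots, parameters, then scalar
measurement variables in first-recording order. Headers are
`step.variable [unit]` (unit omitted when empty); in a master join, step
labels are prefixed with the process name only when a step name collides
across members, so a single-process master equals the vertical
concatenation of its experiments exactly. Nulls are empty CSV fields /
JSON `null`; no sentinel numbers. In the uncommon case that several
values land in one cell (two scalar measurements of one variable on one
entity), they are joined with `|` in recording order rather than silently
dropped. Time series are excluded from the default scalar table; with
`expand_timeseries` each (terminal, timestamp) pair becomes a row.
Event series export to a companion long-format table. XML export is
omitted; CSV and JSON cover the exchange contract.

CSV round-trip identity relies on Python's shortest-repr float formatting;
text cells that themselves look numeric (e.g. `"001"`) would re-import as
numbers — typed round-trips use JSON.

## Exponential-phase detection

Published growth rates are frequently computed from points chosen by eye.
The detector here is fully objective, in two stages:

1. **Window selection** — the longest contiguous window whose log-linear
   fit has R² ≥ `r2_threshold` (default 0.995) and positive slope, with
   ≥ `min_points` (default 5) points; ties go to higher R², then earlier
   start. Computed exactly (all O(n²) windows via prefix sums).
2. **Boundary trimming** — R² is an aggregate criterion: a long window can
   absorb a handful of lag or stationary points while staying above any
   practical threshold, because the total variance grows with the window
   span. The trimmer therefore refits the window and removes the boundary
   point with the largest standardized residual while it exceeds
   `outlier_z` (default 3.0). Residuals are standardized against a robust
   scale (1.4826 × median absolute residual) so that the outliers being
   hunted cannot inflate the scale and mask themselves; a floor of
   1e-9 × the signal range keeps machine-precision residuals of noiseless
   data from registering as outliers.

On noiseless exponential data this recovers the growth rate to machine
precision; at 2% multiplicative noise the estimate is unbiased to well
under 2% relative. Detection is invariant to uniform scaling of the
signal (an offset in log space) and to time translation.

## Rates, yields, chemostats, statistics

μ_max and its standard error come from ordinary least squares on
(t, ln X) (scipy). Y_X/S is the OLS slope of X against consumed glucose
over the same window; glucose must decrease over the window — strictly
point-to-point for the low-level operation, net-only (`strict=False`) in
the table pipeline where observation noise can locally invert a noisy
HPLC series. Yields outside (0, 1] g/g trigger a warning (not an error):
aerobic growth on glucose cannot exceed unit carbon yield.

q_glucose uses M_glucose = 180.156 g/mol; the sign convention is negative
for consumption, and q(μ=0) = 0.

Chemostat: D = F_out/V_L; steady state is accepted when the relative
spread (max−min)/mean of the biomass samples is below `drift_tolerance`
(default 0.05 — a 10% drift is rejected); then μ = D,
Y = X̄/(S_in − S̄_residual), and q follows from μ and Y. The simulator's
independent estimate `estimate_chemostat_mu` adds the residual ln-biomass
slope over the steady window to D, so the reported μ is measured, not
assumed.

Replicate summaries follow the two-culture reporting convention: mean and
*mean* absolute deviation (about the mean, not median-based) of the
per-culture values, plus a pooled standard error across all culture
samples: within-replicate sample variances pooled with (nᵢ−1) weights —
the classical pooled-variance estimator, documented here as an assumption
since only the pooling itself is conventionally specified — and
SE = √(s²_pooled/N_total). Rate-like quantities are multiplicative-error;
for them pooling happens on log-transformed samples and the SE is mapped
back to the linear scale by the delta method (SE ≈ mean × SE_log). Yields
default to additive.

## Synthetic data

Batch: dX/dt = μ(S)X, dS/dt = −(μ/Y)X with μ(S) = μ_max·S/(Ks+S), fixed
X₀ = 0.1 g/L and S₀ = 7.5 g/L by default; chemostat adds −DX and
D(S_in−S) terms. Integration is fixed-step RK4 (0.01 h; stiffness is not
an issue at these rates, and a step above 0.1/μ_max is rejected). Because
dX and dS are exact multiples of the same stage evaluations, the batch
mass balance X−X₀ = Y(S₀−S) holds to machine precision, and glucose
exhaustion snaps the state onto that balance exactly.

Defaults are the study conditions of the reference scenario: μ_max 0.45
h⁻¹ / Y 0.51 g/g (glucose-grown yeast at 30 °C), initial glucose 7.5 g/L,
chemostat D = 0.10 h⁻¹; the demo workspace uses the four strain ×
temperature operating points (0.45/0.51, 0.36/0.52, 0.68/0.49, 0.63/0.49).
Ks is a simulator-only constant: 0.1 g/L is a realistic default for yeast
on glucose, while Ks = 0 selects the analytic limit in which batch growth
is exactly exponential until exhaustion — the only regime in which
recovery of μ_max is exact, which is why the parameter-recovery checks
run there. Observation noise is multiplicative log-normal on sampled
observations only (no process noise), matching the log-transform
rationale for rate statistics; OD660 = dry weight / 0.5 (an arbitrary
documented conversion — only ratios matter to the analytics); the off-gas
CO₂ channel is a baseline plus a term proportional to the volumetric
growth rate, stored but not used in any rate calculation.

What the generator does **not** emulate: temperature dependence of μ_max
(the strain × temperature values are injected, not derived from a thermal
model), pH and dissolved-oxygen dynamics, byproduct formation, sampling
dead volumes, or instrument drift. Passing tests therefore demonstrate
correctness of the bookkeeping and estimators under the stated noise
model, not robustness to every artifact of real cultivation data.

The demo samples each culture at fixed biomass targets (0.3–2.6 g/L)
rather than fixed clock times — as an experimenter sampling by OD would —
which keeps all five samples of every condition inside the exponential
phase and the glucose decrement per sampling interval well above the 2%
HPLC noise.

## Problem sizes

Randomized join-engine checks run 500+ experiments of ≤ 8 steps, ≤ 20
entities and ≤ 40 measurements against a brute-force path-enumeration
oracle; batch recovery uses 0.25 h sampling over 12 h; the chemostat
wash-in runs 150 h at 1 h sampling; replicate-statistics calibration uses
1000 Monte-Carlo draws. These sizes make the full suite run in seconds
while leaving the estimators' asymptotics clearly visible.

## Known limitations

- No concurrent editing, autosave, or ontology integration; the library
  is single-process, in-memory, with JSON persistence.
- The flattened scalar table denormalizes shared ancestors into every
  descendant row; it is an analysis view, not a storage format.
- The phase-detection criteria are a documented, reproducible convention;
  published values computed with other (unpublished) criteria are not
  expected to be reproduced digit-for-digit from raw data.
- CSV re-import infers cell types; ambiguous numeric-looking text is the
  price of a single-header-line, machine-parseable CSV.
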