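"""Synthetic fermentation data with known ground truth.

Batch growth follows Monod kinetics::

    dX/dt =  mu(S) * X          mu(S) = mu_max * S / (Ks + S)
    dS/dt = -(mu(S) / Y) * X

and a chemostat at dilution rate D adds in/outflow terms::

    dX/dt = (mu(S) - D) * X
    dS/dt = D * (S_in - S) - (mu(S) / Y) * X

Integration is fixed-step RK4 (default 0.01 h); because dX and dS are
exact multiples of the same stage evaluations, the mass balance
``X - X0 = Y * (S0 - S)`` holds to machine precision for batch cultures.
``Ks = 0`` is the analytic limit in which batch growth is exactly
exponential until glucose exhaustion — the regime in which parameter
recovery by the analytics pipeline is exact.

Observation noise is multiplicative log-normal applied to the sampled
observations only (no process noise), matching the rationale for
log-transforming rate-like quantities before variance pooling.  Optical
density is biomass divided by a fixed conversion of 0.5 g dry weight per
OD660 unit (an arbitrary documented constant; only ratios matter to the
analytics).  The off-gas CO2 signal is a baseline plus a term proportional
to the volumetric growth rate — a simple invented instrument model, stored
but not used in rate calculations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analytics import ChemostatSample, GrowthCurve
from .errors import DomainError, IntegrationError, ValidationError

#: dry weight equivalent of one OD660 unit [g/L]
GRAMS_PER_OD = 0.5

#: off-gas CO2 model: baseline [%] and gain [% L h / g]
CO2_BASELINE = 0.04
CO2_GAIN = 0.5


@dataclass
class SimulationParams:
    """Ground-truth parameters for a simulated cultivation.

    Defaults follow the batch reference condition: mu_max = 0.45 1/h and
    Y_X/S = 0.51 g/g (glucose-grown yeast at 30 °C), initial glucose
    7.5 g/L.  ``ks`` is a simulator-only Monod constant (0 = analytic
    exponential limit); ``noise_cv`` is the relative multiplicative
    observation noise.
    """

    mu_max: float = 0.45          # 1/h
    yield_xs: float = 0.51        # g biomass / g glucose
    ks: float = 0.1               # g/L; 0 selects the exponential limit
    s0: float = 7.5               # initial / feed glucose g/L
    x0: float = 0.1               # inoculum biomass g/L
    lag: float = 0.0              # h
    dilution_rate: float | None = None   # 1/h (chemostat only)
    noise_cv: float = 0.0
    seed: int = 0
    dt: float = 0.01              # h, RK4 step
    sample_interval: float = 0.25  # h
    duration: float = 12.0        # h

    def __post_init__(self):
        for name in ("mu_max", "yield_xs", "s0", "x0", "dt",
                     "sample_interval", "duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.ks < 0 or self.lag < 0 or self.noise_cv < 0:
            raise ValidationError("ks, lag and noise_cv must be >= 0")
        if self.dilution_rate is not None and self.dilution_rate <= 0:
            raise ValidationError("dilution_rate must be positive")
        if self.dt * self.mu_max > 0.1:
            raise IntegrationError(
                f"step {self.dt} h too large for mu_max {self.mu_max} 1/h")


@dataclass
class SimulatedDataset:
    params: SimulationParams
    times: np.ndarray             # h
    biomass: np.ndarray           # g/L (observed, possibly noisy)
    od: np.ndarray                # OD660 (observed)
    glucose: np.ndarray           # g/L (observed)
    co2: np.ndarray               # % off-gas (observed)
    biomass_true: np.ndarray      # noiseless states
    glucose_true: np.ndarray
    label: str = "batch"          # "batch" | "flask" | "chemostat" | "washout"
    steady_window: tuple[int, int] | None = None

    def growth_curve(self, kind: str = "dryweight") -> GrowthCurve:
        values = self.biomass if kind == "dryweight" else self.od
        return GrowthCurve(self.times.copy(), values.copy(), kind=kind)

    def steady_samples(self, n: int = 5) -> list[ChemostatSample]:
        if self.steady_window is None:
            raise DomainError("dataset has no steady-state window")
        i0, i1 = self.steady_window
        idx = np.unique(np.linspace(i0, i1, n).round().astype(int))
        return [ChemostatSample(time=float(self.times[i]),
                                biomass=float(self.biomass[i]),
                                glucose=float(self.glucose[i]))
                for i in idx]


def _mu(s: float, p: SimulationParams) -> float:
    s = max(s, 0.0)
    if p.ks == 0.0:
        return p.mu_max if s > 0 else 0.0
    return p.mu_max * s / (p.ks + s)


def _integrate(p: SimulationParams, dilution: float | None) -> tuple:
    """RK4-sample the (X, S) system on the observation grid."""
    n_sub = max(1, round(p.sample_interval / p.dt))
    h = p.sample_interval / n_sub
    times = np.arange(0.0, p.duration + 1e-9, p.sample_interval)
    s_in = p.s0

    def f(t, x, s):
        growing = t >= p.lag
        mu = _mu(s, p) if growing else 0.0
        if dilution is None:
            return mu * x, -(mu / p.yield_xs) * x
        return ((mu - dilution) * x,
                dilution * (s_in - s) - (mu / p.yield_xs) * x)

    xs = np.empty_like(times)
    ss = np.empty_like(times)
    x, s = p.x0, p.s0
    xs[0], ss[0] = x, s
    t = 0.0
    for i in range(1, len(times)):
        for _ in range(n_sub):
            k1 = f(t, x, s)
            k2 = f(t + h / 2, x + h / 2 * k1[0], s + h / 2 * k1[1])
            k3 = f(t + h / 2, x + h / 2 * k2[0], s + h / 2 * k2[1])
            k4 = f(t + h, x + h * k3[0], s + h * k3[1])
            x += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            s += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            t += h
            if dilution is None and s <= 0.0:
                # exhaustion: snap onto the exact mass balance
                s = 0.0
                x = p.x0 + p.yield_xs * p.s0
        xs[i], ss[i] = x, s
    return times, xs, ss


def _observe(p: SimulationParams, times, xs, ss) -> tuple:
    rng = np.random.default_rng(p.seed)
    mu_t = np.array([_mu(s, p) if t >= p.lag else 0.0
                     for t, s in zip(times, ss)])
    co2_true = CO2_BASELINE + CO2_GAIN * mu_t * xs

    def noisy(v):
        if p.noise_cv == 0:
            return v.copy()
        return v * np.exp(rng.normal(0.0, p.noise_cv, size=v.shape))

    biomass = noisy(xs)
    od = noisy(xs) / GRAMS_PER_OD
    glucose = noisy(ss)
    co2 = noisy(co2_true)
    return biomass, od, glucose, co2


def simulate_batch(params: SimulationParams) -> SimulatedDataset:
    """Batch bioreactor culture: lag, exponential growth, glucose
    exhaustion, stationary phase."""
    times, xs, ss = _integrate(params, dilution=None)
    biomass, od, glucose, co2 = _observe(params, times, xs, ss)
    return SimulatedDataset(params, times, biomass, od, glucose, co2,
                            xs, ss, label="batch")


def simulate_shake_flask(params: SimulationParams) -> GrowthCurve:
    """Shake-flask culture observed as an OD660 curve (lag + exponential +
    stationary), deterministic per seed."""
    ds = simulate_batch(params)
    return GrowthCurve(ds.times.copy(), ds.od.copy(), kind="od")


def simulate_chemostat(params: SimulationParams) -> SimulatedDataset:
    """Chemostat wash-in to steady state at D = params.dilution_rate.

    Steady state is declared from the first sample where the relative
    biomass change over the preceding volume change (1/D hours) is below
    0.5%.  If D >= mu_max the culture washes out; the dataset is labeled
    ``"washout"`` and has no steady window.
    """
    if params.dilution_rate is None:
        raise ValidationError("chemostat simulation needs dilution_rate")
    d = params.dilution_rate
    times, xs, ss = _integrate(params, dilution=d)
    biomass, od, glucose, co2 = _observe(params, times, xs, ss)
    label = "chemostat"
    steady = None
    if d >= params.mu_max or xs[-1] < 0.01 * params.x0:
        label = "washout"
    else:
        lookback = max(1, round((1.0 / d) / params.sample_interval))
        for i in range(lookback, len(times)):
            rel = abs(xs[i] - xs[i - lookback]) / xs[i]
            if rel < 0.005:
                steady = (i, len(times) - 1)
                break
    return SimulatedDataset(params, times, biomass, od, glucose, co2,
                            xs, ss, label=label, steady_window=steady)


def estimate_chemostat_mu(dataset: SimulatedDataset) -> float:
    """Estimate mu from the data: D plus the residual ln-biomass slope
    across the steady-state window (zero at a perfect steady state)."""
    from scipy import stats
    if dataset.steady_window is None:
        raise DomainError("no steady state reached (washout or too short)")
    if dataset.params.dilution_rate is None:
        raise DomainError("not a chemostat dataset")
    i0, i1 = dataset.steady_window
    t = dataset.times[i0:i1 + 1]
    x = dataset.biomass[i0:i1 + 1]
    res = stats.linregress(t, np.log(x))
    return float(dataset.params.dilution_rate + res.slope)


# ---------------------------------------------------------------------------
# demo workspace: the full stack exercised end to end
# ---------------------------------------------------------------------------

#: demo design: strain x temperature ground truth (mu_max 1/h, yield g/g)
DEMO_CONDITIONS = {
    ("CBS4732", 30): (0.45, 0.51),
    ("CBS11895", 30): (0.36, 0.52),
    ("CBS4732", 40): (0.68, 0.49),
    ("CBS11895", 40): (0.63, 0.49),
}
#: biomass levels (g/L) at which each demo culture is sampled — sampling by
#: OD target (rather than fixed clock times) keeps all five samples inside
#: the exponential phase for every strain/temperature condition
DEMO_BIOMASS_TARGETS = [0.3, 0.6, 1.2, 1.9, 2.6]


def demo_sample_times(mu: float, x0: float = 0.1,
                      grid: float = 0.25) -> list[float]:
    """Sampling times (snapped to the observation grid) at which a culture
    growing exponentially at *mu* reaches the demo biomass targets."""
    return [round(np.log(x / x0) / mu / grid) * grid
            for x in DEMO_BIOMASS_TARGETS]


def build_demo_workspace(seed: int = 0, *, noise_cv: float = 0.02,
                         replicates: int = 2):
    """Build a fully populated workspace: a six-process master (medium
    preparation -> bioreactor preparation -> batch cultivation -> dry
    weight / HPLC / OD analyses), two strains x two temperatures x
    *replicates* cultures, with simulated measurements registered on a
    material genealogy.  Deterministic per seed."""
    from ._ids import Clock, IdGen
    from .model import compose_master, make_link
    from .workspace import Workspace

    idgen, clock = IdGen(seed), Clock(synthetic=True)
    ws = Workspace(idgen=idgen, clock=clock)

    medium = ws.create_process("Medium preparation",
                               "Synthetic glucose medium")
    st = medium.add_step("Prepare medium", "Dissolve, set pH, sterilize")
    medium.add_slot(st, "medium", "material", "output")
    medium.add_parameter(st, "glucose", "g L^-1", 7.5)
    medium.add_parameter(st, "pH", "", 5.0, 4.9, 5.1)

    prep = ws.create_process("Bioreactor preparation",
                             "Assemble, sterilize and charge the reactor")
    st = prep.add_step("Charge reactor", "Transfer medium into the vessel")
    prep.add_slot(st, "medium in", "material", "input")
    prep.add_slot(st, "charged reactor", "material", "output")

    cult = ws.create_process("Batch cultivation",
                             "Aerobic batch culture on glucose")
    st = cult.add_step("Cultivate", "Inoculate and grow; sample over time")
    cult.add_slot(st, "broth in", "material", "input")
    cult.add_slot(st, "reactor", "equipment", "input")
    cult.add_slot(st, "sample", "material", "output")
    cult.add_parameter(st, "temperature", "°C", 40, 29.5, 40.5)
    cult.add_parameter(st, "stirrer", "rpm", 800, 600, 1000)

    analyses = {}
    for name, step_name, var, unit in (
            ("Dryweight analysis", "Dry weight", "dry weight", "g L^-1"),
            ("HPLC analysis", "HPLC", "glucose", "g L^-1"),
            ("OD measurement", "OD660", "OD660", "")):
        p = ws.create_process(name, f"{step_name} on culture samples")
        s = p.add_step(step_name, f"Measure {var}")
        p.add_slot(s, "sample in", "material", "input")
        analyses[name] = p

    links = [
        make_link(medium, "Prepare medium", "medium",
                  prep, "Charge reactor", "medium in"),
        make_link(prep, "Charge reactor", "charged reactor",
                  cult, "Cultivate", "broth in"),
    ]
    for name, step_name in (("Dryweight analysis", "Dry weight"),
                            ("HPLC analysis", "HPLC"),
                            ("OD measurement", "OD660")):
        links.append(make_link(cult, "Cultivate", "sample",
                               analyses[name], step_name, "sample in"))
    master = compose_master(
        [medium, prep, cult] + list(analyses.values()), links,
        name="Batch cultivation master")
    ws.add_master(master)

    exp_medium = ws.instantiate_experiment(medium, "medium prep")
    batch_entity = exp_medium.register_entity(
        "Prepare medium", "medium", "medium batch 1")
    exp_medium.record_parameter("Prepare medium", "glucose", 7.5)
    exp_medium.record_parameter("Prepare medium", "pH", 5.0)

    exp_prep = ws.instantiate_experiment(prep, "reactor prep")
    exp_prep.use_entity("Charge reactor", "medium in", batch_entity)
    conditions = [(strain, temp, r)
                  for (strain, temp) in DEMO_CONDITIONS
                  for r in range(1, replicates + 1)]
    charged = {}
    for i, (strain, temp, r) in enumerate(conditions, start=1):
        charged[(strain, temp, r)] = exp_prep.register_entity(
            "Charge reactor", "charged reactor",
            f"charged reactor {i}", parents=[batch_entity])

    exp_dw = ws.instantiate_experiment(analyses["Dryweight analysis"],
                                       "dry weight")
    exp_hplc = ws.instantiate_experiment(analyses["HPLC analysis"], "HPLC")
    exp_od = ws.instantiate_experiment(analyses["OD measurement"], "OD660")

    cultivations = {}
    rng = np.random.default_rng(seed)
    for i, (strain, temp, r) in enumerate(conditions, start=1):
        mu, y = DEMO_CONDITIONS[(strain, temp)]
        exp = ws.instantiate_experiment(
            cult, f"{strain} {temp}C replicate {r}")
        exp.record_parameter("Cultivate", "temperature",
                             temp + float(rng.normal(0, 0.1)))
        exp.record_parameter("Cultivate", "stirrer", 800)
        exp.register_entity("Cultivate", "reactor", f"bioreactor {i}")
        culture = exp.register_entity(
            "Cultivate", "broth in", f"culture {strain} {temp}C r{r}",
            parents=[charged[(strain, temp, r)]])
        sim = simulate_batch(SimulationParams(
            mu_max=mu, yield_xs=y, ks=0.1, s0=7.5, x0=0.1,
            noise_cv=noise_cv, seed=int(rng.integers(2 ** 31)),
            sample_interval=0.25, duration=12.0))
        exp.record_measurement("Cultivate", culture, "CO2 offgas", "%",
                               list(zip(sim.times.tolist(),
                                        sim.co2.tolist())))
        sample_times = demo_sample_times(mu)
        samples = exp.split_entity("Cultivate", culture, len(sample_times))
        grid = {round(float(t), 6): i for i, t in enumerate(sim.times)}
        for t, sample in zip(sample_times, samples):
            i = grid[round(t, 6)]
            exp.record_measurement("Cultivate", sample, "sample time", "h", t)
            exp_dw.use_entity("Dry weight", "sample in", sample)
            exp_dw.record_measurement("Dry weight", sample, "dry weight",
                                      "g L^-1", float(sim.biomass[i]))
            exp_hplc.use_entity("HPLC", "sample in", sample)
            exp_hplc.record_measurement("HPLC", sample, "glucose", "g L^-1",
                                        float(sim.glucose[i]))
            exp_od.use_entity("OD660", "sample in", sample)
            exp_od.record_measurement("OD660", sample, "OD660", "",
                                      float(sim.od[i]))
        cultivations[(strain, temp, r)] = exp

    return ws
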