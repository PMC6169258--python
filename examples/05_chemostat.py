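"""Chemostat wash-in to steady state: mu equals the dilution rate.

At dilution rate D = F_out/V_L below mu_max, a nutrient-limited steady
state develops in which the specific growth rate equals D — the
experimenter sets the growth rate with a pump.
"""

import provflow as pf

settings = pf.ChemostatSettings(flow_out=0.05, volume=0.5, feed_glucose=7.5)
print(f"D = F_out/V_L = {settings.flow_out}/{settings.volume} "
      f"= {settings.dilution_rate:.2f} 1/h")

ds = pf.simulate_chemostat(pf.SimulationParams(
    mu_max=0.45, yield_xs=0.51, ks=0.1,
    dilution_rate=settings.dilution_rate, duration=150.0,
    sample_interval=1.0))
i0, _ = ds.steady_window
print(f"steady state from t = {ds.times[i0]:.0f} h; "
      f"estimated mu = {pf.estimate_chemostat_mu(ds):.4f} 1/h")

res = pf.chemostat_physiology(settings, ds.steady_samples(5))
print(f"biomass = {res.biomass:.2f} g/L, residual glucose = "
      f"{res.residual_glucose:.3f} g/L")
print(f"Y_X/S = {res.yield_xs:.3f} g/g, q_glucose = {res.q_glucose:.2f} "
      f"mmol/(g h)")

washout = pf.simulate_chemostat(pf.SimulationParams(
    mu_max=0.45, yield_xs=0.51, dilution_rate=0.50, duration=100.0,
    sample_interval=1.0))
print(f"at D = 0.50 > mu_max: {washout.label} "
      f"(biomass -> {washout.biomass_true[-1]:.2e} g/L)")
# Above mu_max the culture cannot keep up with the outflow and is diluted
# out of the reactor.
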