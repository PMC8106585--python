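"""Monte-Carlo simulation of the five socio-economic indicators.

Builds the packaged synthetic study system (seven land uses over a
20-year horizon) and runs the capital-budgeting model under bootstrap
yield/price uncertainty, printing each land use's mean +/- SD per
indicator — the coefficient table the optimiser consumes.
"""

from agroportfolio import make_default_fixture, simulate_indicators

fixture = make_default_fixture(seed=1)
mc = simulate_indicators(fixture, n_reps=10_000, seed=1)

print("Mean indicator scores (NPV $/ha, payback yr, food Mcal/ha/yr,")
print("labour days/ha/yr, investment $/ha):\n")
print(mc.mean.round(0))
print("\nStandard deviations (Monte-Carlo, 10,000 repetitions):\n")
print(mc.sd.round(1))
print(
    "\nForest is 0 +/- 0 throughout (no active management); teak only pays"
    "\nback at the year-20 harvest; labour and investment SDs sit near 10 %"
    "\nof their means, the imposed coefficient of variation."
)
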