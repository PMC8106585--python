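"""Labour availability as a barrier to agroforestry adoption.

Progressively caps the portfolio's labour demand at high risk aversion
(m=3) and reports when agroforestry drops out of the optimal farm, plus
the workforce a 50-ha farm would need at the threshold.
"""

import numpy as np

from agroportfolio import load_baseline_coefficients, sweep_constraint, workers_required

table = load_baseline_coefficients()
caps = list(np.arange(8.0, 20.01, 0.5))
result = sweep_constraint(table, "labour", caps, m=3.0)

print("labour cap (days/ha/yr) -> agroforestry share (%):")
for cap, pf in zip(result.steps, result.portfolios):
    print(f"  {cap:5.1f} -> {100 * pf.agroforestry_share():5.1f}")

threshold = result.zero_agroforestry_threshold(tol=1e-4)
print(f"\nAgroforestry is absent for caps up to ~{threshold:.0f} days/ha/yr.")
print(
    f"A 50-ha farm needs {workers_required(50, 14, 300)} full-time workers to"
    "\nsupply 14 labour days per hectare per year (300 working days each)."
)
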