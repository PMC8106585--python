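"""Farmers' stated land-use preferences as a sixth objective.

Appends a synthetic preference score (silvopasture and pasture ranked
highest, alley cropping lowest) as an additional more-is-better
indicator and re-optimises at moderate and high risk aversion.
"""

from agroportfolio import (
    OptimizationConfig,
    add_preference_indicator,
    load_baseline_coefficients,
    optimize_portfolio,
)
from agroportfolio.scenarios import DEFAULT_PREFERENCE_SCORES

table = load_baseline_coefficients()
with_pref = add_preference_indicator(
    table, DEFAULT_PREFERENCE_SCORES, {name: 5.0 for name in DEFAULT_PREFERENCE_SCORES}
)

for m in (1.5, 3.0):
    base = optimize_portfolio(table, OptimizationConfig(m=m))
    pref = optimize_portfolio(with_pref, OptimizationConfig(m=m))
    print(f"m={m}: silvopasture share {100 * base.share('silvopasture'):.1f}% "
          f"(five objectives) -> {100 * pref.share('silvopasture'):.1f}% "
          "(with preferences)")

print(
    "\nAt moderate risk aversion the preference score pulls silvopasture"
    "\ninto a portfolio that otherwise excludes it; at high risk aversion"
    "\nsilvopasture is already selected on economic grounds and keeps a"
    "\nsubstantial share once the sixth objective competes for balance."
)
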