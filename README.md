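# agroportfolio

Robust multi-criteria optimisation of farm land-use portfolios, built to
assess when agroforestry (alley cropping, silvopasture) becomes an
attractive option for smallholders at a tropical forest frontier. The
package is aimed at land-use modellers and agricultural economists who
want to couple Monte-Carlo capital budgeting with goal programming under
uncertainty.

## The model

A hypothetical farm allocates area shares `a(l) ≥ 0, Σ a(l) = 1` across
seven land uses: rice, maize, cattle pasture, teak plantation, alley
cropping (teak + maize), silvopasture (Spanish cedar over pasture) and
unmanaged natural forest. Each land use `l` carries a predicted score
`ŷ(i,l)` and standard deviation `SD(i,l)` for five socio-economic
indicators `i`: net present value ($/ha, 20-year horizon, 5 % discount
rate), discounted payback period (years), food-energy production
(Mcal/ha/yr), labour demand (days/ha/yr) and investment cost ($/ha).
The coefficients come from a per-hectare cash-flow model whose yield and
price inputs are perturbed by bootstrap resampling from historical
series (10,000 Monte-Carlo repetitions; labour and investment drawn with
a 10 % coefficient of variation).

The optimiser is a Chebyshev (min-max) goal programme. With uncertainty
multiple `m`, every indicator's coefficients can fall to the
unfavourable value `ŷ ∓ m·SD`, and each subset of land uses doing so
simultaneously defines a scenario `u`. The LP

    min β   s.t.   w(i)·D(i,u) ≤ β   for all indicators i, scenarios u,

minimises the worst weighted normalised shortfall `D` between the
portfolio's achieved level `Σ_l a(l)·c(i,l,u)` and the scenario's best
attainable level, expressed in percent of the scenario's best-to-worst
span. `m = 0` is a risk-neutral farmer, `m = 1.5` moderately and
`m = 3.0` strongly risk-averse. Optional caps bound the portfolio's
labour demand and investment cost; portfolio similarity is measured by
Bray–Curtis dissimilarity. A scenario engine re-runs the whole chain
while changing one assumption at a time (objective weights, labour and
investment caps, crop yields, agroforestry subsidies, timber prices, a
stated-preference indicator).

See `docs/methods.md` for conventions, calibration and limitations.

## Worked example

The packaged baseline coefficient table (means ± SDs for all seven land
uses) ships with the package; optimising it at the three risk levels:

```python
from agroportfolio import (OptimizationConfig, load_baseline_coefficients,
                           optimize_portfolio)

table = load_baseline_coefficients()
for m in (0.0, 1.5, 3.0):
    p = optimize_portfolio(table, OptimizationConfig(m=m))
    print(m, {n: round(100 * s) for n, s in p.shares.items() if s > 0.005},
          round(p.worst_distance, 1))
```

prints (see `examples/02_optimize_baseline.py`):

```
m=0.0: maize 58%, alley_cropping 3%, forest 39%   worst distance 41.3 %
m=1.5: rice 19%, maize 36%, pasture 30%, forest 14%   worst distance 52.9 %
m=3.0: rice 27%, maize 29%, teak_plantation 8%, alley_cropping 3%,
       silvopasture 22%, forest 12%   worst distance 63.8 %
```

A risk-neutral farmer plants the high-yield but volatile maize stand and
keeps forest to hold down labour and investment; rising risk aversion
diversifies the farm across crops, pasture and timber systems while the
guaranteed worst shortfall (β) necessarily grows. The other scripts in
`examples/` demonstrate the Monte-Carlo simulation, labour-constraint
sweeps (agroforestry drops out below ≈14 labour days/ha/yr), subsidy and
timber-price sweeps, and the preference indicator.

A thin CLI wraps the same calls:

```sh
agroportfolio optimize --coeffs packaged --m 3.0 --out portfolio.tsv
agroportfolio simulate --seed 1 --reps 10000 --out coefficients.csv
agroportfolio sweep --scenario cedar_price --grid 0:100:10 --m 3.0 --out curve.tsv
agroportfolio run config.yaml
```

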