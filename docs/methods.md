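# Methods

`agroportfolio` models farm-level land-use choice at a tropical forest
frontier in three coupled stages: a discrete land-use cash-flow model
with a Monte-Carlo uncertainty layer, a robust min-max goal programme
over area shares, and a scenario engine that perturbs one assumption at
a time. This note records the model, its conventions and the design
choices made where the design was genuinely open.

## Land-use model

Seven mutually exclusive land uses are parameterised per hectare over a
20-year horizon, years indexed 0..20 with year 0 the establishment year:
rice, maize, cattle pasture (an annual buy–fatten–sell *ceba* cycle at
2 cows/ha), teak plantation, alley cropping (teak rows with maize in the
alleys), silvopasture (Spanish cedar over pasture) and unmanaged natural
forest. Forest is protective: all schedules identically zero.

Five indicators score each land use:

* **NPV** ($/ha): `Σ_t NCF_t (1+r)^(-t)` at discount rate `r = 0.05`.
* **Discounted payback** (years): the first year with positive
  cumulative discounted cash flow. Conventions: an identically zero
  series pays back at year 0; a series that never turns positive is
  assigned the horizon T = 20. These conventions make the protective
  forest score 0 and let a plantation that only recovers its costs at
  final harvest score exactly 20.
* **Food energy** (Mcal/ha/yr): mean annual crop and meat yields times
  dietary-energy factors (rice 3.5, maize 3.65, beef 2.44 Mcal/kg —
  configurable constants); timber is excluded.
* **Labour demand** (days/ha/yr): mean of the per-year labour schedule.
* **Investment cost** ($/ha): the year-0 cost, itemised into components
  (seedlings, tree guards, fencing, cattle purchase, labour at the
  $17.33/day wage, …).

**Stand dynamics.** Tree stems follow the published management regimes:
teak plantation 1110 stems/ha thinned 60 % in year 4 and 50 % in year 10
(222 final stems), alley cropping 555 stems/ha thinned 50 % in years 5
and 10 (≈139), silvopasture 200 cedar stems/ha unthinned. Mortality
(0.5 %/yr) compounds multiplicatively and is excluded from reported stem
numbers. Tree growth itself is not modelled; merchantable volumes at
thinning and harvest years are fixture inputs, and canopy development
enters as a configurable per-year canopy-fraction schedule rather than a
fitted regression.

**Shading.** Clearing a 1-m circle around each seedling removes
`density·π/10⁴` of the hectare; for alley cropping this is the printed
17 % maize-area loss. For silvopasture the package uses the printed 5 %
pasture-area loss (initial stocking 1.9 cows/ha) rather than the
geometric 6.3 % — the two disagree in the source material and the
printed value is authoritative for downstream numbers. Alley maize
follows a calendar: full yield in years 0–2, half yield in the
post-thinning windows (years 6 and 11), zero otherwise. Pasture under
canopy yields 50 %, so the stocking rate in year t is
`S_t = S₀ (A_sun + 0.5 A_canopy)/A₀`; with the default linear canopy
schedule (0 → 36 % by year 20) the year-20 rate is 1.558 ≈ 1.55 cows/ha.

**Monte-Carlo layer.** Per repetition, each commodity's per-year yield
and price multipliers are resampled i.i.d. from the mean-normalised,
log-linearly detrended relative deviations of a 20-point historical
series (shared across land uses, so a price shock hits every user of the
commodity alike). Labour and investment multipliers are normal with
mean 1 and CV 0.10, truncated at zero, drawn independently per land use.
Yield and price draws are independent of each other (no cross
correlation — a known simplification). Defaults: 10,000 repetitions;
everything derives from a single seed, so results repeat bitwise. The
labour multiplier enters the labour indicator only; labour costs inside
the cost schedules are not re-decomposed, so NPV variability comes from
markets and the year-0 investment draw.

## Robust min-max optimisation

Decision variables are area shares `a(l) ≥ 0, Σa = 1`. For indicator i
with direction d(i), the unfavourable coefficient of land use l is
`ŷ ∓ m·SD` (minus when more is better). An uncertainty scenario is, per
indicator, a subset of land uses that simultaneously sit at their
unfavourable value; all 2⁷ = 128 subsets are enumerated per indicator
(5 × 128 = 640 constraints). The LP minimises β subject to, for every
indicator i and scenario u,

    w(i) · 100 · (T_iu − Σ_l a(l)·c(i,l,u)) / (T_iu − W_iu) ≤ β,

where `c(i,l,u)` are the scenario coefficients and `T_iu` / `W_iu` are
the best and worst entries *of that scenario's own coefficient vector*.
Optional side constraints cap the portfolio's expected labour demand or
investment cost. Solved with `scipy.optimize.linprog` (HiGHS); a
degenerate indicator (all coefficients equal in a scenario) contributes
no constraint, and reported distances are clipped to [0, 100].

**Why per-scenario normalisation.** The published formulation of the
normalisation was not available in full, so the anchoring of `T` and `W`
was an open choice. Anchoring both globally (best predicted vs worst
m-adjusted value) makes the constraint set equivalent to the all-worst
scenario alone and produced portfolios far from the published baselines
at m > 0. Re-anchoring within each scenario — each scenario is judged
against what is attainable in that scenario — reproduces the published
baseline compositions at all three uncertainty levels to within a few
percentage points, and is adopted as this package's convention. The
enumeration is not redundant under this convention, because the
normalising span differs between scenarios.

Weights multiply distances (`w(i)·D ≤ β`); "twice as important" means
`w = 2` with the others at 1, and uniformly rescaling all weights leaves
the optimal shares unchanged. Ties among optimal vertices are resolved
by the solver; tests compare shares with a ±3-percentage-point band
rather than exactly. Portfolio similarity is measured with Bray–Curtis
dissimilarity, `Σ|p − q|/2 ∈ [0, 1]`.

## Scenario engine

* **Prioritising objectives** re-weights one indicator (default factor
  2) with the coefficient table unchanged.
* **Constraint sweeps** solve one capped LP per grid value; caps below
  the minimum attainable level are flagged infeasible rather than
  aborting the sweep. The sweep also reports the largest cap at which
  agroforestry (alley cropping + silvopasture) is absent.
* **Parameter sweeps** perturb exactly one fixture parameter per step
  (crop yields, agroforestry year-0 investment, teak or cedar price;
  default ±100 % in 10 % steps), re-simulate with a seed derived from
  (base seed, step index), and re-optimise. The "agroforestry subsidy"
  sweep scales the *entire* year-0 investment of the two agroforestry
  systems, matching how the sweep axis is defined; the free-seedlings-
  and-guards case corresponds to the itemised tree-establishment
  components, which the default fixture sets at 20 % (alley) and 13 %
  (silvopasture) of establishment costs.
* **Preference indicator** appends a sixth, more-is-better score per
  land use. The shipped scores are synthetic (the survey-derived ones
  are not public) and rank silvopasture and pasture highest and alley
  cropping lowest.
* `workers_required` converts a per-hectare labour rate into full-time
  workers assuming 300 working days per worker-year (50 ha × 14
  days/ha/yr → 2.3 workers, reproducing the published conversion).

## The synthetic fixture

The cost tables and historical series behind the original case study
are not public, so the packaged fixture *emulates* them. Printed
structural facts are used verbatim (densities, thinnings, area losses,
wage, discount rate, stocking); absolute cost/yield/price levels are
synthetic, calibrated once so that the deterministic indicator scores
reproduce the published orderings (maize highest food energy, rice
cheapest to establish, teak most expensive and slowest to pay back,
silvopasture more labour-intensive than pasture). Historical series are
lognormal around a linear trend with commodity-specific CVs (crops
0.10–0.22, cattle ≤ 0.05, teak price 0.30, cedar price 0.12), 20 annual
points each. Exact reproduction of the published coefficient table from
the fixture is therefore *not* a contract — the published table itself
ships as packaged data and is the optimiser's baseline input. Passing
tests on the fixture show the machinery behaves correctly and responds
in the published directions; they do not validate the absolute economics
of any real farm.

## Numerical choices and problem sizes

* Payback uses a 1e-9 positivity tolerance; shares are clipped at 0 and
  renormalised after the solve (HiGGS returns values within 1e-9).
* The scenario-enumeration guard refuses more than 20 land uses
  (2²⁰ constraints per indicator).
* Test-suite problem sizes: Monte-Carlo checks run at 10,000
  repetitions (the study's depth); one convergence check runs at
  100,000. Sweep-based tests use 2,000 repetitions per step, enough to
  hold share curves to ~1 percentage point, with a 2-point slack in
  monotonicity assertions to absorb Monte-Carlo noise at LP vertices.
  The LP-vs-grid oracle enumerates all 35 three-land-use subtables at
  1 % simplex resolution.

## Known limitations

Static model (no soil depletion, no staggered planting, fixed harvest
timing); no price–yield covariance; spatially implicit shares with
homogeneous site quality assumed; tree growth and canopy development
are schedules, not biophysical simulations; the published m=1.5 maize
share (31 %) is reproduced at 36 % — outside the ±3-point band used for
the other shares — which we attribute to rounding of the published
coefficient table, since the published composition is not an alternative
optimum of the reconstructed LP.
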