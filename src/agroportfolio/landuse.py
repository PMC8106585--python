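"""Discrete land-use cash-flow model and its Monte-Carlo wrapper.

Each land use is parameterised over a fixed planning horizon (default 20
years, indexed 0..T with year 0 the establishment year) and evaluated
against five socio-economic indicators:

* ``npv``        -- net present value of all net cash flows, $/ha
* ``payback``    -- discounted payback period, years
* ``food``       -- mean annual dietary-energy production, Mcal/ha/yr
* ``labour``     -- mean annual labour demand, days/ha/yr
* ``investment`` -- sum of all costs incurred in year 0, $/ha

Stand dynamics (thinnings, mortality), shading of crops and pasture by
the tree canopy, and the reduced stocking rate of cattle under trees are
all handled here.  The Monte-Carlo layer perturbs yields and prices by
bootstrap-resampling historical relative deviations and draws labour and
investment costs with a fixed coefficient of variation, producing the
mean and standard deviation of every indicator for every land use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .fixtures import StudyFixture

__all__ = [
    "INDICATORS",
    "TIMBER_COMMODITIES",
    "LIVESTOCK_COMMODITIES",
    "TreeSystem",
    "ShadingRule",
    "LandUseSpec",
    "IndicatorVector",
    "MonteCarloResult",
    "stem_count",
    "stocking_rate",
    "cultivable_area_fraction",
    "yield_factor",
    "net_cash_flow",
    "net_cash_flow_series",
    "npv",
    "discounted_payback",
    "food_energy",
    "expected_indicators",
    "simulate_indicators",
]

#: Indicator order used everywhere (rows of the coefficient table).
INDICATORS = ("npv", "payback", "food", "labour", "investment")

#: Commodities that are timber products (never count towards food energy).
TIMBER_COMMODITIES = frozenset({"teak_timber", "cedar_timber"})

#: Commodities produced by grazing livestock (stocking-rate shading rule).
LIVESTOCK_COMMODITIES = frozenset({"beef"})


@dataclass(frozen=True)
class TreeSystem:
    """Stand dynamics of a timber component: density, thinnings, canopy.

    ``thinnings`` is a list of ``(year, fraction_removed)`` pairs with
    strictly increasing years inside ``(0, harvest_year)``.
    ``canopy_fraction_schedule`` gives, for every year 0..T, the fraction
    of the plot that lies under the tree canopy.
    """

    initial_density: float
    thinnings: tuple[tuple[int, float], ...] = ()
    mortality: float = 0.005
    canopy_fraction_schedule: tuple[float, ...] = ()
    harvest_year: int = 20

    def __post_init__(self) -> None:
        if self.initial_density < 0:
            raise ValueError("initial_density must be non-negative")
        years = [y for y, _ in self.thinnings]
        if years != sorted(set(years)):
            raise ValueError("thinning years must be strictly increasing")
        for y, frac in self.thinnings:
            if not 0 < y < self.harvest_year:
                raise ValueError(
                    f"thinning year {y} outside (0, {self.harvest_year})"
                )
            if not 0 <= frac <= 1:
                raise ValueError(f"thinning fraction {frac} outside [0, 1]")
        for c in self.canopy_fraction_schedule:
            if not 0 <= c <= 1:
                raise ValueError("canopy fractions must lie in [0, 1]")

    def canopy_fraction(self, year: int) -> float:
        if not self.canopy_fraction_schedule:
            return 0.0
        return self.canopy_fraction_schedule[year]


@dataclass(frozen=True)
class ShadingRule:
    """How the tree component curtails crop or pasture production.

    ``crop_area_fraction`` is the share of the hectare still cultivable
    after clearing a circle around every seedling.  ``crop_years`` maps a
    year to the relative crop yield in that year (years absent from the
    map carry zero yield, i.e. canopy closure prevents cultivation); when
    ``None`` the crop is unrestricted in time.  Pasture under canopy
    retains ``pasture_canopy_yield_factor`` of its productivity.
    """

    crop_area_fraction: float = 1.0
    crop_years: Mapping[int, float] | None = None
    pasture_canopy_yield_factor: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.crop_area_fraction <= 1:
            raise ValueError("crop_area_fraction must lie in [0, 1]")
        if self.crop_years is not None:
            for y, f in self.crop_years.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"yield factor {f} for year {y} outside [0, 1]")
        if not 0 <= self.pasture_canopy_yield_factor <= 1:
            raise ValueError("pasture_canopy_yield_factor must lie in [0, 1]")


@dataclass(frozen=True)
class LandUseSpec:
    """Full economic/biophysical parameterisation of one land use.

    All per-year schedules run over years ``0..T`` (length ``T + 1``).
    ``yield_schedule`` holds *potential* physical yields per commodity;
    shading and stocking adjustments are applied on evaluation via the
    ``shading`` rule and ``tree_system``.  ``investment_components``
    itemises the year-0 costs and must sum to ``cost_schedule[0]``.
    """

    name: str
    landcover_class: str  # productive | compromise | protective
    cost_schedule: tuple[float, ...]
    labour_schedule: tuple[float, ...]
    yield_schedule: Mapping[str, tuple[float, ...]]
    price_refs: tuple[str, ...]
    investment_components: Mapping[str, float] = field(default_factory=dict)
    tree_system: TreeSystem | None = None
    shading: ShadingRule | None = None

    def __post_init__(self) -> None:
        if self.landcover_class not in ("productive", "compromise", "protective"):
            raise ValueError(f"unknown landcover class {self.landcover_class!r}")
        n = len(self.cost_schedule)
        if len(self.labour_schedule) != n:
            raise ValueError("labour_schedule length differs from cost_schedule")
        for c, ys in self.yield_schedule.items():
            if len(ys) != n:
                raise ValueError(f"yield schedule for {c!r} has wrong length")
        if self.landcover_class == "protective":
            if any(self.cost_schedule) or any(self.labour_schedule) or any(
                any(ys) for ys in self.yield_schedule.values()
            ):
                raise ValueError("protective land uses must have all-zero schedules")
        if self.investment_components:
            total = sum(self.investment_components.values())
            if not math.isclose(total, self.cost_schedule[0], rel_tol=1e-9, abs_tol=1e-6):
                raise ValueError(
                    f"investment components of {self.name!r} sum to {total}, "
                    f"but year-0 cost is {self.cost_schedule[0]}"
                )

    @property
    def horizon(self) -> int:
        return len(self.cost_schedule) - 1

    @property
    def commodities(self) -> tuple[str, ...]:
        return tuple(self.yield_schedule)


@dataclass(frozen=True)
class IndicatorVector:
    """One land use's score on each of the five indicators."""

    npv: float
    payback: float
    food: float
    labour: float
    investment: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.npv, self.payback, self.food, self.labour, self.investment],
            index=list(INDICATORS),
        )


@dataclass(frozen=True)
class MonteCarloResult:
    """Mean and standard deviation of every indicator per land use."""

    mean: pd.DataFrame  # land uses x indicators
    sd: pd.DataFrame
    n_reps: int

    def __post_init__(self) -> None:
        if (self.sd.to_numpy() < 0).any():
            raise ValueError("standard deviations must be non-negative")

    def to_indicator_table(self):
        from .optimizer import IndicatorTable

        return IndicatorTable.from_frames(self.mean, self.sd)


# ---------------------------------------------------------------------------
# Stand dynamics and shading geometry


def stem_count(system: TreeSystem, year: int, include_mortality: bool = False) -> float:
    """Stems per hectare after the thinnings scheduled up to ``year``.

    Mortality (default 0.5 %/yr) is compounded on top when requested.
    The result is a real number; rounding happens only on report.
    """
    if not 0 <= year <= system.harvest_year:
        raise ValueError(f"year {year} outside [0, {system.harvest_year}]")
    stems = system.initial_density
    for thin_year, frac in system.thinnings:
        if thin_year <= year:
            stems *= 1.0 - frac
    if include_mortality:
        stems *= (1.0 - system.mortality) ** year
    return stems


def stocking_rate(s0: float, a0: float, a_sun: float, a_canopy: float) -> float:
    """Cattle stocking rate on partially shaded pasture.

    The initial rate ``s0`` on pasture area ``a0`` is scaled by the
    effective grazing area: full weight for sunlit pasture, half weight
    under the canopy.
    """
    if a0 <= 0:
        raise ValueError("initial pasture area must be positive")
    if a_sun < 0 or a_canopy < 0:
        raise ValueError("areas must be non-negative")
    if a_sun + a_canopy > a0 * (1 + 1e-9):
        raise ValueError("sunlit plus canopy area exceeds the pasture area")
    return s0 * (a_sun + 0.5 * a_canopy) / a0


def cultivable_area_fraction(density: float, clear_radius: float = 1.0) -> float:
    """Fraction of a hectare left for crops after clearing a circle of
    ``clear_radius`` metres around each of ``density`` seedlings."""
    if density < 0 or clear_radius < 0:
        raise ValueError("density and radius must be non-negative")
    return max(0.0, 1.0 - density * math.pi * clear_radius**2 / 10_000.0)


# ---------------------------------------------------------------------------
# Cash flows and indicators


def yield_factor(spec: LandUseSpec, commodity: str, year: int) -> float:
    """Multiplier turning a potential yield into the realised one.

    Combines the cultivable-area loss, the crop-calendar factor (alley
    cropping) and the canopy-dependent stocking reduction (grazing).
    Timber is never shaded.
    """
    if spec.shading is None or commodity in TIMBER_COMMODITIES:
        return 1.0
    sh = spec.shading
    if commodity in LIVESTOCK_COMMODITIES:
        canopy = spec.tree_system.canopy_fraction(year) if spec.tree_system else 0.0
        return sh.crop_area_fraction * (
            1.0 - (1.0 - sh.pasture_canopy_yield_factor) * canopy
        )
    calendar = 1.0 if sh.crop_years is None else sh.crop_years.get(year, 0.0)
    return sh.crop_area_fraction * calendar


def _unit_multipliers(spec: LandUseSpec) -> dict[str, float]:
    return {c: 1.0 for c in spec.commodities}


def net_cash_flow(
    spec: LandUseSpec,
    year: int,
    prices: Mapping[str, float],
    yield_multipliers: Mapping[str, float] | None = None,
    price_multipliers: Mapping[str, float] | None = None,
    investment_multiplier: float = 1.0,
) -> float:
    """Net cash flow (revenue minus cost) of one land use in one year, $/ha.

    ``yield_multipliers`` / ``price_multipliers`` carry one factor per
    commodity for this year (unit factors when omitted); a commodity the
    spec references but the mappings omit raises ``KeyError``.
    """
    ym = _unit_multipliers(spec) if yield_multipliers is None else yield_multipliers
    pm = _unit_multipliers(spec) if price_multipliers is None else price_multipliers
    revenue = 0.0
    for c in spec.commodities:
        if c not in ym or c not in pm:
            raise KeyError(f"no multiplier supplied for commodity {c!r}")
        if c not in prices:
            raise KeyError(f"no price supplied for commodity {c!r}")
        revenue += (
            spec.yield_schedule[c][year]
            * yield_factor(spec, c, year)
            * ym[c]
            * prices[c]
            * pm[c]
        )
    cost = spec.cost_schedule[year]
    if year == 0:
        cost *= investment_multiplier
    return revenue - cost


def net_cash_flow_series(
    spec: LandUseSpec,
    prices: Mapping[str, float],
    yield_multipliers: Mapping[str, Sequence[float]] | None = None,
    price_multipliers: Mapping[str, Sequence[float]] | None = None,
    investment_multiplier: float = 1.0,
) -> np.ndarray:
    """Net cash flow for every year 0..T (per-year multiplier sequences)."""
    T = spec.horizon
    out = np.empty(T + 1)
    for t in range(T + 1):
        ym = None if yield_multipliers is None else {
            c: yield_multipliers[c][t] for c in spec.commodities
        }
        pm = None if price_multipliers is None else {
            c: price_multipliers[c][t] for c in spec.commodities
        }
        out[t] = net_cash_flow(spec, t, prices, ym, pm, investment_multiplier)
    return out


def npv(ncf: Sequence[float], rate: float) -> float:
    """Net present value of a cash-flow series over years 0..T."""
    if rate <= -1:
        raise ValueError("discount rate must exceed -1")
    ncf = np.asarray(ncf, dtype=float)
    t = np.arange(ncf.size)
    return float(np.sum(ncf * (1.0 + rate) ** (-t)))


def discounted_payback(ncf: Sequence[float], rate: float) -> int:
    """First year with a positive cumulative discounted cash flow.

    An identically zero series pays back immediately (0); a series whose
    cumulative discounted flow never turns positive is assigned the full
    horizon T.
    """
    if rate <= -1:
        raise ValueError("discount rate must exceed -1")
    ncf = np.asarray(ncf, dtype=float)
    if not ncf.any():
        return 0
    t = np.arange(ncf.size)
    cumulative = np.cumsum(ncf * (1.0 + rate) ** (-t))
    positive = cumulative > 1e-9
    if not positive.any():
        return ncf.size - 1
    return int(positive.argmax())


def food_energy(
    spec: LandUseSpec,
    energy_factors: Mapping[str, float],
    yield_multipliers: Mapping[str, Sequence[float]] | None = None,
) -> float:
    """Mean annual dietary energy over the horizon, Mcal/ha/yr.

    Timber commodities are excluded; every other commodity must have an
    energy conversion factor (Mcal per yield unit).
    """
    T = spec.horizon
    total = 0.0
    for c in spec.commodities:
        if c in TIMBER_COMMODITIES:
            continue
        if c not in energy_factors:
            raise KeyError(f"no energy factor for food commodity {c!r}")
        ys = np.asarray(spec.yield_schedule[c], dtype=float)
        fac = np.array([yield_factor(spec, c, t) for t in range(T + 1)])
        mult = (
            np.ones(T + 1)
            if yield_multipliers is None
            else np.asarray(yield_multipliers[c], dtype=float)
        )
        total += float(np.sum(ys * fac * mult)) * energy_factors[c]
    return total / (T + 1)


def expected_indicators(fixture: "StudyFixture") -> pd.DataFrame:
    """Deterministic indicator scores at expected yields, prices and costs
    (all multipliers one): land uses x indicators."""
    rows = {}
    for spec in fixture.land_uses:
        ncf = net_cash_flow_series(spec, fixture.prices)
        rows[spec.name] = IndicatorVector(
            npv=npv(ncf, fixture.discount_rate),
            payback=discounted_payback(ncf, fixture.discount_rate),
            food=food_energy(spec, fixture.energy_factors),
            labour=float(np.mean(spec.labour_schedule)),
            investment=spec.cost_schedule[0],
        ).as_series()
    return pd.DataFrame(rows).T.loc[[s.name for s in fixture.land_uses]]


# ---------------------------------------------------------------------------
# Monte-Carlo layer


def _bootstrap_multipliers(
    fixture: "StudyFixture", n_reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-year multiplicative deviations, resampled i.i.d. per year from
    each historical series' detrended relative deviations."""
    T = fixture.horizon
    out = {}
    for key, hist in fixture.histories.items():
        dev = hist.relative_deviations()
        out[key] = rng.choice(dev, size=(n_reps, T + 1))
    return out


def _commodity_multiplier(
    mult: Mapping[str, np.ndarray], commodity: str, kind: str, n_reps: int, T: int
) -> np.ndarray:
    key = f"{commodity}_{kind}"
    if key in mult:
        return mult[key]
    return np.ones((n_reps, T + 1))


def simulate_indicators(
    fixture: "StudyFixture",
    n_reps: int = 10_000,
    seed: int | None = None,
    cost_cv: float = 0.10,
) -> MonteCarloResult:
    """Monte-Carlo distribution of the five indicators for every land use.

    Per repetition, yield and price multipliers are bootstrap-resampled
    from the fixture's historical relative deviations; labour demand and
    investment costs are drawn from a normal distribution (mean 1, CV
    ``cost_cv``) truncated at zero.  A fixed seed reproduces the result
    bit for bit.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng(fixture.seed if seed is None else seed)
    T = fixture.horizon
    disc = (1.0 + fixture.discount_rate) ** (-np.arange(T + 1))
    mult = _bootstrap_multipliers(fixture, n_reps, rng)

    names = [s.name for s in fixture.land_uses]
    mean = pd.DataFrame(index=names, columns=list(INDICATORS), dtype=float)
    sd = pd.DataFrame(index=names, columns=list(INDICATORS), dtype=float)

    for spec in fixture.land_uses:
        lab_mult = np.clip(rng.normal(1.0, cost_cv, n_reps), 0.0, None)
        inv_mult = np.clip(rng.normal(1.0, cost_cv, n_reps), 0.0, None)

        revenue = np.zeros((n_reps, T + 1))
        food = np.zeros(n_reps)
        for c in spec.commodities:
            ym = _commodity_multiplier(mult, c, "yield", n_reps, T)
            pm = _commodity_multiplier(mult, c, "price", n_reps, T)
            ys = np.asarray(spec.yield_schedule[c], dtype=float)
            fac = np.array([yield_factor(spec, c, t) for t in range(T + 1)])
            eff = ys * fac
            revenue += eff[None, :] * ym * fixture.prices[c] * pm
            if c not in TIMBER_COMMODITIES:
                if c not in fixture.energy_factors:
                    raise KeyError(f"no energy factor for food commodity {c!r}")
                food += (eff[None, :] * ym).sum(axis=1) * fixture.energy_factors[c]
        food /= T + 1

        costs = np.tile(np.asarray(spec.cost_schedule, dtype=float), (n_reps, 1))
        costs[:, 0] *= inv_mult
        ncf = revenue - costs

        npv_draws = ncf @ disc
        cumulative = np.cumsum(ncf * disc[None, :], axis=1)
        positive = cumulative > 1e-9
        payback = np.where(positive.any(axis=1), positive.argmax(axis=1), T)
        payback = np.where(np.abs(ncf).max(axis=1) == 0, 0, payback).astype(float)

        labour = float(np.mean(spec.labour_schedule)) * lab_mult
        investment = spec.cost_schedule[0] * inv_mult

        draws = {
            "npv": npv_draws,
            "payback": payback,
            "food": food,
            "labour": labour,
            "investment": investment,
        }
        for ind, values in draws.items():
            mean.loc[spec.name, ind] = float(np.mean(values))
            sd.loc[spec.name, ind] = float(np.std(values, ddof=0))

    return MonteCarloResult(mean=mean, sd=sd, n_reps=n_reps)
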