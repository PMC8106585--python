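"""Synthetic parameter fixtures for the land-use model.

The study region (a forest-frontier farming zone in eastern Panama) is
described by seven land uses — rice, maize, pasture, teak plantation,
alley cropping (teak + maize), silvopasture (Spanish cedar over cattle
pasture) and unmanaged natural forest — each with per-year cost, labour
and yield schedules over a 20-year horizon, plus historical yield/price
series used for bootstrap resampling and dietary-energy conversion
factors.

The cost tables and historical series underlying the original case study
are not public, so this module *emulates* them: absolute levels are
synthetic, chosen so that the resulting indicator scores reproduce the
published orderings (e.g. maize dominates food energy, teak pays back
only at final harvest, silvopasture demands more labour than plain
pasture).  Printed structural quantities — tree densities and thinning
regimes, the 17 % cultivable-area loss in alley cropping, the 5 % pasture
loss and 2 cows/ha base stocking in silvopasture, the $17.33 daily wage,
the 5 % discount rate — are used verbatim.

Everything is a pure function of the seed: identical seeds produce
bit-identical fixtures.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .landuse import LandUseSpec, ShadingRule, TreeSystem

__all__ = [
    "DEFAULT_LAND_USE_NAMES",
    "DEFAULT_SEED",
    "WAGE",
    "HistoricalSeries",
    "StudyFixture",
    "make_history",
    "make_default_fixture",
    "perturb_fixture",
]

#: Fixed land-use ordering used for every table and portfolio.
DEFAULT_LAND_USE_NAMES = (
    "rice",
    "maize",
    "pasture",
    "teak_plantation",
    "alley_cropping",
    "silvopasture",
    "forest",
)

DEFAULT_SEED = 1

#: Daily wage for agricultural workers, $/day.
WAGE = 17.33

_CROP_COMMODITIES = ("rice", "maize")
_AGROFORESTRY = ("alley_cropping", "silvopasture")


@dataclass(frozen=True)
class HistoricalSeries:
    """An annual series of observed yields or prices for one commodity."""

    name: str
    values: tuple[float, ...]
    kind: str  # "yield" | "price"

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("a historical series needs at least two observations")
        if any(v <= 0 for v in self.values):
            raise ValueError("historical values must be positive")
        if self.kind not in ("yield", "price"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    def relative_deviations(self) -> np.ndarray:
        """Multiplicative deviations around the series' log-linear trend,
        normalised to mean one.  These are the factors resampled by the
        Monte-Carlo layer."""
        v = np.asarray(self.values, dtype=float)
        t = np.arange(v.size, dtype=float)
        slope, intercept = np.polyfit(t, np.log(v), 1)
        dev = v / np.exp(intercept + slope * t)
        return dev / dev.mean()


@dataclass(frozen=True)
class StudyFixture:
    """Complete parameterisation of the seven-land-use study system."""

    land_uses: tuple[LandUseSpec, ...]
    prices: Mapping[str, float]
    histories: Mapping[str, HistoricalSeries]
    energy_factors: Mapping[str, float]
    wage: float = WAGE
    horizon: int = 20
    discount_rate: float = 0.05
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be at least one year")
        if self.discount_rate <= -1:
            raise ValueError("discount rate must exceed -1")
        for spec in self.land_uses:
            if spec.horizon != self.horizon:
                raise ValueError(
                    f"land use {spec.name!r} has horizon {spec.horizon}, "
                    f"fixture expects {self.horizon}"
                )

    @property
    def land_use_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.land_uses)

    def land_use(self, name: str) -> LandUseSpec:
        for spec in self.land_uses:
            if spec.name == name:
                return spec
        raise KeyError(f"no land use named {name!r}")

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        def spec_dict(s: LandUseSpec) -> dict:
            d = {
                "name": s.name,
                "landcover_class": s.landcover_class,
                "cost_schedule": list(s.cost_schedule),
                "labour_schedule": list(s.labour_schedule),
                "yield_schedule": {c: list(v) for c, v in s.yield_schedule.items()},
                "price_refs": list(s.price_refs),
                "investment_components": dict(s.investment_components),
            }
            if s.tree_system is not None:
                d["tree_system"] = {
                    "initial_density": s.tree_system.initial_density,
                    "thinnings": [list(t) for t in s.tree_system.thinnings],
                    "mortality": s.tree_system.mortality,
                    "canopy_fraction_schedule": list(
                        s.tree_system.canopy_fraction_schedule
                    ),
                    "harvest_year": s.tree_system.harvest_year,
                }
            if s.shading is not None:
                d["shading"] = {
                    "crop_area_fraction": s.shading.crop_area_fraction,
                    "crop_years": (
                        None
                        if s.shading.crop_years is None
                        else {int(k): v for k, v in s.shading.crop_years.items()}
                    ),
                    "pasture_canopy_yield_factor": s.shading.pasture_canopy_yield_factor,
                }
            return d

        return {
            "wage": self.wage,
            "horizon": self.horizon,
            "discount_rate": self.discount_rate,
            "seed": self.seed,
            "prices": dict(self.prices),
            "energy_factors": dict(self.energy_factors),
            "histories": {
                k: {"name": h.name, "kind": h.kind, "values": list(h.values)}
                for k, h in self.histories.items()
            },
            "land_uses": [spec_dict(s) for s in self.land_uses],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyFixture":
        specs = []
        for sd in d["land_uses"]:
            tree = None
            if "tree_system" in sd:
                ts = sd["tree_system"]
                tree = TreeSystem(
                    initial_density=ts["initial_density"],
                    thinnings=tuple((int(y), f) for y, f in ts["thinnings"]),
                    mortality=ts["mortality"],
                    canopy_fraction_schedule=tuple(ts["canopy_fraction_schedule"]),
                    harvest_year=ts["harvest_year"],
                )
            shading = None
            if "shading" in sd:
                sh = sd["shading"]
                shading = ShadingRule(
                    crop_area_fraction=sh["crop_area_fraction"],
                    crop_years=(
                        None
                        if sh["crop_years"] is None
                        else {int(k): v for k, v in sh["crop_years"].items()}
                    ),
                    pasture_canopy_yield_factor=sh["pasture_canopy_yield_factor"],
                )
            specs.append(
                LandUseSpec(
                    name=sd["name"],
                    landcover_class=sd["landcover_class"],
                    cost_schedule=tuple(sd["cost_schedule"]),
                    labour_schedule=tuple(sd["labour_schedule"]),
                    yield_schedule={
                        c: tuple(v) for c, v in sd["yield_schedule"].items()
                    },
                    price_refs=tuple(sd["price_refs"]),
                    investment_components=dict(sd["investment_components"]),
                    tree_system=tree,
                    shading=shading,
                )
            )
        return cls(
            land_uses=tuple(specs),
            prices=dict(d["prices"]),
            histories={
                k: HistoricalSeries(h["name"], tuple(h["values"]), h["kind"])
                for k, h in d["histories"].items()
            },
            energy_factors=dict(d["energy_factors"]),
            wage=d["wage"],
            horizon=d["horizon"],
            discount_rate=d["discount_rate"],
            seed=d["seed"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "StudyFixture":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# History generation


def make_history(
    name: str,
    n_years: int = 20,
    cv: float = 0.15,
    trend: float = 0.0,
    seed: int = DEFAULT_SEED,
    kind: str = "price",
    level: float = 1.0,
) -> HistoricalSeries:
    """A lognormal-around-trend annual series with the requested
    coefficient of variation.

    The series emulates two decades of national yield or price records:
    ``level * (1 + trend)^t`` modulated by i.i.d. lognormal noise whose
    CV equals ``cv`` (in expectation; sampling error applies)."""
    if n_years < 2:
        raise ValueError("n_years must be at least 2")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    trend_values = level * (1.0 + trend) ** t
    sigma = np.sqrt(np.log1p(cv**2))
    noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, n_years))
    return HistoricalSeries(
        name=name, values=tuple(float(v) for v in trend_values * noise), kind=kind
    )


# ---------------------------------------------------------------------------
# The default study fixture


def _flat(value: float, horizon: int, year0: float | None = None) -> tuple[float, ...]:
    sched = [value] * (horizon + 1)
    if year0 is not None:
        sched[0] = year0
    return tuple(sched)


def _sparse(horizon: int, entries: Mapping[int, float]) -> tuple[float, ...]:
    sched = [0.0] * (horizon + 1)
    for year, v in entries.items():
        sched[year] = v
    return tuple(sched)


def make_default_fixture(seed: int = DEFAULT_SEED) -> StudyFixture:
    """The packaged seven-land-use study system.

    Tree densities and thinning regimes follow the published management
    tables (teak plantation 1110 stems/ha thinned 60 % in year 4 and 50 %
    in year 10; alley cropping 555 stems/ha thinned 50 % in years 5 and
    10; silvopasture 200 stems/ha unthinned).  Cost and yield levels are
    synthetic calibrations (see module docstring).
    """
    T = 20
    w = WAGE

    prices = {
        "rice": 0.88,  # $/kg paddy
        "maize": 0.60,  # $/kg grain
        "beef": 2.00,  # $/kg liveweight gain
        "teak_timber": 130.0,  # $/m3 standing
        "cedar_timber": 180.0,  # $/m3 standing
    }
    energy_factors = {"rice": 3.5, "maize": 3.65, "beef": 2.44}  # Mcal per kg

    # Inter-annual variability of national records: crops fluctuate much
    # more than cattle; teak prices are the most volatile input.
    history_cfg = {
        "rice_yield": (0.10, "yield"),
        "rice_price": (0.15, "price"),
        "maize_yield": (0.18, "yield"),
        "maize_price": (0.22, "price"),
        "beef_yield": (0.04, "yield"),
        "beef_price": (0.05, "price"),
        "teak_timber_price": (0.30, "price"),
        "cedar_timber_price": (0.12, "price"),
    }
    base = np.random.SeedSequence(seed).spawn(len(history_cfg))
    histories = {
        key: make_history(
            key, n_years=20, cv=cv, trend=0.0,
            seed=int(sub.generate_state(1)[0] % 2**31), kind=kind,
        )
        for (key, (cv, kind)), sub in zip(history_cfg.items(), base)
    }

    rice = LandUseSpec(
        name="rice",
        landcover_class="productive",
        cost_schedule=_flat(949.0, T),
        labour_schedule=_flat(32.0, T),
        yield_schedule={"rice": _flat(1800.0, T)},
        price_refs=("rice",),
        investment_components={
            "land_clearing": 150.0,
            "seed": 100.0,
            "fertiliser_pesticide": 949.0 - 150.0 - 100.0 - 32 * w,
            "labour": 32 * w,
        },
    )

    # Maize is planted late in the establishment year, so year-0 yields
    # are reduced and the system only pays back from year 1.
    maize = LandUseSpec(
        name="maize",
        landcover_class="productive",
        cost_schedule=_flat(980.0, T, year0=1073.0),
        labour_schedule=_flat(22.0, T),
        yield_schedule={"maize": _flat(2700.0, T, year0=900.0)},
        price_refs=("maize",),
        investment_components={
            "land_clearing": 150.0,
            "seed": 120.0,
            "fertiliser_pesticide": 1073.0 - 150.0 - 120.0 - 22 * w,
            "labour": 22 * w,
        },
    )

    # Ceba cattle: animals bought in year 0 are sold from year 1 on; the
    # annual cost includes repurchasing young stock.
    pasture = LandUseSpec(
        name="pasture",
        landcover_class="productive",
        cost_schedule=_flat(405.0, T, year0=1433.0),
        labour_schedule=_flat(8.0, T),
        yield_schedule={"beef": _flat(400.0, T, year0=0.0)},
        price_refs=("beef",),
        investment_components={
            "cattle_purchase": 774.0,  # 54 % of establishment
            "fencing": 300.0,
            "pasture_establishment": 1433.0 - 774.0 - 300.0 - 8 * w,
            "labour": 8 * w,
        },
    )

    teak_system = TreeSystem(
        initial_density=1110.0,
        thinnings=((4, 0.60), (10, 0.50)),
        harvest_year=T,
    )
    teak_labour = _sparse(
        T,
        {0: 40.0, 1: 25.0, 2: 25.0, 3: 8.0, 4: 30.0, 10: 28.0, 20: 60.0}
        | {y: 8.0 for y in (5, 6, 7, 8, 9)}
        | {y: 8.0 for y in range(11, 20)},
    )
    teak_costs = tuple(
        2184.0 if t == 0 else teak_labour[t] * w + 60.0 for t in range(T + 1)
    )
    teak = LandUseSpec(
        name="teak_plantation",
        landcover_class="productive",
        cost_schedule=teak_costs,
        labour_schedule=teak_labour,
        yield_schedule={
            "teak_timber": _sparse(T, {4: 8.0, 10: 35.0, 20: 160.0})  # m3/ha
        },
        price_refs=("teak_timber",),
        investment_components={
            "seedlings": 555.0,
            "land_clearing": 350.0,
            "planting_materials": 2184.0 - 555.0 - 350.0 - 40 * w,
            "labour": 40 * w,
        },
        tree_system=teak_system,
    )

    alley_system = TreeSystem(
        initial_density=555.0,
        thinnings=((5, 0.50), (10, 0.50)),
        harvest_year=T,
    )
    alley_labour = _sparse(
        T,
        {0: 28.0, 1: 20.0, 2: 20.0, 3: 6.0, 4: 6.0, 5: 18.0, 6: 12.0,
         10: 18.0, 11: 12.0, 20: 45.0}
        | {y: 5.0 for y in (7, 8, 9)}
        | {y: 5.0 for y in range(12, 20)},
    )
    alley_costs = _sparse(
        T,
        {0: 1835.0, 1: 1100.0, 2: 1100.0, 3: 133.98, 4: 133.98, 5: 351.94,
         6: 427.96, 10: 351.94, 11: 427.96, 20: 839.85}
        | {y: 116.65 for y in (7, 8, 9)}
        | {y: 116.65 for y in range(12, 20)},
    )
    alley = LandUseSpec(
        name="alley_cropping",
        landcover_class="compromise",
        cost_schedule=alley_costs,
        labour_schedule=alley_labour,
        yield_schedule={
            "maize": _flat(2700.0, T),
            "teak_timber": _sparse(T, {5: 6.0, 10: 22.0, 20: 95.0}),
        },
        price_refs=("maize", "teak_timber"),
        investment_components={
            "seedlings": 277.5,
            "tree_guards": 89.5,
            "land_clearing": 300.0,
            "maize_inputs": 420.0,
            "planting_materials": 1835.0 - 277.5 - 89.5 - 300.0 - 420.0 - 28 * w,
            "labour": 28 * w,
        },
        tree_system=alley_system,
        # 555 trees cleared to 1 m leave 83 % of the hectare for maize;
        # canopy closure restricts cropping to the establishment years
        # and the post-thinning windows at half yield.
        shading=ShadingRule(
            crop_area_fraction=0.83,
            crop_years={0: 1.0, 1: 1.0, 2: 1.0, 6: 0.5, 11: 0.5},
        ),
    )

    silvo_system = TreeSystem(
        initial_density=200.0,
        thinnings=(),
        canopy_fraction_schedule=tuple(0.36 * t / T for t in range(T + 1)),
        harvest_year=T,
    )
    silvo_labour = _sparse(
        T,
        {0: 20.0, 20: 40.0}
        | {y: 15.0 for y in (1, 2, 3)}      # pest management
        | {y: 14.0 for y in (4, 5, 6, 7)}   # annual pruning
        | {y: 11.0 for y in range(8, 20)},
    )
    silvo_costs = tuple(
        1970.0
        if t == 0
        else silvo_labour[t] * w
        + 253.0  # cattle repurchase and herd management
        + (30.0 if 1 <= t <= 3 else 20.0 if 4 <= t <= 7 else 80.0 if t == 20 else 0.0)
        for t in range(T + 1)
    )
    silvo = LandUseSpec(
        name="silvopasture",
        landcover_class="compromise",
        cost_schedule=silvo_costs,
        labour_schedule=silvo_labour,
        yield_schedule={
            "beef": _flat(400.0, T, year0=0.0),
            "cedar_timber": _sparse(T, {20: 65.0}),
        },
        price_refs=("beef", "cedar_timber"),
        investment_components={
            "cattle_purchase": 774.0,
            "fencing": 300.0,
            "seedlings": 160.0,
            "tree_guards": 96.0,
            "pasture_establishment": 1970.0 - 774.0 - 300.0 - 160.0 - 96.0 - 20 * w,
            "labour": 20 * w,
        },
        tree_system=silvo_system,
        # 5 % of the hectare is lost to tree clearing (base stocking 2
        # cows/ha drops to 1.9); pasture under canopy yields half.
        shading=ShadingRule(crop_area_fraction=0.95, crop_years=None),
    )

    forest = LandUseSpec(
        name="forest",
        landcover_class="protective",
        cost_schedule=_flat(0.0, T),
        labour_schedule=_flat(0.0, T),
        yield_schedule={},
        price_refs=(),
    )

    return StudyFixture(
        land_uses=(rice, maize, pasture, teak, alley, silvo, forest),
        prices=prices,
        histories=histories,
        energy_factors=energy_factors,
        wage=w,
        horizon=T,
        discount_rate=0.05,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ceteris-paribus perturbation


def perturb_fixture(fixture: StudyFixture, overrides: Mapping[str, float]) -> StudyFixture:
    """A new fixture differing from ``fixture`` only in the named
    parameters (the original is untouched).

    Supported override keys:

    * ``crop_yield_scale`` — multiply rice and maize yield schedules in
      every land use (timber and cattle untouched);
    * ``agroforestry_investment_scale`` — multiply the year-0 costs (and
      itemised investment components) of alley cropping and silvopasture;
    * ``price_scale:<commodity>`` — multiply the expected producer price
      of one commodity;
    * ``wage`` / ``discount_rate`` — replace the scalar.

    Unknown keys raise ``KeyError``.
    """
    prices = dict(fixture.prices)
    wage = fixture.wage
    discount_rate = fixture.discount_rate
    crop_scale = None
    agro_inv_scale = None

    for key, value in overrides.items():
        if key == "crop_yield_scale":
            crop_scale = float(value)
        elif key == "agroforestry_investment_scale":
            agro_inv_scale = float(value)
        elif key.startswith("price_scale:"):
            commodity = key.split(":", 1)[1]
            if commodity not in prices:
                raise KeyError(f"unknown commodity {commodity!r}")
            prices[commodity] = prices[commodity] * float(value)
        elif key == "wage":
            wage = float(value)
        elif key == "discount_rate":
            discount_rate = float(value)
        else:
            raise KeyError(f"unknown override {key!r}")

    specs = []
    for spec in fixture.land_uses:
        new = spec
        if crop_scale is not None and any(
            c in spec.yield_schedule for c in _CROP_COMMODITIES
        ):
            ys = {
                c: (
                    tuple(v * crop_scale for v in sched)
                    if c in _CROP_COMMODITIES
                    else sched
                )
                for c, sched in spec.yield_schedule.items()
            }
            new = replace(new, yield_schedule=ys)
        if agro_inv_scale is not None and spec.name in _AGROFORESTRY:
            costs = list(new.cost_schedule)
            costs[0] *= agro_inv_scale
            comps = {k: v * agro_inv_scale for k, v in new.investment_components.items()}
            new = replace(new, cost_schedule=tuple(costs), investment_components=comps)
        specs.append(new)

    return StudyFixture(
        land_uses=tuple(specs),
        prices=prices,
        histories=copy.deepcopy(fixture.histories),
        energy_factors=dict(fixture.energy_factors),
        wage=wage,
        horizon=fixture.horizon,
        discount_rate=discount_rate,
        seed=fixture.seed,
    )
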