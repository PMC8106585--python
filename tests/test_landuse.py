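"""Deterministic land-use model: stand dynamics, cash flows, indicators."""

import dataclasses

import numpy as np
import pytest

from agroportfolio import (
    LandUseSpec,
    TreeSystem,
    cultivable_area_fraction,
    discounted_payback,
    food_energy,
    net_cash_flow,
    net_cash_flow_series,
    npv,
    stem_count,
    stocking_rate,
)
from agroportfolio.landuse import yield_factor


class TestStemCount:
    @pytest.mark.parametrize(
        "name, year, expected",
        [
            ("teak_plantation", 20, 222.0),
            ("alley_cropping", 20, 138.75),
            ("silvopasture", 20, 200.0),
            ("teak_plantation", 0, 1110.0),
            ("teak_plantation", 3, 1110.0),
            ("teak_plantation", 4, 444.0),
        ],
    )
    def test_thinning_path(self, study_fixture, name, year, expected):
        system = study_fixture.land_use(name).tree_system
        assert stem_count(system, year) == pytest.approx(expected)

    def test_mortality_compounds(self, study_fixture):
        system = study_fixture.land_use("teak_plantation").tree_system
        assert stem_count(system, 20, include_mortality=True) == pytest.approx(
            222.0 * 0.995**20
        )

    def test_year_out_of_range(self, study_fixture):
        system = study_fixture.land_use("teak_plantation").tree_system
        with pytest.raises(ValueError):
            stem_count(system, 21)


class TestStockingRate:
    def test_year20_canopy_reduces_stocking(self):
        # 36 % of the 0.95 ha pasture under canopy, half yield beneath
        a0 = 0.95
        rate = stocking_rate(1.9, a0, a_sun=a0 * 0.64, a_canopy=a0 * 0.36)
        assert rate == pytest.approx(1.558, abs=1e-3)

    def test_no_canopy_leaves_rate_unchanged(self):
        assert stocking_rate(1.9, 0.95, 0.95, 0.0) == pytest.approx(1.9)

    def test_full_canopy_halves_rate(self):
        assert stocking_rate(2.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            stocking_rate(2.0, 0.0, 0.0, 0.0)

    def test_overfull_area_rejected(self):
        with pytest.raises(ValueError):
            stocking_rate(2.0, 1.0, 0.8, 0.4)


class TestCultivableArea:
    @pytest.mark.parametrize(
        "density, expected",
        [(555, 1 - 555 * np.pi / 1e4), (0, 1.0), (200, 1 - 200 * np.pi / 1e4)],
    )
    def test_clearing_geometry(self, density, expected):
        assert cultivable_area_fraction(density, 1.0) == pytest.approx(expected)

    def test_floor_at_zero(self):
        assert cultivable_area_fraction(1e6, 1.0) == 0.0


class TestNpv:
    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(42)
        series = rng.normal(0, 500, 21)
        expected = sum(v / 1.05**t for t, v in enumerate(series))
        assert npv(series, 0.05) == pytest.approx(expected)

    def test_break_even_discounting(self):
        assert npv([-100.0, 105.0], 0.05) == pytest.approx(0.0)

    def test_all_zero(self):
        assert npv(np.zeros(21), 0.05) == 0.0

    def test_rate_floor(self):
        with pytest.raises(ValueError):
            npv([1.0, 2.0], -1.0)


class TestDiscountedPayback:
    def test_all_zero_pays_back_immediately(self):
        assert discounted_payback(np.zeros(21), 0.05) == 0

    def test_profitable_at_establishment(self):
        assert discounted_payback([10.0] + [0.0] * 20, 0.05) == 0

    def test_never_positive_returns_horizon(self):
        assert discounted_payback([-1.0] * 21, 0.05) == 20

    def test_teak_pays_back_at_final_harvest(self, study_fixture):
        spec = study_fixture.land_use("teak_plantation")
        ncf = net_cash_flow_series(spec, study_fixture.prices)
        assert discounted_payback(ncf, 0.05) == 20

    def test_monotone_in_revenue(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            series = rng.normal(100, 400, 21)
            base = discounted_payback(series, 0.05)
            year = rng.integers(0, 21)
            lowered = series.copy()
            lowered[year] -= rng.uniform(0, 500)
            assert discounted_payback(lowered, 0.05) >= base


class TestNetCashFlow:
    def test_forest_is_zero_every_year(self, study_fixture):
        forest = study_fixture.land_use("forest")
        assert np.allclose(net_cash_flow_series(forest, study_fixture.prices), 0.0)

    def test_single_crop_revenue_identity(self):
        spec = LandUseSpec(
            name="toy",
            landcover_class="productive",
            cost_schedule=(0.0, 0.0),
            labour_schedule=(0.0, 0.0),
            yield_schedule={"maize": (3.0, 3.0)},
            price_refs=("maize",),
        )
        assert net_cash_flow(spec, 0, {"maize": 5.0}) == pytest.approx(15.0)

    def test_rice_year0_hand_sum(self, study_fixture):
        # revenue 1800 kg x 0.88 $/kg minus the 949 $ establishment cost
        rice = study_fixture.land_use("rice")
        expected = (
            rice.yield_schedule["rice"][0] * study_fixture.prices["rice"]
            - rice.cost_schedule[0]
        )
        assert net_cash_flow(rice, 0, study_fixture.prices) == pytest.approx(expected)

    def test_missing_multiplier_rejected(self, study_fixture):
        rice = study_fixture.land_use("rice")
        with pytest.raises(KeyError):
            net_cash_flow(rice, 0, study_fixture.prices, yield_multipliers={})

    def test_npv_linear_in_prices(self, study_fixture):
        spec = study_fixture.land_use("alley_cropping")
        free = dataclasses.replace(
            spec,
            cost_schedule=tuple(0.0 for _ in spec.cost_schedule),
            investment_components={},
        )
        base = npv(net_cash_flow_series(free, study_fixture.prices), 0.05)
        doubled_prices = {c: 2 * p for c, p in study_fixture.prices.items()}
        doubled = npv(net_cash_flow_series(free, doubled_prices), 0.05)
        assert doubled == pytest.approx(2 * base)


class TestFoodEnergy:
    def test_pure_timber_produces_no_food(self, study_fixture):
        teak = study_fixture.land_use("teak_plantation")
        assert food_energy(teak, study_fixture.energy_factors) == 0.0

    def test_constant_yield_identity(self):
        spec = LandUseSpec(
            name="toy",
            landcover_class="productive",
            cost_schedule=(0.0,) * 3,
            labour_schedule=(0.0,) * 3,
            yield_schedule={"rice": (4.0,) * 3},
            price_refs=("rice",),
        )
        assert food_energy(spec, {"rice": 3.5}) == pytest.approx(4.0 * 3.5)

    def test_alley_matches_year_by_year_hand_sum(self, study_fixture):
        alley = study_fixture.land_use("alley_cropping")
        factors = study_fixture.energy_factors
        total = 0.0
        for year in range(study_fixture.horizon + 1):
            total += (
                alley.yield_schedule["maize"][year]
                * yield_factor(alley, "maize", year)
                * factors["maize"]
            )
        expected = total / (study_fixture.horizon + 1)
        assert food_energy(alley, factors) == pytest.approx(expected)

    def test_missing_factor_rejected(self, study_fixture):
        rice = study_fixture.land_use("rice")
        with pytest.raises(KeyError):
            food_energy(rice, {})


def test_silvopasture_stocking_path_non_increasing(study_fixture):
    silvo = study_fixture.land_use("silvopasture")
    factors = [
        yield_factor(silvo, "beef", year)
        for year in range(study_fixture.horizon + 1)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(factors, factors[1:]))
    # canopy closure at year 20 leaves the printed 1.55 cows/ha
    assert 2.0 * factors[-1] == pytest.approx(1.558, abs=1e-3)
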