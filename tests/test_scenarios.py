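"""Scenario engine: priorities, caps, preference indicator, sweeps."""

import numpy as np
import pytest

from agroportfolio import (
    OptimizationConfig,
    SweepSpec,
    add_preference_indicator,
    optimize_portfolio,
    prioritize_objective,
    simulate_indicators,
    sweep_constraint,
    sweep_parameter,
    workers_required,
)
from agroportfolio.scenarios import DEFAULT_PREFERENCE_SCORES


class TestPrioritizeObjective:
    def test_unit_factor_is_baseline(self):
        config = prioritize_objective("npv", 1.0)
        assert all(w == 1.0 for w in config.weights.values())

    def test_doubling_npv(self):
        config = prioritize_objective("npv", 2.0)
        assert config.weights["npv"] == 2.0
        assert all(
            w == 1.0 for ind, w in config.weights.items() if ind != "npv"
        )

    def test_unknown_indicator(self):
        with pytest.raises(ValueError):
            prioritize_objective("beauty", 2.0)

    def test_non_positive_factor(self):
        with pytest.raises(ValueError):
            prioritize_objective("npv", 0.0)

    def test_labour_priority_moves_less_than_npv_priority(self, baseline_table):
        # prioritising profitability shifts the agroforestry share far
        # more than prioritising low labour demand
        base = optimize_portfolio(baseline_table, OptimizationConfig(m=0.0))
        npv2 = optimize_portfolio(baseline_table, prioritize_objective("npv", 2.0))
        lab2 = optimize_portfolio(baseline_table, prioritize_objective("labour", 2.0))
        d_npv = abs(npv2.agroforestry_share() - base.agroforestry_share())
        d_lab = abs(lab2.agroforestry_share() - base.agroforestry_share())
        assert d_lab <= d_npv


class TestWorkersRequired:
    @pytest.mark.parametrize(
        "area, rate, days, expected",
        [(50, 14, 300, 2.3), (1, 300, 300, 1.0), (100, 8, 300, 2.7)],
    )
    def test_conversion(self, area, rate, days, expected):
        assert workers_required(area, rate, days) == expected

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            workers_required(0, 14, 300)


class TestSweepConstraint:
    def test_inactive_cap_reproduces_baseline(self, baseline_table):
        base = optimize_portfolio(baseline_table, OptimizationConfig(m=3.0))
        swept = sweep_constraint(baseline_table, "labour", [1e6], m=3.0)
        assert np.allclose(swept.portfolios[0].shares, base.shares, atol=1e-9)

    def test_tightening_investment_cap_lowers_portfolio_investment(
        self, baseline_table
    ):
        grid = [2000.0, 1600.0, 1200.0, 800.0]
        swept = sweep_constraint(baseline_table, "investment", grid, m=3.0)
        achieved = [pf.achieved["investment"] for pf in swept.portfolios]
        assert all(a >= b - 1e-6 for a, b in zip(achieved, achieved[1:]))

    def test_beta_non_decreasing_as_caps_tighten(self, baseline_table):
        grid = [22.0, 18.0, 14.0, 10.0]
        swept = sweep_constraint(baseline_table, "labour", grid, m=3.0)
        betas = [pf.worst_distance for pf in swept.portfolios]
        assert all(a <= b + 1e-9 for a, b in zip(betas, betas[1:]))

    def test_infeasible_step_is_flagged_not_fatal(self, baseline_table):
        sub = baseline_table.subset(["rice", "maize", "teak_plantation"])
        swept = sweep_constraint(sub, "investment", [2000.0, 100.0], m=0.0)
        assert swept.portfolios[0] is not None
        assert swept.portfolios[1] is None
        assert np.isnan(swept.agroforestry_share().iloc[1])

    def test_unknown_kind(self, baseline_table):
        with pytest.raises(ValueError):
            sweep_constraint(baseline_table, "water", [1.0], m=0.0)


class TestPreferenceIndicator:
    def test_appended_shape_and_direction(self, baseline_table):
        table = add_preference_indicator(
            baseline_table, DEFAULT_PREFERENCE_SCORES, None
        )
        assert len(table.indicators) == 6
        assert table.indicators[-1] == "preference"
        assert table.mean.shape == (7, 6)

    def test_uniform_zero_sd_scores_leave_portfolio_unchanged(self, baseline_table):
        uniform = {name: 50.0 for name in baseline_table.land_uses}
        table = add_preference_indicator(baseline_table, uniform, None)
        base = optimize_portfolio(baseline_table, OptimizationConfig(m=1.5))
        with_pref = optimize_portfolio(table, OptimizationConfig(m=1.5))
        assert np.allclose(base.shares, with_pref.shares, atol=1e-9)

    def test_missing_score_rejected(self, baseline_table):
        with pytest.raises(ValueError):
            add_preference_indicator(baseline_table, {"rice": 1.0}, None)

    def test_silvopasture_preference_raises_its_share(self, baseline_table):
        # stated preferences rank silvopasture highest; at moderate risk
        # aversion its share rises above the preference-free baseline
        table = add_preference_indicator(
            baseline_table,
            DEFAULT_PREFERENCE_SCORES,
            {name: 5.0 for name in DEFAULT_PREFERENCE_SCORES},
        )
        base = optimize_portfolio(baseline_table, OptimizationConfig(m=1.5))
        with_pref = optimize_portfolio(table, OptimizationConfig(m=1.5))
        assert with_pref.share("silvopasture") >= base.share("silvopasture")
        assert with_pref.share("silvopasture") > 0.01


class TestSweepParameter:
    def test_zero_step_reproduces_baseline_exactly(self, study_fixture):
        spec = SweepSpec(
            parameter="teak_price", grid=(0.0,), m=3.0, n_reps=400, seed=11
        )
        result = sweep_parameter(study_fixture, spec)
        step_seed = int(
            np.random.SeedSequence((11, 0)).generate_state(1)[0] % 2**31
        )
        mc = simulate_indicators(study_fixture, n_reps=400, seed=step_seed)
        base = optimize_portfolio(mc.to_indicator_table(), OptimizationConfig(m=3.0))
        assert np.allclose(result.portfolios[0].shares, base.shares, atol=1e-12)

    def test_reproducible_under_fixed_seed(self, study_fixture):
        spec = SweepSpec(
            parameter="cedar_price", grid=(0.0, 0.5), m=3.0, n_reps=300, seed=5
        )
        a = sweep_parameter(study_fixture, spec)
        b = sweep_parameter(study_fixture, spec)
        assert a.shares.equals(b.shares)

    def test_lower_crop_yields_shift_from_alley_to_silvopasture(self, study_fixture):
        spec = SweepSpec(
            parameter="crop_yields", grid=(-0.4, 0.0), m=3.0, n_reps=1500, seed=2
        )
        result = sweep_parameter(study_fixture, spec)
        lowered, base = result.portfolios
        assert lowered.share("alley_cropping") <= base.share("alley_cropping") + 1e-9
        assert lowered.share("silvopasture") >= base.share("silvopasture") - 1e-9

    def test_invalid_parameter_and_grid(self, study_fixture):
        with pytest.raises(ValueError):
            SweepSpec(parameter="rainfall", grid=(0.0,))
        with pytest.raises(ValueError):
            SweepSpec(parameter="teak_price", grid=())
        with pytest.raises(ValueError):
            SweepSpec(parameter="teak_price", grid=(0.0, 0.5, 0.2))
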