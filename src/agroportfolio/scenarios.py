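"""Scenario analysis: priorities, constraints and parameter sweeps.

Three families of experiments around the baseline optimisation:

* re-weighting one objective relative to the others (a farmer with a
  clear priority),
* progressively tightening farm-level labour or investment caps (hard
  economic constraints), optionally with farmers' stated land-use
  preferences appended as a sixth indicator,
* ceteris-paribus sweeps of land-use-model parameters (crop yields,
  agroforestry investment costs, timber prices), re-running the Monte
  Carlo simulation and the optimisation at every step.

Every sweep step derives its own seed from the base seed, so curves are
reproducible while steps stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import StudyFixture, perturb_fixture
from .landuse import simulate_indicators
from .optimizer import (
    MORE_IS_BETTER,
    IndicatorTable,
    InfeasibleError,
    OptimizationConfig,
    Portfolio,
    optimize_portfolio,
)

__all__ = [
    "SweepSpec",
    "ScenarioResult",
    "prioritize_objective",
    "sweep_constraint",
    "sweep_parameter",
    "add_preference_indicator",
    "workers_required",
    "DEFAULT_PREFERENCE_SCORES",
]

#: Parameters a sweep may vary and the fixture override they map to.
_SWEEP_PARAMETERS = {
    "crop_yields": "crop_yield_scale",
    "agroforestry_investment": "agroforestry_investment_scale",
    "teak_price": "price_scale:teak_timber",
    "cedar_price": "price_scale:cedar_timber",
}

#: Synthetic stated-preference scores (0-100) ranking the cattle-based
#: systems highest, matching the reported pattern that silvopasture and
#: pasture align best with local farmers' cultural values while alley
#: cropping is least accepted.
DEFAULT_PREFERENCE_SCORES = {
    "rice": 55.0,
    "maize": 60.0,
    "pasture": 85.0,
    "teak_plantation": 40.0,
    "alley_cropping": 30.0,
    "silvopasture": 90.0,
    "forest": 50.0,
}


@dataclass(frozen=True)
class SweepSpec:
    """One ceteris-paribus sweep: which parameter, which grid, how deep.

    ``grid`` holds relative changes for model parameters (e.g. -0.6 for
    a 60 % reduction; scale factor ``1 + step``).  ``n_reps`` is the
    Monte-Carlo depth per step.
    """

    parameter: str
    grid: tuple[float, ...]
    m: float = 3.0
    n_reps: int = 10_000
    seed: int = 1
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parameter not in _SWEEP_PARAMETERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"choose from {sorted(_SWEEP_PARAMETERS)}"
            )
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")
        diffs = np.diff(self.grid)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            if len(self.grid) > 1:
                raise ValueError("sweep grid must be strictly monotone")


@dataclass(frozen=True)
class ScenarioResult:
    """A sweep curve: one optimised portfolio per grid step.

    ``portfolios`` may hold ``None`` for steps flagged infeasible (caps
    below the minimum attainable).  ``shares`` is a tidy frame (step x
    land use) with NaN rows for infeasible steps.
    """

    steps: tuple[float, ...]
    portfolios: tuple[Portfolio | None, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.portfolios):
            raise ValueError("one portfolio per step required")

    @property
    def shares(self) -> pd.DataFrame:
        frames = {}
        for step, pf in zip(self.steps, self.portfolios):
            frames[step] = pf.shares if pf is not None else None
        first = next(pf for pf in self.portfolios if pf is not None)
        return pd.DataFrame(
            {
                step: (s if s is not None else pd.Series(np.nan, index=first.shares.index))
                for step, s in frames.items()
            }
        ).T

    def agroforestry_share(
        self, systems: Sequence[str] = ("alley_cropping", "silvopasture")
    ) -> pd.Series:
        return pd.Series(
            [
                pf.agroforestry_share(systems) if pf is not None else np.nan
                for pf in self.portfolios
            ],
            index=list(self.steps),
        )

    def zero_agroforestry_threshold(self, tol: float = 1e-6) -> float | None:
        """Largest step at which the portfolio contains no agroforestry
        (None when agroforestry is present at every feasible step)."""
        zero_steps = [
            step
            for step, pf in zip(self.steps, self.portfolios)
            if pf is not None and pf.agroforestry_share() <= tol
        ]
        return max(zero_steps) if zero_steps else None


# ---------------------------------------------------------------------------


def prioritize_objective(
    indicator: str, factor: float, indicators: Sequence[str] = ("npv", "payback", "food", "labour", "investment"), **config_kwargs
) -> OptimizationConfig:
    """A configuration making one indicator ``factor`` times as important
    as the (unit-weighted) others."""
    if indicator not in indicators:
        raise ValueError(f"unknown indicator {indicator!r}")
    if factor <= 0:
        raise ValueError("weight factor must be positive")
    weights = {ind: 1.0 for ind in indicators}
    weights[indicator] = float(factor)
    return OptimizationConfig(weights=weights, **config_kwargs)


def sweep_constraint(
    table: IndicatorTable,
    kind: str,
    grid: Sequence[float],
    m: float,
    weights: Mapping[str, float] | None = None,
) -> ScenarioResult:
    """Optimise under a progressively moving labour or investment cap.

    Caps are absolute (days/ha/yr or $/ha).  Steps whose cap lies below
    the minimum attainable coefficient are flagged infeasible rather
    than raising.
    """
    if kind not in ("labour", "investment"):
        raise ValueError("kind must be 'labour' or 'investment'")
    portfolios: list[Portfolio | None] = []
    for cap in grid:
        config = OptimizationConfig(
            m=m,
            weights=dict(weights or {}),
            labour_cap=cap if kind == "labour" else None,
            investment_cap=cap if kind == "investment" else None,
        )
        try:
            portfolios.append(optimize_portfolio(table, config))
        except InfeasibleError:
            portfolios.append(None)
    return ScenarioResult(steps=tuple(grid), portfolios=tuple(portfolios))


def sweep_parameter(fixture: StudyFixture, spec: SweepSpec) -> ScenarioResult:
    """Ceteris-paribus sweep of one land-use-model parameter.

    Per step: perturb the fixture, re-run the Monte-Carlo simulation
    with a step-derived seed, re-optimise, collect the portfolio.
    """
    override_key = _SWEEP_PARAMETERS[spec.parameter]
    portfolios = []
    for index, step in enumerate(spec.grid):
        perturbed = perturb_fixture(fixture, {override_key: 1.0 + step})
        step_seed = int(
            np.random.SeedSequence((spec.seed, index)).generate_state(1)[0] % 2**31
        )
        mc = simulate_indicators(perturbed, n_reps=spec.n_reps, seed=step_seed)
        table = mc.to_indicator_table()
        config = OptimizationConfig(m=spec.m, weights=dict(spec.weights))
        portfolios.append(optimize_portfolio(table, config))
    return ScenarioResult(steps=tuple(spec.grid), portfolios=tuple(portfolios))


def add_preference_indicator(
    table: IndicatorTable,
    scores: Mapping[str, float],
    sd: Mapping[str, float] | None = None,
) -> IndicatorTable:
    """Append farmers' stated land-use preferences as a sixth,
    more-is-better indicator (score per land use, optional SD)."""
    return table.with_indicator(
        "preference", scores, dict(sd or {}), direction=MORE_IS_BETTER
    )


def workers_required(
    area_ha: float, labour_rate: float, working_days_per_year: float = 300.0
) -> float:
    """Full-time workers needed to supply ``labour_rate`` days/ha/yr on a
    farm of ``area_ha`` hectares, to one decimal."""
    if area_ha <= 0 or labour_rate <= 0 or working_days_per_year <= 0:
        raise ValueError("all arguments must be positive")
    return round(area_ha * labour_rate / working_days_per_year, 1)
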