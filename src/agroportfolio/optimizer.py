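"""Robust min-max goal programming over land-use area shares.

The decision variables are the area shares ``a(l)`` of a hypothetical
farm (non-negative, summing to one).  Each land use carries a predicted
score and a standard deviation for five socio-economic indicators.
Uncertainty enters through discrete scenarios: per indicator, every
subset of land uses may simultaneously fall to its unfavourable
coefficient (mean shifted by ``m`` standard deviations against the
indicator's direction).  The optimiser minimises the largest weighted,
normalised shortfall from the per-scenario aspiration level across all
indicators and scenarios — a Chebyshev (min-max) goal programme, solved
as a linear programme.

Normalisation convention: within each scenario the achieved level is
placed on a 0–100 scale spanned by the best (target) and worst
coefficient *of that scenario's own coefficient vector*.  Distances are
percentages of that span; 0 means the target is met, 100 means the
portfolio is no better than the worst pure stand.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "DIRECTIONS",
    "MORE_IS_BETTER",
    "LESS_IS_BETTER",
    "IndicatorTable",
    "OptimizationConfig",
    "Portfolio",
    "InfeasibleError",
    "worst_case_coefficient",
    "enumerate_scenarios",
    "normalize_distance",
    "optimize_portfolio",
    "bray_curtis",
]

logger = logging.getLogger(__name__)

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"

#: Direction registry for the five core indicators; a preference score
#: appended by the scenario engine is more-is-better.
DIRECTIONS: dict[str, str] = {
    "npv": MORE_IS_BETTER,
    "payback": LESS_IS_BETTER,
    "food": MORE_IS_BETTER,
    "labour": LESS_IS_BETTER,
    "investment": LESS_IS_BETTER,
    "preference": MORE_IS_BETTER,
}

#: Scenario-enumeration guard: 2^L constraints per indicator.
MAX_ENUMERABLE_LAND_USES = 20


class InfeasibleError(RuntimeError):
    """The constraint set admits no feasible portfolio."""


@dataclass(frozen=True)
class IndicatorTable:
    """Mean and standard deviation per indicator and land use.

    The sole input of the optimiser: rows are land uses (fixed order),
    columns are indicators with a direction each.
    """

    land_uses: tuple[str, ...]
    indicators: tuple[str, ...]
    directions: Mapping[str, str]
    mean: pd.DataFrame  # land uses x indicators
    sd: pd.DataFrame

    def __post_init__(self) -> None:
        for ind in self.indicators:
            if ind not in self.directions:
                raise ValueError(f"no direction assigned for indicator {ind!r}")
            if self.directions[ind] not in (MORE_IS_BETTER, LESS_IS_BETTER):
                raise ValueError(f"bad direction for {ind!r}")
        for frame, label in ((self.mean, "mean"), (self.sd, "sd")):
            if list(frame.index) != list(self.land_uses) or list(
                frame.columns
            ) != list(self.indicators):
                raise ValueError(f"{label} frame is not aligned with the labels")
            if frame.isna().any().any():
                raise ValueError(f"{label} frame contains missing cells")
        if (self.sd.to_numpy() < 0).any():
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_frames(
        cls, mean: pd.DataFrame, sd: pd.DataFrame, directions: Mapping[str, str] | None = None
    ) -> "IndicatorTable":
        directions = dict(DIRECTIONS if directions is None else directions)
        return cls(
            land_uses=tuple(mean.index),
            indicators=tuple(mean.columns),
            directions=directions,
            mean=mean.astype(float),
            sd=sd.reindex(index=mean.index, columns=mean.columns).astype(float),
        )

    @property
    def n_land_uses(self) -> int:
        return len(self.land_uses)

    def subset(self, land_uses: Sequence[str]) -> "IndicatorTable":
        """Restrict the table to the given land uses (order preserved)."""
        return IndicatorTable.from_frames(
            self.mean.loc[list(land_uses)],
            self.sd.loc[list(land_uses)],
            self.directions,
        )

    def with_indicator(
        self, name: str, mean: Mapping[str, float], sd: Mapping[str, float], direction: str
    ) -> "IndicatorTable":
        missing = [l for l in self.land_uses if l not in mean]
        if missing:
            raise ValueError(f"no score supplied for land uses {missing}")
        new_mean = self.mean.copy()
        new_sd = self.sd.copy()
        new_mean[name] = [float(mean[l]) for l in self.land_uses]
        new_sd[name] = [float(sd.get(l, 0.0)) for l in self.land_uses]
        directions = dict(self.directions)
        directions[name] = direction
        return IndicatorTable.from_frames(new_mean, new_sd, directions)


@dataclass(frozen=True)
class OptimizationConfig:
    """Settings of one optimisation run.

    ``m`` is the uncertainty multiple (0 risk-neutral, 1.5 moderately and
    3.0 strongly risk-averse).  Weights scale the normalised distances;
    caps bound the portfolio's expected labour demand (days/ha/yr) and
    investment costs ($/ha).
    """

    m: float = 0.0
    weights: Mapping[str, float] = field(default_factory=dict)
    labour_cap: float | None = None
    investment_cap: float | None = None
    forced_zero: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("uncertainty multiple m must be non-negative")
        for ind, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"weight for {ind!r} must be positive")

    def weight(self, indicator: str) -> float:
        return float(self.weights.get(indicator, 1.0))


@dataclass(frozen=True)
class Portfolio:
    """An optimised farm composition.

    ``shares`` sum to one; ``worst_distance`` is the guaranteed maximum
    weighted shortfall (percent of the normalisation span) over all
    indicators and uncertainty scenarios; ``achieved`` holds the
    portfolio's indicator levels at predicted coefficients.
    """

    shares: pd.Series
    worst_distance: float
    achieved: Mapping[str, float]
    config: OptimizationConfig

    def __post_init__(self) -> None:
        arr = self.shares.to_numpy()
        if (arr < -1e-9).any():
            raise ValueError("shares must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError("shares must sum to one")
        if self.worst_distance < -1e-9:
            raise ValueError("worst distance must be non-negative")

    def share(self, land_use: str) -> float:
        return float(self.shares[land_use])

    def agroforestry_share(
        self, systems: Sequence[str] = ("alley_cropping", "silvopasture")
    ) -> float:
        return float(sum(self.shares.get(s, 0.0) for s in systems))


# ---------------------------------------------------------------------------


def worst_case_coefficient(mean: float, sd: float, m: float, direction: str) -> float:
    """Unfavourably shifted coefficient: ``mean - m*sd`` when more is
    better, ``mean + m*sd`` when less is better."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if m < 0:
        raise ValueError("m must be non-negative")
    if direction == MORE_IS_BETTER:
        return mean - m * sd
    if direction == LESS_IS_BETTER:
        return mean + m * sd
    raise ValueError(f"unknown direction {direction!r}")


def enumerate_scenarios(n_land_uses: int) -> Iterator[np.ndarray]:
    """All 2^L boolean masks over land uses; ``True`` marks a land use at
    its worst-case coefficient, the rest stay at the predicted value."""
    if n_land_uses < 1:
        raise ValueError("need at least one land use")
    if n_land_uses > MAX_ENUMERABLE_LAND_USES:
        raise ValueError(
            f"refusing to enumerate 2^{n_land_uses} scenarios "
            f"(limit {MAX_ENUMERABLE_LAND_USES} land uses)"
        )
    for bits in itertools.product((False, True), repeat=n_land_uses):
        yield np.asarray(bits, dtype=bool)


def normalize_distance(
    achieved: float, target: float, worst: float, direction: str
) -> float:
    """Shortfall from the target as a percentage of the target-to-worst
    span, clipped to [0, 100].  A degenerate span (target == worst)
    carries no information and scores 0."""
    if direction not in (MORE_IS_BETTER, LESS_IS_BETTER):
        raise ValueError(f"unknown direction {direction!r}")
    span = target - worst
    if span == 0:
        return 0.0
    return float(np.clip(100.0 * (target - achieved) / span, 0.0, 100.0))


def _scenario_rows(
    table: IndicatorTable,
    config: OptimizationConfig,
    scenario_masks: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LP rows ``w*100*(T_u - c_u . a)/(T_u - W_u) <= beta`` for every
    indicator and uncertainty scenario ``u``, with the target ``T_u`` and
    worst ``W_u`` taken from the scenario's own coefficient vector."""
    L = table.n_land_uses
    rows, rhs = [], []
    for ind in table.indicators:
        direction = table.directions[ind]
        w = config.weight(ind)
        y = table.mean[ind].to_numpy(dtype=float)
        sd = table.sd[ind].to_numpy(dtype=float)
        shifted = np.array(
            [worst_case_coefficient(mu, s, config.m, direction) for mu, s in zip(y, sd)]
        )
        masks = enumerate_scenarios(L) if scenario_masks is None else scenario_masks
        for mask in masks:
            c = np.where(mask, shifted, y)
            if direction == MORE_IS_BETTER:
                target, worst = c.max(), c.min()
            else:
                target, worst = c.min(), c.max()
            span = target - worst
            if abs(span) < 1e-12:
                continue  # degenerate: no discriminating information
            # w*100*(target - c.a)/span <= beta
            rows.append(np.append(-w * 100.0 / span * c, -1.0))
            rhs.append(-w * 100.0 * target / span)
    return np.asarray(rows), np.asarray(rhs)


def optimize_portfolio(
    table: IndicatorTable,
    config: OptimizationConfig | None = None,
    scenario_masks: Sequence[np.ndarray] | None = None,
) -> Portfolio:
    """Solve the robust min-max goal programme.

    Minimises ``beta`` subject to one normalised-shortfall constraint per
    indicator and uncertainty scenario, the unit-simplex constraint on
    the shares, optional labour/investment caps on the portfolio's
    expected coefficients, and optional exclusions.  Raises
    :class:`InfeasibleError` when the caps admit no portfolio.

    ``scenario_masks`` restricts the enumeration to the given subsets
    (e.g. only all-predicted and all-worst), yielding a relaxation whose
    optimum bounds the full problem from below.
    """
    config = OptimizationConfig() if config is None else config
    L = table.n_land_uses
    A_ub, b_ub = _scenario_rows(table, config, scenario_masks)
    logger.debug(
        "min-max LP: %d land uses, %d indicators, %d scenario constraints",
        L, len(table.indicators), len(b_ub),
    )
    A_ub = A_ub.tolist() if A_ub.size else []
    b_ub = b_ub.tolist() if np.size(b_ub) else []

    for cap, ind in ((config.labour_cap, "labour"), (config.investment_cap, "investment")):
        if cap is not None:
            if ind not in table.indicators:
                raise ValueError(f"cannot cap {ind!r}: not in the table")
            A_ub.append(np.append(table.mean[ind].to_numpy(dtype=float), 0.0))
            b_ub.append(float(cap))

    bounds = [
        (0.0, 0.0 if name in config.forced_zero else None) for name in table.land_uses
    ] + [(0.0, None)]
    cost = np.append(np.zeros(L), 1.0)
    A_eq = [np.append(np.ones(L), 0.0)]

    res = linprog(
        cost,
        A_ub=np.asarray(A_ub) if A_ub else None,
        b_ub=np.asarray(b_ub) if b_ub else None,
        A_eq=np.asarray(A_eq),
        b_eq=np.asarray([1.0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(
            "no feasible portfolio under the given constraints "
            f"(labour_cap={config.labour_cap}, investment_cap={config.investment_cap})"
        )
    if not res.success:  # pragma: no cover - cannot occur on a bounded simplex
        raise RuntimeError(f"LP solver failed: {res.message}")

    shares = pd.Series(np.clip(res.x[:L], 0.0, None), index=list(table.land_uses))
    shares /= shares.sum()
    achieved = {
        ind: float(shares.to_numpy() @ table.mean[ind].to_numpy(dtype=float))
        for ind in table.indicators
    }
    return Portfolio(
        shares=shares,
        worst_distance=float(res.x[-1]),
        achieved=achieved,
        config=config,
    )


def bray_curtis(p: Sequence[float], q: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity between two share compositions on the
    same land-use ordering: half the summed absolute differences."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("share vectors must have the same length")
    return float(np.abs(p - q).sum() / 2.0)
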