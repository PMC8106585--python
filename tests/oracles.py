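"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration rather than
calling the implementation paths they check.
"""

import itertools

import numpy as np

from agroportfolio.optimizer import (
    LESS_IS_BETTER,
    MORE_IS_BETTER,
    IndicatorTable,
)


def worst_weighted_distance(table: IndicatorTable, shares: np.ndarray, m: float,
                            weights=None) -> float:
    """Maximum weighted normalised shortfall of a fixed portfolio over
    every indicator and every uncertainty scenario, by direct
    enumeration (no LP involved)."""
    weights = weights or {}
    L = table.n_land_uses
    worst = 0.0
    for ind in table.indicators:
        direction = table.directions[ind]
        w = float(weights.get(ind, 1.0))
        y = table.mean[ind].to_numpy(dtype=float)
        sd = table.sd[ind].to_numpy(dtype=float)
        shifted = y - m * sd if direction == MORE_IS_BETTER else y + m * sd
        for bits in itertools.product((False, True), repeat=L):
            c = np.where(bits, shifted, y)
            if direction == MORE_IS_BETTER:
                target, low = c.max(), c.min()
            else:
                target, low = c.min(), c.max()
            span = target - low
            if abs(span) < 1e-12:
                continue
            d = 100.0 * (target - float(shares @ c)) / span
            worst = max(worst, w * min(max(d, 0.0), 100.0))
    return worst


def simplex_grid(n: int, step: float):
    """All share vectors of length ``n`` on the unit simplex with the
    given resolution."""
    k = round(1.0 / step)
    if n == 3:
        for i in range(k + 1):
            for j in range(k + 1 - i):
                yield np.array([i, j, k - i - j], dtype=float) / k
    else:
        for combo in itertools.product(range(k + 1), repeat=n - 1):
            if sum(combo) <= k:
                yield np.append(np.array(combo, float), k - sum(combo)) / k


def grid_search_beta(table: IndicatorTable, m: float, step: float = 0.01) -> float:
    """Exhaustive minimisation of the worst distance over a simplex grid
    (vectorised over grid points, but the same enumeration as
    :func:`worst_weighted_distance`)."""
    L = table.n_land_uses
    coeffs, targets, spans = [], [], []
    for ind in table.indicators:
        direction = table.directions[ind]
        y = table.mean[ind].to_numpy(dtype=float)
        sd = table.sd[ind].to_numpy(dtype=float)
        shifted = y - m * sd if direction == MORE_IS_BETTER else y + m * sd
        for bits in itertools.product((False, True), repeat=L):
            c = np.where(bits, shifted, y)
            if direction == MORE_IS_BETTER:
                target, low = c.max(), c.min()
            else:
                target, low = c.min(), c.max()
            span = target - low
            if abs(span) < 1e-12:
                continue
            coeffs.append(c)
            targets.append(target)
            spans.append(span)
    C = np.asarray(coeffs)
    targets = np.asarray(targets)
    spans = np.asarray(spans)
    grid = np.array(list(simplex_grid(L, step)))
    distances = 100.0 * (targets[None, :] - grid @ C.T) / spans[None, :]
    beta = np.clip(distances, 0.0, 100.0).max(axis=1)
    return float(beta.min())
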