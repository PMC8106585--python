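"""Interchange formats, packaged data and the pipeline runner.

Coefficient tables travel as CSV (one row per land use, paired
``<indicator>_mean`` / ``<indicator>_sd`` columns — the layout of the
published baseline table); portfolios as JSON or flat TSV; pipeline runs
emit a JSON manifest recording configuration hash, seeds, package
version and output digests so every number is reproducible.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .fixtures import StudyFixture, make_default_fixture
from .landuse import simulate_indicators
from .optimizer import (
    DIRECTIONS,
    IndicatorTable,
    OptimizationConfig,
    Portfolio,
    optimize_portfolio,
)

__all__ = [
    "CoefficientTableError",
    "load_baseline_coefficients",
    "read_coefficient_table",
    "write_coefficient_table",
    "write_portfolio",
    "RunManifest",
    "run_pipeline",
]

_CURRENT_LAND_USE_SHARES = {
    # Aggregated land cover of the study area used for the Bray-Curtis
    # plausibility check: pasture 60 %, cropland 26 % (split between the
    # two annual crops), natural forest 14 %.
    "rice": 0.13,
    "maize": 0.13,
    "pasture": 0.60,
    "teak_plantation": 0.0,
    "alley_cropping": 0.0,
    "silvopasture": 0.0,
    "forest": 0.14,
}


class CoefficientTableError(ValueError):
    """A coefficient CSV violated the expected layout or invariants."""


def load_baseline_coefficients() -> IndicatorTable:
    """The packaged baseline coefficient table for the seven land uses
    (means and standard deviations of the five indicators, as published
    for the eastern-Panama case study)."""
    with resources.files("agroportfolio.data").joinpath(
        "baseline_coefficients.csv"
    ).open() as fh:
        return _parse_coefficient_table(fh)


def read_coefficient_table(path) -> IndicatorTable:
    """Read a coefficient CSV and attach indicator directions from the
    registry.  Malformed cells raise :class:`CoefficientTableError`
    naming the offending row and column."""
    with open(path) as fh:
        return _parse_coefficient_table(fh)


def _parse_coefficient_table(fh) -> IndicatorTable:
    frame = pd.read_csv(fh)
    if "land_use" not in frame.columns:
        raise CoefficientTableError("missing 'land_use' column")
    frame = frame.set_index("land_use")
    indicators = []
    for col in frame.columns:
        if not col.endswith("_mean"):
            continue
        ind = col[: -len("_mean")]
        if f"{ind}_sd" not in frame.columns:
            raise CoefficientTableError(f"indicator {ind!r} has no '{ind}_sd' column")
        if ind not in DIRECTIONS:
            raise CoefficientTableError(f"unknown indicator {ind!r}")
        indicators.append(ind)
    if not indicators:
        raise CoefficientTableError("no '<indicator>_mean' columns found")
    for land_use, row in frame.iterrows():
        for col in frame.columns:
            if pd.isna(row[col]):
                raise CoefficientTableError(
                    f"missing cell at row {land_use!r}, column {col!r}"
                )
        for ind in indicators:
            if row[f"{ind}_sd"] < 0:
                raise CoefficientTableError(
                    f"negative SD at row {land_use!r}, column '{ind}_sd'"
                )
    mean = frame[[f"{i}_mean" for i in indicators]].astype(float)
    mean.columns = indicators
    sd = frame[[f"{i}_sd" for i in indicators]].astype(float)
    sd.columns = indicators
    return IndicatorTable.from_frames(mean, sd)


def write_coefficient_table(table: IndicatorTable, path) -> None:
    """Write a coefficient table in the interchange CSV layout."""
    out = pd.DataFrame(index=list(table.land_uses))
    for ind in table.indicators:
        out[f"{ind}_mean"] = table.mean[ind]
        out[f"{ind}_sd"] = table.sd[ind]
    out.index.name = "land_use"
    out.to_csv(path)


def write_portfolio(portfolio: Portfolio, path, format: str = "tsv") -> None:
    """Persist a portfolio: shares to four decimals plus the worst
    distance and achieved indicator levels.  ``format`` is 'tsv' (flat
    ``land_use<TAB>share``) or 'json'."""
    path = Path(path)
    if format == "tsv":
        lines = ["land_use\tshare"]
        lines += [
            f"{name}\t{share:.4f}" for name, share in portfolio.shares.items()
        ]
        lines.append(f"# worst_distance\t{portfolio.worst_distance:.4f}")
        for ind, level in portfolio.achieved.items():
            lines.append(f"# achieved_{ind}\t{level:.4f}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "shares": {k: round(float(v), 4) for k, v in portfolio.shares.items()},
            "worst_distance": float(portfolio.worst_distance),
            "achieved": {k: float(v) for k, v in portfolio.achieved.items()},
            "config": {
                "m": portfolio.config.m,
                "weights": dict(portfolio.config.weights),
                "labour_cap": portfolio.config.labour_cap,
                "investment_cap": portfolio.config.investment_cap,
                "forced_zero": sorted(portfolio.config.forced_zero),
            },
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unsupported portfolio format {format!r}")


def read_portfolio_shares(path) -> pd.Series:
    """Re-read the shares from a JSON portfolio file."""
    payload = json.loads(Path(path).read_text())
    return pd.Series(payload["shares"], dtype=float)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass(frozen=True)
class RunManifest:
    """Provenance record of one pipeline run."""

    command: str
    config_digest: str
    seed: int
    package_version: str
    started: str
    finished: str
    input_digests: Mapping[str, str] = field(default_factory=dict)
    output_digests: Mapping[str, str] = field(default_factory=dict)
    stage_seconds: Mapping[str, float] = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=dict) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path) -> RunManifest:
    """Execute the configured stages (simulate -> optimise) and write all
    outputs plus a run manifest.

    The YAML configuration supports::

        seed: 42            # master seed for every random draw
        reps: 10000         # Monte-Carlo repetitions
        m_levels: [0, 1.5, 3.0]
        stages: [simulate, optimize]
        coeffs: packaged    # 'packaged', 'simulate' or a CSV path
        fixture: default    # 'default' or a fixture YAML path
        out_dir: out
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text()) or {}
    seed = int(config.get("seed", 1))
    reps = int(config.get("reps", 10_000))
    m_levels = [float(m) for m in config.get("m_levels", [0.0, 1.5, 3.0])]
    stages = list(config.get("stages", ["simulate", "optimize"]))
    out_dir = Path(config.get("out_dir", "out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    input_digests = {str(config_path): _digest(config_path)}
    outputs: dict[str, Path] = {}
    stage_seconds: dict[str, float] = {}

    table: IndicatorTable | None = None
    coeffs = config.get("coeffs", "simulate" if "simulate" in stages else "packaged")

    if "simulate" in stages:
        tic = time.perf_counter()
        fixture_cfg = config.get("fixture", "default")
        if fixture_cfg == "default":
            fixture = make_default_fixture(seed)
        else:
            fixture = StudyFixture.load(fixture_cfg)
            input_digests[str(fixture_cfg)] = _digest(Path(fixture_cfg))
        mc = simulate_indicators(fixture, n_reps=reps, seed=seed)
        table = mc.to_indicator_table()
        coeff_path = out_dir / "coefficients.csv"
        write_coefficient_table(table, coeff_path)
        outputs["coefficients"] = coeff_path
        stage_seconds["simulate"] = time.perf_counter() - tic

    if "optimize" in stages:
        tic = time.perf_counter()
        if table is None or coeffs not in ("simulate",):
            if coeffs == "packaged":
                table = load_baseline_coefficients()
            elif coeffs != "simulate":
                table = read_coefficient_table(coeffs)
                input_digests[str(coeffs)] = _digest(Path(coeffs))
        for m in m_levels:
            pf = optimize_portfolio(table, OptimizationConfig(m=m))
            pf_path = out_dir / f"portfolio_m{m:g}.json"
            write_portfolio(pf, pf_path, format="json")
            outputs[f"portfolio_m{m:g}"] = pf_path
        stage_seconds["optimize"] = time.perf_counter() - tic

    finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest = RunManifest(
        command=f"run {config_path}",
        config_digest=_digest(config_path),
        seed=seed,
        package_version=__version__,
        started=started,
        finished=finished,
        input_digests=input_digests,
        output_digests={k: _digest(p) for k, p in outputs.items()},
        stage_seconds=stage_seconds,
    )
    manifest.save(out_dir / "manifest.json")
    return manifest


def current_land_use_shares() -> pd.Series:
    """Aggregated present-day land cover of the study area, for the
    Bray-Curtis plausibility comparison."""
    return pd.Series(_CURRENT_LAND_USE_SHARES, dtype=float)
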