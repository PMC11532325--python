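"""Scenario orchestration: single runs and the full 5 x 3 experiment.

A run initializes one landscape archetype at the default 100 x 100 grid
(10 m cells), applies one grazing regime for 50 years, and records the
landscape abundance of every functional group each year (year 0 is the
initialized state).  The full experiment covers all five vegetation types
under all three regimes — 15 runs of 50 years.  Apart from seed dispersal
the model is deterministic, so each configuration is run once; the
dispersal noise is pinned by the run seed.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .engine import annual_step
from .grazing import REGIME_DEFAULTS, GrazingScenario
from .landscape import (ArchetypeProfile, Landscape, dominance_map,
                        init_landscape, landscape_abundance, load_archetypes,
                        render_dominance_png, write_dominance_labels,
                        write_state)
from .params import GROUPS, FunctionalGroupParams, default_params, params_by_name

__all__ = ["RunConfig", "RunResult", "run_scenario", "run_experiment",
           "DEFAULT_YEARS", "DEFAULT_GRID", "REGIMES"]

DEFAULT_YEARS = 50
DEFAULT_GRID = (100, 100)
REGIMES = ("none", "moderate", "overgrazing")


@dataclass(frozen=True)
class RunConfig:
    """One simulation configuration."""

    landscape: int | ArchetypeProfile = 1
    regime: str | GrazingScenario = "none"
    years: int = DEFAULT_YEARS
    grid: tuple[int, int] = DEFAULT_GRID
    cell_size: float = 10.0
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self):
        if self.years < 0:
            raise ValueError("years must be >= 0")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid dimensions must be >= 1")

    def profile(self) -> ArchetypeProfile:
        if isinstance(self.landscape, ArchetypeProfile):
            return self.landscape
        catalogue = load_archetypes()
        if self.landscape not in catalogue:
            raise KeyError(f"unknown landscape archetype {self.landscape!r}; "
                           f"expected one of {sorted(catalogue)}")
        return catalogue[self.landscape]

    def scenario(self) -> GrazingScenario:
        if isinstance(self.regime, GrazingScenario):
            return self.regime
        return GrazingScenario.for_regime(self.regime)


@dataclass
class RunResult:
    config: RunConfig
    series: pd.DataFrame  # index: year 0..years; columns: groups (percent)
    initial: Landscape
    final: Landscape

    def final_abundances(self) -> pd.Series:
        return self.series.iloc[-1]


def _record(ls: Landscape) -> dict[str, float]:
    return {g: landscape_abundance(ls, g) for g in GROUPS}


def run_scenario(config: RunConfig,
                 params: list[FunctionalGroupParams] | None = None,
                 progress: bool = False) -> RunResult:
    """Run one (landscape, regime) scenario and optionally write outputs."""
    pmap = params_by_name(params if params is not None else default_params())
    profile = config.profile()
    scenario = config.scenario()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ls = init_landscape(profile, config.grid, rng, pmap, cell_size=config.cell_size)
    initial = ls.copy()
    records = [_record(ls)]
    for year in range(1, config.years + 1):
        annual_step(ls, pmap, scenario, year, rng)
        records.append(_record(ls))
        if progress and (year % 10 == 0 or year == config.years):
            print(f"  year {year:3d}/{config.years}", file=sys.stderr)
    series = pd.DataFrame(records, index=pd.RangeIndex(config.years + 1, name="year"))
    result = RunResult(config, series, initial, ls)
    if config.outdir is not None:
        _write_run_outputs(result)
    return result


def _run_tag(config: RunConfig) -> str:
    lid = (config.landscape if isinstance(config.landscape, int)
           else config.landscape.name.replace(" ", "_"))
    regime = config.regime if isinstance(config.regime, str) else config.regime.regime
    return f"landscape{lid}_{regime}"


def _write_run_outputs(result: RunResult) -> None:
    cfg = result.config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = _run_tag(cfg)
    result.series.to_csv(outdir / f"abundance_{tag}.csv")
    result.final_abundances().rename("abundance_pct").to_csv(
        outdir / f"final_abundance_{tag}.csv")
    pmap = params_by_name(default_params())
    for label, ls in (("initial", result.initial), ("final", result.final)):
        dom = dominance_map(ls, pmap)
        write_dominance_labels(dom, outdir / f"dominance_{tag}_{label}.tsv")
        render_dominance_png(dom, outdir / f"dominance_{tag}_{label}.png")
    write_state(result.final, outdir / f"state_{tag}_final.tsv")
    meta = {
        "config": {
            "landscape": cfg.landscape if isinstance(cfg.landscape, int)
            else cfg.landscape.name,
            "regime": cfg.regime if isinstance(cfg.regime, str) else asdict(cfg.regime),
            "years": cfg.years, "grid": list(cfg.grid),
            "cell_size": cfg.cell_size, "seed": cfg.seed,
        },
        "versions": {"steppesim": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (outdir / f"run_{tag}.json").write_text(json.dumps(meta, indent=2))


def derive_seed(base_seed: int, landscape_id: int, regime: str) -> int:
    """Stable per-combination seed below 2**31."""
    ridx = REGIMES.index(regime)
    return (base_seed * 1_000_003 + landscape_id * 101 + ridx) % (2**31)


def run_experiment(seed: int = 0,
                   years: int = DEFAULT_YEARS,
                   grid: tuple[int, int] = DEFAULT_GRID,
                   outdir: str | Path | None = None,
                   params: list[FunctionalGroupParams] | None = None,
                   progress: bool = False) -> tuple[pd.DataFrame, dict[tuple[int, str], RunResult]]:
    """Run all 15 (landscape, regime) combinations.

    Returns a tidy long-format table (landscape, regime, group, year,
    abundance) and the per-combination results.
    """
    catalogue = load_archetypes()
    rows = []
    results: dict[tuple[int, str], RunResult] = {}
    for lid in sorted(catalogue):
        for regime in REGIMES:
            if progress:
                print(f"landscape {lid}, regime {regime}", file=sys.stderr)
            cfg = RunConfig(landscape=lid, regime=regime, years=years, grid=grid,
                            seed=derive_seed(seed, lid, regime), outdir=outdir)
            res = run_scenario(cfg, params=params, progress=progress)
            results[(lid, regime)] = res
            long = res.series.reset_index().melt(
                id_vars="year", var_name="group", value_name="abundance")
            long.insert(0, "regime", regime)
            long.insert(0, "landscape", lid)
            rows.append(long)
    table = pd.concat(rows, ignore_index=True)
    if outdir is not None:
        outdir = Path(outdir)
        table.to_csv(outdir / "experiment_long.csv", index=False)
        finals = table[table["year"] == years].pivot_table(
            index=["landscape", "regime"], columns="group", values="abundance")
        finals.to_csv(outdir / "experiment_final_abundance.csv")
    return table, results
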