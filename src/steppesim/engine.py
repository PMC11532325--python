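"""Annual demographic step: aging, light competition, survival, seed rain.

One simulated year applies, in order: (1) grazing disturbance, (2) aging and
stage promotion with senescence, (3) per-cell, per-stratum resource
computation from canopy occupancy, (4) the survival pass, (5) seed
production and stochastic dispersal, and (6) germination of the seed rain.
All steps except dispersal are deterministic; replaying a run with the same
seed reproduces it bit for bit.

Light competition is asymmetric: a cohort querying stratum ``q`` is shaded
only by plants occupying strata strictly above ``q``.  The shading score is
the sum of abundance-weighted canopy contributions (matures weigh 1,
immatures ``size_class / 4``); scores below 0.33 leave resources high,
below 0.66 medium, and low otherwise — mirroring the ordinal abundance-class
thresholds.

Seed dispersal uses a three-band kernel per group: a distance band
(short / medium / long) is chosen with probability proportional to the
band's ordinal capacity; within the short and medium bands the distance is
uniform over the annulus, while beyond the medium limit the distance density
decays exponentially, shaped by the two kernel constants (onset and tail
scale) and truncated at the long-distance limit.  Direction is uniform on
the circle and seeds landing off-grid are lost (absorbing boundary).
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .grazing import GrazingScenario, graze_landscape
from .landscape import ABUNDANCE_THRESHOLDS, Cell, Cohort, Landscape
from .params import (GROUPS, FunctionalGroupParams, Resource, Stage,
                     level_to_fraction, params_by_name)

__all__ = [
    "SeedEvent",
    "resource_from_shading",
    "compute_resource",
    "survive_step",
    "age_and_promote",
    "produce_and_disperse",
    "germinate",
    "annual_step",
]


class SeedEvent(NamedTuple):
    group: str
    source: tuple[int, int]
    target: tuple[int, int]


def resource_from_shading(score: float) -> Resource:
    """Resource level left under a given shading score."""
    if score < ABUNDANCE_THRESHOLDS[0]:
        return Resource.HIGH
    if score < ABUNDANCE_THRESHOLDS[1]:
        return Resource.MEDIUM
    return Resource.LOW


def _shade_weight(cohort: Cohort, p: FunctionalGroupParams) -> tuple[int, float]:
    """(occupied stratum, canopy weight) of a cohort; germinants cast no shade."""
    if cohort.stage == Stage.MATURE:
        return p.stratum_mature, 1.0
    if cohort.stage == Stage.IMMATURE:
        return p.stratum_immature, p.size_class / 4.0
    return 1, 0.0


def compute_resource(cell: Cell, stratum: int,
                     params: Mapping[str, FunctionalGroupParams]) -> Resource:
    """Resource level available in ``stratum`` of ``cell``.

    Only cohorts occupying strata strictly above ``stratum`` shade it; a
    query at stratum 5 therefore always sees high resources.
    """
    if not 1 <= stratum <= 5:
        raise ValueError(f"stratum {stratum} outside 1..5")
    score = 0.0
    for co in cell.cohorts:
        s, w = _shade_weight(co, params[co.group])
        if s > stratum:
            score += w * co.abundance
    return resource_from_shading(score)


def survive_step(cohort: Cohort, resource: Resource,
                 p: FunctionalGroupParams) -> Cohort | None:
    """Apply the binary survival matrix; ``None`` means the cohort is removed."""
    if cohort.stage == Stage.PROPAGULE:
        raise ValueError("propagules have no survival-matrix entry")
    return cohort if p.survival.survives(cohort.stage, resource) else None


def age_and_promote(cohort: Cohort, p: FunctionalGroupParams) -> Cohort | None:
    """Advance a cohort by one year, promoting stages and enforcing lifespan.

    Germinants become immature after their first year (or mature directly
    for groups maturing at age 1); cohorts older than the group lifespan are
    removed.
    """
    age = cohort.age + 1
    if age > p.max_age:
        return None
    return Cohort(cohort.group, p.stage_of(age), age, cohort.abundance)


# ---------------------------------------------------------------------------
# Dispersal


def _band_probabilities(p: FunctionalGroupParams) -> np.ndarray | None:
    w = np.array(p.dispersal.band_weights())
    tot = w.sum()
    if tot == 0:
        return None
    return w / tot


def _sample_long_band(p: FunctionalGroupParams, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Distances in the long band: exponential decay beyond the medium limit.

    The decay sets in at the medium limit with onset scale ``k2 / k1`` and
    tail scale ``k2`` (a sum of two exponentials), truncated by resampling at
    the long limit.
    """
    k1, k2 = p.dispersal.k_disp
    l2, l3 = p.dispersal.limits[1], p.dispersal.limits[2]
    span = l3 - l2
    x = rng.exponential(k2 / k1, n) + rng.exponential(k2, n)
    for _ in range(100):
        bad = x > span
        if not bad.any():
            break
        nb = int(bad.sum())
        x[bad] = rng.exponential(k2 / k1, nb) + rng.exponential(k2, nb)
    np.clip(x, 0.0, span, out=x)
    return l2 + x


def _sample_distances(p: FunctionalGroupParams, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` dispersal distances from the full three-band kernel."""
    probs = _band_probabilities(p)
    if probs is None:
        raise ValueError("all dispersal band rates are zero")
    l1, l2, _ = p.dispersal.limits
    bands = rng.choice(3, size=n, p=probs)
    d = np.empty(n)
    sel = bands == 0
    d[sel] = rng.uniform(0.0, l1, int(sel.sum()))
    sel = bands == 1
    d[sel] = rng.uniform(l1, l2, int(sel.sum()))
    sel = bands == 2
    d[sel] = _sample_long_band(p, int(sel.sum()), rng)
    return d


def _sample_landings(ls: Landscape, p: FunctionalGroupParams,
                     rng: np.random.Generator):
    """Vectorized seed rain: returns (src_r, src_c, tgt_r, tgt_c, in_bounds).

    Every mature cohort emits ``fecundity`` seeds from its cell center; the
    landing cell is the cell containing the sampled point.
    """
    empty = (np.empty(0, int),) * 4 + (np.empty(0, bool),)
    if p.fecundity == 0:
        return empty
    n_mat = np.zeros((ls.height, ls.width), dtype=int)
    for age, layer in ls.cohorts[p.name].items():
        if age >= p.mature_age:
            n_mat += layer > 0
    seeds = p.fecundity * n_mat
    total = int(seeds.sum())
    if total == 0:
        return empty
    rr, cc = np.nonzero(seeds)
    counts = seeds[rr, cc]
    src_r = np.repeat(rr, counts)
    src_c = np.repeat(cc, counts)
    if _band_probabilities(p) is None:
        # seeds are produced but have nowhere to go
        return (src_r, src_c, np.empty(0, int), np.empty(0, int),
                np.zeros(total, bool))
    d = _sample_distances(p, total, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, total)
    cs = ls.cell_size
    x = (src_c + 0.5) * cs + d * np.cos(theta)
    y = (src_r + 0.5) * cs + d * np.sin(theta)
    tgt_c = np.floor(x / cs).astype(int)
    tgt_r = np.floor(y / cs).astype(int)
    ok = (tgt_r >= 0) & (tgt_r < ls.height) & (tgt_c >= 0) & (tgt_c < ls.width)
    return src_r, src_c, tgt_r, tgt_c, ok


def produce_and_disperse(ls: Landscape, p: FunctionalGroupParams,
                         rng: np.random.Generator) -> list[SeedEvent]:
    """Seed rain of one group as discrete events (off-grid seeds discarded)."""
    src_r, src_c, tgt_r, tgt_c, ok = _sample_landings(ls, p, rng)
    if ok.size == 0 or not ok.any():
        return []
    return [SeedEvent(p.name, (int(sr), int(sc)), (int(tr), int(tc)))
            for sr, sc, tr, tc in zip(src_r[ok], src_c[ok], tgt_r[ok], tgt_c[ok])]


# ---------------------------------------------------------------------------
# Germination


def germinate(cell: Cell, group: str, resource: Resource,
              p: FunctionalGroupParams) -> Cohort | None:
    """Turn a cell's seed arrivals into a germinant cohort.

    The cohort abundance is the germination fraction at the local resource
    level times the seed saturation ``min(1, events / fecundity)``.  If
    germinants of the group cannot survive at this resource level the cohort
    dies in the same step and ``None`` is returned.
    """
    events = float(cell.seeds.get(group, 0.0))
    if events <= 0 or p.fecundity == 0:
        return None
    frac = level_to_fraction(p.germination_rate[resource])
    if frac == 0.0:
        return None
    if not p.survival.germinant[resource]:
        return None
    abundance = frac * min(1.0, events / p.fecundity)
    return Cohort(group, Stage.GERMINANT, 0, abundance)


# ---------------------------------------------------------------------------
# Vectorized annual step


def _stratum_occupancy(ls: Landscape,
                       pmap: Mapping[str, FunctionalGroupParams]) -> dict[int, np.ndarray]:
    """Per-stratum canopy occupancy grids (germinants cast no shade)."""
    occ = {s: np.zeros((ls.height, ls.width)) for s in range(1, 6)}
    for g, ages in ls.cohorts.items():
        p = pmap[g]
        for age, layer in ages.items():
            if age == 0:
                continue
            if age >= p.mature_age:
                occ[p.stratum_mature] += layer
            else:
                occ[p.stratum_immature] += p.size_class / 4.0 * layer
    return occ


def _resource_grids(ls: Landscape,
                    pmap: Mapping[str, FunctionalGroupParams]) -> dict[int, np.ndarray]:
    """Resource-level code grid (Resource values) for each stratum 1..5."""
    occ = _stratum_occupancy(ls, pmap)
    lo, hi = ABUNDANCE_THRESHOLDS
    grids = {}
    above = np.zeros((ls.height, ls.width))
    for s in range(5, 0, -1):
        res = np.full((ls.height, ls.width), int(Resource.HIGH), dtype=np.int8)
        res[above >= lo] = int(Resource.MEDIUM)
        res[above >= hi] = int(Resource.LOW)
        grids[s] = res
        above = above + occ[s]
    return grids


def annual_step(ls: Landscape,
                params: Sequence[FunctionalGroupParams] | Mapping[str, FunctionalGroupParams],
                scenario: GrazingScenario,
                year: int,
                rng: np.random.Generator) -> Landscape:
    """Advance the landscape by one year in place and return it."""
    pmap = params if isinstance(params, Mapping) else params_by_name(params)

    # (1) grazing disturbance
    graze_landscape(ls, pmap, scenario, rng)

    # (2) aging, promotion, senescence
    for g, ages in ls.cohorts.items():
        max_age = pmap[g].max_age
        ls.cohorts[g] = {age + 1: layer for age, layer in sorted(ages.items())
                         if age + 1 <= max_age}

    # (3) per-stratum resource levels
    res = _resource_grids(ls, pmap)

    # (4) survival pass
    for g, ages in ls.cohorts.items():
        p = pmap[g]
        for age, layer in ages.items():
            stage = p.stage_of(age)
            row = np.array(
                p.survival.germinant if stage == Stage.GERMINANT
                else p.survival.immature if stage == Stage.IMMATURE
                else p.survival.mature, dtype=float)
            layer *= row[res[p.stratum_of(age)]]

    # (5) seed production and dispersal.  Cohorts reduced below the local-
    # extinction threshold this year still shed their seed crop before being
    # culled at the end of the step (annuals in particular complete their
    # cycle in the year they are grazed down).
    for g in GROUPS:
        p = pmap[g]
        src_r, src_c, tgt_r, tgt_c, ok = _sample_landings(ls, p, rng)
        if ok.size and ok.any():
            np.add.at(ls.propagules[g], (tgt_r[ok], tgt_c[ok]), 1.0)

    # (6) germination of this year's seed rain (no multi-year seed bank)
    res1 = res[1]
    for g in GROUPS:
        p = pmap[g]
        pool = ls.propagules[g]
        if p.fecundity > 0 and pool.any():
            gfrac = np.array([level_to_fraction(v) for v in p.germination_rate])
            gsurv = np.array(p.survival.germinant, dtype=float)
            new = (gfrac[res1] * gsurv[res1]
                   * np.minimum(1.0, pool / p.fecundity) * (pool > 0))
            if new.any():
                layer = ls.cohorts[g].setdefault(0, np.zeros((ls.height, ls.width)))
                np.minimum(layer + new, 1.0, out=layer)
        pool[:] = 0.0

    ls.cap_group_abundance(pmap)
    ls.prune()
    return ls
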