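"""Grid state container, archetype initialization, summaries and grid I/O.

The landscape is a ``height x width`` lattice of square cells (10 m by
default).  Internally the state is stored group-wise as dense per-age
abundance grids, ``cohorts[group][age] -> (H, W) float array``, plus a
propagule (seed) pool per group.  Abundance is continuous in ``[0, 1]`` per
group and cell; the four ordinal abundance classes (absent / low / medium /
high) are a reporting view with thresholds 0, 0.33 and 0.66.

Coordinates are 0-based ``(row, col)``, row-major.  A cohort's life stage is
fully determined by its age (0 = germinant, then immature until the group's
mature age); :class:`Cohort` objects are a per-cell view used by the scalar
operations and the state file format.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources as _resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .params import (GROUPS, FunctionalGroupParams, ParamError, Stage,
                     params_by_name)

__all__ = [
    "ABUNDANCE_THRESHOLDS",
    "AbundanceClass",
    "Cohort",
    "Cell",
    "Landscape",
    "ArchetypeProfile",
    "load_archetypes",
    "abundance_class",
    "init_landscape",
    "landscape_abundance",
    "dominance_map",
    "dominance_colors",
    "render_dominance_png",
    "write_dominance_labels",
    "write_state",
    "read_state",
    "StateParseError",
]

#: Upper edges of the low and medium abundance classes.
ABUNDANCE_THRESHOLDS = (0.33, 0.66)

#: Local-extinction threshold: a per-cell cohort reduced below 5% cover by
#: the year's mortality cannot maintain itself and is removed at the end of
#: the annual step (after shedding any seed produced that year).
EXTINCTION_EPS = 0.05


class AbundanceClass(Enum):
    ABSENT = "absent"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


def abundance_class(x: float) -> AbundanceClass:
    """Ordinal abundance class of a continuous abundance in [0, 1]."""
    if x < 0 or x > 1:
        raise ValueError(f"abundance {x} outside [0, 1]")
    if x == 0:
        return AbundanceClass.ABSENT
    if x <= ABUNDANCE_THRESHOLDS[0]:
        return AbundanceClass.LOW
    if x <= ABUNDANCE_THRESHOLDS[1]:
        return AbundanceClass.MEDIUM
    return AbundanceClass.HIGH


@dataclass
class Cohort:
    """A same-aged population of one group in one cell."""

    group: str
    stage: Stage
    age: int
    abundance: float

    @classmethod
    def for_age(cls, group: str, age: int, abundance: float,
                params: FunctionalGroupParams) -> "Cohort":
        return cls(group, params.stage_of(age), age, abundance)


@dataclass
class Cell:
    """Per-cell view: cohorts plus the per-group propagule pool."""

    coords: tuple[int, int]
    cohorts: list[Cohort] = field(default_factory=list)
    seeds: dict[str, float] = field(default_factory=dict)

    def group_abundance(self, group: str) -> float:
        return min(1.0, sum(c.abundance for c in self.cohorts if c.group == group))


class Landscape:
    """W x H grid of cells holding per-group, per-age abundance layers."""

    def __init__(self, width: int = 100, height: int = 100, cell_size: float = 10.0):
        if width < 1 or height < 1:
            raise ValueError("grid dimensions must be >= 1")
        self.width = int(width)
        self.height = int(height)
        self.cell_size = float(cell_size)
        self.cohorts: dict[str, dict[int, np.ndarray]] = {g: {} for g in GROUPS}
        self.propagules: dict[str, np.ndarray] = {
            g: np.zeros((self.height, self.width)) for g in GROUPS
        }

    # -- basic properties ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def copy(self) -> "Landscape":
        other = Landscape(self.width, self.height, self.cell_size)
        other.cohorts = {g: {a: arr.copy() for a, arr in ages.items()}
                         for g, ages in self.cohorts.items()}
        other.propagules = {g: arr.copy() for g, arr in self.propagules.items()}
        return other

    # -- state editing ------------------------------------------------------

    def add_abundance(self, group: str, age: int, rc: tuple[int, int], value: float) -> None:
        """Saturating add of ``value`` into the (group, age) layer at one cell."""
        if group not in self.cohorts:
            raise KeyError(f"unknown group {group!r}")
        layer = self.cohorts[group].setdefault(age, np.zeros((self.height, self.width)))
        r, c = rc
        layer[r, c] = min(1.0, layer[r, c] + value)

    def group_total(self, group: str, *, include_germinants: bool = True) -> np.ndarray:
        """Per-cell total abundance of ``group`` over its cohort layers."""
        tot = np.zeros((self.height, self.width))
        for age, layer in self.cohorts[group].items():
            if not include_germinants and age == 0:
                continue
            tot += layer
        return tot

    def established(self, group: str) -> np.ndarray:
        """Per-cell established-plant abundance (immature + mature, age >= 1)."""
        return np.minimum(1.0, self.group_total(group, include_germinants=False))

    def prune(self) -> None:
        """Apply local extinction and drop all-zero layers."""
        for g, ages in self.cohorts.items():
            for age in list(ages):
                arr = ages[age]
                arr[arr < EXTINCTION_EPS] = 0.0
                if not arr.any():
                    del ages[age]

    def cap_group_abundance(self, params: Mapping[str, FunctionalGroupParams]) -> None:
        """Truncate cohort layers so each cell's per-group total <= maxab cap.

        Under the adopted reading maxab = 1 caps the continuous per-group
        abundance at 1.0.  Where the cap is exceeded the youngest cohorts
        are trimmed first: recruitment into a full cell fails rather than
        displacing standing plants.
        """
        for g, ages in self.cohorts.items():
            if not ages:
                continue
            cap = min(float(params[g].maxab) if g in params else 1.0, 1.0)
            if self.group_total(g).max() <= cap:
                continue
            taken = np.zeros((self.height, self.width))
            for age in sorted(ages, reverse=True):
                layer = ages[age]
                np.minimum(layer, np.clip(cap - taken, 0.0, None), out=layer)
                taken += layer

    # -- per-cell views -----------------------------------------------------

    def cell(self, r: int, c: int, params: Mapping[str, FunctionalGroupParams]) -> Cell:
        cohorts = []
        for g in GROUPS:
            for age in sorted(self.cohorts[g]):
                ab = float(self.cohorts[g][age][r, c])
                if ab > 0:
                    cohorts.append(Cohort.for_age(g, age, ab, params[g]))
        seeds = {g: float(self.propagules[g][r, c]) for g in GROUPS
                 if self.propagules[g][r, c] > 0}
        return Cell((r, c), cohorts, seeds)

    def set_cell(self, cell: Cell, params: Mapping[str, FunctionalGroupParams]) -> None:
        """Write a per-cell view back into the array state."""
        r, c = cell.coords
        for g in GROUPS:
            for layer in self.cohorts[g].values():
                layer[r, c] = 0.0
            self.propagules[g][r, c] = 0.0
        for co in cell.cohorts:
            self.add_abundance(co.group, co.age, (r, c), co.abundance)
        for g, n in cell.seeds.items():
            self.propagules[g][r, c] = n

    def iter_cohorts(self):
        """Yield (group, age, layer) over all stored layers, in fixed order."""
        for g in GROUPS:
            for age in sorted(self.cohorts[g]):
                yield g, age, self.cohorts[g][age]


# ---------------------------------------------------------------------------
# Archetype profiles and initialization


@dataclass(frozen=True)
class ArchetypeProfile:
    """Initialization target of one vegetation type.

    ``targets`` are landscape-mean established-plant abundances per group in
    percent; ``stage_mix`` gives per-group (propagule, immature, mature)
    fractions for occupied cells (``"default"`` applies to unlisted groups).
    """

    name: str
    targets: Mapping[str, float]
    stage_mix: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"default": (0.2, 0.3, 0.5)})
    abundance_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"default": (0.5, 1.0)})

    def mix_for(self, group: str) -> tuple[float, float, float]:
        mix = self.stage_mix.get(group, self.stage_mix.get("default", (0.2, 0.3, 0.5)))
        s = sum(mix)
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"stage mix for {group} sums to {s}, expected 1")
        return tuple(mix)  # type: ignore[return-value]

    def range_for(self, group: str) -> tuple[float, float]:
        lo, hi = self.abundance_range.get(
            group, self.abundance_range.get("default", (0.5, 1.0)))
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"abundance range ({lo}, {hi}) for {group} invalid")
        return lo, hi

    def validate(self) -> None:
        for g, pct in self.targets.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in profile {self.name!r}")
            if not 0 <= pct <= 100:
                raise ValueError(f"profile {self.name!r}: {g} target {pct}% outside [0, 100]")
            self.mix_for(g)
            self.range_for(g)


def load_archetypes(source=None) -> dict[int, ArchetypeProfile]:
    """Load the shipped (or a user) landscape-archetype catalogue."""
    if source is None:
        text = (_resources.files("steppesim") / "data" / "archetypes.yaml").read_text()
        doc = yaml.safe_load(text)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    out = {}
    for key, block in doc["archetypes"].items():
        mix = {k: tuple(v) for k, v in block.get("stage_mix", {}).items()}
        if "default" not in mix:
            mix["default"] = (0.2, 0.3, 0.5)
        rng_ = {k: tuple(v) for k, v in block.get("abundance_range", {}).items()}
        if "default" not in rng_:
            rng_["default"] = (0.5, 1.0)
        prof = ArchetypeProfile(name=block.get("name", f"landscape {key}"),
                                targets=dict(block["targets"]), stage_mix=mix,
                                abundance_range=rng_)
        prof.validate()
        out[int(key)] = prof
    return out


def _quantized_mature_ages(p: FunctionalGroupParams, n: int = 6) -> np.ndarray:
    """A small set of representative mature ages (keeps age layers few)."""
    hi = max(p.mature_age, p.max_age // 2)
    ages = np.unique(np.linspace(p.mature_age, hi, n).round().astype(int))
    return ages


def init_landscape(profile: ArchetypeProfile,
                   dims: tuple[int, int],
                   rng: np.random.Generator,
                   params: Sequence[FunctionalGroupParams] | Mapping[str, FunctionalGroupParams],
                   cell_size: float = 10.0) -> Landscape:
    """Randomly seed a landscape so group means match the archetype targets.

    For each group, cells are occupied independently with probability ``q``
    and occupied cells receive a single cohort with abundance drawn
    uniformly from the profile's per-group abundance range (default
    U(0.5, 1); annual herbs ship with a sparse range, standing for
    widespread thin populations rather than dense stands) at a stage drawn
    from the profile's stage mix.  ``q`` is chosen so that the expected
    landscape-mean established abundance equals the target:
    ``q * (1 - f_propagule) * mean_range = target / 100``.  Propagule-stage
    cells receive a seed pool of ``fecundity`` instead of a plant cohort.
    """
    if not isinstance(params, Mapping):
        params = params_by_name(params)
    profile.validate()
    width, height = dims
    ls = Landscape(width=width, height=height, cell_size=cell_size)
    for g in GROUPS:
        pct = float(profile.targets.get(g, 0.0))
        if pct < 0 or pct > 100:
            raise ValueError(f"target {pct}% for {g} outside [0, 100]")
        if pct == 0:
            continue
        p = params[g]
        mix = profile.mix_for(g)
        lo, hi = profile.range_for(g)
        mean_ab = (lo + hi) / 2.0
        f_est = mix[1] + mix[2]
        if f_est <= 0:
            raise ValueError(f"profile {profile.name!r}: {g} has no plant stages in mix")
        q = pct / 100.0 / (mean_ab * f_est)
        if q > 1.0:
            raise ValueError(
                f"profile {profile.name!r}: {g} target {pct}% unreachable with stage mix "
                f"{mix} and abundance range ({lo}, {hi}) (required occupancy {q:.2f} > 1)")
        occ = rng.random((height, width)) < q
        rr, cc = np.nonzero(occ)
        if rr.size == 0:
            continue
        stages = rng.choice(3, size=rr.size, p=mix)
        abund = rng.uniform(lo, hi, size=rr.size)
        # propagule cells: a seed pool sized to saturate first-year germination
        sel = stages == 0
        ls.propagules[g][rr[sel], cc[sel]] += p.fecundity
        # immature cells (groups maturing at age 1 have no immature ages)
        sel = stages == 1
        if p.mature_age > 1:
            imm_ages = rng.integers(1, p.mature_age, size=int(sel.sum()))
        else:
            imm_ages = np.full(int(sel.sum()), p.mature_age)
        for age in np.unique(imm_ages):
            pick = np.nonzero(sel)[0][imm_ages == age]
            layer = ls.cohorts[g].setdefault(int(age), np.zeros((height, width)))
            layer[rr[pick], cc[pick]] = abund[pick]
        # mature cells, ages quantized to keep the number of layers small
        sel = stages == 2
        choices = _quantized_mature_ages(p)
        mat_ages = rng.choice(choices, size=int(sel.sum()))
        for age in np.unique(mat_ages):
            pick = np.nonzero(sel)[0][mat_ages == age]
            layer = ls.cohorts[g].setdefault(int(age), np.zeros((height, width)))
            layer[rr[pick], cc[pick]] = abund[pick]
    ls.prune()
    return ls


# ---------------------------------------------------------------------------
# Summaries


def landscape_abundance(ls: Landscape, group: str) -> float:
    """Landscape abundance of ``group`` in percent.

    100 x the mean over all cells of the established-plant (immature +
    mature) continuous abundance; germinants and propagules do not count
    toward standing vegetation.
    """
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}")
    return 100.0 * float(ls.established(group).mean())


def dominance_map(ls: Landscape,
                  params: Mapping[str, FunctionalGroupParams] | None = None) -> np.ndarray:
    """Per-cell index of the dominant group (-1 = empty).

    The dominant group holds the maximal established abundance; ties are
    broken by the taller mature stratum, then by fixed group order.  The
    returned integer grid indexes into :data:`steppesim.params.GROUPS`.
    """
    if params is None:
        from .params import default_params
        params = params_by_name(default_params())
    stacked = np.stack([ls.established(g) for g in GROUPS])
    # order groups by (stratum_mature desc, canonical order asc); argmax picks
    # the first maximum, which then realizes the tie-break exactly
    order = sorted(range(len(GROUPS)),
                   key=lambda i: (-params[GROUPS[i]].stratum_mature, i))
    reordered = stacked[order]
    best = np.argmax(reordered, axis=0)
    idx = np.array(order)[best]
    empty = stacked.sum(axis=0) == 0
    out = idx.astype(int)
    out[empty] = -1
    return out


def dominance_colors() -> dict[int, str]:
    """Map colors: green trees, red subshrubs, purple spiny subshrubs,
    orange forbs, blue gramineae, gray annuals, white empty."""
    palette = {
        "tree": "#2a9d2a",
        "non_spiny_subshrub": "#d62728",
        "spiny_subshrub": "#8a2be2",
        "perennial_forb": "#ff8c00",
        "perennial_gramineae": "#1f6fd6",
        "annual_herb": "#9a9a9a",
    }
    colors = {-1: "#ffffff"}
    colors.update({i: palette[g] for i, g in enumerate(GROUPS)})
    return colors


def render_dominance_png(dom: np.ndarray, path) -> None:
    """Write a bird's-eye dominance map as a PNG image."""
    from matplotlib import colors as mcolors
    from matplotlib import pyplot as plt

    cmap_colors = [dominance_colors()[i] for i in range(-1, len(GROUPS))]
    cmap = mcolors.ListedColormap(cmap_colors)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(dom + 1, cmap=cmap, vmin=0, vmax=len(GROUPS), interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def write_dominance_labels(dom: np.ndarray, path) -> None:
    """Write the dominance map as a delimited label matrix ('' = empty)."""
    labels = np.where(dom >= 0, np.array(list(GROUPS) + [""])[dom], "")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for row in labels:
            writer.writerow(row.tolist())


# ---------------------------------------------------------------------------
# Grid state I/O


class StateParseError(ValueError):
    """Malformed landscape state file; carries the offending line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


_STATE_HEADER = ["row", "col", "group", "stage", "age", "abundance"]


def write_state(ls: Landscape, path) -> None:
    """Write the full grid state as headered tab-separated text.

    One row per cohort (row, col, group, stage, age, abundance); propagule
    pools appear as stage ``propagule`` rows whose abundance column carries
    the seed count.  A leading comment line records dimensions and cell size.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# landscape width={ls.width} height={ls.height} cell_size={ls.cell_size}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_STATE_HEADER)
        from .params import default_params
        pmap = params_by_name(default_params())
        for g, age, layer in ls.iter_cohorts():
            stage = pmap[g].stage_of(age).name.lower()
            rr, cc = np.nonzero(layer)
            for r, c in zip(rr.tolist(), cc.tolist()):
                writer.writerow([r, c, g, stage, age, repr(float(layer[r, c]))])
        for g in GROUPS:
            rr, cc = np.nonzero(ls.propagules[g])
            for r, c in zip(rr.tolist(), cc.tolist()):
                writer.writerow([r, c, g, "propagule", -1,
                                 repr(float(ls.propagules[g][r, c]))])


def read_state(path) -> Landscape:
    """Read a landscape written by :func:`write_state` (lossless round-trip)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# landscape"):
            raise StateParseError(1, "missing '# landscape ...' header comment")
        try:
            meta = dict(tok.split("=") for tok in first.split()[2:])
            ls = Landscape(width=int(meta["width"]), height=int(meta["height"]),
                           cell_size=float(meta["cell_size"]))
        except (KeyError, ValueError) as exc:
            raise StateParseError(1, f"bad header: {exc}") from None
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _STATE_HEADER:
            raise StateParseError(2, f"expected header {_STATE_HEADER}, got {header}")
        for lineno, rowvals in enumerate(reader, start=3):
            if not rowvals:
                continue
            if len(rowvals) != 6:
                raise StateParseError(lineno, f"expected 6 fields, got {len(rowvals)}")
            try:
                r, c = int(rowvals[0]), int(rowvals[1])
                g = rowvals[2]
                stage = rowvals[3]
                age = int(rowvals[4])
                ab = float(rowvals[5])
            except ValueError as exc:
                raise StateParseError(lineno, str(exc)) from None
            if g not in GROUPS:
                raise StateParseError(lineno, f"unknown group {g!r}")
            if not (0 <= r < ls.height and 0 <= c < ls.width):
                raise StateParseError(lineno, f"cell ({r}, {c}) outside grid")
            if stage == "propagule":
                ls.propagules[g][r, c] = ab
            else:
                layer = ls.cohorts[g].setdefault(age, np.zeros((ls.height, ls.width)))
                layer[r, c] = ab
    return ls
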