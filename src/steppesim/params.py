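"""Functional-group parameterization for the steppe vegetation simulator.

Six plant functional groups (growth forms) drive the dynamics: resprouter
tree, non-spiny subshrub, spiny subshrub, perennial forb, perennial
gramineae, and annual herb.  Each group is described by a bundle of
life-history, dispersal, germination/survival, and grazing-response
parameters.  Most responses are coded on ordinal scales:

* a five-level scale ``0..4`` (none / low / half-medium / high-most / all)
  used for germination rates, kill and resprout levels, propagule kill and
  post-disturbance seedling emergence;
* a binary survival matrix over three life stages (germinant, immature,
  mature) crossed with three resource levels (low, medium, high).

The packaged default configuration (``data/functional_groups.yaml``) holds
the full parameterization of the six Central Anatolian steppe growth forms.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources as _resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "GROUPS",
    "GROUP_LABELS",
    "Resource",
    "Stage",
    "ParamError",
    "DispersalSpec",
    "SurvivalMatrix",
    "DisturbanceResponse",
    "FunctionalGroupParams",
    "level_to_fraction",
    "level_label",
    "age_class_of",
    "load_params",
    "default_params",
    "save_params",
    "params_by_name",
    "monotonicity_violations",
]

#: Canonical group identifiers, in the fixed order used for tie-breaking.
GROUPS: tuple[str, ...] = (
    "tree",
    "non_spiny_subshrub",
    "spiny_subshrub",
    "perennial_forb",
    "perennial_gramineae",
    "annual_herb",
)

#: Human-readable names for reports and figures.
GROUP_LABELS: Mapping[str, str] = {
    "tree": "resprouter tree",
    "non_spiny_subshrub": "non-spiny subshrub",
    "spiny_subshrub": "spiny subshrub",
    "perennial_forb": "perennial forb",
    "perennial_gramineae": "perennial gramineae",
    "annual_herb": "annual herb",
}

_LEVEL_LABELS = ("none", "low", "medium", "high", "all")


class Resource(IntEnum):
    """Ordinal resource (light) availability within a stratum."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


class Stage(IntEnum):
    """Ordered life stages of a cohort."""

    PROPAGULE = 0
    GERMINANT = 1
    IMMATURE = 2
    MATURE = 3


class ParamError(ValueError):
    """Validation failure in a functional-group parameter bundle."""

    def __init__(self, group: str | None, fld: str, message: str):
        self.group = group
        self.field = fld
        where = f"group {group!r}, field {fld!r}" if group else f"field {fld!r}"
        super().__init__(f"{where}: {message}")


def level_to_fraction(level: int) -> float:
    """Map an ordinal five-point level (0..4) to a fraction in [0, 1].

    The verbal scale none/few/half/most/all anchors 0, 0.25, 0.5, 0.75, 1.
    """
    if not isinstance(level, (int,)) or isinstance(level, bool):
        raise ParamError(None, "level", f"ordinal level must be an integer, got {level!r}")
    if not 0 <= level <= 4:
        raise ParamError(None, "level", f"ordinal level must be in 0..4, got {level}")
    return level / 4.0


def level_label(level: int) -> str:
    """Verbal label of an ordinal five-point level."""
    level_to_fraction(level)  # validate
    return _LEVEL_LABELS[level]


def age_class_of(age: int, breakpoints: Sequence[int]) -> int:
    """Return the grazing-response age class of ``age``.

    Classes are half-open on the right: ``[0, b1), [b1, b2), [b2, inf)``,
    i.e. the smallest ``i`` with ``age < breakpoints[i]``, or
    ``len(breakpoints)`` when no breakpoint exceeds ``age``.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    bp = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
        raise ValueError(f"breakpoints must be strictly increasing, got {bp}")
    return bisect.bisect_right(bp, age)


def _check_level(group: str, fld: str, value: int, lo: int = 0, hi: int = 4) -> int:
    if not isinstance(value, int) or isinstance(value, bool):
        raise ParamError(group, fld, f"expected integer ordinal level, got {value!r}")
    if not lo <= value <= hi:
        raise ParamError(group, fld, f"ordinal level {value} outside {lo}..{hi}")
    return value


@dataclass(frozen=True)
class DispersalSpec:
    """Three-band seed dispersal kernel.

    ``rates`` are the ordinal capacities (0..3) of the short, medium and long
    band; ``limits`` are the outer edges of the three bands in meters;
    ``k_disp`` are the two constants shaping the exponential decay of the
    long band (onset steepness, tail scale in meters).
    """

    rates: tuple[int, int, int]
    k_disp: tuple[float, float]
    limits: tuple[float, float, float]

    def validate(self, group: str) -> None:
        for name, r in zip(("short", "medium", "long"), self.rates):
            _check_level(group, f"dispersal.{name}", r, 0, 3)
        if len(self.limits) != 3 or not (0 < self.limits[0] < self.limits[1] < self.limits[2]):
            raise ParamError(group, "dispersal.limits",
                             f"limits must be three strictly increasing distances, got {self.limits}")
        if len(self.k_disp) != 2 or any(k <= 0 for k in self.k_disp):
            raise ParamError(group, "dispersal.k_disp",
                             f"k_disp must be a pair of positive reals, got {self.k_disp}")

    def band_weights(self) -> tuple[float, float, float]:
        """Unnormalized probability weights of the three distance bands."""
        return tuple(level_to_fraction(r) for r in self.rates)  # type: ignore[return-value]


@dataclass(frozen=True)
class SurvivalMatrix:
    """Nine boolean entries: (germinant, immature, mature) x (low, medium, high)."""

    germinant: tuple[bool, bool, bool]
    immature: tuple[bool, bool, bool]
    mature: tuple[bool, bool, bool]

    def validate(self, group: str) -> None:
        for stage_name in ("germinant", "immature", "mature"):
            row = getattr(self, stage_name)
            if len(row) != 3 or not all(isinstance(v, bool) for v in row):
                raise ParamError(group, f"survival.{stage_name}",
                                 f"expected three booleans, got {row!r}")

    def survives(self, stage: Stage, resource: Resource) -> bool:
        if stage == Stage.GERMINANT:
            return self.germinant[resource]
        if stage == Stage.IMMATURE:
            return self.immature[resource]
        if stage == Stage.MATURE:
            return self.mature[resource]
        raise ValueError(f"no survival entry for stage {stage!r}")


@dataclass(frozen=True)
class DisturbanceResponse:
    """Grazing response of one group, by age class.

    ``age_breakpoints`` partition ages into 2-3 half-open classes (see
    :func:`age_class_of`).  Per class: ``kill`` is the ordinal fraction of
    non-resprouting individuals removed by one grazing event; ``resprout``
    the ordinal fraction of the cohort that regenerates vegetatively, its
    shoots re-entering at functional age ``respage`` (-1 = the group never
    resprouts).  ``propkill`` reduces the propagule pool and ``seed_broken``
    is a post-disturbance germination stimulus (both zero for all steppe
    groups).
    """

    age_breakpoints: tuple[int, ...]
    seed_broken: int
    propkill: int
    kill: tuple[int, ...]
    resprout: tuple[int, ...]
    respage: tuple[int, ...]

    def validate(self, group: str, max_age: int) -> None:
        if not 1 <= len(self.age_breakpoints) <= 2:
            raise ParamError(group, "disturbance.age_breakpoints",
                             f"expected 1-2 breakpoints, got {self.age_breakpoints}")
        if any(b2 <= b1 for b1, b2 in zip(self.age_breakpoints, self.age_breakpoints[1:])):
            raise ParamError(group, "disturbance.age_breakpoints",
                             f"breakpoints must be strictly increasing, got {self.age_breakpoints}")
        n = len(self.age_breakpoints) + 1
        for fld in ("kill", "resprout", "respage"):
            tup = getattr(self, fld)
            if len(tup) != n:
                raise ParamError(group, f"disturbance.{fld}",
                                 f"length {len(tup)} does not match {n} age classes "
                                 f"(breakpoints {self.age_breakpoints})")
        for i, k in enumerate(self.kill):
            _check_level(group, f"disturbance.kill[{i}]", k)
        for i, r in enumerate(self.resprout):
            _check_level(group, f"disturbance.resprout[{i}]", r)
        for i, a in enumerate(self.respage):
            if a < -1 or a >= max_age:
                raise ParamError(group, f"disturbance.respage[{i}]",
                                 f"respage {a} must be -1 or in [0, max_age={max_age})")
        _check_level(group, "disturbance.seed_broken", self.seed_broken)
        _check_level(group, "disturbance.propkill", self.propkill)

    @property
    def n_classes(self) -> int:
        return len(self.age_breakpoints) + 1


@dataclass(frozen=True)
class FunctionalGroupParams:
    """Complete parameter bundle for one plant functional group."""

    name: str
    maxab: int
    mature_age: int
    max_age: int
    size_class: int
    stratum_immature: int
    stratum_mature: int
    dispersal: DispersalSpec
    fecundity: int
    germination_rate: tuple[int, int, int]  # indexed by Resource
    survival: SurvivalMatrix
    disturbance: DisturbanceResponse

    def __post_init__(self):
        g = self.name
        if g not in GROUPS:
            raise ParamError(g, "name", f"unknown group; expected one of {GROUPS}")
        if not 1 <= self.maxab <= 3:
            raise ParamError(g, "maxab", f"maxab {self.maxab} outside 1..3")
        if self.mature_age < 1:
            raise ParamError(g, "mature_age", "mature_age must be >= 1")
        if not self.mature_age < self.max_age:
            raise ParamError(g, "max_age",
                             f"mature_age {self.mature_age} must be < max_age {self.max_age}")
        if not 1 <= self.size_class <= 4:
            raise ParamError(g, "size_class", f"size_class {self.size_class} outside 1..4")
        for fld in ("stratum_immature", "stratum_mature"):
            s = getattr(self, fld)
            if not 1 <= s <= 5:
                raise ParamError(g, fld, f"stratum {s} outside 1..5")
        if self.stratum_immature > self.stratum_mature:
            raise ParamError(g, "stratum_immature",
                             "immature stratum cannot exceed mature stratum")
        if self.fecundity < 0:
            raise ParamError(g, "fecundity", "fecundity must be >= 0")
        for i, lev in enumerate(self.germination_rate):
            _check_level(g, f"germination_rate[{i}]", lev)
        self.dispersal.validate(g)
        self.survival.validate(g)
        self.disturbance.validate(g, self.max_age)

    def stage_of(self, age: int) -> Stage:
        """Life stage implied by ``age``: 0 = germinant, then immature, mature."""
        if age < 0:
            raise ValueError("age must be non-negative")
        if age == 0:
            return Stage.GERMINANT
        if age < self.mature_age:
            return Stage.IMMATURE
        return Stage.MATURE

    def stratum_of(self, age: int) -> int:
        """Stratum occupied at ``age``; germinants sit in stratum 1."""
        stage = self.stage_of(age)
        if stage == Stage.GERMINANT:
            return 1
        if stage == Stage.IMMATURE:
            return self.stratum_immature
        return self.stratum_mature


# ---------------------------------------------------------------------------
# Serialization


def _require(block: Mapping, group: str, key: str, label: str | None = None):
    if key not in block:
        raise ParamError(group, label or key, "missing field")
    return block[key]


def _group_from_dict(name: str, block: Mapping) -> FunctionalGroupParams:
    disp = _require(block, name, "dispersal")
    rates = _require(disp, name, "rates", "dispersal.rates")
    surv = _require(block, name, "survival")
    dist = _require(block, name, "disturbance")
    germ = _require(block, name, "germination_rate")
    strat = _require(block, name, "stratum")

    def _bools(row) -> tuple[bool, bool, bool]:
        return tuple(bool(v) for v in row)  # type: ignore[return-value]

    return FunctionalGroupParams(
        name=name,
        maxab=int(_require(block, name, "maxab")),
        mature_age=int(_require(block, name, "mature_age")),
        max_age=int(_require(block, name, "max_age")),
        size_class=int(_require(block, name, "size_class")),
        stratum_immature=int(_require(strat, name, "immature", "stratum.immature")),
        stratum_mature=int(_require(strat, name, "mature", "stratum.mature")),
        dispersal=DispersalSpec(
            rates=(int(rates["short"]), int(rates["medium"]), int(rates["long"])),
            k_disp=tuple(float(k) for k in _require(disp, name, "k_disp")),
            limits=tuple(float(x) for x in _require(disp, name, "limits")),
        ),
        fecundity=int(_require(block, name, "fecundity")),
        germination_rate=(int(germ["low"]), int(germ["medium"]), int(germ["high"])),
        survival=SurvivalMatrix(
            germinant=_bools(_require(surv, name, "germinant", "survival.germinant")),
            immature=_bools(_require(surv, name, "immature", "survival.immature")),
            mature=_bools(_require(surv, name, "mature", "survival.mature")),
        ),
        disturbance=DisturbanceResponse(
            age_breakpoints=tuple(int(b) for b in _require(dist, name, "age_breakpoints", "disturbance.age_breakpoints")),
            seed_broken=int(_require(dist, name, "seed_broken", "disturbance.seed_broken")),
            propkill=int(_require(dist, name, "propkill", "disturbance.propkill")),
            kill=tuple(int(k) for k in _require(dist, name, "kill", "disturbance.kill")),
            resprout=tuple(int(r) for r in _require(dist, name, "resprout", "disturbance.resprout")),
            respage=tuple(int(a) for a in _require(dist, name, "respage", "disturbance.respage")),
        ),
    )


def load_params(source=None) -> list[FunctionalGroupParams]:
    """Load functional-group parameters from a YAML document.

    ``source`` may be a path, an open text stream, or ``None`` for the
    packaged default configuration.  Returns one validated bundle per group,
    in canonical group order.
    """
    if source is None:
        text = (_resources.files("steppesim") / "data" / "functional_groups.yaml").read_text()
        doc = yaml.safe_load(text)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "groups" not in doc:
        raise ParamError(None, "groups", "config must contain a top-level 'groups' mapping")
    blocks = doc["groups"]
    out = []
    for name in sorted(blocks, key=lambda n: GROUPS.index(n) if n in GROUPS else 99):
        out.append(_group_from_dict(name, blocks[name]))
    return out


def default_params() -> list[FunctionalGroupParams]:
    """The packaged default parameterization of the six steppe growth forms."""
    return load_params(None)


def params_by_name(params: Iterable[FunctionalGroupParams]) -> dict[str, FunctionalGroupParams]:
    return {p.name: p for p in params}


def _group_to_dict(p: FunctionalGroupParams) -> dict:
    return {
        "maxab": p.maxab,
        "mature_age": p.mature_age,
        "max_age": p.max_age,
        "size_class": p.size_class,
        "stratum": {"immature": p.stratum_immature, "mature": p.stratum_mature},
        "dispersal": {
            "rates": {"short": p.dispersal.rates[0], "medium": p.dispersal.rates[1],
                      "long": p.dispersal.rates[2]},
            "k_disp": list(p.dispersal.k_disp),
            "limits": list(p.dispersal.limits),
        },
        "fecundity": p.fecundity,
        "germination_rate": {"low": p.germination_rate[0], "medium": p.germination_rate[1],
                             "high": p.germination_rate[2]},
        "survival": {
            "germinant": list(p.survival.germinant),
            "immature": list(p.survival.immature),
            "mature": list(p.survival.mature),
        },
        "disturbance": {
            "age_breakpoints": list(p.disturbance.age_breakpoints),
            "seed_broken": p.disturbance.seed_broken,
            "propkill": p.disturbance.propkill,
            "kill": list(p.disturbance.kill),
            "resprout": list(p.disturbance.resprout),
            "respage": list(p.disturbance.respage),
        },
    }


def save_params(params: Iterable[FunctionalGroupParams], path) -> None:
    """Serialize parameter bundles to YAML (round-trips with :func:`load_params`)."""
    doc = {"groups": {p.name: _group_to_dict(p) for p in params}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def monotonicity_violations(params: Iterable[FunctionalGroupParams]) -> list[str]:
    """Report survival/germination entries that decrease with resource level.

    For every steppe group both survival (per stage) and germination rate are
    non-decreasing from low to high resources; this is a consistency check on
    a parameterization, not a hard constraint of the types.
    """
    bad = []
    for p in params:
        for stage_name in ("germinant", "immature", "mature"):
            row = [int(v) for v in getattr(p.survival, stage_name)]
            if any(b < a for a, b in zip(row, row[1:])):
                bad.append(f"{p.name}: survival.{stage_name} {row}")
        g = p.germination_rate
        if any(b < a for a, b in zip(g, g[1:])):
            bad.append(f"{p.name}: germination_rate {list(g)}")
    return bad
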