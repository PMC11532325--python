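"""Synthetic phytosociological dataset generator.

Emulates the statistical structure of a regional relevé compilation —
alliances drawn around vegetation-type archetypes, relevés sampling species
of six growth forms on the Braun-Blanquet scale — so that the full
aggregation and clustering pipeline can be exercised and tested without any
field data.  Species are synthetic tokens (growth-form prefix + index); no
attempt is made to mimic real floristic composition or spatial structure.

The default specification mirrors the scale of the regional compilation the
landscape archetypes are built from: 58 alliances in 5 vegetation types and
668 relevés in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import GROUPS
from .releves import BB_CODES, RELEVE_COLUMNS, percent_to_bb

__all__ = ["GeneratorSpec", "STAND_PROFILES", "default_spec", "generate_releves"]

_CODES_ASC = ["r", "+", "1", "2", "3", "4", "5"]

#: Plot-scale (stand) growth-form cover profiles of the five vegetation
#: types.  Relevés are laid out inside vegetated stands, so covers of the
#: characteristic groups run well above the landscape-mean abundances used
#: to initialize simulation grids (landscape mean = stand cover x
#: prevalence of the stand type across the landscape).
STAND_PROFILES: tuple[Mapping[str, float], ...] = (
    {"tree": 55, "perennial_gramineae": 20, "perennial_forb": 15,
     "non_spiny_subshrub": 5, "spiny_subshrub": 5, "annual_herb": 5},
    {"tree": 15, "perennial_gramineae": 30, "perennial_forb": 20,
     "non_spiny_subshrub": 20, "spiny_subshrub": 12, "annual_herb": 8},
    {"tree": 0, "perennial_gramineae": 45, "perennial_forb": 35,
     "non_spiny_subshrub": 30, "spiny_subshrub": 8, "annual_herb": 12},
    {"tree": 0, "perennial_gramineae": 10, "perennial_forb": 8,
     "non_spiny_subshrub": 30, "spiny_subshrub": 5, "annual_herb": 5},
    {"tree": 0, "perennial_gramineae": 18, "perennial_forb": 12,
     "non_spiny_subshrub": 12, "spiny_subshrub": 45, "annual_herb": 6},
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Layout and noise model of a synthetic relevé dataset.

    ``archetypes`` are per-type growth-form mean covers (percent).
    ``n_alliances`` gives the number of alliances per archetype;
    ``n_releves`` the number of relevés per alliance (scalar or one entry
    per alliance, flattened over archetypes).  ``noise_sd`` is the standard
    deviation (percent scale) of the within-alliance Gaussian jitter of
    relevé covers around the alliance target; ``alliance_sd`` scatters the
    alliance targets themselves around the archetype means.  All covers are
    truncated to [0, 100].
    """

    archetypes: Sequence[Mapping[str, float]]
    n_alliances: Sequence[int]
    n_releves: int | Sequence[int] = 12
    species_pool: int = 8
    noise_sd: float = 5.0
    alliance_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if len(self.archetypes) != len(self.n_alliances):
            raise ValueError("need one alliance count per archetype")
        if any(n < 1 for n in self.n_alliances):
            raise ValueError("alliance counts must be positive")
        if self.noise_sd < 0 or self.alliance_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.species_pool < 1:
            raise ValueError("species_pool must be positive")

    @property
    def total_alliances(self) -> int:
        return int(sum(self.n_alliances))

    def releves_per_alliance(self) -> list[int]:
        if isinstance(self.n_releves, int):
            return [self.n_releves] * self.total_alliances
        counts = list(self.n_releves)
        if len(counts) != self.total_alliances:
            raise ValueError("per-alliance relevé counts must match alliance total")
        return counts


def default_spec(seed: int = 0, noise_sd: float = 5.0) -> GeneratorSpec:
    """Five-archetype spec at the regional compilation's scale.

    58 alliances split 12/12/12/11/11 over the five stand-scale vegetation
    type profiles; 668 relevés total (the first 30 alliances carry 12
    relevés, the remaining 28 carry 11: 30*12 + 28*11 = 668).
    """
    n_alliances = [12, 12, 12, 11, 11]
    total = sum(n_alliances)
    releves = [12 if i < 30 else 11 for i in range(total)]
    return GeneratorSpec(archetypes=STAND_PROFILES, n_alliances=n_alliances,
                         n_releves=releves, noise_sd=noise_sd, seed=seed)


def _codes_up_to(code: str) -> list[str]:
    return _CODES_ASC[: _CODES_ASC.index(code) + 1]


def generate_releves(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a relevé table plus its ground-truth sidecar.

    Per alliance, growth-form target covers are the archetype means plus
    truncated Gaussian scatter (``alliance_sd``).  Per relevé, each growth
    form's realized cover jitters around the alliance target by the
    within-alliance noise; a growth form with a nonzero cover contributes a
    random subset of its species pool, one species carrying the
    Braun-Blanquet code of the realized cover (so the per-group maximum
    recovers it up to code discretization) and the others codes no larger.
    Averaging the relevé maxima per alliance therefore recovers the
    alliance targets up to discretization and sampling error.

    Returns ``(releves, truth)`` where ``truth`` maps each alliance to its
    generating archetype index (0-based).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    rel_counts = spec.releves_per_alliance()
    alliance_no = 0
    for arch_idx, arch in enumerate(spec.archetypes):
        for _ in range(spec.n_alliances[arch_idx]):
            alliance_id = f"A{alliance_no + 1:03d}"
            truth_rows.append({"alliance_id": alliance_id, "archetype": arch_idx})
            targets = {}
            for g in GROUPS:
                base = float(arch.get(g, 0.0))
                t = base + rng.normal(0.0, spec.alliance_sd) if spec.alliance_sd > 0 else base
                targets[g] = float(np.clip(t, 0.0, 100.0))
            n_rel = rel_counts[alliance_no]
            for j in range(n_rel):
                releve_id = f"{alliance_id}R{j + 1:02d}"
                for g in GROUPS:
                    cover = targets[g]
                    if spec.noise_sd > 0:
                        cover = float(np.clip(cover + rng.normal(0.0, spec.noise_sd),
                                              0.0, 100.0))
                    code = percent_to_bb(cover)
                    if code is None:
                        continue
                    n_sp = int(rng.integers(1, min(spec.species_pool, 4) + 1))
                    sp_idx = rng.choice(spec.species_pool, size=n_sp, replace=False)
                    lower = _codes_up_to(code)
                    for rank, si in enumerate(sp_idx):
                        sp_code = code if rank == 0 else lower[rng.integers(len(lower))]
                        rows.append({
                            "releve_id": releve_id,
                            "alliance_id": alliance_id,
                            "species": f"{g}_sp{si + 1}",
                            "growth_form": g,
                            "bb_code": sp_code,
                        })
            alliance_no += 1
    releves = pd.DataFrame(rows, columns=RELEVE_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return releves, truth
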