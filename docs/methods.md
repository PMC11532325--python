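# Model description and methods

This note documents the model implemented in `steppesim`: its state
variables, the annual cycle, the parameter semantics, the initialization
and scenario conventions, the synthetic data generator, and the numerical
choices made where the design was genuinely open.  It states no empirical
result that the test suite does not itself compute.

## State and scales

The landscape is a `height × width` grid (default 100 × 100) of square
cells (default 10 m), holding per functional group a set of cohorts.  A
cohort is a same-aged population of one group in one cell with a continuous
abundance (cover fraction) in [0, 1].  Life stage is a function of age:
age 0 is the germinant (first-year seedling) stage, ages below the group's
maturity age are immature, and all older ages are mature.  Propagules
(seeds) are not cohorts; they live in a per-group, per-cell seed pool that
exists only within a year (there is no multi-year seed bank — the two
parameters that would make one matter, propagule kill and post-disturbance
seedling emergence, are zero for every group in the shipped
parameterization).

Two ordinal scales recur throughout:

* the five-level response scale *none / few–low / half–medium / most–high /
  all*, mapped linearly to fractions 0, 0.25, 0.5, 0.75, 1 ("half" anchors
  0.5 and the scale is symmetric);
* the four-level abundance reporting scale *absent / low / medium / high*
  with thresholds 0, 0.33, 0.66 on the continuous cover.

Reported **landscape abundance** of a group is 100 × the mean over cells of
its *established* cover — the summed abundance of immature and mature
cohorts, capped at 1.  Germinants are excluded deliberately: they are a
transient recruitment pulse recreated every year wherever seeds land, and
counting them would systematically inflate any group with nonzero
germination everywhere (most visibly the perennial gramineae, whose
standing abundance is observed to be grazing-stable).  Dominance maps use
the same established cover; ties are broken by the taller mature stratum,
then by a fixed group order.

## The annual cycle

Sub-steps run in a fixed order: grazing → aging → resource computation →
survival → seed production and dispersal → germination → abundance cap →
local extinction.  The ordering is a design choice (the annual time step is
given; the intra-year order is not); its main observable consequences are
that disturbance acts on the previous year's state and that plants grazed
down during a year still shed that year's seed crop before being culled —
which is how annual herbs, whose adults are heavily grazed, persist under
overgrazing, exactly as short-lived seeders do in the field.

### Light competition

Each cell has five canopy strata.  A cohort occupies stratum 1 as a
germinant, its group's immature stratum as an immature, and its group's
mature stratum as an adult.  The shading score above stratum *s* is the sum
over cohorts in strata strictly greater than *s* of abundance × weight,
with weight 1 for matures and `size_class / 4` for immatures (the size
trait is the height of immatures relative to adults).  Scores below
0.33 leave the resource level high, below 0.66 medium, otherwise low —
mirroring the abundance-class thresholds, for want of any stated
alternative.  Equal-height vegetation does not shade itself; only strictly
taller plants pre-empt light.  Germinants cast no shade.

### Survival, aging, senescence

Survival is a Boolean lookup per (stage, resource level); a failing cohort
is removed whole.  Aging adds a year and promotes stages; a cohort older
than its group's lifespan is removed.  Resource levels are evaluated once
per year, after aging and before the survival pass.

### Seed production and dispersal

Every mature cohort emits a fixed number of seeds per year (the fecundity
trait) regardless of its abundance — the number of cohorts, not their
cover, sets propagule pressure.  Each seed samples:

1. a **band** — short, medium, long — with probability proportional to the
   ordinal band capacities (a group with all capacities zero produces seeds
   that are never placed);
2. a **distance** — uniform on [0, l₁) in the short band, uniform on
   [l₁, l₂) in the medium band; in the long band the density decays
   exponentially beyond l₂ with an onset scale k₂/k₁ and a tail scale k₂
   (a sum of two exponentials, truncated at l₃ by resampling) — one
   concrete reading of "rate of decrease of the dispersal curve from the
   medium distance onward" that uses both printed constants;
3. a **direction** uniform on the circle.

The landing cell is the cell containing the sampled point from the source
cell center; seeds leaving the grid are lost (the landscape is a bounded
1 km² site, not a torus).  Dispersal is the model's only stochastic
element; a run seed pins it exactly, and replaying a configuration
reproduces every output bit for bit.

### Germination

A cell's seed pool converts to a germinant cohort with abundance =
(germination fraction at the ground-level resource) × min(1, seeds /
fecundity).  If germinants of the group cannot survive at that resource
level, no cohort is created.  The pool is then cleared.

### Abundance cap and local extinction

Per group and cell, total abundance is capped at 1 (the shipped
parameterization sets every group's maximum within-cell abundance to the
lowest class, read as a cap of 1.0 on the continuous scale).  When the cap
is exceeded the youngest cohorts are trimmed first: recruitment into a full
stand fails rather than displacing established plants.

A per-cell cohort reduced below 0.05 (5% cover) is removed at the end of
the year: a population that small cannot maintain itself.  This threshold
is what makes "completely lost after 50 years" an exact zero rather than an
asymptote, and what prevents repeatedly browsed trace cohorts of juvenile
trees from limping to maturity through decades of grazing.  Its companion
rule lives in the grazing operator (below).

## Grazing

Three regimes: **none** (grazing excluded), **moderate** (one event per
year on 60% of cells, drawn uniformly anew each year), **overgrazing**
(four events per year on every cell, standing for livestock at about four
times carrying capacity).  The encoding of regime intensity as spatial
extent × event multiplicity is one consistent choice among several the
source material does not distinguish; the moderate extent is the model's
calibration knob and was set so that the qualitative regime contrasts hold
(at lower extents, enough juvenile trees escape browsing that the canopy
closes even under moderate grazing).

A grazing event transforms each cohort through its response age class *c*
(half-open classes over the age breakpoints; a breakpoint age belongs to
the older class):

* a fraction `resprout[c]` regenerates vegetatively: it survives and
  re-enters at functional age `respage[c]` (no resprouting when
  `respage[c]` is −1);
* of the remainder, a fraction `kill[c]` (plus any scenario severity
  shift, clamped to the scale) is killed; the rest is untouched;
* the propagule pool is reduced by the propagule-kill fraction and a
  germination pulse proportional to the seedling-emergence parameter would
  be scheduled — both are zero for every steppe group, so these terms are
  inert.

Resprouting is deliberately *not* a subset of the killed abundance: a
resprouter regenerates from surviving tissue, so the resprout fraction
survives with its age reset.  This is the only reading under which
resprouter gramineae — lifespan 5 years, no kill but high resprouting in
the adult class — persist indefinitely under annual grazing: each event
resets most adult shoots to functional age 2, so the population cycles
below its senescence age while its abundance is conserved.  Under the
alternative (resprout ⊆ killed) they would be unable to reset age, senesce
within five years, and vanish under exactly the grazing pressure they are
observed to withstand.  Grazing never increases a group's total abundance
in a cell.

One numerical companion rule: when an event leaves the non-resprouting
remainder of a resprouting cohort below the extinction threshold, the
remainder is consolidated into the resprout transfer.  The distinction
between "escaped" and "resprouted" shoots is below the model's abundance
resolution at that point; without the rule, the 0.25⁴ unresprouted residue
of four annual events is culled every year and a grazing-immune gramineae
stand spuriously loses ≈ 0.4% of its cover per year.

## Initial landscapes

Five archetype profiles are shipped (`data/archetypes.yaml`).  The tree
means of the two woodland-steppe types (50% and 10%) are fixed by the study
area description; the other targets encode the verbal characterizations of
the five vegetation types — they are documented, overridable numbers, not
field measurements.  The spiny-dominated type is initialized near its
moderate-grazing equilibrium on the argument that spiny dominance is itself
a signature of grazed steppe.

For each group with target mean abundance *p* (percent), cells are occupied
independently with probability `q = p / 100 / (mean_cover × plant_fraction)`
so that the expected established cover equals the target exactly, where
`mean_cover` is the mean of the within-cell abundance draw and
`plant_fraction` the non-propagule share of the stage mix.  Occupied cells
receive a single cohort with abundance ~ U(0.5, 1) at a stage drawn from
the per-group stage mix (default 0.2 propagule / 0.3 immature / 0.5
mature); propagule cells get a seed pool sized to saturate first-year
germination.  Immature ages are uniform over the immature range; mature
ages are drawn from a small quantized set between maturity and half the
lifespan (keeping the number of distinct age layers, and hence run time,
bounded — a deliberate resolution choice, not a biological claim).

Two groups deviate from the default stage mix, on demographic grounds:

* **trees** use 0.2 / 0.05 / 0.75 — with a 10-year juvenile phase in a
  300-year lifespan, a standing woodland carries few immatures at any
  instant; a 30% immature share would also make tree cover drop sharply
  under overgrazing (immature trees are browse-susceptible) when observed
  woodlands under heavy grazing keep their canopy;
* **annual herbs** use 0.5 / 0 / 0.5 with a sparse within-cell cover draw
  U(0.05, 0.25) — annuals overwinter largely as seed and occur as
  widespread thin populations rather than dense stands.

## Scenario runs and outputs

A run records landscape abundance per group each year (year 0 = the
initialized state) and writes a time-series table, a final-abundance
summary, initial and final dominance maps (label matrix and PNG), the final
grid state (headered tab-separated text, one row per cohort), and a
run-metadata file.  The full experiment crosses the five landscapes with
the three regimes — 15 runs of 50 years, each run once (the model is
deterministic given the seed; the per-combination seeds are derived
reproducibly from the base seed).

## Synthetic phytosociological data

The generator emulates the statistical shape of a regional relevé
compilation: 58 alliances in five vegetation types, 668 relevés, species
recorded on the Braun-Blanquet scale with growth-form labels.  Alliance
target covers scatter around stand-scale archetype profiles (σ = 2);
relevé covers jitter around their alliance targets with the within-alliance
noise (default σ = 5); each growth form contributes one to four synthetic
species, one carrying the Braun-Blanquet code of the realized cover and the
rest codes no larger, so the per-relevé growth-form maximum recovers the
realized cover up to code discretization.

The generator's archetypes are *plot-scale* profiles: relevés sample
vegetated stands, so characteristic-group covers run higher than the
landscape means used to initialize simulation grids (a landscape mean is a
stand cover diluted by the stand type's prevalence).  This matters
quantitatively: the Braun-Blanquet scale maps the whole 5–25% range to one
class, and at landscape-mean scale two of the five types collapse onto
nearly the same code vector, making type recovery unstable.  At stand scale
the five types are separated by several class widths and the full pipeline
(generate → aggregate → cluster) recovers k = 5 with high assignment purity
across seeds and noise levels 0–10.

What the generator does **not** emulate: real floristic composition,
spatial or historical autocorrelation among relevés, unequal relevé quality
across surveys, and rare-species tails.  Passing pipeline tests therefore
demonstrate that the analysis machinery is correct and noise-robust under
the stated noise model — not that it would classify any particular real
survey identically.

## Vegetation typing

Braun-Blanquet codes convert by the conventional class midpoints (r → 0.1,
+ → 0.5, 1 → 2.5, 2 → 15, 3 → 37.5, 4 → 62.5, 5 → 87.5; the dialect is
config-overridable).  Growth-form abundance per relevé is the maximum
converted cover over member species; alliances average their relevés;
k-means (10 restarts, fixed seed) runs for k = 1..k_max and the elbow is
the k maximizing the second difference of **log** WSS.  The log scale is a
deliberate choice: with one dominant split (woodland vs treeless) the
absolute second difference always peaks at k = 2 regardless of the true
structure, while the strongest *relative* flattening recovers the
generative k; a degenerate matrix of identical rows yields k = 1 directly.

## Problem sizes in the test suite

Unit and property tests run on small grids (4–25 cells on a side) chosen to
exercise every code path quickly; the endpoint tests run the full 15-run
experiment at the default 100 × 100 × 50-year scale, shared across tests
via a session fixture.  The dispersal sampler is checked against an
independent rejection sampler of the same analytic density by a two-sample
Kolmogorov–Smirnov test at n = 10⁵, and the vectorized annual step is
checked cell-for-cell against a reference composition of the scalar
operations.

## Known limitations and divergences

* **Intensity encoding.**  Grazing intensity enters as spatial extent ×
  event multiplicity with fixed per-event severities.  Other encodings
  (severity shifts, herbivore selectivity) are possible; the scenario block
  exposes extent, events and a severity shift for experimentation.
* **Trees under moderate grazing** increase slowly in the woodland
  landscapes (canopy filling within already-occupied cells) rather than
  staying exactly flat; browsing suppresses their spread into open cells
  but not in-stand densification.
* **Non-spiny subshrubs in the tree-poor woodland steppe**: under grazing
  exclusion they end slightly (≈ 3 pp) above their moderate-grazing
  endpoint at year 50.  Their 30-year lifespan lets the expansion pulse
  that precedes canopy closure persist through the simulation horizon; the
  exclusion run still ends below its initial abundance.  In the
  tree-dominated landscape every non-gramineae group ends below its
  moderate endpoint, as expected for tree suppression.
* **Annuals in closed or heavily vegetated cells** disappear under
  exclusion (and, in densely vegetated treeless landscapes, late in
  moderate runs): their germinants require high light at ground level.
  Their grazing-resilience — persistence and slight increase under
  overgrazing — is reproduced.
* No climate forcing, no fire, no below-ground resource axis distinct from
  light, no within-stratum crowding, no herbivore population dynamics.
  Cohorts are population fractions, not individuals.
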