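# Shipped landscape archetype profiles for the five Central Anatolian steppe
# vegetation types.  Targets are landscape-mean established-plant abundances
# in percent.  Only the tree means of the two woodland-steppe types (50% and
# 10%) are fixed by the study-area description; the remaining targets encode
# the verbal characterizations of the vegetation types (see docs/methods.md)
# and can be overridden from a user file.
#
# stage_mix entries are (propagule, immature, mature) fractions of occupied
# cells.  Two groups deviate from the default mix on demographic grounds:
# trees use a mature-skewed mix (with a 10-year juvenile phase and 300-year
# lifespan, standing woodland carries few immatures at any instant) and
# annual herbs overwinter largely as seeds, so half of their occupied cells
# start as propagule pools.
archetypes:
  1:
    name: tree-dominated woodland steppe
    targets:
      tree: 50
      perennial_gramineae: 15
      perennial_forb: 10
      non_spiny_subshrub: 5
      spiny_subshrub: 5
      annual_herb: 2
    stage_mix:
      default: [0.2, 0.3, 0.5]
      tree: [0.2, 0.05, 0.75]
      annual_herb: [0.5, 0.0, 0.5]
    abundance_range:
      default: [0.5, 1.0]
      annual_herb: [0.05, 0.25]
  2:
    name: woodland steppe with less abundant trees
    targets:
      tree: 10
      perennial_gramineae: 20
      perennial_forb: 15
      non_spiny_subshrub: 15
      spiny_subshrub: 10
      annual_herb: 3
    stage_mix:
      default: [0.2, 0.3, 0.5]
      tree: [0.2, 0.05, 0.75]
      annual_herb: [0.5, 0.0, 0.5]
    abundance_range:
      default: [0.5, 1.0]
      annual_herb: [0.05, 0.25]
  3:
    name: herbaceous-dominated steppe with abundant non-spiny subshrubs
    targets:
      tree: 0
      perennial_gramineae: 30
      perennial_forb: 25
      non_spiny_subshrub: 25
      spiny_subshrub: 5
      annual_herb: 5
    stage_mix:
      default: [0.2, 0.3, 0.5]
      annual_herb: [0.5, 0.0, 0.5]
    abundance_range:
      default: [0.5, 1.0]
      annual_herb: [0.05, 0.25]
  4:
    name: non-spiny subshrub-dominated steppe with low total abundance
    targets:
      tree: 0
      perennial_gramineae: 8
      perennial_forb: 6
      non_spiny_subshrub: 20
      spiny_subshrub: 4
      annual_herb: 2
    stage_mix:
      default: [0.2, 0.3, 0.5]
      annual_herb: [0.5, 0.0, 0.5]
    abundance_range:
      default: [0.5, 1.0]
      annual_herb: [0.05, 0.25]
  5:
    name: spiny subshrub-dominated steppe
    targets:
      tree: 0
      perennial_gramineae: 15
      perennial_forb: 10
      non_spiny_subshrub: 10
      spiny_subshrub: 30
      annual_herb: 3
    stage_mix:
      default: [0.2, 0.3, 0.5]
      annual_herb: [0.5, 0.0, 0.5]
    abundance_range:
      default: [0.5, 1.0]
      annual_herb: [0.05, 0.25]
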