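# Default parameterization of the six Central Anatolian steppe growth forms.
#
# Ordinal levels are coded 0..4 (none / low / medium-half / high-most / all);
# dispersal band rates use 0..3 only.  Survival entries are booleans for the
# three resource levels [low, medium, high].  kill / resprout / respage are
# per grazing-response age class; classes are [0,b1), [b1,b2), [b2,inf) over
# the age_breakpoints.
groups:
  tree:
    maxab: 1
    mature_age: 10
    max_age: 300
    size_class: 1
    stratum: {immature: 1, mature: 3}
    dispersal:
      rates: {short: 3, medium: 3, long: 3}
      k_disp: [2, 10]
      limits: [10, 50, 100]
    fecundity: 2
    germination_rate: {low: 1, medium: 2, high: 3}
    survival:
      germinant: [false, true, true]
      immature: [true, true, true]
      mature: [true, true, true]
    disturbance:
      age_breakpoints: [3, 10]
      seed_broken: 0
      propkill: 0
      kill: [3, 2, 0]
      resprout: [0, 1, 0]
      respage: [1, 5, 10]
  non_spiny_subshrub:
    maxab: 1
    mature_age: 2
    max_age: 30
    size_class: 1
    stratum: {immature: 1, mature: 2}
    dispersal:
      rates: {short: 3, medium: 1, long: 1}
      k_disp: [2, 10]
      limits: [5, 10, 50]
    fecundity: 3
    germination_rate: {low: 0, medium: 1, high: 2}
    survival:
      germinant: [false, false, true]
      immature: [false, true, true]
      mature: [true, true, true]
    disturbance:
      age_breakpoints: [2, 5]
      seed_broken: 0
      propkill: 0
      kill: [3, 3, 1]
      resprout: [0, 1, 2]
      respage: [0, 1, 2]
  spiny_subshrub:
    maxab: 1
    mature_age: 2
    max_age: 30
    size_class: 1
    stratum: {immature: 1, mature: 2}
    dispersal:
      rates: {short: 3, medium: 1, long: 1}
      k_disp: [2, 10]
      limits: [5, 10, 50]
    fecundity: 3
    germination_rate: {low: 0, medium: 1, high: 2}
    survival:
      germinant: [false, false, true]
      immature: [false, true, true]
      mature: [true, true, true]
    disturbance:
      age_breakpoints: [2, 5]
      seed_broken: 0
      propkill: 0
      kill: [3, 2, 0]
      resprout: [0, 1, 1]
      respage: [0, 1, 2]
  perennial_forb:
    maxab: 1
    mature_age: 1
    max_age: 5
    size_class: 2
    stratum: {immature: 1, mature: 1}
    dispersal:
      rates: {short: 3, medium: 2, long: 1}
      k_disp: [3, 20]
      limits: [5, 30, 100]
    fecundity: 3
    germination_rate: {low: 1, medium: 1, high: 1}
    survival:
      germinant: [false, true, true]
      immature: [true, true, true]
      mature: [true, true, true]
    disturbance:
      age_breakpoints: [2]
      seed_broken: 0
      propkill: 0
      kill: [3, 1]
      resprout: [0, 2]
      respage: [1, 2]
  perennial_gramineae:
    maxab: 1
    mature_age: 2
    max_age: 5
    size_class: 2
    stratum: {immature: 1, mature: 1}
    dispersal:
      rates: {short: 3, medium: 1, long: 1}
      k_disp: [3, 10]
      limits: [5, 10, 50]
    fecundity: 3
    germination_rate: {low: 1, medium: 1, high: 1}
    survival:
      germinant: [false, true, true]
      immature: [true, true, true]
      mature: [true, true, true]
    disturbance:
      age_breakpoints: [1]
      seed_broken: 0
      propkill: 0
      kill: [3, 0]
      resprout: [0, 3]
      respage: [1, 2]
  annual_herb:
    maxab: 1
    mature_age: 1
    max_age: 2
    size_class: 4
    stratum: {immature: 1, mature: 1}
    dispersal:
      rates: {short: 3, medium: 1, long: 0}
      k_disp: [2, 10]
      limits: [5, 10, 20]
    fecundity: 5
    germination_rate: {low: 1, medium: 1, high: 1}
    survival:
      germinant: [false, false, true]
      immature: [false, false, true]
      mature: [false, true, true]
    disturbance:
      age_breakpoints: [1]
      seed_broken: 0
      propkill: 0
      kill: [1, 3]
      resprout: [0, 0]
      respage: [-1, -1]
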