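"""Annual demographic step: resources, survival, aging, dispersal, germination."""

import dataclasses

import numpy as np
import pytest

from steppesim.engine import (age_and_promote, annual_step, compute_resource,
                              germinate, produce_and_disperse,
                              resource_from_shading, survive_step,
                              _sample_distances)
from steppesim.grazing import GrazingScenario, apply_grazing
from steppesim.landscape import (EXTINCTION_EPS, Cell, Cohort, Landscape,
                                 landscape_abundance)
from steppesim.params import Resource, Stage

from conftest import make_landscape


def cell_of(pmap, *entries):
    """Cell from (group, age, abundance) triples."""
    cohorts = [Cohort.for_age(g, age, ab, pmap[g]) for g, age, ab in entries]
    return Cell((0, 0), cohorts, {})


def no_dispersal(pmap):
    return {g: dataclasses.replace(p, fecundity=0) for g, p in pmap.items()}


class TestResourceComputation:
    def test_empty_cell_sees_high_resources(self, pmap):
        assert compute_resource(cell_of(pmap), 3, pmap) is Resource.HIGH

    def test_full_tree_canopy_shades_understory_to_low(self, pmap):
        cell = cell_of(pmap, ("tree", 50, 1.0))
        assert compute_resource(cell, 1, pmap) is Resource.LOW

    def test_top_stratum_is_never_shaded(self, pmap):
        cell = cell_of(pmap, ("tree", 50, 1.0))
        assert compute_resource(cell, 5, pmap) is Resource.HIGH

    def test_equal_height_plants_do_not_shade_each_other(self, pmap):
        # gramineae occupy stratum 1 and never shade a stratum-1 query
        cell = cell_of(pmap, ("perennial_gramineae", 3, 1.0))
        assert compute_resource(cell, 1, pmap) is Resource.HIGH

    def test_invalid_stratum_rejected(self, pmap):
        with pytest.raises(ValueError):
            compute_resource(cell_of(pmap), 0, pmap)

    def test_thresholds_mirror_abundance_classes(self):
        assert resource_from_shading(0.32) is Resource.HIGH
        assert resource_from_shading(0.33) is Resource.MEDIUM
        assert resource_from_shading(0.66) is Resource.LOW


class TestSurvival:
    @pytest.mark.parametrize("group,age,resource,survives", [
        ("annual_herb", 0, Resource.MEDIUM, False),   # immature annual (age<1 is germinant; use germinant row)
        ("perennial_gramineae", 1, Resource.LOW, True),
        ("non_spiny_subshrub", 10, Resource.LOW, True),
        ("annual_herb", 1, Resource.LOW, False),      # mature annual needs light
        ("tree", 0, Resource.LOW, False),             # tree germinant in deep shade
    ])
    def test_matrix_lookup(self, pmap, group, age, resource, survives):
        co = Cohort.for_age(group, age, 0.5, pmap[group])
        out = survive_step(co, resource, pmap[group])
        assert (out is not None) == survives
        if out is not None:
            assert out == co  # survivors are unchanged

    def test_full_survival_matrix_entry_for_entry(self, pmap):
        # frozen from the germination/survival response table
        truth = {
            "non_spiny_subshrub": ([0, 0, 1], [0, 1, 1], [1, 1, 1]),
            "spiny_subshrub": ([0, 0, 1], [0, 1, 1], [1, 1, 1]),
            "perennial_forb": ([0, 1, 1], [1, 1, 1], [1, 1, 1]),
            "perennial_gramineae": ([0, 1, 1], [1, 1, 1], [1, 1, 1]),
            "annual_herb": ([0, 0, 1], [0, 0, 1], [0, 1, 1]),
            "tree": ([0, 1, 1], [1, 1, 1], [1, 1, 1]),
        }
        for g, (germ, imm, mat) in truth.items():
            s = pmap[g].survival
            assert [int(v) for v in s.germinant] == germ, g
            assert [int(v) for v in s.immature] == imm, g
            assert [int(v) for v in s.mature] == mat, g


class TestAgingAndPromotion:
    def test_germinant_becomes_immature(self, pmap):
        co = Cohort.for_age("tree", 0, 0.4, pmap["tree"])
        out = age_and_promote(co, pmap["tree"])
        assert out.age == 1 and out.stage is Stage.IMMATURE

    def test_forb_matures_after_first_year(self, pmap):
        out = age_and_promote(Cohort.for_age("perennial_forb", 0, 0.4,
                                             pmap["perennial_forb"]),
                              pmap["perennial_forb"])
        assert out.stage is Stage.MATURE

    def test_senescence_removes_over_aged_annuals(self, pmap):
        co = Cohort.for_age("annual_herb", 2, 0.4, pmap["annual_herb"])
        assert age_and_promote(co, pmap["annual_herb"]) is None


class TestDispersal:
    def test_zero_fecundity_emits_nothing(self, pmap):
        p0 = dataclasses.replace(pmap["tree"], fecundity=0)
        ls = make_landscape(pmap, [("tree", 50, 10, 10, 1.0)], width=21, height=21)
        assert produce_and_disperse(ls, p0, np.random.default_rng(0)) == []

    def test_single_mature_tree_emits_its_fecundity(self, pmap):
        # center of a 21x21 grid: the 100 m kernel cannot reach the boundary
        ls = make_landscape(pmap, [("tree", 50, 10, 10, 1.0)], width=21, height=21)
        events = produce_and_disperse(ls, pmap["tree"], np.random.default_rng(0))
        assert len(events) == 2
        assert all(ev.source == (10, 10) for ev in events)

    def test_all_zero_band_rates_place_no_seeds(self, pmap):
        disp = dataclasses.replace(pmap["tree"].dispersal, rates=(0, 0, 0))
        p = dataclasses.replace(pmap["tree"], dispersal=disp)
        ls = make_landscape(pmap, [("tree", 50, 10, 10, 1.0)], width=21, height=21)
        assert produce_and_disperse(ls, p, np.random.default_rng(0)) == []

    def test_band_choice_frequencies_match_rate_fractions(self, pmap):
        # forb bands high/medium/low capacity -> (0.75, 0.5, 0.25)/1.5
        p = pmap["perennial_forb"]
        n = 100_000
        d = _sample_distances(p, n, np.random.default_rng(42))
        l1, l2, _ = p.dispersal.limits
        counts = np.array([(d < l1).sum(), ((d >= l1) & (d < l2)).sum(),
                           (d >= l2).sum()])
        probs = np.array([0.75, 0.5, 0.25]) / 1.5
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(counts / n - probs) < 3 * se)

    def test_distances_respect_band_limits(self, pmap):
        for g in ("tree", "perennial_forb", "annual_herb"):
            p = pmap[g]
            d = _sample_distances(p, 20_000, np.random.default_rng(1))
            assert d.min() >= 0
            assert d.max() <= p.dispersal.limits[2]


class TestGermination:
    def _cell_with_seeds(self, group, n):
        return Cell((0, 0), [], {group: float(n)})

    def test_shade_intolerant_seeds_fail_at_low_resources(self, pmap):
        cell = self._cell_with_seeds("non_spiny_subshrub", 3)
        assert germinate(cell, "non_spiny_subshrub", Resource.LOW,
                         pmap["non_spiny_subshrub"]) is None

    def test_tree_germination_strongest_at_high_resources(self, pmap):
        p = pmap["tree"]
        cell = self._cell_with_seeds("tree", p.fecundity)
        cohort = germinate(cell, "tree", Resource.HIGH, p)
        assert cohort.stage is Stage.GERMINANT and cohort.age == 0
        fr = [germinate(self._cell_with_seeds("tree", p.fecundity), "tree", r, p)
              for r in (Resource.MEDIUM, Resource.HIGH)]
        assert cohort.abundance == max(c.abundance for c in fr if c)
        assert cohort.abundance == 0.75  # saturated seed rain, high resources

    def test_no_seeds_no_germinant(self, pmap):
        assert germinate(self._cell_with_seeds("tree", 0), "tree",
                         Resource.HIGH, pmap["tree"]) is None

    def test_seed_saturation_scales_with_fecundity(self, pmap):
        p = pmap["perennial_forb"]
        half = germinate(self._cell_with_seeds(p.name, p.fecundity / 2),
                         p.name, Resource.HIGH, p)
        full = germinate(self._cell_with_seeds(p.name, 10 * p.fecundity),
                         p.name, Resource.HIGH, p)
        assert half.abundance == pytest.approx(full.abundance / 2)


class TestAnnualStep:
    def test_pure_aging_without_grazing(self, pmap):
        ls = make_landscape(pmap, [("tree", 50, r, c, 0.8)
                                   for r in range(4) for c in range(4)],
                            width=4, height=4)
        pm = no_dispersal(pmap)
        annual_step(ls, pm, GrazingScenario.for_regime("none"), 1,
                    np.random.default_rng(0))
        assert set(ls.cohorts["tree"]) == {51}
        assert float(ls.cohorts["tree"][51].sum()) == pytest.approx(0.8 * 16)

    def test_replay_determinism(self, pmap, archetypes):
        from steppesim.landscape import init_landscape
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            ls = init_landscape(archetypes[2], (20, 20), rng, pmap)
            sc = GrazingScenario.for_regime("moderate")
            for year in range(1, 6):
                annual_step(ls, pmap, sc, year, rng)
            outs.append({(g, a): layer.copy() for g, a, layer in ls.iter_cohorts()})
        assert outs[0].keys() == outs[1].keys()
        for key in outs[0]:
            np.testing.assert_array_equal(outs[0][key], outs[1][key])

    def test_closed_population_only_loses_abundance_to_senescence(self, pmap):
        # benign survival everywhere, no seeds, no grazing: totals can only drop
        ls = make_landscape(pmap, [("non_spiny_subshrub", 28, r, c, 0.9)
                                   for r in range(5) for c in range(5)],
                            width=5, height=5)
        pm = no_dispersal(pmap)
        sc = GrazingScenario.for_regime("none")
        totals = [landscape_abundance(ls, "non_spiny_subshrub")]
        for year in range(1, 5):
            annual_step(ls, pm, sc, year, np.random.default_rng(0))
            totals.append(landscape_abundance(ls, "non_spiny_subshrub"))
        assert all(b <= a for a, b in zip(totals, totals[1:]))
        assert totals[-1] == 0.0  # lifespan of 30 exceeded at age 31

    def test_annuals_need_reseeding_to_persist(self, pmap):
        ls = make_landscape(pmap, [("annual_herb", 1, r, c, 0.5)
                                   for r in range(4) for c in range(4)],
                            width=4, height=4)
        pm = no_dispersal(pmap)  # dispersal off: no recruitment possible
        sc = GrazingScenario.for_regime("none")
        for year in range(1, 4):
            annual_step(ls, pm, sc, year, np.random.default_rng(0))
        assert landscape_abundance(ls, "annual_herb") == 0.0

    def test_abundance_bounds_and_lifespans_hold_throughout(self, pmap, archetypes):
        rng = np.random.default_rng(7)
        from steppesim.landscape import init_landscape
        ls = init_landscape(archetypes[2], (20, 20), rng, pmap)
        sc = GrazingScenario.for_regime("overgrazing")
        for year in range(1, 11):
            annual_step(ls, pmap, sc, year, rng)
            for g, age, layer in ls.iter_cohorts():
                assert 0 <= layer.min() and layer.max() <= 1.0
                assert age <= pmap[g].max_age
                tot = ls.group_total(g)
                assert tot.max() <= 1.0 + 1e-9


class TestVectorScalarEquivalence:
    """The array engine must match the per-cell composition of the scalar ops."""

    def _reference_step(self, ls, pmap, scenario):
        out = Landscape(ls.width, ls.height, ls.cell_size)
        for r in range(ls.height):
            for c in range(ls.width):
                cell = ls.cell(r, c, pmap)
                cell = apply_grazing(cell, pmap, scenario)
                aged = [age_and_promote(co, pmap[co.group]) for co in cell.cohorts]
                cell = Cell((r, c), [co for co in aged if co], cell.seeds)
                survivors = []
                for co in cell.cohorts:
                    res = compute_resource(cell, pmap[co.group].stratum_of(co.age), pmap)
                    kept = survive_step(co, res, pmap[co.group])
                    if kept is not None and kept.abundance >= EXTINCTION_EPS:
                        survivors.append(kept)
                for co in survivors:
                    out.add_abundance(co.group, co.age, (r, c), co.abundance)
        out.cap_group_abundance(pmap)
        out.prune()
        return out

    def test_one_grazed_year_matches_cellwise_oracle(self, pmap):
        rng = np.random.default_rng(5)
        entries = []
        groups_ages = [("tree", 50), ("tree", 5), ("perennial_gramineae", 3),
                       ("perennial_forb", 2), ("non_spiny_subshrub", 12),
                       ("spiny_subshrub", 3), ("annual_herb", 1)]
        for r in range(6):
            for c in range(6):
                for g, age in groups_ages:
                    if rng.random() < 0.5:
                        entries.append((g, age, r, c, float(rng.uniform(0.1, 1.0))))
        pm = no_dispersal(pmap)
        sc = GrazingScenario.for_regime("overgrazing")  # full coverage: no draw
        ls_vec = make_landscape(pmap, entries, width=6, height=6)
        expected = self._reference_step(ls_vec.copy(), pm, sc)
        annual_step(ls_vec, pm, sc, 1, np.random.default_rng(0))
        keys_vec = {(g, a) for g, a, _ in ls_vec.iter_cohorts()}
        keys_ref = {(g, a) for g, a, _ in expected.iter_cohorts()}
        assert keys_vec == keys_ref
        for g, a, layer in ls_vec.iter_cohorts():
            np.testing.assert_allclose(layer, expected.cohorts[g][a],
                                       atol=1e-12, err_msg=f"{g} age {a}")
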