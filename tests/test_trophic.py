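"""Fractional trophic levels, Lindeman decomposition, catch trophic level."""

import numpy as np
import pytest

import fjordweb as fw
from fjordweb.model_io import ModelError
from fjordweb.synthetic_webs import GeneratorSpec, generate

from conftest import make_model

# Fractional trophic levels printed for the fjord model.
PRINTED_TL = {
    "Killer whales": 4.49, "Sea lions": 4.13, "Pink cusk-eel": 4.12,
    "Southern hake": 3.93, "Seabirds": 3.91, "Red cod": 3.86,
    "Penguins": 3.83, "Salmon": 3.79, "Long-tailed hake": 3.49,
    "Patagonian robalo": 3.46, "Benthic fish": 3.44, "Humpback whales": 3.41,
    "Cephalopods": 3.17, "Fuegian sprat": 2.79, "Squat lobster": 2.34,
    "Amphipods": 2.34, "Benthos": 2.19, "Euphausiids": 2.18,
    "Mesozooplankton": 2.00, "Phytoplankton": 1.00,
}


class TestTrophicLevels:
    @pytest.mark.parametrize("group, expected", sorted(PRINTED_TL.items()))
    def test_fixture_levels(self, trophic, group, expected):
        assert trophic[group] == pytest.approx(expected, abs=0.011)

    def test_basal_groups_exactly_one(self, trophic):
        assert trophic["Phytoplankton"] == 1.0
        assert trophic["Detritus"] == 1.0

    def test_duplicated_diet_gives_equal_level(self, coloane):
        model = coloane.copy()
        clone = fw.FunctionalGroup(
            "Sprat clone", role="consumer", biomass=1.0, pb=3.0, qb=9.0, ee=0.0
        )
        diet = model.diet.copy()
        diet["Sprat clone"] = 0.0
        model = fw.FoodWebModel(groups=model.groups + [clone], diet=diet)
        model.diet["Sprat clone"] = model.diet["Fuegian sprat"]
        tl = fw.trophic_levels(model)
        assert tl["Sprat clone"] == pytest.approx(tl["Fuegian sprat"], rel=1e-12)

    def test_generated_producers_at_level_one(self):
        web = generate(GeneratorSpec(n_groups=8, seed=1))
        tl = fw.trophic_levels(web.full)
        for p in web.full.producers:
            assert tl[p] == 1.0


class TestLindeman:
    def test_basal_mass_at_level_one(self, balanced):
        dec = fw.lindeman_decomposition(balanced)
        assert dec.level_fractions.loc["Phytoplankton", 1] == pytest.approx(1.0)
        assert dec.level_fractions.loc["Detritus", 1] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, balanced):
        dec = fw.lindeman_decomposition(balanced)
        assert np.allclose(dec.level_fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_sprat_split_between_levels_two_and_three(self, balanced):
        dec = fw.lindeman_decomposition(balanced)
        row = dec.level_fractions.loc["Fuegian sprat"]
        assert row[2] == pytest.approx(0.24, abs=0.02)
        assert row[3] == pytest.approx(0.72, abs=0.02)

    def test_two_level_chain_herbivore_entirely_level_two(self):
        model = make_model(
            [
                fw.FunctionalGroup("algae", role="producer", biomass=100.0, pb=10.0),
                fw.FunctionalGroup("grazer", role="consumer", biomass=1.0, pb=1.0,
                                   qb=10.0, ee=0.0),
            ],
            {("algae", "grazer"): 1.0},
        )
        dec = fw.lindeman_decomposition(fw.solve_mass_balance(model))
        assert dec.level_fractions.loc["grazer", 2] == pytest.approx(1.0)
        assert dec.aggregated_flows[2] == pytest.approx(10.0)  # grazer Q

    def test_expectation_identity_on_shallow_webs(self):
        # mean discrete level equals the fractional level when nothing is
        # folded into the cap
        web = generate(GeneratorSpec(n_groups=6, n_producers=2, seed=7))
        bal = fw.solve_mass_balance(web.full)
        dec = fw.lindeman_decomposition(bal, max_level=8)
        tl = fw.trophic_levels(bal)
        levels = np.arange(1, 9)
        mean_level = (dec.level_fractions * levels).sum(axis=1)
        assert np.allclose(mean_level, tl, atol=1e-9)


class TestMeanTLCatch:
    def test_fixture_catch_level(self, balanced):
        assert fw.mean_tl_catch(balanced) == pytest.approx(2.3, abs=0.05)

    def test_single_species_catch(self):
        model = make_model(
            [
                fw.FunctionalGroup("algae", role="producer", biomass=100.0, pb=10.0),
                fw.FunctionalGroup("grazer", role="consumer", biomass=1.0, pb=1.0,
                                   qb=10.0, ee=None, landings=0.5),
            ],
            {("algae", "grazer"): 1.0},
        )
        bal = fw.solve_mass_balance(model)
        assert fw.mean_tl_catch(bal) == pytest.approx(2.0)

    def test_symmetric_catches_average(self):
        # equal landings from a level-2 and a level-4 group average to 3
        model = make_model(
            [
                fw.FunctionalGroup("algae", role="producer", biomass=1000.0, pb=10.0),
                fw.FunctionalGroup("herb", role="consumer", biomass=50.0, pb=2.0,
                                   qb=10.0, ee=None, landings=0.2),
                fw.FunctionalGroup("meso", role="consumer", biomass=5.0, pb=1.0,
                                   qb=5.0, ee=None),
                fw.FunctionalGroup("top", role="consumer", biomass=0.5, pb=0.5,
                                   qb=2.0, ee=None, landings=0.2),
            ],
            {("algae", "herb"): 1.0, ("herb", "meso"): 1.0, ("meso", "top"): 1.0},
        )
        bal = fw.solve_mass_balance(model)
        tl = fw.trophic_levels(bal)
        assert tl["herb"] == pytest.approx(2.0) and tl["top"] == pytest.approx(4.0)
        assert fw.mean_tl_catch(bal) == pytest.approx(3.0)

    def test_no_landings_is_an_error(self):
        model = make_model(
            [
                fw.FunctionalGroup("algae", role="producer", biomass=100.0, pb=10.0),
                fw.FunctionalGroup("grazer", role="consumer", biomass=1.0, pb=1.0,
                                   qb=10.0, ee=0.0),
            ],
            {("algae", "grazer"): 1.0},
        )
        with pytest.raises(ModelError, match="landings"):
            fw.mean_tl_catch(fw.solve_mass_balance(model))
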