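"""Model structures, tabular I/O, diet normalization and validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fjordweb as fw
from fjordweb.model_io import ModelError
from fjordweb.synthetic_webs import GeneratorSpec, generate

from conftest import make_model


class TestFixtureStructure:
    def test_group_census(self, coloane):
        assert len(coloane.groups) == 21
        assert len(coloane.producers) == 1
        assert len(coloane.detritus_groups) == 1
        assert len(coloane.consumers) == 19

    def test_diet_columns_normalized(self, coloane):
        sums = coloane.diet.sum(axis=0) + coloane.diet_import
        assert np.allclose(sums[coloane.consumers], 1.0, atol=1e-12)

    def test_no_diet_imports(self, coloane):
        assert float(coloane.diet_import.abs().sum()) == 0.0

    @pytest.mark.parametrize(
        "prey, frac",
        [("Benthos", 0.0010), ("Mesozooplankton", 0.3397),
         ("Phytoplankton", 0.3297), ("Detritus", 0.3297)],
    )
    def test_squat_lobster_diet_fractions(self, coloane, prey, frac):
        assert coloane.diet.loc[prey, "Squat lobster"] == pytest.approx(frac, abs=1e-3)

    def test_killer_whale_raw_column_sum(self, coloane):
        # entries of the source table sum to the printed total up to the
        # rounding of individual cells
        assert coloane.consumption_column_sums["Killer whales"] == pytest.approx(
            0.504, abs=0.005
        )

    def test_flow_to_detritus_reference_kept(self, coloane):
        assert coloane.flow_to_detritus_reference["Killer whales"] == pytest.approx(0.109)


class TestNormalizeDiet:
    def test_single_prey_column(self):
        mat = pd.DataFrame({"c": [3.7, 0.0]}, index=["a", "b"])
        frac, imp = fw.normalize_diet(mat, ["c"])
        assert frac.loc["a", "c"] == 1.0
        assert imp["c"] == 0.0

    def test_import_share(self):
        mat = pd.DataFrame({"c": [6.0]}, index=["a"])
        frac, imp = fw.normalize_diet(mat, ["c"], import_row=pd.Series({"c": 2.0}))
        assert frac.loc["a", "c"] == pytest.approx(0.75)
        assert imp["c"] == pytest.approx(0.25)

    def test_zero_column_is_an_error(self):
        mat = pd.DataFrame({"c": [0.0]}, index=["a"])
        with pytest.raises(ModelError, match="zero diet column"):
            fw.normalize_diet(mat, ["c"])

    def test_negative_entries_rejected(self):
        mat = pd.DataFrame({"c": [-1.0]}, index=["a"])
        with pytest.raises(ModelError, match="negative"):
            fw.normalize_diet(mat, ["c"])

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=1, max_size=8)
    )
    def test_columns_sum_to_one(self, values):
        mat = pd.DataFrame({"c": values}, index=[f"p{i}" for i in range(len(values))])
        frac, _ = fw.normalize_diet(mat, ["c"])
        assert frac["c"].sum() == pytest.approx(1.0, abs=1e-12)


class TestReadWrite:
    def test_round_trip_is_identity(self, coloane, tmp_path):
        fw.write_model(coloane, tmp_path)
        again = fw.read_model(tmp_path)
        assert (again.diet.to_numpy() == coloane.diet.to_numpy()).all()
        assert again.groups == coloane.groups

    def test_round_trip_synthetic(self, tmp_path):
        model = generate(GeneratorSpec(n_groups=7, seed=11)).full
        fw.write_model(model, tmp_path)
        again = fw.read_model(tmp_path)
        assert again.groups == model.groups
        assert (again.diet.to_numpy() == model.diet.to_numpy()).all()

    def test_producer_only_model(self, tmp_path):
        model = make_model(
            [fw.FunctionalGroup("algae", role="producer", biomass=1.0, pb=10.0, ee=0.0)],
            {},
        )
        fw.write_model(model, tmp_path)
        again = fw.read_model(tmp_path)
        assert again.consumers == []
        assert again.producers == ["algae"]

    def test_unknown_prey_name_rejected(self, coloane, tmp_path):
        fw.write_model(coloane, tmp_path)
        diet = (tmp_path / "diet.tsv").read_text()
        (tmp_path / "diet.tsv").write_text(diet.replace("Benthos\t", "Krill\t", 1))
        with pytest.raises(ModelError, match="Krill"):
            fw.read_model(tmp_path)

    def test_both_unknowns_rejected(self, tmp_path):
        model = make_model(
            [
                fw.FunctionalGroup("algae", role="producer", biomass=1.0, pb=10.0, ee=0.5),
                fw.FunctionalGroup("grazer", role="consumer", pb=1.0, qb=5.0),
            ],
            {("algae", "grazer"): 1.0},
        )
        fw.write_model(model, tmp_path)
        with pytest.raises(ModelError, match="both biomass and EE unknown"):
            fw.read_model(tmp_path)


class TestValidate:
    def test_fixture_flags_inconsistent_consumption_columns(self, coloane, balanced):
        diags = fw.validate(coloane, biomass=balanced.biomass)
        warned = {d.group for d in diags if d.level == "warning"}
        # the three source-table columns whose totals disagree with B*(Q/B)
        assert {"Mesozooplankton", "Squat lobster", "Fuegian sprat"} <= warned
        assert not [d for d in diags if d.level == "error"]

    def test_synthetic_web_is_clean(self):
        model = generate(GeneratorSpec(n_groups=9, seed=2)).full
        assert fw.validate(model) == []

    def test_ee_above_one_is_invariant_error(self):
        model = make_model(
            [
                fw.FunctionalGroup("algae", role="producer", biomass=1.0, pb=10.0, ee=1.2),
            ],
            {},
        )
        diags = fw.validate(model)
        assert any(d.level == "error" and "EE" in d.message for d in diags)

    def test_detritus_with_rates_is_error(self):
        model = make_model(
            [
                fw.FunctionalGroup("algae", role="producer", biomass=1.0, pb=10.0, ee=0.0),
                fw.FunctionalGroup("mud", role="detritus", pb=1.0),
            ],
            {},
        )
        diags = fw.validate(model)
        assert any(d.level == "error" and d.group == "mud" for d in diags)
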