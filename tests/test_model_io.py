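"""Model container, SBML/JSON readers, and result-table I/O."""

import json

import numpy as np
import pytest
import scipy.sparse as sp

from fvakit.fixtures import make_diamond, make_linear_pathway, make_random_model
from fvakit.model_io import (
    MetabolicModel,
    ModelValidationError,
    read_fva_tsv,
    read_json_model,
    read_reaction_subset,
    read_sbml,
    validate_model,
    write_fva_tsv,
    write_json_model,
    write_sbml,
)

DIAMOND_JSON = {
    "id": "diamond",
    "metabolites": ["A", "B"],
    "reactions": [
        {"id": "R1", "metabolites": {"A": 1}, "lower_bound": 0,
         "upper_bound": 10, "objective_coefficient": 0},
        {"id": "R2", "metabolites": {"A": -1, "B": 1}, "lower_bound": 0,
         "upper_bound": 1000, "objective_coefficient": 0},
        {"id": "R3", "metabolites": {"A": -1, "B": 1}, "lower_bound": 0,
         "upper_bound": 1000, "objective_coefficient": 0},
        {"id": "R4", "metabolites": {"B": -1}, "lower_bound": 0,
         "upper_bound": 1000, "objective_coefficient": 1},
    ],
}


class TestMetabolicModel:
    def test_invariants_enforced_on_construction(self):
        with pytest.raises(ModelValidationError, match="lower bound"):
            MetabolicModel("m", ["A"], ["R1"], sp.csc_matrix(np.ones((1, 1))),
                           [5.0], [1.0], [1.0])
        with pytest.raises(ModelValidationError, match="duplicate"):
            MetabolicModel("m", ["A"], ["R1", "R1"],
                           sp.csc_matrix(np.ones((1, 2))),
                           [0, 0], [1, 1], [1, 0])

    def test_with_objective_moves_weight(self, diamond):
        m2 = diamond.with_objective("R2")
        assert m2.objective[diamond.reaction_index("R2")] == 1.0
        assert m2.objective.sum() == 1.0
        # original untouched
        assert diamond.objective[3] == 1.0


class TestJsonModel:
    def test_diamond_dimensions(self, tmp_path):
        path = tmp_path / "diamond.json"
        path.write_text(json.dumps(DIAMOND_JSON))
        m = read_json_model(str(path))
        assert m.n_reactions == 4 and m.n_metabolites == 2
        assert m.reaction_ids == ["R1", "R2", "R3", "R4"]
        assert m.S.toarray()[0].tolist() == [1, -1, -1, 0]

    def test_unknown_metabolite_names_reaction(self, tmp_path):
        doc = json.loads(json.dumps(DIAMOND_JSON))
        doc["reactions"][1]["metabolites"]["X"] = 1
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="'R2'.*'X'"):
            read_json_model(str(path))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_write_read_round_trip(self, tmp_path, seed):
        m = make_random_model(5, 11, seed)
        path = tmp_path / "m.json"
        write_json_model(m, str(path))
        m2 = read_json_model(str(path))
        assert m2.reaction_ids == m.reaction_ids
        assert np.array_equal(m.S.toarray(), m2.S.toarray())
        assert np.array_equal(m.lower_bounds, m2.lower_bounds)
        assert np.array_equal(m.upper_bounds, m2.upper_bounds)
        assert np.array_equal(m.objective, m2.objective)


class TestSbml:
    def test_round_trip_preserves_everything(self, tmp_path):
        m = make_random_model(6, 14, seed=9)
        path = tmp_path / "m.xml"
        write_sbml(m, str(path))
        m2 = read_sbml(str(path))
        assert m2.reaction_ids == m.reaction_ids
        assert m2.metabolite_ids == m.metabolite_ids
        assert np.allclose(m.S.toarray(), m2.S.toarray())
        assert np.allclose(m.lower_bounds, m2.lower_bounds)
        assert np.allclose(m.upper_bounds, m2.upper_bounds)
        assert np.allclose(m.objective, m2.objective)
        assert m2.objective_sense == m.objective_sense

    def test_linear_pathway_dimensions(self, tmp_path):
        path = tmp_path / "lp.xml"
        write_sbml(make_linear_pathway(3, 10.0), str(path))
        m = read_sbml(str(path))
        assert m.n_reactions == 3 and m.n_metabolites == 2

    def test_reader_is_deterministic(self, tmp_path):
        path = tmp_path / "m.xml"
        write_sbml(make_diamond(10.0), str(path))
        a, b = read_sbml(str(path)), read_sbml(str(path))
        assert a.reaction_ids == b.reaction_ids
        assert np.array_equal(a.S.toarray(), b.S.toarray())

    def test_boundary_species_excluded(self, tmp_path):
        # hand-written L3+FBC document with one boundary species
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
 <model id="toy" fbc:strict="true">
  <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c" boundaryCondition="false" constant="false"
            hasOnlySubstanceUnits="false"/>
   <species id="ext" compartment="c" boundaryCondition="true" constant="false"
            hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="lb" value="0" constant="true"/>
   <parameter id="ub" value="10" constant="true"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="R1" reversible="false" fast="false"
             fbc:lowerFluxBound="lb" fbc:upperFluxBound="ub">
    <listOfReactants>
     <speciesReference species="ext" stoichiometry="1" constant="true"/>
    </listOfReactants>
    <listOfProducts>
     <speciesReference species="A" stoichiometry="1" constant="true"/>
    </listOfProducts>
   </reaction>
   <reaction id="R2" reversible="false" fast="false"
             fbc:lowerFluxBound="lb" fbc:upperFluxBound="ub">
    <listOfReactants>
     <speciesReference species="A" stoichiometry="1" constant="true"/>
    </listOfReactants>
   </reaction>
  </listOfReactions>
  <fbc:listOfObjectives fbc:activeObjective="obj">
   <fbc:objective fbc:id="obj" fbc:type="maximize">
    <fbc:listOfFluxObjectives>
     <fbc:fluxObjective fbc:reaction="R2" fbc:coefficient="1"/>
    </fbc:listOfFluxObjectives>
   </fbc:objective>
  </fbc:listOfObjectives>
 </model>
</sbml>
"""
        path = tmp_path / "boundary.xml"
        path.write_text(sbml)
        m = read_sbml(str(path))
        assert m.metabolite_ids == ["A"]
        assert m.n_metabolites == 1 and m.n_reactions == 2
        assert m.objective.tolist() == [0.0, 1.0]

    def test_level2_kinetic_law_fallback(self, tmp_path):
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="l2toy">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" reversible="true">
    <listOfProducts><speciesReference species="A"/></listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="-7"/>
      <parameter id="UPPER_BOUND" value="7"/>
      <parameter id="OBJECTIVE_COEFFICIENT" value="0"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="R2" reversible="false">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="0"/>
      <parameter id="UPPER_BOUND" value="9"/>
      <parameter id="OBJECTIVE_COEFFICIENT" value="1"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""
        path = tmp_path / "l2.xml"
        path.write_text(sbml)
        m = read_sbml(str(path))
        assert m.lower_bounds.tolist() == [-7.0, 0.0]
        assert m.upper_bounds.tolist() == [7.0, 9.0]
        assert m.objective.tolist() == [0.0, 1.0]

    def test_default_bounds_when_missing(self, tmp_path):
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="nobounds">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies><species id="A" compartment="c"/></listOfSpecies>
  <listOfReactions>
   <reaction id="Rrev" reversible="true">
    <listOfProducts><speciesReference species="A"/></listOfProducts>
   </reaction>
   <reaction id="Rirr" reversible="false">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""
        path = tmp_path / "nb.xml"
        path.write_text(sbml)
        m = read_sbml(str(path))
        assert m.lower_bounds.tolist() == [-1000.0, 0.0]
        assert m.upper_bounds.tolist() == [1000.0, 1000.0]

    def test_sbml_and_json_readers_agree(self, tmp_path):
        m = make_random_model(4, 9, seed=21)
        write_sbml(m, str(tmp_path / "m.xml"))
        write_json_model(m, str(tmp_path / "m.json"))
        a = read_sbml(str(tmp_path / "m.xml"))
        b = read_json_model(str(tmp_path / "m.json"))
        assert np.allclose(a.S.toarray(), b.S.toarray())
        assert np.allclose(a.lower_bounds, b.lower_bounds)
        assert np.allclose(a.upper_bounds, b.upper_bounds)
        assert np.allclose(a.objective, b.objective)


class TestValidate:
    def test_clean_model_has_no_findings(self, linear_pathway):
        assert validate_model(linear_pathway) == []

    def test_bound_inversion_named(self, diamond):
        diamond.lower_bounds[1] = 5.0
        diamond.upper_bounds[1] = 1.0
        findings = validate_model(diamond)
        assert any("R2" in f and "bound inversion" in f for f in findings)

    def test_zero_column_named(self, diamond):
        S = diamond.S.toarray()
        S[:, 2] = 0.0
        diamond.S = sp.csc_matrix(S)
        findings = validate_model(diamond)
        assert any("R3" in f and "all-zero" in f for f in findings)

    def test_zero_objective_flagged(self, diamond):
        diamond.objective[:] = 0.0
        assert any("objective" in f for f in validate_model(diamond))


class TestResultTable:
    def test_tsv_shape_and_round_trip(self, tmp_path, linear_pathway):
        from fvakit import FVAConfig, run_fva

        res = run_fva(linear_pathway, FVAConfig(gamma=0.9))
        path = tmp_path / "out.tsv"
        write_fva_tsv(res, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0].split("\t") == [
            "reaction_id", "minimum", "maximum", "status_min", "status_max"]
        df = read_fva_tsv(str(path))
        # full double precision survives the round trip
        assert np.allclose(df["minimum"].to_numpy(), res.min_flux, rtol=1e-15)
        assert np.allclose(df["maximum"].to_numpy(), res.max_flux, rtol=1e-15)

    def test_infinite_ranges_written_as_inf_tokens(self, tmp_path):
        class Dummy:
            reaction_ids = ["R1"]
            min_flux = np.array([-np.inf])
            max_flux = np.array([np.inf])
            status_min = ["unbounded"]
            status_max = ["unbounded"]

        path = tmp_path / "inf.tsv"
        write_fva_tsv(Dummy(), str(path))
        row = path.read_text().splitlines()[1].split("\t")
        assert row[1] == "-inf" and row[2] == "inf"


def test_reaction_subset_parsing(tmp_path):
    path = tmp_path / "subset.txt"
    path.write_text("# comment line\nR1\nR3  # trailing comment\n\nR2\n")
    assert read_reaction_subset(str(path)) == ["R1", "R3", "R2"]
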