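"""Model structures, SBML round trips, editing and purge semantics."""

import math

import pytest

from fluxcheck import (
    Compartment,
    EditPatch,
    Model,
    PatchError,
    Reaction,
    Species,
    ValidationError,
    apply_patch,
    purge_boundary_species,
    purge_disconnected_clusters,
    purge_isolated_nodes,
    read_sbml,
    search,
    stoichiometric_matrix,
    write_sbml,
)
from fluxcheck.fixtures import random_model, plant


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------


def test_roundtrip_identity_on_all_toys(toys, tmp_path):
    for name, model in toys.items():
        path = tmp_path / f"{name}.xml"
        write_sbml(model, str(path))
        again = read_sbml(str(path))
        assert model.equal_fields(again), name
        # read∘write∘read is stable
        path2 = tmp_path / f"{name}_2.xml"
        write_sbml(again, str(path2))
        assert again.equal_fields(read_sbml(str(path2)))


def test_roundtrip_identity_on_random_planted_models(tmp_path):
    for seed, kind in [(3, "dead_end"), (4, "misdirected"), (5, "trap")]:
        model, _ = plant(random_model(15, 22, 0.3, seed), kind, seed)
        path = tmp_path / f"m{seed}.xml"
        write_sbml(model, str(path))
        assert model.equal_fields(read_sbml(str(path)))


def test_biomass_designation_survives_roundtrip(toys, tmp_path):
    model = toys["biomass_toy"]
    path = tmp_path / "bio.xml"
    write_sbml(model, str(path))
    assert read_sbml(str(path)).biomass == "BIO"


def test_empty_model_roundtrip(tmp_path):
    path = tmp_path / "empty.xml"
    write_sbml(Model("nothing"), str(path))
    again = read_sbml(str(path))
    assert not again.species and not again.reactions


def test_reversible_flag_follows_bounds(toys, tmp_path):
    model = toys["chain3"].copy()
    model.reactions["R_AB"].lb = -1000.0
    path = tmp_path / "rev.xml"
    write_sbml(model, str(path))
    again = read_sbml(str(path))
    assert again.reactions["R_AB"].reversible
    assert again.reactions["R_AB"].lb < 0


def test_default_bounds_when_sbml_has_none(tmp_path):
    # plain L3 document, no fbc bounds, no kinetic law
    xml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="m">
  <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c" hasOnlySubstanceUnits="false"
            boundaryCondition="false" constant="false"/>
   <species id="B" compartment="c" hasOnlySubstanceUnits="false"
            boundaryCondition="false" constant="false"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="Rrev" reversible="true" fast="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
   </reaction>
   <reaction id="Rirr" reversible="false" fast="false">
    <listOfReactants><speciesReference species="B" stoichiometry="1" constant="true"/></listOfReactants>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
    path = tmp_path / "nobounds.xml"
    path.write_text(xml)
    model = read_sbml(str(path))
    assert (model.reactions["Rrev"].lb, model.reactions["Rrev"].ub) == (-1000.0, 1000.0)
    assert (model.reactions["Rirr"].lb, model.reactions["Rirr"].ub) == (0.0, 1000.0)


def test_kinetic_law_bounds_are_read(tmp_path):
    xml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="m">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c"/>
   <species id="A_b" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" reversible="false">
    <listOfReactants><speciesReference species="A_b"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
    <kineticLaw>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="0"/>
      <parameter id="UPPER_BOUND" value="42.5"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
    path = tmp_path / "l2.xml"
    path.write_text(xml)
    model = read_sbml(str(path))
    assert model.reactions["R1"].ub == 42.5
    # "_b" suffix convention flags the boundary placeholder
    assert model.species["A_b"].boundary and not model.species["A"].boundary


def test_dangling_species_reference_names_offender(tmp_path):
    xml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="m">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies><species id="A" compartment="c"/></listOfSpecies>
  <listOfReactions>
   <reaction id="R1" reversible="false">
    <listOfReactants><speciesReference species="X"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
    path = tmp_path / "dangling.xml"
    path.write_text(xml)
    with pytest.raises(ValidationError, match="X"):
        read_sbml(str(path))


def test_missing_file_raises_io_error():
    with pytest.raises((IOError, ValidationError)):
        read_sbml("/no/such/file.xml")


# ---------------------------------------------------------------------------
# Editing
# ---------------------------------------------------------------------------


def test_set_irreversible_clamps_lower_bound(toys):
    model = toys["chain3"].copy()
    model.reactions["R_AB"].lb = -500.0
    patch = EditPatch([{"action": "modify", "kind": "reaction", "id": "R_AB",
                        "fields": {"reversible": False}}])
    out, _ = apply_patch(model, patch)
    assert out.reactions["R_AB"].lb == 0.0
    assert not out.reactions["R_AB"].reversible


def test_delete_species_cascades_and_reports(toys):
    out, report = apply_patch(
        toys["chain3"],
        EditPatch([{"action": "delete", "kind": "species", "id": "B"}]),
    )
    assert out.reactions["R_AB"].stoich == {"A": -1.0}  # A -> nothing: export
    assert "R_AB" in report.affected_reactions
    assert "EX_B" in report.affected_reactions


def test_patch_is_atomic_on_failure(toys):
    model = toys["chain3"]
    patch = EditPatch([
        {"action": "modify", "kind": "reaction", "id": "R_AB", "fields": {"name": "renamed"}},
        {"action": "add", "kind": "reaction", "id": "RX",
         "fields": {"stoich": {"ghost": -1.0}}},
    ])
    with pytest.raises(PatchError):
        apply_patch(model, patch)
    # the input model never saw the first (valid) edit
    assert model.reactions["R_AB"].name == ""


def test_duplicate_add_and_unknown_modify_fail(toys):
    with pytest.raises(PatchError):
        apply_patch(toys["chain3"], EditPatch(
            [{"action": "add", "kind": "species", "id": "A", "fields": {}}]))
    with pytest.raises(PatchError):
        apply_patch(toys["chain3"], EditPatch(
            [{"action": "modify", "kind": "reaction", "id": "NOPE", "fields": {}}]))


def test_delete_compartment_requires_emptying_first(toys):
    model = toys["deadend"]
    with pytest.raises(PatchError):
        apply_patch(model, EditPatch(
            [{"action": "delete", "kind": "compartment", "id": "c"}]))
    patch = EditPatch(
        [{"action": "delete", "kind": "species", "id": sid} for sid in ("A", "B")]
        + [{"action": "delete", "kind": "compartment", "id": "c"}]
    )
    out, report = apply_patch(model, patch)
    assert not out.compartments and report.removed_compartments == ["c"]


# ---------------------------------------------------------------------------
# Purges
# ---------------------------------------------------------------------------


def _with_boundary(toys):
    model = toys["chain3"].copy()
    model.add_species(Species("A_b", compartment="c", boundary=True))
    model.add_reaction(Reaction("R_in", stoich={"A_b": -1.0, "A": 1.0}, lb=0, ub=1000))
    return model


def test_boundary_purge_converts_to_import(toys):
    model = _with_boundary(toys)
    out, report = purge_boundary_species(model)
    assert "A_b" not in out.species
    assert out.reactions["R_in"].stoich == {"A": 1.0}
    assert ("R_in", "import") in report.converted_reactions


def test_boundary_purge_keeps_partial_reactant_sides(toys):
    model = _with_boundary(toys)
    model.reactions["R_in"].stoich["B"] = -1.0  # A_b + B -> A
    out, report = purge_boundary_species(model)
    assert out.reactions["R_in"].stoich == {"B": -1.0, "A": 1.0}
    assert ("R_in", "import") not in report.converted_reactions


def test_boundary_purge_without_boundary_species_is_identity(toys):
    out, report = purge_boundary_species(toys["chain3"])
    assert out.equal_fields(toys["chain3"]) and report.is_empty()


def test_boundary_purge_unknown_compartment_errors(toys):
    with pytest.raises(ValidationError):
        purge_boundary_species(toys["chain3"], compartment="nope")


def test_disconnected_purge_keeps_anchor_component(toys):
    model = toys["chain3"].copy()
    model.add_species(Species("C", compartment="c"))
    model.add_reaction(Reaction("R_C", stoich={"C": -1.0}, lb=0, ub=1000))
    out, report = purge_disconnected_clusters(model, anchor="A")
    assert set(out.species) == {"A", "B"}
    assert sorted(report.removed_species) == ["C"]
    assert sorted(report.removed_reactions) == ["R_C"]


def test_disconnected_purge_tie_breaks_on_smallest_id(toys):
    model = Model("ties", compartments=[Compartment("c")])
    for sid in ("A", "Z"):
        model.add_species(Species(sid, compartment="c"))
    model.add_reaction(Reaction("R_A", stoich={"A": 1.0}, lb=0, ub=1000))
    model.add_reaction(Reaction("R_Z", stoich={"Z": 1.0}, lb=0, ub=1000))
    out, _ = purge_disconnected_clusters(model)
    assert set(out.species) == {"A"}


def test_purges_are_idempotent(toys):
    model = _with_boundary(toys)
    model.add_species(Species("lonely", compartment="c"))
    once_b, _ = purge_boundary_species(model)
    twice_b, rep = purge_boundary_species(once_b)
    assert once_b.equal_fields(twice_b) and rep.is_empty()
    once_d, _ = purge_disconnected_clusters(model, anchor="A")
    twice_d, rep = purge_disconnected_clusters(once_d, anchor="A")
    assert once_d.equal_fields(twice_d) and rep.is_empty()
    once_i, _ = purge_isolated_nodes(model)
    twice_i, rep = purge_isolated_nodes(once_i)
    assert once_i.equal_fields(twice_i) and rep.is_empty()


def test_isolated_purge_removes_unused_species_and_empty_reactions(toys):
    model = toys["chain3"].copy()
    model.add_species(Species("U1", compartment="c"))
    model.add_species(Species("U2", compartment="c"))
    model.add_reaction(Reaction("R_empty", stoich={}, lb=0, ub=1000))
    out, report = purge_isolated_nodes(model)
    assert sorted(report.removed_species) == ["U1", "U2"]
    assert report.removed_reactions == ["R_empty"]
    assert out.equal_fields(purge_isolated_nodes(toys["chain3"])[0])


# ---------------------------------------------------------------------------
# Search & matrix
# ---------------------------------------------------------------------------


def test_search_substring_case_insensitive_and_sorted(toys):
    model = toys["chain3"].copy()
    model.species["A"].name = "Adenosine triphosphate"
    hits = search(model, "ab")
    assert hits == [("R_AB", "reaction", "id")]
    hits = search(model, "TRIPHOS")
    assert hits == [("A", "species", "name")]
    assert search(model, "ZZZZ") == []
    with pytest.raises(ValueError):
        search(model, "")


def test_search_prefers_id_when_both_match(toys):
    model = toys["chain3"].copy()
    model.reactions["R_AB"].name = "r_ab conversion"
    assert search(model, "r_ab") == [("R_AB", "reaction", "id")]


def test_stoichiometric_matrix_layout(toys):
    model = Model("m", compartments=[Compartment("c")])
    for sid in ("A", "B", "C", "X_b"):
        model.add_species(Species(sid, compartment="c", boundary=sid.endswith("_b")))
    model.add_reaction(Reaction("R1", stoich={"A": -1.0, "B": -2.0, "C": 1.0},
                                lb=0, ub=1000))
    model.add_reaction(Reaction("EX_A", stoich={"A": 1.0, "X_b": -1.0}, lb=0, ub=1000))
    S, rows, cols = stoichiometric_matrix(model)
    assert S.shape == (3, 2)  # boundary species contributes no row
    col = S[:, cols["R1"]].toarray().ravel()
    assert col[rows["A"]] == -1.0 and col[rows["B"]] == -2.0 and col[rows["C"]] == 1.0
    ex = S[:, cols["EX_A"]].toarray().ravel()
    assert ex[rows["A"]] == 1.0 and abs(ex).sum() == 1.0
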