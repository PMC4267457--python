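"""Format parsing, writing and component extraction."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluxkit import (
    FormatError,
    ModelValidationError,
    ConfigurationError,
    detect_exchange_reactions,
    extract_components,
    parse_flat_reactions,
    parse_metatool,
    parse_sbml,
    write_flat_reactions,
    write_metatool,
)
from fluxkit.gpr import parse_gpr
from fluxkit.toys import ToySpec, make_toy, write_sbml_fbc, write_sbml_notes

MINIMAL_METATOOL = """
-ENZREV

-ENZIRREV
R1
-METINT
A B
-METEXT

-CAT
R1 : A = B .
"""


# -- SBML ----------------------------------------------------------------

def test_sbml_notes_round_trip_preserves_everything(branch_toy):
    model, _ = branch_toy
    model.get_reaction("R_b1").gpr = parse_gpr("(g1 and g2) or g3")
    parsed = parse_sbml(write_sbml_notes(model))
    assert [s.id for s in parsed.species] == [s.id for s in model.species]
    assert {s.id for s in parsed.boundary_species} == {"X_ext", "Y_ext"}
    assert {r.id: r.stoichiometry for r in parsed.reactions} == {
        r.id: r.stoichiometry for r in model.reactions
    }
    assert parsed.get_reaction("R_up").upper_bound == 10.0
    assert parsed.objective_ids == ["R_ex"]
    assert parsed.get_reaction("R_b1").gpr == parse_gpr("(g1 and g2) or g3")


def test_sbml_fbc_round_trip(lethal_pair_toy):
    model, _ = lethal_pair_toy
    parsed = parse_sbml(write_sbml_fbc(model))
    assert {r.id: r.stoichiometry for r in parsed.reactions} == {
        r.id: r.stoichiometry for r in model.reactions
    }
    assert parsed.objective_ids == ["R_ex"]
    assert parsed.genes() == ["g1", "g2"]
    assert parsed.get_reaction("R_iso1").gpr == parse_gpr("g1")


def test_sbml_gene_association_grammar(chain_toy):
    """A notes field `GENE_ASSOCIATION: (g1 and g2) or g3` maps to OR(AND(g1,g2),g3)."""
    model, _ = chain_toy
    model.get_reaction("R_mid").gpr = parse_gpr("(g1 and g2) or g3")
    parsed = parse_sbml(write_sbml_notes(model))
    gpr = parsed.get_reaction("R_mid").gpr
    assert gpr == parse_gpr("(g1 and g2) or g3")
    assert gpr.genes() == {"g1", "g2", "g3"}


def test_sbml_degenerate_model_no_reactions():
    doc = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="tiny">
    <listOfCompartments><compartment id="c"/></listOfCompartments>
    <listOfSpecies><species id="A" compartment="c"/></listOfSpecies>
  </model>
</sbml>"""
    model = parse_sbml(doc)
    assert [s.id for s in model.species] == ["A"]
    assert model.reactions == []


def test_sbml_malformed_xml_raises_format_error():
    with pytest.raises(FormatError, match="line"):
        parse_sbml("<sbml><model></sbml>")


def test_sbml_undeclared_species_raises_validation_error(chain_toy):
    model, _ = chain_toy
    text = write_sbml_notes(model).replace('species="B"', 'species="Zmissing"', 1)
    with pytest.raises(ModelValidationError, match="Zmissing"):
        parse_sbml(text)


def test_sbml_dialect_detection(chain_toy, lethal_pair_toy):
    notes = write_sbml_notes(chain_toy[0])
    fbc = write_sbml_fbc(lethal_pair_toy[0])
    assert parse_sbml(notes, dialect="cobra-notes").objective_ids == ["R_ex"]
    assert parse_sbml(fbc, dialect="fbc").objective_ids == ["R_ex"]
    with pytest.raises(FormatError):
        parse_sbml(notes, dialect="fbc")


def test_ecoli_core_parses_with_expected_dimensions(ecoli_core_sbml):
    model = parse_sbml(ecoli_core_sbml)
    assert len(model.species) == 72
    assert len(model.reactions) == 95
    assert len(model.genes()) == 137
    assert len(model.objective_ids) == 1


# -- Metatool ------------------------------------------------------------

def test_metatool_minimal_file():
    model = parse_metatool(MINIMAL_METATOOL)
    assert len(model.reactions) == 1
    r = model.get_reaction("R1")
    assert not r.reversible
    assert r.stoichiometry == {"A": Fraction(-1), "B": Fraction(1)}


def test_metatool_enzrev_marks_reversible():
    text = MINIMAL_METATOOL.replace("-ENZREV\n", "-ENZREV\nR2\n") + "R2 : B = A .\n"
    model = parse_metatool(text)
    assert model.get_reaction("R2").reversible
    assert not model.get_reaction("R1").reversible


def test_metatool_metext_marks_boundary():
    text = MINIMAL_METATOOL.replace("-METEXT\n", "-METEXT\nX\n").replace(
        "R1 : A = B .", "R1 : X + A = B ."
    )
    model = parse_metatool(text)
    assert {s.id for s in model.boundary_species} == {"X"}


def test_metatool_missing_section_raises():
    with pytest.raises(FormatError, match="-METEXT"):
        parse_metatool(MINIMAL_METATOOL.replace("-METEXT\n", ""))


def test_metatool_undeclared_metabolite_raises():
    with pytest.raises(ModelValidationError, match="Zmissing"):
        parse_metatool(MINIMAL_METATOOL.replace("A = B", "A = Zmissing"))


def test_metatool_round_trip(any_toy):
    model, _ = any_toy
    once = parse_metatool(write_metatool(model))
    twice = parse_metatool(write_metatool(once))
    assert once == twice
    assert {r.id: r.stoichiometry for r in once.reactions} == {
        r.id: r.stoichiometry for r in model.reactions
    }
    assert {s.id for s in once.boundary_species} == {
        s.id for s in model.boundary_species
    }


# -- flat reaction text --------------------------------------------------

def test_flat_format_examples():
    model = parse_flat_reactions("R1 : 2 A + B -> C\nR2 : C <-> D\n")
    r1 = model.get_reaction("R1")
    assert r1.stoichiometry == {"A": Fraction(-2), "B": Fraction(-1), "C": Fraction(1)}
    assert not r1.reversible
    assert model.get_reaction("R2").reversible


def test_flat_writer_format(chain_toy):
    model, _ = chain_toy
    text = write_flat_reactions(model)
    assert "R_up : X_ext -> A" in text
    rev = parse_flat_reactions("R : A <-> B\n")
    assert "<->" in write_flat_reactions(rev)


def test_flat_missing_arrow_reports_line_number():
    with pytest.raises(FormatError, match="line 2"):
        parse_flat_reactions("R1 : A -> B\nR2 : B C\n")


@given(
    st.lists(
        st.dictionaries(
            st.sampled_from(["A", "B", "C", "D"]),
            st.fractions(min_value=-5, max_value=5).filter(lambda f: f != 0),
            min_size=1,
            max_size=4,
        ),
        min_size=1,
        max_size=5,
    )
)
def test_flat_round_trip_preserves_coefficients(stoichs):
    """write-then-parse is the identity on stoichiometric content."""
    from fluxkit.core import MetabolicModel, Reaction, Species

    model = MetabolicModel(
        "m",
        [Species(s) for s in "ABCD"],
        [Reaction(f"R{i}", stoich) for i, stoich in enumerate(stoichs)],
    )
    parsed = parse_flat_reactions(write_flat_reactions(model))
    assert {r.id: r.stoichiometry for r in parsed.reactions} == {
        r.id: r.stoichiometry for r in model.reactions
    }


# -- component extraction ------------------------------------------------

def test_extract_genes_and_empty_gene_list(lethal_pair_toy, chain_toy):
    assert extract_components(lethal_pair_toy[0], "genes") == ["g1", "g2"]
    assert extract_components(chain_toy[0], "genes") == []


def test_extract_reactions_indexes_model(branch_toy):
    model, _ = branch_toy
    ids = extract_components(model, "reactions")
    assert ids == [r.id for r in model.reactions]
    assert len(ids) == len(set(ids))
    index = model.reaction_index
    assert all(index[rid].id == rid for rid in ids)


def test_extract_constraints_table(branch_toy):
    table = extract_components(branch_toy[0], "constraints")
    assert list(table.columns) == ["reaction", "lb", "ub"]
    assert table.set_index("reaction").loc["R_up", "ub"] == 10.0


def test_extract_objective_and_biomass_fallback(chain_toy):
    model, _ = chain_toy
    assert extract_components(model, "objective") == ["R_ex"]
    model.get_reaction("R_ex").objective_coefficient = 0.0
    with pytest.raises(ConfigurationError, match="no objective"):
        extract_components(model, "objective")
    model.get_reaction("R_mid").name = "Biomass drain"
    assert extract_components(model, "objective") == ["R_mid"]


def test_extract_catalysts(chain_toy):
    model, _ = chain_toy
    model.get_reaction("R_mid").catalysts = ["enzA", "enzB"]
    assert extract_components(model, "catalysts") == ["enzA", "enzB"]
    table = extract_components(model, "catalyst-table")
    assert table.set_index("reaction").loc["R_mid", "catalysts"] == "enzA enzB"


# -- exchange detection --------------------------------------------------

def test_exchange_detection_definition(chain_toy):
    model, _ = chain_toy
    # R_up and R_ex touch boundary species; R_mid is purely internal
    assert detect_exchange_reactions(model) == ["R_up", "R_ex"]


def test_exchange_detection_single_species_convention(ecoli_core_sbml):
    """In BiGG fbc models every EX_-prefixed reaction is a single-species
    exchange and must be detected as such."""
    model = parse_sbml(ecoli_core_sbml)
    detected = set(detect_exchange_reactions(model))
    ex_named = {r.id for r in model.reactions if r.id.startswith("R_EX_")}
    assert ex_named <= detected


def test_exchange_detection_invariant_under_reordering(branch_toy):
    model, _ = branch_toy
    before = set(detect_exchange_reactions(model))
    model.reactions = list(reversed(model.reactions))
    assert set(detect_exchange_reactions(model)) == before
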