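"""Programmatic toy networks with analytically known results.

Every module is testable without downloading a genome-scale model: the
generators here build miniature networks whose optima, essential sets,
variability intervals and pathway counts follow from the topology, and the
expected-results record returned alongside each model states them.  The
records themselves are asserted against the analysis modules in the test
suite, so the generator cannot drift from the code it exercises.

Topologies
----------
chain
    X_ext -> A -> B -> Y_ext with a capped uptake: optimum = cap, every
    reaction essential, one extreme path, no cycles.
branch
    Two parallel two-step routes A -> B -> D and A -> C -> D: optimum =
    cap, each branch reaction singly non-essential with flux interval
    [0, cap] at the optimum, four synthetic-lethal reaction pairs, two
    extreme paths.
cycle
    The chain plus a reverse reaction B -> A: one internal cycle.
lethal-pair
    Two parallel one-step routes gated by genes g1 and g2 (AND-free GPRs):
    singly non-essential, the pair {g1, g2} lethal.
custom
    An explicit edge list of unit A -> B conversions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from .core import INF, MetabolicModel, Reaction, Species
from .errors import ModelValidationError
from .gpr import parse_gpr

__all__ = ["ToySpec", "make_toy", "emit_fixture_files", "FIXTURE_FORMATS"]

FIXTURE_FORMATS = ("sbml-notes", "sbml-fbc", "metatool", "flat")

TOPOLOGIES = ("chain", "branch", "cycle", "lethal-pair", "custom")


@dataclass
class ToySpec:
    topology: str = "chain"
    cap: float = 10.0  # uptake flux cap, mmol/gDW/hr
    gpr: dict[str, str] | None = None  # reaction id -> GPR string
    seed: int = 0
    edges: list[tuple[str, str, str]] | None = None  # (rid, substrate, product)
    species: list[str] | None = None  # custom: declared species (all must be used)


def _rxn(rid, stoich, lb=0.0, ub=INF, rev=False, obj=0.0, gpr=None):
    return Reaction(
        id=rid,
        stoichiometry={s: Fraction(c) for s, c in stoich.items()},
        reversible=rev,
        lower_bound=lb,
        upper_bound=ub,
        objective_coefficient=obj,
        gpr=parse_gpr(gpr),
    )


def make_toy(spec: ToySpec) -> tuple[MetabolicModel, dict]:
    """Build the model for ``spec`` plus its expected-results record."""
    if spec.topology not in TOPOLOGIES:
        raise ModelValidationError(f"unknown toy topology: {spec.topology!r}")
    cap = float(spec.cap)
    builder = {
        "chain": _build_chain,
        "branch": _build_branch,
        "cycle": _build_cycle,
        "lethal-pair": _build_lethal_pair,
        "custom": _build_custom,
    }[spec.topology]
    model, expected = builder(spec, cap)
    if spec.gpr:
        for rid, text in spec.gpr.items():
            model.get_reaction(rid).gpr = parse_gpr(text)
    model.validate()
    return model, expected


def _boundary_pair(cap):
    species = [
        Species("X_ext", compartment="e", is_boundary=True),
        Species("Y_ext", compartment="e", is_boundary=True),
    ]
    return species


def _build_chain(spec, cap):
    model = MetabolicModel(f"toy_chain_{spec.seed}")
    model.species = _boundary_pair(cap) + [
        Species("A", compartment="c"),
        Species("B", compartment="c"),
    ]
    model.reactions = [
        _rxn("R_up", {"X_ext": -1, "A": 1}, ub=cap),
        _rxn("R_mid", {"A": -1, "B": 1}),
        _rxn("R_ex", {"B": -1, "Y_ext": 1}, obj=1.0),
    ]
    expected = {
        "optimum": cap,
        "objective_id": "R_ex",
        "essential_reactions": ["R_up", "R_mid", "R_ex"],
        "n_extreme_paths": 1,
        "n_cycles": 0,
        "fva_fraction1": {r: (cap, cap) for r in ("R_up", "R_mid", "R_ex")},
    }
    return model, expected


def _build_branch(spec, cap):
    model = MetabolicModel(f"toy_branch_{spec.seed}")
    model.species = _boundary_pair(cap) + [
        Species(s, compartment="c") for s in ("A", "B", "C", "D")
    ]
    model.reactions = [
        _rxn("R_up", {"X_ext": -1, "A": 1}, ub=cap),
        _rxn("R_b1", {"A": -1, "B": 1}),
        _rxn("R_b2", {"A": -1, "C": 1}),
        _rxn("R_c1", {"B": -1, "D": 1}),
        _rxn("R_c2", {"C": -1, "D": 1}),
        _rxn("R_ex", {"D": -1, "Y_ext": 1}, obj=1.0),
    ]
    branch = ["R_b1", "R_b2", "R_c1", "R_c2"]
    expected = {
        "optimum": cap,
        "objective_id": "R_ex",
        "essential_reactions": ["R_up", "R_ex"],
        "singly_nonessential": branch,
        # joint deletions that sever both routes
        "lethal_pairs": [
            ("R_b1", "R_b2"),
            ("R_b1", "R_c2"),
            ("R_b2", "R_c1"),
            ("R_c1", "R_c2"),
        ],
        "branch_reactions": branch,
        "branch_fva_fraction1": (0.0, cap),
        "n_extreme_paths": 2,
        "n_cycles": 0,
    }
    return model, expected


def _build_cycle(spec, cap):
    model = MetabolicModel(f"toy_cycle_{spec.seed}")
    model.species = _boundary_pair(cap) + [
        Species("A", compartment="c"),
        Species("B", compartment="c"),
    ]
    model.reactions = [
        _rxn("R_up", {"X_ext": -1, "A": 1}, ub=cap),
        _rxn("R_ab", {"A": -1, "B": 1}),
        _rxn("R_ba", {"B": -1, "A": 1}),
        _rxn("R_ex", {"B": -1, "Y_ext": 1}, obj=1.0),
    ]
    expected = {
        "optimum": cap,
        "objective_id": "R_ex",
        "n_cycles": 1,
        "cycle_support": ("R_ab", "R_ba"),
    }
    return model, expected


def _build_lethal_pair(spec, cap):
    model = MetabolicModel(f"toy_lethal_pair_{spec.seed}")
    model.species = _boundary_pair(cap) + [
        Species("A", compartment="c"),
        Species("B", compartment="c"),
    ]
    model.reactions = [
        _rxn("R_up", {"X_ext": -1, "A": 1}, ub=cap),
        _rxn("R_iso1", {"A": -1, "B": 1}, gpr="g1"),
        _rxn("R_iso2", {"A": -1, "B": 1}, gpr="g2"),
        _rxn("R_ex", {"B": -1, "Y_ext": 1}, obj=1.0),
    ]
    expected = {
        "optimum": cap,
        "objective_id": "R_ex",
        "singly_nonessential_genes": ["g1", "g2"],
        "lethal_gene_pair": ("g1", "g2"),
    }
    return model, expected


def _build_custom(spec, cap):
    if not spec.edges:
        raise ModelValidationError("custom topology requires an edge list")
    model = MetabolicModel(f"toy_custom_{spec.seed}")
    used: dict[str, None] = {}
    for _, src, dst in spec.edges:
        used.setdefault(src, None)
        used.setdefault(dst, None)
    declared = spec.species if spec.species is not None else list(used)
    dangling = sorted(set(declared) - set(used))
    if dangling:
        raise ModelValidationError(f"dangling species in custom toy: {dangling}")
    missing = sorted(set(used) - set(declared))
    if missing:
        raise ModelValidationError(f"edge species not declared: {missing}")
    model.species = [
        Species(sid, compartment="e" if sid.endswith("_ext") else "c",
                is_boundary=sid.endswith("_ext"))
        for sid in declared
    ]
    model.reactions = [
        _rxn(rid, {src: -1, dst: 1}, ub=cap if src.endswith("_ext") else INF)
        for rid, src, dst in spec.edges
    ]
    if model.reactions:
        model.reactions[-1].objective_coefficient = 1.0
    return model, {"objective_id": model.reactions[-1].id if model.reactions else None}


# -- fixture emission ----------------------------------------------------

def emit_fixture_files(
    model: MetabolicModel, formats=FIXTURE_FORMATS, outdir: str | Path = "."
) -> dict[str, Path]:
    """Write the model in each requested format; every file parses back to
    an equivalent model through :mod:`fluxkit.io`."""
    from .io import write_flat_reactions, write_metatool

    unknown = sorted(set(formats) - set(FIXTURE_FORMATS))
    if unknown:
        raise ModelValidationError(f"unknown fixture format(s): {unknown}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "sbml-notes":
            path = outdir / f"{model.id}.notes.xml"
            path.write_text(write_sbml_notes(model))
        elif fmt == "sbml-fbc":
            path = outdir / f"{model.id}.fbc.xml"
            path.write_text(write_sbml_fbc(model))
        elif fmt == "metatool":
            path = outdir / f"{model.id}.mt"
            path.write_text(write_metatool(model))
        else:
            path = outdir / f"{model.id}.reactions"
            path.write_text(write_flat_reactions(model))
        paths[fmt] = path
    return paths


def write_sbml_notes(model: MetabolicModel) -> str:
    """Serialize as SBML Level 2 with COBRA-style notes and kinetic-law
    bound parameters (fixture writer; genome-scale authoring is out of scope)."""
    import libsbml

    doc = libsbml.SBMLDocument(2, 4)
    m = doc.createModel()
    m.setId(model.id)
    _add_compartments(m, model)
    for s in model.species:
        sp = m.createSpecies()
        sp.setId(s.id)
        sp.setName(s.name or s.id)
        sp.setCompartment(s.compartment or "c")
        sp.setBoundaryCondition(s.is_boundary)
    for r in model.reactions:
        rx = m.createReaction()
        rx.setId(r.id)
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        _add_stoich(rx, r)
        notes = []
        if r.gpr is not None:
            notes.append(f"GENE_ASSOCIATION: {r.gpr}")
        if r.catalysts:
            notes.append(f"PROTEIN_ASSOCIATION: {' or '.join(r.catalysts)}")
        if notes:
            body = "".join(f"<p>{n}</p>" for n in notes)
            rx.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
        kl = rx.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pname, pval in (
            ("LOWER_BOUND", r.lower_bound),
            ("UPPER_BOUND", r.upper_bound),
            ("OBJECTIVE_COEFFICIENT", r.objective_coefficient),
            ("FLUX_VALUE", 0.0),
        ):
            p = kl.createParameter()
            p.setId(pname)
            p.setValue(float(pval))
    return libsbml.writeSBMLToString(doc)


def write_sbml_fbc(model: MetabolicModel) -> str:
    """Serialize as SBML Level 3 + fbc version 2 (fixture writer)."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    m = doc.createModel()
    m.setId(model.id)
    mplug = m.getPlugin("fbc")
    mplug.setStrict(True)
    _add_compartments(m, model, l3=True)
    for s in model.species:
        sp = m.createSpecies()
        sp.setId(s.id)
        sp.setName(s.name or s.id)
        sp.setCompartment(s.compartment or "c")
        sp.setBoundaryCondition(s.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
    for r in model.reactions:
        for which, val in (("lb", r.lower_bound), ("ub", r.upper_bound)):
            p = m.createParameter()
            p.setId(f"{r.id}_{which}")
            p.setValue(float(val))
            p.setConstant(True)
        rx = m.createReaction()
        rx.setId(r.id)
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        _add_stoich(rx, r, l3=True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(f"{r.id}_lb")
        rplug.setUpperFluxBound(f"{r.id}_ub")
        if r.gpr is not None:
            # setAssociation parses the infix by gene *label*, creating the
            # geneProduct entries as a side effect
            rplug.createGeneProductAssociation().setAssociation(str(r.gpr))
    obj_ids = model.objective_ids
    if obj_ids:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        for rid in obj_ids:
            fo = objective.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(model.get_reaction(rid).objective_coefficient)
        mplug.setActiveObjectiveId("obj")
    return libsbml.writeSBMLToString(doc)


def _add_compartments(m, model, l3=False):
    comps = {s.compartment or "c" for s in model.species} or {"c"}
    for cid in sorted(comps):
        c = m.createCompartment()
        c.setId(cid)
        if l3:
            c.setConstant(True)


def _add_stoich(rx, r: Reaction, l3=False):
    for sid, coeff in r.stoichiometry.items():
        sr = rx.createReactant() if coeff < 0 else rx.createProduct()
        sr.setSpecies(sid)
        sr.setStoichiometry(float(abs(coeff)))
        if l3:
            sr.setConstant(True)
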