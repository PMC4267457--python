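"""SBML readers for the two constraint-based dialects in circulation.

* **cobra-notes** (SBML Level 2): flux bounds and objective coefficients as
  ``LOWER_BOUND`` / ``UPPER_BOUND`` / ``OBJECTIVE_COEFFICIENT`` kinetic-law
  parameters, gene associations in the reaction notes field
  (``GENE_ASSOCIATION: (g1 and g2) or g3``), boundary metabolites flagged
  with ``boundaryCondition="true"``.
* **fbc** (SBML Level 3 with the flux-balance-constraints package): bounds as
  global parameters referenced by ``fbc:lowerFluxBound``, gene associations
  as ``fbc:geneProductAssociation`` trees, the objective as an explicit
  ``fbc:listOfObjectives`` entry.

Both carry the same information, so a single reader with auto-detection
(fbc package present -> fbc path, else notes path) serves both.
"""

from __future__ import annotations

import math
import re
from fractions import Fraction
from pathlib import Path

import libsbml

from ..core import INF, MetabolicModel, Reaction, Species
from ..errors import FormatError
from ..gpr import And, Gene, Gpr, Or, parse_gpr

__all__ = ["parse_sbml", "read_sbml_file"]

# Compartment names conventionally used for the outside world when the
# boundaryCondition attribute is not set.
_EXTERNAL_COMPARTMENTS = {"b", "boundary", "extraorganism"}

_NOTE_KEYS_GPR = ("GENE_ASSOCIATION", "GENE ASSOCIATION")
_NOTE_KEYS_PROTEIN = ("PROTEIN_ASSOCIATION", "PROTEIN ASSOCIATION")


def parse_sbml(document: str, dialect: str = "auto") -> MetabolicModel:
    """Parse SBML text into a :class:`MetabolicModel`.

    Parameters
    ----------
    document:
        The SBML file content.
    dialect:
        ``"auto"`` (default), ``"cobra-notes"`` or ``"fbc"``.  Auto-detection
        uses the fbc path whenever the document declares the fbc package.
    """
    if dialect not in ("auto", "cobra-notes", "fbc"):
        raise ValueError(f"unknown SBML dialect: {dialect!r}")
    doc = libsbml.readSBMLFromString(document)
    _raise_on_errors(doc)
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML document contains no model element")

    fbc_plug = sbml_model.getPlugin("fbc")
    if dialect == "auto":
        dialect = "fbc" if fbc_plug is not None else "cobra-notes"
    if dialect == "fbc" and fbc_plug is None:
        raise FormatError("fbc dialect requested but the document has no fbc package")

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for s in sbml_model.getListOfSpecies():
        boundary = bool(s.getBoundaryCondition())
        if not boundary and s.getCompartment().lower() in _EXTERNAL_COMPARTMENTS:
            boundary = True
        model.species.append(
            Species(
                id=s.getId(),
                name=s.getName() or "",
                compartment=s.getCompartment() or "",
                is_boundary=boundary,
            )
        )

    gene_labels = _gene_product_labels(fbc_plug) if dialect == "fbc" else {}

    for r in sbml_model.getListOfReactions():
        stoich: dict[str, Fraction] = {}
        for sr in r.getListOfReactants():
            stoich[sr.getSpecies()] = (
                stoich.get(sr.getSpecies(), Fraction(0)) - _coeff(sr)
            )
        for sr in r.getListOfProducts():
            stoich[sr.getSpecies()] = (
                stoich.get(sr.getSpecies(), Fraction(0)) + _coeff(sr)
            )
        stoich = {sid: c for sid, c in stoich.items() if c != 0}

        reversible = bool(r.getReversible())
        lb, ub, obj = _bounds_and_objective(sbml_model, r, dialect, reversible)
        gpr = _gene_association(r, dialect, gene_labels)
        catalysts = _catalysts(r)

        model.reactions.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or "",
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                catalysts=catalysts,
                objective_coefficient=obj,
            )
        )

    if dialect == "fbc":
        _apply_fbc_objective(model, fbc_plug)

    model.validate()
    return model


def read_sbml_file(path: str | Path, dialect: str = "auto") -> MetabolicModel:
    return parse_sbml(Path(path).read_text(), dialect=dialect)


def _raise_on_errors(doc: libsbml.SBMLDocument) -> None:
    fatal = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            fatal.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if fatal:
        raise FormatError("SBML parse failed: " + "; ".join(fatal))


def _coeff(sr: libsbml.SpeciesReference) -> Fraction:
    v = sr.getStoichiometry()
    if math.isnan(v):
        v = 1.0
    return Fraction(str(v))


def _param_value(kl, name: str) -> float | None:
    if kl is None:
        return None
    p = kl.getParameter(name)
    if p is None or not p.isSetValue():
        return None
    return p.getValue()


def _global_bound(sbml_model, pid: str) -> float | None:
    if not pid:
        return None
    p = sbml_model.getParameter(pid)
    if p is None or not p.isSetValue():
        return None
    return p.getValue()


def _bounds_and_objective(sbml_model, r, dialect, reversible):
    lb = ub = None
    obj = 0.0
    if dialect == "fbc":
        rplug = r.getPlugin("fbc")
        if rplug is not None:
            lb = _global_bound(sbml_model, rplug.getLowerFluxBound())
            ub = _global_bound(sbml_model, rplug.getUpperFluxBound())
    else:
        kl = r.getKineticLaw()
        lb = _param_value(kl, "LOWER_BOUND")
        ub = _param_value(kl, "UPPER_BOUND")
        obj = _param_value(kl, "OBJECTIVE_COEFFICIENT") or 0.0
    if lb is None:
        lb = -INF if reversible else 0.0
    if ub is None:
        ub = INF
    return float(lb), float(ub), float(obj)


def _notes_field(r, keys) -> str | None:
    if not r.isSetNotes():
        return None
    text = r.getNotesString()
    text = re.sub(r"<[^>]+>", "\n", text)  # strip XHTML tags
    for line in text.splitlines():
        line = line.strip()
        for key in keys:
            if line.upper().startswith(key + ":"):
                return line[len(key) + 1 :].strip()
    return None


def _gene_association(r, dialect, gene_labels) -> Gpr | None:
    if dialect == "fbc":
        rplug = r.getPlugin("fbc")
        if rplug is None or rplug.getGeneProductAssociation() is None:
            return None
        assoc = rplug.getGeneProductAssociation().getAssociation()
        return _fbc_association_to_gpr(assoc, gene_labels)
    return parse_gpr(_notes_field(r, _NOTE_KEYS_GPR))


def _fbc_association_to_gpr(assoc, gene_labels) -> Gpr | None:
    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return Gene(gene_labels.get(gid, gid))
    children = tuple(
        g
        for i in range(assoc.getNumAssociations())
        if (g := _fbc_association_to_gpr(assoc.getAssociation(i), gene_labels))
        is not None
    )
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    if isinstance(assoc, libsbml.FbcAnd):
        return And(children)
    return Or(children)


def _gene_product_labels(fbc_plug) -> dict[str, str]:
    labels = {}
    if fbc_plug is None:
        return labels
    for gp in fbc_plug.getListOfGeneProducts():
        labels[gp.getId()] = gp.getLabel() or gp.getId()
    return labels


def _apply_fbc_objective(model: MetabolicModel, fbc_plug) -> None:
    if fbc_plug is None or fbc_plug.getNumObjectives() == 0:
        return
    active = fbc_plug.getActiveObjective() or fbc_plug.getObjective(0)
    if active is None:
        return
    coeffs = {
        fo.getReaction(): fo.getCoefficient() for fo in active.getListOfFluxObjectives()
    }
    for r in model.reactions:
        r.objective_coefficient = float(coeffs.get(r.id, 0.0))


def _catalysts(r) -> list[str]:
    out: dict[str, None] = {}
    for i in range(r.getNumModifiers()):
        out.setdefault(r.getModifier(i).getSpecies(), None)
    prot = _notes_field(r, _NOTE_KEYS_PROTEIN)
    if prot:
        tree = parse_gpr(prot)
        if tree is not None:
            for name in sorted(tree.genes()):
                out.setdefault(name, None)
    return list(out)
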