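"""Flat reaction-equation text: one reaction per line.

::

    R1 : 2 A + B -> C
    R2 : C <-> D

``->`` marks an irreversible reaction, ``<->`` a reversible one.  Unit
coefficients are omitted; fractional ones are written ``p/q``.  The format
carries no bounds, boundary flags or gene associations — it is the minimal
stoichiometric view (the "reactions without ids" retriever drops the id and
colon as well).
"""

from __future__ import annotations

from fractions import Fraction

from ..core import INF, MetabolicModel, Reaction, Species
from ..errors import FormatError
from .metatool import _parse_side, _side_text

__all__ = ["parse_flat_reactions", "write_flat_reactions"]


def parse_flat_reactions(text: str, model_id: str = "model") -> MetabolicModel:
    model = MetabolicModel(id=model_id)
    seen_species: dict[str, None] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "<->" in line:
            arrow, reversible = "<->", True
        elif "->" in line:
            arrow, reversible = "->", False
        else:
            raise FormatError(f"line {lineno}: no '->' or '<->' arrow: {line!r}")
        if ":" in line:
            rid, _, body = line.partition(":")
            rid = rid.strip()
        else:
            rid, body = f"R{lineno}", line
        lhs, _, rhs = body.partition(arrow)
        stoich: dict[str, Fraction] = {}
        _parse_side(lhs, -1, stoich)
        _parse_side(rhs, +1, stoich)
        stoich = {s: c for s, c in stoich.items() if c != 0}
        if not stoich:
            raise FormatError(f"line {lineno}: reaction {rid!r} has empty stoichiometry")
        for sid in stoich:
            seen_species.setdefault(sid, None)
        model.reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=-INF if reversible else 0.0,
                upper_bound=INF,
            )
        )
    model.species = [Species(id=sid) for sid in seen_species]
    model.validate()
    return model


def write_flat_reactions(model: MetabolicModel, with_ids: bool = True) -> str:
    lines = []
    for r in model.reactions:
        lhs = _side_text([(s, -c) for s, c in r.stoichiometry.items() if c < 0])
        rhs = _side_text([(s, c) for s, c in r.stoichiometry.items() if c > 0])
        arrow = "<->" if r.reversible else "->"
        body = f"{lhs} {arrow} {rhs}".strip()
        lines.append(f"{r.id} : {body}" if with_ids else body)
    return "\n".join(lines) + "\n"
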