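"""Metatool input-file format (read/write).

The classic elementary-flux-mode tool takes a sectioned text file::

    -ENZREV
    R2
    -ENZIRREV
    R1
    -METINT
    A B
    -METEXT
    X
    -CAT
    R1 : X = A .
    R2 : A = B .

``-ENZREV`` / ``-ENZIRREV`` list reversible / irreversible reaction names,
``-METINT`` / ``-METEXT`` internal / external metabolites, and ``-CAT`` the
equations (``=`` separates substrates from products, a line ends with
``.``).  External metabolites become boundary species.  Bounds are not part
of the format; reversible reactions get (-inf, inf) and irreversible ones
(0, inf).

Fractional coefficients are written as ``p/q`` so that a write/parse round
trip is exact.
"""

from __future__ import annotations

import re
from fractions import Fraction

from ..core import INF, MetabolicModel, Reaction, Species
from ..errors import FormatError, ModelValidationError

__all__ = ["parse_metatool", "write_metatool"]

_SECTIONS = ("-ENZREV", "-ENZIRREV", "-METINT", "-METEXT", "-CAT")


def parse_metatool(text: str, model_id: str = "model") -> MetabolicModel:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.split()[0] in _SECTIONS:
            current = line.split()[0]
            sections[current] = []
            rest = line[len(current) :].strip()
            if rest:
                sections[current].append(rest)
        elif current is None:
            raise FormatError(f"content before any section header: {line!r}")
        else:
            sections[current].append(line)

    missing = [s for s in _SECTIONS if s not in sections]
    if missing:
        raise FormatError(f"missing Metatool section header(s): {missing}")

    rev = _names(sections["-ENZREV"])
    irr = _names(sections["-ENZIRREV"])
    both = set(rev) & set(irr)
    if both:
        raise FormatError(f"reactions listed as both reversible and irreversible: {sorted(both)}")
    met_int = _names(sections["-METINT"])
    met_ext = _names(sections["-METEXT"])

    model = MetabolicModel(id=model_id)
    for sid in met_int:
        model.species.append(Species(id=sid))
    for sid in met_ext:
        model.species.append(Species(id=sid, is_boundary=True))
    declared = set(met_int) | set(met_ext)

    equations = _join_equations(sections["-CAT"])
    seen: set[str] = set()
    for eq in equations:
        rid, stoich = _parse_equation(eq, declared)
        if rid not in set(rev) | set(irr):
            raise FormatError(f"reaction {rid!r} in -CAT missing from -ENZREV/-ENZIRREV")
        reversible = rid in set(rev)
        model.reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=-INF if reversible else 0.0,
                upper_bound=INF,
            )
        )
        seen.add(rid)
    undefined = (set(rev) | set(irr)) - seen
    if undefined:
        raise FormatError(f"reaction(s) without a -CAT equation: {sorted(undefined)}")
    model.validate()
    return model


def write_metatool(model: MetabolicModel) -> str:
    lines = ["-ENZREV"]
    lines.append(" ".join(r.id for r in model.reactions if r.reversible))
    lines.append("")
    lines.append("-ENZIRREV")
    lines.append(" ".join(r.id for r in model.reactions if not r.reversible))
    lines.append("")
    lines.append("-METINT")
    lines.append(" ".join(s.id for s in model.species if not s.is_boundary))
    lines.append("")
    lines.append("-METEXT")
    lines.append(" ".join(s.id for s in model.species if s.is_boundary))
    lines.append("")
    lines.append("-CAT")
    for r in model.reactions:
        lhs = _side_text([(s, -c) for s, c in r.stoichiometry.items() if c < 0])
        rhs = _side_text([(s, c) for s, c in r.stoichiometry.items() if c > 0])
        lines.append(f"{r.id} : {lhs} = {rhs} .")
    return "\n".join(lines) + "\n"


def _names(lines: list[str]) -> list[str]:
    out: list[str] = []
    for line in lines:
        out.extend(line.split())
    return out


def _join_equations(lines: list[str]) -> list[str]:
    """Equations end with '.'; a long one may wrap over several lines."""
    eqs: list[str] = []
    buf: list[str] = []
    for line in lines:
        buf.append(line)
        if line.rstrip().endswith("."):
            eqs.append(" ".join(buf))
            buf = []
    if buf:
        eqs.append(" ".join(buf))
    return eqs


_COEFF_RE = re.compile(r"^\d+(/\d+)?$|^\d*\.\d+$")


def _parse_side(text: str, sign: int, stoich: dict[str, Fraction]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        parts = term.split()
        if not parts:
            raise FormatError(f"empty term in equation side: {text!r}")
        if len(parts) == 2 and _COEFF_RE.match(parts[0]):
            coeff, name = Fraction(parts[0]), parts[1]
        elif len(parts) == 1:
            coeff, name = Fraction(1), parts[0]
        else:
            raise FormatError(f"cannot parse term {term.strip()!r}")
        stoich[name] = stoich.get(name, Fraction(0)) + sign * coeff


def _parse_equation(eq: str, declared: set[str]) -> tuple[str, dict[str, Fraction]]:
    eq = eq.strip()
    if eq.endswith("."):
        eq = eq[:-1]
    if ":" not in eq:
        raise FormatError(f"-CAT line without ':' separator: {eq!r}")
    rid, _, body = eq.partition(":")
    rid = rid.strip()
    if "=" not in body:
        raise FormatError(f"-CAT equation for {rid!r} has no '='")
    lhs, _, rhs = body.partition("=")
    stoich: dict[str, Fraction] = {}
    _parse_side(lhs, -1, stoich)
    _parse_side(rhs, +1, stoich)
    stoich = {s: c for s, c in stoich.items() if c != 0}
    unknown = sorted(set(stoich) - declared)
    if unknown:
        raise ModelValidationError(
            f"reaction {rid!r} names metabolite(s) absent from -METINT/-METEXT: {unknown}"
        )
    return rid, stoich


def _side_text(terms: list[tuple[str, Fraction]]) -> str:
    parts = []
    for sid, coeff in terms:
        parts.append(sid if coeff == 1 else f"{coeff} {sid}")
    return " + ".join(parts)
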