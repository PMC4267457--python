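"""In-memory representation of a constraint-based metabolic model.

A model is an ordered collection of chemical species and reactions.  Species
flagged ``is_boundary`` sit outside the system boundary (external metabolite
pools) and are excluded from mass balance.  Each reaction carries a signed
rational stoichiometry (negative = consumed, positive = produced), flux
bounds in mmol/gDW/hr, an optional gene association, an optional catalyst
list, and an objective coefficient (its entry in the vector c of the LP
``maximize c'v  s.t.  S v = 0,  lb <= v <= ub``).

Unbounded fluxes are stored as genuine ``math.inf`` sentinels; a finite
magnitude is substituted only when a linear program is assembled (see
:mod:`fluxkit.fba`), keeping the model semantics exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

from .errors import ModelValidationError, UnknownIdError
from .gpr import Gpr

INF = math.inf
#: Finite magnitude substituted for an infinite bound when an LP is solved.
DEFAULT_INF_BOUND = 1000.0

__all__ = [
    "INF",
    "DEFAULT_INF_BOUND",
    "Species",
    "Reaction",
    "MetabolicModel",
    "detect_exchange_reactions",
]


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = ""
    is_boundary: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    name: str = ""
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = INF
    gpr: Gpr | None = None
    catalysts: list[str] = field(default_factory=list)
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        self.stoichiometry = {
            sid: coeff if isinstance(coeff, Fraction) else Fraction(str(coeff))
            for sid, coeff in self.stoichiometry.items()
        }
        # Irreversible reactions may not run backwards; clamp a sloppy lb.
        if not self.reversible and self.lower_bound < 0:
            self.lower_bound = 0.0

    def reactants(self) -> list[str]:
        return [s for s, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [s for s, c in self.stoichiometry.items() if c > 0]

    def copy(self) -> "Reaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            catalysts=list(self.catalysts),
        )


class MetabolicModel:
    """Ordered species + reactions with unique ids; the target of every parser."""

    def __init__(
        self,
        id: str = "model",
        species: list[Species] | None = None,
        reactions: list[Reaction] | None = None,
    ):
        self.id = id
        self.species: list[Species] = list(species or [])
        self.reactions: list[Reaction] = list(reactions or [])
        #: populated by split_reversible: split reaction id -> (original id, sign)
        self.split_map: dict[str, tuple[str, int]] = {}

    # -- lookups ---------------------------------------------------------
    @property
    def species_index(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    @property
    def reaction_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self.reaction_index[rid]
        except KeyError:
            raise UnknownIdError(f"unknown reaction id: {rid!r}") from None

    def get_species(self, sid: str) -> Species:
        try:
            return self.species_index[sid]
        except KeyError:
            raise UnknownIdError(f"unknown species id: {sid!r}") from None

    # -- derived collections ---------------------------------------------
    @property
    def internal_species(self) -> list[Species]:
        return [s for s in self.species if not s.is_boundary]

    @property
    def boundary_species(self) -> list[Species]:
        return [s for s in self.species if s.is_boundary]

    def genes(self) -> list[str]:
        """All GPR leaf genes, model order, duplicate-free."""
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.gpr is not None:
                for g in sorted(r.gpr.genes()):
                    seen.setdefault(g, None)
        return list(seen)

    def catalysts(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for c in r.catalysts:
                seen.setdefault(c, None)
        return list(seen)

    @property
    def objective_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.objective_coefficient != 0.0]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        problems: list[str] = []
        sids = [s.id for s in self.species]
        if len(sids) != len(set(sids)):
            dups = sorted({x for x in sids if sids.count(x) > 1})
            problems.append(f"duplicate species ids: {dups}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dups = sorted({x for x in rids if rids.count(x) > 1})
            problems.append(f"duplicate reaction ids: {dups}")
        declared = set(sids)
        for r in self.reactions:
            missing = sorted(set(r.stoichiometry) - declared)
            if missing:
                problems.append(f"reaction {r.id!r} references undeclared species: {missing}")
            if not any(c != 0 for c in r.stoichiometry.values()):
                problems.append(f"reaction {r.id!r} has no nonzero coefficient")
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id!r} has lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
                )
        for s in self.species:
            if not s.id:
                problems.append("species with empty id")
        if problems:
            raise ModelValidationError("; ".join(problems))

    # -- copying ---------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(
            self.id,
            [replace(s) for s in self.species],
            [r.copy() for r in self.reactions],
        )
        m.split_map = dict(self.split_map)
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            [(s.id, s.compartment, s.is_boundary) for s in self.species]
            == [(s.id, s.compartment, s.is_boundary) for s in other.species]
            and [
                (r.id, r.stoichiometry, r.reversible, r.lower_bound, r.upper_bound)
                for r in self.reactions
            ]
            == [
                (r.id, r.stoichiometry, r.reversible, r.lower_bound, r.upper_bound)
                for r in other.reactions
            ]
        )

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id!r}: {len(self.species)} species, "
            f"{len(self.reactions)} reactions>"
        )


def detect_exchange_reactions(model: MetabolicModel) -> list[str]:
    """Reactions that move mass across the system boundary (the b_i fluxes).

    A reaction is an exchange if it touches a boundary-flagged species, or if
    after dropping boundary species exactly one species remains (the BiGG
    ``EX_`` convention, where the external pool is left implicit).
    """
    boundary = {s.id for s in model.species if s.is_boundary}
    out: list[str] = []
    for r in model.reactions:
        sids = set(r.stoichiometry)
        if sids & boundary or len(sids - boundary) == 1:
            out.append(r.id)
    return out
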