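"""The stoichiometric matrix and structural network transformations.

The matrix S is m x n over *internal* species (rows) and reactions
(columns); S[i, j] is the signed rational coefficient of species i in
reaction j.  Steady state is the linear system S v = 0 — boundary species
are outside the balance, which is exactly what makes net exchange possible.

Transformations here are exact (rational arithmetic, no tolerances):
reversible splitting, stoichiometric-equivalence detection, redundancy
removal, and a conservative dead-end reduction that preserves the
steady-state flux cone on the surviving reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np

from .core import MetabolicModel, Reaction

__all__ = [
    "StoichMatrix",
    "build_stoich_matrix",
    "generate_linear_equations",
    "split_reversible",
    "find_equivalent_reactions",
    "remove_redundant",
    "reduce_network",
]

FWD_SUFFIX = "_fwd"
REV_SUFFIX = "_rev"


@dataclass
class StoichMatrix:
    row_ids: list[str]
    col_ids: list[str]
    entries: dict[tuple[int, int], Fraction] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_ids), len(self.col_ids))

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape)
        for (i, j), c in self.entries.items():
            dense[i, j] = float(c)
        return dense

    def to_tsv(self) -> str:
        lines = ["\t".join(["species", *self.col_ids])]
        for i, rid in enumerate(self.row_ids):
            row = [str(self.entries.get((i, j), Fraction(0))) for j in range(len(self.col_ids))]
            lines.append("\t".join([rid, *row]))
        return "\n".join(lines) + "\n"

    def to_triplets(self) -> list[tuple[str, str, Fraction]]:
        """Sparse (species, reaction, coefficient) triplets, row-major order."""
        return [
            (self.row_ids[i], self.col_ids[j], c)
            for (i, j), c in sorted(self.entries.items())
        ]


def build_stoich_matrix(model: MetabolicModel) -> StoichMatrix:
    """S over internal species x reactions, in model order."""
    row_ids = [s.id for s in model.internal_species]
    col_ids = [r.id for r in model.reactions]
    row_pos = {sid: i for i, sid in enumerate(row_ids)}
    entries: dict[tuple[int, int], Fraction] = {}
    for j, r in enumerate(model.reactions):
        for sid, coeff in r.stoichiometry.items():
            i = row_pos.get(sid)
            if i is not None and coeff != 0:
                entries[(i, j)] = coeff
    return StoichMatrix(row_ids, col_ids, entries)


def generate_linear_equations(matrix: StoichMatrix) -> str:
    """Render S v = 0 as one mass-balance equation per internal species."""
    by_row: dict[int, list[tuple[int, Fraction]]] = {i: [] for i in range(len(matrix.row_ids))}
    for (i, j), c in sorted(matrix.entries.items()):
        by_row[i].append((j, c))
    lines = []
    for i, sid in enumerate(matrix.row_ids):
        terms = []
        for j, c in by_row[i]:
            rid = matrix.col_ids[j]
            if c == 1:
                term = f"v_{rid}"
            elif c == -1:
                term = f"-v_{rid}"
            else:
                term = f"{c}*v_{rid}"
            if terms and not term.startswith("-"):
                term = "+ " + term
            elif terms:
                term = "- " + term.lstrip("-")
            terms.append(term)
        lhs = " ".join(terms) if terms else "0"
        lines.append(f"{lhs} = 0    # {sid}")
    return "\n".join(lines) + "\n"


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Replace each reversible reaction R by irreversible R_fwd and R_rev.

    R_fwd keeps the stoichiometry with bounds (0, ub); R_rev negates it with
    bounds (0, -lb).  The objective coefficient goes to R_fwd and its
    negation to R_rev, so every optimum of the split model maps back (via
    v = v_fwd - v_rev) to an original flux with the same objective value.
    Idempotent: an already-irreversible model passes through unchanged.
    """
    out = MetabolicModel(id=model.id, species=[s for s in model.copy().species])
    out.split_map = dict(model.split_map)
    for r in model.reactions:
        if not r.reversible:
            out.reactions.append(r.copy())
            continue
        fwd = r.copy()
        fwd.id = r.id + FWD_SUFFIX
        fwd.reversible = False
        fwd.lower_bound = 0.0
        fwd.upper_bound = max(r.upper_bound, 0.0)
        rev = r.copy()
        rev.id = r.id + REV_SUFFIX
        rev.reversible = False
        rev.stoichiometry = {s: -c for s, c in r.stoichiometry.items()}
        rev.lower_bound = 0.0
        rev.upper_bound = max(-r.lower_bound, 0.0)
        rev.objective_coefficient = -r.objective_coefficient
        out.reactions.extend([fwd, rev])
        out.split_map[fwd.id] = (r.id, +1)
        out.split_map[rev.id] = (r.id, -1)
    return out


def fold_split_id(model: MetabolicModel, rid: str) -> str:
    """Map a split reaction id back to its original id (identity otherwise)."""
    return model.split_map.get(rid, (rid, +1))[0]


def _primitive_form(stoich: dict[str, Fraction]) -> tuple[tuple[str, int], ...]:
    """Scale a stoichiometry by the unique positive rational making it the
    smallest integer vector; direction (sign pattern) is preserved."""
    items = sorted(stoich.items())
    denom_lcm = 1
    for _, c in items:
        denom_lcm = denom_lcm * c.denominator // gcd(denom_lcm, c.denominator)
    ints = [int(c * denom_lcm) for _, c in items]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    return tuple((sid, v // g) for (sid, _), v in zip(items, ints))


def find_equivalent_reactions(model: MetabolicModel) -> list[list[str]]:
    """Groups of reactions equal up to a *positive* scalar (same direction).

    Comparison is exact: each stoichiometry is normalised to its smallest
    integer form and grouped by equality.  Only groups of size >= 2 are
    returned, in model order.
    """
    groups: dict[tuple, list[str]] = {}
    for r in model.reactions:
        groups.setdefault(_primitive_form(r.stoichiometry), []).append(r.id)
    return [ids for ids in groups.values() if len(ids) >= 2]


def remove_redundant(model: MetabolicModel) -> MetabolicModel:
    """Drop stoichiometric duplicates, keeping the first of each group with
    the union of the group's bound intervals (so no feasible flux is lost)."""
    out = model.copy()
    drop: set[str] = set()
    keeper_of: dict[str, Reaction] = {}
    for group in find_equivalent_reactions(model):
        keeper = out.get_reaction(group[0])
        keeper_of[keeper.id] = keeper
        for rid in group[1:]:
            dup = out.get_reaction(rid)
            keeper.lower_bound = min(keeper.lower_bound, dup.lower_bound)
            keeper.upper_bound = max(keeper.upper_bound, dup.upper_bound)
            keeper.reversible = keeper.reversible or dup.reversible
            if keeper.objective_coefficient == 0.0:
                keeper.objective_coefficient = dup.objective_coefficient
            drop.add(rid)
    out.reactions = [r for r in out.reactions if r.id not in drop]
    return out


def reduce_network(model: MetabolicModel) -> MetabolicModel:
    """Conservative size reduction for cycle hunting.

    Iterates to fixpoint: (a) drop internal species touched by no reaction;
    (b) drop any reaction containing an internal species that appears in
    only that one reaction (a dead end — at steady state the reaction can
    carry no flux).  The steady-state cone restricted to the surviving
    reactions is unchanged.
    """
    out = model.copy()
    changed = True
    while changed:
        changed = False
        internal = {s.id for s in out.internal_species}
        count: dict[str, int] = {sid: 0 for sid in internal}
        for r in out.reactions:
            for sid in r.stoichiometry:
                if sid in internal:
                    count[sid] += 1
        dead_species = {sid for sid, n in count.items() if n == 0}
        if dead_species:
            out.species = [s for s in out.species if s.id not in dead_species]
            changed = True
            continue
        for r in out.reactions:
            if any(sid in internal and count[sid] == 1 for sid in r.stoichiometry):
                out.reactions = [x for x in out.reactions if x.id != r.id]
                changed = True
                break
    return out
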