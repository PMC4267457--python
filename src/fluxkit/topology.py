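"""Structure-only network analyses: no LP, no tolerances.

* species participation — which reactions consume/produce a metabolite;
* chokepoints — reactions that uniquely consume some metabolite or uniquely
  produce some metabolite (their enzymes are candidate drug targets:
  blocking one either starves the cell of a product or accumulates a
  substrate);
* extreme paths and internal cycles — the generators (extreme rays) of the
  nonnegative steady-state flux cone of the irreversible-split network,
  enumerated with the double description method in exact rational
  arithmetic.  Internal cycles are the rays that balance with every
  exchange flux pinned to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd

from .core import MetabolicModel, detect_exchange_reactions
from .errors import SizeCapError, UnknownIdError
from .stoichiometry import build_stoich_matrix, fold_split_id, split_reversible

__all__ = [
    "species_participation",
    "chokepoints",
    "chokepoint_report",
    "PathwayRay",
    "identify_extreme_paths",
    "identify_cycles",
    "DEFAULT_RAY_CAP",
]

#: refuse enumeration beyond this many (post-split) reactions
DEFAULT_RAY_CAP = 40


# -- species participation ----------------------------------------------

def species_participation(
    model: MetabolicModel, species_ids, role: str = "any"
) -> dict[str, list[str]]:
    """Per species, the reactions where it appears as reactant, product or
    either.  A reversible reaction runs both ways, so it matches both roles.
    """
    if role not in ("reactant", "product", "any"):
        raise ValueError(f"role must be 'reactant', 'product' or 'any', got {role!r}")
    known = {s.id for s in model.species}
    unknown = sorted(set(species_ids) - known)
    if unknown:
        raise UnknownIdError(f"unknown species id(s): {unknown}")
    out: dict[str, list[str]] = {sid: [] for sid in species_ids}
    for r in model.reactions:
        for sid in species_ids:
            coeff = r.stoichiometry.get(sid)
            if coeff is None or coeff == 0:
                continue
            consumed = coeff < 0 or r.reversible
            produced = coeff > 0 or r.reversible
            if role == "any" or (role == "reactant" and consumed) or (
                role == "product" and produced
            ):
                out[sid].append(r.id)
    return out


# -- chokepoints ---------------------------------------------------------

def chokepoint_report(
    model: MetabolicModel, exclude_species=()
) -> dict[str, dict[str, list[str]]]:
    """Chokepoint reactions with the species each uniquely consumes/produces.

    Computed on the reversible-split network (each direction assessed
    separately), over internal species only, with exchange reactions
    excluded — an exchange trivially "uniquely produces" its pool species
    and would flood the list with non-targets.  ``exclude_species`` lets the
    caller drop currency metabolites (ATP, H2O, ...) from consideration.
    Results are folded back to original reaction ids.
    """
    split = split_reversible(model)
    exchanges = set(detect_exchange_reactions(split))
    internal = {s.id for s in split.internal_species} - set(exclude_species)

    consumers: dict[str, list[str]] = {sid: [] for sid in internal}
    producers: dict[str, list[str]] = {sid: [] for sid in internal}
    for r in split.reactions:
        if r.id in exchanges:
            continue
        for sid, coeff in r.stoichiometry.items():
            if sid not in internal:
                continue
            if coeff < 0:
                consumers[sid].append(r.id)
            elif coeff > 0:
                producers[sid].append(r.id)

    report: dict[str, dict[str, list[str]]] = {}
    for sid in internal:
        if len(consumers[sid]) == 1:
            rid = fold_split_id(split, consumers[sid][0])
            report.setdefault(rid, {"uniquely_consumes": [], "uniquely_produces": []})[
                "uniquely_consumes"
            ].append(sid)
        if len(producers[sid]) == 1:
            rid = fold_split_id(split, producers[sid][0])
            report.setdefault(rid, {"uniquely_consumes": [], "uniquely_produces": []})[
                "uniquely_produces"
            ].append(sid)
    return report


def chokepoints(model: MetabolicModel, exclude_species=()) -> list[str]:
    """Chokepoint reaction ids, in model order."""
    found = chokepoint_report(model, exclude_species)
    return [r.id for r in model.reactions if r.id in found]


# -- extreme rays --------------------------------------------------------

@dataclass
class PathwayRay:
    coefficients: dict[str, Fraction]  # reaction id -> nonnegative coefficient
    kind: str  # "extreme_path" | "internal_cycle"

    def support(self) -> frozenset[str]:
        return frozenset(r for r, c in self.coefficients.items() if c != 0)


def _normalize_ray(vec: list[Fraction]) -> tuple[Fraction, ...]:
    """Scale to the smallest nonnegative integer vector."""
    denom_lcm = 1
    for c in vec:
        denom_lcm = denom_lcm * c.denominator // gcd(denom_lcm, c.denominator)
    ints = [int(c * denom_lcm) for c in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g == 0:
        return tuple(Fraction(0) for _ in vec)
    return tuple(Fraction(v, g) for v in ints)


def _double_description(rows: list[list[Fraction]], n: int) -> list[tuple[Fraction, ...]]:
    """Extreme rays of {v >= 0 : A v = 0} by incremental double description.

    Starts from the unit rays of the nonnegative orthant and intersects with
    each hyperplane A_i v = 0 in turn.  Because the cone stays inside the
    orthant it is pointed, extreme rays have minimal support, and the
    combinatorial support test decides adjacency.
    """
    rays: list[list[Fraction]] = [
        [Fraction(1) if i == j else Fraction(0) for i in range(n)] for j in range(n)
    ]
    for row in rows:
        pos, zero, neg = [], [], []
        for ray in rays:
            d = sum(a * b for a, b in zip(row, ray))
            (pos if d > 0 else neg if d < 0 else zero).append((ray, d))
        new_rays = [r for r, _ in zero]
        supports = [frozenset(i for i, c in enumerate(r) if c != 0) for r in rays]
        for rp, dp in pos:
            sp = frozenset(i for i, c in enumerate(rp) if c != 0)
            for rn, dn in neg:
                sn = frozenset(i for i, c in enumerate(rn) if c != 0)
                union = sp | sn
                # adjacency: no third ray's support fits inside the union
                adjacent = True
                for other in supports:
                    if other <= union and other != sp and other != sn:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = [dp * cn - dn * cp for cp, cn in zip(rp, rn)]
                new_rays.append(list(_normalize_ray(combo)))
        # dedupe (combinations can coincide after normalization)
        seen: dict[tuple, None] = {}
        for r in new_rays:
            seen.setdefault(tuple(_normalize_ray(r)), None)
        rays = [list(t) for t in seen if any(c != 0 for c in t)]
    return [tuple(r) for r in rays]


def _enumerate_rays(
    model: MetabolicModel, size_cap: int, zero_exchanges: bool
) -> list[PathwayRay]:
    split = split_reversible(model)
    n = len(split.reactions)
    if n > size_cap:
        raise SizeCapError(
            f"network has {n} reactions after reversible splitting, "
            f"exceeding the enumeration cap of {size_cap}"
        )
    keep = [r.id for r in split.reactions]
    if zero_exchanges:
        exchanges = set(detect_exchange_reactions(split))
        keep = [rid for rid in keep if rid not in exchanges]
    sub = MetabolicModel(
        split.id,
        [s for s in split.species],
        [split.get_reaction(rid) for rid in keep],
    )
    sub.split_map = split.split_map
    S = build_stoich_matrix(sub)
    rows = [
        [S.entries.get((i, j), Fraction(0)) for j in range(len(keep))]
        for i in range(len(S.row_ids))
    ]
    kind = "internal_cycle" if zero_exchanges else "extreme_path"
    rays = []
    for vec in _double_description(rows, len(keep)):
        coeffs = {rid: c for rid, c in zip(keep, vec) if c != 0}
        if coeffs:
            rays.append(PathwayRay(coeffs, kind))
    rays.sort(key=lambda r: sorted(r.coefficients))
    return rays


def identify_extreme_paths(
    model: MetabolicModel, size_cap: int = DEFAULT_RAY_CAP
) -> list[PathwayRay]:
    """Complete set of extreme rays of {v >= 0, S v = 0} (exchanges free,
    i.e. boundary species unbalanced), each in smallest-integer form."""
    return _enumerate_rays(model, size_cap, zero_exchanges=False)


def identify_cycles(
    model: MetabolicModel, size_cap: int = DEFAULT_RAY_CAP
) -> list[PathwayRay]:
    """Extreme rays of the exchange-free subnetwork: flux loops that balance
    with no import or export."""
    return _enumerate_rays(model, size_cap, zero_exchanges=True)
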