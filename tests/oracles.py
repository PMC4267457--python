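"""Independent exact-arithmetic oracles used to check the LP and ray code.

Everything here works over fractions.Fraction and shares no code with the
implementation under test: the LP oracle enumerates basic solutions of the
flux polytope directly, and the ray oracle enumerates candidate supports
and exact nullspaces.  Both are exponential and only meant for tiny
networks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product

ZERO = Fraction(0)


def rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form (returns a copy) and pivot columns."""
    M = [list(r) for r in rows]
    nrows = len(M)
    ncols = len(M[0]) if M else 0
    pivots: list[int] = []
    r = 0
    for col in range(ncols):
        piv = next((i for i in range(r, nrows) if M[i][col] != 0), None)
        if piv is None:
            continue
        M[r], M[piv] = M[piv], M[r]
        scale = M[r][col]
        M[r] = [x / scale for x in M[r]]
        for i in range(nrows):
            if i != r and M[i][col] != 0:
                f = M[i][col]
                M[i] = [a - f * b for a, b in zip(M[i], M[r])]
        pivots.append(col)
        r += 1
        if r == nrows:
            break
    return M, pivots


def nullspace(rows: list[list[Fraction]], ncols: int) -> list[list[Fraction]]:
    """Exact basis of {x : A x = 0}."""
    if not rows:
        return [
            [Fraction(int(i == j)) for i in range(ncols)] for j in range(ncols)
        ]
    R, pivots = rref(rows)
    free = [j for j in range(ncols) if j not in pivots]
    basis = []
    for f in free:
        vec = [ZERO] * ncols
        vec[f] = Fraction(1)
        for r, p in enumerate(pivots):
            vec[p] = -R[r][f]
        basis.append(vec)
    return basis


def solve_exact(A: list[list[Fraction]], b: list[Fraction]):
    """Solve A x = b exactly.  Returns (x, unique) or None when inconsistent."""
    ncols = len(A[0]) if A else 0
    aug = [row + [bi] for row, bi in zip(A, b)]
    R, pivots = rref(aug)
    if ncols in pivots:  # pivot in the rhs column -> inconsistent
        return None
    x = [ZERO] * ncols
    for r, p in enumerate(pivots):
        x[p] = R[r][ncols]
    unique = len(pivots) == ncols
    return x, unique


def _model_arrays(model, inf_bound: Fraction):
    internal = [s.id for s in model.species if not s.is_boundary]
    pos = {sid: i for i, sid in enumerate(internal)}
    n = len(model.reactions)
    S = [[ZERO] * n for _ in internal]
    for j, r in enumerate(model.reactions):
        for sid, coeff in r.stoichiometry.items():
            if sid in pos:
                S[pos[sid]][j] = Fraction(coeff)
    def frac_bound(v, sign):
        if v == float("inf"):
            return inf_bound
        if v == float("-inf"):
            return -inf_bound
        return Fraction(str(v))
    lb = [frac_bound(r.lower_bound, -1) for r in model.reactions]
    ub = [frac_bound(r.upper_bound, +1) for r in model.reactions]
    c = [Fraction(str(r.objective_coefficient)) for r in model.reactions]
    return S, lb, ub, c


def lp_vertex_oracle(model, sense="max", inf_bound=Fraction(1000)):
    """Optimal objective of max/min c'v s.t. S v = 0, lb <= v <= ub, by
    exhaustive basic-solution enumeration (bounds made finite first, so the
    polytope is a polytope and the optimum sits on a vertex).

    Returns the exact optimum as a Fraction, or None when infeasible.
    """
    S, lb, ub, c = _model_arrays(model, inf_bound)
    n = len(lb)
    best = None
    better = (lambda a, b: a > b) if sense == "max" else (lambda a, b: a < b)
    for assign in product((0, 1, 2), repeat=n):
        free = [j for j in range(n) if assign[j] == 0]
        v = [lb[j] if assign[j] == 1 else ub[j] if assign[j] == 2 else None
             for j in range(n)]
        if free:
            A = [[row[j] for j in free] for row in S]
            b = [
                -sum(row[j] * v[j] for j in range(n) if assign[j] != 0)
                for row in S
            ]
            sol = solve_exact(A, b)
            if sol is None or not sol[1]:
                continue
            for j, val in zip(free, sol[0]):
                v[j] = val
            if any(not (lb[j] <= v[j] <= ub[j]) for j in free):
                continue
        else:
            if any(sum(row[j] * v[j] for j in range(n)) != 0 for row in S):
                continue
        obj = sum(ci * vi for ci, vi in zip(c, v))
        if best is None or better(obj, best):
            best = obj
    return best


def extreme_ray_oracle(rows: list[list[Fraction]], n: int) -> set[tuple[Fraction, ...]]:
    """All extreme rays of {v >= 0 : A v = 0}, normalised to smallest
    integers, by support enumeration: a support is extreme iff the columns
    have a one-dimensional nullspace with a strictly positive generator and
    no smaller candidate support is contained in it.
    """
    from math import gcd

    candidates: list[tuple[frozenset[int], tuple[Fraction, ...]]] = []
    for k in range(1, n + 1):
        for support in combinations(range(n), k):
            A = [[row[j] for j in support] for row in rows]
            ns = nullspace(A, len(support))
            if len(ns) != 1:
                continue
            gen = ns[0]
            if any(x == 0 for x in gen):
                continue  # actual support is smaller; covered elsewhere
            if all(x < 0 for x in gen):
                gen = [-x for x in gen]
            if not all(x > 0 for x in gen):
                continue
            vec = [ZERO] * n
            for j, x in zip(support, gen):
                vec[j] = x
            candidates.append((frozenset(support), tuple(vec)))
    rays = set()
    for supp, vec in candidates:
        if any(other < supp for other, _ in candidates):
            continue
        lcm = 1
        for x in vec:
            lcm = lcm * x.denominator // gcd(lcm, x.denominator)
        ints = [int(x * lcm) for x in vec]
        g = 0
        for x in ints:
            g = gcd(g, abs(x))
        rays.add(tuple(Fraction(x, g) for x in ints))
    return rays
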