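"""Flux balance analysis: the linear-programming core.

FBA poses growth (or any reaction of interest) as the LP

    maximize  c'v   subject to   S v = 0,   lb <= v <= ub

where S is the internal-species stoichiometric matrix, v the flux vector
(internal fluxes and exchange fluxes alike), and c the objective vector —
typically the biomass pseudo-reaction, whose optimal flux is the predicted
growth rate in gDW/gDW/hr.

Solved with scipy's HiGHS backend.  Alternate optima are ubiquitous in
genome-scale models, so only the objective value is contractual; the
returned flux vector is one optimal vertex among possibly many (flux
variability analysis characterises the rest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import DEFAULT_INF_BOUND, MetabolicModel
from .errors import ConfigurationError, ModelValidationError, SolverError, UnknownIdError
from .io.components import find_objective_ids
from .stoichiometry import build_stoich_matrix

__all__ = [
    "FbaResult",
    "solve_fba",
    "solve_multi_objective",
    "replace_constraint",
    "compare_flux_distributions",
    "random_objectives",
    "random_constraints",
    "apply_constraint_table",
    "add_constraint_row",
    "select_first",
    "select_last",
    "remove_beginning",
]

#: feasibility tolerance used when checking/reporting solutions
FEASIBILITY_TOL = 1e-9
#: default tolerance for flux-distribution comparison
COMPARE_TOL = 1e-6


@dataclass
class FbaResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: dict[str, float]
    objective_ids: list[str]
    sense: str = "max"

    def flux_table(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.fluxes.items()), columns=["reaction", "flux"])


def _effective_bounds(model: MetabolicModel, inf_bound: float | None):
    """Flux bounds with the infinity sentinel substituted for the LP."""
    bounds = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if inf_bound is not None:
            lb = -inf_bound if lb == -np.inf else lb
            ub = inf_bound if ub == np.inf else ub
        bounds.append((lb, ub))
    return bounds


def _objective_vector(model: MetabolicModel, objective_ids: list[str] | None):
    rids = [r.id for r in model.reactions]
    c = np.zeros(len(rids))
    if objective_ids is not None:
        if not objective_ids:
            raise ConfigurationError("empty objective set")
        pos = {rid: i for i, rid in enumerate(rids)}
        for rid in objective_ids:
            if rid not in pos:
                raise UnknownIdError(f"unknown reaction id in objective: {rid!r}")
            c[pos[rid]] = 1.0
        return c, list(objective_ids)
    ids = find_objective_ids(model)  # raises ConfigurationError when undefined
    coeffs = {r.id: r.objective_coefficient for r in model.reactions}
    pos = {rid: i for i, rid in enumerate(rids)}
    for rid in ids:
        c[pos[rid]] = coeffs[rid] if coeffs[rid] != 0.0 else 1.0
    return c, ids


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    model: MetabolicModel,
    c: np.ndarray,
    sense: str = "max",
    inf_bound: float | None = DEFAULT_INF_BOUND,
    extra_A_ub: np.ndarray | None = None,
    extra_b_ub: np.ndarray | None = None,
):
    """Low-level LP solve over the model's steady-state polytope.

    Returns (status string, optimal value of c'v under `sense`, flux array).
    ``extra_A_ub x <= extra_b_ub`` rows let callers add side constraints
    (e.g. the objective-fraction cut in FVA).
    """
    S = build_stoich_matrix(model).to_dense()
    n = len(model.reactions)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=_effective_bounds(model, inf_bound),
        method="highs",
    )
    status = _STATUS.get(res.status, f"solver_status_{res.status}")
    if status == "iteration_limit" or status.startswith("solver_status"):
        raise SolverError(f"LP backend failed: {res.message}")
    if status != "optimal":
        return status, None, None
    return status, float(sign * res.fun) + 0.0, res.x  # + 0.0 drops -0.0


def solve_fba(
    model: MetabolicModel,
    sense: str = "max",
    objective_ids: list[str] | None = None,
    inf_bound: float | None = DEFAULT_INF_BOUND,
) -> FbaResult:
    """Optimise the model's objective (or an explicit reaction set).

    ``inf_bound`` replaces infinite bounds by a finite magnitude at solve
    time (default 1000); pass ``None`` to keep true infinities, in which
    case an unbounded LP is reported as status ``"unbounded"``.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c, ids = _objective_vector(model, objective_ids)
    status, value, x = solve_lp(model, c, sense=sense, inf_bound=inf_bound)
    fluxes = (
        {r.id: float(v) for r, v in zip(model.reactions, x)} if x is not None else {}
    )
    return FbaResult(status, value, fluxes, ids, sense)


def solve_multi_objective(
    model: MetabolicModel,
    objective_sets: list[list[str]],
    sense: str = "max",
    inf_bound: float | None = DEFAULT_INF_BOUND,
) -> list[FbaResult]:
    """One independent FBA per objective set, on the same constraints."""
    return [
        solve_fba(model, sense=sense, objective_ids=objs, inf_bound=inf_bound)
        for objs in objective_sets
    ]


def replace_constraint(
    model: MetabolicModel, reaction_id: str, lb: float, ub: float
) -> MetabolicModel:
    """Return a copy of the model with the reaction's bounds replaced."""
    if lb > ub:
        raise ModelValidationError(f"lower bound {lb} exceeds upper bound {ub}")
    out = model.copy()
    r = out.get_reaction(reaction_id)
    r.lower_bound = float(lb)
    r.upper_bound = float(ub)
    if lb < 0:
        r.reversible = True
    return out


def compare_flux_distributions(
    v1: dict[str, float], v2: dict[str, float], tolerance: float = COMPARE_TOL
) -> tuple[bool, pd.DataFrame]:
    """Componentwise equality within ``tolerance``; report lists violations."""
    if set(v1) != set(v2):
        diff = sorted(set(v1) ^ set(v2))
        raise ModelValidationError(f"flux distributions cover different reactions: {diff}")
    rows = [
        (rid, v1[rid], v2[rid], abs(v1[rid] - v2[rid]))
        for rid in v1
        if abs(v1[rid] - v2[rid]) > tolerance
    ]
    report = pd.DataFrame(rows, columns=["reaction", "flux_1", "flux_2", "abs_diff"])
    return len(rows) == 0, report


# -- random generators (reproducible test inputs) ------------------------

def random_objectives(model: MetabolicModel, count: int, seed: int) -> list[list[str]]:
    """``count`` single-reaction objective sets drawn uniformly (with a fixed
    seed the draw is reproducible)."""
    rng = np.random.default_rng(seed)
    rids = [r.id for r in model.reactions]
    return [[rids[int(rng.integers(len(rids)))]] for _ in range(count)]


def random_constraints(
    model: MetabolicModel,
    count: int,
    seed: int,
    bound_range: tuple[float, float] = (-1000.0, 1000.0),
) -> pd.DataFrame:
    """Random (reaction, lb, ub) rows with lb <= ub inside ``bound_range``."""
    rng = np.random.default_rng(seed)
    rids = [r.id for r in model.reactions]
    lo, hi = bound_range
    rows = []
    for _ in range(count):
        rid = rids[int(rng.integers(len(rids)))]
        a, b = sorted(rng.uniform(lo, hi, size=2))
        rows.append((rid, float(a), float(b)))
    return pd.DataFrame(rows, columns=["reaction", "lb", "ub"])


# -- constraint-table utilities (the file-operations toolbox) ------------

def apply_constraint_table(model: MetabolicModel, table: pd.DataFrame) -> MetabolicModel:
    """Apply every (reaction, lb, ub) row of a constraint table to a copy."""
    out = model.copy()
    for row in table.itertuples(index=False):
        out = replace_constraint(out, row.reaction, row.lb, row.ub)
    return out


def add_constraint_row(table: pd.DataFrame, reaction: str, lb: float, ub: float) -> pd.DataFrame:
    if lb > ub:
        raise ModelValidationError(f"lower bound {lb} exceeds upper bound {ub}")
    new = pd.DataFrame([(reaction, lb, ub)], columns=["reaction", "lb", "ub"])
    return pd.concat([table, new], ignore_index=True)


def select_first(table: pd.DataFrame, n: int) -> pd.DataFrame:
    return table.head(n).reset_index(drop=True)


def select_last(table: pd.DataFrame, n: int) -> pd.DataFrame:
    return table.tail(n).reset_index(drop=True)


def remove_beginning(table: pd.DataFrame, n: int = 1) -> pd.DataFrame:
    return table.iloc[n:].reset_index(drop=True)
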