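"""Flux variability analysis and constraint-scenario sweeps.

FVA reports, per reaction, the minimum and maximum flux compatible with the
constraints — optionally after pinning the objective to at least a fraction
of its optimum.  A degenerate interval means the flux is uniquely
determined at that objective level; a wide one exposes alternate optima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_INF_BOUND, MetabolicModel
from .errors import FluxKitError, ModelValidationError
from .fba import solve_fba, solve_lp, _objective_vector

__all__ = [
    "FluxInterval",
    "flux_variability",
    "constraint_variations",
    "run_variations",
    "identify_flux_caps",
    "compare_intervals",
]


@dataclass
class FluxInterval:
    reaction: str
    min_flux: float
    max_flux: float


def flux_variability(
    model: MetabolicModel,
    fix_objective_fraction: float | None = None,
    inf_bound: float | None = DEFAULT_INF_BOUND,
) -> list[FluxInterval]:
    """Min/max flux of every reaction over the feasible set (2n LPs).

    With ``fix_objective_fraction`` = f, the extra cut c'v >= f * optimum is
    imposed first (f = 1 explores the optimal face only).
    """
    n = len(model.reactions)
    A_ub = b_ub = None
    if fix_objective_fraction is not None:
        if not 0.0 <= fix_objective_fraction <= 1.0:
            raise ModelValidationError(
                f"fix_objective_fraction must be in [0, 1], got {fix_objective_fraction}"
            )
        base = solve_fba(model, inf_bound=inf_bound)
        if base.status != "optimal":
            raise FluxKitError(f"base FBA not solvable (status {base.status})")
        c, _ = _objective_vector(model, None)
        # c'v >= f*opt  as  -c'v <= -f*opt
        A_ub = -c.reshape(1, n)
        b_ub = np.array([-fix_objective_fraction * base.objective_value])

    intervals = []
    for j, r in enumerate(model.reactions):
        c = np.zeros(n)
        c[j] = 1.0
        lo_status, lo, _ = solve_lp(
            model, c, sense="min", inf_bound=inf_bound, extra_A_ub=A_ub, extra_b_ub=b_ub
        )
        hi_status, hi, _ = solve_lp(
            model, c, sense="max", inf_bound=inf_bound, extra_A_ub=A_ub, extra_b_ub=b_ub
        )
        if lo_status != "optimal" or hi_status != "optimal":
            if "infeasible" in (lo_status, hi_status):
                raise FluxKitError(f"FVA subproblem infeasible for {r.id!r}")
            lo = -math.inf if lo_status == "unbounded" else lo
            hi = math.inf if hi_status == "unbounded" else hi
        intervals.append(FluxInterval(r.id, lo, hi))
    return intervals


def constraint_variations(
    model: MetabolicModel,
    reaction_id: str,
    values,
    bound: str = "upper",
) -> pd.DataFrame:
    """Scenario table: one (reaction, lb, ub) row per value, with the chosen
    bound replaced by that value (``bound``: upper | lower | both)."""
    r = model.get_reaction(reaction_id)  # raises UnknownIdError
    if bound not in ("upper", "lower", "both"):
        raise ValueError(f"bound must be 'upper', 'lower' or 'both', got {bound!r}")
    rows = []
    for v in values:
        v = float(v)
        lb = v if bound in ("lower", "both") else r.lower_bound
        ub = v if bound in ("upper", "both") else r.upper_bound
        if lb > ub:
            raise ModelValidationError(
                f"scenario value {v} makes lb {lb} exceed ub {ub} for {reaction_id!r}"
            )
        rows.append((reaction_id, lb, ub))
    return pd.DataFrame(rows, columns=["reaction", "lb", "ub"])


def run_variations(
    model: MetabolicModel,
    table: pd.DataFrame,
    inf_bound: float | None = DEFAULT_INF_BOUND,
) -> pd.DataFrame:
    """Solve one FBA per scenario row; returns (reaction, lb, ub, status,
    objective) in input order."""
    from .fba import replace_constraint

    rows = []
    for row in table.itertuples(index=False):
        scenario = replace_constraint(model, row.reaction, row.lb, row.ub)
        res = solve_fba(scenario, inf_bound=inf_bound)
        rows.append((row.reaction, row.lb, row.ub, res.status, res.objective_value))
    return pd.DataFrame(rows, columns=["reaction", "lb", "ub", "status", "objective"])


def identify_flux_caps(model: MetabolicModel) -> pd.DataFrame:
    """Attainable extrema for every reaction with an unbounded declared bound.

    Solved with true infinities (no sentinel) so that genuine unboundedness
    is observable: such directions are reported as +/-inf rather than capped
    silently.  Columns: reaction, bound (lower|upper), cap, bounded.
    """
    rows = []
    n = len(model.reactions)
    for j, r in enumerate(model.reactions):
        for which, declared, sense in (
            ("lower", r.lower_bound, "min"),
            ("upper", r.upper_bound, "max"),
        ):
            if not math.isinf(declared):
                continue
            c = np.zeros(n)
            c[j] = 1.0
            status, val, _ = solve_lp(model, c, sense=sense, inf_bound=None)
            if status == "unbounded":
                cap = -math.inf if sense == "min" else math.inf
                rows.append((r.id, which, cap, False))
            elif status == "optimal":
                rows.append((r.id, which, val, True))
            else:
                raise FluxKitError(f"flux-cap LP for {r.id!r} returned {status}")
    return pd.DataFrame(rows, columns=["reaction", "bound", "cap", "bounded"])


def compare_intervals(
    list1: list[FluxInterval],
    list2: list[FluxInterval],
    tolerance: float = 1e-6,
) -> tuple[bool, pd.DataFrame]:
    """Endpointwise equality within tolerance; the report lists mismatches."""
    d1 = {i.reaction: i for i in list1}
    d2 = {i.reaction: i for i in list2}
    if set(d1) != set(d2):
        raise ModelValidationError(
            f"interval lists cover different reactions: {sorted(set(d1) ^ set(d2))}"
        )
    rows = []
    for rid in d1:
        a, b = d1[rid], d2[rid]
        dmin = abs(a.min_flux - b.min_flux)
        dmax = abs(a.max_flux - b.max_flux)
        if dmin > tolerance or dmax > tolerance:
            rows.append((rid, a.min_flux, a.max_flux, b.min_flux, b.max_flux))
    report = pd.DataFrame(
        rows, columns=["reaction", "min_1", "max_1", "min_2", "max_2"]
    )
    return len(rows) == 0, report
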