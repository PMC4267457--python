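"""Knockout and essentiality analysis.

A knockout forces flux to zero: directly (reaction), through boolean GPR
evaluation (gene — a reaction is disabled when its gene association
evaluates false with the deleted genes absent), or through the catalyst
list (catalyst).  A knock-down scales bounds by a fraction in [0, 1]
instead of zeroing them.

Essentiality is judged on the growth ratio mutant/wild-type: an entity set
is essential at threshold t% when deletion reduces the optimal objective by
more than t% of wild type.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import pandas as pd

from .core import DEFAULT_INF_BOUND, MetabolicModel
from .errors import FluxKitError, ModelValidationError, UnknownIdError
from .fba import FbaResult, solve_fba

__all__ = [
    "KnockoutRecord",
    "apply_knockout",
    "knockout_scan",
    "pairwise_knockout_scan",
    "make_pairs",
    "essential_entities",
    "DEFAULT_ESSENTIALITY_THRESHOLD",
]

ENTITY_KINDS = ("reaction", "gene", "catalyst")
#: percent biomass reduction above which an entity counts as essential
DEFAULT_ESSENTIALITY_THRESHOLD = 90.0


@dataclass
class KnockoutRecord:
    entity_kind: str
    entities: tuple[str, ...]
    status: str
    mutant_objective: float
    growth_ratio: float
    wild_type_objective: float

    def reduction_pct(self) -> float:
        return (1.0 - self.growth_ratio) * 100.0


def _known_ids(model: MetabolicModel, entity_kind: str) -> set[str]:
    if entity_kind == "reaction":
        return {r.id for r in model.reactions}
    if entity_kind == "gene":
        return set(model.genes())
    if entity_kind == "catalyst":
        return set(model.catalysts())
    raise ValueError(f"entity_kind must be one of {ENTITY_KINDS}, got {entity_kind!r}")


def apply_knockout(
    model: MetabolicModel,
    entity_kind: str,
    entities,
    fraction: float = 0.0,
) -> MetabolicModel:
    """Return a copy with the entity set deleted (or knocked down).

    ``fraction`` scales the bounds of every affected reaction: 0 (default)
    is a full knockout, 0.5 halves the allowed flux range, 1 is a no-op.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ModelValidationError(f"knock-down fraction must be in [0, 1], got {fraction}")
    entities = tuple(entities)
    known = _known_ids(model, entity_kind)
    unknown = sorted(set(entities) - known)
    if unknown:
        raise UnknownIdError(f"unknown {entity_kind} id(s): {unknown}")

    out = model.copy()
    if entity_kind == "reaction":
        hit = set(entities)
    elif entity_kind == "gene":
        deleted = frozenset(entities)
        hit = {
            r.id
            for r in out.reactions
            if r.gpr is not None and not r.gpr.evaluate(deleted)
        }
    else:  # catalyst
        hit = {r.id for r in out.reactions if set(r.catalysts) & set(entities)}

    for r in out.reactions:
        if r.id in hit:
            # 0 * inf is nan, so a full knockout zeroes the bounds outright
            r.lower_bound = 0.0 if fraction == 0.0 else r.lower_bound * fraction
            r.upper_bound = 0.0 if fraction == 0.0 else r.upper_bound * fraction
    return out


def _scan(
    model: MetabolicModel,
    entity_kind: str,
    entity_sets,
    fraction: float,
    inf_bound: float | None,
) -> list[KnockoutRecord]:
    wt: FbaResult = solve_fba(model, inf_bound=inf_bound)
    if wt.status != "optimal":
        raise FluxKitError(f"wild-type FBA is not solvable (status {wt.status})")
    wt_obj = wt.objective_value
    if wt_obj == 0.0:
        warnings.warn(
            "wild-type objective is zero; all growth ratios reported as 0",
            stacklevel=3,
        )
    records = []
    for entities in entity_sets:
        entities = tuple(entities)
        try:
            mutant = apply_knockout(model, entity_kind, entities, fraction=fraction)
            res = solve_fba(mutant, inf_bound=inf_bound)
            status = res.status
            obj = res.objective_value if res.status == "optimal" else 0.0
        except FluxKitError as exc:  # never abort a scan on one bad entry
            status, obj = f"error: {exc}", 0.0
        ratio = 0.0 if wt_obj == 0.0 else max(obj, 0.0) / wt_obj + 0.0
        records.append(
            KnockoutRecord(entity_kind, entities, status, obj, ratio, wt_obj)
        )
    return records


def knockout_scan(
    model: MetabolicModel,
    entity_kind: str,
    entity_sets=None,
    fraction: float = 0.0,
    inf_bound: float | None = DEFAULT_INF_BOUND,
) -> list[KnockoutRecord]:
    """Knock out each entity set in turn and record the mutant optimum.

    ``entity_sets`` defaults to all single deletions of the given kind.  The
    wild-type objective is solved once; per-entry solver trouble is recorded
    in the entry's status, never raised.
    """
    if entity_sets is None:
        entity_sets = [(e,) for e in sorted(_known_ids(model, entity_kind))] \
            if entity_kind != "reaction" else [(r.id,) for r in model.reactions]
    return _scan(model, entity_kind, entity_sets, fraction, inf_bound)


def make_pairs(ids) -> list[tuple[str, str]]:
    """All C(n,2) unordered pairs in lexicographic order; no self-pairs."""
    ids = list(ids)
    if len(ids) != len(set(ids)):
        raise ModelValidationError("duplicate ids passed to make_pairs")
    return list(itertools.combinations(sorted(ids), 2))


def pairwise_knockout_scan(
    model: MetabolicModel,
    entity_kind: str,
    pairs,
    fraction: float = 0.0,
    inf_bound: float | None = DEFAULT_INF_BOUND,
) -> list[KnockoutRecord]:
    """Double-deletion scan over explicit pairs (see :func:`make_pairs`)."""
    return _scan(model, entity_kind, pairs, fraction, inf_bound)


def essential_entities(
    records: list[KnockoutRecord],
    threshold_pct: float = DEFAULT_ESSENTIALITY_THRESHOLD,
) -> list[tuple[str, ...]]:
    """Entity sets whose deletion cuts the objective by more than
    ``threshold_pct`` percent of wild type."""
    if not 0.0 <= threshold_pct <= 100.0:
        raise ModelValidationError(
            f"essentiality threshold must be in [0, 100], got {threshold_pct}"
        )
    return [r.entities for r in records if r.reduction_pct() > threshold_pct]


def records_table(records: list[KnockoutRecord]) -> pd.DataFrame:
    """Flatten a scan into a TSV-ready table."""
    return pd.DataFrame(
        [
            (
                " + ".join(r.entities),
                r.entity_kind,
                r.status,
                r.mutant_objective,
                r.growth_ratio,
            )
            for r in records
        ],
        columns=["entities", "kind", "status", "mutant_objective", "growth_ratio"],
    )
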