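"""Component extraction: the "network information retriever" operations.

Everything returns deterministic, duplicate-free listings in model order;
tables come back as pandas DataFrames so they can be written straight to
TSV.
"""

from __future__ import annotations

import pandas as pd

from ..core import MetabolicModel
from ..errors import ConfigurationError

__all__ = ["extract_components", "COMPONENT_KINDS", "find_objective_ids"]

COMPONENT_KINDS = (
    "genes",
    "reactions",
    "species",
    "catalysts",
    "constraints",
    "objective",
    "gpr-table",
    "catalyst-table",
)


def find_objective_ids(model: MetabolicModel) -> list[str]:
    """Reaction ids carrying the objective.

    Detection order: explicit nonzero objective coefficients (set by the fbc
    objective or the notes dialect's OBJECTIVE_COEFFICIENT); failing that,
    the first reaction whose id or name contains "biomass" (the universal
    growth-objective naming convention); failing both, an error.
    """
    ids = model.objective_ids
    if ids:
        return ids
    for r in model.reactions:
        if "biomass" in r.id.lower() or "biomass" in r.name.lower():
            return [r.id]
    raise ConfigurationError(
        f"model {model.id!r} has no objective defined "
        "(no nonzero objective coefficient and no biomass-named reaction)"
    )


def extract_components(model: MetabolicModel, kind: str):
    """Extract one component listing; ``kind`` is one of COMPONENT_KINDS."""
    if kind == "genes":
        return model.genes()
    if kind == "reactions":
        return [r.id for r in model.reactions]
    if kind == "species":
        return [s.id for s in model.species]
    if kind == "catalysts":
        return model.catalysts()
    if kind == "constraints":
        return pd.DataFrame(
            [(r.id, r.lower_bound, r.upper_bound) for r in model.reactions],
            columns=["reaction", "lb", "ub"],
        )
    if kind == "objective":
        return find_objective_ids(model)
    if kind == "gpr-table":
        return pd.DataFrame(
            [(r.id, str(r.gpr) if r.gpr is not None else "") for r in model.reactions],
            columns=["reaction", "gpr"],
        )
    if kind == "catalyst-table":
        return pd.DataFrame(
            [(r.id, " ".join(r.catalysts)) for r in model.reactions],
            columns=["reaction", "catalysts"],
        )
    raise ValueError(f"unknown component kind: {kind!r} (expected one of {COMPONENT_KINDS})")
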