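"""Declarative analysis workflows.

A workflow is data, not code: an ordered list of steps, each naming a
registered operation, parameter bindings, and the wiring of named artifacts
between steps.  Steps can only be joined when the producing step's output
role matches the consuming step's input role (model, id-list,
constraint-table, flux-table, report, image), which is checked by
:meth:`WorkflowSpec.validate` before anything runs.

Eight workflows covering the common simulations ship built in (automated
and customized FBA, gene/reaction/catalyst essentiality, pairwise
gene/reaction/catalyst knockout); users can author new ones as YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from .core import MetabolicModel
from .errors import FluxKitError, ModelValidationError
from .fba import apply_constraint_table, solve_fba
from .io import (
    extract_components,
    find_objective_ids,
    parse_flat_reactions,
    parse_metatool,
    read_sbml_file,
    write_flat_reactions,
)
from .perturbation import (
    DEFAULT_ESSENTIALITY_THRESHOLD,
    essential_entities,
    knockout_scan,
    make_pairs,
    pairwise_knockout_scan,
    records_table,
)
from .topology import chokepoints

__all__ = [
    "WorkflowStep",
    "WorkflowSpec",
    "WorkflowError",
    "OP_REGISTRY",
    "builtin_workflows",
    "run_workflow",
    "load_workflow",
    "save_workflow",
]

ROLES = ("model-file", "model", "id-list", "constraint-table", "flux-table", "report", "image")


class WorkflowError(FluxKitError):
    def __init__(self, step: str, message: str, artifacts: dict | None = None):
        super().__init__(f"workflow step {step!r} failed: {message}")
        self.step = step
        self.artifact_paths = artifacts or {}


@dataclass(frozen=True)
class OpDef:
    name: str
    inputs: dict[str, str]  # slot -> role
    outputs: dict[str, str]
    fn: Callable[[dict[str, Any], dict[str, Any]], dict[str, Any]]
    optional_inputs: dict[str, str] = field(default_factory=dict)


# -- operation implementations ------------------------------------------

def _op_upload(inp, params):
    return {"file": inp["file"]}


def _op_read_model(inp, params):
    src = inp["file"]
    if isinstance(src, MetabolicModel):
        return {"model": src.copy()}
    path = Path(src)
    fmt = params.get("format", "auto")
    if fmt == "auto":
        fmt = {".xml": "sbml", ".sbml": "sbml", ".mt": "metatool"}.get(
            path.suffix.lower(), "flat"
        )
    if fmt == "sbml":
        return {"model": read_sbml_file(path)}
    if fmt == "metatool":
        return {"model": parse_metatool(path.read_text())}
    return {"model": parse_flat_reactions(path.read_text())}


def _fetcher(kind):
    def fn(inp, params):
        return {"out": extract_components(inp["model"], kind)}

    return fn


def _op_fetch_objective(inp, params):
    return {"objective": find_objective_ids(inp["model"])}


def _op_chokepoints(inp, params):
    cps = chokepoints(inp["model"], exclude_species=params.get("exclude_species", ()))
    universe = set(inp.get("ids") or cps)
    return {"ids": [c for c in cps if c in universe]}


def _op_optimize(inp, params):
    model = apply_constraint_table(inp["model"], inp["constraints"])
    res = solve_fba(model, sense=params.get("sense", "max"), objective_ids=inp["objective"])
    return {"fluxes": res.flux_table(), "result": res}


def _op_optimize_custom(inp, params):
    objective = params.get("objective")
    if not objective:
        raise ModelValidationError("optimize_custom requires an 'objective' parameter")
    model = apply_constraint_table(inp["model"], inp["constraints"])
    res = solve_fba(model, sense=params.get("sense", "max"), objective_ids=list(objective))
    return {"fluxes": res.flux_table(), "result": res}


def _op_knockout_scan(inp, params):
    model = apply_constraint_table(inp["model"], inp["constraints"])
    kind = params["kind"]
    entity_sets = [(e,) for e in inp["entities"]]
    records = knockout_scan(
        _with_objective(model, inp["objective"]), kind, entity_sets,
        fraction=params.get("fraction", 0.0),
    )
    return {"records": records}


def _op_make_pairs(inp, params):
    return {"pairs": make_pairs(inp["ids"])}


def _op_pairwise_scan(inp, params):
    model = apply_constraint_table(inp["model"], inp["constraints"])
    records = pairwise_knockout_scan(
        _with_objective(model, inp["objective"]), params["kind"], inp["pairs"],
        fraction=params.get("fraction", 0.0),
    )
    return {"records": records}


def _op_essential_reporter(inp, params):
    threshold = params.get("threshold", DEFAULT_ESSENTIALITY_THRESHOLD)
    return {"essential": essential_entities(inp["records"], threshold)}


def _op_plot_fluxes(inp, params):
    from .plotting import plot_flux_distribution

    return {"image": plot_flux_distribution(inp["result"])}


def _op_plot_knockouts(inp, params):
    from .plotting import plot_essentiality, plot_knockout_scan

    if "threshold" in params:
        return {"image": plot_essentiality(inp["records"], params["threshold"])}
    return {"image": plot_knockout_scan(inp["records"])}


def _with_objective(model: MetabolicModel, objective_ids) -> MetabolicModel:
    out = model.copy()
    wanted = set(objective_ids)
    for r in out.reactions:
        r.objective_coefficient = 1.0 if r.id in wanted else 0.0
    return out


OP_REGISTRY: dict[str, OpDef] = {
    op.name: op
    for op in [
        OpDef("upload", {"file": "model-file"}, {"file": "model-file"}, _op_upload),
        OpDef("read_model", {"file": "model-file"}, {"model": "model"}, _op_read_model),
        OpDef("fetch_constraints", {"model": "model"}, {"out": "constraint-table"},
              _fetcher("constraints")),
        OpDef("fetch_objective", {"model": "model"}, {"objective": "id-list"},
              _op_fetch_objective),
        OpDef("fetch_gene_ids", {"model": "model"}, {"out": "id-list"}, _fetcher("genes")),
        OpDef("fetch_reaction_ids", {"model": "model"}, {"out": "id-list"},
              _fetcher("reactions")),
        OpDef("fetch_catalyst_ids", {"model": "model"}, {"out": "id-list"},
              _fetcher("catalysts")),
        OpDef("fetch_species_ids", {"model": "model"}, {"out": "id-list"},
              _fetcher("species")),
        OpDef("fetch_gene_associations", {"model": "model"}, {"out": "report"},
              _fetcher("gpr-table")),
        OpDef("fetch_catalyst_associations", {"model": "model"}, {"out": "report"},
              _fetcher("catalyst-table")),
        OpDef("find_chokepoints", {"model": "model"}, {"ids": "id-list"},
              _op_chokepoints, optional_inputs={"ids": "id-list"}),
        OpDef("optimize",
              {"model": "model", "constraints": "constraint-table", "objective": "id-list"},
              {"fluxes": "flux-table", "result": "report"}, _op_optimize),
        OpDef("optimize_custom",
              {"model": "model", "constraints": "constraint-table"},
              {"fluxes": "flux-table", "result": "report"}, _op_optimize_custom),
        OpDef("knockout_scan",
              {"model": "model", "constraints": "constraint-table",
               "objective": "id-list", "entities": "id-list"},
              {"records": "report"}, _op_knockout_scan,
              optional_inputs={"associations": "report"}),
        OpDef("make_pairs", {"ids": "id-list"}, {"pairs": "report"}, _op_make_pairs),
        OpDef("pairwise_scan",
              {"model": "model", "constraints": "constraint-table",
               "objective": "id-list", "pairs": "report"},
              {"records": "report"}, _op_pairwise_scan,
              optional_inputs={"associations": "report"}),
        OpDef("essential_reporter", {"records": "report"}, {"essential": "report"},
              _op_essential_reporter),
        OpDef("plot_fluxes", {"result": "report"}, {"image": "image"}, _op_plot_fluxes),
        OpDef("plot_knockouts", {"records": "report"}, {"image": "image"},
              _op_plot_knockouts),
    ]
}


# -- workflow schema -----------------------------------------------------

@dataclass
class WorkflowStep:
    op: str
    inputs: dict[str, str] = field(default_factory=dict)  # slot -> artifact name
    outputs: dict[str, str] = field(default_factory=dict)  # slot -> artifact name
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class WorkflowSpec:
    name: str
    steps: list[WorkflowStep]
    description: str = ""

    def validate(self) -> None:
        """Check every step exists, its wiring resolves, and roles match."""
        available: dict[str, str] = {"model_file": "model-file"}  # workflow input
        for i, step in enumerate(self.steps, start=1):
            opdef = OP_REGISTRY.get(step.op)
            if opdef is None:
                raise ModelValidationError(
                    f"workflow {self.name!r} step {i}: unknown operation {step.op!r}"
                )
            for slot, role in opdef.inputs.items():
                art = step.inputs.get(slot)
                if art is None:
                    raise ModelValidationError(
                        f"workflow {self.name!r} step {i} ({step.op}): input slot "
                        f"{slot!r} is not wired"
                    )
                if art not in available:
                    raise ModelValidationError(
                        f"workflow {self.name!r} step {i} ({step.op}): artifact "
                        f"{art!r} is not produced by any earlier step"
                    )
                if available[art] != role:
                    raise ModelValidationError(
                        f"workflow {self.name!r} step {i} ({step.op}): artifact "
                        f"{art!r} has role {available[art]!r}, slot {slot!r} needs {role!r}"
                    )
            for slot, art in step.inputs.items():
                if slot not in opdef.inputs and slot not in opdef.optional_inputs:
                    raise ModelValidationError(
                        f"workflow {self.name!r} step {i} ({step.op}): unknown input "
                        f"slot {slot!r}"
                    )
                if slot in opdef.optional_inputs:
                    if art not in available:
                        raise ModelValidationError(
                            f"workflow {self.name!r} step {i} ({step.op}): artifact "
                            f"{art!r} is not produced by any earlier step"
                        )
            for slot, art in step.outputs.items():
                if slot not in opdef.outputs:
                    raise ModelValidationError(
                        f"workflow {self.name!r} step {i} ({step.op}): unknown output "
                        f"slot {slot!r}"
                    )
                if art in available:
                    raise ModelValidationError(
                        f"workflow {self.name!r} step {i} ({step.op}): artifact name "
                        f"{art!r} already exists"
                    )
                available[art] = opdef.outputs[slot]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "steps": [
                {"op": s.op, "inputs": s.inputs, "outputs": s.outputs, "params": s.params}
                for s in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "WorkflowSpec":
        return cls(
            name=data["name"],
            description=data.get("description", ""),
            steps=[
                WorkflowStep(
                    op=s["op"],
                    inputs=dict(s.get("inputs", {})),
                    outputs=dict(s.get("outputs", {})),
                    params=dict(s.get("params", {})),
                )
                for s in data.get("steps", [])
            ],
        )


def save_workflow(spec: WorkflowSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_workflow(path: str | Path) -> WorkflowSpec:
    spec = WorkflowSpec.from_dict(yaml.safe_load(Path(path).read_text()))
    spec.validate()
    return spec


# -- execution -----------------------------------------------------------

def _persist(name: str, role: str, value, outdir: Path) -> Path | None:
    if role == "model-file":
        return None
    path = outdir / name
    if role == "model":
        path = path.with_suffix(".reactions")
        path.write_text(write_flat_reactions(value))
    elif role == "id-list":
        path = path.with_suffix(".txt")
        path.write_text("\n".join(value) + ("\n" if value else ""))
    elif role in ("constraint-table", "flux-table"):
        path = path.with_suffix(".tsv")
        value.to_csv(path, sep="\t", index=False)
    elif role == "image":
        path = path.with_suffix(".png")
        path.write_bytes(value)
    elif role == "report":
        path = path.with_suffix(".tsv")
        if isinstance(value, pd.DataFrame):
            value.to_csv(path, sep="\t", index=False)
        elif hasattr(value, "objective_value"):  # FbaResult
            path.write_text(
                f"status\t{value.status}\n"
                f"objective\t{' '.join(value.objective_ids)}\n"
                f"objective_value\t{value.objective_value}\n"
            )
        elif value and hasattr(value[0], "entity_kind"):
            records_table(value).to_csv(path, sep="\t", index=False)
        elif isinstance(value, list):
            path.write_text(
                "\n".join(
                    " + ".join(v) if isinstance(v, (tuple, list)) else str(v)
                    for v in value
                )
                + ("\n" if value else "")
            )
        else:
            path.write_text(str(value))
    return path


def run_workflow(
    spec: WorkflowSpec,
    model,
    params: dict[str, dict] | None = None,
    outdir: str | Path = ".",
) -> dict[str, Path]:
    """Execute a validated workflow on a model (path or MetabolicModel).

    ``params`` overrides per-step parameters keyed by 1-based step index or
    op name.  Every named artifact is persisted into ``outdir``; the mapping
    artifact name -> file path is returned.  A failing step aborts with the
    step name, leaving upstream artifacts on disk.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or {}
    artifacts: dict[str, Any] = {"model_file": model}
    roles: dict[str, str] = {"model_file": "model-file"}
    paths: dict[str, Path] = {}
    for i, step in enumerate(spec.steps, start=1):
        opdef = OP_REGISTRY[step.op]
        step_params = {**step.params, **params.get(step.op, {}), **params.get(i, {})}
        inputs = {slot: artifacts[art] for slot, art in step.inputs.items()}
        try:
            outputs = opdef.fn(inputs, step_params)
        except FluxKitError as exc:
            raise WorkflowError(step.op, str(exc), paths) from exc
        for slot, art in step.outputs.items():
            artifacts[art] = outputs[slot]
            roles[art] = opdef.outputs[slot]
            p = _persist(art, roles[art], outputs[slot], outdir)
            if p is not None:
                paths[art] = p
    return paths


# -- the eight built-in workflows ---------------------------------------

def _fba_steps(custom_objective: bool) -> list[WorkflowStep]:
    steps = [
        WorkflowStep("upload", {"file": "model_file"}, {"file": "uploaded"}),
        WorkflowStep("read_model", {"file": "uploaded"}, {"model": "model"}),
        WorkflowStep("fetch_constraints", {"model": "model"}, {"out": "constraints"}),
    ]
    if custom_objective:
        steps.append(
            WorkflowStep(
                "optimize_custom",
                {"model": "model", "constraints": "constraints"},
                {"fluxes": "fluxes", "result": "fba_result"},
            )
        )
    else:
        steps.append(
            WorkflowStep("fetch_objective", {"model": "model"}, {"objective": "objective"})
        )
        steps.append(
            WorkflowStep(
                "optimize",
                {"model": "model", "constraints": "constraints", "objective": "objective"},
                {"fluxes": "fluxes", "result": "fba_result"},
            )
        )
    steps.append(
        WorkflowStep("plot_fluxes", {"result": "fba_result"}, {"image": "flux_plot"})
    )
    return steps


def _essentiality_steps(kind: str) -> list[WorkflowStep]:
    steps = [
        WorkflowStep("upload", {"file": "model_file"}, {"file": "uploaded"}),
        WorkflowStep("read_model", {"file": "uploaded"}, {"model": "model"}),
        WorkflowStep(f"fetch_{kind}_ids", {"model": "model"}, {"out": "entities"}),
        WorkflowStep("fetch_constraints", {"model": "model"}, {"out": "constraints"}),
        WorkflowStep("fetch_objective", {"model": "model"}, {"objective": "objective"}),
    ]
    scan_inputs = {
        "model": "model",
        "constraints": "constraints",
        "objective": "objective",
        "entities": "entities",
    }
    if kind in ("gene", "catalyst"):
        steps.append(
            WorkflowStep(
                f"fetch_{kind}_associations", {"model": "model"}, {"out": "associations"}
            )
        )
        scan_inputs["associations"] = "associations"
    steps.append(
        WorkflowStep("knockout_scan", scan_inputs, {"records": "records"},
                     {"kind": kind})
    )
    steps.append(
        WorkflowStep("essential_reporter", {"records": "records"},
                     {"essential": "essential"})
    )
    return steps


def _pairwise_steps(kind: str) -> list[WorkflowStep]:
    steps = [
        WorkflowStep("upload", {"file": "model_file"}, {"file": "uploaded"}),
        WorkflowStep("read_model", {"file": "uploaded"}, {"model": "model"}),
        WorkflowStep(f"fetch_{kind}_ids", {"model": "model"}, {"out": "entities"}),
        WorkflowStep("fetch_constraints", {"model": "model"}, {"out": "constraints"}),
        WorkflowStep("fetch_objective", {"model": "model"}, {"objective": "objective"}),
    ]
    scan_inputs = {
        "model": "model",
        "constraints": "constraints",
        "objective": "objective",
        "pairs": "pairs",
    }
    if kind == "reaction":
        # the pair count is quadratic: pre-filter to chokepoint reactions
        steps.append(
            WorkflowStep(
                "find_chokepoints",
                {"model": "model", "ids": "entities"},
                {"ids": "chokepoint_ids"},
            )
        )
        pair_source = "chokepoint_ids"
    else:
        steps.append(
            WorkflowStep(
                f"fetch_{kind}_associations", {"model": "model"}, {"out": "associations"}
            )
        )
        scan_inputs["associations"] = "associations"
        pair_source = "entities"
    steps.append(WorkflowStep("make_pairs", {"ids": pair_source}, {"pairs": "pairs"}))
    steps.append(
        WorkflowStep("pairwise_scan", scan_inputs, {"records": "records"},
                     {"kind": kind})
    )
    return steps


def builtin_workflows() -> list[WorkflowSpec]:
    """The eight published workflows; every spec passes wiring validation."""
    specs = [
        WorkflowSpec(
            "automated-fba", _fba_steps(False),
            "FBA with the model's own (default) objective; plots the flux distribution.",
        ),
        WorkflowSpec(
            "customized-fba", _fba_steps(True),
            "FBA with a user-supplied objective (parameter 'objective' of optimize_custom).",
        ),
        WorkflowSpec("gene-essentiality", _essentiality_steps("gene"),
                     "Single gene deletions; reports lethal genes."),
        WorkflowSpec("reaction-essentiality", _essentiality_steps("reaction"),
                     "Single reaction deletions; reports lethal reactions."),
        WorkflowSpec("catalyst-essentiality", _essentiality_steps("catalyst"),
                     "Single catalyst deletions; reports lethal catalysts."),
        WorkflowSpec("pairwise-gene-knockout", _pairwise_steps("gene"),
                     "All gene pairs deleted jointly (synthetic lethality screen)."),
        WorkflowSpec("pairwise-reaction-knockout", _pairwise_steps("reaction"),
                     "Reaction pairs, pre-filtered to chokepoints to tame the count."),
        WorkflowSpec("pairwise-catalyst-knockout", _pairwise_steps("catalyst"),
                     "All catalyst pairs deleted jointly."),
    ]
    for spec in specs:
        spec.validate()
    return specs
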