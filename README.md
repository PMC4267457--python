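# fluxkit

Constraint-based analysis of metabolic networks, as a plain Python library
and command line tool: model I/O, flux balance analysis, flux variability,
knockout and essentiality screens, chokepoint and pathway topology, and
declarative multi-step workflows — with no server, MATLAB or Java
dependency.

It is written for systems biologists who work with genome-scale metabolic
reconstructions (SBML in the COBRA-notes or fbc dialect, Metatool input
files, or flat reaction text) and want to predict growth phenotypes,
screen *in silico* deletions for drug-target candidates, and inspect
network structure from scripts or a shell.

## The model

A metabolic network with m internal metabolites and n reactions is encoded
in its stoichiometric matrix S ∈ ℚ^(m×n).  At steady state, mass balance
requires

    S v = 0,        lb ≤ v ≤ ub

where v is the flux vector (internal fluxes νᵢ and exchange fluxes bᵢ
alike, in mmol/gDW/hr) and the bounds encode reversibility, nutrient
availability and capacity.  Flux balance analysis (FBA) picks a reaction
of interest — typically the biomass pseudo-reaction — and solves the
linear program

    maximize cᵀv   s.t.   S v = 0,   lb ≤ v ≤ ub

whose optimum is the predicted growth rate (gDW/gDW/hr).  On top of this
LP core the package provides:

* **Flux variability analysis (FVA)** — per-reaction min/max flux,
  optionally on the optimal face (`fix_objective_fraction=1`), exposing
  alternate optima.
* **Perturbation analysis** — single and pairwise knockouts of reactions,
  genes (through boolean gene–protein–reaction associations) and
  catalysts; knock-downs as bound scaling; essentiality at a configurable
  biomass-reduction threshold (default 90%).
* **Topology** — species participation, chokepoint reactions (sole
  consumer or sole producer of some metabolite; their enzymes are
  candidate drug targets), and exact enumeration of extreme pathways and
  internal cycles of the flux cone via the double description method in
  rational arithmetic.
* **Workflows** — eight built-in, validated tool chains (automated and
  customized FBA, gene/reaction/catalyst essentiality, pairwise
  knockouts), user-extensible as YAML.

LPs are solved with scipy's HiGHS backend; all structural operations
(splitting, equivalence, ray enumeration) use exact rational arithmetic.

## Worked example

Generate a toy network with two parallel routes and analyse it:

```sh
$ fluxkit fixtures make branch --cap 10 --out demo
$ fluxkit fba demo/toy_branch_0.notes.xml
status  optimal
objective       10
reaction        flux
R_up    10.0
R_b1    10.0
...
```

The uptake cap of 10 mmol/gDW/hr fully determines the optimum.  FVA at
the optimum shows the two routes are interchangeable (each branch flux may
lie anywhere in [0, 10]):

```sh
$ fluxkit fva demo/toy_branch_0.notes.xml --fraction 1.0
reaction        min_flux        max_flux
R_up    10      10
R_b1    0       10
R_b2    0       10
...
```

so no branch reaction is singly essential — but chokepoint-filtered
pairwise knockouts find the four reaction pairs whose joint deletion
severs both routes:

```sh
$ fluxkit knockout demo/toy_branch_0.notes.xml --pairs --filter-chokepoints
...
# essential at >90% reduction: 4
# R_b1 + R_b2
# R_b1 + R_c2
# R_b2 + R_c1
# R_c1 + R_c2
```

The same analyses are one call each from Python (`solve_fba`,
`flux_variability`, `pairwise_knockout_scan`, `chokepoints`, ...), and
`fluxkit workflow run automated-fba MODEL` chains read → constraints →
objective → optimize → plot in one step.

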