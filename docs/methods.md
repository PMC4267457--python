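# Methods

## Model representation

A model is an ordered list of species and reactions.  Species flagged as
boundary (external metabolite pools) are excluded from mass balance; this
is what allows net import and export.  Stoichiometric coefficients are
stored as exact rationals (`fractions.Fraction`), so structural operations
— equivalence grouping, reversible splitting, ray enumeration — never
depend on a float tolerance.  Flux bounds are floats in mmol/gDW/hr and
may be genuinely infinite: the infinity is kept as a sentinel in the model
and replaced by a finite magnitude (default 1000, the convention used in
published genome-scale models) only when an LP is assembled.  This keeps
model semantics exact while keeping the solver's problem finite; passing
`inf_bound=None` keeps true infinities, in which case unboundedness is
reported as a status rather than masked.

### SBML dialects

Two constraint-based SBML dialects circulate: Level 2 files with
COBRA-style notes (`GENE_ASSOCIATION`, kinetic-law `LOWER_BOUND` /
`UPPER_BOUND` / `OBJECTIVE_COEFFICIENT` parameters, `boundaryCondition`
flags) and Level 3 files using the fbc package (global bound parameters,
`geneProductAssociation` trees, explicit objectives).  Both carry the same
information, so a single reader auto-detects: fbc package present → fbc
path, else notes path.  Parsing is done with python-libsbml; fbc gene
products are reported by their label (the gene name) rather than their
munged XML id.

Objective detection order: explicit nonzero objective coefficients (fbc
objective, or the notes dialect's `OBJECTIVE_COEFFICIENT`), then the first
reaction whose id or name contains "biomass" (the universal naming
convention), then an explicit "no objective" error.  Catalyst lists are
read from SBML modifier species plus `PROTEIN_ASSOCIATION`-style notes
(leaves of the association expression); the SBML standard has no canonical
catalyst slot, so this is a documented convention, not a guarantee.

Boundary species are flagged by the `boundaryCondition` attribute or by an
external-compartment naming convention (`b`, `boundary`, `extraorganism`).
Reactions are classified as exchanges when they touch a boundary species
or when, after dropping boundary species, a single species remains (the
BiGG `EX_` style, where the external pool is implicit).

### Metatool and flat text

The Metatool format carries reversibility (ENZREV/ENZIRREV), the
internal/external split (METINT/METEXT) and equations (CAT), but no
bounds: reversible reactions get (−∞, ∞) and irreversible ones (0, ∞) on
read.  Fractional coefficients are written `p/q` so write∘parse is exact.
The flat format (`R1 : 2 A + B -> C`, `<->` for reversible) is the minimal
stoichiometric view used for artifact files and quick editing; it carries
no boundary flags or objectives by design.

## Flux balance analysis

The LP `maximize c'v s.t. S v = 0, lb ≤ v ≤ ub` is solved with scipy's
HiGHS.  Genome-scale optima are massively degenerate, so only the
objective value is contractual; the returned flux vector is one optimal
vertex.  All internal tests therefore compare objective values, never flux
vectors, unless FVA proves an interval degenerate.  Feasibility is
reported at τ = 1e−9; flux-distribution and interval comparisons default
to a 1e−6 tolerance (both configurable).  Maximisation is the default
sense, matching how growth objectives are posed.

## Flux variability analysis

2n LPs, minimising and maximising each reaction's flux.  With
`fix_objective_fraction` = f, the cut cᵀv ≥ f·z* (z* the FBA optimum) is
added first.  The drive-by-scenario-file path (`constraint_variations` /
`run_variations`) is kept alongside the direct form for command-line
parity; both produce the same intervals on shared scenarios.  Flux caps
are computed with true infinite bounds so that genuinely unbounded
directions (e.g. unconstrained internal loops) surface as ±∞ instead of
being silently capped.

## Perturbation analysis

Reaction knockouts set bounds to (0, 0).  Gene knockouts evaluate each
reaction's GPR boolean tree with the deleted genes absent and disable the
reaction when it evaluates false; reactions without a GPR are untouched.
Catalyst knockouts disable every reaction listing a deleted catalyst.
Knock-down — mentioned alongside knock-out in the tool catalogue but never
defined there — is realised as scaling a reaction's bounds by a fraction
in [0, 1], with full knockout (fraction 0) as the default.

Scans solve the wild type once and report per-entity records; per-entry
solver failures are recorded in the record's status rather than aborting
the scan.  Growth ratio is mutant/wild-type objective, clamped at 0, and
defined as 0 (with a warning) when the wild type itself cannot grow.  An
entity set is essential at threshold t% when the reduction exceeds t% of
wild type; the default of 90% follows the standard worked usage of such
reporters.  Pairwise scans accept any pair list; the built-in pairwise
reaction workflow pre-filters to chokepoint reactions to tame the C(n,2)
growth.

## Topology

Chokepoints are computed on the reversible-split network so each direction
is assessed separately, over internal species only, with exchange
reactions excluded — an exchange trivially "uniquely produces" its pool
species and would flood the list with non-targets.  An optional exclusion
list lets callers drop currency metabolites (ATP, H₂O, ...); none are
excluded by default.  Results are folded back to original reaction ids.

"Cycles" are interpreted as exchange-free flux modes: extreme rays of the
cone {v ≥ 0, S v = 0} with every exchange flux fixed to zero.  This is the
standard stoichiometric meaning of an internal loop and, unlike a
graph-theoretic notion, is directly testable against the mass-balance
equations.  Extreme paths are the extreme rays with exchanges free.
Enumeration uses the double description method over exact rationals,
starting from the nonnegative orthant and intersecting one balance
hyperplane at a time, with the combinatorial (support-based) adjacency
test — valid here because the cone lies inside the orthant and is
therefore pointed.  Rays are normalised to smallest integers.  Enumeration
is worst-case exponential, so a hard cap (default 40 post-split reactions)
refuses oversized inputs with an explicit error instead of hanging.

The network reducer applies a conservative fixpoint: drop internal species
touched by no reaction, and drop reactions containing an internal species
that appears in only that reaction (a dead end can carry no steady-state
flux).  This preserves the flux cone restricted to the survivors, which is
all that cycle hunting needs; more aggressive reductions (enzyme-subset
merging) are deliberately not attempted.

## Workflows

A workflow is data: ordered steps naming registered operations, parameter
bindings, and artifact wiring.  Steps join only when the producer's output
role matches the consumer's input role (model, id-list, constraint-table,
flux-table, report, image); validation checks the whole chain before
execution.  Every artifact is persisted as a deterministic text file (TSV,
id lists, flat reactions) or PNG, so reruns are byte-identical — plots are
rendered with timestamp metadata stripped for exactly this reason.  The
eight built-in chains mirror the common simulations; step counts include
the initial upload step, which is why automated FBA has 6 steps and the
customized variant (objective passed as a parameter rather than fetched)
has 5.

## The toy generator

The generator builds miniature networks whose results follow analytically
from the topology: a capped linear chain (optimum = cap, every step
essential, one extreme path), a double two-step branch (optimum = cap,
each branch reaction singly non-essential with interval [0, cap] at the
optimum, four synthetic-lethal pairs, two extreme paths), a chain with a
back-reaction (one internal cycle), a gene-gated isozyme pair (single
deletions harmless, joint deletion lethal), and custom edge lists.  Each
`make_toy` call returns the expected-results record alongside the model,
and the test suite asserts the records against the analysis modules, so
the generator's claims are themselves under test.

What the toys emulate: capacity-limited uptake, route redundancy,
internal loops, isozyme redundancy, boundary exchange.  What they do not:
cofactor coupling, biomass compositions spanning dozens of precursors,
compartmentalisation, and the degenerate-optimum structure of
genome-scale models.  Passing the toy suite therefore demonstrates
correctness of the algorithms, not predictive accuracy on real
reconstructions; the iJR904-based end-to-end tests cover the latter when
a copy of that model is present (see README), and the whole parse+solve
path is additionally cross-checked against cobrapy on the bundled
*E. coli* core model.

## Numerical choices and limitations

* HiGHS default tolerances; feasibility τ = 1e−9, comparisons 1e−6.
* Infinite-bound sentinel 1000 at LP time (configurable); flux caps and
  the cobra cross-check run with true infinities.
* Exact rational arithmetic everywhere structure is decided; floats only
  inside LPs.
* Stoichiometries parsed from SBML floats go through their shortest
  decimal representation, which is exact for the coefficients that occur
  in practice.
* Alternate optima make flux vectors non-unique; any consumer needing
  uniqueness must establish it with FVA first.
* Triple and higher-order knockouts, parsimonious FBA, MOMA, sampling and
  conserved-moiety analysis are out of scope.
* Problem sizes: the property suite runs on networks of 3–8 reactions so
  that the exhaustive rational oracles (3^n vertex assignments, 2^n ray
  supports) stay exact and fast; the acceptance script reports the n it
  measured at alongside every value.
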