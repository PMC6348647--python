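# Methods

## Model representation

A reconstruction is held as compartments, species and reactions with *net*
signed stoichiometry: a species appearing on both sides of a reaction is
stored with the summed coefficient, and an exact zero drops it. Reversibility
is a derived property reconciled against the bounds — `lb < 0 ⇔ reversible` —
because the bounds are the only thing the linear programmes ever see; when an
SBML file's `reversible` flag disagrees with its bounds, the bounds win and
the flag is rewritten. Default bounds when a file specifies none are the
COBRA convention: [−1000, 1000] for reversible and [0, 1000] for
irreversible reactions (flux units, conventionally mmol·gDW⁻¹·h⁻¹).

Boundary species (placeholders exempt from mass balance) are recognised by
the SBML `boundaryCondition` attribute or the conventional `_b` id suffix;
both rules can be disabled. They contribute no row to the stoichiometric
matrix. The biomass reaction is taken from the fbc objective when present,
else the first reaction whose id or name contains "biomass"
(case-insensitive), else left unset; a CLI flag overrides either.

## Consistency checking

All LPs are solved with scipy's HiGHS interface. Any solver status other
than optimal or infeasible raises; nothing is ever silently mislabelled.

**Activation threshold.** A reaction is *active* when it can carry
|v| ≥ 0.99·ε with ε = 10⁻⁴ (the customary FastCC-family threshold); the 1%
margin absorbs solver round-off. The numerical zero ζ = 10⁻⁹ is used when
reading weights out of solutions. The classification is invariant under
jointly scaling the bounds and ε, which the tests assert.

**Per-reaction oracle.** `blocked_oracle` maximizes each reaction's flux
subject to S·v = 0 and the bounds, then minimizes it as well if the reaction
may run backwards: at most one LP per irreversible and two per reversible
reaction. It is the reference implementation everything else is tested
against.

**Batched algorithm.** `check_fba` reproduces the oracle's classification
with far fewer LPs. Its primitive is the activation LP: for oriented
candidates (r, σ), maximize Σ w_r subject to S·v = 0, the bounds,
0 ≤ w_r ≤ ε and w_r ≤ σ·v_r. Two structural facts shape the schedule:

1. The constraint pair w ≥ 0, w ≤ σ·v pins sign(v_r) = σ for **every**
   candidate, whether or not its weight ends up positive. For irreversible
   reactions this is vacuous (lb ≥ 0 already), so one batch over all
   irreversible reactions decides them exactly: their activation
   certificates superpose without sign cancellation, hence every consistent
   candidate attains w = ε at the optimum and the rest are blocked.
   Reversible reactions must never share that batch — their orientation
   constraint genuinely restricts the polytope and can starve consistent
   irreversible candidates (observed, not hypothetical).
2. For reversible candidates a batch can therefore only *certify activity*
   (any reaction with |v| ≥ 0.99·ε in any solved LP is active — the flux
   vector itself is the certificate); blockedness always requires individual
   confirmation in both directions.

The schedule is: one irreversible batch; then batched rounds over the
still-unresolved reversible reactions in seeded random orientations, flipping
all orientations after a stagnant round; finally individual two-direction
confirmation of survivors, still harvesting the support of every LP solved.
A reversible round is only allowed while previously batch-certified
reversible reactions outnumber the rounds already spent — each certified
reaction saved at least one individual LP, so batching always pays for
itself. This budget makes two bounds provable and the tests assert both on
every fixture: `lp_count ≤ 1 + 2·(#reversible)` and
`lp_count ≤ blocked_oracle's count`. On the synthetic sweep the batched
algorithm needs ~40× fewer LPs than the oracle. `max_batch_rounds`
(default 10) caps the rounds regardless.

**Species classification.** A reaction *can generate* species s when it
produces s and may run forward (coefficient > 0, ub > 0) or consumes s and
may run backward (coefficient < 0, lb < 0). A species is blocked when every
generating reaction is blocked — vacuously when nothing can generate it.

**Bi-directional mode** re-runs the batched check on a copy with every
reaction's bounds set to [−M, M], M = 1000. Its blocked set is contained in
FBA mode's on every model (relaxation can only activate), which isolates
inactivity caused by over-constrained or misdirected reactions.

**Dynamic mode** asks whether each metabolite can be continuously drained
while the model grows — the producibility question FBA's strict steady state
cannot pose. Every non-boundary species gets a dilution variable d_s ≥ 0 in
S·v − d = 0; the biomass flux is forced to at least δ = 10⁻⁴ when a biomass
reaction is designated (omitted otherwise, so draft models without a biomass
function or exports can still be assessed from their imports alone). One LP
maximizes Σ w_s with 0 ≤ w_s ≤ min(ε, d_s); dilution certificates for
individual species superpose, so the optimum drains every drainable species
simultaneously and species s is blocked iff w_s ≤ ζ. A reaction is blocked
iff one of its reactants — the negative-coefficient side as written — is
blocked. If the LP is infeasible the model cannot grow at all; everything is
reported blocked with an explicit warning. The per-species reference oracle
maximizes one species' ε-capped dilution per LP; forcing d_s ≥ ζ directly
would sit below the solver's feasibility tolerance (~10⁻⁷) and is
deliberately avoided.

## Topology tools

The bipartite graph has species→reaction edges for consumption and
reaction→species edges for production, flagged bidirectional on reversible
reactions. Blocked modules are the connected components of the undirected
subgraph induced by blocked nodes, numbered by decreasing size then smallest
member id; they partition the blocked set and the tests verify the partition
against an independent union-find. A module can be extracted as a standalone
sub-model (ids preserved, optional halo of adjacent context nodes) so edits
recorded against the extract re-apply to the parent.

Ancestry minimizes total node count (species + reactions) — "smallest"
needed a concrete metric and node count is directly testable. The search is
a layered fixpoint over the AND-OR structure: an oriented reaction's member
set is itself plus the union of its reactants' sets (the union de-duplicates
shared ancestors); a species' set is itself plus its cheapest producer's
set, ties to the smaller reaction id. Reversible reactions contribute one
candidate direction per permissive bound; boundary species count as freely
available. The union heuristic is not an exact minimal-subset search (that
is combinatorial), so the tests compare it against brute-force enumeration
only on generated models of ≤ 12 nodes with a unique minimum, where it
agrees. When the target never resolves, production is irreducibly cyclic and
the strongly connected component at the first unresolvable dependency is
reported; the acyclicity guarantee refers to the derivation (each member
species with its chosen producer), since byproduct edges among members can
close cosmetic cycles in the induced subgraph.

## Layout and rendering

Layout is two-phase: a Fruchterman–Reingold spring embedding (networkx,
seeded, 500 iterations by default) per compartment over its species and
internal reactions, then deterministic packing of the compartments'
padded bounding boxes along an Archimedean spiral, largest first, first
fit. Contours are convex hulls of member positions buffered by one node
diameter, so species containment holds by construction and disjoint boxes
guarantee non-overlapping contours. Transport reactions sit at the centroid
of their participants, nudged outside any contour that covers them;
reactions with empty stoichiometry are parked on a row below the canvas.
Rendering is pure string generation with a fixed style table (exact hex
values chosen once to keep snapshots stable): identical inputs give
byte-identical SVG. DOT export mirrors the same encoding with compartments
as clusters and `dir=both` on reversible edges.

## Synthetic models

The generator builds a flux-consistent backbone: one import feeding a
random tree over all species with unit stoichiometry, an export at every
leaf, and single-substrate/single-product cross-links for the remaining
reaction budget — every reaction can route flux from the import to an
export, which `blocked_oracle` confirms in the tests. A requested fraction
of conversions becomes reversible. Four planted failure kinds mirror what
curators meet in real drafts: a dead-end metabolite (produced, never
consumed), an orphan substrate (consumed, never produced), a misdirected
exchange (a new species consumed into the network and exported but never
imported — blocked as written, fully active once directionality is relaxed)
and a stoichiometric trap (a carrier consumed by a transport pair with no
regeneration). Ground truth is recorded by running the oracle on the emitted
model rather than asserted by hand, so labels cannot drift from the
generator; the dead-end and orphan labels are additionally checked
analytically in the tests.

What the generator does *not* emulate: realistic biochemistry or
thermodynamics, genome-scale size (a few hundred reactions at most),
non-unit stoichiometry along the backbone, and compartmentalised transport
chains. Passing the sweep therefore demonstrates algorithmic correctness on
the planted failure taxonomy, not performance or recall on published
reconstructions.

## Problem sizes and defaults

The bundled sweep uses 200 models of 20–120 reactions with reversible
fraction 0–0.5 and one planted inconsistency each; dynamic mode is
cross-checked against its per-species oracle on 100 of them, and ancestry
against exhaustive enumeration on ≤ 12-node instances. Defaults: ε = 10⁻⁴,
ζ = 10⁻⁹, δ = 10⁻⁴, M = 1000, 10 batch rounds, exchanges as distributed
(`open_exchanges` opens every exchange reaction's bounds for the
"blocked under any input conditions" reading).

## Known limitations

- Exactness of the single irreversible batch relies on activation
  certificates superposing within the bounds; with ε = 10⁻⁴ against bounds
  of 10³ this holds unless stoichiometric ratios span ~7 orders of
  magnitude.
- The dynamic mode treats the reactant side "as written" for reversible
  reactions; products of a reversible reaction are not treated as reactants
  of its reverse direction when propagating species blocks to reactions.
- Ancestry is a heuristic beyond small instances; minimality is only
  guaranteed where the tests enumerate.
- Purging boundary species keeps reactions whose stoichiometry becomes
  empty (they remain as import/export stubs); combine with the isolated-node
  purge to drop them.
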