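# Methods

This note records the modelling semantics, the defaults and why they are
set where they are, and the places where a design was genuinely open.

## Logical semantics

**Components and functions.** Activity levels are integers `0..max_level`
with `max_level ∈ {1, 2}`.  Ternary levels are reserved for proteins whose
low and high activities do different things (ATM-P, the IKK complex,
IκBα).  Functions are sums of products of threshold literals; a term's
`target_level` may be 0, modelling induced inactivation/degradation.

**Resolution rule.** In a total state, the target level of a component is:
0 if any satisfied term has `target_level` 0; else the maximum
`target_level` over satisfied terms; else the basal `default_level`.  The
0-override is what lets a single degradation term (IKK ≥ 2 → IκBα = 0)
coexist with the partial-degradation term (IKK ≥ 1 → IκBα = 1) without
arbitration.  Curated models are expected to be conflict-free; a state in
which a 0-term and a 2-term fire together is a curation error, which
`find_conflicts` reports.  Evaluation itself never raises on it (randomly
generated models must remain total functions), and the bundled generator
emits no 0-terms at all, so generated models are conflict-free by
construction.

**Inputs.** A component with no incoming terms is an input; it holds its
clamp, else its basal default.  Housekeeping presences (e.g. the
chaperone Hsp90) are inputs with default 1.

**Signs.** Splitting a term yields one arc per literal with
`sign = literal sign × term direction`, direction −1 for 0-terms: an
activator appearing in a degradation term is drawn (and analysed) as an
inhibitor of the target.

## Logical steady states

The LSS is the least fixpoint of "forced under all completions": a
component becomes determined once its resolved target is identical under
every completion of the currently undetermined components appearing in
its terms.  This is a monotone closure, hence order-independent, and it
is exactly the updating-scheme-independent notion needed to reason about
attractors (no total LSS ⇒ cyclic attractor).  The price is that
feedback is never "resolved by simulation": components on unresolved
cycles stay undetermined, and requirements on them are unmet by
convention (a goal `x = 0` needs a *determined* 0).

One modelling consequence: a double-negative (positive) loop such as
"low ATM inactivates PP2A, and PP2A absence permits high ATM" cannot be
resolved by any scheme-independent steady-state notion — every
propagation semantics that could pick the active branch would be an
updating-scheme commitment.  The bundled subnetwork therefore encodes
ATM's high-activity term without the ¬PP2A literal and keeps PP2A as a
downstream target of ATM only; the cutoff-2 steady state then determines
the whole damage response, which is what scenario comparison needs.

**Time scales.** The cutoff is cumulative: `τ = 2` keeps scales 1–2 and
excludes the late feedback layer (scale 3).  Components whose every term
lies beyond the cutoff sit at their default — before the feedback phase,
feedback proteins like Wip1 and MDM2 are simply not yet expressed.  All
scenario comparisons and intervention searches run at `τ = 2`, the time
window in which every pro-arrest, pro-apoptotic, and anti-apoptotic arm
is maximally active; `τ = 3` is the feedback view (where the p53 axis
correctly dissolves into undetermined oscillation).

## Dependency matrix

Path signs are taken over **simple paths**, not walks: a negative
self-loop hanging off an otherwise positive chain does not make the chain
ambivalent — it makes its downstream influence *weak* (the influenced
species is feedback-regulated).  "Weak" means at least one species on at
least one connecting simple path (endpoints included) lies on a negative
simple cycle.  Diagonal entries classify the simple cycles through the
component itself.  Simple-path enumeration is exponential in principle;
an explicit extension budget (default 2·10⁶ DFS steps) turns pathological
inputs into a clean error instead of a hang.  The separate
`signed_reachability` operation keeps the cheap walk-parity semantics
(product-graph BFS) for use as a substrate.

## Motifs and functionality

FFL classification follows the standard convention: type from the signs
of the indirect path ((+,+) → 1, (−,−) → 2, (+,−) → 3, (−,+) → 4),
coherent iff the direct sign equals the indirect product.  The gate is
read off the target's terms: AND if the two inputs co-occur in one term,
OR if they act through distinct terms, MIXED if both patterns occur.

A feedback loop's functionality context is an assignment of its external
regulators under which *every* loop arc can change its target's resolved
level (a discrete derivative across some threshold of the arc's source).
Regulators of the target that are neither the arc source nor external —
other loop members, self-literals — are quantified existentially.  Loops
with no context are structurally present but dynamically inert (e.g. an
arc shadowed by an always-satisfied OR alternative).

## Dynamics

Transitions are asynchronous single steps of ±1 toward the resolved
target (the standard multi-valued convention; a ternary component passes
through its intermediate level).  A priority scheme ranks (component,
direction) pairs; among concurrent candidates only the top-ranked class
fires, asynchronously within the class; unranked pairs share the lowest
rank.  The damage-response preset ranks activations of the sensor
kinases and the two transcription factors first, lesion maturation
second, and their feedback-driven deactivations third.

Attractors are terminal SCCs of the reachable state-transition graph:
steady state (singleton, no exit), simple loop (every member exactly one
internal successor), complex loop (overlapping cycles).  The state-space
cap (default 10⁶ states) raises an explicit overflow error.  The
symbolic fixed-point search assigns forced components first (all
regulators decided) and branches only inside feedback, so it scales past
any enumerable state space; inputs sit at clamp/default, so "fixed points
per input condition" is the natural unit — also the right unit for the
positive-feedback/multistationarity theorem, which holds per frozen
input assignment.

## Reduction

`remove_component` substitutes the removed component's resolved-level
condition (as a DNF over its regulators, obtained by enumerating their
assignments) into every consuming literal, then simplifies by
contradiction removal, absorption and de-duplication only — no full
minimisation, so results stay predictable.  Autoregulated components are
refused: a feedback loop reduces at most to its minimal form, an
autoregulation, and removing that would destroy attractors.  Merged
terms carry the maximum time scale of the pieces (a path is as late as
its latest step); this is a convention, and cutoff-restricted analyses
of reduced models should be interpreted accordingly.

`reduce_to` additionally prunes unconsumed components (outputs outside
the study focus — deleting a sink cannot change anyone's function) and
folds stimuli or pinned constants outside the keep set into their
consumers at their default/clamped level.  The removal order (fewest
regulators first, ties alphabetical, recomputed each round) is a
repository convention; order-independence of the resulting truth tables
is property-tested.  Fixed points of the reduction are exactly the
projections of the original's; trajectories of the asynchronous dynamics
are not all preserved, so state-transition graphs before and after
reduction are compared only at the level of attractor type.

## Intervention searches

Candidates default to removals (clamp 0) of every non-input, non-output
component; defect searches add constitutive activation at every
attainable level.  The lesion pseudo-node `DSBs_late` is excluded by
default (lesions are neither drug targets nor genes); model-specific
exclusion lists plug in the same way (templates under `src/lddr/data/`).
Search is breadth-first in cardinality (default bound 3) with superset
pruning, so exactly the subset-minimal solutions emerge in deterministic
order.  If the scenario alone meets the goal, the empty set is the unique
minimal solution and the result is empty — "no targets found" is a
biological statement, not a failure.

## The two bundled models

**Core model (6 components, Boolean).** DSBs_early (stimulus) → DSBs_late
(scale 2); DSBs_early → ATM-P; DSBs_late → RPA-ATR-ATRIP-P; ATM-P or
RPA-ATR-ATRIP-P → p53-P; ATM-P → nuclear p50-p65-P.  The late feedback
layers are folded in as reduction would produce them: active p53
suppresses ATM-P, RPA-ATR-ATRIP-P and itself (the Wip1/MDM2 layer),
nuclear NF-κB suppresses itself (the IκBα layer).  The published core
is defined only graphically, so these functions are this package's
reconstruction; they were written down once from the folding argument
above, and the resulting variant behaviour (wildtype: one complex cyclic
attractor of 16 states; single feedback interruptions: still cyclic;
p53 loss + constitutive NF-κB, or constitutive p53: one steady state)
is asserted by the acceptance tests rather than assumed.  All components
are Boolean; state labels are digit strings in the component order above.

**Synthetic DDR subnetwork (31 components, 47 interactions).**  A
synthetic stand-in for the full curated 96-component network, wiring the
well-documented mechanisms: MRN- and PP5-dependent ATM activation with
ternary low/high activity (low ATM silences PP2A), RPA-ATR-ATRIP sensing
of SSBs and of ATM-processed late DSBs, claspin-dependent Chk1, Chk2,
the two Cdc25A-degradation routes and Cdc25C phosphorylation, p53 with
HIPK2-dependent Ser46 phosphorylation and late Wip1/MDM2 feedback,
TAK1-mediated c-Myc downregulation, the genotoxic IKK/IκBα/NF-κB branch
(ternary IKK and IκBα, basal c-Rel activation, NF-κB-driven IκBα
resynthesis at scale 3), and three apoptosis-onset routes (p53-Ser46,
E2F-1, PIDDosome).  SSB-induced replication-fork collapse feeds the late
DSB pool, which is how SSBs reach the ATM/Chk2 arm.  Its function list
is this package's own curation for exercising the machinery end to end;
it reproduces the qualitative scenario phenotypes (ATM loss blocking all
survival arms, MRN-subunit disorders being indistinguishable, PP5 and
ATM singleton sensitization targets) but its counts — 31 components,
pathway multiplicities, numbers of intervention sets — are properties of
the stand-in, not of the published full network.  Full-network numbers
require transcribing the published supplementary function list
(`load_full_model` validates the census: 96 components, 98 interactions,
exactly the ternary trio).

## Random model generator

Defaults emulate the curated structural class: mostly Boolean components
with a configurable ternary fraction, 1–3 literals per term, negation
probability ~0.3, time-scale weights (0.6, 0.3, 0.1) favouring early
interactions, no 0-terms.  Forbidding both cycle signs is enforced
structurally (topological wiring); forbidding one sign uses seeded
re-generation with a retry budget, refusing rather than returning a
violating model.  Planted motifs live on dedicated fresh nodes untouched
by the random part, so recovery tests have exact ground truth.  A single
integer seed drives everything; no global random state is touched.

What passing the synthetic-suite tests shows is that the *engine* is
correct on this structural class (verified against independent
brute-force oracles: global-completion enumeration for the LSS,
exhaustive simple-path/cycle search for the matrix and motifs, full
state-space sweeps for fixed points and loop functionality, exhaustive
subset search for interventions).  It does not show that any particular
curated model is biologically right — real networks have hub structure,
long-tailed degree distributions and correlated time scales that the
generator does not emulate.

## Problem sizes

Property batteries run on networks of 5–8 components (where the
exhaustive oracles are exact) with 200 seeds for the steady-state checks
and 25–60 seeds for the others; the bundled analyses run on the
6-component core (state spaces ≤ 64) and the 31-component subnetwork
(steady-state based, no state enumeration).  The whole test suite runs
in well under a minute; the acceptance script in a few seconds.

## Known limitations

* No CellDesigner/SBML-qual interchange; the native JSON format plus
  SIF/GraphML/DOT export is the interface.
* The dependency matrix is exact but worst-case exponential; it is meant
  for curated-model sparsity, and the budget guard is the escape hatch.
* Functionality contexts enumerate full assignments of the external
  regulators (no symbolic compression of equivalent contexts).
* Reduction does not rewrite priority schemes; a scheme must be restated
  for a reduced model.
* Quantitative/kinetic semantics (rates, delays, stochastic switching)
  are out of scope by design.
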