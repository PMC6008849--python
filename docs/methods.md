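# Methods

## Model

A network is a directed graph. Nodes are genes/proteins, compounds,
complexes, user-defined custom nodes, or *signal* nodes representing
external inputs (a drug dose, a hormone injection). Every node carries an
integer activity state in **[0, 9]** (0 = inactive, 9 = maximal); time is
discrete (t = 0, 1, 2, …). Edges carry a nonzero signed integer weight —
positive for activating interactions, negative for inhibitory ones — and a
nonnegative integer delay d (default 0).

The *effect* of node i on node j is s_i(t − d_ij) · w_ij; the *net effect*
on j is the sum over j's incoming, non-blocked edges. The synchronous
update, applied to all non-signal nodes simultaneously from the same
pre-step state, is

    s_j(t+1) = clamp(s_j(t) + sign(net_j(t)), 0, 9)

so only the **sign** of the net effect matters and states move by at most
one level per step. Signal nodes ignore the rule and replay their preset
pattern cyclically (a constant signal is a length-1 pattern).

Assumptions worth spelling out: the update is deterministic and
synchronous (no stochastic or asynchronous semantics); interaction
strength enters only through the sign of an integer sum, making the model
robust to imprecise weights but blind to graded kinetics; and the 0–9
scale is ordinal, not a concentration.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| state range | 0–9 | integer activity levels |
| activation / expression / phosphorylation weight | +2 | overcomes the −1 self-degradation loop at equal source activity |
| inhibition / repression / dephosphorylation weight | −1 | adds to the degradation pressure |
| self-degradation weight | −1 | automatic self-loop on every non-signal node; models decay of biological material |
| edge delay | 0 steps | reads the source state d steps in the past |
| max_steps | 100 | step cap for `simulate`; pathway-scale networks observed here settle well within it. `None` runs to the guaranteed steady state/cycle |
| blocking threshold | 1 | a blocker is active when its state ≥ threshold (i.e. > 0); configurable per rule |

Unmapped KGML relation subtypes (e.g. `binding/association`,
`indirect effect`, `state change`) produce **no** edge and are reported,
because guessing a sign would silently corrupt the dynamics; users can map
them explicitly in the weight-scheme file.

## Import and fusion

Entries of type `gene`/`ortholog`/`enzyme` become gene nodes, `compound`
entries compound nodes, `group` entries one complex node whose aliases are
the union of the member names; `map` (pathway-link) entries and any
relation touching them are dropped as non-molecular. Fusion — within one
pathway and across pathways — joins nodes whose alias sets intersect,
transitively (connected components of the alias-overlap relation), keeping
the union of aliases and re-targeting every incident edge.

Two deliberate choices here:

* **Fusion is restricted to nodes of the same kind.** A complex carries
  its member gene names as aliases; unrestricted alias fusion would
  collapse a dimer with its standalone monomer node, which are distinct
  biological entities (and behave differently — e.g. a homodimer given its
  monomer's expression while a heterodimer starts at 0). Alias
  disjointness is therefore an invariant *per kind*.
* **Edge collisions keep the larger-magnitude weight** (ties resolved
  toward the positive sign), deterministically, and every collision is
  reported — so each input relation is accounted for either as a surviving
  edge or as a logged collision, never silently lost.

Fused node ids are the lexicographically smallest alias (complexes: the
"+"-joined sorted member names), which makes merges order-invariant up to
nothing at all — identical inputs in any order give the identical network.

## Expression discretization

`round(9 · value / M)` with M the maximal matched value in the whole
network; rounding is half-away-from-zero (4.5 → 5), chosen as the
deterministic, direction-unbiased convention for positive data. Negative
and zero values, and nodes with no expression row (typically compounds and
complexes), map to state 0. When several aliases of one fused node match
different rows, the maximum value is taken and the conflict logged.
Whole-network scaling means one extreme outlier compresses all other
nodes toward 0 — use log-scale data.

## Termination detection

The extended dynamical state is the window of the last D+1 configurations
(D = maximal edge delay) plus each signal's phase; it is finite, so with no
step cap every run provably ends in a fixed point or a cycle.

* **Steady state** is declared when the last D+2 configurations are
  identical and every signal pattern is constant. With D = 0 this is
  exactly "two consecutive identical configurations"; the D+2-deep check
  is the sound generalization under delays, because two equal consecutive
  configurations alone do not guarantee a fixed point when older window
  entries still differ. The final configuration is then a verified fixed
  point (re-applying the step rule returns it unchanged).
* **Cycle** is declared at the first recurrence of the extended state
  (hashing the full window plus signal phases, so delayed or
  signal-driven dynamics cannot alias); `cycle_start` is the earlier
  occurrence, and replaying from it reproduces the recorded cycle exactly.

Blocking rules are evaluated on the pre-step configuration (synchronous
consistency); an edge delay means "read an older source state", not
"suppress the edge for d steps". Batch mode deduplicates attractors by a
canonical representative — the steady configuration, or the
lexicographically least rotation of the cycle — and reports frequency and
mean steps to absorption (for a steady run, the index of the first
configuration of its final constant run; for a cycle, `cycle_start`).

## Trajectory comparison

Per node: Euclidean distance √Σ_t (a(t) − b(t))², unnormalized (no
division by length). Unequal-length runs are aligned by continuing the
shorter one — repeating its final configuration if steady/capped, or
unrolling its cycle — up to the longer length; a `truncate` option cuts
both to the shorter length instead. The *differential* flag requires the
per-step gap to exceed the initial gap **strictly** at some step, so a
constant inherited offset (e.g. [5,5,5] vs [3,3,3]) is never flagged, while
[2,4,6] vs [2,2,2] is.

## Synthetic data

The KGML generator emits structurally valid pathway XML (entries,
relations, subtypes, groups with components) with controllable cross-
pathway name overlap, deterministically per seed. It emulates the format
and the fusion-relevant structure of real pathway files, **not** their
biology: no realistic degree distributions, no curated interaction signs,
no organism-specific identifiers, and entry names are synthetic tokens.
Likewise `random_network` draws uniform weights in {−2,−1,1,2} and uniform
initial states. Passing tests therefore demonstrate correctness of
parsing, fusion, dynamics and statistics — they say nothing about the
biological fidelity of any particular KEGG pathway or expression dataset,
which depend on database versions and curation quality.

The toy four-node fixture (constant signal → A → B → C ⊣ A, weights
+1/+2/+2/−2, −1 self-loops) is the canonical demonstration that a
negative-feedback loop under constant drive oscillates: the run ends in a
detected cycle in which A, B and C repeatedly rise and fall while the
signal stays constant.

## Problem sizes used in the checks

The automated checks run at sizes chosen to give dense coverage of the
small-network state space where every property can be verified against
brute force: 1,000 random networks of ≤ 8 nodes for step-rule agreement,
200 networks of ≤ 6 nodes with delays ≤ 2 for unbounded termination
soundness, 1,000 random trajectory pairs for the differential filter, 300
random expression tables, 60 random graphs for the structural analyses,
and all permutations of 3-pathway merge sets. These exercise every code
path; the implementation itself has no size-dependent branches, and
imports of dozens of real pathways differ only in runtime.

## Known limitations

* Only KGML `relation` elements are imported; metabolic `reaction`
  elements are out of scope, as is downloading from KEGG and gene-id
  translation.
* The ±1-per-step sign rule cannot express magnitude-dependent response
  speeds; a weight of −10 and −1 differ only when summed against opposing
  inputs.
* Name matching for expression rows is exact and case-sensitive; no
  probe-to-gene mapping, multi-sample averaging or automatic log
  transform.
* Attractor statistics enumerate explicitly provided or randomly sampled
  initial conditions; exhaustive sweeps grow as 10^k in the number of
  swept nodes.
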