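# Methods

## The model

A first-order Boolean recurrent neural network is a tuple
(X, U, W, U_in, b): a set of N activation cells and M input units, an
N×N rational matrix of cell-to-cell synaptic weights, an M×N matrix of
input-to-cell weights, and a per-cell rational background activity.  The
dynamics are synchronous McCulloch–Pitts updates: cell j fires at time
t+1 iff

    Σ_i W[i,j]·x_i(t) + Σ_k U_in[k,j]·u_k(t) + b_j  ⋈  θ_j,

with all thresholds θ_j = 1 by default and ⋈ either ≥ (`at_least`, the
default) or > (`strictly_greater`).  All arithmetic is exact
(`fractions.Fraction`), so the dynamics are bit-reproducible and invariant
under a common positive rescaling of weights, backgrounds and thresholds.
Network states are identified with integers, cell #1 the most significant
bit.

Driven by an infinite input stream, a network with N cells visits only
2^N states, so some set of states recurs forever: the *attractor* of the
evolution (the inf set).  Each attractor is typed *meaningful* or
*spurious*; the set of streams whose attractor is meaningful is the
network's neural language.  Streams are represented as ultimately periodic
words u·v^ω, the decidable test surface for every acceptance claim.

## Networks and ω-automata

A network is simulated by a deterministic automaton on its own state
space: states are the 2^N state codes, the initial state is all-quiet, and
δ(q, a) is one synchronous update.  With a designated output layer the
automaton is Büchi (finals = states where some output cell fires); with a
free attractor typing it is Muller (table = the meaningful attractors,
evaluated lazily because the number of cycles can be exponential).

The converse construction simulates a deterministic automaton by a
threshold network whose cells one-hot encode the automaton's letters,
transitions and states:

* one *letter cell* per letter a, firing at t+1 iff the input at t was
  exactly a (weights 1/#ones(a) from the letter's one-positions, −1 from
  its zero-positions; the all-zero letter uses background 1 and −1 from
  every input bit);
* one *transition cell* per (state, letter) pair — the recurrent layer.
  A transition cell fires iff its state group and its letter cell fired,
  a conjunction of two one-hot groups implemented with two half-weights
  against threshold 1.  The pair layer is essential: wiring letter and
  predecessor-state cells directly into successor-state cells at
  half-weights is unsound, because with several transitions sharing a
  target a mismatched (state, letter) pairing also sums to the threshold —
  the transition relation of a general deterministic automaton is not
  threshold-separable over the two one-hot groups;
* one read-out *state cell* per automaton state (an OR over the
  transition cells targeting it);
* a two-cell igniter: a *delay* cell with background 1 that is inhibited
  both by itself and by a *latch* cell that turns on one step later and
  stays on, so the delay cell fires exactly once and starts the run in the
  initial state.  (A single self-inhibiting cell with background 1 would
  oscillate rather than fire once.)

From step 2 on exactly one state cell fires per step, and after any finite
prefix the firing state cell is the automaton state reached (with a fixed
start-up lag).  Language equality with the source automaton — Büchi via
the output layer imaging the finals, Muller via projecting attractors onto
the state cells — is the tested contract; the tests check it exhaustively
on all u·v^ω with |u|, |v| ≤ 4.

## Cycles, attractors and their decomposition

A *cycle* of an automaton graph is a state set admitting a closed path
visiting precisely those states.  Two enumerable universes are exposed,
and they genuinely differ:

* `strongly_connected` — every state set whose induced subgraph is
  strongly connected.  This is the formal notion (closed paths may reuse
  transitions) and the default for degree computations; it is in exact
  bijection with the attractors of the source network.
* `trail_support` — state sets realisable as supports of *edge-distinct*
  closed walks (closed trails).  This is the operational notion behind
  per-state cycle censuses (see the case study), strictly contained in the
  former: a set may be strongly connected yet not coverable without
  reusing a transition.

Any closed walk decomposes into vertex-simple *constitutive cycles* by a
stack algorithm: push states along the walk; when the next state is
already on the stack, pop the enclosed segment as one constitutive cycle.
Every step of the walk lands in exactly one constitutive cycle, so lengths
are conserved.

## Type assignments

Output-layer typing (meaningful iff some output cell fires inside the
cycle) is inclusion-monotone: a supercycle inherits the finals of its
subcycles, so no meaningful cycle sits inside a spurious one.  This
monotonicity is exactly what pins output-layer networks to deterministic
Büchi expressive power; `buchi_segment_check` tests an arbitrary
assignment for it.

The case study's neurobiological rule types a vertex-simple cycle
spurious iff, over one traversal (endpoint counted once), some state has
SC active with the Thalamus quiet, or GPi/SNr is quiet during *at least
half* of the duration; composite walks take the majority type of their
constitutive decomposition with ties meaningful.  The half-duration
(rather than strict-majority) reading of the output-nuclei criterion is
forced by the published type labels: the even-length chain cycle
(0, 384, 223, 511, 63, 33, 0), with the output nuclei quiet in exactly
3 of 6 states, is printed spurious.  The strict reading would type it
meaningful; both readings agree on every odd-length printed cycle.  The
rule is walk-sensitive in principle, so cycles carry a deterministic
witness walk (the discovering trail for the census universe, a greedy
shortest-path cover for the formal universe).

## Degrees

The attractor-based degree is the length of a maximal alternating or
co-alternating structure, an ordinal < ω^ω stored in Cantor normal form.

**Chains (Büchi).** A chain is a sequence of distinct cycles of strictly
alternating success in which each cycle is accessible from its predecessor
but not conversely; an ω-chain is a communicating (mutually accessible)
opposite-type pair.  Since any two cycles in one strongly connected
component communicate, an SCC hosting both types immediately yields ω;
otherwise every cyclic SCC carries a single type and the maximal chain is
a longest type-alternating path over the condensation, computed by dynamic
programming.  Both computations are exact.

**Trees (Muller).** Inside one SCC an alternating tree is a strictly
increasing inclusion sequence of cycles with strictly alternating types
(communicating opposite-type cycles do *not* force ω here, because Muller
acceptance depends on the exact inf set).  Across SCCs, segments are
concatenated along one-way accessibility with alternation preserved at the
junctions.  The finite fragment is exact (inclusion DP inside each SCC,
condensation DP across); it is cross-checked against an independent
exhaustive search on every random and planted instance in the tests.
Transfinite levels are *reported as lower bounds*: when m nested branch
points exist (condensation nodes from which two mutually unreachable
components of opposite type are reachable), the result ω·m carries status
`lower_bound` rather than a claimed exact value.  The case study and all
planted instances live in the finite fragment, where results are exact.

The degree trichotomy: a one-sidedly maximal (co-)alternating structure of
length n gives degree n, non-self-dual, of that kind; equal maximal
lengths give a self-dual degree; an ω-chain gives ω, non-self-dual.
Degrees are invariant under complementing the assignment (alternating and
co-alternating structures swap), which the tests assert on random
fixtures.

## Case-study calibration

The published circuit gives the 9-cell weight matrix (packaged verbatim in
`data/basal_ganglia.tsv`), one input unit projecting to SC and Thalamus at
weight 1, a 12-state reference walk of the derived automaton, the 16-state
strongly connected component, a per-state census, and a seven-cycle
co-alternating tree.  It does not give backgrounds, the threshold
comparison, or the census counting conventions.  These are calibrated:

* **Dynamics.** Zero backgrounds are provably infeasible: after the
  all-firing state 511, SC and Thalamus receive identical net input
  (−1/2 each plus drive) yet the reference walk requires SC quiet and
  Thalamus firing.  A grid search over per-cell backgrounds in
  {0, ±1/2, ±1} and both comparison modes, pruned cell-by-cell against the
  walk's transitions and filtered on reproducing the published component,
  leaves 8 feasible calibrations — all inducing the *same* automaton
  (the structure is also unchanged under per-cell mixed comparison modes,
  so the calibrated object is unique even though the parameters are not).
  The reported calibration is the lexicographically smallest feasible
  background, 1/2 on the Thalamus and 0 elsewhere, with `at_least`.
* **Census.** "Number of cycles starting from s" is reproduced exactly
  (16/16 rows) as the number of distinct supports of edge-distinct closed
  walks rooted at s on the collapsed graph; "number of constitutive
  cycles" exactly (16/16) as the number of distinct *rooted* constitutive
  cycles in the stack decompositions of the first trail that discovers
  each support, under ascending depth-first successor order.  Competing
  conventions (raw trail counts, rotation-classes, simple cycles through
  the state) are all computed and scored in the calibration report; the
  selected pair is the only one matching all 32 printed cells.

The degree pipeline types every census cycle with the neurobiological rule
and computes the maximal structures over the census (`trail_support`)
universe, reproducing the published finding: a co-alternating inclusion
chain of seven cycles starting spurious, no alternating tree of that
length, hence a non-self-dual network of finite degree 7.  Under the
formal `strongly_connected` universe the cycle family is larger (357 sets
against 99) and the maximal co-alternating chain is one longer; the
package exposes both, and the case study pins the census universe because
the published analysis enumerated cycles by trails.

## Synthetic fixtures

Random networks draw weights from {±1/2, ±1, 2} at configurable density;
random automata draw complete transition functions uniformly.  Planted
instances use a line gadget — state j returns to 0 on letter 0 and
advances on letter 1 — whose cycles are exactly the k nested prefix sets,
so the planted tree length is known by construction and re-verified at
build time by the independent brute-force search.  All generators are
deterministic functions of an explicit seed.

What the synthetic fixtures do not emulate: biologically structured
topology (degree distributions, Dale's law sign constraints), noise, or
plasticity.  Passing the recovery tests shows the degree machinery is
correct on known ground truth, not that real circuits have any particular
degree.

## Numerical and size choices

Everything is exact integer/rational arithmetic; there are no tolerances.
Enumerations carry explicit caps (default 2·10^6 objects) and raise rather
than truncate.  Problem sizes used by the test-suite cross-checks: random
automata of ≤ 5 states, exhaustive word sets with |u|, |v| ≤ 4, planted
lengths 1–5 and ω with 20 seeds; the case-study automaton has 2^9 states
with a 16-state live component, and its full pipeline (calibration,
census, degree) runs in a few seconds.

## Known limitations

* Transfinite tree degrees are structural lower bounds, not exact values;
  only the finite fragment and ω-chains are exact.
* The census constitutive convention depends on an enumeration order
  (ascending depth-first); it reproduces the published counts exactly,
  but other orders give counts differing by ±2 — the published table does
  not determine the convention uniquely, only this one fits all rows.
* `strongly_connected` cycle enumeration is exponential in the SCC size
  and capped at 24 states per component.
* The walk-sensitivity of the neurobiological rule means composite-cycle
  types depend on the canonical witness; constitutive (vertex-simple)
  cycle types depend only on the state set.
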