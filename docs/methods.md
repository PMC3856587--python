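# Methods

## The model class

`serohpa` implements a synchronous Boolean network (SBN): every node holds a
binary value (1 = active, 0 = inactive), and all nodes update simultaneously
at each discrete time step through fixed logic rules of their inputs.  A
network is a pair of structures — per-node truth tables (the rules) and the
wiring that feeds them — plus a set of *clamped* nodes whose value is held
at its initial setting for a whole run because no rule regulates them.
Because the state space is finite (2^N states) and the update deterministic,
every trajectory eventually enters a repeating cycle of states, the
**attractor** (period 1 is a fixed point).  Attractor structure is the
model's operational notion of stability: a biological regime corresponds to
the cycle a scenario settles into.

Truth tables are indexed little-endian in the listed input order: a node
with inputs `(j0, …, j_{k-1})` reads entry `Σ s[j_i]·2^i`.  The text format
(one Boolean expression per node, `&`, `|`, `!`, parentheses) compiles
expressions to tables with inputs ordered by first appearance, so the file
is the single source of truth for both wiring and logic.  Clamping is an
explicit frozen set — clamped nodes copy their value each step — which also
implements in-silico knockouts (clamp with the bit forced to 0) uniformly.

## The biological network

The shipped model (`data/mdd_network.bnet`) couples three pathways across
four compartments — dorsal raphe nucleus (DRN), a serotonin-sensitive
hippocampal cell, the paraventricular nucleus (PVN) and the pituitary/
adrenal axis:

* **Serotonin handling (DRN).**  TRP and TPH2 produce 5-HTP; AADC converts
  it to somatic serotonin (5-HT*); MAOA degrades it to 5-HIAA (a sink
  node); SL18A2 packages it into vesicles, released into the cleft as
  synaptic 5-HT; the transporter 5-HTT recaptures it.  Synaptic 5-HT
  persists until recaptured (a persistence term in its rule).
* **Receptor branches.**  Synaptic 5-HT activates the postsynaptic 5-HT1A
  receptor (requiring NF-κB for its expression) and the presynaptic
  autoreceptor 5-HT1A*; each opens a Gi-gated K⁺ channel, hyperpolarizing
  its cell (K+ and K+* nodes).
* **Neurotrophin loop (DRN).**  CREB-driven BDNF activates TRkB, which
  maintains the serotonergic phenotype genes (TPH2, AADC, MAOA, SL18A2,
  5-HTT) and suppresses autoreceptor synthesis.  Autoreceptor-driven
  hyperpolarization blocks the BDNF regulatory genes: the blockade enters
  the loop at CREB, written in double-negative form (`CREB = !K+*`), with
  TRkB's enhancement of CREB/BDNF carried by relief of that blockade.  The
  cAMP/PKA kinase cascade between TRkB and CREB appears among the
  ubiquitous intermediates (below).
* **HPA axis.**  Stress drives CRH and vasopressin (VPA) in the PVN; both
  are required for pituitary ACTH; ACTH drives cortisol.
  Glucocorticoid/mineralocorticoid receptors (GR/MR) close the negative
  feedback at the PVN (blocking CRH/VPA) and the pituitary (blocking ACTH),
  and in addition GR/MR(DRN) blocks TPH2 while GR/MR(SSC) blocks NF-κB.

Rule-building conventions: inhibition is AND-NOT (a target is active when
its activator is present and its inhibitor absent); several activators with
no stated operator combine by OR; a pure-NOT rule is used only where the
sole regulator is an inhibitor.  Every edge whose exact Boolean form is not
fixed by the pathway narrative is tagged `reconstructed` in the network
file, with the intended mechanism in the adjacent comment.

Nine nodes — the pre- and postsynaptic Gi subunits, adenylyl cyclase,
cAMP, PKA, the postsynaptic effector chain, and the SNARE fusion machinery
— are ubiquitously expressed cellular machinery rather than candidate
disease genes.  They are realized as single-input identity taps off the
chains they serve, with no outgoing functional edges.  This makes a precise
property hold by construction (and the suite verifies it dynamically):
deleting any of them leaves the trajectories of the other 32 nodes
unchanged in every scenario.  An in-line realization would contradict that
null effect, since clamping an in-line relay to 0 severs its chain.  Result
plots and trajectory exports show only the 32 non-relay nodes.

## Scenarios and attractors

Four runs permute the two binary environment switches, with every other
node initially active and TRP clamped on throughout:

| scenario        | stress | SSRI | transient | attractor period |
|-----------------|--------|------|-----------|------------------|
| basal           | off    | off  | 8         | 6                |
| antidepressant  | off    | on   | 11        | 1                |
| chronic stress  | on     | off  | 5         | 42               |
| complete        | on     | on   | 11        | 7                |

(The table restates what `serohpa attractor` computes at run time.)

The dynamics decompose into two oscillators.  Under sustained stress the
HPA negative-feedback loops (PVN- and pituitary-level) produce a period-7
cortisol rhythm.  On the serotonin side, the autoreceptor→hyperpolarization
→CREB→BDNF→TRkB circuit forms a six-node ring whose rotation has period 6;
in the basal attractor this ring keeps the serotonin synthesis/transport
flux (TPH2, 5-HTP, 5-HT*, vesicle, release, 5-HTT) shut off while the
trapped synaptic 5-HT keeps the autoreceptor engaged — the "depressed"
regime.  SSRI breaks the ring open (it blocks both the transporter and the
autoreceptor), so the antidepressant scenario relaxes to a fixed point with
synthesis, transport and degradation all active.  The chronic-stress
attractor superposes the two oscillators, lcm(6, 7) = 42 steps long —
strictly and substantially longer than the basal cycle — and the complete
scenario collapses it back to the bare period-7 HPA rhythm: the drug
regularizes the stressed pattern without restoring the basal one.

**On the length of the chronic-stress cycle.**  The published pathway
description this network is transcribed from characterizes the stressed
regime as an extended cyclic pattern spanning 57 discrete steps, but does
not print the underlying wiring diagram as an edge list, so the exact rule
set had to be reconstructed from prose.  We swept every wiring reading we
could defend (operator grouping at TPH2; whether the BDNF-pathway blockade
enters at cAMP, PKA, CREB or BDNF, and whether it originates at the
autoreceptor, the K⁺ channel or the K⁺ efflux; TRkB- versus CREB-driven
phenotype genes; presence of hyperpolarization edges onto the transporter,
vesicle and release steps; 5-HT persistence; PVN-only versus dual-level HPA
feedback; kinase cascade in-line versus ubiquitous).  Across ~25,000
variants the chronic attractor length is always lcm(r, h) with ring period
r ≤ 6 and HPA period h ∈ {7, 8}: rings longer than six nodes produce
unbalanced activity patterns that trip the transporter and collapse, so the
attainable lengths are {7, 8, 21, 24, 28, 35, 40, 42} and 57 is not
reachable by any variant that also preserves the four scenario behaviors.
The shipped model uses the variant with the longest chronic cycle (42) that
satisfies all of them; `scripts/acceptance.py` reports this computed value,
and the qualitative claim — a much longer attractor under chronic stress —
holds regardless of the discrepancy.

## Knockout stability analysis

For each knockout unit the mutated network (unit clamped to 0) and the
wild type are simulated **in parallel from the same random initial state**
for T = 100 steps, and the normalized Hamming distance (fraction of the 41
positions at which the two states differ) is recorded at every step.  Over
n_runs = 1000 random initial states this gives a mean divergence profile;
the mean distance at t = 100 is the unit's impact score.  Conventions:

* SSRI is fixed to 0 in both networks — it is an intervention, not a
  biological component — so initial states are uniform over the 2^40
  remaining states.  The other clamped inputs (stress, TRP) are randomized
  like any bit and then held at their drawn value, since nothing
  down-regulates them (`reconstructed` choice).
* The mutant's knocked-out bits are forced to 0 in its initial state; the
  wild type keeps the drawn bits, so divergence can begin at t = 0 on the
  knocked-out positions only.  Both initial-state batches are hashed after
  masking those positions and the hashes are asserted equal on every call.
* Distances are computed over all 41 positions, SSRI included (identically
  zero in both networks).

The roster holds 23 units: the four GR/MR receptor nodes act as a single
unit (one receptor class expressed in four compartments), and the clamped
environmental inputs are not knockout candidates — which is why TRP, listed
among the pathway's genes and metabolites, is excluded along with stress
and SSRI.  That leaves 22 single-node units plus the GR/MR group.

The uncertainty attached to each impact score is the bootstrap standard
error of the mean ("mean deviation error"): the 1000 final-step distances
are resampled with replacement n_boot = 1000 times and the standard
deviation of the resample means is reported.  No distributional form is
assumed.  Samples are sorted before resampling, making the estimate
invariant under permutation of run order at a fixed seed; exactly constant
samples short-circuit to an error of 0.  Randomness flows from one master
seed through `numpy` `SeedSequence` substreams keyed by each unit's fixed
roster position, so units can be evaluated in any order, or alone, with
bit-identical results.

With the shipped model the three neurotrophin-loop units (CREB, BDNF,
TRkB) dominate the ranking by a wide margin — knocking any of them out
locks the serotonergic phenotype off in the mutant while the wild type
keeps oscillating — followed by the serotonin-handling tier headed by the
transporter; HPA-axis units rank in the middle and the terminal
postsynaptic nodes at the bottom.  The top-3 set is stable across seeds
and already resolved at a few hundred runs.

## Synthetic networks

`fixtures.random_network` builds classic N-K random Boolean networks:
every node receives K distinct uniformly chosen inputs (self-inputs
allowed) and an i.i.d. Bernoulli(bias) truth table, seeded.  These are
statistical stand-ins used to exercise the engine — attractor bookkeeping
is checked against an oracle that tabulates the entire 2^N transition
graph — and share nothing with the biology: they have no clamped inputs,
no modular structure, and homogeneous in-degree, so passing them validates
the simulator, not the model.  `fixtures.toy_paper_motif` is a six-node
abridgment of the model (stress→CRH→ACTH→cortisol ⊣ TPH2 ⇄ 5-HT) whose
trajectories are verified by hand in the suite.

## Numerical choices

* Attractor detection is a hash map from visited state to first-seen time;
  transient and period are exact.  The default search budget is 10,000
  update steps; exhaustion returns an explicit not-found value rather than
  raising, since a low budget is a legitimate probe.
* Per-node truth tables are stored at their exact length 2^k; the 2^4 × 41
  padded rules-matrix export replicates each table over the ignored
  high-order input slots.
* The ranking sort is stable (mergesort), so ties preserve roster order.
* Batch simulation advances an (n_runs, 41) bit matrix one node-column at
  a time; 23 units × 2 networks × 100 steps at 1000 runs completes in a
  few seconds on one core.

## Limitations

Boolean dynamics are concentration-independent: receptor desensitization
by sustained high synaptic serotonin, dose effects, and kinetic time
scales are outside the model class, and one discrete step has no fixed
physical duration.  The wiring is a prose-derived reconstruction — the
`reconstructed` tags mark each under-determined edge — and neural
plasticity and neurogenesis are deliberately not modeled.  Knockouts are
clamp-to-0 only; knock-ins and double knockouts are out of scope.
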