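# Methods

## Scope and model

`canmap` analyses *canalization* — redundancy in the transition logic of
Boolean automata — and uses it to characterize control of collective dynamics
in Boolean networks.  The pipeline has four layers:

1. **Micro level.** Each automaton's look-up table (LUT) is redescribed as
   wildcard schemata (all prime implicants of each transition) and then as
   two-symbol schemata that additionally mark symmetric (permutable) input
   groups.
2. **Compilation.** The schemata are compiled into Canalizing Maps —
   McCulloch–Pitts-style threshold networks with fused fibre endings — and
   integrated into a network-wide Dynamics Canalization Map (DCM) whose size
   grows linearly with the number of nodes.
3. **Macro level.** The DCM supports three-valued (0/1/unknown) *dynamical
   unfolding*, which certifies state transitions that hold for *every*
   completion of a partial configuration.  A stochastic search over the DCM
   finds *minimal configurations* (MCs): partial configurations that
   guarantee convergence to a target attractor and cannot be relaxed further.
4. **Control.** MC sets quantify macro-level canalization (node redundancy,
   effective control, node symmetry), assign each literal enput a *power*
   (the fraction of covered configurations whose covering MCs require it),
   and a noisy-pinning protocol measures robustness of attractor convergence
   when an enput is stochastically disrupted.

The worked model is the Boolean segment polarity network (SPN) of Drosophila
body segmentation: 15 intra-cellular species (sloppy-paired, wingless,
engrailed, hedgehog, patched, cubitus interruptus, and their products) in a
four-cell parasegment with periodic boundaries.  We implement the fully
synchronous form of the model: the originally instantaneous PH and SMO
updates are folded into the CIA/CIR rules, which provably leaves the
dynamics unchanged, and PH/SMO themselves update at t+1 as ordinary output
nodes.

## Conventions and key algorithmic choices

* **LUT row order.** Row index ν encodes the input condition with input 1 as
  the most significant bit.  This is asserted in the tests; no analysis
  depends on the row order itself.
* **Prime implicants.** Quine–McCluskey merge-and-subsume, returning *all*
  prime implicants (not an essential cover) — the complete, minimal, unique
  redescription of each transition.  Above k = 12 an iterated-consensus
  construction with explicit absorption provides the same output contract.
  An independent brute-force cube oracle (enumerate all 3^k cubes, keep
  sound ones, drop subsumed ones) backs the tests.
* **Two-symbol search.** Wildcard schemata are partitioned into classes by
  their (n0, n1, n#) symbol counts; candidate symmetric groups are tried
  from the largest variable subsets downwards and verified by exhaustive
  arrangement membership, so expansion validity always holds.  Groups must
  have at least two of (n0, n1, n#) positive, which excludes trivial
  all-same-state groups.  When the arrangement-check budget is exhausted the
  result carries `maximality_certified=False` rather than being silently
  truncated.
* **Thresholds (CM).** A literal enput contributes one single-fibre ending
  (τ += 1).  A group subconstraint "at least m of g members in state s"
  contributes one fused ending per subset of size g−m+1 of the same-state
  s-units (τ += C(g, g−m+1)); by pigeonhole all endings pulse exactly when at
  least m members fire.  The printed construction is validated by exhaustive
  firing equivalence against the schema semantics.  Endings are materialized
  for g ≤ 12; larger groups use an equivalent counting gate with the same
  observable contract.  τ = 1 t-units driving the same transition are merged
  (endings de-fused), and only that merge is applied — no further logic
  factoring.
* **Constant nodes** are represented as always-firing source t-units (τ = 0,
  no inputs); the behaviour of k = 0 automata is otherwise unspecified by
  the construction.
* **Unfolding semantics.** A node takes state s at t+1 iff some t-unit for
  (node, s) is certainly satisfied — every constraint met counting known
  states only; unknown members never count toward satisfaction.  A node
  whose next state is not certified becomes unknown even if currently known
  (synchronous soundness forces this decay); pinned nodes are exempt.
  Stability is exact repetition of the three-valued vector; the default step
  budget is 4N, and exhaustion yields a distinguished "undecided" result.
* **Convergence certification.** The default criterion requires the stable
  outcome to determine and match every node the target specifies.  A weaker
  catalog mode additionally accepts a stable outcome whose determined nodes
  are consistent with exactly one pattern of a supplied stable-pattern
  catalog; it is valid when the catalog exhaustively lists the reachable
  stable patterns and is used for the single-cell analysis, where three of
  the eight input regimes resolve only a subset of nodes yet pin down the
  final pattern uniquely.
* **MC minimization.** Nodes are raised to unknown in a uniformly random
  order (one pass per permutation, repeated until a fruitless sweep).
  Because certified information is monotone in the initial knowledge, a
  failed raise can never succeed later, so each sweep ends in a true MC and
  per-literal minimality holds by construction; the invariants are
  nevertheless re-verified in the tests.  The two-step set search uses
  tolerances t_reuse = 500 (consecutive fruitless re-minimizations of one
  seed) and t_new = 1000 (consecutive fresh seeds already covered), both
  counters resetting whenever a new MC appears.  Duplicate conditions are
  removed; subsumed MCs are retained, mirroring the all-prime-implicants
  philosophy (an optional filter can drop them).
* **Two-symbol MCs.** Candidate groups over the 60-node condition vectors
  are seeded by transpositions between MCs in the set, grown greedily and
  verified by arrangement membership; only schemata redescribing at least
  η = 8 wildcard MCs are reported, matching the published search constraint.
* **Coverage counting.** Exact union cardinality uses the
  inclusion–exclusion principle over the MCs' cube expansions with
  incompatibility pruning, capped by default at 24 MCs; beyond the cap,
  certified bounds (max single coverage, sum of coverages) are returned.
* **Sampling estimators.** Configurations are sampled by roulette wheel over
  MC coverages with uniform wildcard and group fill-ins, exactly as the
  estimation protocol specifies.  Because this draws a configuration with
  probability proportional to the number of MCs covering it, the macro
  measures and power estimates weight each draw by the reciprocal of its
  cover count, making them unbiased for the uniform covered-set measure;
  exhaustive and sampled estimates then agree on small instances.
  Confidence intervals are normal-approximation 95% bands over 10
  independent repeat means by default.
* **Disruption protocol.** Per step of the noise window (T = 100 by
  default), the disrupted node is set to reference XOR flip with flip
  probability p ("noisy pinning"); the flipped state is read by the other
  nodes at the same step.  After the window the network runs freely to an
  attractor.  The alternative "toggle current state" mode is available as a
  flag.  Power categories: full = 1, null = 0, high ≥ 0.5, low otherwise
  (configurable).

## Segment-polarity reference catalog

The wild-type initial configuration (pair-rule SLP pre-pattern off/off/on/on;
wingless in the posterior cell; engrailed and hedgehog in the anterior cell;
patched and cubitus interruptus in all but the anterior cell; no proteins) is
transcribed from the underlying Boolean model.  Everything else in the
catalog is *derived* at load time by the package's own operations and
verified on construction: the five stable per-cell patterns come from
exhaustive fixed-point enumeration over the eight steady input combinations,
the ten parasegment attractors from fixed-point-consistent composition of
per-cell patterns over the 4-cell ring (5^4 candidates), and the wild-type
attractor from the 7-configuration trajectory.  Any transcription error in
the rules would break these verification contracts immediately.  The P1–P5
labels order the patterns as: quiescent repressor pattern (P1), quiescent
activator pattern (P2), engrailed/hedgehog with PTC off (P3) and with PTC on
(P4, seen only in mutants), and the wingless pattern (P5); the wild-type
cell sequence is P3, P2, P1, P5.

## Synthetic data

Random NK-style networks (inputs drawn without replacement, LUT bits
Bernoulli with configurable bias) provide the test fixtures for the
property-based checks: prime-implicant oracle equivalence, unfolding
soundness over exhaustive completions, and MC validity by exact simulation.
They emulate the combinatorial structure of regulatory rules but none of the
biological features of real models (degree heterogeneity, composition of
canalizing functions, spatial coupling), so passing these properties shows
correctness of the algorithms, not biological adequacy of any particular
model.

## Problem sizes used in the shipped analyses

The packaged analyses are desk-scale: exhaustive enumerations cover the
single-cell model (2^14 free states per input regime) and the pattern
composition (5^4 candidates); the stochastic reproduction is the
trajectory-seeded wild-type MC search (7 seeds, t_reuse = 500, about 75k
three-valued unfoldings).  The full two-step basin-wide search (t_new = 1000
with random fresh seeds over 2^56 configurations) that yields thousands of
MCs is exposed through `canmap find-mcs` but is a long-running computation
by design; its published counts depend on unprinted tolerance values and are
treated as order-of-magnitude targets.

## Known limitations

* Group-invariant enputs' power and disruption are not analysed (the source
  analyses defer both); only literal enputs get power values.
* Upper-bound measures drive all reported analyses; lower bounds are
  computed and tested but not used downstream.
* The symmetry search for very large schema classes is heuristic above its
  budget (flagged, never silently wrong); arrangement verification keeps
  validity exact in all cases.
* Asynchronous update schemes and multi-valued automata are out of scope.
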