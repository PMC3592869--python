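# canmap

Canalization analysis and control of Boolean automata networks via schema
redescription and threshold-network canalizing maps.

Boolean networks are the workhorse qualitative models of gene regulation and
signalling.  Their automata are usually highly *canalizing*: only a subset of
each node's input states actually determines its transition.  `canmap` makes
that redundancy explicit and exploits it, end to end:

* **Schema redescription (micro level).**  Each automaton's look-up table is
  redescribed as *wildcard schemata* — the set of all prime implicants of each
  transition, with `#` marking irrelevant inputs — and further into
  *two-symbol schemata* whose position-free symbol marks symmetric input
  groups (inputs that can permute without changing the transition).  From
  these, canalization is quantified per automaton: input redundancy
  k_r (mean number of irrelevant inputs over LUT entries), effective
  connectivity k_e = k − k_r, and input symmetry k_s (mean number of
  permutable inputs).
* **Canalizing maps.**  Schemata compile into McCulloch–Pitts-style threshold
  networks: s-units carry node states, one t-unit executes each schema, and
  fused fibre endings implement "at least m of g" group constraints with
  threshold contributions C(g, g−m+1).  Integrating all node maps gives the
  **Dynamics Canalization Map (DCM)** — the executable control logic of the
  whole network, with size linear in the number of nodes.
* **Dynamical unfolding and control (macro level).**  The DCM runs on
  three-valued states (0/1/unknown), propagating only transitions certain for
  *every* completion of a partial configuration.  A stochastic search finds
  **minimal configurations (MCs)**: fewest node states that guarantee
  convergence to a target attractor.  MC sets yield macro-level canalization
  measures (node redundancy n_r, effective control n_e = N − n_r, node
  symmetry n_s), *enput power* (how critical each node state is across the
  covered basin), and robustness curves under stochastic disruption of
  critical node states.

The packaged worked model is the Boolean segment polarity network of
*Drosophila* body segmentation (wingless, engrailed, hedgehog, patched,
cubitus interruptus and their products; 15 species per cell, four coupled
cells with periodic boundaries), in its fully synchronous form.

## Worked example

Redescribe the wingless gene's transition logic in a single cell:

```python
from canmap import build_spn, prime_implicants, two_symbol_redescribe, \
    canalization_measures

net = build_spn("single_cell_merged_inputs")
wg = net.node("wg")
print([net.nodes[i].name for i in wg.inputs])
for t in (0, 1):
    for s in sorted(two_symbol_redescribe(prime_implicants(wg, t)), key=str):
        print(f"  transition {t}: {s}")
m = canalization_measures(wg)
print(f"k={m.k} kr={m.kr_upper} ke={m.ke} ks={m.ks_upper} "
      f"class={m.canalization_class}")
```

prints

```
['CIA', 'SLP', 'CIR', 'wg']
  transition 0: #### g(0,1,3;n0=2,n1=0)
  transition 0: ##1#
  transition 1: ##0# g(0,1,3;n0=0,n1=2)
k=4 kr=2.25 ke=1.75 ks=2.25 class=A
```

Reading: wingless is expressed iff the repressor CIR is off **and** at least
two of {CIA, SLP, wg} are on (a symmetric group — the three activators are
functionally equivalent); it is inhibited iff CIR is on **or** at least two of
them are off.  Although wg has four inputs, on average only 1.75 are needed to
decide its transition and 2.25 can permute freely — strong canalization of
both kinds (class A).

The same surface drives the network-level analyses, e.g. the two minimal
conditions that force a cell into the quiescent attractor pattern (hedgehog
signals absent plus either SLP on or neighbour wingless off), found by
`search_mc_set` on the single-cell DCM.

A CLI mirrors the library: `canmap net|redescribe|dcm|unfold|find-mcs|power|
perturb|spn` (see `canmap --help`).

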