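"""Canalizing Maps: threshold-network compilation of schemata.

A Canalizing Map (CM) executes a two-symbol schema with a single threshold
unit (t-unit) and a one-step delay.  *State units* (s-units) represent an
automaton in a specific Boolean state — at most two per automaton, which
never fire together.  Fibres run from s-units to t-units; fibres from
distinct s-units may *fuse* into a single ending, which carries one pulse
when at least one of its sources fires.  A t-unit fires when at least tau of
its endings carry pulses.

Wiring of one schema: each literal enput contributes a single-fibre ending
(tau += 1); each group-invariant subconstraint "at least m of the group's g
members in state s" contributes one fused ending per subset of size
g - m + 1 of the corresponding s-units (tau += C(g, g-m+1)) — by pigeonhole,
all those endings pulse exactly when at least m members fire.  Endings are
materialized explicitly for g <= FUSE_CAP; above that an equivalent counting
gate (fires iff >= m same-state members fire) backs the same observable
contract.

The node CM combines the t-units of both transitions; t-units with tau = 1
driving the same transition are merged into a single tau = 1 t-unit (their
endings de-fused into single fibres).  The Dynamics Canalization Map (DCM)
integrates all node CMs over one shared pair of s-units per automaton, so its
size grows linearly with the network.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .network import BooleanNetwork, BooleanNode
from .schemata import (
    TwoSymbolSchema,
    prime_implicants,
    two_symbol_redescribe,
)

__all__ = [
    "SUnit",
    "Ending",
    "Constraint",
    "TUnit",
    "ThresholdNetwork",
    "schema_to_cm",
    "build_node_cm",
    "build_dcm",
    "dcm_to_graphml",
    "dcm_to_json",
    "dcm_from_json",
]

FUSE_CAP = 12  # materialize C(g, g-m+1) endings only up to this group size


@dataclass(frozen=True)
class SUnit:
    node: int
    state: int


@dataclass(frozen=True)
class Ending:
    """A (possibly fused) fibre ending; pulses when any source fires."""

    sources: tuple[SUnit, ...]


@dataclass(frozen=True)
class Constraint:
    """At least ``m`` of ``units`` firing; the semantic form of a t-unit's
    incoming wiring (literal endings, group subconstraints, merged units)."""

    units: tuple[SUnit, ...]
    m: int


@dataclass
class TUnit:
    id: int
    tau: int
    output: SUnit
    constraints: tuple[Constraint, ...]
    endings: tuple[Ending, ...] | None  # None above FUSE_CAP (counting gate)
    materialized: bool = True

    def fires(self, states) -> bool:
        """Closed-world firing on complete states (list/array of 0/1)."""
        return all(
            sum(states[u.node] == u.state for u in c.units) >= c.m
            for c in self.constraints
        )

    def fires_by_endings(self, states) -> bool:
        """Firing evaluated through the fibre endings and tau (used to verify
        the pigeonhole construction)."""
        if self.endings is None:
            raise ValueError("endings not materialized for this t-unit")
        pulses = sum(
            any(states[u.node] == u.state for u in e.sources)
            for e in self.endings
        )
        return pulses >= self.tau


class ThresholdNetwork:
    """A CM (one schema or one node) or DCM (whole network)."""

    def __init__(self, n_nodes: int, tunits: list[TUnit], scope: str):
        self.n_nodes = n_nodes
        self.tunits = list(tunits)
        self.scope = scope
        self._compiled = None

    @property
    def sunits(self) -> set[SUnit]:
        out = set()
        for t in self.tunits:
            out.add(t.output)
            for c in t.constraints:
                out.update(c.units)
        return out

    def stats(self) -> dict:
        return {
            "scope": self.scope,
            "n_nodes": self.n_nodes,
            "n_tunits": len(self.tunits),
            "n_sunits": len(self.sunits),
            "n_endings": sum(
                len(t.endings) for t in self.tunits if t.endings is not None
            ),
        }

    # -- closed-world simulation -------------------------------------------

    def step_complete(self, states) -> np.ndarray:
        """One synchronous step on complete states; every node must be driven
        to exactly one state (checked)."""
        states = np.asarray(states, dtype=np.uint8)
        nxt = np.full(self.n_nodes, 255, dtype=np.uint8)
        for t in self.tunits:
            if t.fires(states):
                prev = nxt[t.output.node]
                if prev not in (255, t.output.state):
                    raise AssertionError(
                        f"contradiction: node {t.output.node} driven to both states"
                    )
                nxt[t.output.node] = t.output.state
        driven = {t.output.node for t in self.tunits}
        for i in driven:
            if nxt[i] == 255:
                raise AssertionError(f"node {i} not driven by any t-unit")
        for i in range(self.n_nodes):
            if i not in driven:
                nxt[i] = states[i]  # undriven (pure input) nodes hold state
        return nxt

    # -- compiled form for three-valued unfolding ---------------------------

    def compiled(self):
        """(A, m, row_tunit, nrows_per_tunit, out_index): constraint-count
        matrix over the 2N s-unit space plus bookkeeping arrays."""
        if self._compiled is None:
            rows = []
            mvec = []
            row_tunit = []
            for ti, t in enumerate(self.tunits):
                for c in t.constraints:
                    row = np.zeros(2 * self.n_nodes, dtype=np.int32)
                    for u in c.units:
                        row[2 * u.node + u.state] = 1
                    rows.append(row)
                    mvec.append(c.m)
                    row_tunit.append(ti)
            A = (
                np.array(rows, dtype=np.int32)
                if rows
                else np.zeros((0, 2 * self.n_nodes), dtype=np.int32)
            )
            nrows = np.bincount(
                np.array(row_tunit, dtype=np.intp),
                minlength=len(self.tunits),
            )
            out_index = np.array(
                [2 * t.output.node + t.output.state for t in self.tunits],
                dtype=np.intp,
            )
            self._compiled = (
                A,
                np.array(mvec, dtype=np.int32),
                np.array(row_tunit, dtype=np.intp),
                nrows,
                out_index,
            )
        return self._compiled


def _group_constraints(
    schema: TwoSymbolSchema, inputs: tuple[int, ...]
) -> tuple[list[Constraint], list[Ending] | None, int]:
    """Constraints, endings and tau for one schema (Eq.-9 style threshold)."""
    constraints: list[Constraint] = []
    endings: list[Ending] | None = []
    tau = 0
    for p, s in schema.literal:
        u = SUnit(inputs[p], s)
        constraints.append(Constraint((u,), 1))
        if endings is not None:
            endings.append(Ending((u,)))
        tau += 1
    for g in schema.groups:
        members = sorted(g.members)
        size = len(members)
        for s, m in ((0, g.n0), (1, g.n1)):
            if m <= 0:
                continue
            units = tuple(SUnit(inputs[p], s) for p in members)
            constraints.append(Constraint(units, m))
            tau += comb(size, size - m + 1)
            if endings is None:
                continue
            if size <= FUSE_CAP:
                for subset in itertools.combinations(units, size - m + 1):
                    endings.append(Ending(tuple(subset)))
            else:
                endings = None  # counting gate backs the contract instead
    return constraints, endings, tau


def schema_to_cm(
    schema: TwoSymbolSchema,
    inputs: tuple[int, ...] | None = None,
    output: SUnit | None = None,
    n_nodes: int | None = None,
) -> ThresholdNetwork:
    """CM of a single (nonempty) schema.

    Default wiring uses node ids 0..k-1 for the inputs and id k for the
    automaton itself.
    """
    if not schema.literal and not schema.groups:
        raise ValueError("schema has no enputs")
    if inputs is None:
        inputs = tuple(range(schema.k))
    if output is None:
        output = SUnit(schema.k, schema.transition)
    if n_nodes is None:
        n_nodes = max(list(inputs) + [output.node]) + 1
    constraints, endings, tau = _group_constraints(schema, inputs)
    t = TUnit(
        0,
        tau,
        output,
        tuple(constraints),
        tuple(endings) if endings is not None else None,
        materialized=endings is not None,
    )
    return ThresholdNetwork(n_nodes, [t], "schema")


def _node_tunits(
    node: BooleanNode,
    inputs: tuple[int, ...],
    node_id: int,
    next_id: int,
) -> tuple[list[TUnit], int]:
    """T-units of one automaton's CM (both transitions, tau=1 merge rule)."""
    if node.constant_flag:
        state = int(node.lut[0]) if node.k >= 0 else 0
        t = TUnit(next_id, 0, SUnit(node_id, state), (), (), True)
        return [t], next_id + 1
    tunits: list[TUnit] = []
    for transition in (0, 1):
        schemata = sorted(
            two_symbol_redescribe(prime_implicants(node, transition)),
            key=str,
        )
        plain: list[tuple] = []  # (constraints, endings, tau) with tau == 1
        for sch in schemata:
            constraints, endings, tau = _group_constraints(sch, inputs)
            if tau == 1:
                plain.append((constraints, endings))
            else:
                tunits.append(
                    TUnit(
                        next_id,
                        tau,
                        SUnit(node_id, transition),
                        tuple(constraints),
                        tuple(endings) if endings is not None else None,
                        endings is not None,
                    )
                )
                next_id += 1
        if plain:
            # merge all tau=1 units for this transition; de-fuse endings
            units: list[SUnit] = []
            for constraints, _ in plain:
                for c in constraints:
                    units.extend(u for u in c.units if u not in units)
            merged = Constraint(tuple(units), 1)
            endings = tuple(Ending((u,)) for u in units)
            tunits.append(
                TUnit(
                    next_id, 1, SUnit(node_id, transition), (merged,), endings
                )
            )
            next_id += 1
    return tunits, next_id


def build_node_cm(node: BooleanNode, net: BooleanNetwork | None = None) -> ThresholdNetwork:
    """CM of one automaton over its local input wiring (ids 0..k-1, node=k)
    or, when a network is given, over the global node ids."""
    if net is None:
        inputs = tuple(range(node.k))
        node_id = node.k
        n_nodes = node.k + 1
    else:
        inputs = node.inputs
        node_id = node.id
        n_nodes = net.n
    tunits, _ = _node_tunits(node, inputs, node_id, 0)
    return ThresholdNetwork(n_nodes, tunits, "node")


def build_dcm(net: BooleanNetwork) -> ThresholdNetwork:
    """Dynamics Canalization Map: all node CMs over shared global s-units."""
    tunits: list[TUnit] = []
    next_id = 0
    for node in net.nodes:
        ts, next_id = _node_tunits(node, node.inputs, node.id, next_id)
        tunits.extend(ts)
    return ThresholdNetwork(net.n, tunits, "network")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def dcm_to_graphml(tn: ThresholdNetwork, names: list[str] | None = None):
    """networkx graph of s-units, t-units and typed ending edges."""
    import networkx as nx

    g = nx.MultiDiGraph()
    label = (lambda i: names[i]) if names else (lambda i: str(i))
    for u in sorted(tn.sunits, key=lambda u: (u.node, u.state)):
        g.add_node(f"s:{label(u.node)}={u.state}", kind="s-unit",
                   node=int(u.node), state=int(u.state))
    for t in tn.tunits:
        tid = f"t:{t.id}"
        g.add_node(tid, kind="t-unit", tau=int(t.tau),
                   materialized=bool(t.materialized))
        g.add_edge(
            tid, f"s:{label(t.output.node)}={t.output.state}", kind="output"
        )
        if t.endings is not None:
            for ei, e in enumerate(t.endings):
                for u in e.sources:
                    g.add_edge(
                        f"s:{label(u.node)}={u.state}", tid,
                        kind="ending", ending=ei, fused=len(e.sources) > 1,
                    )
        else:
            for ci, c in enumerate(t.constraints):
                for u in c.units:
                    g.add_edge(
                        f"s:{label(u.node)}={u.state}", tid,
                        kind="counting", constraint=ci, m=int(c.m),
                    )
    return g


def dcm_to_json(tn: ThresholdNetwork) -> str:
    obj = {
        "scope": tn.scope,
        "n_nodes": tn.n_nodes,
        "tunits": [
            {
                "id": t.id,
                "tau": t.tau,
                "output": [t.output.node, t.output.state],
                "constraints": [
                    {"units": [[u.node, u.state] for u in c.units], "m": c.m}
                    for c in t.constraints
                ],
                "endings": None
                if t.endings is None
                else [
                    [[u.node, u.state] for u in e.sources] for e in t.endings
                ],
            }
            for t in tn.tunits
        ],
    }
    return json.dumps(obj, indent=1)


def dcm_from_json(text: str) -> ThresholdNetwork:
    obj = json.loads(text)
    tunits = []
    for t in obj["tunits"]:
        endings = (
            None
            if t["endings"] is None
            else tuple(
                Ending(tuple(SUnit(n, s) for n, s in e)) for e in t["endings"]
            )
        )
        tunits.append(
            TUnit(
                t["id"],
                t["tau"],
                SUnit(*t["output"]),
                tuple(
                    Constraint(
                        tuple(SUnit(n, s) for n, s in c["units"]), c["m"]
                    )
                    for c in t["constraints"]
                ),
                endings,
                endings is not None,
            )
        )
    return ThresholdNetwork(obj["n_nodes"], tunits, obj["scope"])
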