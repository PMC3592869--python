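"""Three-valued dynamical unfolding of a Dynamics Canalization Map.

A *partial configuration* assigns each node 0, 1 or unknown (#).  Unfolding
propagates only transitions that are *certain*: node v takes state s at t+1
iff some t-unit for (v, s) is certainly satisfied at t, i.e. every constraint
"at least m of these s-units firing" is met counting known states only
(unknown members never count).  A node whose next state is not certified
becomes unknown — synchronous semantics demand this decay — except pinned
nodes, which sustain their state.  Consequently every determined value agrees
with the plain synchronous trajectory of *every* completion of the initial
partial configuration (soundness), at the price of conservatism.

Convergence certification supports two criteria:

* ``full`` — the unfolding reaches a three-valued fixed point whose
  determined nodes cover and match every node specified in the target;
* ``unique_match`` — the stable outcome is additionally accepted when its
  determined nodes are consistent with exactly one pattern of a supplied
  catalog of stable patterns, and that pattern is the target.  This weaker
  criterion is valid when the catalog exhaustively lists the reachable stable
  patterns (e.g. the five per-cell segment-polarity patterns).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .cm import ThresholdNetwork

__all__ = [
    "UNKNOWN",
    "PartialConfiguration",
    "UnfoldingTrace",
    "PatternCatalog",
    "Tri",
    "unfold",
    "guarantees_convergence",
    "PathwayModule",
    "extract_pathway_module",
    "partial_from_string",
    "partial_to_string",
]

UNKNOWN = 2


class Tri(enum.Enum):
    """Three-valued certification result; only YES is truthy."""

    YES = "yes"
    NO = "no"
    UNDECIDED = "undecided"

    def __bool__(self) -> bool:
        return self is Tri.YES


@dataclass
class PartialConfiguration:
    """States over {0, 1, UNKNOWN}; pinned nodes sustain their known state."""

    states: np.ndarray
    pinned: frozenset[int] = frozenset()

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.uint8)
        self.pinned = frozenset(self.pinned)
        for i in self.pinned:
            if self.states[i] == UNKNOWN:
                raise ValueError(f"pinned node {i} is unknown")

    @property
    def n(self) -> int:
        return self.states.size

    def specified(self) -> list[int]:
        return [i for i in range(self.n) if self.states[i] != UNKNOWN]


def partial_from_string(s: str, pinned=()) -> PartialConfiguration:
    table = {"0": 0, "1": 1, "#": UNKNOWN}
    return PartialConfiguration(
        np.array([table[c] for c in s], dtype=np.uint8), frozenset(pinned)
    )


def partial_to_string(states: np.ndarray) -> str:
    return "".join("01#"[int(x)] for x in states)


@dataclass
class UnfoldingTrace:
    steps: list[np.ndarray]
    status: str  # stable | cycle | budget
    outcome: np.ndarray  # terminal partial configuration

    def determined(self) -> dict[int, int]:
        return {
            i: int(s) for i, s in enumerate(self.outcome) if s != UNKNOWN
        }


def _step3(dcm: ThresholdNetwork, states: np.ndarray, pinned) -> np.ndarray:
    A, mvec, row_tunit, nrows, out_index = dcm.compiled()
    n = dcm.n_nodes
    firing = np.zeros(2 * n, dtype=np.int32)
    known = states != UNKNOWN
    idx = 2 * np.arange(n)[known] + states[known]
    firing[idx] = 1
    if A.shape[0]:
        sat = (A @ firing) >= mvec
        ok = (
            np.bincount(row_tunit, weights=sat, minlength=len(dcm.tunits))
            == nrows
        )
    else:
        ok = nrows == 0
    certain = np.zeros(2 * n, dtype=bool)
    np.logical_or.at(certain, out_index, ok)
    both = certain[0::2] & certain[1::2]
    if np.any(both):
        bad = int(np.where(both)[0][0])
        raise AssertionError(
            f"node {bad} certified for both transitions (schema defect)"
        )
    nxt = np.full(n, UNKNOWN, dtype=np.uint8)
    nxt[certain[0::2]] = 0
    nxt[certain[1::2]] = 1
    for i in pinned:
        nxt[i] = states[i]
    return nxt


def unfold(
    dcm: ThresholdNetwork,
    init: PartialConfiguration,
    max_steps: int | None = None,
) -> UnfoldingTrace:
    """Unfold until the three-valued state repeats (period 1 = stable,
    longer = cycle) or the step budget runs out."""
    if max_steps is None:
        max_steps = 4 * dcm.n_nodes
    s = init.states.copy()
    steps = [s]
    seen = {s.tobytes(): 0}
    for t in range(1, max_steps + 1):
        s = _step3(dcm, s, init.pinned)
        key = s.tobytes()
        if key in seen:
            status = "stable" if seen[key] == t - 1 else "cycle"
            return UnfoldingTrace(steps, status, s)
        seen[key] = t
        steps.append(s)
    return UnfoldingTrace(steps, "budget", s)


@dataclass
class PatternCatalog:
    """Stable patterns over a node subset, for unique-match certification."""

    node_ids: tuple[int, ...]
    patterns: list[tuple[int, ...]]

    def consistent(self, outcome: np.ndarray) -> list[int]:
        """Indices of patterns consistent with the outcome's determined
        nodes."""
        hits = []
        for pi, p in enumerate(self.patterns):
            ok = True
            for i, v in zip(self.node_ids, p):
                if outcome[i] != UNKNOWN and int(outcome[i]) != v:
                    ok = False
                    break
            if ok:
                hits.append(pi)
        return hits


def guarantees_convergence(
    dcm: ThresholdNetwork,
    init: PartialConfiguration,
    target: PartialConfiguration | np.ndarray,
    max_steps: int | None = None,
    catalog: PatternCatalog | None = None,
    target_pattern: int | None = None,
) -> Tri:
    """Certify that every completion of ``init`` converges to ``target``.

    With a catalog, certification additionally succeeds when the stable
    outcome uniquely matches catalog pattern ``target_pattern``.
    Budget exhaustion yields UNDECIDED, never a silent NO.
    """
    tstates = (
        target.states if isinstance(target, PartialConfiguration) else target
    )
    specified = [i for i in range(len(tstates)) if tstates[i] != UNKNOWN]
    if not specified:
        raise ValueError("target specifies no nodes")
    trace = unfold(dcm, init, max_steps)
    if trace.status == "budget":
        return Tri.UNDECIDED
    if trace.status != "stable":
        return Tri.NO
    out = trace.outcome
    if all(out[i] == tstates[i] for i in specified):
        return Tri.YES
    if catalog is not None and target_pattern is not None:
        hits = catalog.consistent(out)
        if hits == [target_pattern]:
            return Tri.YES
    return Tri.NO


@dataclass
class PathwayModule:
    """A cascade of certain transitions triggered by a small signal set,
    independent of all other node states."""

    signals: tuple[tuple[int, int, bool], ...]  # (node, state, sustained)
    schedule: tuple[tuple[int, int, int], ...]  # (time, node, state)
    trace: UnfoldingTrace


def extract_pathway_module(
    dcm: ThresholdNetwork,
    signals,
    max_steps: int | None = None,
) -> PathwayModule:
    """Unfold from the signals alone; the schedule records each node's first
    certain determination (the signals themselves are not scheduled)."""
    signals = tuple(signals)
    states = np.full(dcm.n_nodes, UNKNOWN, dtype=np.uint8)
    pinned = set()
    for node, state, sustained in signals:
        if states[node] != UNKNOWN and states[node] != state:
            raise ValueError(f"inconsistent signals for node {node}")
        states[node] = state
        if sustained:
            pinned.add(node)
    if not signals:
        return PathwayModule(
            (), (), UnfoldingTrace([states], "stable", states)
        )
    trace = unfold(
        dcm, PartialConfiguration(states, frozenset(pinned)), max_steps
    )
    signal_nodes = {node for node, _, _ in signals}
    first: dict[int, tuple[int, int]] = {}
    for t, s in enumerate(trace.steps):
        for i in range(dcm.n_nodes):
            if s[i] != UNKNOWN and i not in first and i not in signal_nodes:
                first[i] = (t, int(s[i]))
    schedule = tuple(
        sorted((t, node, state) for node, (t, state) in first.items())
    )
    return PathwayModule(signals, schedule, trace)
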