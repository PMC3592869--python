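"""Segment polarity network (SPN) models and reference patterns.

The SPN is the Boolean model of Drosophila segment-polarity gene regulation
(sloppy-paired, wingless, engrailed, hedgehog, patched, cubitus interruptus
and their protein products) in its fully synchronous form: the instantaneous
PH/SMO updates of the original formulation are folded into the CIA/CIR rules,
so every node updates at t+1.

Three variants are provided:

``single_cell_merged_inputs``
    17 nodes: the 15 intra-cellular species plus two consolidated neighbour
    signals, nWG ("wingless protein expressed in at least one adjacent cell")
    and nHH (likewise for hedgehog; the gene and protein neighbour signals are
    merged, which is exact under the steady-state input assumption since the
    HH protein copies the hh gene one step later).
``single_cell_explicit``
    21 nodes: the 15 intra-cellular species plus the six explicit neighbour
    signals WG_prev, WG_next, HH_prev, HH_next, hh_prev, hh_next.
``parasegment_4cell``
    60 nodes: four coupled cells with periodic boundary conditions; neighbour
    signals are wired to the adjacent cells' own WG/HH/hh nodes.

Input nodes (SLP and the neighbour signals) carry identity self-loops, i.e.
the steady-state assumption; analyses that hold them fixed pin them
explicitly.

The reference catalog (wild-type initial configuration and trajectory, the
five stable per-cell patterns P1..P5 and the ten parasegment attractors) is
derived by exact enumeration and verified on construction, so any
transcription error in the rules is caught immediately.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import numpy as np

from .network import (
    BooleanNetwork,
    BooleanNode,
    find_attractors,
    lut_from_expression,
    synchronous_step,
    trajectory,
)

__all__ = [
    "INTRA_NODES",
    "INNER_OUTPUT_NODES",
    "SLP_WILD_TYPE",
    "build_spn",
    "wild_type_initial_configuration",
    "ReferenceCatalog",
    "reference_catalog",
    "random_network",
]

# Intra-cellular node order (Table-style numbering 1..15).
INTRA_NODES = [
    "SLP", "wg", "WG", "en", "EN", "hh", "HH", "ptc", "PTC", "PH", "SMO",
    "ci", "CI", "CIA", "CIR",
]
INNER_OUTPUT_NODES = [n for n in INTRA_NODES if n != "SLP"]

# Neighbour-signal order (indices 16..21 in the parasegment tables).
NEIGHBOUR_SIGNALS = ["WG_prev", "WG_next", "HH_prev", "HH_next", "hh_prev", "hh_next"]

# Wild-type sloppy-paired pre-pattern over the four cells (anterior first).
SLP_WILD_TYPE = (0, 0, 1, 1)

# State-transition formulas; neighbour placeholders {WGn1}/{WGn2} etc. are
# substituted per variant.  SLP's self-loop encodes its upstream steady state.
_RULES = {
    "SLP": "SLP",
    "wg": "(CIA & SLP & !CIR) | (wg & (CIA | SLP) & !CIR)",
    "WG": "wg",
    "en": "({WGn}) & !SLP",
    "EN": "en",
    "hh": "EN & !CIR",
    "HH": "hh",
    "ptc": "CIA & !EN & !CIR",
    "PTC": "ptc | (PTC & !({HHn}))",
    "PH": "PTC & ({HHn})",
    "SMO": "!PTC | ({HHn})",
    "ci": "!EN",
    "CI": "ci",
    "CIA": "CI & (!PTC | ({HHn}) | ({hhn}))",
    "CIR": "CI & PTC & !({HHn}) & !({hhn})",
}


def _build_from_rules(names: list[str], rules: dict[str, str]) -> BooleanNetwork:
    name_to_id = {n: i for i, n in enumerate(names)}
    nodes = []
    for i, name in enumerate(names):
        expr = rules[name]
        # ordered inputs: order of first appearance in the formula
        seen: list[str] = []
        for tok in expr.replace("(", " ").replace(")", " ").replace("!", " ").replace("&", " ").replace("|", " ").split():
            if tok in name_to_id and tok not in seen:
                seen.append(tok)
        lut = lut_from_expression(expr, seen)
        nodes.append(BooleanNode(i, name, tuple(name_to_id[s] for s in seen), lut))
    return BooleanNetwork(nodes)


def spn_rules_text(variant: str = "parasegment_4cell") -> str:
    """Human-readable BoolNet-style rule file for an SPN variant."""
    rules = _variant_rules(variant)
    lines = ["targets, factors"]
    for name, expr in rules:
        lines.append(f"{name}, {expr}")
    return "\n".join(lines) + "\n"


def _variant_rules(variant: str) -> list[tuple[str, str]]:
    if variant == "single_cell_merged_inputs":
        out = [
            (n, _RULES[n].format(WGn="nWG", HHn="nHH", hhn="nHH"))
            for n in INTRA_NODES
        ]
        out += [("nWG", "nWG"), ("nHH", "nHH")]
        return out
    if variant == "single_cell_explicit":
        out = [
            (
                n,
                _RULES[n].format(
                    WGn="WG_prev | WG_next",
                    HHn="HH_prev | HH_next",
                    hhn="hh_prev | hh_next",
                ),
            )
            for n in INTRA_NODES
        ]
        out += [(s, s) for s in NEIGHBOUR_SIGNALS]
        return out
    if variant == "parasegment_4cell":
        out = []
        for c in range(4):
            prev, nxt = (c - 1) % 4, (c + 1) % 4
            for n in INTRA_NODES:
                expr = _RULES[n].format(
                    WGn=f"WG_{prev + 1} | WG_{nxt + 1}",
                    HHn=f"HH_{prev + 1} | HH_{nxt + 1}",
                    hhn=f"hh_{prev + 1} | hh_{nxt + 1}",
                )
                for m in INTRA_NODES:
                    expr = _qualify(expr, m, f"{m}_{c + 1}")
                out.append((f"{n}_{c + 1}", expr))
        return out
    raise ValueError(f"unknown SPN variant {variant!r}")


def build_spn(variant: str = "parasegment_4cell") -> BooleanNetwork:
    """Build an SPN variant (see module docstring for the node layouts)."""
    rules = _variant_rules(variant)
    return _build_from_rules([n for n, _ in rules], dict(rules))


def _qualify(expr: str, name: str, repl: str) -> str:
    out = []
    i = 0
    while i < len(expr):
        if expr[i].isalpha() or expr[i] == "_":
            j = i
            while j < len(expr) and (expr[j].isalnum() or expr[j] == "_"):
                j += 1
            tok = expr[i:j]
            out.append(repl if tok == name else tok)
            i = j
        else:
            out.append(expr[i])
            i += 1
    return "".join(out)


def _pid(name: str, cell: int) -> int:
    """Parasegment node id for intra-cellular ``name`` in cell 1..4."""
    return (cell - 1) * 15 + INTRA_NODES.index(name)


def wild_type_initial_configuration() -> np.ndarray:
    """The known wild-type initial expression pattern of the parasegment.

    Sloppy-paired follows the pair-rule pre-pattern (off, off, on, on);
    wingless is expressed in the posterior cell, engrailed and hedgehog in the
    anterior cell, patched and cubitus interruptus everywhere but the anterior
    cell; all proteins start unexpressed.
    """
    c = np.zeros(60, dtype=np.uint8)
    for cell, s in enumerate(SLP_WILD_TYPE, start=1):
        c[_pid("SLP", cell)] = s
    c[_pid("wg", 4)] = 1
    c[_pid("en", 1)] = 1
    c[_pid("hh", 1)] = 1
    for cell in (2, 3, 4):
        c[_pid("ptc", cell)] = 1
        c[_pid("ci", cell)] = 1
    return c


@dataclass
class ReferenceCatalog:
    """Verified reference objects for the parasegment model."""

    initial_configuration: np.ndarray
    wild_type_trajectory: list[np.ndarray]  # IC .. attractor (inclusive)
    wild_type_attractor: tuple[int, ...]
    attractors: list[tuple[int, ...]]  # the ten parasegment fixed points
    attractor_groups: list[str]  # qualitative label per attractor
    cell_patterns: list[tuple[int, ...]]  # P1..P5 over INNER_OUTPUT_NODES
    wild_type_pattern_sequence: tuple[int, ...]  # per-cell pattern index (0-based)

    def pattern_label(self, i: int) -> str:
        return f"P{i + 1}"


def _stable_cell_patterns() -> list[tuple[int, ...]]:
    """Exhaustively enumerate the stable inner/output patterns of one cell.

    For each of the 8 steady combinations of (SLP, nWG, nHH) the fixed points
    of the 14 free inner/output nodes are collected; exactly five distinct
    patterns exist, ordered here as P1..P5.
    """
    net = build_spn("single_cell_merged_inputs")
    ids = {n: net.name_to_id[n] for n in ("SLP", "nWG", "nHH")}
    inner = [net.name_to_id[n] for n in INNER_OUTPUT_NODES]
    found: dict[tuple[int, ...], None] = {}
    for slp, nwg, nhh in itertools.product((0, 1), repeat=3):
        pinned = {ids["SLP"]: slp, ids["nWG"]: nwg, ids["nHH"]: nhh}
        aset = find_attractors(net, "exhaustive", pinned=pinned)
        for fp in aset.fixed_points:
            found.setdefault(tuple(fp[i] for i in inner))
    patterns = list(found)

    def by_name(p, name):
        return p[INNER_OUTPUT_NODES.index(name)]

    def sort_key(p):
        # P1: quiescent, CIR on.  P2: as P1 with the CI-activator branch on
        # instead of the repressor.  P3: en-expressing, PTC off.  P4:
        # en-expressing, PTC on (seen only in mutants).  P5: wg-expressing.
        if by_name(p, "en"):
            return 2 if not by_name(p, "PTC") else 3
        if by_name(p, "wg"):
            return 4
        if by_name(p, "CIR") and by_name(p, "PTC"):
            return 0
        return 1

    patterns.sort(key=sort_key)
    return patterns


def _classify_attractor(config: tuple[int, ...], wild_type: tuple[int, ...]) -> str:
    en = [config[_pid("EN", c)] for c in (1, 2, 3, 4)]
    wg = [config[_pid("WG", c)] for c in (1, 2, 3, 4)]
    if sum(en) == 0 and sum(wg) == 0:
        return "no segmentation"
    if sum(en) >= 2 and sum(wg) >= 2:
        return "broad stripe" if en[1] or en[2] else "wild type"
    if en[0]:
        return "wild type"
    return "ectopic"


@functools.lru_cache(maxsize=1)
def reference_catalog() -> ReferenceCatalog:
    """Build and verify the reference catalog (cached)."""
    net = build_spn("parasegment_4cell")
    pinned = {
        _pid("SLP", c): s for c, s in enumerate(SLP_WILD_TYPE, start=1)
    }

    ic = wild_type_initial_configuration()
    configs, start = trajectory(net, ic, pinned=pinned)
    cycle = configs[start:]
    if len(cycle) != 1:
        raise AssertionError("wild-type trajectory does not reach a fixed point")
    wt = tuple(int(x) for x in cycle[0])

    patterns = _stable_cell_patterns()
    if len(patterns) != 5:
        raise AssertionError(
            f"expected 5 stable per-cell patterns, found {len(patterns)}"
        )

    cells = [
        [(c - 1) * 15 + INTRA_NODES.index(n) for n in INNER_OUTPUT_NODES]
        for c in (1, 2, 3, 4)
    ]
    aset = find_attractors(
        net,
        "pattern_composition",
        pattern_options={"cells": cells, "patterns": patterns, "fixed": pinned},
    )
    attractors = [a[0] for a in aset.attractors]
    for a in attractors:
        nxt = synchronous_step(net, np.array(a, dtype=np.uint8), pinned)
        if not np.array_equal(nxt, np.array(a)):
            raise AssertionError("catalog attractor is not a fixed point")
    if wt not in attractors:
        raise AssertionError("wild-type attractor missing from composition set")
    attractors.sort(key=lambda a: (a != wt, a))

    wt_seq = []
    for cell_nodes in cells:
        p = tuple(wt[i] for i in cell_nodes)
        wt_seq.append(patterns.index(p))

    groups = [_classify_attractor(a, wt) for a in attractors]
    groups[0] = "wild type"

    return ReferenceCatalog(
        initial_configuration=ic,
        wild_type_trajectory=configs[: start + 1],
        wild_type_attractor=wt,
        attractors=attractors,
        attractor_groups=groups,
        cell_patterns=patterns,
        wild_type_pattern_sequence=tuple(wt_seq),
    )


def random_network(
    N: int,
    K: int | None = 2,
    bias: float = 0.5,
    rng: np.random.Generator | int | None = None,
    k_sampler=None,
) -> BooleanNetwork:
    """Random NK-style Boolean network: inputs drawn without replacement,
    LUT bits Bernoulli(``bias``)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= bias <= 1:
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(rng)
    nodes = []
    for i in range(N):
        k = int(k_sampler(rng)) if k_sampler is not None else int(K)
        k = min(k, N)
        inputs = tuple(sorted(rng.choice(N, size=k, replace=False).tolist()))
        lut = (rng.random(2**k) < bias).astype(np.uint8)
        nodes.append(BooleanNode(i, f"n{i}", inputs, lut))
    return BooleanNetwork(nodes)
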