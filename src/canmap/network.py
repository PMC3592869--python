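"""Boolean automata networks: representation, rule-file parsing, synchronous
dynamics and exact attractor enumeration.

A network is a collection of :class:`BooleanNode` objects.  Each node carries
an ordered input list and a look-up table (LUT) of length ``2**k``.  LUT rows
are indexed by the integer obtained from the input states with *input 1 as the
most significant bit*; this convention is fixed throughout the package and
asserted in the tests.

Two text dialects are supported: a BoolNet-style expression dialect
(``targets, factors`` header, operators ``&``, ``|``, ``!``) and an explicit
LUT dialect (one block per node listing its ordered inputs and output bits).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BooleanNode",
    "BooleanNetwork",
    "AttractorSet",
    "ParseError",
    "lut_from_expression",
    "parse_network",
    "serialize_network",
    "synchronous_step",
    "step_batch",
    "trajectory",
    "find_attractors",
]

DEFAULT_EXHAUSTIVE_CAP = 22  # refuse exhaustive enumeration above 2**cap states


class ParseError(ValueError):
    """Raised for malformed rule files; carries a token/position message."""


# ---------------------------------------------------------------------------
# Expression parsing
# ---------------------------------------------------------------------------

_TOKEN_CHARS = set("&|!()")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in _TOKEN_CHARS:
            tokens.append((c, i))
            i += 1
            continue
        if c.isalnum() or c == "_":
            j = i
            while j < len(expr) and (expr[j].isalnum() or expr[j] == "_"):
                j += 1
            tokens.append((expr[i:j], i))
            i = j
            continue
        raise ParseError(f"unexpected character {c!r} at position {i} in {expr!r}")
    return tokens


class _ExprParser:
    """Recursive-descent parser for `!`, `&`, `|`, parentheses, 0/1 constants."""

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0

    def peek(self) -> str | None:
        if self.pos < len(self.tokens):
            return self.tokens[self.pos][0]
        return None

    def next(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise ParseError(f"unexpected end of expression in {self.expr!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.pos != len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise ParseError(
                f"unexpected token {tok!r} at position {at} in {self.expr!r}"
            )
        return node

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.next()
            terms.append(self.parse_and())
        return ("or", terms) if len(terms) > 1 else terms[0]

    def parse_and(self):
        terms = [self.parse_unary()]
        while self.peek() == "&":
            self.next()
            terms.append(self.parse_unary())
        return ("and", terms) if len(terms) > 1 else terms[0]

    def parse_unary(self):
        tok = self.peek()
        if tok == "!":
            self.next()
            return ("not", self.parse_unary())
        return self.parse_atom()

    def parse_atom(self):
        tok, at = self.next()
        if tok == "(":
            node = self.parse_or()
            closing, cat = self.next()
            if closing != ")":
                raise ParseError(
                    f"expected ')' but found {closing!r} at position {cat} "
                    f"in {self.expr!r}"
                )
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in ("(", ")", "&", "|", "!"):
            raise ParseError(
                f"unexpected token {tok!r} at position {at} in {self.expr!r}"
            )
        return ("var", tok)


def _expr_vars(ast) -> set[str]:
    kind = ast[0]
    if kind == "var":
        return {ast[1]}
    if kind == "const":
        return set()
    if kind == "not":
        return _expr_vars(ast[1])
    out: set[str] = set()
    for child in ast[1]:
        out |= _expr_vars(child)
    return out


def _eval_expr(ast, env: Mapping[str, int]) -> int:
    kind = ast[0]
    if kind == "var":
        return env[ast[1]]
    if kind == "const":
        return ast[1]
    if kind == "not":
        return 1 - _eval_expr(ast[1], env)
    if kind == "and":
        return int(all(_eval_expr(c, env) for c in ast[1]))
    return int(any(_eval_expr(c, env) for c in ast[1]))


def lut_from_expression(expr: str, input_order: Sequence[str]) -> np.ndarray:
    """Materialize the LUT of a logical formula over the given ordered inputs.

    Row ``nu`` holds the value of ``expr`` under the condition encoded by
    ``nu`` with ``input_order[0]`` as the most significant bit.
    """
    ast = _ExprParser(expr).parse()
    used = _expr_vars(ast)
    unknown = used - set(input_order)
    if unknown:
        raise ParseError(f"unknown variable(s) {sorted(unknown)} in {expr!r}")
    k = len(input_order)
    if k == 0 and used:
        raise ParseError(f"non-constant expression {expr!r} with no inputs")
    lut = np.zeros(2**k, dtype=np.uint8)
    for nu in range(2**k):
        env = {
            name: (nu >> (k - 1 - j)) & 1 for j, name in enumerate(input_order)
        }
        lut[nu] = _eval_expr(ast, env)
    return lut


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BooleanNode:
    """One automaton: ordered inputs and a complete transition look-up table."""

    id: int
    name: str
    inputs: tuple[int, ...]
    lut: np.ndarray

    def __post_init__(self):
        self.inputs = tuple(self.inputs)
        self.lut = np.asarray(self.lut, dtype=np.uint8)
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError(f"node {self.name}: duplicate inputs")
        if self.lut.shape != (2 ** len(self.inputs),):
            raise ValueError(
                f"node {self.name}: LUT length {self.lut.size} != 2^k"
            )

    @property
    def k(self) -> int:
        return len(self.inputs)

    @property
    def constant_flag(self) -> bool:
        """True when the node ignores all inputs (k=0 or a constant LUT)."""
        return self.k == 0 or bool(np.all(self.lut == self.lut[0]))


class BooleanNetwork:
    """A Boolean network: nodes, name lookup and structural roles."""

    def __init__(self, nodes: Sequence[BooleanNode]):
        self.nodes = list(nodes)
        self.name_to_id = {n.name: n.id for n in self.nodes}
        if len(self.name_to_id) != len(self.nodes):
            raise ValueError("duplicate node names")
        ids = {n.id for n in self.nodes}
        if ids != set(range(len(self.nodes))):
            raise ValueError("node ids must be 0..N-1")
        for n in self.nodes:
            for i in n.inputs:
                if i not in ids:
                    raise ValueError(
                        f"node {n.name} references undeclared input id {i}"
                    )

    @property
    def n(self) -> int:
        return len(self.nodes)

    def node(self, key: int | str) -> BooleanNode:
        if isinstance(key, str):
            return self.nodes[self.name_to_id[key]]
        return self.nodes[key]

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def roles(self) -> dict[int, str]:
        """Classify nodes: input (depends on nobody else), output (feeds
        nobody), inner (both)."""
        feeds: dict[int, set[int]] = {n.id: set() for n in self.nodes}
        for n in self.nodes:
            for i in n.inputs:
                feeds[i].add(n.id)
        out = {}
        for n in self.nodes:
            depends = set(n.inputs) - {n.id}
            fed = feeds[n.id] - {n.id}
            if not depends:
                out[n.id] = "input"
            elif not fed:
                out[n.id] = "output"
            else:
                out[n.id] = "inner"
        return out

    # -- evaluation helpers -------------------------------------------------

    def _compiled(self):
        """Per-node input index arrays and stacked LUTs for batch stepping."""
        if not hasattr(self, "_compiled_cache"):
            inputs = [np.array(n.inputs, dtype=np.intp) for n in self.nodes]
            shifts = [
                np.arange(n.k - 1, -1, -1, dtype=np.int64) for n in self.nodes
            ]
            self._compiled_cache = (inputs, shifts)
        return self._compiled_cache


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def _check_pins(config: np.ndarray, pinned: Mapping[int, int] | None):
    if pinned:
        for i, s in pinned.items():
            if config[i] != s:
                raise ValueError(
                    f"pinned node {i} has state {config[i]}, expected {s}"
                )


def synchronous_step(
    net: BooleanNetwork,
    config: Sequence[int] | np.ndarray,
    pinned: Mapping[int, int] | None = None,
) -> np.ndarray:
    """One synchronous update; pinned nodes keep their pinned state."""
    c = np.asarray(config, dtype=np.uint8)
    if c.shape != (net.n,):
        raise ValueError("configuration length mismatch")
    _check_pins(c, pinned)
    out = np.empty(net.n, dtype=np.uint8)
    for node in net.nodes:
        if node.k == 0:
            out[node.id] = node.lut[0]
            continue
        nu = 0
        for i in node.inputs:
            nu = (nu << 1) | int(c[i])
        out[node.id] = node.lut[nu]
    if pinned:
        for i, s in pinned.items():
            out[i] = s
    return out


def step_batch(
    net: BooleanNetwork,
    states: np.ndarray,
    pinned: Mapping[int, int] | None = None,
) -> np.ndarray:
    """Vectorized synchronous update of a (B, N) batch of configurations."""
    S = np.asarray(states, dtype=np.uint8)
    out = np.empty_like(S)
    inputs, shifts = net._compiled()
    for node in net.nodes:
        if node.k == 0:
            out[:, node.id] = node.lut[0]
            continue
        idx = (S[:, inputs[node.id]].astype(np.int64) << shifts[node.id]).sum(
            axis=1
        )
        out[:, node.id] = node.lut[idx]
    if pinned:
        for i, s in pinned.items():
            out[:, i] = s
    return out


def trajectory(
    net: BooleanNetwork,
    config: Sequence[int] | np.ndarray,
    pinned: Mapping[int, int] | None = None,
    max_steps: int = 10_000,
) -> tuple[list[np.ndarray], int]:
    """Iterate until a configuration repeats.

    Returns ``(configs, cycle_start)`` where ``configs[cycle_start:]`` is the
    attractor cycle (its first configuration repeats after the last).
    """
    c = np.asarray(config, dtype=np.uint8).copy()
    seen: dict[bytes, int] = {}
    configs: list[np.ndarray] = []
    for t in range(max_steps + 1):
        key = c.tobytes()
        if key in seen:
            return configs, seen[key]
        seen[key] = t
        configs.append(c)
        c = synchronous_step(net, c, pinned)
    raise RuntimeError(f"no attractor found within {max_steps} steps")


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------


@dataclass
class AttractorSet:
    """Cycles of the synchronous dynamics; fixed points have period 1.

    ``basin_counts`` is populated only by exhaustive enumeration and then sums
    to the number of enumerated initial configurations.
    """

    attractors: list[tuple[tuple[int, ...], ...]]
    basin_counts: list[int] | None = None
    n_enumerated: int | None = None

    def __len__(self) -> int:
        return len(self.attractors)

    @property
    def fixed_points(self) -> list[tuple[int, ...]]:
        return [a[0] for a in self.attractors if len(a) == 1]


def _canonical_cycle(cycle: list[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    """Rotate a cycle so it starts at its lexicographically smallest state."""
    i = min(range(len(cycle)), key=lambda j: cycle[j])
    return tuple(cycle[i:] + cycle[:i])


def _attractor_from_trajectory(net, seed, pinned) -> tuple[tuple[int, ...], ...]:
    configs, start = trajectory(net, seed, pinned)
    cycle = [tuple(int(x) for x in c) for c in configs[start:]]
    return _canonical_cycle(cycle)


def find_attractors(
    net: BooleanNetwork,
    mode: str = "exhaustive",
    *,
    pinned: Mapping[int, int] | None = None,
    seeds: Iterable[Sequence[int]] | None = None,
    max_exhaustive: int = DEFAULT_EXHAUSTIVE_CAP,
    pattern_options: dict | None = None,
) -> AttractorSet:
    """Enumerate attractors.

    ``exhaustive``
        All cycles plus exact basin sizes over every assignment of the free
        (non-pinned) nodes; refuses above ``2**max_exhaustive`` states.
    ``from_seeds``
        Cycles reachable from the given seed configurations.
    ``pattern_composition``
        Global fixed points assembled from a per-cell stable-pattern catalog
        over a cell ring; ``pattern_options`` must provide ``cells`` (list of
        per-cell node-id lists), ``patterns`` (list of per-cell state vectors
        over those nodes) and ``fixed`` (dict node-id -> state for the
        remaining, e.g. pinned, nodes).
    """
    pinned = dict(pinned or {})
    if mode == "from_seeds":
        if seeds is None:
            raise ValueError("from_seeds mode requires a nonempty seed set")
        seeds = list(seeds)
        if not seeds:
            raise ValueError("from_seeds mode requires a nonempty seed set")
        found: dict[tuple, None] = {}
        for s in seeds:
            found.setdefault(_attractor_from_trajectory(net, s, pinned))
        return AttractorSet(list(found))

    if mode == "pattern_composition":
        if not pattern_options:
            raise ValueError("pattern_composition requires pattern_options")
        cells = pattern_options["cells"]
        patterns = pattern_options["patterns"]
        fixed = pattern_options.get("fixed", {})
        found = {}
        for choice in itertools.product(range(len(patterns)), repeat=len(cells)):
            c = np.zeros(net.n, dtype=np.uint8)
            for i, s in fixed.items():
                c[i] = s
            for cell_nodes, p in zip(cells, choice):
                for i, s in zip(cell_nodes, patterns[p]):
                    c[i] = s
            if np.array_equal(synchronous_step(net, c, pinned), c):
                found.setdefault((tuple(int(x) for x in c),))
        return AttractorSet(list(found))

    if mode != "exhaustive":
        raise ValueError(f"unknown mode {mode!r}")

    free = [i for i in range(net.n) if i not in pinned]
    nf = len(free)
    if nf > max_exhaustive:
        raise ValueError(
            f"{nf} free nodes exceeds the exhaustive cap of {max_exhaustive}"
        )
    total = 1 << nf
    # successor of every configuration, encoded over the free nodes
    succ = np.empty(total, dtype=np.int64)
    chunk = 1 << 16
    weights = 1 << np.arange(nf - 1, -1, -1, dtype=np.int64)
    base = np.zeros(net.n, dtype=np.uint8)
    for i, s in pinned.items():
        base[i] = s
    for lo in range(0, total, chunk):
        hi = min(lo + chunk, total)
        codes = np.arange(lo, hi, dtype=np.int64)
        S = np.tile(base, (hi - lo, 1))
        S[:, free] = ((codes[:, None] >> np.arange(nf - 1, -1, -1)) & 1).astype(
            np.uint8
        )
        S2 = step_batch(net, S, pinned)
        succ[lo:hi] = S2[:, free].astype(np.int64) @ weights

    # locate cycles and basins with a colouring walk
    attractor_of = np.full(total, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    on_path = np.full(total, -1, dtype=np.int64)
    for start in range(total):
        if attractor_of[start] >= 0:
            continue
        path = []
        x = start
        while attractor_of[x] < 0 and on_path[x] != start:
            on_path[x] = start
            path.append(x)
            x = int(succ[x])
        if attractor_of[x] >= 0:
            aid = int(attractor_of[x])
        else:
            # new cycle: x is on the current path
            pos = path.index(x)
            cycles.append(path[pos:])
            aid = len(cycles) - 1
        for y in path:
            attractor_of[y] = aid

    counts = np.bincount(attractor_of, minlength=len(cycles))

    def decode(code: int) -> tuple[int, ...]:
        c = base.copy()
        for j, i in enumerate(free):
            c[i] = (code >> (nf - 1 - j)) & 1
        return tuple(int(x) for x in c)

    attractors = [_canonical_cycle([decode(x) for x in cyc]) for cyc in cycles]
    return AttractorSet(attractors, [int(c) for c in counts], total)


# ---------------------------------------------------------------------------
# Rule files
# ---------------------------------------------------------------------------


def _implicant_to_term(names: Sequence[str], mask: int, bits: int, k: int) -> str:
    lits = []
    for j in range(k):
        b = 1 << (k - 1 - j)
        if mask & b:
            lits.append(names[j] if bits & b else f"!{names[j]}")
    return " & ".join(lits) if lits else "1"


def _lut_to_expression(node: BooleanNode, names: Sequence[str]) -> str:
    k = node.k
    if k == 0:
        return str(int(node.lut[0]))
    ones = [nu for nu in range(2**k) if node.lut[nu]]
    # constant LUTs keep their declared inputs through a round-trip by
    # referencing every input in a tautology/contradiction
    if not ones:
        return " & ".join(f"({n} & !{n})" for n in names)
    if len(ones) == 2**k:
        return " & ".join(f"({n} | !{n})" for n in names)
    # plain minterm DNF; round-trips bit-exactly
    full = (1 << k) - 1
    terms = [_implicant_to_term(names, full, nu, k) for nu in ones]
    return " | ".join(f"({t})" if " " in t else t for t in terms)


def parse_network(text: str, dialect: str = "expression") -> BooleanNetwork:
    """Parse a rule file in the ``expression`` (.bnet) or ``lut`` dialect."""
    if dialect == "expression":
        return _parse_bnet(text)
    if dialect == "lut":
        return _parse_lut_text(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_bnet(text: str) -> BooleanNetwork:
    rules: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'target, factors'")
        name, expr = line.split(",", 1)
        name = name.strip()
        if not name:
            raise ParseError(f"line {lineno}: empty target name")
        rules.append((name, expr.strip()))
    names = [name for name, _ in rules]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"duplicate node name(s): {dup}")
    name_to_id = {name: i for i, name in enumerate(names)}
    nodes = []
    for i, (name, expr) in enumerate(rules):
        ast = _ExprParser(expr).parse()
        used = _expr_vars(ast)
        undeclared = used - set(names)
        if undeclared:
            raise ParseError(
                f"rule for {name!r} references undeclared node(s) "
                f"{sorted(undeclared)}"
            )
        input_names = sorted(used, key=lambda v: name_to_id[v])
        lut = lut_from_expression(expr, input_names)
        nodes.append(
            BooleanNode(i, name, tuple(name_to_id[v] for v in input_names), lut)
        )
    return BooleanNetwork(nodes)


def _parse_lut_text(text: str) -> BooleanNetwork:
    blocks: list[tuple[str, list[str], str]] = []
    cur_name = None
    cur_inputs: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "node":
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 'node NAME'")
            cur_name = parts[1]
            cur_inputs = None
        elif parts[0] == "inputs":
            cur_inputs = parts[1:]
        elif parts[0] == "lut":
            if cur_name is None or cur_inputs is None:
                raise ParseError(f"line {lineno}: lut before node/inputs")
            if len(parts) != 2 or set(parts[1]) - {"0", "1"}:
                raise ParseError(f"line {lineno}: lut must be a 0/1 string")
            blocks.append((cur_name, cur_inputs, parts[1]))
            cur_name, cur_inputs = None, None
        else:
            raise ParseError(f"line {lineno}: unexpected directive {parts[0]!r}")
    names = [b[0] for b in blocks]
    if len(set(names)) != len(names):
        raise ParseError("duplicate node name in LUT file")
    name_to_id = {name: i for i, name in enumerate(names)}
    nodes = []
    for i, (name, input_names, bits) in enumerate(blocks):
        for v in input_names:
            if v not in name_to_id:
                raise ParseError(f"node {name!r}: undeclared input {v!r}")
        lut = np.array([int(b) for b in bits], dtype=np.uint8)
        nodes.append(
            BooleanNode(
                i, name, tuple(name_to_id[v] for v in input_names), lut
            )
        )
    return BooleanNetwork(nodes)


def serialize_network(net: BooleanNetwork, dialect: str = "expression") -> str:
    """Serialize to rule-file text; round-trips through parse bit-exactly."""
    if dialect == "expression":
        lines = ["targets, factors"]
        for node in net.nodes:
            names = [net.nodes[i].name for i in node.inputs]
            lines.append(f"{node.name}, {_lut_to_expression(node, names)}")
        return "\n".join(lines) + "\n"
    if dialect == "lut":
        lines = []
        for node in net.nodes:
            lines.append(f"node {node.name}")
            lines.append(
                "inputs " + " ".join(net.nodes[i].name for i in node.inputs)
            )
            lines.append("lut " + "".join(str(int(b)) for b in node.lut))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")
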