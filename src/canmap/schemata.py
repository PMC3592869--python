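"""Schema redescription of automata look-up tables and micro-level
canalization measures.

A *wildcard schema* redescribes a set of LUT entries with a third symbol
``#`` marking inputs whose state is irrelevant; the set of all wildcard
schemata of one transition is exactly the set of all prime implicants of that
transition's on-set (the first step of Quine–McCluskey minimization, keeping
*all* prime implicants rather than an essential cover).

A *two-symbol schema* additionally marks subsets of inputs whose states may
permute without affecting the transition (symmetric groups).  A
group-invariant enput over a position set X is characterized by minimum
counts (n0, n1) of members required off/on; the remaining |X| - n0 - n1
members carry position-free wildcards.  At least two of (n0, n1, n#) must be
positive, which precludes trivial all-same-state groups.

Canalization of an automaton is quantified from the schemata:

* input redundancy  k_r  — mean number of wildcards over LUT entries, taking
  per entry the max (upper bound) or min (lower bound) over the schemata of
  the entry's transition that cover it;
* effective connectivity  k_e = k - k_r (upper bound);
* input symmetry  k_s  — likewise for the number of position-free symbols in
  covering two-symbol schemata.

Averages weight every one of the 2^k LUT entries equally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .network import BooleanNode

__all__ = [
    "WildcardSchema",
    "GroupInvariantEnput",
    "TwoSymbolSchema",
    "CanalizationMeasures",
    "prime_implicants",
    "prime_implicants_bruteforce",
    "covered_entries",
    "two_symbol_redescribe",
    "canalization_measures",
]

WILDCARD = 2  # third symbol in condition vectors

PRIME_IMPLICANT_CAP = 20


@dataclass(frozen=True)
class WildcardSchema:
    """A prime implicant: condition over {0, 1, #} plus the transition.

    Internally the condition is held as (mask, bits) over the LUT row index:
    bit ``k-1-j`` of the integers corresponds to input position ``j`` (input 1
    is the most significant bit, matching the LUT row convention).
    """

    k: int
    mask: int  # 1-bits mark literal positions
    bits: int  # literal values (subset of mask)
    transition: int

    @property
    def n_hash(self) -> int:
        return self.k - bin(self.mask).count("1")

    def symbol(self, pos: int) -> int:
        b = 1 << (self.k - 1 - pos)
        if not self.mask & b:
            return WILDCARD
        return 1 if self.bits & b else 0

    def condition(self) -> tuple[int, ...]:
        return tuple(self.symbol(j) for j in range(self.k))

    def covers(self, row: int) -> bool:
        return (row & self.mask) == self.bits

    def __str__(self) -> str:
        return "".join("01#"[s] for s in self.condition())

    @classmethod
    def from_string(cls, s: str, transition: int) -> "WildcardSchema":
        k = len(s)
        mask = bits = 0
        for j, c in enumerate(s):
            b = 1 << (k - 1 - j)
            if c in "01":
                mask |= b
                if c == "1":
                    bits |= b
            elif c != "#":
                raise ValueError(f"bad schema symbol {c!r}")
        return cls(k, mask, bits, transition)


@dataclass(frozen=True)
class GroupInvariantEnput:
    """A permutable input subset with minimum off/on member counts."""

    members: frozenset[int]  # input positions
    n0: int  # at least this many members off
    n1: int  # at least this many members on

    @property
    def n_hash_g(self) -> int:
        return len(self.members) - self.n0 - self.n1

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("group needs at least two members")
        if self.n0 + self.n1 > len(self.members):
            raise ValueError("n0 + n1 exceeds group size")
        if sum(x > 0 for x in (self.n0, self.n1, self.n_hash_g)) < 2:
            raise ValueError("trivial group: fewer than two positive counts")

    def matches(self, row: int, k: int) -> bool:
        ones = sum((row >> (k - 1 - p)) & 1 for p in self.members)
        zeros = len(self.members) - ones
        return zeros >= self.n0 and ones >= self.n1


@dataclass(frozen=True)
class TwoSymbolSchema:
    """A wildcard schema with symmetric (position-free) input groups."""

    k: int
    literal: tuple[tuple[int, int], ...]  # sorted (position, state) pairs
    groups: tuple[GroupInvariantEnput, ...]
    transition: int
    maximality_certified: bool = True

    @property
    def wildcards(self) -> frozenset[int]:
        taken = {p for p, _ in self.literal}
        for g in self.groups:
            taken |= g.members
        return frozenset(set(range(self.k)) - taken)

    @property
    def n_circle(self) -> int:
        """Total positions carrying a position-free symbol."""
        return sum(len(g.members) for g in self.groups)

    def matches(self, row: int) -> bool:
        for p, s in self.literal:
            if (row >> (self.k - 1 - p)) & 1 != s:
                return False
        return all(g.matches(row, self.k) for g in self.groups)

    def expansion(self) -> frozenset[WildcardSchema]:
        """All wildcard schemata obtained by arranging each group's multiset
        {n0 zeros, n1 ones, n# wildcards} over its members."""
        base = [WILDCARD] * self.k
        for p, s in self.literal:
            base[p] = s
        per_group = [
            _arrangements(sorted(g.members), g.n0, g.n1) for g in self.groups
        ]
        out = set()
        for combo in itertools.product(*per_group):
            cond = list(base)
            for assignment in combo:
                for p, s in assignment:
                    cond[p] = s
            out.add(_schema_from_condition(cond, self.transition))
        return frozenset(out)

    def __str__(self) -> str:
        cond = ["#"] * self.k
        for p, s in self.literal:
            cond[p] = str(s)
        parts = ["".join(cond)]
        for g in self.groups:
            parts.append(
                "g(%s;n0=%d,n1=%d)"
                % (",".join(str(p) for p in sorted(g.members)), g.n0, g.n1)
            )
        return " ".join(parts)


def _arrangements(members: list[int], n0: int, n1: int):
    """All assignments of n0 zeros, n1 ones and wildcards to the members."""
    out = []
    g = len(members)
    for zeros in itertools.combinations(range(g), n0):
        rest = [i for i in range(g) if i not in zeros]
        for ones in itertools.combinations(rest, n1):
            assignment = []
            for i, p in enumerate(members):
                if i in zeros:
                    assignment.append((p, 0))
                elif i in ones:
                    assignment.append((p, 1))
                else:
                    assignment.append((p, WILDCARD))
            out.append(tuple(assignment))
    return out


def _schema_from_condition(cond, transition) -> WildcardSchema:
    k = len(cond)
    mask = bits = 0
    for j, s in enumerate(cond):
        if s != WILDCARD:
            b = 1 << (k - 1 - j)
            mask |= b
            if s == 1:
                bits |= b
    return WildcardSchema(k, mask, bits, transition)


# ---------------------------------------------------------------------------
# Prime implicants
# ---------------------------------------------------------------------------


def prime_implicants(
    node: BooleanNode | np.ndarray,
    transition: int,
    cap: int = PRIME_IMPLICANT_CAP,
) -> frozenset[WildcardSchema]:
    """The complete set of prime implicants of one transition's on-set.

    Quine–McCluskey merge-and-subsume for moderate k; an iterative-consensus
    construction with explicit absorption (same output contract) above k=12.
    """
    lut = node.lut if isinstance(node, BooleanNode) else np.asarray(lut_arg(node))
    k = int(np.log2(lut.size))
    if k > cap:
        raise ValueError(f"in-degree {k} exceeds prime-implicant cap {cap}")
    rows = [r for r in range(lut.size) if lut[r] == transition]
    if not rows:
        return frozenset()
    if k <= 12:
        cubes = _qm_prime_implicants(rows, k)
    else:
        cubes = _consensus_prime_implicants(rows, k)
    return frozenset(WildcardSchema(k, m, b, transition) for m, b in cubes)


def lut_arg(lut):
    lut = np.asarray(lut, dtype=np.uint8)
    if lut.size & (lut.size - 1):
        raise ValueError("LUT length must be a power of two")
    return lut


def _qm_prime_implicants(rows: list[int], k: int) -> set[tuple[int, int]]:
    full = (1 << k) - 1
    current = {(full, r) for r in rows}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        by_group: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for mask, bits in current:
            by_group.setdefault((mask, bin(bits).count("1")), []).append(
                (mask, bits)
            )
        for (mask, ones), cubes in by_group.items():
            partners = by_group.get((mask, ones + 1), [])
            for c1 in cubes:
                for c2 in partners:
                    diff = c1[1] ^ c2[1]
                    if diff and not diff & (diff - 1):  # single-bit difference
                        merged.add((mask & ~diff, c1[1] & ~diff))
                        used.add(c1)
                        used.add(c2)
        primes |= current - used
        current = merged
    return primes


def _consensus_prime_implicants(rows: list[int], k: int) -> set[tuple[int, int]]:
    """Blake canonical form by iterated consensus with absorption."""

    def absorbs(a, b):  # a subsumes b
        return (a[0] & b[0]) == a[0] and (b[1] & a[0]) == a[1]

    full = (1 << k) - 1
    cubes: list[tuple[int, int]] = []
    for r in rows:
        cubes.append((full, r))
    changed = True
    cubes = _absorb(cubes, absorbs)
    while changed:
        changed = False
        new: list[tuple[int, int]] = []
        for i in range(len(cubes)):
            for j in range(i + 1, len(cubes)):
                m1, b1 = cubes[i]
                m2, b2 = cubes[j]
                opp = m1 & m2 & (b1 ^ b2)
                if opp and not opp & (opp - 1):  # exactly one opposed literal
                    m = (m1 | m2) & ~opp
                    b = (b1 | b2) & m
                    cand = (m, b)
                    if not any(absorbs(c, cand) for c in cubes + new):
                        new.append(cand)
        if new:
            changed = True
            cubes = _absorb(cubes + new, absorbs)
    return set(cubes)


def _absorb(cubes, absorbs):
    out = []
    for c in cubes:
        if any(absorbs(o, c) and o != c for o in cubes):
            continue
        if c not in out:
            out.append(c)
    return out


def prime_implicants_bruteforce(
    lut: np.ndarray, transition: int
) -> frozenset[WildcardSchema]:
    """Independent oracle: enumerate all 3^k cubes, keep the sound ones, then
    drop any cube subsumed by a larger sound cube."""
    lut = lut_arg(lut)
    k = int(np.log2(lut.size))
    sound = []
    for cond in itertools.product((0, 1, WILDCARD), repeat=k):
        schema = _schema_from_condition(list(cond), transition)
        covered = [r for r in range(lut.size) if schema.covers(r)]
        if covered and all(lut[r] == transition for r in covered):
            sound.append(schema)
    primes = []
    for s in sound:
        subsumed = any(
            o is not s
            and (o.mask & s.mask) == o.mask
            and (s.bits & o.mask) == o.bits
            and o.mask != s.mask
            for o in sound
        )
        if not subsumed:
            primes.append(s)
    return frozenset(primes)


# ---------------------------------------------------------------------------
# Covered entries
# ---------------------------------------------------------------------------


def covered_entries(
    schema: WildcardSchema | TwoSymbolSchema, k: int | None = None
) -> frozenset[int]:
    """LUT row indices matched by a schema (exact expansion)."""
    if isinstance(schema, WildcardSchema):
        if k is not None and k != schema.k:
            raise ValueError("schema dimension mismatch")
        k = schema.k
        free = [j for j in range(k) if schema.symbol(j) == WILDCARD]
        rows = set()
        for fill in itertools.product((0, 1), repeat=len(free)):
            row = schema.bits
            for j, s in zip(free, fill):
                row |= s << (k - 1 - j)
            rows.add(row)
        return frozenset(rows)
    if k is not None and k != schema.k:
        raise ValueError("schema dimension mismatch")
    out: set[int] = set()
    for w in schema.expansion():
        out |= covered_entries(w)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Two-symbol redescription
# ---------------------------------------------------------------------------


def two_symbol_redescribe(
    W: frozenset[WildcardSchema] | set[WildcardSchema],
    budget: int = 200_000,
) -> frozenset[TwoSymbolSchema]:
    """Redescribe a complete prime-implicant set into two-symbol schemata.

    The schemata are partitioned into equivalence classes by their
    (n0, n1, n#) symbol counts — a necessary condition for symmetry — and each
    class is searched for symmetric groups over the largest possible variable
    subsets, shrinking on failure.  Groups are verified by exhaustive
    arrangement membership, so expansion validity always holds; when the
    search budget is exhausted the result is returned with
    ``maximality_certified=False`` on the affected schemata.
    """
    W = set(W)
    if not W:
        return frozenset()
    k = next(iter(W)).k
    transition = next(iter(W)).transition
    Wset = frozenset(W)

    def counts(s: WildcardSchema):
        ones = bin(s.bits).count("1")
        zeros = bin(s.mask).count("1") - ones
        return (zeros, ones, s.n_hash)

    classes: dict[tuple[int, int, int], list[WildcardSchema]] = {}
    for s in W:
        classes.setdefault(counts(s), []).append(s)

    result: list[TwoSymbolSchema] = []
    covered: set[WildcardSchema] = set()
    work = [0]  # arrangement checks consumed

    for cls in classes.values():
        for schema in sorted(cls, key=lambda s: (s.mask, s.bits)):
            if schema in covered:
                continue
            ts = _best_two_symbol(schema, Wset, budget, work)
            result.append(ts)
            covered.update(ts.expansion())
    return frozenset(result)


def _best_two_symbol(
    schema: WildcardSchema, W: frozenset[WildcardSchema], budget: int, work
) -> TwoSymbolSchema:
    """Greedily attach maximal symmetric groups to one wildcard schema."""
    k = schema.k
    cond = list(schema.condition())
    groups: list[GroupInvariantEnput] = []
    free = list(range(k))
    certified = True
    while True:
        found = None
        for size in range(len(free), 1, -1):
            for X in itertools.combinations(free, size):
                syms = [cond[p] for p in X]
                c0, c1 = syms.count(0), syms.count(1)
                ch = len(X) - c0 - c1
                if sum(x > 0 for x in (c0, c1, ch)) < 2:
                    continue
                n_arr = (
                    comb(len(X), c0) * comb(len(X) - c0, c1) or 1
                ) * max(len(groups), 1)
                if work[0] + n_arr > budget:
                    certified = False
                    continue
                work[0] += n_arr
                cand = GroupInvariantEnput(frozenset(X), c0, c1)
                trial = _assemble(k, cond, groups + [cand], schema.transition)
                if trial.expansion() <= W:
                    found = cand
                    break
            if found:
                break
        if not found:
            break
        groups.append(found)
        free = [p for p in free if p not in found.members]
    ts = _assemble(k, cond, groups, schema.transition)
    if not certified:
        ts = TwoSymbolSchema(
            ts.k, ts.literal, ts.groups, ts.transition, maximality_certified=False
        )
    return ts


def _assemble(k, cond, groups, transition) -> TwoSymbolSchema:
    grouped = set()
    for g in groups:
        grouped |= g.members
    literal = tuple(
        (p, cond[p])
        for p in range(k)
        if cond[p] != WILDCARD and p not in grouped
    )
    return TwoSymbolSchema(k, literal, tuple(groups), transition)


# ---------------------------------------------------------------------------
# Canalization measures
# ---------------------------------------------------------------------------


@dataclass
class CanalizationMeasures:
    k: int
    kr_upper: float
    kr_lower: float
    ke: float
    ks_upper: float
    ks_lower: float
    kr_rel: float
    ks_rel: float
    canalization_class: str


def canalization_measures(
    node: BooleanNode,
    on_set_only: bool = False,
    class_threshold: float = 0.5,
) -> CanalizationMeasures:
    """Input redundancy, effective connectivity and input symmetry (Eqs. of
    the module docstring), averaged over all 2^k LUT entries (or the on-set
    only when requested)."""
    k = node.k
    if k == 0:
        return CanalizationMeasures(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, "A")
    pis = {t: prime_implicants(node, t) for t in (0, 1)}
    tss = {t: two_symbol_redescribe(pis[t]) for t in (0, 1)}
    rows = range(2**k)
    kr_up = kr_lo = ks_up = ks_lo = 0.0
    n_rows = 0
    for row in rows:
        t = int(node.lut[row])
        if on_set_only and t != 1:
            continue
        n_rows += 1
        hashes = [s.n_hash for s in pis[t] if s.covers(row)]
        circles = [s.n_circle for s in tss[t] if s.matches(row)]
        # every entry is covered: the entry itself is retained as a schema
        kr_up += max(hashes)
        kr_lo += min(hashes)
        ks_up += max(circles)
        ks_lo += min(circles)
    if n_rows == 0:  # on-set-only averaging of a constant-0 function
        return CanalizationMeasures(k, 0.0, 0.0, float(k), 0.0, 0.0, 0.0, 0.0, "D")
    kr_up /= n_rows
    kr_lo /= n_rows
    ks_up /= n_rows
    ks_lo /= n_rows
    kr_rel = kr_up / k
    ks_rel = ks_up / k
    high_r = kr_rel >= class_threshold
    high_s = ks_rel >= class_threshold
    cls = {(1, 1): "A", (1, 0): "B", (0, 1): "C", (0, 0): "D"}[
        (int(high_r), int(high_s))
    ]
    return CanalizationMeasures(
        k, kr_up, kr_lo, k - kr_up, ks_up, ks_lo, kr_rel, ks_rel, cls
    )


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------


def schema_to_dict(s: WildcardSchema | TwoSymbolSchema) -> dict:
    if isinstance(s, WildcardSchema):
        return {"condition": str(s), "transition": s.transition}
    cond = ["#"] * s.k
    for p, v in s.literal:
        cond[p] = str(v)
    return {
        "condition": "".join(cond),
        "transition": s.transition,
        "groups": [
            {"members": sorted(g.members), "n0": g.n0, "n1": g.n1}
            for g in s.groups
        ],
        "maximality_certified": s.maximality_certified,
    }
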