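"""Minimal configurations (MCs): network-level schema redescription of a
basin of attraction.

An MC is a partial configuration that guarantees convergence to a target
pattern and from which no specified node can be raised to unknown (nor any
symmetric group enlarged) without losing the guarantee.  MCs are found by
stochastic minimization on the Dynamics Canalization Map: starting from a
seed configuration known to converge, nodes are raised to unknown in random
order, keeping a raise whenever the three-valued unfolding still certifies
convergence.  Because certified information only shrinks when states are
removed, a raise that fails can never succeed later in the same minimization,
so each randomized sweep terminates in a true MC; different sweep orders
reach different MCs.

The two-step set search mirrors the estimation protocol: (1) each seed is
re-minimized until ``t_reuse`` consecutive sweeps yield no new MC; (2) when a
seed sampler is available, fresh random seeds are drawn until ``t_new``
consecutive converging seeds are already covered by the current set.  Both
counters reset whenever a new MC is found.

Macro-level canalization is quantified from an MC set exactly like the
micro-level measures: node redundancy n_r (mean wildcards over covered
configurations, max/min over covering MCs for the upper/lower bound),
effective control n_e = N - n_r, and node symmetry n_s (mean position-free
symbols).  Exact counting of covered configurations uses the
inclusion–exclusion principle; large sets are estimated by roulette-wheel
sampling of configurations proportionally to each MC's coverage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .cm import ThresholdNetwork
from .schemata import GroupInvariantEnput
from .unfolding import (
    UNKNOWN,
    PartialConfiguration,
    PatternCatalog,
    Tri,
    guarantees_convergence,
)

__all__ = [
    "MinimalConfiguration",
    "MCSet",
    "SearchParameters",
    "MacroMeasures",
    "ConvergenceTest",
    "minimize_configuration",
    "search_mc_set",
    "two_symbol_mcs",
    "count_covered",
    "sample_covered",
    "macro_measures",
]


@dataclass
class ConvergenceTest:
    """Bundles the DCM, target and certification mode used as the oracle."""

    dcm: ThresholdNetwork
    target: np.ndarray  # over {0,1,UNKNOWN}
    catalog: PatternCatalog | None = None
    target_pattern: int | None = None
    max_steps: int | None = None
    target_id: str = "target"

    def check(self, condition: np.ndarray) -> Tri:
        init = PartialConfiguration(np.asarray(condition, dtype=np.uint8))
        return guarantees_convergence(
            self.dcm,
            init,
            self.target,
            self.max_steps,
            self.catalog,
            self.target_pattern,
        )


@dataclass(frozen=True)
class MinimalConfiguration:
    """Condition over {0,1,#} plus optional group-invariant node enputs."""

    condition: tuple[int, ...]
    groups: tuple[GroupInvariantEnput, ...] = ()
    target_id: str = "target"

    @property
    def n(self) -> int:
        return len(self.condition)

    @property
    def n_literals(self) -> int:
        grouped = set()
        for g in self.groups:
            grouped |= g.members
        return sum(
            1
            for i, s in enumerate(self.condition)
            if s != UNKNOWN and i not in grouped
        )

    @property
    def n_wildcards(self) -> int:
        grouped = set()
        for g in self.groups:
            grouped |= g.members
        return sum(
            1
            for i, s in enumerate(self.condition)
            if s == UNKNOWN and i not in grouped
        )

    @property
    def n_circle(self) -> int:
        return sum(len(g.members) for g in self.groups)

    def coverage(self) -> int:
        """Number of complete configurations this MC redescribes."""
        total = 1 << self.n_wildcards
        for g in self.groups:
            size = len(g.members)
            total *= sum(
                comb(size, j) for j in range(g.n1, size - g.n0 + 1)
            )
        return total

    def matches(self, config: np.ndarray) -> bool:
        grouped = set()
        for g in self.groups:
            grouped |= g.members
        for i, s in enumerate(self.condition):
            if i in grouped or s == UNKNOWN:
                continue
            if int(config[i]) != s:
                return False
        for g in self.groups:
            ones = sum(int(config[i]) for i in g.members)
            if ones < g.n1 or len(g.members) - ones < g.n0:
                return False
        return True

    def __str__(self) -> str:
        s = "".join("01#"[c] for c in self.condition)
        for g in self.groups:
            s += " g(%s;n0=%d,n1=%d)" % (
                ",".join(map(str, sorted(g.members))),
                g.n0,
                g.n1,
            )
        return s


@dataclass
class SearchParameters:
    t_reuse: int = 500
    t_new: int = 1000
    eta: int = 8
    rng_seed: int | None = None

    def __post_init__(self):
        if self.t_reuse <= 0 or self.t_new <= 0 or self.eta <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class MCSet:
    members: list[MinimalConfiguration]
    target_id: str = "target"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def covers(self, config: np.ndarray) -> bool:
        return any(mc.matches(config) for mc in self.members)

    def without_subsumed(self) -> "MCSet":
        """Optional filter: drop wildcard MCs whose coverage is contained in
        another member's (by default subsumed MCs are retained, mirroring
        the all-prime-implicants philosophy)."""

        def subsumes(a: MinimalConfiguration, b: MinimalConfiguration) -> bool:
            if a.groups or b.groups or a.condition == b.condition:
                return False
            return all(
                sa == UNKNOWN or sa == sb
                for sa, sb in zip(a.condition, b.condition)
            )

        kept = [
            mc
            for mc in self.members
            if not any(subsumes(other, mc) for other in self.members)
        ]
        return MCSet(kept, self.target_id, dict(self.metadata))


# ---------------------------------------------------------------------------
# Minimization and search
# ---------------------------------------------------------------------------


def minimize_configuration(
    ct: ConvergenceTest,
    seed: np.ndarray,
    rng: np.random.Generator,
) -> MinimalConfiguration:
    """One randomized minimization sweep; returns a wildcard MC."""
    cond = np.asarray(seed, dtype=np.uint8).copy()
    if ct.check(cond) is not Tri.YES:
        raise ValueError("seed does not guarantee convergence to the target")
    while True:
        raised = False
        specified = [i for i in range(cond.size) if cond[i] != UNKNOWN]
        for i in rng.permutation(specified):
            old = cond[i]
            cond[i] = UNKNOWN
            if ct.check(cond) is Tri.YES:
                raised = True
            else:
                cond[i] = old
        if not raised:
            break
    return MinimalConfiguration(
        tuple(int(x) for x in cond), (), ct.target_id
    )


def _reuse_loop(ct, seed, rng, t_reuse, found: dict) -> int:
    """Re-minimize one seed until t_reuse consecutive fruitless sweeps;
    returns the number of new MCs."""
    new = 0
    fruitless = 0
    while fruitless < t_reuse:
        mc = minimize_configuration(ct, seed, rng)
        if mc.condition not in found:
            found[mc.condition] = mc
            new += 1
            fruitless = 0
        else:
            fruitless += 1
    return new


def search_mc_set(
    ct: ConvergenceTest,
    seeds,
    params: SearchParameters,
    seed_sampler=None,
    rng: np.random.Generator | None = None,
) -> MCSet:
    """Two-step stochastic MC search (see module docstring)."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    found: dict[tuple, MinimalConfiguration] = {}
    seeds = [np.asarray(s, dtype=np.uint8) for s in (seeds or [])]
    any_valid = False
    for s in seeds:
        if ct.check(s) is not Tri.YES:
            raise ValueError("seed does not converge to the target")
        any_valid = True
        _reuse_loop(ct, s, rng, params.t_reuse, found)
    if seed_sampler is not None:
        fruitless = 0
        tried = set()
        # non-converging or repeated draws do not count toward t_new, so an
        # overall draw budget bounds the loop when valid seeds are scarce
        draws, max_draws = 0, 200 * params.t_new
        while fruitless < params.t_new and draws < max_draws:
            draws += 1
            c = np.asarray(seed_sampler(rng), dtype=np.uint8)
            key = c.tobytes()
            if key in tried:
                continue
            tried.add(key)
            if any(mc.matches(c) for mc in found.values()):
                fruitless += 1
                continue
            if ct.check(c) is not Tri.YES:
                continue
            any_valid = True
            new = _reuse_loop(ct, c, rng, params.t_reuse, found)
            fruitless = 0 if new else fruitless + 1
    if not any_valid:
        raise ValueError("no converging seed found within the search budget")
    return MCSet(
        list(found.values()),
        ct.target_id,
        {
            "t_reuse": params.t_reuse,
            "t_new": params.t_new,
            "n_seeds": len(seeds),
            "rng_seed": params.rng_seed,
        },
    )


# ---------------------------------------------------------------------------
# Two-symbol MCs
# ---------------------------------------------------------------------------


def _swap(cond: tuple[int, ...], p: int, q: int) -> tuple[int, ...]:
    c = list(cond)
    c[p], c[q] = c[q], c[p]
    return tuple(c)


def _group_counts(cond, X):
    syms = [cond[p] for p in X]
    return syms.count(0), syms.count(1), syms.count(UNKNOWN)


def _arrangement_conditions(cond, groups):
    """All condition vectors obtained by re-arranging each group's symbols."""
    per_group = []
    for g in groups:
        members = sorted(g.members)
        size = len(members)
        arrs = []
        for zeros in itertools.combinations(range(size), g.n0):
            rest = [i for i in range(size) if i not in zeros]
            for ones in itertools.combinations(rest, g.n1):
                assign = {}
                for i, p in enumerate(members):
                    assign[p] = (
                        0 if i in zeros else 1 if i in ones else UNKNOWN
                    )
                arrs.append(assign)
        per_group.append(arrs)
    out = []
    for combo in itertools.product(*per_group):
        c = list(cond)
        for assign in combo:
            for p, s in assign.items():
                c[p] = s
        out.append(tuple(c))
    return out


def two_symbol_mcs(
    mcs: MCSet, eta: int = 8, grow_limit: int = 2000
) -> list[MinimalConfiguration]:
    """Redescribe a wildcard MC set into two-symbol MCs.

    Candidate symmetric groups are seeded by transpositions between MCs
    (same condition after swapping two node symbols), grown greedily, and
    verified by exhaustive arrangement membership in the set.  Only schemata
    whose wildcard expansion has at least ``eta`` members are returned.
    """
    conditions = {mc.condition for mc in mcs}
    n = next(iter(conditions)).__len__() if conditions else 0
    results: list[MinimalConfiguration] = []
    claimed: set[tuple] = set()
    for mc in sorted(mcs.members, key=lambda m: m.condition):
        cond = mc.condition
        if cond in claimed:
            continue
        groups: list[GroupInvariantEnput] = []
        used: set[int] = set()
        # transposition-seeded candidate pairs
        pairs = [
            (p, q)
            for p in range(n)
            for q in range(p + 1, n)
            if cond[p] != cond[q] and _swap(cond, p, q) in conditions
        ]
        work = 0
        for p, q in pairs:
            if p in used or q in used:
                continue
            X = {p, q}
            grown = True
            while grown and work < grow_limit:
                grown = False
                for r in range(n):
                    if r in X or r in used:
                        continue
                    X2 = sorted(X | {r})
                    c0, c1, ch = _group_counts(cond, X2)
                    if sum(x > 0 for x in (c0, c1, ch)) < 2:
                        continue
                    cand = GroupInvariantEnput(frozenset(X2), c0, c1)
                    arrs = _arrangement_conditions(cond, groups + [cand])
                    work += len(arrs)
                    if all(a in conditions for a in arrs):
                        X = set(X2)
                        grown = True
                        break
            c0, c1, ch = _group_counts(cond, sorted(X))
            if sum(x > 0 for x in (c0, c1, ch)) < 2:
                continue
            cand = GroupInvariantEnput(frozenset(X), c0, c1)
            arrs = _arrangement_conditions(cond, groups + [cand])
            if all(a in conditions for a in arrs):
                groups.append(cand)
                used |= X
        if not groups:
            continue
        arrs = _arrangement_conditions(cond, groups)
        expansion = set(arrs)
        if len(expansion) < eta:
            continue
        claimed |= expansion
        base = list(cond)
        results.append(
            MinimalConfiguration(tuple(base), tuple(groups), mc.target_id)
        )
    return results


# ---------------------------------------------------------------------------
# Coverage counting and sampling
# ---------------------------------------------------------------------------


def _mc_cubes(mc: MinimalConfiguration) -> list[tuple[int, int]]:
    """(mask, bits) cubes whose union is the MC's coverage; bit n-1-i is
    node i."""
    n = mc.n
    cubes = []
    for cond in _arrangement_conditions(mc.condition, mc.groups):
        mask = bits = 0
        for i, s in enumerate(cond):
            if s != UNKNOWN:
                b = 1 << (n - 1 - i)
                mask |= b
                if s == 1:
                    bits |= b
        cubes.append((mask, bits))
    return cubes


def count_covered(
    mcs: MCSet, method: str = "exact_inclusion_exclusion", max_exact: int = 24
):
    """Exact union cardinality of the covered configurations, or certified
    (lower, upper) bounds."""
    if not mcs.members:
        return 0 if method.startswith("exact") else (0, 0)
    n = mcs.members[0].n
    if method == "bounds":
        covers = [mc.coverage() for mc in mcs.members]
        return max(covers), sum(covers)
    if method != "exact_inclusion_exclusion":
        raise ValueError(f"unknown method {method!r}")
    if len(mcs.members) > max_exact:
        raise ValueError(
            f"{len(mcs.members)} MCs exceeds the exact-counting cap "
            f"{max_exact}; use method='bounds'"
        )
    cubes: list[tuple[int, int]] = []
    for mc in mcs.members:
        cubes.extend(_mc_cubes(mc))
    # de-duplicate exact duplicates to keep the recursion small
    cubes = sorted(set(cubes))
    total = 0

    def rec(start: int, mask: int, bits: int, sign: int):
        nonlocal total
        for j in range(start, len(cubes)):
            m2, b2 = cubes[j]
            common = mask & m2
            if (bits & common) != (b2 & common):
                continue  # incompatible: the whole branch is empty
            nm, nb = mask | m2, bits | b2
            total += sign * (1 << (n - bin(nm).count("1")))
            rec(j + 1, nm, nb, -sign)

    rec(0, 0, 0, 1)
    return total


def sample_covered(
    mcs: MCSet, m: int, rng: np.random.Generator
) -> np.ndarray:
    """m configurations sampled proportionally to MC coverage (roulette
    wheel), wildcards and group fill-ins uniform."""
    if not mcs.members:
        raise ValueError("empty MC set")
    if m <= 0:
        raise ValueError("m must be positive")
    weights = np.array([mc.coverage() for mc in mcs.members], dtype=float)
    weights /= weights.sum()
    n = mcs.members[0].n
    out = np.empty((m, n), dtype=np.uint8)
    choices = rng.choice(len(mcs.members), size=m, p=weights)
    for row, ci in enumerate(choices):
        mc = mcs.members[ci]
        c = np.array(
            [s if s != UNKNOWN else 0 for s in mc.condition], dtype=np.uint8
        )
        free = [
            i
            for i, s in enumerate(mc.condition)
            if s == UNKNOWN and not any(i in g.members for g in mc.groups)
        ]
        c[free] = rng.integers(0, 2, size=len(free))
        for g in mc.groups:
            members = sorted(g.members)
            size = len(members)
            admissible = [
                v
                for v in itertools.product((0, 1), repeat=size)
                if sum(v) >= g.n1 and size - sum(v) >= g.n0
            ]
            pick = admissible[rng.integers(0, len(admissible))]
            for i, s in zip(members, pick):
                c[i] = s
        out[row] = c
    return out


# ---------------------------------------------------------------------------
# Macro-level measures
# ---------------------------------------------------------------------------


@dataclass
class MacroMeasures:
    N: int
    nr_upper: float
    nr_lower: float
    ne: float
    ns_upper: float
    ns_lower: float
    nr_rel: float
    ne_rel: float
    ns_rel: float
    estimated: bool
    m: int | None = None
    repeats: int | None = None
    ci95: dict | None = None


def _per_config_stats(mcs: MCSet, config) -> tuple[int, int, int, int]:
    hashes = []
    circles = []
    for mc in mcs.members:
        if mc.matches(config):
            hashes.append(mc.n_wildcards)
            circles.append(mc.n_circle)
    if not hashes:
        raise ValueError("configuration not covered by the MC set")
    return max(hashes), min(hashes), max(circles), min(circles)


def _enumerate_covered(mcs: MCSet):
    seen = set()
    n = mcs.members[0].n
    for mc in mcs.members:
        for mask, bits in _mc_cubes(mc):
            free = [j for j in range(n) if not mask & (1 << (n - 1 - j))]
            for fill in itertools.product((0, 1), repeat=len(free)):
                v = bits
                for j, s in zip(free, fill):
                    v |= s << (n - 1 - j)
                if v not in seen:
                    seen.add(v)
                    yield np.array(
                        [(v >> (n - 1 - j)) & 1 for j in range(n)],
                        dtype=np.uint8,
                    )


def macro_measures(
    mcs: MCSet,
    sample: tuple[int, int, np.random.Generator] | None = None,
) -> MacroMeasures:
    """Node redundancy / effective control / node symmetry of an MC set.

    ``sample=None`` enumerates the covered set exhaustively; otherwise
    ``sample=(m, repeats, rng)`` estimates the measures from ``repeats``
    independent roulette-wheel samples of ``m`` configurations each, with
    normal-approximation 95% confidence intervals over the repeat means.
    """
    if not mcs.members:
        raise ValueError("empty MC set")
    N = mcs.members[0].n
    if sample is None:
        sums = np.zeros(4)
        count = 0
        for config in _enumerate_covered(mcs):
            sums += _per_config_stats(mcs, config)
            count += 1
        nr_up, nr_lo, ns_up, ns_lo = sums / count
        est, m, repeats, ci = False, None, None, None
    else:
        m, repeats, rng = sample
        means = np.empty((repeats, 4))
        for r in range(repeats):
            configs = sample_covered(mcs, m, rng)
            vals, weights = [], []
            for c in configs:
                stats = _per_config_stats(mcs, c)
                # roulette sampling draws a configuration proportionally to
                # the number of MCs covering it; weighting by its reciprocal
                # makes the estimate unbiased for the uniform covered set
                k_cover = sum(1 for mc in mcs.members if mc.matches(c))
                vals.append(stats)
                weights.append(1.0 / k_cover)
            vals = np.array(vals, dtype=float)
            w = np.array(weights)[:, None]
            means[r] = (vals * w).sum(axis=0) / w.sum()
        nr_up, nr_lo, ns_up, ns_lo = means.mean(axis=0)
        half = 1.96 * means.std(axis=0, ddof=1) / np.sqrt(repeats)
        ci = {
            "nr_upper": float(half[0]),
            "nr_lower": float(half[1]),
            "ns_upper": float(half[2]),
            "ns_lower": float(half[3]),
        }
        est = True
    return MacroMeasures(
        N,
        float(nr_up),
        float(nr_lo),
        float(N - nr_up),
        float(ns_up),
        float(ns_lo),
        float(nr_up / N),
        float((N - nr_up) / N),
        float(ns_up / N),
        est,
        m,
        repeats,
        ci,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def mcs_to_csv(mcs: MCSet) -> str:
    lines = ["condition,groups,n_literals,n_wildcards,coverage"]
    for mc in mcs.members:
        groups = ";".join(
            "%s:%d:%d" % ("|".join(map(str, sorted(g.members))), g.n0, g.n1)
            for g in mc.groups
        )
        lines.append(
            "%s,%s,%d,%d,%d"
            % (
                "".join("01#"[c] for c in mc.condition),
                groups,
                mc.n_literals,
                mc.n_wildcards,
                mc.coverage(),
            )
        )
    return "\n".join(lines) + "\n"
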