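"""Minimal configurations: minimization, set search, coverage, measures."""

import itertools

import numpy as np
import pytest

from canmap.cm import build_dcm
from canmap.minimal import (
    ConvergenceTest,
    MCSet,
    MinimalConfiguration,
    SearchParameters,
    count_covered,
    macro_measures,
    minimize_configuration,
    sample_covered,
    search_mc_set,
    two_symbol_mcs,
)
from canmap.network import parse_network, trajectory
from canmap.schemata import GroupInvariantEnput
from canmap.spn import INNER_OUTPUT_NODES, random_network
from canmap.unfolding import UNKNOWN, PatternCatalog, Tri


@pytest.fixture(scope="module")
def p1_test(request):
    """Convergence test for the quiescent single-cell pattern P1 (unique
    catalog matching)."""
    spn_cell = request.getfixturevalue("spn_cell")
    catalog = request.getfixturevalue("catalog")
    dcm = build_dcm(spn_cell)
    inner = [spn_cell.name_to_id[n] for n in INNER_OUTPUT_NODES]
    pcat = PatternCatalog(tuple(inner), catalog.cell_patterns)
    target = np.full(17, UNKNOWN, dtype=np.uint8)
    for i, v in zip(inner, catalog.cell_patterns[0]):
        target[i] = v
    return spn_cell, ConvergenceTest(
        dcm, target, catalog=pcat, target_pattern=0, target_id="P1"
    )


def test_fixed_point_seed_yields_mc():
    """A fixed-point attractor used as its own target admits an MC covering
    the seed."""
    net = parse_network("targets, factors\na, a\nb, a & b\n")
    dcm = build_dcm(net)
    target = np.array([1, 1], dtype=np.uint8)
    ct = ConvergenceTest(dcm, target)
    mc = minimize_configuration(ct, target, np.random.default_rng(0))
    assert mc.matches(target)
    assert ct.check(np.array(mc.condition, dtype=np.uint8)) is Tri.YES


def test_non_converging_seed_rejected(p1_test):
    spn_cell, ct = p1_test
    bad = np.ones(17, dtype=np.uint8)  # SLP=nWG=nHH=1 drives wg/en patterns
    with pytest.raises(ValueError):
        minimize_configuration(ct, bad, np.random.default_rng(0))


def test_single_cell_p1_search_finds_the_two_mcs(p1_test):
    """The complete MC set for the quiescent pattern consists of exactly two
    two-enput conditions: hedgehog signals absent plus either SLP expressed
    or neighbour wingless absent."""
    spn_cell, ct = p1_test
    rng = np.random.default_rng(0)
    seeds, sampler_tries = [], 0
    while len(seeds) < 8:
        c = rng.integers(0, 2, 17).astype(np.uint8)
        if ct.check(c) is Tri.YES:
            seeds.append(c)
    mcset = search_mc_set(
        ct, seeds, SearchParameters(t_reuse=40, rng_seed=1)
    )
    assert len(mcset) == 2
    ids = spn_cell.name_to_id
    conds = {
        frozenset(
            (i, int(s))
            for i, s in enumerate(mc.condition)
            if s != UNKNOWN
        )
        for mc in mcset
    }
    assert conds == {
        frozenset({(ids["nHH"], 0), (ids["SLP"], 1)}),
        frozenset({(ids["nHH"], 0), (ids["nWG"], 0)}),
    }


def test_minimality_and_convergence_reverified(p1_test):
    """Every emitted MC passes both invariants when re-checked
    independently: it certifies convergence, and raising any single literal
    breaks the certificate."""
    spn_cell, ct = p1_test
    rng = np.random.default_rng(3)
    c = None
    while c is None or ct.check(c) is not Tri.YES:
        c = rng.integers(0, 2, 17).astype(np.uint8)
    mc = minimize_configuration(ct, c, rng)
    cond = np.array(mc.condition, dtype=np.uint8)
    assert ct.check(cond) is Tri.YES
    for i in range(17):
        if cond[i] == UNKNOWN:
            continue
        probe = cond.copy()
        probe[i] = UNKNOWN
        assert ct.check(probe) is Tri.NO


def test_search_reproducibility(p1_test):
    spn_cell, ct = p1_test
    rng = np.random.default_rng(9)
    seed = None
    while seed is None or ct.check(seed) is not Tri.YES:
        seed = rng.integers(0, 2, 17).astype(np.uint8)
    a = search_mc_set(ct, [seed], SearchParameters(t_reuse=15, rng_seed=7))
    b = search_mc_set(ct, [seed], SearchParameters(t_reuse=15, rng_seed=7))
    assert [m.condition for m in a] == [m.condition for m in b]


def test_mc_validity_by_simulation():
    """On small random networks, every configuration covered by an emitted
    MC reaches the target attractor under the exact dynamics (exhaustive
    over completions)."""
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 12:
        N = int(rng.integers(4, 9))
        net = random_network(N, 2, rng=rng)
        configs, start = trajectory(net, rng.integers(0, 2, N).astype(np.uint8))
        cycle = configs[start:]
        if len(cycle) != 1:
            continue  # fixed-point targets only
        target = cycle[0]
        dcm = build_dcm(net)
        ct = ConvergenceTest(dcm, target)
        if ct.check(configs[0]) is not Tri.YES:
            continue
        mcset = search_mc_set(
            ct, [configs[0]], SearchParameters(t_reuse=10, rng_seed=checked)
        )
        for mc in mcset:
            unknown = [i for i, s in enumerate(mc.condition) if s == UNKNOWN]
            for fill in itertools.product((0, 1), repeat=len(unknown)):
                c = np.array(
                    [0 if s == UNKNOWN else s for s in mc.condition],
                    dtype=np.uint8,
                )
                for i, s in zip(unknown, fill):
                    c[i] = s
                cfgs, st = trajectory(net, c)
                assert len(cfgs[st:]) == 1
                assert cfgs[st].tolist() == target.tolist()
        checked += 1


# -- two-symbol MCs ---------------------------------------------------------


def mc_from_string(s):
    return MinimalConfiguration(
        tuple({"0": 0, "1": 1, "#": UNKNOWN}[c] for c in s)
    )


def test_two_symbol_mcs_detects_constructed_swap():
    """A 2-node symmetric swap replicated across the set is detected when it
    redescribes at least eta wildcard MCs."""
    members = []
    # group over nodes 0,1 (one on, one off) x group over nodes 2,3:
    # 4 arrangements, all sharing literals elsewhere
    for a, b in itertools.product(("01", "10"), repeat=2):
        members.append(mc_from_string(a + b + "11##"))
    mcset = MCSet(members)
    ts = two_symbol_mcs(mcset, eta=4)
    assert len(ts) == 1
    groups = sorted(ts[0].groups, key=lambda g: min(g.members))
    assert [sorted(g.members) for g in groups] == [[0, 1], [2, 3]]
    assert all((g.n0, g.n1) == (1, 1) for g in groups)


def test_two_symbol_mcs_eta_filter():
    members = [mc_from_string("011#"), mc_from_string("101#")]
    assert two_symbol_mcs(MCSet(members), eta=4) == []
    found = two_symbol_mcs(MCSet(members), eta=2)
    assert len(found) == 1


def test_two_symbol_mcs_no_structure_empty():
    members = [mc_from_string("0011"), mc_from_string("1100")]
    assert two_symbol_mcs(MCSet(members), eta=2) == []


def test_subsumption_filter_optional():
    general, specific = mc_from_string("0###"), mc_from_string("01#1")
    mcset = MCSet([general, specific])
    assert len(mcset) == 2  # retained by default
    filtered = mcset.without_subsumed()
    assert [m.condition for m in filtered] == [general.condition]


# -- coverage counting and sampling -----------------------------------------


def brute_force_union(members, n):
    covered = set()
    for v in range(2**n):
        c = np.array([(v >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.uint8)
        if any(mc.matches(c) for mc in members):
            covered.add(v)
    return len(covered)


def test_count_covered_single_mc():
    mc = mc_from_string("01####")
    assert count_covered(MCSet([mc])) == 2**4 == mc.coverage()


def test_count_covered_disjoint():
    a, b = mc_from_string("0#####"), mc_from_string("1##00#")
    assert count_covered(MCSet([a, b])) == a.coverage() + b.coverage()


def test_count_covered_overlapping_matches_bruteforce():
    rng = np.random.default_rng(0)
    for _ in range(20):
        members = []
        for _ in range(3):
            s = "".join(rng.choice(list("01##"), size=10))
            members.append(mc_from_string(s))
        mcset = MCSet(members)
        assert count_covered(mcset) == brute_force_union(members, 10)


def test_count_covered_group_mc_matches_bruteforce():
    mc = MinimalConfiguration(
        tuple(mc_from_string("01##10##").condition),
        (GroupInvariantEnput(frozenset({2, 3}), 1, 1),),
    )
    assert count_covered(MCSet([mc])) == brute_force_union([mc], 8)
    assert mc.coverage() == brute_force_union([mc], 8)


def test_count_covered_cap_and_bounds():
    members = [mc_from_string("0#"), mc_from_string("1#")]
    with pytest.raises(ValueError, match="cap"):
        count_covered(MCSet(members * 20), max_exact=24)
    lo, hi = count_covered(MCSet(members), "bounds")
    assert lo == 2 and hi == 4


def test_sample_covered_uniform_over_expansion(rng):
    """Samples from a single MC are uniform over its 2^w expansions
    (chi-square sanity check)."""
    mc = mc_from_string("01###")
    samples = sample_covered(MCSet([mc]), 10_000, rng)
    counts = np.zeros(8)
    for c in samples:
        counts[c[2] * 4 + c[3] * 2 + c[4]] += 1
    expected = 10_000 / 8
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    assert chi2 < 24.3  # chi-square(7) at p=0.001


def test_sample_covered_roulette_proportionality(rng):
    big, small = mc_from_string("0##########"), mc_from_string("100000000##")
    samples = sample_covered(MCSet([big, small]), 20_000, rng)
    n_small = int(sum(1 for c in samples if small.matches(c) and not big.matches(c)))
    # coverage ratio 2^10 : 2^2 = 256:1
    assert n_small < 20_000 * (4 / (1024 + 4)) * 3
    for c in samples[:200]:
        assert big.matches(c) or small.matches(c)


def test_sample_covered_empty_set_rejected(rng):
    with pytest.raises(ValueError):
        sample_covered(MCSet([]), 10, rng)


# -- macro measures ---------------------------------------------------------


def test_macro_measures_single_cell_eq10_values(p1_test):
    """The two-MC single-cell set: n_e = 2, upper node redundancy 15, no
    node symmetry, over the 17-node network."""
    spn_cell, _ = p1_test
    ids = spn_cell.name_to_id
    a = np.full(17, UNKNOWN, dtype=np.uint8)
    a[ids["nHH"]], a[ids["SLP"]] = 0, 1
    b = np.full(17, UNKNOWN, dtype=np.uint8)
    b[ids["nHH"]], b[ids["nWG"]] = 0, 0
    mcset = MCSet(
        [
            MinimalConfiguration(tuple(int(x) for x in a)),
            MinimalConfiguration(tuple(int(x) for x in b)),
        ]
    )
    mm = macro_measures(mcset)
    assert mm.N == 17
    assert mm.ne == pytest.approx(2.0)
    assert mm.nr_upper == pytest.approx(15.0)
    assert mm.ns_upper == 0.0
    assert mm.nr_upper + mm.ne == pytest.approx(mm.N)


def test_macro_measures_estimated_converges_to_exhaustive(rng):
    members = [mc_from_string("01###"), mc_from_string("0#1##"),
               mc_from_string("#10##")]
    mcset = MCSet(members)
    exact = macro_measures(mcset)
    est = macro_measures(mcset, (4000, 8, rng))
    assert est.estimated and est.ci95 is not None
    assert abs(est.nr_upper - exact.nr_upper) < 0.1
    assert abs(est.ns_upper - exact.ns_upper) < 0.1
    assert est.nr_upper + est.ne == pytest.approx(est.N)
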