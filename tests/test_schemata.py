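"""Prime implicants, two-symbol redescription and canalization measures."""

import itertools

import numpy as np
import pytest

from canmap.network import BooleanNode
from canmap.schemata import (
    WildcardSchema,
    canalization_measures,
    covered_entries,
    prime_implicants,
    prime_implicants_bruteforce,
    two_symbol_redescribe,
)


def node_from_lut(lut):
    lut = np.asarray(lut, dtype=np.uint8)
    k = int(np.log2(lut.size))
    return BooleanNode(0, "f", tuple(range(1, k + 1)), lut)


AND = node_from_lut([0, 0, 0, 1])
XOR = node_from_lut([0, 1, 1, 0])


def schema_strings(schemata):
    return sorted(str(s) for s in schemata)


def test_and_prime_implicants():
    assert schema_strings(prime_implicants(AND, 1)) == ["11"]
    assert schema_strings(prime_implicants(AND, 0)) == ["#0", "0#"]


def test_xor_prime_implicants_have_no_wildcards():
    on = prime_implicants(XOR, 1)
    assert schema_strings(on) == ["01", "10"]
    assert all(s.n_hash == 0 for s in on)


def test_automaton_x_prime_implicants(automaton_x):
    on = prime_implicants(automaton_x, 1)
    off = prime_implicants(automaton_x, 0)
    assert len(on) == 12 and all(s.n_hash == 2 for s in on)
    assert sorted(s.n_hash for s in off) == [2, 2, 5, 5]
    assert on == prime_implicants_bruteforce(automaton_x.lut, 1)
    assert off == prime_implicants_bruteforce(automaton_x.lut, 0)


def test_oracle_equivalence_all_functions_k_le_3():
    for k in (1, 2, 3):
        for bits in range(2 ** (2**k)):
            lut = np.array(
                [(bits >> r) & 1 for r in range(2**k)], dtype=np.uint8
            )
            node = node_from_lut(lut)
            for t in (0, 1):
                assert prime_implicants(node, t) == prime_implicants_bruteforce(
                    lut, t
                )


@pytest.mark.parametrize("k,n_random", [(4, 100), (5, 60)])
def test_oracle_equivalence_random_functions(k, n_random):
    rng = np.random.default_rng(k)
    for _ in range(n_random):
        lut = rng.integers(0, 2, size=2**k).astype(np.uint8)
        node = node_from_lut(lut)
        for t in (0, 1):
            assert prime_implicants(node, t) == prime_implicants_bruteforce(
                lut, t
            )


def test_consensus_fallback_matches_quine_mccluskey():
    from canmap.schemata import _consensus_prime_implicants, _qm_prime_implicants

    rng = np.random.default_rng(7)
    for _ in range(30):
        lut = rng.integers(0, 2, size=2**5).astype(np.uint8)
        rows = [r for r in range(32) if lut[r]]
        if rows:
            assert _consensus_prime_implicants(rows, 5) == _qm_prime_implicants(
                rows, 5
            )


def test_blake_form_reconstruction_spn(spn_cell_explicit):
    """The disjunction of the transition-1 schemata equals the LUT."""
    for node in spn_cell_explicit.nodes:
        on = prime_implicants(node, 1)
        for row in range(2**node.k):
            assert any(s.covers(row) for s in on) == bool(node.lut[row])


def test_covered_entries_counts(automaton_x):
    s = WildcardSchema.from_string("0#1###", 1)
    assert len(covered_entries(s)) == 16
    literal = WildcardSchema.from_string("010101", 1)
    assert covered_entries(literal) == frozenset({0b010101})
    ts = next(iter(two_symbol_redescribe(prime_implicants(automaton_x, 1))))
    assert len(covered_entries(ts)) == 14


def test_two_symbol_automaton_x(automaton_x):
    tss = two_symbol_redescribe(prime_implicants(automaton_x, 1))
    assert len(tss) == 1
    ts = next(iter(tss))
    assert dict(ts.literal) == {1: 0, 2: 1}
    assert len(ts.groups) == 1
    g = ts.groups[0]
    assert g.members == frozenset({0, 3, 4, 5})
    assert (g.n0, g.n1, g.n_hash_g) == (1, 1, 2)
    assert ts.expansion() == prime_implicants(automaton_x, 1)


def test_two_symbol_xor_symmetric_group():
    tss = two_symbol_redescribe(prime_implicants(XOR, 1))
    assert len(tss) == 1
    g = next(iter(tss)).groups[0]
    assert g.members == frozenset({0, 1}) and (g.n0, g.n1) == (1, 1)


def test_two_symbol_and_trivial_group_precluded():
    tss = two_symbol_redescribe(prime_implicants(AND, 1))
    assert len(tss) == 1
    assert next(iter(tss)).groups == ()


def test_two_symbol_multiple_groups():
    # (x1 xor x2) and (x3 xor x4): two independent symmetric pairs
    lut = np.zeros(16, dtype=np.uint8)
    for r in range(16):
        x = [(r >> (3 - j)) & 1 for j in range(4)]
        lut[r] = int((x[0] ^ x[1]) and (x[2] ^ x[3]))
    tss = two_symbol_redescribe(prime_implicants(node_from_lut(lut), 1))
    assert len(tss) == 1
    groups = sorted(next(iter(tss)).groups, key=lambda g: min(g.members))
    assert [sorted(g.members) for g in groups] == [[0, 1], [2, 3]]


def test_two_symbol_soundness_random_and_spn(spn_cell_explicit, rng):
    """Expanding every two-symbol schema re-collects exactly the wildcard
    set."""
    nodes = list(spn_cell_explicit.nodes)
    for seed in range(30):
        lut = np.random.default_rng(seed).integers(0, 2, 16).astype(np.uint8)
        nodes.append(node_from_lut(lut))
    for node in nodes:
        for t in (0, 1):
            W = prime_implicants(node, t)
            tss = two_symbol_redescribe(W)
            expanded = frozenset().union(*(ts.expansion() for ts in tss)) if tss else frozenset()
            assert expanded == W


def test_two_symbol_budget_flags_uncertified_maximality(automaton_x):
    """An exhausted arrangement-check budget yields valid schemata flagged
    as not certified maximal, never a silent truncation."""
    W = prime_implicants(automaton_x, 1)
    tss = two_symbol_redescribe(W, budget=3)
    expanded = frozenset().union(*(t.expansion() for t in tss))
    assert expanded == W  # expansion validity still holds
    assert any(not t.maximality_certified for t in tss)


@pytest.mark.parametrize("k", [2, 3])
def test_non_canalizing_census(k):
    """Exactly two functions of k inputs have zero input redundancy."""
    count = 0
    for bits in range(2 ** (2**k)):
        lut = np.array([(bits >> r) & 1 for r in range(2**k)], dtype=np.uint8)
        node = node_from_lut(lut)
        if canalization_measures(node).kr_upper == 0:
            count += 1
    assert count == 2


def test_measures_constant_node():
    m = canalization_measures(node_from_lut([1, 1, 1, 1]))
    assert m.kr_upper == 2 and m.ke == 0


def test_measures_xor():
    m = canalization_measures(XOR)
    assert m.kr_upper == 0 and m.ke == 2 and m.ks_upper == 1.0
    assert m.ks_lower == 1.0


def test_measures_automaton_x(automaton_x):
    m = canalization_measures(automaton_x)
    assert m.kr_upper == pytest.approx(4.25)
    assert m.ke == pytest.approx(1.75)
    assert m.ks_upper == pytest.approx(0.875)


def test_measure_identities_and_bound_ordering(spn_cell_explicit, rng):
    nodes = list(spn_cell_explicit.nodes)
    for seed in range(20):
        lut = np.random.default_rng(100 + seed).integers(0, 2, 16)
        nodes.append(node_from_lut(lut.astype(np.uint8)))
    for node in nodes:
        m = canalization_measures(node)
        assert m.kr_upper + m.ke == pytest.approx(node.k)
        assert 0 <= m.kr_lower <= m.kr_upper <= node.k
        assert 0 <= m.ks_lower <= m.ks_upper <= node.k


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**16 - 1))
    def test_prime_implicants_sound_minimal_complete(bits):
        """Every prime implicant is sound (covers only its transition's
        rows), minimal (no literal can be raised), and the set covers the
        whole on-set — for arbitrary k=4 functions."""
        lut = np.array([(bits >> r) & 1 for r in range(16)], dtype=np.uint8)
        node = node_from_lut(lut)
        for t in (0, 1):
            pis = prime_implicants(node, t)
            covered = set()
            for s in pis:
                rows = covered_entries(s)
                assert all(lut[r] == t for r in rows)  # soundness
                covered |= rows
                for j in range(4):  # minimality
                    if s.symbol(j) == 2:
                        continue
                    raised = WildcardSchema(
                        4,
                        s.mask & ~(1 << (3 - j)),
                        s.bits & ~(1 << (3 - j)),
                        t,
                    )
                    assert any(
                        lut[r] != t for r in covered_entries(raised)
                    )
            assert covered == {r for r in range(16) if lut[r] == t}

except ImportError:  # pragma: no cover - hypothesis is in the test extra
    pass


def test_sympy_blake_cross_check(automaton_x):
    """Independent symbolic cross-check: our transition-1 DNF is logically
    equivalent to the SOP form sympy builds from the same minterms."""
    sympy = pytest.importorskip("sympy")
    from sympy.logic import SOPform

    syms = sympy.symbols("x1:7")
    minterms = [
        [(r >> (5 - j)) & 1 for j in range(6)]
        for r in range(64)
        if automaton_x.lut[r]
    ]
    ref = SOPform(syms, minterms)
    terms = []
    for s in prime_implicants(automaton_x, 1):
        lits = []
        for j in range(6):
            v = s.symbol(j)
            if v == 1:
                lits.append(syms[j])
            elif v == 0:
                lits.append(~syms[j])
        terms.append(sympy.And(*lits))
    ours = sympy.Or(*terms)
    assert sympy.simplify_logic(sympy.Xor(ref, ours)) == sympy.false
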