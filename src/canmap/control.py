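"""Enput power over an MC set and robustness of attractor convergence under
stochastic enput disruption.

The *power* of a literal enput e = (node, state) in an MC set is the
proportion of covered configurations that are redescribed by at least one MC
containing e; an enput present in every MC has full power (P = 1) and is a
critical controller of the target behaviour.

The disruption protocol follows a noisy-pinning scheme: for T steps the
disrupted node is held at its reference state but flips with probability p at
each step (returning to the reference when no flip recurs); all other nodes
follow the synchronous dynamics, reading the flipped state at the same step.
After the noise window the network runs freely to an attractor.  Fractions of
R trials converging to each attractor are reported; attractors outside the
supplied catalog are appended to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import BooleanNetwork, step_batch, trajectory
from .minimal import MCSet, sample_covered, _enumerate_covered

__all__ = [
    "PowerTable",
    "PerturbationProtocol",
    "OutcomeDistribution",
    "enput_power",
    "perturb_and_converge",
    "noise_sweep",
    "DEFAULT_P_GRID",
]

DEFAULT_P_GRID = (
    0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
    0.95, 0.99, 1.0,
)


@dataclass
class PowerTable:
    table: pd.DataFrame  # columns: node, state, power, category
    estimated: bool
    m: int | None = None

    def power(self, node: int, state: int) -> float:
        df = self.table
        row = df[(df.node == node) & (df.state == state)]
        return float(row.power.iloc[0]) if len(row) else 0.0

    def full_power(self) -> list[tuple[int, int]]:
        df = self.table[self.table.category == "full"]
        return list(zip(df.node.tolist(), df.state.tolist()))


def _categorize(p: float, high: float = 0.5) -> str:
    if p == 1.0:
        return "full"
    if p == 0.0:
        return "null"
    return "high" if p >= high else "low"


def enput_power(
    mcs: MCSet,
    sample: tuple[int, np.random.Generator] | None = None,
    high_threshold: float = 0.5,
) -> PowerTable:
    """Power of every literal enput occurring in the MC set.

    Exhaustive over the covered set when ``sample`` is None, otherwise
    estimated from ``sample=(m, rng)`` roulette-wheel samples.
    """
    if not mcs.members:
        raise ValueError("empty MC set")
    n = mcs.members[0].n
    # literal enputs per MC
    from .unfolding import UNKNOWN

    mc_enputs = []
    enputs: set[tuple[int, int]] = set()
    for mc in mcs.members:
        grouped = set()
        for g in mc.groups:
            grouped |= g.members
        lits = {
            (i, int(s))
            for i, s in enumerate(mc.condition)
            if s != UNKNOWN and i not in grouped
        }
        mc_enputs.append(lits)
        enputs |= lits

    counts = {e: 0.0 for e in enputs}
    total = 0.0
    n_used = 0
    if sample is None:
        configs = _enumerate_covered(mcs)
    else:
        m, rng = sample
        configs = sample_covered(mcs, m, rng)
    for c in configs:
        present: set[tuple[int, int]] = set()
        n_cover = 0
        for mc, lits in zip(mcs.members, mc_enputs):
            if mc.matches(c):
                present |= lits
                n_cover += 1
        # under roulette sampling a configuration is drawn proportionally to
        # the number of MCs covering it; the reciprocal weight restores the
        # uniform covered-set measure (weight is 1 when enumerating)
        w = 1.0 if sample is None else 1.0 / n_cover
        total += w
        n_used += 1
        for e in present:
            counts[e] += w
    rows = []
    for (node, state), cnt in sorted(counts.items()):
        p = cnt / total
        rows.append(
            {
                "node": node,
                "state": state,
                "power": p,
                "category": _categorize(p, high_threshold),
            }
        )
    return PowerTable(
        pd.DataFrame(rows),
        estimated=sample is not None,
        m=None if sample is None else n_used,
    )


# ---------------------------------------------------------------------------
# Stochastic disruption
# ---------------------------------------------------------------------------


@dataclass
class PerturbationProtocol:
    node: int
    reference_state: int
    p: float
    T: int = 100
    R: int = 1000
    noise_mode: str = "pin"  # "pin": reference XOR flip; "toggle": flip current
    max_converge: int = 2000

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.T <= 0 or self.R <= 0:
            raise ValueError("T and R must be positive")


@dataclass
class OutcomeDistribution:
    fractions: dict[tuple, float]  # attractor key -> fraction of trials
    unresolved: float
    catalog: list[tuple]  # attractor keys, possibly extended
    labels: dict[tuple, str] = field(default_factory=dict)

    def fraction_of(self, attractor) -> float:
        return self.fractions.get(tuple(attractor), 0.0)


def _attractor_key(net, config, pinned) -> tuple:
    configs, start = trajectory(net, config, pinned)
    cycle = [tuple(int(x) for x in c) for c in configs[start:]]
    i = min(range(len(cycle)), key=lambda j: cycle[j])
    return tuple(cycle[i:] + cycle[:i])


def perturb_and_converge(
    net: BooleanNetwork,
    init: np.ndarray,
    protocol: PerturbationProtocol,
    rng: np.random.Generator,
    catalog: list[tuple] | None = None,
    pinned: dict[int, int] | None = None,
) -> OutcomeDistribution:
    """Run R noisy trials and report the attractor outcome distribution.

    The disrupted node's pin (if any) is released for the trial; remaining
    pins are kept.
    """
    pinned = dict(pinned or {})
    pinned.pop(protocol.node, None)
    init = np.asarray(init, dtype=np.uint8)
    R, T = protocol.R, protocol.T
    S = np.tile(init, (R, 1))
    for t in range(T):
        flips = rng.random(R) < protocol.p
        if protocol.noise_mode == "pin":
            S[:, protocol.node] = protocol.reference_state ^ flips
        elif protocol.noise_mode == "toggle":
            S[flips, protocol.node] ^= 1
        else:
            raise ValueError(f"unknown noise mode {protocol.noise_mode!r}")
        S = step_batch(net, S, pinned)
    # free convergence: batch-iterate to fixed points, fall back per trial
    done = np.zeros(R, dtype=bool)
    keys: list[tuple | None] = [None] * R
    for _ in range(protocol.max_converge):
        S2 = step_batch(net, S, pinned)
        fixed = np.all(S2 == S, axis=1) & ~done
        for i in np.where(fixed)[0]:
            keys[i] = (tuple(int(x) for x in S[i]),)
        done |= fixed
        if done.all():
            break
        S = S2
    unresolved = 0
    for i in np.where(~done)[0]:
        try:
            keys[i] = _attractor_key(net, S[i], pinned)
        except RuntimeError:
            unresolved += 1
    catalog = list(catalog or [])
    fractions: dict[tuple, float] = {}
    for key in keys:
        if key is None:
            continue
        if key not in catalog:
            catalog.append(key)
        fractions[key] = fractions.get(key, 0.0) + 1.0 / R
    return OutcomeDistribution(fractions, unresolved / R, catalog)


def noise_sweep(
    net: BooleanNetwork,
    init: np.ndarray,
    enputs,  # sequence of (node, reference_state)
    p_values=DEFAULT_P_GRID,
    T: int = 100,
    R: int = 1000,
    rng: np.random.Generator | int | None = None,
    catalog: list[tuple] | None = None,
    pinned: dict[int, int] | None = None,
    wild_type: tuple | None = None,
) -> pd.DataFrame:
    """Outcome distributions over a (enput, p) grid, in long format."""
    rng = np.random.default_rng(rng)
    catalog = list(catalog or [])
    rows = []
    for node, ref in enputs:
        for p in p_values:
            proto = PerturbationProtocol(node, ref, p, T=T, R=R)
            dist = perturb_and_converge(
                net, init, proto, rng, catalog, pinned
            )
            catalog = dist.catalog
            for key, frac in sorted(dist.fractions.items()):
                rows.append(
                    {
                        "node": node,
                        "reference_state": ref,
                        "p": p,
                        "attractor": catalog.index(key),
                        "fraction": frac,
                        "is_wild_type": (
                            key == wild_type if wild_type else None
                        ),
                    }
                )
            if dist.unresolved:
                rows.append(
                    {
                        "node": node,
                        "reference_state": ref,
                        "p": p,
                        "attractor": -1,
                        "fraction": dist.unresolved,
                        "is_wild_type": False,
                    }
                )
    return pd.DataFrame(rows)
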