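"""Bipartite cycles and cycle-product principal minors.

The characteristic-polynomial coefficients of the transition matrix H are
signed principal minors, and each principal minor b_q is a sum over all
combinations of pairwise non-overlapping bipartite cycles whose species
lengths add up to q, with a factor -1 for every even-length cycle in the
combination (Sachs' theorem, lifted to the species-reaction graph).  The
bipartite non-overlap rule is stricter than the unipartite one: two cycles
in a combination may share neither a species *nor* a reaction — terms that
reuse a reaction cancel identically under the stoichiometric permutation
sum, so excluding them up front is exact, not an approximation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx
import sympy as sp

from .topology import InfluenceTopology, JacobianEdge, StoichEdge, UnknownSignError

__all__ = [
    "BipartiteCycle",
    "CycleCombination",
    "MinorExpression",
    "enumerate_cycles",
    "nonoverlapping_combinations",
    "principal_minors",
    "minors_from_cycles",
    "combinations_table",
    "MAX_CYCLES",
]

MAX_CYCLES = 10_000


@dataclasses.dataclass(frozen=True)
class BipartiteCycle:
    """An alternating species/reaction cycle.

    ``length`` is the number of species in the cycle (the unipartite cycle
    length); ``weight`` is the signed product of its edge weights.  The
    canonical rotation starts at the lexicographically smallest species.
    """

    species: tuple[str, ...]
    reactions: tuple[str, ...]
    edges: tuple  # alternating JacobianEdge, StoichEdge, ...
    sign: int
    weight: sp.Expr

    @property
    def length(self) -> int:
        return len(self.species)

    @property
    def id(self) -> str:
        return "/".join(
            f"{s}>{r}" for s, r in zip(self.species, self.reactions)
        )

    def __repr__(self):
        return f"BipartiteCycle({self.id}, sign={self.sign:+d}, weight={self.weight})"


@dataclasses.dataclass(frozen=True)
class CycleCombination:
    cycles: tuple[BipartiteCycle, ...]
    coefficient: int  # (-1)**(number of even-length member cycles)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.cycles)

    @property
    def value(self) -> sp.Expr:
        out = sp.Integer(self.coefficient)
        for c in self.cycles:
            out *= c.weight
        return out


@dataclasses.dataclass(frozen=True)
class MinorExpression:
    """Principal minor b_q as a signed sum of non-overlapping cycle products."""

    q: int
    terms: tuple[CycleCombination, ...]
    value: sp.Expr


def enumerate_cycles(topology: InfluenceTopology) -> list[BipartiteCycle]:
    """All simple directed cycles of the bipartite graph, canonically rotated.

    Uses Johnson's simple-cycle enumeration on the species/reaction digraph;
    alternation is automatic because edges only run species -> reaction ->
    species.  Clamped species and orphan reactions cannot carry dynamical
    feedback and are excluded.  Deterministic order: by species length, then
    lexicographically by the canonical node sequence.
    """
    if topology.unknown_sign_edges:
        raise UnknownSignError("expand sign assignments before enumerating cycles")
    clamped = {s.id for s in topology.species if s.clamped}
    orphans = topology.orphan_reaction_ids
    G = nx.DiGraph()
    jac_lookup: dict[tuple[str, str], JacobianEdge] = {}
    sto_lookup: dict[tuple[str, str], StoichEdge] = {}
    for e in topology.jac_edges:
        if e.species in clamped:
            continue
        G.add_edge(("x", e.species), ("v", e.reaction))
        jac_lookup[(e.species, e.reaction)] = e
    for e in topology.stoich_edges:
        if e.reaction in orphans or e.species in clamped:
            continue
        G.add_edge(("v", e.reaction), ("x", e.species))
        sto_lookup[(e.reaction, e.species)] = e
    cycles: list[BipartiteCycle] = []
    for nodes in nx.simple_cycles(G):
        if len(cycles) >= MAX_CYCLES:
            raise TopologyOverflowError(
                f"more than {MAX_CYCLES} bipartite cycles; refusing enumeration"
            )
        # rotate so the lexicographically smallest species comes first
        sp_positions = [i for i, (kind, _) in enumerate(nodes) if kind == "x"]
        start = min(sp_positions, key=lambda i: nodes[i][1])
        nodes = nodes[start:] + nodes[:start]
        species = tuple(name for kind, name in nodes if kind == "x")
        reactions = tuple(name for kind, name in nodes if kind == "v")
        edges = []
        for s, r in zip(species, reactions):
            edges.append(jac_lookup[(s, r)])
        # stoich edge r_i -> species_{i+1}
        for i, r in enumerate(reactions):
            tgt = species[(i + 1) % len(species)]
            edges.insert(2 * i + 1, sto_lookup[(r, tgt)])
        sign = 1
        weight = sp.Integer(1)
        for e in edges:
            sign *= e.sign
            weight *= e.weight
        cycles.append(
            BipartiteCycle(species, reactions, tuple(edges), sign, sign * weight)
        )
    cycles.sort(key=lambda c: (c.length, c.species, c.reactions))
    return cycles


class TopologyOverflowError(RuntimeError):
    """Cycle count beyond the supported desk scale."""


def nonoverlapping_combinations(
    cycles: Sequence[BipartiteCycle], q: int
) -> list[CycleCombination]:
    """All species- and reaction-disjoint cycle subsets of total length q.

    q = 0 yields the single empty combination with coefficient +1 (b_0 = 1).
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if len(cycles) > MAX_CYCLES:
        raise TopologyOverflowError("too many cycles for combination search")
    out: list[CycleCombination] = []

    def recurse(start: int, used_sp: frozenset, used_rx: frozenset, chosen: tuple, remaining: int):
        if remaining == 0:
            coeff = (-1) ** sum(1 for c in chosen if c.length % 2 == 0)
            out.append(CycleCombination(chosen, coeff))
            return
        for i in range(start, len(cycles)):
            c = cycles[i]
            if c.length > remaining:
                continue
            csp, crx = frozenset(c.species), frozenset(c.reactions)
            if used_sp & csp or used_rx & crx:
                continue
            recurse(i + 1, used_sp | csp, used_rx | crx, chosen + (c,), remaining - c.length)

    recurse(0, frozenset(), frozenset(), (), q)
    return out


def minors_from_cycles(cycles: Sequence[BipartiteCycle], n: int) -> list[MinorExpression]:
    """b_0 .. b_n from an explicit cycle list (used for reduced topologies too)."""
    minors = []
    for q in range(n + 1):
        terms = tuple(nonoverlapping_combinations(cycles, q))
        value = sp.expand(sum((t.value for t in terms), sp.Integer(0)))
        minors.append(MinorExpression(q, terms, value))
    return minors


def principal_minors(topology: InfluenceTopology) -> list[MinorExpression]:
    """Principal minors b_0 .. b_n of H as signed non-overlapping cycle sums."""
    return minors_from_cycles(enumerate_cycles(topology), topology.n)


def combinations_table(minors: Iterable[MinorExpression]):
    """Per-q table of contributing cycle combinations (report writer)."""
    import pandas as pd

    rows = []
    for minor in minors:
        for t in minor.terms:
            rows.append(
                {
                    "q": minor.q,
                    "cycles": " * ".join(c.id for c in t.cycles) or "(empty)",
                    "coefficient": t.coefficient,
                    "monomial": str(sp.expand(t.value)),
                }
            )
    return pd.DataFrame(rows, columns=["q", "cycles", "coefficient", "monomial"])
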