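"""Network decomposition: special nodes, upstream/downstream levels,
and node-sign canonicalization.

A general network splits into strongly connected components of its
bipartite graph.  Components containing at least one cycle ("levels") are
analyzed upstream-first: an upstream level that settles to a steady value
acts like a constant (orphan-reaction-like) input to the next level, which
can then be treated as an asymptotically autonomous subnetwork.  If an
upstream level is unstable or oscillatory, downstream levels are driven and
no longer autonomous — first-order steady-state analysis does not apply to
them and they are flagged instead of analyzed.

Sign canonicalization exploits the node-negation degeneracy: substituting
x -> -x (or v -> -v) negates every edge at that node but preserves the sign
of every cycle, hence all principal minors and Hurwitz determinants.  Two
topologies differing only by node negations are the same stability problem;
the canonical form is the orbit-minimal sign vector.
"""

from __future__ import annotations

import dataclasses
import itertools
import networkx as nx
import sympy as sp

from .cycles import enumerate_cycles, minors_from_cycles
from .hurwitz import charpoly_coefficients, count_unstable_roots, hurwitz_determinants
from .topology import InfluenceTopology, JacobianEdge, StoichEdge, UnknownSignError

__all__ = [
    "NodeClassification",
    "Level",
    "LevelDecomposition",
    "CanonicalForm",
    "classify_special_nodes",
    "level_decomposition",
    "canonical_sign_form",
    "EXHAUSTIVE_CANONICAL_LIMIT",
]

EXHAUSTIVE_CANONICAL_LIMIT = 16  # nodes; beyond this a greedy fixpoint is used


@dataclasses.dataclass(frozen=True)
class NodeClassification:
    orphan_species: tuple[str, ...]  # no reaction parent (incl. clamped)
    childless_species: tuple[str, ...]  # feed no reaction (bookkeeping only)
    orphan_reactions: tuple[str, ...]  # no species parent (constant inputs)
    childless_reactions: tuple[str, ...]  # no species child (no dynamical effect)


def classify_special_nodes(topology: InfluenceTopology) -> NodeClassification:
    has_parent = {e.species for e in topology.stoich_edges}
    has_child = {e.species for e in topology.jac_edges}
    rx_parent = {e.reaction for e in topology.jac_edges}
    rx_child = {e.reaction for e in topology.stoich_edges}
    orphan_sp = tuple(
        s.id for s in topology.species if s.clamped or s.id not in has_parent
    )
    childless_sp = tuple(s.id for s in topology.species if s.id not in has_child)
    orphan_rx = tuple(r.id for r in topology.reactions if r.id not in rx_parent)
    childless_rx = tuple(r.id for r in topology.reactions if r.id not in rx_child)
    return NodeClassification(orphan_sp, childless_sp, orphan_rx, childless_rx)


@dataclasses.dataclass(frozen=True)
class Level:
    index: int
    depth: int  # 1 = most upstream; equal depths run in parallel
    species: tuple[str, ...]
    reactions: tuple[str, ...]
    subtopology: InfluenceTopology
    verdict: str  # stable / unstable(k=..) / indeterminate / symbolic
    autonomous: bool


@dataclasses.dataclass(frozen=True)
class LevelDecomposition:
    levels: tuple[Level, ...]
    dag_edges: tuple[tuple[int, int], ...]  # influence between level indices
    acyclic_remainder: tuple[str, ...]  # node ids in no cycle


def _bipartite_digraph(topology: InfluenceTopology) -> nx.DiGraph:
    G = nx.DiGraph()
    clamped = {s.id for s in topology.species if s.clamped}
    for s in topology.species:
        G.add_node(("x", s.id))
    for r in topology.reactions:
        G.add_node(("v", r.id))
    for e in topology.jac_edges:
        if e.species not in clamped:
            G.add_edge(("x", e.species), ("v", e.reaction))
    for e in topology.stoich_edges:
        G.add_edge(("v", e.reaction), ("x", e.species))
    return G


def _level_subtopology(topology: InfluenceTopology, species: set, reactions: set) -> InfluenceTopology:
    sp_nodes = tuple(s for s in topology.species if s.id in species)
    rx_nodes = tuple(r for r in topology.reactions if r.id in reactions)
    jac = tuple(
        e for e in topology.jac_edges if e.species in species and e.reaction in reactions
    )
    sto = tuple(
        e for e in topology.stoich_edges if e.species in species and e.reaction in reactions
    )
    return InfluenceTopology(sp_nodes, rx_nodes, jac, sto)


def _level_verdict(sub: InfluenceTopology) -> str:
    minors = minors_from_cycles(enumerate_cycles(sub), sub.n)
    coeffs = charpoly_coefficients(minors)
    deltas = hurwitz_determinants(coeffs).deltas
    signs: list[int] = []
    for d in deltas:
        if d.is_zero:
            signs.append(0)
        elif d.is_positive:
            signs.append(1)
        elif d.is_negative:
            signs.append(-1)
        else:
            return "symbolic (instantiate weights for a verdict)"
    try:
        rc = count_unstable_roots(1, signs)
    except ValueError:
        return "degenerate"
    if rc.indeterminate:
        return "indeterminate at first order"
    return "stable" if rc.k == 0 else f"unstable (k={rc.k})"


def level_decomposition(topology: InfluenceTopology) -> LevelDecomposition:
    """Partition into topologically ordered cycle-containing levels.

    Levels are the strongly connected components of the bipartite digraph
    that contain at least one cycle; they are reported upstream-first, with
    parallel (incomparable) levels at equal depth.  Downstream levels whose
    upstream levels are not verifiably stable are flagged non-autonomous:
    driven dynamics are outside first-order steady-state analysis.
    """
    if topology.unknown_sign_edges:
        raise UnknownSignError("expand sign assignments before decomposition")
    G = _bipartite_digraph(topology)
    sccs = [scc for scc in nx.strongly_connected_components(G)]
    cond = nx.condensation(G, scc=sccs)
    # map condensation node -> member scc
    members = {i: scc for i, scc in enumerate(sccs)}
    cyclic_ids = {i for i, scc in members.items() if len(scc) >= 2}
    # depth: 1 + longest chain of upstream cyclic components
    depth: dict[int, int] = {}
    for i in nx.topological_sort(cond):
        if i in cyclic_ids:
            depth[i] = 1 + max(
                (depth[a] for a in nx.ancestors(cond, i) if a in cyclic_ids),
                default=0,
            )
    levels: list[Level] = []
    cyclic_sorted = sorted(cyclic_ids, key=lambda i: (depth[i], sorted(members[i])[0]))
    index_of: dict[int, int] = {}
    for idx, ci in enumerate(cyclic_sorted):
        scc = members[ci]
        species = {name for kind, name in scc if kind == "x"}
        reactions = {name for kind, name in scc if kind == "v"}
        sub = _level_subtopology(topology, species, reactions)
        verdict = _level_verdict(sub)
        ancestors = nx.ancestors(cond, ci)
        driven = any(a in index_of for a in ancestors if a in cyclic_ids)
        autonomous = True
        if driven:
            unstable_upstream = any(
                not levels[index_of[a]].verdict.startswith("stable")
                for a in ancestors
                if a in index_of
            )
            autonomous = not unstable_upstream
        if not autonomous:
            verdict = "non-autonomous - out of scope of first-order analysis"
        levels.append(
            Level(
                idx,
                depth[ci],
                tuple(sorted(species)),
                tuple(sorted(reactions)),
                sub,
                verdict,
                autonomous,
            )
        )
        index_of[ci] = idx
    dag_edges = []
    for a in cyclic_sorted:
        for b in cyclic_sorted:
            if a != b and b in nx.descendants(cond, a):
                dag_edges.append((index_of[a], index_of[b]))
    acyclic = tuple(
        sorted(name for scc in sccs if len(scc) == 1 for kind, name in scc)
    )
    return LevelDecomposition(tuple(levels), tuple(sorted(set(dag_edges))), acyclic)


# ---------------------------------------------------------------------------
# sign canonicalization

@dataclasses.dataclass(frozen=True)
class CanonicalForm:
    topology: InfluenceTopology
    negated_nodes: tuple[str, ...]


def _edge_order(topology: InfluenceTopology) -> list:
    jac = sorted(topology.jac_edges, key=lambda e: (e.species, e.reaction))
    sto = sorted(topology.stoich_edges, key=lambda e: (e.reaction, e.species))
    return jac + sto


def canonical_sign_form(topology: InfluenceTopology) -> CanonicalForm:
    """Orbit-minimal sign assignment under node negations.

    The edge-sign vector is read in canonical order (Jacobian edges sorted
    by (species, reaction), then stoichiometric edges by (reaction,
    species)); '+' sorts before '-'.  For up to 16 nodes the minimum over
    all 2^(n+m) negation subsets is taken exactly (negations form a linear
    group over GF(2)); beyond that a greedy sweep to fixpoint is used, which
    is deterministic but not guaranteed orbit-minimal.  Cycle signs — and
    therefore all minors and determinants — are preserved by construction.
    """
    if topology.unknown_sign_edges:
        raise UnknownSignError("expand sign assignments before canonicalization")
    edges = _edge_order(topology)
    nodes = [("x", s.id) for s in sorted(topology.species, key=lambda s: s.id)]
    nodes += [("v", r.id) for r in sorted(topology.reactions, key=lambda r: r.id)]
    nbits = len(edges)
    base = 0
    for i, e in enumerate(edges):
        if e.sign < 0:
            base |= 1 << (nbits - 1 - i)
    masks = []
    for kind, name in nodes:
        mask = 0
        for i, e in enumerate(edges):
            touches = (
                (isinstance(e, JacobianEdge) and ((kind == "x" and e.species == name) or (kind == "v" and e.reaction == name)))
                or (isinstance(e, StoichEdge) and ((kind == "x" and e.species == name) or (kind == "v" and e.reaction == name)))
            )
            if touches:
                mask |= 1 << (nbits - 1 - i)
        masks.append(mask)
    if len(nodes) <= EXHAUSTIVE_CANONICAL_LIMIT:
        best = base
        best_subset: tuple[int, ...] = ()
        for r in range(len(nodes) + 1):
            for subset in itertools.combinations(range(len(nodes)), r):
                vec = base
                for i in subset:
                    vec ^= masks[i]
                if vec < best or (vec == best and (len(subset), subset) < (len(best_subset), best_subset)):
                    best, best_subset = vec, subset
        chosen = best_subset
        vec = best
    else:
        vec = base
        chosen_set: set[int] = set()
        changed = True
        while changed:
            changed = False
            for i in range(len(nodes)):
                cand = vec ^ masks[i]
                if cand < vec:
                    vec = cand
                    chosen_set.symmetric_difference_update({i})
                    changed = True
        chosen = tuple(sorted(chosen_set))
    new_signs = {}
    for i, e in enumerate(edges):
        bit = (vec >> (nbits - 1 - i)) & 1
        new_signs[e.key] = -1 if bit else 1
    jac = tuple(
        dataclasses.replace(e, sign=new_signs[e.key]) for e in topology.jac_edges
    )
    sto = tuple(
        dataclasses.replace(e, sign=new_signs[e.key]) for e in topology.stoich_edges
    )
    canon = topology.replace_edges(jac_edges=jac, stoich_edges=sto)
    negated = tuple(nodes[i][1] for i in chosen)
    return CanonicalForm(canon, negated)
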