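"""Parameter reduction of the influence topology.

Three exact reductions shrink the S + J edge weights that a priori govern
steady-state stability down to a handful of parameters:

1. *Stoichiometric scaling* — each reaction is rescaled so one of its
   stoichiometric outputs is +-1 (the factor moves into the reaction's
   Jacobian edges).  Which output is chosen matters for the final count, so
   by default every per-reaction selection is tried and the one minimizing
   the final dimensionality is kept (deterministic lexicographic
   tie-break).
2. *Cycle compaction* — the Hurwitz determinants depend on edge weights only
   through bipartite cycle products, so all edges sharing exactly the same
   cycle-membership pattern ("barcode") collapse into one parameter.
3. *Temporal scaling* — time is rescaled by beta = |q_0|^(1/z) for a chosen
   compaction group containing z >= 1 Jacobian edges, dividing every
   eigenvalue by beta > 0 and removing one more degree of freedom without
   touching stability.

The surviving parameters rho_1..rho_d are strictly positive by convention:
sign information lives entirely in the topology, and each sign pattern is a
distinct influence topology.  Final dimensionality: d = (S - m) + J - c - 1
with c the dimensions removed by compaction.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import sympy as sp

from .cycles import (
    BipartiteCycle,
    MinorExpression,
    enumerate_cycles,
    minors_from_cycles,
)
from .hurwitz import (
    CharPolyCoeffs,
    HurwitzResult,
    charpoly_coefficients,
    hurwitz_determinants,
)
from .topology import InfluenceTopology, JacobianEdge, StoichEdge, TopologyError

__all__ = [
    "ScaledTopology",
    "EdgeGroup",
    "CompactionResult",
    "ReducedTopology",
    "SymmetryReport",
    "stoichiometric_scaling",
    "cycle_compaction",
    "temporal_scaling",
    "reduce_topology",
    "reduced_dimension",
    "detect_exchange_symmetries",
]

MAX_SCALING_COMBINATIONS = 100_000


def _is_one(expr: sp.Expr) -> bool:
    expr = sp.cancel(expr)
    return expr == 1


@dataclasses.dataclass(frozen=True)
class ScaledTopology:
    """Topology after stoichiometric scaling (one unit output per reaction)."""

    base: InfluenceTopology
    alpha: Mapping[str, sp.Expr]  # reaction -> original magnitude of the unit edge
    choice: Mapping[str, str]  # reaction -> species of the chosen output
    sigma_params: tuple[sp.Symbol, ...]
    r_params: tuple[sp.Symbol, ...]


@dataclasses.dataclass(frozen=True)
class EdgeGroup:
    """Edges sharing an identical cycle-membership barcode."""

    barcode: tuple[int, ...]
    edges: tuple
    sign: int
    magnitude: sp.Expr  # positive product of member magnitudes
    z: int  # number of Jacobian edges in the group
    symbol: sp.Symbol | None  # compaction parameter; None for a fixed +-1 group

    @property
    def keys(self) -> tuple[tuple, ...]:
        return tuple(e.key for e in self.edges)


@dataclasses.dataclass(frozen=True)
class CompactionResult:
    topology: InfluenceTopology
    cycles: tuple[BipartiteCycle, ...]
    groups: tuple[EdgeGroup, ...]
    q_params: tuple[sp.Symbol, ...]
    definitions: Mapping[sp.Symbol, sp.Expr]  # q symbol -> magnitude over edge weights
    reduced_cycles: tuple[sp.Expr, ...]  # cycle weights over the q symbols
    c: int  # dimensions removed

    @property
    def parameter_groups(self) -> tuple[EdgeGroup, ...]:
        return tuple(g for g in self.groups if g.symbol is not None)


@dataclasses.dataclass(frozen=True)
class ReducedTopology:
    """Fully reduced parametrization of a stability phase space."""

    base: InfluenceTopology
    compaction: CompactionResult
    cycles: tuple[BipartiteCycle, ...]  # weights over rho/sigma symbols
    rho_params: tuple[sp.Symbol, ...]  # temporally scaled (Jacobian-bearing)
    sigma_params: tuple[sp.Symbol, ...]  # surviving pure-stoichiometric parameters
    beta: sp.Expr  # temporal scale over the original weights
    scaled_unit: EdgeGroup | None  # the group set to +-1
    d: int
    definitions: Mapping[sp.Symbol, sp.Expr]  # each parameter over original weights

    @property
    def params(self) -> tuple[sp.Symbol, ...]:
        return self.rho_params + self.sigma_params

    @property
    def n(self) -> int:
        return self.base.n

    def minors(self) -> list[MinorExpression]:
        return minors_from_cycles(self.cycles, self.n)

    def charpoly(self) -> CharPolyCoeffs:
        return charpoly_coefficients(self.minors())

    def hurwitz(self) -> HurwitzResult:
        return hurwitz_determinants(self.charpoly())

    def parameter_values(self, weight_subs: Mapping) -> dict[sp.Symbol, sp.Expr]:
        """Numeric values of the reduced parameters for given edge weights."""
        subs = {sp.Symbol(str(k), positive=True): sp.sympify(v) for k, v in weight_subs.items()}
        return {p: sp.cancel(self.definitions[p].subs(subs)) for p in self.params}


@dataclasses.dataclass(frozen=True)
class SymmetryReport:
    """Parameter permutations leaving every principal minor invariant."""

    params: tuple[sp.Symbol, ...]
    permutations: tuple[tuple[int, ...], ...]  # non-identity, as index maps
    psi_candidates: tuple[sp.Expr, ...]  # symmetric aggregates over the orbits


# ---------------------------------------------------------------------------
# stoichiometric scaling

def _apply_choice(topology: InfluenceTopology, choice: Mapping[str, str]) -> ScaledTopology:
    alpha: dict[str, sp.Expr] = {}
    new_sto: list[StoichEdge] = []
    new_jac: list[JacobianEdge] = list(topology.jac_edges)
    orphans = topology.orphan_reaction_ids
    for e in topology.stoich_edges:
        if e.reaction in orphans:
            new_sto.append(e)
            continue
        a = alpha.setdefault(e.reaction, None)
        new_sto.append(e)
    for rx, sid in choice.items():
        edges = [e for e in topology.stoich_of_reaction(rx)]
        chosen = [e for e in edges if e.species == sid]
        if not chosen:
            raise TopologyError(f"reaction {rx!r} has no output to species {sid!r}")
        alpha[rx] = chosen[0].weight
    sto_out: list[StoichEdge] = []
    for e in new_sto:
        a = alpha.get(e.reaction)
        if a is None or e.reaction in orphans:
            sto_out.append(e)
        elif e.species == choice[e.reaction]:
            sto_out.append(dataclasses.replace(e, weight=sp.Integer(1)))
        else:
            sto_out.append(dataclasses.replace(e, weight=sp.cancel(e.weight / a)))
    jac_out: list[JacobianEdge] = []
    for e in new_jac:
        a = alpha.get(e.reaction)
        if a is None or a == 1:
            jac_out.append(e)
        else:
            jac_out.append(dataclasses.replace(e, weight=sp.cancel(a * e.weight)))
    base = topology.replace_edges(jac_edges=tuple(jac_out), stoich_edges=tuple(sto_out))
    sigma = tuple(sorted({s for e in sto_out if e.reaction not in orphans for s in e.weight.free_symbols}, key=str))
    rpar = tuple(sorted({s for e in jac_out for s in e.weight.free_symbols}, key=str))
    return ScaledTopology(base, dict(alpha), dict(choice), sigma, rpar)


def _selection_dimension(scaled: ScaledTopology) -> int:
    comp = cycle_compaction(scaled)
    has_temporal = any(g.z >= 1 for g in comp.parameter_groups)
    return len(comp.parameter_groups) - (1 if has_temporal else 0)


def stoichiometric_scaling(
    topology: InfluenceTopology, choice: Mapping[str, str] | None = None
) -> ScaledTopology:
    """Set one stoichiometric edge per reaction to +-1.

    With an explicit ``choice`` (reaction id -> output species id) that
    selection is applied.  Otherwise every per-reaction selection is tried
    and the one minimizing the post-compaction dimensionality d is kept;
    ties break lexicographically over (reaction order, output species id).
    """
    orphans = topology.orphan_reaction_ids
    reactions = [r.id for r in topology.reactions if not r.is_orphan]
    if choice is not None:
        full = {}
        for rx in reactions:
            if rx in choice:
                full[rx] = choice[rx]
            else:
                full[rx] = sorted(e.species for e in topology.stoich_of_reaction(rx))[0]
        return _apply_choice(topology, full)
    options = [sorted(e.species for e in topology.stoich_of_reaction(rx)) for rx in reactions]
    total = 1
    for opts in options:
        total *= len(opts)
    if total > MAX_SCALING_COMBINATIONS:
        raise TopologyError(
            f"{total} stoichiometric scaling selections exceed the search guard; "
            "pass an explicit choice"
        )
    best = None
    best_d = None
    for combo in itertools.product(*options):
        cand = _apply_choice(topology, dict(zip(reactions, combo)))
        d = _selection_dimension(cand)
        if best_d is None or d < best_d:
            best, best_d = cand, d
    return best


# ---------------------------------------------------------------------------
# cycle compaction

def cycle_compaction(scaled: ScaledTopology | InfluenceTopology) -> CompactionResult:
    """Group edges by identical cycle membership; one parameter per group.

    Exact: every cycle weight re-expressed over the group parameters equals
    its original edge product.  Acyclic topologies yield an empty result
    with c = 0.
    """
    top = scaled.base if isinstance(scaled, ScaledTopology) else scaled
    cycles = tuple(enumerate_cycles(top))
    orphans = top.orphan_reaction_ids
    all_edges = {e.key: e for e in top.jac_edges}
    all_edges.update({e.key: e for e in top.stoich_edges if e.reaction not in orphans})
    if not cycles:
        n_free = sum(1 for e in all_edges.values() if not _is_one(e.weight))
        return CompactionResult(top, (), (), (), {}, (), c=n_free)
    barcode: dict[tuple, set[int]] = {}
    for i, cyc in enumerate(cycles):
        for e in cyc.edges:
            barcode.setdefault(e.key, set()).add(i)
    by_code: dict[tuple[int, ...], list] = {}
    for key, members in barcode.items():
        by_code.setdefault(tuple(sorted(members)), []).append(all_edges[key])
    groups: list[EdgeGroup] = []
    definitions: dict[sp.Symbol, sp.Expr] = {}
    q_params: list[sp.Symbol] = []
    counter = 0
    for code in sorted(by_code):
        edges = tuple(sorted(by_code[code], key=lambda e: e.key))
        sign = 1
        mag = sp.Integer(1)
        z = 0
        for e in edges:
            sign *= e.sign
            mag *= e.weight
            z += isinstance(e, JacobianEdge)
        mag = sp.cancel(mag)
        if _is_one(mag):
            groups.append(EdgeGroup(code, edges, sign, sp.Integer(1), z, None))
        else:
            sym = sp.Symbol(f"q{counter}", positive=True)
            counter += 1
            groups.append(EdgeGroup(code, edges, sign, mag, z, sym))
            definitions[sym] = mag
            q_params.append(sym)
    reduced_cycles = []
    for i in range(len(cycles)):
        expr = sp.Integer(1)
        for g in groups:
            if i in g.barcode:
                expr *= g.sign * (g.symbol if g.symbol is not None else 1)
        reduced_cycles.append(expr)
    n_free = sum(1 for e in all_edges.values() if not _is_one(e.weight))
    c = n_free - len(q_params)
    return CompactionResult(
        top, cycles, tuple(groups), tuple(q_params), definitions, tuple(reduced_cycles), c
    )


# ---------------------------------------------------------------------------
# temporal scaling

def _find_group(compacted: CompactionResult, spec) -> EdgeGroup:
    if isinstance(spec, EdgeGroup):
        return spec
    for g in compacted.groups:
        if isinstance(spec, sp.Symbol) and g.symbol == spec:
            return g
        if isinstance(spec, tuple) and spec in g.keys:
            return g
    raise TopologyError(f"no compaction group matches {spec!r}")


def temporal_scaling(
    compacted: CompactionResult,
    unit=None,
    names: Mapping[tuple, str] | None = None,
) -> ReducedTopology:
    """Rescale time by the chosen compaction group, removing one parameter.

    ``unit`` selects the temporal group (an :class:`EdgeGroup`, its q
    symbol, or any member edge key); it must contain at least one Jacobian
    edge.  By default the parameter group holding a Jacobian edge with the
    lexicographically smallest barcode is used — the choice is arbitrary and
    only reparametrizes the same phase space.  ``names`` optionally maps a
    member edge key to the desired parameter name (e.g. to match a
    published figure's rho numbering).
    """
    names = dict(names or {})
    groups = compacted.groups
    param_groups = [g for g in groups if g.symbol is not None]
    unit_group: EdgeGroup | None
    if unit is not None:
        unit_group = _find_group(compacted, unit)
        if unit_group.z < 1:
            raise TopologyError("temporal unit must contain at least one Jacobian edge")
    else:
        candidates = [g for g in param_groups if g.z >= 1]
        unit_group = min(candidates, key=lambda g: g.barcode) if candidates else None
    beta = (
        unit_group.magnitude ** sp.Rational(1, unit_group.z)
        if unit_group is not None
        else sp.Integer(1)
    )

    def requested_name(g: EdgeGroup) -> str | None:
        for key in g.keys:
            if key in names:
                return names[key]
        return None

    rep: dict[tuple[int, ...], sp.Expr] = {}
    definitions: dict[sp.Symbol, sp.Expr] = {}
    rho: list[sp.Symbol] = []
    sigma: list[sp.Symbol] = []
    auto = itertools.count(1)
    for g in sorted(groups, key=lambda g: g.barcode):
        scaled_mag = sp.cancel(g.magnitude / beta**g.z) if g.z else g.magnitude
        if scaled_mag.is_number:
            rep[g.barcode] = g.sign * scaled_mag
            continue
        name = requested_name(g)
        if g.z >= 1:
            sym = sp.Symbol(name or f"rho{next(auto)}", positive=True)
            rho.append(sym)
        else:
            if name is None and isinstance(scaled_mag, sp.Symbol):
                sym = scaled_mag
            else:
                sym = sp.Symbol(name or f"q{next(auto)}", positive=True)
            sigma.append(sym)
        definitions[sym] = scaled_mag
        rep[g.barcode] = g.sign * sym
    reduced_cycles = []
    for i, cyc in enumerate(compacted.cycles):
        expr = sp.Integer(1)
        for g in groups:
            if i in g.barcode:
                expr *= rep[g.barcode]
        reduced_cycles.append(
            BipartiteCycle(cyc.species, cyc.reactions, cyc.edges, cyc.sign, sp.expand(expr))
        )
    d = len(rho) + len(sigma)
    return ReducedTopology(
        base=compacted.topology,
        compaction=compacted,
        cycles=tuple(reduced_cycles),
        rho_params=tuple(rho),
        sigma_params=tuple(sigma),
        beta=beta,
        scaled_unit=unit_group,
        d=d,
        definitions=definitions,
    )


def reduce_topology(
    topology: InfluenceTopology,
    choice: Mapping[str, str] | None = None,
    unit=None,
    names: Mapping[tuple, str] | None = None,
) -> ReducedTopology:
    """Full reduction pipeline: scaling, compaction, temporal scaling."""
    scaled = stoichiometric_scaling(topology, choice)
    return temporal_scaling(cycle_compaction(scaled), unit=unit, names=names)


def reduced_dimension(topology: InfluenceTopology) -> int:
    """Final stability-phase-space dimensionality d = (S - m) + J - c - 1
    under the best stoichiometric-scaling choice."""
    return reduce_topology(topology).d


# ---------------------------------------------------------------------------
# exchange symmetries

def detect_exchange_symmetries(
    minors: Sequence[MinorExpression], params: Sequence[sp.Symbol]
) -> SymmetryReport:
    """Parameter permutations under which every principal minor is invariant.

    Checks all permutations for up to 6 parameters (beyond that, the group
    generated by invariant transpositions).  Each reported permutation is
    verified by simultaneous substitution.  Orbits of size >= 2 suggest
    symmetric aggregates Psi (sums over the orbit).
    """
    params = tuple(params)
    exprs = [
        sp.expand(m.value if isinstance(m, MinorExpression) else sp.sympify(m))
        for m in minors
    ]
    k = len(params)

    def invariant(perm: tuple[int, ...]) -> bool:
        mapping = {params[i]: params[perm[i]] for i in range(k)}
        return all(sp.expand(e.subs(mapping, simultaneous=True) - e) == 0 for e in exprs)

    identity = tuple(range(k))
    found: set[tuple[int, ...]] = set()
    if k <= 6:
        for perm in itertools.permutations(range(k)):
            if perm != identity and invariant(perm):
                found.add(perm)
    else:
        gens = []
        for i, j in itertools.combinations(range(k), 2):
            perm = list(identity)
            perm[i], perm[j] = perm[j], perm[i]
            if invariant(tuple(perm)):
                gens.append(tuple(perm))
        frontier = set(gens)
        found = set(gens)
        while frontier:
            new = set()
            for p in frontier:
                for g in gens:
                    comp = tuple(p[g[i]] for i in range(k))
                    if comp != identity and comp not in found:
                        new.add(comp)
            found |= new
            frontier = new
    # orbits under the found permutations
    parent = list(range(k))

    def root(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for perm in found:
        for i in range(k):
            ri, rj = root(i), root(perm[i])
            if ri != rj:
                parent[ri] = rj
    orbits: dict[int, list[int]] = {}
    for i in range(k):
        orbits.setdefault(root(i), []).append(i)
    psi = tuple(
        sum((params[i] for i in orbit), sp.Integer(0))
        for orbit in orbits.values()
        if len(orbit) >= 2
    )
    return SymmetryReport(params, tuple(sorted(found)), psi)
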