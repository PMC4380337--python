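"""Domain model of the influence topology.

The influence topology (also called the directed species-reaction, DSR,
graph) of a dynamical system ``dx_j/dt = sum_k v_k(x) s_jk`` is a signed
directed bipartite graph with two node classes:

* species nodes ``x_i``, and
* reaction nodes ``v_k``.

Edges run species -> reaction (Jacobian edges, carrying the sign and
magnitude of the monotonic dependence ``dv_k/dx_i`` at the steady state
under study) and reaction -> species (stoichiometric edges, carrying the
signed scalar ``s_jk``).  Near a steady state the linearized dynamics are
governed by the transition matrix ``H = R.S`` whose entry ``H_ij`` sums, over
reactions, the product of the Jacobian edge ``i -> k`` and the
stoichiometric edge ``k -> j``.  Everything downstream (cycles, principal
minors, Hurwitz determinants) is computed from this graph.

Sign alphabet: ``+1``, ``-1``, or ``None`` for an unknown monotonicity
(rendered ``?``).  A *single* influence topology is fixed-sign; graphs with
unknown signs stand for the collection obtained by
:func:`expand_sign_assignments`, and all downstream mathematics refuses
unknown signs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import re
from fractions import Fraction
from typing import Mapping, Sequence

import sympy as sp

__all__ = [
    "SpeciesNode",
    "ReactionNode",
    "JacobianEdge",
    "StoichEdge",
    "InfluenceTopology",
    "TransitionMatrix",
    "TopologyError",
    "SchemaError",
    "UnknownSignError",
    "build_topology",
    "expand_sign_assignments",
    "assemble_transition_matrix",
    "load_topology",
    "save_topology",
    "to_dot",
]

SCHEMA = "influence-topology/1"


class TopologyError(ValueError):
    """Invalid influence-topology structure."""


class SchemaError(TopologyError):
    """Malformed serialized document."""


class UnknownSignError(TopologyError):
    """An operation requiring fixed signs met an unknown-sign edge."""


@dataclasses.dataclass(frozen=True)
class SpeciesNode:
    id: str
    clamped: bool = False


@dataclasses.dataclass(frozen=True)
class ReactionNode:
    id: str
    is_orphan: bool = False


@dataclasses.dataclass(frozen=True)
class JacobianEdge:
    """Monotonic dependence of a reaction on a species (dv_k/dx_i)."""

    species: str
    reaction: str
    sign: int | None
    weight: sp.Expr  # strictly positive magnitude (numeric or symbolic)

    @property
    def key(self) -> tuple:
        return ("J", self.species, self.reaction)

    @property
    def signed_weight(self) -> sp.Expr:
        if self.sign is None:
            raise UnknownSignError(f"edge {self.key} has unknown sign")
        return self.sign * self.weight


@dataclasses.dataclass(frozen=True)
class StoichEdge:
    """Signed stoichiometric output of a reaction (s_jk)."""

    reaction: str
    species: str
    sign: int | None
    weight: sp.Expr

    @property
    def key(self) -> tuple:
        return ("S", self.reaction, self.species)

    @property
    def signed_weight(self) -> sp.Expr:
        if self.sign is None:
            raise UnknownSignError(f"edge {self.key} has unknown sign")
        return self.sign * self.weight


def _is_positive_magnitude(w: sp.Expr) -> bool:
    if w.is_number:
        return bool(w > 0)
    return True  # symbolic magnitudes are declared positive at creation


class InfluenceTopology:
    """Validated signed directed bipartite graph of a reaction network.

    ``n`` counts dynamical (non-clamped) species, ``m`` non-orphan
    reactions; ``S`` and ``J`` count stoichiometric and Jacobian edges of
    non-orphan reactions (orphan reactions are constant inputs: they are
    kept for bookkeeping but excluded from all first-order mathematics).
    """

    def __init__(
        self,
        species: Sequence[SpeciesNode],
        reactions: Sequence[ReactionNode],
        jac_edges: Sequence[JacobianEdge],
        stoich_edges: Sequence[StoichEdge],
    ):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.jac_edges = tuple(jac_edges)
        self.stoich_edges = tuple(stoich_edges)
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        sp_ids = [s.id for s in self.species]
        rx_ids = [r.id for r in self.reactions]
        if len(set(sp_ids)) != len(sp_ids):
            raise TopologyError("duplicate species ids")
        if len(set(rx_ids)) != len(rx_ids):
            raise TopologyError("duplicate reaction ids")
        sset, rset = set(sp_ids), set(rx_ids)
        orphans = {r.id for r in self.reactions if r.is_orphan}
        seen = set()
        for e in self.jac_edges:
            if e.species not in sset or e.reaction not in rset:
                raise TopologyError(f"Jacobian edge {e.key} references a missing node")
            if e.reaction in orphans:
                raise TopologyError(f"Jacobian edge into orphan reaction {e.reaction!r}")
            if (e.species, e.reaction) in seen:
                raise TopologyError(f"duplicate Jacobian edge {e.key}")
            seen.add((e.species, e.reaction))
            if e.sign not in (1, -1, None):
                raise TopologyError(f"bad sign on {e.key}")
            if not _is_positive_magnitude(e.weight):
                raise TopologyError(f"non-positive weight on {e.key}")
        seen = set()
        for e in self.stoich_edges:
            if e.species not in sset or e.reaction not in rset:
                raise TopologyError(f"stoichiometric edge {e.key} references a missing node")
            if (e.reaction, e.species) in seen:
                raise TopologyError(f"duplicate stoichiometric edge {e.key}")
            seen.add((e.reaction, e.species))
            if e.sign not in (1, -1, None):
                raise TopologyError(f"bad sign on {e.key}")
            if not _is_positive_magnitude(e.weight):
                raise TopologyError(f"non-positive weight on {e.key}")
        with_out = {e.reaction for e in self.stoich_edges}
        for r in self.reactions:
            if r.id not in with_out:
                raise TopologyError(f"reaction {r.id!r} has no stoichiometric output")

    # -- counts ----------------------------------------------------------
    @property
    def dynamical_species(self) -> tuple[SpeciesNode, ...]:
        return tuple(s for s in self.species if not s.clamped)

    @property
    def orphan_reaction_ids(self) -> frozenset[str]:
        return frozenset(r.id for r in self.reactions if r.is_orphan)

    @property
    def n(self) -> int:
        return len(self.dynamical_species)

    @property
    def m(self) -> int:
        return sum(1 for r in self.reactions if not r.is_orphan)

    @property
    def S(self) -> int:
        orphans = self.orphan_reaction_ids
        return sum(1 for e in self.stoich_edges if e.reaction not in orphans)

    @property
    def J(self) -> int:
        return len(self.jac_edges)

    @property
    def unknown_sign_edges(self) -> tuple:
        return tuple(e for e in (*self.jac_edges, *self.stoich_edges) if e.sign is None)

    @property
    def childless_species(self) -> tuple[str, ...]:
        """Species feeding no reaction: pure bookkeeping nodes."""
        parents = {e.species for e in self.jac_edges}
        return tuple(s.id for s in self.species if s.id not in parents)

    # -- helpers ---------------------------------------------------------
    def jac_of_reaction(self, rx: str) -> tuple[JacobianEdge, ...]:
        return tuple(e for e in self.jac_edges if e.reaction == rx)

    def stoich_of_reaction(self, rx: str) -> tuple[StoichEdge, ...]:
        return tuple(e for e in self.stoich_edges if e.reaction == rx)

    def free_symbols(self) -> set[sp.Symbol]:
        out: set[sp.Symbol] = set()
        for e in (*self.jac_edges, *self.stoich_edges):
            out |= e.weight.free_symbols
        return out

    def with_weights(self, values: Mapping) -> "InfluenceTopology":
        """Substitute numeric values (by symbol or name) into edge weights."""
        subs = {sp.Symbol(str(k), positive=True): sp.sympify(v) for k, v in values.items()}
        jac = tuple(
            dataclasses.replace(e, weight=e.weight.subs(subs)) for e in self.jac_edges
        )
        sto = tuple(
            dataclasses.replace(e, weight=e.weight.subs(subs)) for e in self.stoich_edges
        )
        return self.replace_edges(jac_edges=jac, stoich_edges=sto)

    def replace_edges(self, jac_edges=None, stoich_edges=None) -> "InfluenceTopology":
        return InfluenceTopology(
            self.species,
            self.reactions,
            self.jac_edges if jac_edges is None else jac_edges,
            self.stoich_edges if stoich_edges is None else stoich_edges,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, InfluenceTopology):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and self.jac_edges == other.jac_edges
            and self.stoich_edges == other.stoich_edges
        )

    def __hash__(self):
        return hash((self.species, self.reactions, self.jac_edges, self.stoich_edges))

    def __repr__(self) -> str:
        return (
            f"InfluenceTopology(n={self.n}, m={self.m}, S={self.S}, J={self.J}, "
            f"orphans={sorted(self.orphan_reaction_ids)})"
        )


@dataclasses.dataclass(frozen=True)
class TransitionMatrix:
    """First-order transition matrix H, row i = perturbed (input) species.

    ``H_ij = sum_k (dv_k/dx_i) s_jk``; the row-vector convention means the
    unipartite cycle ``H_12 H_23 H_31`` reads 1 -> 2 -> 3 -> 1.  Spectra are
    transpose-invariant, so stability is unaffected by the convention.
    """

    species: tuple[str, ...]
    matrix: sp.Matrix

    def to_numpy(self):
        import numpy as np

        return np.array(self.matrix.tolist(), dtype=float)


# ---------------------------------------------------------------------------
# construction

_NUM_RE = re.compile(r"^[0-9]+(/[0-9]+)?(\.[0-9]+)?$")


def _default_jac_symbol(species: str, reaction: str) -> sp.Symbol:
    return sp.Symbol(f"r_{species}_{reaction}", positive=True)


def _default_stoich_symbol(reaction: str, species: str) -> sp.Symbol:
    return sp.Symbol(f"s_{reaction}_{species}", positive=True)


def _parse_magnitude(text: str, default: sp.Symbol) -> sp.Expr:
    text = text.strip()
    if not text:
        return default
    if _NUM_RE.match(text):
        mag = sp.Rational(text) if "." not in text else sp.Rational(str(text))
        if mag <= 0:
            raise SchemaError(f"non-positive magnitude {text!r}")
        return mag
    if not re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", text):
        raise SchemaError(f"cannot parse weight token {text!r}")
    return sp.Symbol(text, positive=True)


def _parse_signed(value, default: sp.Symbol, allow_unknown: bool) -> tuple[int | None, sp.Expr]:
    """Parse '+', '-', '?', '+name', '-2', 'sigma1', 3, -1.5 ... -> (sign, magnitude)."""
    if isinstance(value, bool):
        raise SchemaError(f"cannot parse weight {value!r}")
    if isinstance(value, (int, float, Fraction)):
        if value == 0:
            raise SchemaError("zero weight is not an edge")
        sign = 1 if value > 0 else -1
        mag = sp.Rational(str(abs(value))) if isinstance(value, float) else sp.Rational(abs(value))
        return sign, mag
    if not isinstance(value, str):
        raise SchemaError(f"cannot parse weight {value!r}")
    text = value.strip()
    if not text:
        raise SchemaError("empty weight token")
    sign: int | None = 1
    if text[0] in "+-?":
        sign = {"+": 1, "-": -1, "?": None}[text[0]]
        text = text[1:]
    if sign is None and not allow_unknown:
        raise SchemaError("'?' sign is not allowed here")
    return sign, _parse_magnitude(text, default)


def build_topology(spec: Mapping) -> InfluenceTopology:
    """Build a validated influence topology from a network description.

    ``spec`` is a mapping with keys ``species`` (list of ids or
    ``{"id", "clamped"}`` mappings) and ``reactions`` (list of
    ``{"id", "inputs", "outputs"}``).  Input values give the sign of the
    reaction's monotonic dependence on that species (``"+"``, ``"-"`` or
    ``"?"``, optionally followed by a magnitude token); output values are
    signed stoichiometric scalars (numbers or signed symbol tokens).  A
    reaction with empty ``inputs`` is an orphan (constant) reaction.
    Unspecified magnitudes become distinct fresh positive symbols so that
    symbolic minors are fully general.
    """
    if "species" not in spec or "reactions" not in spec:
        raise SchemaError("network description needs 'species' and 'reactions'")
    species: list[SpeciesNode] = []
    for item in spec["species"]:
        if isinstance(item, str):
            species.append(SpeciesNode(item))
        else:
            species.append(SpeciesNode(item["id"], bool(item.get("clamped", False))))
    if not species:
        raise SchemaError("at least one species is required")
    reactions: list[ReactionNode] = []
    jac: list[JacobianEdge] = []
    sto: list[StoichEdge] = []
    for rx in spec["reactions"]:
        rid = rx["id"]
        inputs = rx.get("inputs", {}) or {}
        outputs = rx.get("outputs", {}) or {}
        if not outputs:
            raise TopologyError(f"reaction {rid!r} has no stoichiometric output")
        reactions.append(ReactionNode(rid, is_orphan=not inputs))
        for sid, value in inputs.items():
            sign, mag = _parse_signed(value, _default_jac_symbol(sid, rid), allow_unknown=True)
            jac.append(JacobianEdge(sid, rid, sign, mag))
        for sid, value in outputs.items():
            sign, mag = _parse_signed(value, _default_stoich_symbol(rid, sid), allow_unknown=True)
            sto.append(StoichEdge(rid, sid, sign, mag))
    if not reactions:
        raise TopologyError("empty reaction list")
    return InfluenceTopology(species, reactions, jac, sto)


def expand_sign_assignments(topology: InfluenceTopology) -> list[InfluenceTopology]:
    """All fixed-sign topologies represented by a graph with '?' edges.

    The ``2**u`` assignments are returned in deterministic lexicographic
    order over the unknown edges (sorted by edge key), ``+`` before ``-``.
    """
    unknown = sorted(topology.unknown_sign_edges, key=lambda e: e.key)
    if not unknown:
        return [topology]
    out = []
    for signs in itertools.product((1, -1), repeat=len(unknown)):
        assign = dict(zip((e.key for e in unknown), signs))
        jac = tuple(
            dataclasses.replace(e, sign=assign[e.key]) if e.key in assign else e
            for e in topology.jac_edges
        )
        sto = tuple(
            dataclasses.replace(e, sign=assign[e.key]) if e.key in assign else e
            for e in topology.stoich_edges
        )
        out.append(topology.replace_edges(jac_edges=jac, stoich_edges=sto))
    return out


def assemble_transition_matrix(
    topology: InfluenceTopology, values: Mapping | None = None
) -> TransitionMatrix:
    """Assemble H = R.S from the signed edge weights.

    ``values`` optionally substitutes numeric values for the weight symbols
    (keys may be symbols or their names).  Orphan reactions contribute
    nothing, clamped species are excluded.
    """
    if topology.unknown_sign_edges:
        raise UnknownSignError("expand sign assignments before assembling H")
    subs = {}
    if values:
        subs = {sp.Symbol(str(k), positive=True): sp.sympify(v) for k, v in values.items()}
    ids = [s.id for s in topology.dynamical_species]
    index = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    orphans = topology.orphan_reaction_ids
    jac_by_rx: dict[str, list[JacobianEdge]] = {}
    for e in topology.jac_edges:
        if e.species in index:
            jac_by_rx.setdefault(e.reaction, []).append(e)
    H = sp.zeros(n, n)
    for e in topology.stoich_edges:
        if e.reaction in orphans or e.species not in index:
            continue
        j = index[e.species]
        s_w = e.signed_weight.subs(subs) if subs else e.signed_weight
        for je in jac_by_rx.get(e.reaction, ()):
            i = index[je.species]
            j_w = je.signed_weight.subs(subs) if subs else je.signed_weight
            H[i, j] += j_w * s_w
    if values is not None:
        bad = H.free_symbols
        if bad:
            raise TopologyError(f"missing numeric values for {sorted(map(str, bad))}")
    return TransitionMatrix(tuple(ids), H)


# ---------------------------------------------------------------------------
# serialization

def _weight_token(sign: int | None, weight: sp.Expr, default: sp.Symbol):
    schar = {1: "+", -1: "-", None: "?"}[sign]
    if weight == default:
        return schar
    if weight.is_Integer and sign is not None:
        return int(sign * weight)
    return f"{schar}{weight}"


def save_topology(topology: InfluenceTopology) -> str:
    """Serialize to the versioned JSON dialect (deterministic layout)."""
    doc = {
        "schema": SCHEMA,
        "species": [{"id": s.id, "clamped": s.clamped} for s in topology.species],
        "reactions": [],
    }
    for r in topology.reactions:
        inputs = {
            e.species: _weight_token(e.sign, e.weight, _default_jac_symbol(e.species, r.id))
            for e in topology.jac_of_reaction(r.id)
        }
        outputs = {
            e.species: _weight_token(e.sign, e.weight, _default_stoich_symbol(r.id, e.species))
            for e in topology.stoich_of_reaction(r.id)
        }
        doc["reactions"].append({"id": r.id, "inputs": inputs, "outputs": outputs})
    return json.dumps(doc, indent=1, sort_keys=False) + "\n"


def load_topology(text: str) -> InfluenceTopology:
    """Parse the JSON dialect back into a topology."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("document must be a JSON object")
    schema = doc.get("schema")
    if schema != SCHEMA:
        raise SchemaError(f"unknown schema version {schema!r} (expected {SCHEMA!r})")
    for key in ("species", "reactions"):
        if key not in doc:
            raise SchemaError(f"document missing {key!r} key")
    return build_topology(doc)


def to_dot(topology: InfluenceTopology) -> str:
    """GraphViz DOT export: arrows for +, tee arrowheads for -, diamonds for ?."""
    head = {1: "normal", -1: "tee", None: "odiamond"}
    lines = ["digraph influence_topology {", "  rankdir=LR;"]
    for s in topology.species:
        extra = ' style="filled" fillcolor="lightgrey"' if s.clamped else ""
        lines.append(f'  "{s.id}" [shape=ellipse{extra}];')
    for r in topology.reactions:
        extra = ' style="dashed"' if r.is_orphan else ""
        lines.append(f'  "{r.id}" [shape=box{extra}];')
    orphans = topology.orphan_reaction_ids
    for e in topology.jac_edges:
        lines.append(f'  "{e.species}" -> "{e.reaction}" [arrowhead={head[e.sign]}, label="{e.weight}"];')
    for e in topology.stoich_edges:
        style = ', style="dashed"' if e.reaction in orphans else ""
        lines.append(f'  "{e.reaction}" -> "{e.species}" [arrowhead={head[e.sign]}, label="{e.weight}"{style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
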