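"""Special-node classification, level decomposition, sign canonicalization."""

import dataclasses
import itertools

import networkx as nx
import numpy as np
import pytest
import sympy as sp

from dsrstab import (
    build_topology,
    canonical_sign_form,
    classify_special_nodes,
    level_decomposition,
    principal_minors,
)
from dsrstab.fixtures import make_ncycle, random_topology, simulate_trajectories


def test_jenkin_maxwell_classification(bundles):
    cls = classify_special_nodes(bundles["jenkin_maxwell"].topology)
    assert cls.orphan_reactions == ("v0",)
    assert cls.orphan_species == ()
    assert cls.childless_species == ()
    assert cls.childless_reactions == ()


def test_repressilator_classification_empty(bundles):
    cls = classify_special_nodes(bundles["repressilator"].topology)
    assert (
        cls.orphan_species
        == cls.childless_species
        == cls.orphan_reactions
        == cls.childless_reactions
        == ()
    )


def test_childless_species_detected():
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [{"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": -1, "x2": 1}}],
        }
    )
    assert classify_special_nodes(top).childless_species == ("x2",)


def test_clamped_species_forced_orphan():
    top = build_topology(
        {
            "species": [{"id": "x1", "clamped": True}, "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+", "x2": "+"}, "outputs": {"x1": 1, "x2": -1}}
            ],
        }
    )
    assert "x1" in classify_special_nodes(top).orphan_species


def _two_level_network(decay_upstream: bool):
    """Predator-prey pair coupled to a linear decay species.

    With the decay upstream it modulates the predation reaction; with the
    levels swapped the predation output drives the decay species.
    """
    if decay_upstream:
        reactions = [
            {"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": 1}},
            {
                "id": "v2",
                "inputs": {"x1": "+", "x2": "+", "x3": "+"},
                "outputs": {"x1": -1, "x2": 1},
            },
            {"id": "v3", "inputs": {"x2": "+"}, "outputs": {"x2": -1}},
            {"id": "v4", "inputs": {"x3": "+"}, "outputs": {"x3": -1}},
        ]
    else:
        reactions = [
            {"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": 1}},
            {"id": "v2", "inputs": {"x1": "+", "x2": "+"}, "outputs": {"x1": -1, "x2": 1, "x3": 1}},
            {"id": "v3", "inputs": {"x2": "+"}, "outputs": {"x2": -1}},
            {"id": "v4", "inputs": {"x3": "+"}, "outputs": {"x3": -1}},
        ]
    return build_topology({"species": ["x1", "x2", "x3"], "reactions": reactions})


def test_two_levels_decay_upstream(bundles):
    dec = level_decomposition(_two_level_network(decay_upstream=True))
    assert len(dec.levels) == 2
    first, second = dec.levels
    assert first.species == ("x3",) and first.verdict == "stable" and first.autonomous
    assert second.species == ("x1", "x2")
    assert second.autonomous  # upstream verifiably stable
    assert dec.dag_edges == ((0, 1),)
    # the downstream level's topology is the predator-prey motif (signs included)
    lv_top = bundles["lotka_volterra"].topology

    def graph(t):
        G = nx.DiGraph()
        for e in t.jac_edges:
            G.add_edge(("x", e.species), ("v", e.reaction), sign=e.sign)
        for e in t.stoich_edges:
            G.add_edge(("v", e.reaction), ("x", e.species), sign=e.sign)
        for node in G.nodes:
            G.nodes[node]["kind"] = node[0]
        return G

    iso = nx.algorithms.isomorphism.DiGraphMatcher(
        graph(second.subtopology),
        graph(lv_top),
        node_match=lambda a, b: a["kind"] == b["kind"],
        edge_match=lambda a, b: a["sign"] == b["sign"],
    )
    assert iso.is_isomorphic()


def test_two_levels_swapped_downstream_non_autonomous():
    dec = level_decomposition(_two_level_network(decay_upstream=False))
    assert len(dec.levels) == 2
    first, second = dec.levels
    assert first.species == ("x1", "x2")
    assert second.species == ("x3",)
    assert not second.autonomous
    assert "non-autonomous" in second.verdict


def test_single_scc_fixture_one_level(bundles):
    dec = level_decomposition(bundles["selkov"].topology)
    assert len(dec.levels) == 1
    assert set(dec.levels[0].species) == {"x1", "x2"}


def test_driven_species_oscillates_only_when_upstream_oscillates():
    """Trajectory check for the two orderings of the two-level network."""
    f_decay_up = lambda x: [
        x[0] - (1 + x[2]) * x[0] * x[1],
        (1 + x[2]) * x[0] * x[1] - x[1],
        -0.1 * x[2],
    ]
    tr = simulate_trajectories(f_decay_up, [1.0, 3.0, 1.0], horizon=100, step=0.01)
    assert not tr.diverged
    assert tr.x[-1, 2] < 1e-3  # upstream decay settles (e^-10 ~ 4.5e-5)
    d1 = np.diff(tr.x[:, 0])
    assert (d1 > 0).any() and (d1 < 0).any()  # prey keeps oscillating, bounded
    assert np.all(np.isfinite(tr.x))

    f_decay_down = lambda x: [
        x[0] - x[0] * x[1],
        x[0] * x[1] - x[1],
        x[0] * x[1] - 0.1 * x[2],
    ]
    tr2 = simulate_trajectories(f_decay_down, [1.0, 3.0, 1.0], horizon=100, step=0.01)
    d3 = np.diff(tr2.x[:, 2])
    assert (d3 > 0).any() and (d3 < 0).any()  # driven oscillation downstream


def test_ncycle_canonical_forms():
    plus = canonical_sign_form(make_ncycle(4, 1).topology)
    assert all(e.sign == 1 for e in plus.topology.jac_edges)
    assert all(e.sign == 1 for e in plus.topology.stoich_edges)
    minus = canonical_sign_form(make_ncycle(4, -1).topology)
    negatives = [
        e for e in (*minus.topology.jac_edges, *minus.topology.stoich_edges) if e.sign == -1
    ]
    assert len(negatives) == 1  # single blunt arrow


def test_already_canonical_identity():
    top = canonical_sign_form(make_ncycle(3, 1).topology).topology
    again = canonical_sign_form(top)
    assert again.topology == top
    assert again.negated_nodes == ()


def _negate_node(top, node):
    jac = tuple(
        dataclasses.replace(e, sign=-e.sign) if node in (e.species, e.reaction) else e
        for e in top.jac_edges
    )
    sto = tuple(
        dataclasses.replace(e, sign=-e.sign) if node in (e.species, e.reaction) else e
        for e in top.stoich_edges
    )
    return top.replace_edges(jac, sto)


def test_negation_preserves_minors(bundles):
    top = bundles["selkov"].topology
    base = [m.value for m in principal_minors(top)]
    for node in ("x1", "x2", "v2"):
        negated = _negate_node(top, node)
        assert [m.value for m in principal_minors(negated)] == base


@pytest.mark.parametrize("seed", range(10))
def test_canonical_form_invariant_under_negation(seed):
    top = random_topology(seed + 50, n_max=3, m_max=3)
    canon = canonical_sign_form(top)
    nodes = [s.id for s in top.species] + [r.id for r in top.reactions]
    rng = np.random.default_rng(seed)
    perturbed = top
    for node in nodes:
        if rng.random() < 0.5:
            perturbed = _negate_node(perturbed, node)
    canon2 = canonical_sign_form(perturbed)
    assert canon.topology == canon2.topology
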