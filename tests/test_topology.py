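"""Influence-topology construction, transition matrix, serialization."""

import importlib.resources

import numpy as np
import pytest
import sympy as sp

from dsrstab import (
    SchemaError,
    TopologyError,
    assemble_transition_matrix,
    build_topology,
    expand_sign_assignments,
    load_topology,
    save_topology,
    to_dot,
)
from dsrstab.fixtures import make_classical_network


def test_jenkin_maxwell_counts(bundles):
    top = bundles["jenkin_maxwell"].topology
    assert (top.n, top.m, top.S, top.J) == (3, 3, 5, 3)
    assert top.orphan_reaction_ids == {"v0"}


@pytest.mark.parametrize(
    "spec",
    [
        {"species": ["x1"], "reactions": []},  # empty reaction list
        {"species": ["x1", "x1"], "reactions": [{"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": 1}}]},
        {"species": ["x1"], "reactions": [{"id": "v1", "inputs": {"x2": "+"}, "outputs": {"x1": 1}}]},
        {"species": ["x1"], "reactions": [{"id": "v1", "inputs": {"x1": "+"}, "outputs": {}}]},
        {"species": ["x1"], "reactions": [{"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": 0}}]},
    ],
)
def test_invalid_specs_rejected(spec):
    with pytest.raises(TopologyError):
        build_topology(spec)


def test_unknown_sign_recording_and_expansion():
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "?", "x2": "+"}, "outputs": {"x2": 1}},
                {"id": "v2", "inputs": {"x2": "+"}, "outputs": {"x1": -1}},
            ],
        }
    )
    assert len(top.unknown_sign_edges) == 1
    expanded = expand_sign_assignments(top)
    assert len(expanded) == 2
    # lexicographic: + before -
    signs = [
        next(e.sign for e in t.jac_edges if e.species == "x1") for t in expanded
    ]
    assert signs == [1, -1]
    # u = 0: identity
    assert expand_sign_assignments(expanded[0]) == [expanded[0]]


def test_pm_three_cycle_expands_to_eight():
    top = build_topology(
        {
            "species": ["x1", "x2", "x3"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x2": "?"}},
                {"id": "v2", "inputs": {"x2": "+"}, "outputs": {"x3": "?"}},
                {"id": "v3", "inputs": {"x3": "+"}, "outputs": {"x1": "?"}},
            ],
        }
    )
    expanded = expand_sign_assignments(top)
    assert len(expanded) == 8
    assert all(not t.unknown_sign_edges for t in expanded)


def test_rotation_network_transition_matrix():
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x2": "+"}, "outputs": {"x1": -1}},
                {"id": "v2", "inputs": {"x1": "+"}, "outputs": {"x2": 1}},
            ],
        }
    )
    weights = {str(s): 1 for s in top.free_symbols()}
    H = assemble_transition_matrix(top, weights)
    assert H.matrix == sp.Matrix([[0, 1], [-1, 0]])


def test_no_jacobian_edges_gives_zero_matrix():
    top = build_topology(
        {"species": ["x1"], "reactions": [{"id": "v0", "inputs": {}, "outputs": {"x1": 1}}]}
    )
    assert assemble_transition_matrix(top, {}).matrix == sp.zeros(1, 1)


def test_transition_matrix_is_R_dot_S(bundles):
    """H assembled edge-by-edge equals the explicit matrix product R.S."""
    top = bundles["selkov"].topology
    ids = [s.id for s in top.dynamical_species]
    rx = [r.id for r in top.reactions if not r.is_orphan]
    R = sp.zeros(len(ids), len(rx))
    S = sp.zeros(len(rx), len(ids))
    for e in top.jac_edges:
        R[ids.index(e.species), rx.index(e.reaction)] = e.signed_weight
    for e in top.stoich_edges:
        if e.reaction in rx:
            S[rx.index(e.reaction), ids.index(e.species)] = e.signed_weight
    assert sp.simplify(assemble_transition_matrix(top).matrix - R * S) == sp.zeros(2, 2)


def _fd_jacobian(f, x0, h=1e-6):
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    H = np.zeros((n, n))
    for i in range(n):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        H[i, :] = (np.array(f(xp)) - np.array(f(xm))) / (2 * h)
    return H


@pytest.mark.parametrize(
    "name",
    ["jenkin_maxwell", "van_der_pol", "lotka_volterra", "brusselator", "selkov", "repressilator"],
)
def test_H_matches_finite_difference_jacobian(name, bundles):
    """Topology-assembled H equals the numeric Jacobian of the rate laws."""
    b = bundles[name]
    c = b.default_constants
    f = b.rate_laws(c)
    ss = [float(v) for v in b.steady_state(c)]
    assert max(abs(v) for v in f(ss)) < 1e-9
    H = assemble_transition_matrix(b.topology, b.edge_values(c)).to_numpy()
    Hfd = _fd_jacobian(f, ss)
    assert np.max(np.abs(H - Hfd)) <= 1e-6 * (1 + np.max(np.abs(Hfd)))


def test_missing_weight_raises(bundles):
    with pytest.raises(TopologyError):
        assemble_transition_matrix(bundles["jenkin_maxwell"].topology, {"r1": 1})


def test_round_trip_bundled_fixture_files():
    data = importlib.resources.files("dsrstab") / "data"
    count = 0
    for entry in sorted(data.iterdir()):
        if not entry.name.endswith(".json"):
            continue
        text = entry.read_text()
        top = load_topology(text)
        assert save_topology(top) == text  # byte-stable after one normalization
        assert load_topology(save_topology(top)) == top
        count += 1
    assert count >= 6


@pytest.mark.parametrize(
    "text",
    ['{"schema": "influence-topology/1", "species": []}', '{"schema": "other/9"}', "not json"],
)
def test_load_rejects_malformed_documents(text):
    with pytest.raises(SchemaError):
        load_topology(text)


def test_dot_export_repressilator(bundles):
    dot = to_dot(bundles["repressilator"].topology)
    assert dot.count("shape=ellipse") == 3
    assert dot.count("shape=box") == 6
    edge_lines = [l for l in dot.splitlines() if "->" in l]
    assert len(edge_lines) == 12  # 6 Jacobian + 6 stoichiometric
    assert dot.count("arrowhead=tee") == len(
        [e for e in bundles["repressilator"].topology.jac_edges if e.sign < 0]
    ) + len([e for e in bundles["repressilator"].topology.stoich_edges if e.sign < 0])


def test_childless_species_flagged():
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [{"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": -1, "x2": 1}}],
        }
    )
    assert top.childless_species == ("x2",)
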