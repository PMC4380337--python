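"""Stoichiometric scaling, cycle compaction, temporal scaling, symmetries."""

import pytest
import sympy as sp

from dsrstab import (
    assemble_transition_matrix,
    build_topology,
    cycle_compaction,
    detect_exchange_symmetries,
    reduce_topology,
    reduced_dimension,
    stoichiometric_scaling,
    temporal_scaling,
)
from dsrstab.fixtures import eigen_oracle, random_instantiation
from dsrstab.hurwitz import count_unstable_roots
from dsrstab.topology import TopologyError


def test_forced_rescaling_single_output():
    top = build_topology(
        {
            "species": ["x1"],
            "reactions": [{"id": "v1", "inputs": {"x1": "+r"}, "outputs": {"x1": -2}}],
        }
    )
    scaled = stoichiometric_scaling(top, choice={"v1": "x1"})
    sto = scaled.base.stoich_edges[0]
    jac = scaled.base.jac_edges[0]
    assert sto.weight == 1 and sto.sign == -1
    assert sp.expand(jac.weight - 2 * sp.Symbol("r", positive=True)) == 0


def _choice_dependent_network():
    """Scaling choice changes the final dimensionality (compaction interplay)."""
    return build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+r1"}, "outputs": {"x1": "-s1", "x2": "+s2"}},
                {"id": "v2", "inputs": {"x2": "+r2"}, "outputs": {"x1": "+s3"}},
            ],
        }
    )


def test_scaling_choice_changes_dimension_and_search_finds_min():
    top = _choice_dependent_network()
    d_by_choice = {}
    for sid in ("x1", "x2"):
        scaled = stoichiometric_scaling(top, choice={"v1": sid, "v2": "x1"})
        d_by_choice[sid] = temporal_scaling(cycle_compaction(scaled)).d
    assert d_by_choice["x1"] != d_by_choice["x2"]
    assert reduced_dimension(top) == min(d_by_choice.values())


def test_scaling_preserves_unstable_count():
    top = _choice_dependent_network()
    for seed in range(5):
        vals = random_instantiation(top, seed)
        numeric = top.with_weights(vals)
        before = eigen_oracle(assemble_transition_matrix(numeric)).unstable_count
        for sid in ("x1", "x2"):
            scaled = stoichiometric_scaling(numeric, choice={"v1": sid, "v2": "x1"})
            after = eigen_oracle(assemble_transition_matrix(scaled.base)).unstable_count
            assert after == before


def test_compaction_group_counts(bundles):
    # three-parameter decay ring: repression edges merge into one group
    comp = bundles["repressilator"].reduced.compaction
    assert len(comp.parameter_groups) == 4  # three decay groups + the ring
    assert comp.c == 2
    ring = max(comp.parameter_groups, key=lambda g: g.z)
    assert ring.z == 3
    r4, r5, r6 = (sp.Symbol(f"r{i}", positive=True) for i in (4, 5, 6))
    assert sp.expand(ring.magnitude - r4 * r5 * r6) == 0


def test_two_overlapping_cycles_two_groups():
    # one 1-cycle overlapping a 2-cycle: parameters q0 (overlap) and q1
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": 1, "x2": 1}},
                {"id": "v2", "inputs": {"x2": "+"}, "outputs": {"x1": 1}},
            ],
        }
    )
    comp = cycle_compaction(stoichiometric_scaling(top, choice={"v1": "x1", "v2": "x1"}))
    assert len(comp.cycles) == 2
    assert len(comp.parameter_groups) == 2


def test_four_cycle_network_group_bound():
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+", "x2": "+"}, "outputs": {"x1": 1, "x2": 1}},
                {"id": "v2", "inputs": {"x2": "+"}, "outputs": {"x1": 1, "x2": 1}},
            ],
        }
    )
    comp = cycle_compaction(stoichiometric_scaling(top, choice={"v1": "x1", "v2": "x1"}))
    c = len(comp.cycles)
    assert c == 4
    assert len(comp.groups) <= 2**c - 1  # barcode upper bound


def test_single_cycle_compacts_to_one_group():
    from dsrstab.fixtures import make_ncycle

    comp = make_ncycle(4, 1).reduced.compaction
    assert len(comp.parameter_groups) == 1
    assert comp.parameter_groups[0].z == 4


def test_compaction_exactness(bundles):
    """Reduced cycle expressions reproduce the original weights exactly."""
    for name in ("jenkin_maxwell", "van_der_pol", "lotka_volterra", "selkov"):
        comp = bundles[name].reduced.compaction
        for cyc, expr in zip(comp.cycles, comp.reduced_cycles):
            subs = {g.symbol: g.magnitude for g in comp.parameter_groups}
            assert sp.simplify(expr.subs(subs) - cyc.weight) == 0


def test_temporal_scaling_jenkin_maxwell(bundles):
    red = bundles["jenkin_maxwell"].reduced
    r1, r2, r3 = (sp.Symbol(f"r{i}", positive=True) for i in (1, 2, 3))
    s1, s2 = sp.Symbol("sigma1", positive=True), sp.Symbol("sigma2", positive=True)
    assert sp.expand(red.beta - s1 * s2 * r3) == 0
    assert sp.simplify(red.definitions[sp.Symbol("rho1", positive=True)] - r1 / (s1 * s2 * r3)) == 0
    assert red.d == 2


def test_temporal_scaling_repressilator_cube_root(bundles):
    red = bundles["repressilator"].reduced
    r4, r5, r6 = (sp.Symbol(f"r{i}", positive=True) for i in (4, 5, 6))
    assert sp.simplify(red.beta - (r4 * r5 * r6) ** sp.Rational(1, 3)) == 0
    assert red.d == 3


def test_temporal_unit_requires_jacobian_content(bundles):
    comp = bundles["brusselator"].reduced.compaction
    with pytest.raises(TopologyError):
        temporal_scaling(comp, unit=("S", "v1", "x1"))  # pure stoichiometric group


def test_unit_weights_are_identity():
    top = build_topology(
        {
            "species": ["x1"],
            "reactions": [{"id": "v1", "inputs": {"x1": "+1"}, "outputs": {"x1": -1}}],
        }
    )
    red = reduce_topology(top)
    assert red.beta == 1 and red.d == 0
    assert red.cycles[0].weight == -1


@pytest.mark.parametrize(
    "name,d",
    [("jenkin_maxwell", 2), ("van_der_pol", 2), ("lotka_volterra", 3)],
)
def test_reduced_dimension_fixtures(name, d, bundles):
    assert reduced_dimension(bundles[name].topology) == d
    assert bundles[name].reduced.d == d


def test_dimension_counts_free_symbols(bundles):
    for b in bundles.values():
        free = set()
        for m in b.reduced.minors():
            free |= m.value.free_symbols
        assert len(free) == b.reduced.d


def test_reduction_preserves_unstable_count(bundles):
    """Unstable-root counts from reduced determinants match the eigenvalue
    oracle of the unreduced transition matrix."""
    for name in ("jenkin_maxwell", "lotka_volterra", "brusselator", "repressilator"):
        b = bundles[name]
        deltas = b.reduced.hurwitz().deltas
        for seed in range(4):
            vals = random_instantiation(b.topology, seed)
            oracle = eigen_oracle(assemble_transition_matrix(b.topology, vals))
            if oracle.margin < 1e-6:
                continue
            pv = b.reduced.parameter_values(vals)
            rc = count_unstable_roots(1, [float(d.subs(pv)) for d in deltas])
            assert rc.k == oracle.unstable_count, (name, seed)


def test_exchange_symmetries(bundles):
    jm = bundles["jenkin_maxwell"]
    rep = detect_exchange_symmetries(jm.reduced.minors(), jm.reduced.params)
    assert rep.permutations == ((1, 0),)  # swap(rho1, rho2)
    assert rep.psi_candidates == (sp.Symbol("rho1", positive=True) + sp.Symbol("rho2", positive=True),)

    r3 = bundles["repressilator"]
    rep = detect_exchange_symmetries(r3.reduced.minors(), r3.reduced.params)
    assert len(rep.permutations) == 5  # full S3 on (rho1, rho2, rho3)

    vdp = bundles["van_der_pol"]
    rep = detect_exchange_symmetries(vdp.reduced.minors(), vdp.reduced.params)
    assert rep.permutations == ()  # identity only
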