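"""Phase-space scans, zone classification, Hopf flags, steady-state maps."""

from fractions import Fraction

import numpy as np
import pytest
import sympy as sp

from dsrstab import (
    GridSpec,
    assemble_transition_matrix,
    classify_zones,
    count_unstable_roots,
    map_steady_state,
    scan_phase_space,
)
from dsrstab.fixtures import eigen_oracle
from dsrstab.phasespace import (
    K_INDETERMINATE,
    _rationalize_rho,
    rho_of_zeta,
    to_dataframe,
    zeta_of_rho,
)
from conftest import instantiate_at_params


def test_gridspec_validation():
    with pytest.raises(ValueError):
        GridSpec(axes=("rho1",), resolution=2)
    with pytest.raises(ValueError):
        GridSpec(axes=("rho1", "rho2", "rho3"))
    with pytest.raises(ValueError):
        GridSpec(axes=("rho1",), fixed={"rho2": -1})


def test_zeta_transform_monotone_roundtrip():
    rhos = [sp.Rational(1, 100), sp.Rational(1, 2), 1, 7, 1000]
    zetas = [float(zeta_of_rho(r)) for r in rhos]
    assert zetas == sorted(zetas)
    for r in rhos:
        back = float(rho_of_zeta(zeta_of_rho(r)))
        assert abs(back - float(r)) <= 1e-12 * (1 + float(r))


def test_rationalized_grid_values_positive_increasing():
    zs = [Fraction(i, 12) for i in range(1, 12)]
    rs = [_rationalize_rho(z) for z in zs]
    assert all(r > 0 for r in rs)
    assert rs == sorted(rs)


def test_one_cycle_network_II_single_stable_zone():
    pmap = classify_zones(_scan_one_cycle())
    assert len(pmap.zone_table) == 1
    assert pmap.zone_table[0]["k"] == 0
    assert np.all(pmap.signs > 0)


def _scan_one_cycle():
    """A stable 1-cycle with a free decay weight: Delta_1 = rho1 > 0 everywhere."""
    from dsrstab import build_topology, reduce_topology

    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+"}, "outputs": {"x1": -1}},
                {"id": "v2", "inputs": {"x2": "+"}, "outputs": {"x2": -1}},
            ],
        }
    )
    red = reduce_topology(top, unit=("J", "x1", "v1"))
    return scan_phase_space(red, GridSpec(axes=(str(red.params[0]),), resolution=15))


def test_jenkin_maxwell_zones_and_hopf(bundles):
    pmap = classify_zones(
        scan_phase_space(
            bundles["jenkin_maxwell"].reduced, GridSpec(axes=("rho1", "rho2"), resolution=31)
        )
    )
    sign_vectors = {z["signs"] for z in pmap.zone_table}
    assert sign_vectors == {(1, 1, 1), (1, -1, -1)}
    unstable = next(z for z in pmap.zone_table if z["signs"] == (1, -1, -1))
    assert unstable["k"] == 2
    # Hopf candidates line the boundary of the rho1 + rho2 < 1 zone
    assert pmap.hopf.any()
    assert np.all(pmap.kmap[pmap.hopf] == 2)


def test_brusselator_boundary_within_one_cell(bundles):
    """Sign changes of Delta_1 and Delta_2 straddle rho1 + rho2 = 1."""
    red = bundles["brusselator"].reduced
    pmap = scan_phase_space(
        red,
        GridSpec(
            axes=("rho1", "rho2"),
            fixed={"sigma1": 1, "sigma2": sp.Rational(1, 2)},
            resolution=41,
        ),
    )
    rho = pmap.rho[0]
    for q in range(2):
        for i in range(41):
            row = pmap.signs[i, :, q]
            for j in np.flatnonzero(row[:-1] != row[1:]):
                lo = rho[i] + rho[j + 1]
                hi = rho[i] + rho[j]
                assert min(lo, hi) <= 1 <= max(lo, hi)


def test_brusselator_sigma_product_above_one_no_hopf(bundles):
    """For sigma1*sigma2 > 1 only saddle zones (k = 1) appear, never a
    stable-to-double-crossing Hopf transition."""
    pmap = classify_zones(
        scan_phase_space(
            bundles["brusselator"].reduced,
            GridSpec(axes=("rho1", "rho2"), fixed={"sigma1": 1, "sigma2": 2}, resolution=21),
        )
    )
    ks = {z["k"] for z in pmap.zone_table}
    assert ks <= {1}
    assert not pmap.hopf.any()


def test_zone_topology_stable_under_refinement(bundles):
    red = bundles["jenkin_maxwell"].reduced
    coarse = classify_zones(scan_phase_space(red, GridSpec(axes=("rho1", "rho2"), resolution=21)))
    fine = classify_zones(scan_phase_space(red, GridSpec(axes=("rho1", "rho2"), resolution=41)))
    assert {z["signs"] for z in coarse.zone_table} == {z["signs"] for z in fine.zone_table}
    assert len(coarse.zone_table) == len(fine.zone_table)


@pytest.mark.parametrize("name", ["jenkin_maxwell", "lotka_volterra", "brusselator", "repressilator"])
def test_grid_counts_match_eigen_oracle(name, bundles):
    """Routh counts at random grid points equal the eigenvalue count of a
    numeric transition matrix instantiated at those reduced parameters."""
    red = bundles[name].reduced
    deltas = red.hurwitz().deltas
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 12:
        values = {
            str(p): sp.Rational(int(rng.integers(1, 40)), int(rng.integers(1, 40)))
            for p in red.params
        }
        vals = [d.subs({sp.Symbol(k, positive=True): v for k, v in values.items()}) for d in deltas]
        if any(v == 0 for v in vals):
            continue
        rc = count_unstable_roots(1, [sp.Rational(v) for v in vals])
        weights = instantiate_at_params(red, values)
        oracle = eigen_oracle(assemble_transition_matrix(red.base, weights))
        if oracle.margin < 1e-6:
            continue
        assert rc.k == oracle.unstable_count, (name, values)
        checked += 1


def test_even_cycle_grid_is_indeterminate():
    from dsrstab import build_topology, reduce_topology

    rotation = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x2": "+"}, "outputs": {"x1": -1}},
                {"id": "v2", "inputs": {"x1": "+"}, "outputs": {"x2": 1}},
            ],
        }
    )
    red = reduce_topology(rotation)
    # fully compacted: no free parameters; evaluate the determinants directly
    deltas = red.hurwitz().deltas
    assert all(d == 0 for d in deltas)
    rc = count_unstable_roots(1, [sp.Rational(d) for d in deltas])
    assert rc.indeterminate


def test_map_steady_state_lotka_volterra():
    loc = map_steady_state("lotka_volterra", {"k1": 1, "k3": 1, "sigma1": 2})
    assert loc.rho["rho3"] == sp.Rational(1, 2)
    assert loc.rho["rho1"] == loc.rho["rho2"] == sp.Rational(1, 2)  # k1/(2 k3)


def test_map_steady_state_van_der_pol():
    loc = map_steady_state("van_der_pol", {"k1": 3, "k3": 1, "sigma1": 1})
    assert loc.rho["rho1"] == 3 and loc.rho["rho2"] == 0
    assert "rho2 = 0" in loc.region


def test_map_steady_state_brusselator_region_and_errors():
    loc = map_steady_state("brusselator", {"k0": 1, "k1": 1, "k2": 2, "a": 1})
    assert loc.rho["rho1"] > 0 and loc.rho["rho2"] > 0
    assert "quadrant" in loc.region
    with pytest.raises(ValueError):
        map_steady_state("brusselator", {"k0": 1, "k1": 1, "k2": 1, "a": 2})
    with pytest.raises(ValueError):
        map_steady_state("repressilator", {})


def test_dataframe_export(bundles):
    pmap = classify_zones(
        scan_phase_space(bundles["van_der_pol"].reduced, GridSpec(axes=("rho1", "rho2"), resolution=11))
    )
    df = to_dataframe(pmap)
    assert len(df) == 121
    assert {"zeta_1", "zeta_2", "sign_delta_1", "sign_delta_2", "k", "zone", "hopf"} <= set(df.columns)
    assert df["k"].isin([0, 2, K_INDETERMINATE]).all()
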