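"""Stability phase space: exact grid scans, zone classification, Hopf flags.

The reduced parameters rho_i range over (0, inf); the compactified
coordinate zeta_i = (2/pi) arctan(rho_i) maps that range onto (0, 1) so a
finite grid covers the whole phase space.  At every grid point the Hurwitz
determinants are evaluated in exact rational arithmetic (the grid rho
values are rationalized once, at high precision, from the arctan
transform), the Routh array counts the unstable roots, and contiguous
regions of constant determinant-sign vector form the zones of the map.  A
cell is a Hopf candidate when the last two determinants are negative, every
earlier one is positive, and a fully stable cell lies 4-adjacent — the
necessary sign collision for a pair of purely imaginary roots.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Mapping

import numpy as np
import sympy as sp

from ._ratpoly import RationalPoly
from .hurwitz import count_unstable_roots
from .reduction import ReducedTopology

__all__ = [
    "GridSpec",
    "PhaseSpaceMap",
    "SteadyStateLocus",
    "scan_phase_space",
    "classify_zones",
    "map_steady_state",
    "zeta_of_rho",
    "rho_of_zeta",
    "to_dataframe",
    "plot_map",
    "K_INDETERMINATE",
    "K_DEGENERATE",
]

K_INDETERMINATE = -1  # all determinants vanish: no first-order information
K_DEGENERATE = -2  # zero pattern outside the classical Routh rules


def zeta_of_rho(rho) -> sp.Expr:
    return 2 / sp.pi * sp.atan(rho)


def rho_of_zeta(zeta) -> sp.Expr:
    return sp.tan(sp.pi * zeta / 2)


def _rationalize_rho(zeta: Fraction, digits: int = 40) -> Fraction:
    """Exact rational standing for tan(pi*zeta/2), fixed once per grid line."""
    val = sp.tan(sp.pi * sp.Rational(zeta.numerator, zeta.denominator) / 2).evalf(digits)
    rat = sp.Rational(val)
    return Fraction(int(rat.p), int(rat.q))


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """A 1- or 2-axis scan over reduced parameters.

    ``axes`` name the varied parameters, ``fixed`` pins the rest at strictly
    positive values, ``resolution`` is the number of grid points per axis
    placed at zeta = i/(resolution+1), i = 1..resolution.
    """

    axes: tuple[str, ...]
    fixed: Mapping[str, object] = dataclasses.field(default_factory=dict)
    resolution: int = 201

    def __post_init__(self):
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("scans support one or two axes")
        if self.resolution < 3:
            raise ValueError("resolution must be at least 3")
        for name, value in self.fixed.items():
            if sp.nsimplify(value, rational=True) <= 0:
                raise ValueError(f"fixed value for {name} must be strictly positive")


@dataclasses.dataclass
class PhaseSpaceMap:
    """Grid of determinant signs, unstable-root counts, zones and Hopf flags.

    Arrays are indexed [i, j] with i along ``axes[0]`` and j along
    ``axes[1]`` (j has extent 1 for a 1D scan).  ``kmap`` holds the
    unstable-root count, or K_INDETERMINATE / K_DEGENERATE sentinels.
    """

    axes: tuple[str, ...]
    fixed: dict
    zeta: tuple[tuple[Fraction, ...], ...]
    rho: tuple[tuple[Fraction, ...], ...]
    signs: np.ndarray  # int8, shape (R1, R2, n)
    kmap: np.ndarray  # int16, shape (R1, R2)
    zones: np.ndarray | None = None
    zone_table: list | None = None
    hopf: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.signs.shape[2]


def scan_phase_space(reduced: ReducedTopology, spec: GridSpec) -> PhaseSpaceMap:
    """Evaluate the Hurwitz determinants exactly over the grid."""
    deltas = reduced.hurwitz().deltas
    params = set(map(str, reduced.params))
    unknown = [a for a in spec.axes if a not in params]
    if unknown:
        raise ValueError(f"axes {unknown} are not reduced parameters of this topology")
    fixed_subs = {
        sp.Symbol(name, positive=True): sp.nsimplify(value, rational=True)
        for name, value in spec.fixed.items()
    }
    gens = [sp.Symbol(a, positive=True) for a in spec.axes]
    polys = [RationalPoly(sp.expand(d.subs(fixed_subs)), gens) for d in deltas]
    R = spec.resolution
    zeta_axis = tuple(Fraction(i + 1, R + 1) for i in range(R))
    rho_axis = tuple(_rationalize_rho(z) for z in zeta_axis)
    axes_z = (zeta_axis,) * len(spec.axes)
    axes_r = (rho_axis,) * len(spec.axes)
    R2 = R if len(spec.axes) == 2 else 1
    n = len(deltas)
    signs = np.zeros((R, R2, n), dtype=np.int8)
    kmap = np.zeros((R, R2), dtype=np.int16)
    for i in range(R):
        for j in range(R2):
            point = (rho_axis[i], rho_axis[j]) if len(spec.axes) == 2 else (rho_axis[i],)
            vals = [p(point) for p in polys]
            for q, v in enumerate(vals):
                signs[i, j, q] = 0 if v == 0 else (1 if v > 0 else -1)
            try:
                rc = count_unstable_roots(1, vals)
                kmap[i, j] = K_INDETERMINATE if rc.indeterminate else rc.k
            except ValueError:
                kmap[i, j] = K_DEGENERATE
    return PhaseSpaceMap(
        axes=tuple(spec.axes),
        fixed=dict(spec.fixed),
        zeta=axes_z,
        rho=axes_r,
        signs=signs,
        kmap=kmap,
    )


def classify_zones(pmap: PhaseSpaceMap) -> PhaseSpaceMap:
    """Annotate connected constant-sign zones and Hopf-candidate cells."""
    from scipy import ndimage

    R1, R2, n = pmap.signs.shape
    codes = np.zeros((R1, R2), dtype=np.int64)
    for q in range(n):
        codes = codes * 3 + (pmap.signs[:, :, q] + 1)
    zones = np.full((R1, R2), -1, dtype=np.int32)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-neighborhood
    zone_table = []
    next_zone = 0
    for code in np.unique(codes):
        mask = codes == code
        labeled, count = ndimage.label(mask, structure=structure)
        for lab in range(1, count + 1):
            cells = labeled == lab
            i, j = np.argwhere(cells)[0]
            ks = np.unique(pmap.kmap[cells])
            zones[cells] = next_zone
            zone_table.append(
                {
                    "zone": next_zone,
                    "signs": tuple(int(s) for s in pmap.signs[i, j]),
                    "k": int(ks[0]) if len(ks) == 1 else tuple(int(k) for k in ks),
                    "cells": int(cells.sum()),
                }
            )
            next_zone += 1
    all_pos = np.all(pmap.signs > 0, axis=2)
    hopf_sign = (pmap.signs[:, :, n - 1] < 0) & (pmap.signs[:, :, n - 2] < 0 if n >= 2 else False)
    if n > 2:
        hopf_sign &= np.all(pmap.signs[:, :, : n - 2] > 0, axis=2)
    near_stable = np.zeros_like(all_pos)
    near_stable[1:, :] |= all_pos[:-1, :]
    near_stable[:-1, :] |= all_pos[1:, :]
    near_stable[:, 1:] |= all_pos[:, :-1]
    near_stable[:, :-1] |= all_pos[:, 1:]
    hopf = hopf_sign & near_stable
    return dataclasses.replace(pmap, zones=zones, zone_table=zone_table, hopf=hopf)


@dataclasses.dataclass(frozen=True)
class SteadyStateLocus:
    """Projection of a model's steady state into reduced coordinates."""

    fixture: str
    rho: Mapping[str, sp.Expr]
    region: str


def map_steady_state(fixture: str, constants: Mapping) -> SteadyStateLocus:
    """Closed-form steady-state location of a bundled classical network.

    Delegates to the fixture factory's published constants -> rho mapping;
    raises for fixtures without a closed form.
    """
    from .fixtures import make_classical_network

    bundle = make_classical_network(fixture)
    if bundle.steady_state_map is None:
        raise ValueError(f"{fixture!r} has no closed-form steady-state mapping")
    rho, region = bundle.steady_state_map(constants)
    return SteadyStateLocus(fixture, rho, region)


def to_dataframe(pmap: PhaseSpaceMap):
    """Flat CSV-ready table: coordinates, determinant signs, k, zone, Hopf."""
    import pandas as pd

    R1, R2, n = pmap.signs.shape
    rows = []
    for i in range(R1):
        for j in range(R2):
            row = {"zeta_1": float(pmap.zeta[0][i]), "rho_1": float(pmap.rho[0][i])}
            if len(pmap.axes) == 2:
                row["zeta_2"] = float(pmap.zeta[1][j])
                row["rho_2"] = float(pmap.rho[1][j])
            for q in range(n):
                row[f"sign_delta_{q + 1}"] = int(pmap.signs[i, j, q])
            row["k"] = int(pmap.kmap[i, j])
            if pmap.zones is not None:
                row["zone"] = int(pmap.zones[i, j])
            if pmap.hopf is not None:
                row["hopf"] = bool(pmap.hopf[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


_DELTA_COLORS = ["black", "red", "blue", "green", "purple", "orange"]


def plot_map(pmap: PhaseSpaceMap, path: str) -> None:
    """Basic figure: shaded negativity of each determinant over zeta."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    R1, R2, n = pmap.signs.shape
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if len(pmap.axes) == 2:
        extent = [0, 1, 0, 1]
        for q in range(n):
            mask = (pmap.signs[:, :, q] < 0).T.astype(float)
            ax.contourf(
                np.array([float(z) for z in pmap.zeta[0]]),
                np.array([float(z) for z in pmap.zeta[1]]),
                mask,
                levels=[0.5, 1.5],
                colors=[_DELTA_COLORS[q % len(_DELTA_COLORS)]],
                alpha=0.3,
            )
        ax.set_xlabel(f"zeta({pmap.axes[0]})")
        ax.set_ylabel(f"zeta({pmap.axes[1]})")
    else:
        z = [float(x) for x in pmap.zeta[0]]
        for q in range(n):
            ax.step(
                z,
                pmap.signs[:, 0, q],
                where="mid",
                color=_DELTA_COLORS[q % len(_DELTA_COLORS)],
                label=f"sign Delta_{q + 1}",
            )
        ax.set_xlabel(f"zeta({pmap.axes[0]})")
        ax.set_ylabel("sign")
        ax.legend(fontsize=8)
    ax.set_title("stability phase space (negative-determinant zones shaded)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
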