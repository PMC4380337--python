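"""Classical network factory, numeric oracles, and a small integrator.

Bundled networks (control theory, electronics, ecology, chemistry,
biochemistry, synthetic biology):

* ``jenkin_maxwell``  — the governor servo loop: two damping 1-cycles and
  one destabilizing negative 3-cycle.
* ``van_der_pol``     — Lienard-transformed relaxation oscillator.
* ``lotka_volterra``  — predator-prey with a generalized predation
  stoichiometry sigma_1.
* ``brusselator``     — autocatalytic chemical oscillator.
* ``selkov``          — glycolytic oscillator.
* ``repressilator``   — three-gene repression ring (``repressilator_positive``
  flips one repression into activation, making the 3-cycle positive).

Each bundle carries the influence topology, its reduction with the
published parameter naming, transcribed reference expressions for the
principal minors and Hurwitz determinants (flagged where the transcription
is known to disagree with direct expansion), the constants -> rho
steady-state projection where a closed form exists, and explicit rate laws
for numeric cross-checks.  ``make_ncycle`` builds single-cycle networks of
any length with their closed-form determinants and unstable-root counts.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

from .hurwitz import HurwitzResult
from .reduction import ReducedTopology, reduce_topology
from .topology import InfluenceTopology, TransitionMatrix, build_topology

__all__ = [
    "FixtureBundle",
    "OracleResult",
    "Trajectory",
    "CLASSICAL_NETWORKS",
    "make_classical_network",
    "make_ncycle",
    "one_cycle_network",
    "ncycle_expected_deltas",
    "ncycle_expected_unstable",
    "eigen_oracle",
    "random_instantiation",
    "random_topology",
    "simulate_trajectories",
]


@dataclasses.dataclass(frozen=True)
class ExpectedExpr:
    """A transcribed reference expression, with its parsed form.

    ``matches_pipeline`` is False for the one known transcription whose
    printed form disagrees with direct expansion (the Sel'kov b_2 cross
    term); such entries are kept verbatim so the difference stays visible.
    """

    verbatim: str
    expr: sp.Expr
    matches_pipeline: bool = True


@dataclasses.dataclass(frozen=True)
class FixtureBundle:
    name: str
    topology: InfluenceTopology
    reduced: ReducedTopology
    expected_minors: tuple[ExpectedExpr, ...]  # b_1 .. b_n
    expected_deltas: tuple[ExpectedExpr, ...]  # Delta_1 .. Delta_n
    steady_state_map: Callable | None  # constants -> (rho dict, region text)
    rate_laws: Callable | None  # constants -> f(x) -> dx/dt list
    steady_state: Callable | None  # constants -> tuple of floats/exprs
    edge_values: Callable | None  # constants -> {weight symbol name: value at ss}
    default_constants: Mapping

    def hurwitz(self) -> HurwitzResult:
        return self.reduced.hurwitz()


@dataclasses.dataclass(frozen=True)
class OracleResult:
    eigenvalues: tuple[complex, ...]
    unstable_count: int
    margin: float  # min |Re lambda|: distance to the stability boundary


@dataclasses.dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    x: np.ndarray  # shape (len(t), n)
    diverged: bool


def _parse(text: str) -> sp.Expr:
    symbols = {
        name: sp.Symbol(name, positive=True)
        for name in ("rho1", "rho2", "rho3", "sigma1", "sigma2", "sigma3")
    }
    return sp.sympify(text, locals=symbols)


def _expected(entries: Sequence[tuple]) -> tuple[ExpectedExpr, ...]:
    out = []
    for entry in entries:
        text, *rest = entry
        out.append(ExpectedExpr(text, _parse(text), rest[0] if rest else True))
    return tuple(out)


# ---------------------------------------------------------------------------
# classical networks

def _jenkin_maxwell() -> FixtureBundle:
    top = build_topology(
        {
            "species": ["x1", "x2", "x3"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+r1"}, "outputs": {"x1": -1, "x2": "+sigma1"}},
                {"id": "v2", "inputs": {"x3": "+r2"}, "outputs": {"x1": "+sigma2", "x3": -1}},
                {"id": "v3", "inputs": {"x2": "+r3"}, "outputs": {"x3": -1}},
                {"id": "v0", "inputs": {}, "outputs": {"x1": -1, "x3": "+sigma3"}},
            ],
        }
    )
    reduced = reduce_topology(
        top,
        choice={"v1": "x1", "v2": "x3", "v3": "x3"},
        unit=("J", "x2", "v3"),
        names={("J", "x1", "v1"): "rho1", ("J", "x3", "v2"): "rho2"},
    )

    def ss_map(c: Mapping):
        c = dict(c)
        if "Y" in c:  # original governor constants
            rho1 = sp.nsimplify(c["Y"]) ** 2 / (sp.nsimplify(c["G"]) * sp.nsimplify(c["B"]))
            rho2 = (
                sp.nsimplify(c["F"]) * sp.nsimplify(c["Y"]) / (sp.nsimplify(c["G"]) * sp.nsimplify(c["M"]))
            )
        else:
            q0 = sp.nsimplify(c.get("sigma1", 1)) * sp.nsimplify(c.get("sigma2", 1)) * sp.nsimplify(c["k3"])
            rho1 = sp.nsimplify(c["k1"]) / q0
            rho2 = sp.nsimplify(c["k2"]) / q0
        return {"rho1": rho1, "rho2": rho2}, "entire open positive quadrant reachable"

    def rate_laws(c: Mapping):
        k0, k1, k2, k3 = (float(c[k]) for k in ("k0", "k1", "k2", "k3"))
        s1, s2, s3 = (float(c.get(k, 1)) for k in ("sigma1", "sigma2", "sigma3"))

        def f(x):
            x1, x2, x3 = x
            return [-k0 - k1 * x1 + s2 * k2 * x3, s1 * k1 * x1, s3 * k0 - k2 * x3 - k3 * x2]

        return f

    def steady_state(c: Mapping):
        k0, k2, k3 = (sp.nsimplify(c[k]) for k in ("k0", "k2", "k3"))
        s2, s3 = (sp.nsimplify(c.get(k, 1)) for k in ("sigma2", "sigma3"))
        x3 = k0 / (s2 * k2)
        x2 = (s3 * k0 - k2 * x3) / k3
        return (sp.Integer(0), x2, x3)

    def edge_values(c: Mapping):
        return {
            "r1": sp.nsimplify(c["k1"]),
            "r2": sp.nsimplify(c["k2"]),
            "r3": sp.nsimplify(c["k3"]),
            "sigma1": sp.nsimplify(c.get("sigma1", 1)),
            "sigma2": sp.nsimplify(c.get("sigma2", 1)),
            "sigma3": sp.nsimplify(c.get("sigma3", 1)),
        }

    return FixtureBundle(
        "jenkin_maxwell",
        top,
        reduced,
        _expected([("-rho1 - rho2",), ("rho1*rho2",), ("-rho1*rho2",)]),
        _expected(
            [
                ("rho1 + rho2",),
                ("rho1*rho2*(rho1 + rho2 - 1)",),
                ("rho1**2*rho2**2*(rho1 + rho2 - 1)",),
            ]
        ),
        ss_map,
        rate_laws,
        steady_state,
        edge_values,
        {"k0": 1, "k1": 1, "k2": 1, "k3": 1, "sigma1": 1, "sigma2": 1, "sigma3": 2},
    )


def _van_der_pol() -> FixtureBundle:
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+r1"}, "outputs": {"x1": 1, "x2": "+sigma1"}},
                {"id": "v2", "inputs": {"x1": "+r2"}, "outputs": {"x1": -1}},
                {"id": "v3", "inputs": {"x2": "+r3"}, "outputs": {"x1": -1}},
            ],
        }
    )
    reduced = reduce_topology(
        top,
        choice={"v1": "x1", "v2": "x1", "v3": "x1"},
        unit=("J", "x2", "v3"),
        names={("J", "x1", "v1"): "rho1", ("J", "x1", "v2"): "rho2"},
    )

    def ss_map(c: Mapping):
        rho1 = sp.nsimplify(c["k1"]) / (sp.nsimplify(c.get("sigma1", 1)) * sp.nsimplify(c["k3"]))
        return {"rho1": rho1, "rho2": sp.Integer(0)}, (
            "steady-state locus is the boundary line rho2 = 0 (the cubic "
            "damping reaction has zero slope at the origin)"
        )

    def rate_laws(c: Mapping):
        k1, k2, k3 = (float(c[k]) for k in ("k1", "k2", "k3"))
        s1 = float(c.get("sigma1", 1))

        def f(x):
            x1, x2 = x
            return [k1 * x1 - k2 * x1**3 - k3 * x2, s1 * k1 * x1]

        return f

    def steady_state(c: Mapping):
        return (sp.Integer(0), sp.Integer(0))

    def edge_values(c: Mapping):
        # d(k2 x1^3)/dx1 = 0 at the origin: the r2 edge weight degenerates
        return {
            "r1": sp.nsimplify(c["k1"]),
            "r2": sp.Integer(0),
            "r3": sp.nsimplify(c["k3"]),
            "sigma1": sp.nsimplify(c.get("sigma1", 1)),
        }

    return FixtureBundle(
        "van_der_pol",
        top,
        reduced,
        _expected([("rho1 - rho2",), ("rho1",)]),
        _expected([("rho2 - rho1",), ("rho1*(rho2 - rho1)",)]),
        ss_map,
        rate_laws,
        steady_state,
        edge_values,
        {"k1": 1, "k2": 1, "k3": 1, "sigma1": 1},
    )


def _lotka_volterra() -> FixtureBundle:
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+r1"}, "outputs": {"x1": 1}},
                {
                    "id": "v2",
                    "inputs": {"x1": "+r2", "x2": "+r4"},
                    "outputs": {"x1": -1, "x2": "+sigma1"},
                },
                {"id": "v3", "inputs": {"x2": "+r3"}, "outputs": {"x2": -1}},
            ],
        }
    )
    reduced = reduce_topology(
        top,
        choice={"v1": "x1", "v2": "x1", "v3": "x2"},
        unit=("J", "x2", "v2"),
        names={
            ("J", "x1", "v1"): "rho1",
            ("J", "x1", "v2"): "rho2",
            ("J", "x2", "v3"): "rho3",
        },
    )

    def ss_map(c: Mapping):
        # the published projection: rho3 = 1/sigma1, rho1 = rho2 = k1/(sigma1 k3)
        s1 = sp.nsimplify(c.get("sigma1", 1))
        rho12 = sp.nsimplify(c["k1"]) / (s1 * sp.nsimplify(c["k3"]))
        return {"rho1": rho12, "rho2": rho12, "rho3": 1 / s1}, (
            "steady states lie on the rho1 = rho2 diagonal"
        )

    def rate_laws(c: Mapping):
        k1, k2, k3 = (float(c[k]) for k in ("k1", "k2", "k3"))
        s1 = float(c.get("sigma1", 1))

        def f(x):
            x1, x2 = x
            return [k1 * x1 - k2 * x1 * x2, s1 * k2 * x1 * x2 - k3 * x2]

        return f

    def steady_state(c: Mapping):
        k1, k2, k3 = (sp.nsimplify(c[k]) for k in ("k1", "k2", "k3"))
        s1 = sp.nsimplify(c.get("sigma1", 1))
        return (k3 / (s1 * k2), k1 / k2)

    def edge_values(c: Mapping):
        k1, k2, k3 = (sp.nsimplify(c[k]) for k in ("k1", "k2", "k3"))
        s1 = sp.nsimplify(c.get("sigma1", 1))
        x1s, x2s = steady_state(c)
        return {
            "r1": k1,
            "r2": k2 * x2s,
            "r4": k2 * x1s,
            "r3": k3,
            "sigma1": s1,
        }

    return FixtureBundle(
        "lotka_volterra",
        top,
        reduced,
        _expected(
            [("1 + rho1 - rho2 - rho3",), ("rho1 + rho2*rho3 - rho1*rho3",)]
        ),
        _expected(
            [
                ("rho2 + rho3 - rho1 - 1",),
                ("(rho2 + rho3 - rho1 - 1)*(rho1 + rho2*rho3 - rho1*rho3)",),
            ]
        ),
        ss_map,
        rate_laws,
        steady_state,
        edge_values,
        {"k1": 1, "k2": 1, "k3": 1, "sigma1": 1},
    )


def _brusselator() -> FixtureBundle:
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {
                    "id": "v1",
                    "inputs": {"x1": "+r0", "x2": "+r1"},
                    "outputs": {"x1": "+sigma1", "x2": -1},
                },
                {"id": "v2", "inputs": {"x1": "+r2"}, "outputs": {"x1": -1, "x2": "+sigma2"}},
                {"id": "v0", "inputs": {}, "outputs": {"x1": 1}},
            ],
        }
    )
    reduced = reduce_topology(
        top,
        choice={"v1": "x2", "v2": "x1"},
        unit=("J", "x1", "v1"),
        names={("J", "x2", "v1"): "rho1", ("J", "x1", "v2"): "rho2"},
    )

    def ss_map(c: Mapping):
        k0, k1, k2, a = (sp.nsimplify(c[k]) for k in ("k0", "k1", "k2", "a"))
        if not k2 > a:
            raise ValueError("Brusselator requires k2 > a (so that 0 < sigma2 < 1)")
        x1s = k0 / a
        r0 = 2 * (k2 - a)  # d v1/d x1 = 2 k1 x1 x2 = 2 sigma2 k2 at steady state
        return {
            "rho1": k1 * x1s**2 / r0,
            "rho2": k2 / r0,
            "sigma1": sp.Integer(1),
            "sigma2": (k2 - a) / k2,
        }, "entire open positive (rho1, rho2) quadrant reachable"

    def rate_laws(c: Mapping):
        k0, k1, k2 = (float(c[k]) for k in ("k0", "k1", "k2"))
        s1 = float(c.get("sigma1", 1))
        s2 = float(c.get("sigma2", (float(c["k2"]) - float(c["a"])) / float(c["k2"]) if "a" in c else 1))

        def f(x):
            x1, x2 = x
            return [k0 + s1 * k1 * x1**2 * x2 - k2 * x1, -k1 * x1**2 * x2 + s2 * k2 * x1]

        return f

    def steady_state(c: Mapping):
        k0, k1, k2, a = (sp.nsimplify(c[k]) for k in ("k0", "k1", "k2", "a"))
        s2 = (k2 - a) / k2
        x1s = k0 / a
        x2s = s2 * k2 / (k1 * x1s)
        return (x1s, x2s)

    def edge_values(c: Mapping):
        k0, k1, k2, a = (sp.nsimplify(c[k]) for k in ("k0", "k1", "k2", "a"))
        x1s, x2s = steady_state(c)
        return {
            "r0": 2 * k1 * x1s * x2s,
            "r1": k1 * x1s**2,
            "r2": k2,
            "sigma1": sp.Integer(1),
            "sigma2": (k2 - a) / k2,
        }

    return FixtureBundle(
        "brusselator",
        top,
        reduced,
        _expected(
            [("sigma1 - rho1 - rho2",), ("rho1*rho2 - sigma1*sigma2*rho1*rho2",)]
        ),
        _expected(
            [
                ("rho1 + rho2 - sigma1",),
                ("(rho1 + rho2 - sigma1)*rho1*rho2*(1 - sigma1*sigma2)",),
            ]
        ),
        ss_map,
        rate_laws,
        steady_state,
        edge_values,
        {"k0": 1, "k1": 1, "k2": 2, "a": 1},
    )


def _selkov() -> FixtureBundle:
    top = build_topology(
        {
            "species": ["x1", "x2"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+r0"}, "outputs": {"x1": -1}},
                {
                    "id": "v2",
                    "inputs": {"x1": "+r1", "x2": "+r2"},
                    "outputs": {"x1": "+sigma1", "x2": -1},
                },
                {"id": "v3", "inputs": {"x2": "+r3"}, "outputs": {"x1": "+sigma2", "x2": -1}},
                {"id": "v0", "inputs": {}, "outputs": {"x2": 1}},
            ],
        }
    )
    reduced = reduce_topology(
        top,
        choice={"v1": "x1", "v2": "x2", "v3": "x2"},
        unit=("J", "x1", "v1"),
        names={
            ("J", "x1", "v2"): "rho1",
            ("J", "x2", "v2"): "rho2",
            ("J", "x2", "v3"): "rho3",
        },
    )

    def ss_map(c: Mapping):
        k0, k1, k2, k3 = (sp.nsimplify(c[k]) for k in ("k0", "k1", "k2", "k3"))
        rho1 = 2 / (1 + k1**2 * k3 / (k0**2 * k2))
        return {
            "rho1": rho1,
            "rho2": k0**2 * k2 / k1**3,
            "rho3": k3 / k1,
            "sigma1": sp.Integer(1),
            "sigma2": sp.Integer(1),
        }, "rho1 < 2 for every choice of positive constants"

    def rate_laws(c: Mapping):
        k0, k1, k2, k3 = (float(c[k]) for k in ("k0", "k1", "k2", "k3"))
        s1 = float(c.get("sigma1", 1))
        s2 = float(c.get("sigma2", 1))

        def f(x):
            x1, x2 = x
            return [
                -k1 * x1 + s1 * k2 * x1**2 * x2 + s2 * k3 * x2,
                k0 - k2 * x1**2 * x2 - k3 * x2,
            ]

        return f

    def steady_state(c: Mapping):
        k0, k1, k2, k3 = (sp.nsimplify(c[k]) for k in ("k0", "k1", "k2", "k3"))
        x1s = k0 / k1
        x2s = k0 / (k2 * x1s**2 + k3)
        return (x1s, x2s)

    def edge_values(c: Mapping):
        k0, k1, k2, k3 = (sp.nsimplify(c[k]) for k in ("k0", "k1", "k2", "k3"))
        x1s, x2s = steady_state(c)
        return {
            "r0": k1,
            "r1": 2 * k2 * x1s * x2s,
            "r2": k2 * x1s**2,
            "r3": k3,
            "sigma1": sp.Integer(1),
            "sigma2": sp.Integer(1),
        }

    return FixtureBundle(
        "selkov",
        top,
        reduced,
        _expected(
            [
                ("-1 + sigma1*rho1 - rho2 - rho3",),
                # printed form; direct expansion gives +sigma2*rho1*rho3
                ("rho2 + rho3 - sigma1*rho1*rho3 - sigma2*rho1*rho3", False),
            ]
        ),
        _expected(
            [
                ("1 + rho2 + rho3 - sigma1*rho1",),
                (
                    "(1 + rho2 + rho3 - sigma1*rho1)"
                    "*(rho2 + rho3 - sigma1*rho1*rho3 - sigma2*rho1*rho3)",
                    False,
                ),
            ]
        ),
        ss_map,
        rate_laws,
        steady_state,
        edge_values,
        {"k0": 1, "k1": 1, "k2": 1, "k3": 1},
    )


def _repressilator(positive_cycle: bool = False) -> FixtureBundle:
    ring_sign = "+" if positive_cycle else "-"
    top = build_topology(
        {
            "species": ["x1", "x2", "x3"],
            "reactions": [
                {"id": "p1", "inputs": {"x3": f"{ring_sign}r4"}, "outputs": {"x1": 1}},
                {"id": "p2", "inputs": {"x1": "-r5"}, "outputs": {"x2": 1}},
                {"id": "p3", "inputs": {"x2": "-r6"}, "outputs": {"x3": 1}},
                {"id": "d1", "inputs": {"x1": "+r1"}, "outputs": {"x1": -1}},
                {"id": "d2", "inputs": {"x2": "+r2"}, "outputs": {"x2": -1}},
                {"id": "d3", "inputs": {"x3": "+r3"}, "outputs": {"x3": -1}},
            ],
        }
    )
    reduced = reduce_topology(
        top,
        choice={r: s for r, s in [("p1", "x1"), ("p2", "x2"), ("p3", "x3"), ("d1", "x1"), ("d2", "x2"), ("d3", "x3")]},
        unit=("J", "x3", "p1"),
        names={
            ("J", "x1", "d1"): "rho1",
            ("J", "x2", "d2"): "rho2",
            ("J", "x3", "d3"): "rho3",
        },
    )
    cyc = 1 if positive_cycle else -1
    b3 = f"-rho1*rho2*rho3 + ({cyc})"
    d3 = (
        "(rho1*rho2*rho3 - 1)*((rho1 + rho2 + rho3)*(rho1*rho2 + rho1*rho3 + rho2*rho3) - rho1*rho2*rho3 + 1)"
        if positive_cycle
        else "(rho1*rho2*rho3 + 1)*((rho1 + rho2 + rho3)*(rho1*rho2 + rho1*rho3 + rho2*rho3) - rho1*rho2*rho3 - 1)"
    )
    d2 = (
        "(rho1 + rho2 + rho3)*(rho1*rho2 + rho1*rho3 + rho2*rho3) - rho1*rho2*rho3 + 1"
        if positive_cycle
        else "(rho1 + rho2 + rho3)*(rho1*rho2 + rho1*rho3 + rho2*rho3) - rho1*rho2*rho3 - 1"
    )

    def rate_laws(c: Mapping):
        k = {key: float(v) for key, v in c.items()}
        a, b, cc = k.get("a", 1), k.get("b", 1), k.get("c", 1)

        def f(x):
            x1, x2, x3 = x
            return [
                k["k3"] / (1 + x3**cc) - k["k4"] * x1,
                k["k1"] / (1 + x1**a) - k["k5"] * x2,
                k["k2"] / (1 + x2**b) - k["k6"] * x3,
            ]

        return f

    def steady_state(c: Mapping):
        from scipy.optimize import fsolve

        f = rate_laws(c)
        sol = fsolve(f, [1.0, 1.0, 1.0], full_output=False)
        return tuple(float(v) for v in sol)

    def edge_values(c: Mapping):
        x1, x2, x3 = steady_state(c)
        k = {key: float(v) for key, v in c.items()}
        a, b, cc = k.get("a", 1), k.get("b", 1), k.get("c", 1)
        return {
            "r4": abs(k["k3"] * cc * x3 ** (cc - 1) / (1 + x3**cc) ** 2),
            "r5": abs(k["k1"] * a * x1 ** (a - 1) / (1 + x1**a) ** 2),
            "r6": abs(k["k2"] * b * x2 ** (b - 1) / (1 + x2**b) ** 2),
            "r1": k["k4"],
            "r2": k["k5"],
            "r3": k["k6"],
        }

    return FixtureBundle(
        "repressilator_positive" if positive_cycle else "repressilator",
        top,
        reduced,
        _expected(
            [
                ("-rho1 - rho2 - rho3",),
                ("rho1*rho2 + rho1*rho3 + rho2*rho3",),
                (b3,),
            ]
        ),
        _expected([("rho1 + rho2 + rho3",), (d2,), (d3,)]),
        None,  # no closed-form steady-state projection (Hill-coefficient dependent)
        None if positive_cycle else rate_laws,
        None if positive_cycle else steady_state,
        None if positive_cycle else edge_values,
        {"k1": 10, "k2": 10, "k3": 10, "k4": 1, "k5": 1, "k6": 1, "a": 2, "b": 2, "c": 2},
    )


_FACTORY = {
    "jenkin_maxwell": _jenkin_maxwell,
    "van_der_pol": _van_der_pol,
    "lotka_volterra": _lotka_volterra,
    "brusselator": _brusselator,
    "selkov": _selkov,
    "repressilator": _repressilator,
    "repressilator_positive": lambda: _repressilator(positive_cycle=True),
}

CLASSICAL_NETWORKS = tuple(_FACTORY)


def make_classical_network(name: str, constants: Mapping | None = None) -> FixtureBundle:
    """Build a bundled classical network (see module docstring for names)."""
    if name not in _FACTORY:
        raise ValueError(f"unknown network {name!r}; choose from {CLASSICAL_NETWORKS}")
    bundle = _FACTORY[name]()
    if constants:
        merged = {**bundle.default_constants, **dict(constants)}
        bundle = dataclasses.replace(bundle, default_constants=merged)
    return bundle


# ---------------------------------------------------------------------------
# n-cycle networks

def make_ncycle(n: int, cycle_sign: int = 1) -> FixtureBundle:
    """Single n-cycle network: species x1 -> v1 -> x2 -> ... -> xn -> vn -> x1.

    ``cycle_sign`` fixes the product of edge signs (a negative cycle is
    built with a single blunt arrow on the closing stoichiometric edge —
    the node-negation canonical form).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cycle_sign not in (1, -1):
        raise ValueError("cycle_sign must be +1 or -1")
    reactions = []
    for i in range(1, n + 1):
        target = i % n + 1
        sign = cycle_sign if i == n else 1
        reactions.append(
            {
                "id": f"v{i}",
                "inputs": {f"x{i}": "+"},
                "outputs": {f"x{target}": sign},
            }
        )
    top = build_topology({"species": [f"x{i}" for i in range(1, n + 1)], "reactions": reactions})
    reduced = reduce_topology(top)
    deltas = ncycle_expected_deltas(n, cycle_sign)
    minors = [sp.Integer(0)] * n
    minors[n - 1] = sp.Integer(cycle_sign if n % 2 == 1 else -cycle_sign)
    return FixtureBundle(
        f"{n}-cycle({cycle_sign:+d})",
        top,
        reduced,
        tuple(ExpectedExpr(str(m), m) for m in minors),
        tuple(ExpectedExpr(str(d), d) for d in deltas),
        None,
        None,
        None,
        None,
        {},
    )


def one_cycle_network(variant: str) -> InfluenceTopology:
    """The four 1-cycle networks: I (+,+), II (-,+), III (+,-), IV (-,-).

    First sign: stoichiometric output; second: monotonicity.  I and IV have
    a positive feedback cycle (unstable); II and III a negative one
    (stable).
    """
    signs = {"I": (1, 1), "II": (-1, 1), "III": (1, -1), "IV": (-1, -1)}
    if variant not in signs:
        raise ValueError("variant must be one of I, II, III, IV")
    sto, jac = signs[variant]
    return build_topology(
        {
            "species": ["x1"],
            "reactions": [
                {"id": "v1", "inputs": {"x1": "+" if jac > 0 else "-"}, "outputs": {"x1": sto}},
                {"id": "v0", "inputs": {}, "outputs": {"x1": 1}},
            ],
        }
    )


def ncycle_expected_deltas(n: int, cycle_sign: int) -> tuple[sp.Expr, ...]:
    """Closed-form Hurwitz determinants of a reduced single n-cycle.

    Even n: all determinants vanish (no first-order information).  Odd n:
    all vanish except the last two,

        Delta_{n-1} = (-1)^floor(((n-1)/2)/2) c^((n-1)/2),
        Delta_n     = -c Delta_{n-1},

    with c the compacted cycle weight (the sign alternates with period 4 in
    (n-1)/2: +, -, -, +, ...; verified against direct determinant expansion
    through n = 13).  For n = 3 and n = 5 this reduces to Delta_3 = -1 and
    Delta_4 = -1 at c = +1.
    """
    c = sp.Integer(cycle_sign)
    deltas = [sp.Integer(0)] * n
    if n == 1:
        return (-c,)
    if n % 2 == 1:
        m = (n - 1) // 2
        d_nm1 = sp.Integer((-1) ** (m // 2)) * c**m
        deltas[n - 2] = d_nm1
        deltas[n - 1] = -c * d_nm1
    return tuple(deltas)


def ncycle_expected_unstable(n: int, cycle_sign: int) -> int:
    """k = (n + (-1)^((n-1)/2) c_n) / 2 for odd n."""
    if n % 2 == 0:
        raise ValueError("even cycles carry no first-order stability information")
    return (n + (-1) ** ((n - 1) // 2) * cycle_sign) // 2


# ---------------------------------------------------------------------------
# numeric oracles

def eigen_oracle(H) -> OracleResult:
    """Full spectrum of the transition matrix; the ground truth for k."""
    if isinstance(H, TransitionMatrix):
        arr = H.to_numpy()
    elif isinstance(H, sp.Matrix):
        arr = np.array(H.tolist(), dtype=float)
    else:
        arr = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite entries in transition matrix")
    lam = np.linalg.eigvals(arr)
    unstable = int(np.sum(lam.real > 0))
    margin = float(np.min(np.abs(lam.real))) if len(lam) else float("inf")
    return OracleResult(tuple(lam), unstable, margin)


def random_instantiation(topology: InfluenceTopology, seed: int) -> dict[str, sp.Rational]:
    """Reproducible positive edge magnitudes, log-uniform on [0.1, 10].

    Returns a name -> rational mapping over the topology's free weight
    symbols (rationalized at 6 decimal digits so downstream arithmetic can
    stay exact).
    """
    rng = np.random.default_rng(seed)
    values: dict[str, sp.Rational] = {}
    for sym in sorted(topology.free_symbols(), key=str):
        x = float(10 ** rng.uniform(-1.0, 1.0))
        values[str(sym)] = sp.Rational(int(round(x * 10**6)), 10**6)
    return values


def random_topology(seed: int, n_max: int = 5, m_max: int = 6) -> InfluenceTopology:
    """Random fixed-sign topology for property tests (plumbing, not physics)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    species = [f"x{i}" for i in range(1, n + 1)]
    reactions = []
    for k in range(1, m + 1):
        n_in = int(rng.integers(0 if k > 1 else 1, min(n, 3) + 1))
        inputs = {
            species[i]: "+" if rng.random() < 0.5 else "-"
            for i in rng.choice(n, size=n_in, replace=False)
        }
        n_out = int(rng.integers(1, min(n, 3) + 1))
        outputs = {
            species[i]: 1 if rng.random() < 0.5 else -1
            for i in rng.choice(n, size=n_out, replace=False)
        }
        reactions.append({"id": f"v{k}", "inputs": inputs, "outputs": outputs})
    return build_topology({"species": species, "reactions": reactions})


def simulate_trajectories(
    rate_laws: Callable,
    initial: Sequence[float],
    horizon: float,
    step: float = 1e-3,
    divergence_limit: float = 1e9,
) -> Trajectory:
    """Fixed-step classical Runge-Kutta (RK4) integration.

    Stops early with ``diverged=True`` if any state magnitude exceeds the
    divergence limit.  Meant for qualitative demonstrations, not for stiff
    or long-horizon quantitative work.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    x = np.asarray(initial, dtype=float)
    steps = int(round(horizon / step))
    ts = [0.0]
    xs = [x.copy()]
    diverged = False
    f = lambda y: np.asarray(rate_laws(y), dtype=float)
    for i in range(steps):
        k1 = f(x)
        k2 = f(x + 0.5 * step * k1)
        k3 = f(x + 0.5 * step * k2)
        k4 = f(x + step * k3)
        x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append((i + 1) * step)
        xs.append(x.copy())
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > divergence_limit:
            diverged = True
            break
    return Trajectory(np.array(ts), np.vstack(xs), diverged)
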