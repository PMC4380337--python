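"""Characteristic polynomial, Hurwitz determinants and unstable-root counts.

A steady state is locally asymptotically stable iff every Hurwitz
determinant Delta_1 .. Delta_n of the characteristic polynomial
``a_0 lambda^n + ... + a_n`` (a_q = (-1)^q b_q over the principal minors) is
strictly positive.  When some determinants are negative, the Routh array

    (a_0, Delta_1, Delta_2/Delta_1, ..., Delta_n/Delta_{n-1})

counts the eigenvalues with positive real part by its sign changes; runs of
zero determinants are handled by the classical degenerate-case rules (a
trailing run truncates the array, an interior or leading run of odd length p
contributes (p+1)/2 or (p+3)/2 changes depending on the signs that bracket
it).  All-zero determinants carry no first-order information at all — even
cycle-only topologies land here — and are reported as indeterminate rather
than as a count.
"""

from __future__ import annotations

import dataclasses
import math
from fractions import Fraction
from numbers import Rational
from typing import Sequence

import sympy as sp

from .cycles import MinorExpression

__all__ = [
    "CharPolyCoeffs",
    "HurwitzResult",
    "RouthCount",
    "charpoly_coefficients",
    "hurwitz_matrix",
    "hurwitz_determinants",
    "hurwitz_from_cycles",
    "count_unstable_roots",
    "orlando_check",
    "negative_monomials",
]

FLOAT_ZERO_RTOL = 1e-9


@dataclasses.dataclass(frozen=True)
class CharPolyCoeffs:
    """Coefficients a_0 .. a_n of det(lambda I - H), a_0 = 1."""

    a: tuple[sp.Expr, ...]

    @property
    def n(self) -> int:
        return len(self.a) - 1


@dataclasses.dataclass(frozen=True)
class HurwitzResult:
    """Hurwitz determinants Delta_1 .. Delta_n with their negative monomials.

    ``negative_terms[q-1]`` lists the monomials of Delta_q with negative
    coefficient once expanded over the (positive) reduced parameters: these
    are the candidate destabilizing *multiplicative topologies*.
    """

    deltas: tuple[sp.Expr, ...]
    negative_terms: tuple[tuple[sp.Expr, ...], ...]

    @property
    def n(self) -> int:
        return len(self.deltas)


@dataclasses.dataclass(frozen=True)
class RouthCount:
    """Number of unstable roots k, or indeterminate when all Delta vanish."""

    k: int | None
    zero_strings: tuple[tuple[int, int], ...]  # (start s, length p): Delta_{s+1..s+p} = 0
    truncated: bool
    indeterminate: bool = False


def charpoly_coefficients(minors: Sequence[MinorExpression]) -> CharPolyCoeffs:
    """a_q = (-1)^q b_q from the principal minors (b_0 must be 1)."""
    b0 = minors[0].value if isinstance(minors[0], MinorExpression) else minors[0]
    if sp.simplify(b0 - 1) != 0:
        raise ValueError("b_0 must equal 1")
    a = []
    for q, minor in enumerate(minors):
        bq = minor.value if isinstance(minor, MinorExpression) else sp.sympify(minor)
        a.append(sp.expand((-1) ** q * bq))
    return CharPolyCoeffs(tuple(a))


def hurwitz_matrix(coeffs: CharPolyCoeffs, q: int) -> sp.Matrix:
    """The q x q Hurwitz matrix with entries a_{2i-j} (zero out of range)."""
    a = coeffs.a
    n = coeffs.n

    def entry(i, j):  # 1-indexed
        k = 2 * i - j
        return a[k] if 0 <= k <= n else sp.Integer(0)

    return sp.Matrix(q, q, lambda i, j: entry(i + 1, j + 1))


def negative_monomials(expr: sp.Expr) -> tuple[sp.Expr, ...]:
    """Monomials with negative coefficient in the expanded expression."""
    expanded = sp.expand(expr)
    out = []
    for term in sp.Add.make_args(expanded):
        coeff = term.as_coeff_Mul()[0]
        if coeff.is_number and coeff < 0:
            out.append(term)
    return tuple(out)


def hurwitz_determinants(coeffs: CharPolyCoeffs) -> HurwitzResult:
    """Delta_1 .. Delta_n via fraction-free (Bareiss) determinants."""
    deltas = []
    for q in range(1, coeffs.n + 1):
        M = hurwitz_matrix(coeffs, q)
        deltas.append(sp.expand(M.det(method="bareiss")))
    return HurwitzResult(tuple(deltas), tuple(negative_monomials(d) for d in deltas))


# explicit principal-minor templates for n <= 4 (pedagogical cycle-product route)
def _template_deltas(b: Sequence[sp.Expr]) -> list[sp.Expr]:
    def bq(q):
        return b[q] if q < len(b) else sp.Integer(0)

    b0, b1, b2, b3, b4, b5, b6, b7 = (bq(i) for i in range(8))
    return [
        -b1,
        -b1 * b2 + b0 * b3,
        b1 * b2 * b3 - b0 * b3 * b3 + b0 * b1 * b5 - b1 * b1 * b4,
        (
            b1 * b2 * b3 * b4
            - b0 * b3**2 * b4
            - b1**2 * b4**2
            - b1 * b2**2 * b5
            + b0 * b2 * b3 * b5
            + 2 * b0 * b1 * b4 * b5
            - b0**2 * b5**2
            + b1**2 * b2 * b6
            - b0 * b1 * b3 * b6
            - b0 * b1 * b2 * b7
            + b0**2 * b3 * b7
        ),
    ]


def hurwitz_from_cycles(minors: Sequence[MinorExpression]) -> HurwitzResult:
    """Hurwitz determinants assembled from the principal-minor templates.

    For n <= 4 this uses the closed cycle-product forms over b_q; larger
    systems delegate to the determinant route.  Values are identical either
    way — the template route exists for the per-term topology reports.
    """
    n = len(minors) - 1
    coeffs = charpoly_coefficients(minors)
    if n > 4:
        return hurwitz_determinants(coeffs)
    b = [m.value if isinstance(m, MinorExpression) else sp.sympify(m) for m in minors]
    deltas = tuple(sp.expand(d) for d in _template_deltas(b)[:n])
    return HurwitzResult(deltas, tuple(negative_monomials(d) for d in deltas))


# ---------------------------------------------------------------------------
# Routh counting with zero strings

def _exact_signs(a0_sign, deltas) -> list[int]:
    """Signs (-1, 0, +1) of (a0, Delta_1..Delta_n); exact for rationals,
    relative tolerance for floats."""
    values = [a0_sign, *deltas]
    signs: list[int] = []
    scale = 0.0
    for v in values:
        if isinstance(v, (int, Rational)) or (
            isinstance(v, sp.Expr) and v.is_number and v.is_rational
        ):
            x = Fraction(v) if not isinstance(v, sp.Expr) else Fraction(int(v.p), int(v.q)) if v.is_Rational else None
            if x is None:
                raise ValueError(f"non-rational exact value {v}")
            signs.append(0 if x == 0 else (1 if x > 0 else -1))
            scale = max(scale, abs(float(x)))
        else:
            x = float(v)
            if not math.isfinite(x):
                raise ValueError("non-finite Hurwitz determinant")
            tol = FLOAT_ZERO_RTOL * (1.0 + scale)
            signs.append(0 if abs(x) <= tol else (1 if x > 0 else -1))
            scale = max(scale, abs(x))
    return signs


def count_unstable_roots(a0_sign, deltas: Sequence) -> RouthCount:
    """Count eigenvalues with positive real part from the Hurwitz determinants.

    ``a0_sign`` is the (nonzero) sign of a_0; ``deltas`` are numeric
    Delta_1 .. Delta_n (exact rationals preferred; floats are zero-tested at
    relative tolerance 1e-9).  Returns an indeterminate result when every
    determinant vanishes (no first-order information, e.g. even-cycle-only
    topologies).
    """
    signs = _exact_signs(a0_sign, deltas)
    if signs[0] == 0:
        raise ValueError("a_0 must be nonzero")
    n = len(signs) - 1
    if all(s == 0 for s in signs[1:]):
        return RouthCount(None, ((0, n),) if n else (), truncated=n > 0, indeterminate=True)

    # trailing zero string terminating at Delta_n: truncate
    N = n
    truncated = False
    zero_strings: list[tuple[int, int]] = []
    while N >= 1 and signs[N] == 0:
        N -= 1
        truncated = True
    if truncated:
        zero_strings.append((N, n - N))

    # maximal interior/leading zero runs within Delta_1..Delta_N
    runs: list[tuple[int, int]] = []  # (s, p): Delta_{s+1..s+p} == 0
    q = 1
    while q <= N:
        if signs[q] == 0:
            start = q
            while q <= N and signs[q] == 0:
                q += 1
            runs.append((start - 1, q - start))
        else:
            q += 1
    zero_strings = runs + zero_strings

    # ratio(q) = sign(Delta_q / Delta_{q-1}), with Delta_0 = a0, Delta_{-1} = 1
    def ratio(q: int) -> int:
        if q == 0:
            return signs[0]
        return signs[q] * signs[q - 1]

    k = 0
    run_starts = {s + 1 for s, _ in runs}
    run_ends = {s + p for s, p in runs}
    # defined ratio indices, split into segments delimited by the runs:
    # a run (s, p) consumes ratios s+1 .. r+1 (undefined) and the bracketing
    # sign change between ratio(s) and ratio(r+2) via the closed formula.
    segment: list[int] = []
    segments: list[list[int]] = []
    q = 0
    while q <= N:
        if signs[q] == 0:
            if segment:
                segments.append(segment)
                segment = []
            # skip the run; the first ratio after the run, ratio(r+2), opens
            # the next segment (ratio(r+1) has a zero denominator).
            while q <= N and signs[q] == 0:
                q += 1
            q += 1  # skip ratio(r+1)
            continue
        segment.append(q)
        q += 1
    if segment:
        segments.append(segment)
    for seg in segments:
        for prev, cur in zip(seg, seg[1:]):
            if ratio(prev) * ratio(cur) < 0:
                k += 1
    for s, p in runs:
        if p % 2 == 0:
            raise ValueError(
                f"even-length interior zero string (s={s}, p={p}) is outside the "
                "classical Routh degeneracy rules"
            )
        end = s + p
        if end + 2 > N:
            raise ValueError("zero string extends too close to a nonzero Delta_n")
        bracket = ratio(s) * ratio(end + 2)
        if bracket == 0:
            raise ValueError("zero strings separated by a single nonzero Delta")
        k += (p + 1) // 2
        if (-1) ** ((p + 1) // 2) * bracket == -1:
            k += 1
    return RouthCount(k, tuple(zero_strings), truncated, indeterminate=False)


def orlando_check(eigenvalues: Sequence[complex]) -> tuple[complex, complex]:
    """Orlando's closed forms for the last two Hurwitz determinants.

    Delta_{n-1} = (-1)^{n(n-1)/2} prod_{i<k} (lambda_i + lambda_k) for the
    monic polynomial with the given roots; Delta_n is returned as
    a_n * Delta_{n-1}, which both determinants of the reconstructed
    polynomial satisfy identically.  Both vanish at a purely imaginary pair
    — the necessary condition for a Hopf bifurcation.
    """
    lam = list(eigenvalues)
    n = len(lam)
    if n < 1:
        raise ValueError("need at least one eigenvalue")
    sign = (-1) ** (n * (n - 1) // 2)
    prod = sp.Integer(1)
    for i in range(n):
        for k in range(i + 1, n):
            prod *= sp.sympify(lam[i]) + sp.sympify(lam[k])
    d_nm1 = sp.expand(sign * prod)
    a_n = sp.expand(sp.prod([-sp.sympify(x) for x in lam]))
    d_n = sp.expand(a_n * d_nm1)
    return d_nm1, d_n
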