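"""Exact multivariate polynomial evaluation over Fractions.

Sign decisions near stability boundaries must not suffer float rounding, so
grid scans evaluate the Hurwitz determinants at exactly representable
rational coordinates in rational arithmetic.  sympy substitution is exact
but far too slow per grid point; this helper flattens a polynomial once
into (coefficient, exponent) terms and evaluates with ``fractions.Fraction``.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import sympy as sp

__all__ = ["RationalPoly"]


class RationalPoly:
    """A polynomial with rational coefficients, callable on Fraction points."""

    def __init__(self, expr: sp.Expr, gens: Sequence[sp.Symbol]):
        self.gens = tuple(gens)
        expr = sp.expand(expr)
        if expr.free_symbols - set(self.gens):
            raise ValueError(
                f"expression has free symbols beyond the generators: "
                f"{expr.free_symbols - set(self.gens)}"
            )
        if expr == 0:
            self.terms: list[tuple[Fraction, tuple[int, ...]]] = []
        else:
            poly = sp.Poly(expr, *self.gens)
            self.terms = []
            for exps, coeff in poly.terms():
                if not coeff.is_Rational:
                    raise ValueError(f"non-rational coefficient {coeff}")
                self.terms.append(
                    (Fraction(int(coeff.p), int(coeff.q)), tuple(int(e) for e in exps))
                )
        self._max_exp = [
            max((t[1][i] for t in self.terms), default=0) for i in range(len(self.gens))
        ]

    def __call__(self, point: Sequence[Fraction]) -> Fraction:
        powers = []
        for x, emax in zip(point, self._max_exp):
            col = [Fraction(1)]
            for _ in range(emax):
                col.append(col[-1] * x)
            powers.append(col)
        total = Fraction(0)
        for coeff, exps in self.terms:
            term = coeff
            for i, e in enumerate(exps):
                if e:
                    term *= powers[i][e]
            total += term
        return total
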