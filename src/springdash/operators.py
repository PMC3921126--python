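"""Exact algebra of linear differential operators with parameter coefficients.

A :class:`DiffOperator` is a polynomial in the differentiation symbol ``D``
whose coefficients are exact multivariate polynomials (sympy expressions with
rational coefficients) in the network's spring and viscosity parameters.
All arithmetic is exact; no floating point enters the symbolic path.

The *shape* of an operator is the pair ``(hi, lo)`` of its highest and lowest
stored differential orders — the key invariant driving the A/B/C/D type
classification of constitutive equations.

Genericity claims ("these two operators share only the factor D^m",
"this matrix is generically invertible") are certified numerically-exactly:
parameters are replaced by random rational points and the claim is checked
with exact rational arithmetic, in several independent draws.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import sympy as sp

__all__ = [
    "Shape",
    "DiffOperator",
    "op_add",
    "op_mul",
    "shape_of",
    "generic_gcd",
    "sylvester_matrix",
    "GenericEvaluator",
]

D = sp.Symbol("D")  # the differentiation symbol


@dataclass(frozen=True, order=True)
class Shape:
    """Highest and lowest differential order of a nonzero operator."""

    hi: int
    lo: int

    def __post_init__(self):
        if not (0 <= self.lo <= self.hi):
            raise ValueError(f"invalid shape ({self.hi}, {self.lo})")

    @property
    def n_coeffs(self) -> int:
        return self.hi - self.lo + 1

    def __str__(self) -> str:
        return f"({self.hi}, {self.lo})"


def _expand_nonzero(expr) -> sp.Expr:
    e = sp.expand(sp.sympify(expr))
    return e


class DiffOperator:
    """Polynomial in D with exact parameter-polynomial coefficients.

    Stored as a sparse map from derivative order to a nonzero expanded
    coefficient; the zero operator has an empty map.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs: Mapping[int, object]):
        clean: dict[int, sp.Expr] = {}
        for order, c in coeffs.items():
            if order < 0:
                raise ValueError("derivative orders must be non-negative")
            c = _expand_nonzero(c)
            if c != 0:
                clean[int(order)] = c
        self.coeffs = clean

    # -- constructors -------------------------------------------------------
    @classmethod
    def constant(cls, value) -> "DiffOperator":
        return cls({0: value})

    @classmethod
    def from_list(cls, ascending: Sequence, lo: int = 0) -> "DiffOperator":
        return cls({lo + i: c for i, c in enumerate(ascending)})

    # -- basic queries ------------------------------------------------------
    @property
    def is_zero(self) -> bool:
        return not self.coeffs

    @property
    def degree(self) -> int:
        if self.is_zero:
            raise ValueError("zero operator has no degree")
        return max(self.coeffs)

    @property
    def low_order(self) -> int:
        if self.is_zero:
            raise ValueError("zero operator has no low order")
        return min(self.coeffs)

    def coeff(self, order: int) -> sp.Expr:
        return self.coeffs.get(order, sp.Integer(0))

    @property
    def leading_coeff(self) -> sp.Expr:
        return self.coeffs[self.degree]

    def free_symbols(self) -> set:
        syms: set = set()
        for c in self.coeffs.values():
            syms |= c.free_symbols
        return syms

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: "DiffOperator") -> "DiffOperator":
        merged = dict(self.coeffs)
        for order, c in other.coeffs.items():
            merged[order] = merged.get(order, sp.Integer(0)) + c
        return DiffOperator(merged)

    def __mul__(self, other: "DiffOperator") -> "DiffOperator":
        out: dict[int, sp.Expr] = {}
        for o1, c1 in self.coeffs.items():
            for o2, c2 in other.coeffs.items():
                order = o1 + o2
                out[order] = out.get(order, sp.Integer(0)) + c1 * c2
        return DiffOperator(out)

    def scale(self, factor) -> "DiffOperator":
        """Multiply every coefficient by a scalar expression (exact)."""
        factor = sp.sympify(factor)
        return DiffOperator(
            {order: sp.cancel(c * factor) for order, c in self.coeffs.items()}
        )

    def shift_down(self, m: int) -> "DiffOperator":
        """Exact division by D**m (all orders must be >= m)."""
        if m == 0:
            return self
        if self.is_zero:
            return self
        if self.low_order < m:
            raise ValueError(f"operator not divisible by D**{m}")
        return DiffOperator({order - m: c for order, c in self.coeffs.items()})

    def subs(self, mapping) -> "DiffOperator":
        out = {}
        for order, c in self.coeffs.items():
            out[order] = c.subs(mapping)
        return DiffOperator(out)

    def as_poly_expr(self) -> sp.Expr:
        """The operator as a sympy polynomial expression in D."""
        return sp.Add(*(c * D**order for order, c in self.coeffs.items()))

    # -- comparison / display -----------------------------------------------
    def equals(self, other: "DiffOperator") -> bool:
        if set(self.coeffs) != set(other.coeffs):
            return False
        return all(
            sp.simplify(self.coeffs[k] - other.coeffs[k]) == 0 for k in self.coeffs
        )

    def __repr__(self) -> str:
        return f"DiffOperator({self.pretty()})"

    def pretty(self) -> str:
        """Render e.g. ``n1*n2*D^2 + (E1*n2 + E2*n1)*D + E1*E2``."""
        if self.is_zero:
            return "0"
        terms = []
        for order in sorted(self.coeffs, reverse=True):
            c = self.coeffs[order]
            cs = sp.sstr(sp.factor(c))
            needs_parens = ("+" in cs[1:]) or (" - " in cs)
            if needs_parens:
                cs = f"({cs})"
            if order == 0:
                terms.append(cs)
            else:
                dpart = "D" if order == 1 else f"D^{order}"
                terms.append(dpart if cs == "1" else f"{cs}*{dpart}")
        return " + ".join(terms)


def op_add(f: DiffOperator, g: DiffOperator) -> DiffOperator:
    return f + g


def op_mul(f: DiffOperator, g: DiffOperator) -> DiffOperator:
    return f * g


def shape_of(f: DiffOperator) -> Shape:
    """Shape (highest, lowest stored differential order) of a nonzero operator."""
    if f.is_zero:
        raise ValueError("the zero operator has no shape")
    return Shape(hi=f.degree, lo=f.low_order)


class GenericEvaluator:
    """Random rational parameter points for certifying generic claims.

    Each parameter is drawn independently and uniformly from the integers
    2..1000 (as exact rationals); a claim is accepted only when *draws*
    independent samples agree.  Exact arithmetic avoids float tolerances.
    """

    LOW, HIGH = 2, 1000

    def __init__(self, seed: int = 0, draws: int = 3):
        self.rng = random.Random(seed)
        self.draws = draws

    def point(self, symbols: Iterable[sp.Symbol]) -> dict:
        return {
            s: sp.Rational(self.rng.randint(self.LOW, self.HIGH)) for s in symbols
        }

    def points(self, symbols: Iterable[sp.Symbol]) -> list[dict]:
        symbols = list(symbols)
        return [self.point(symbols) for _ in range(self.draws)]


class GenericDegeneracyError(RuntimeError):
    """Random rational draws disagreed on a generic claim."""


def _numeric_poly(f: DiffOperator, point: dict) -> sp.Poly:
    expr = f.as_poly_expr().subs(point)
    return sp.Poly(expr, D)


def generic_gcd(
    f: DiffOperator,
    g: DiffOperator,
    evaluator: GenericEvaluator | None = None,
) -> DiffOperator:
    """Generic gcd of two operators in D, treating parameters generically.

    For spring-dashpot operators the only generic common factor is a power of
    D: a common factor can arise solely because both operators lack low-order
    terms.  The structural candidate ``D**min(lo_f, lo_g)`` is therefore
    returned, after certifying that the residual pair is generically coprime:
    the resultant of the residuals must be nonzero at every random rational
    parameter point drawn by the evaluator.
    """
    if f.is_zero or g.is_zero:
        raise ValueError("generic_gcd requires nonzero operators")
    evaluator = evaluator or GenericEvaluator()
    m = min(f.low_order, g.low_order)
    rf, rg = f.shift_down(m), g.shift_down(m)
    symbols = rf.free_symbols() | rg.free_symbols()
    if rf.degree == 0 or rg.degree == 0:
        # a nonzero constant (in D) shares no root with anything
        return DiffOperator({m: 1})
    failures = 0
    for point in evaluator.points(symbols):
        pf, pg = _numeric_poly(rf, point), _numeric_poly(rg, point)
        if sp.resultant(pf.as_expr(), pg.as_expr(), D) == 0:
            failures += 1
    if failures:
        raise GenericDegeneracyError(
            f"residual resultant vanished in {failures}/{evaluator.draws} draws; "
            "re-sample or inspect the operators"
        )
    return DiffOperator({m: 1})


def sylvester_matrix(f, g) -> sp.Matrix:
    """Sylvester matrix of two polynomials in D (DiffOperators or coeff lists).

    For ``deg f = m`` and ``deg g = n`` the matrix is ``(m+n) x (m+n)``, with
    the coefficients of *f* repeated *n* times as columns and those of *g*
    repeated *m* times (band layout).  Its determinant is the resultant: zero
    exactly when the polynomials share a root.
    """
    fc = _coeff_list(f)
    gc = _coeff_list(g)
    m, n = len(fc) - 1, len(gc) - 1
    if m < 0 or n < 0:
        raise ValueError("sylvester_matrix requires nonzero polynomials")
    size = m + n
    M = sp.zeros(size, size)
    # column j of the f-band holds f's coefficients shifted down by j
    for j in range(n):
        for i, c in enumerate(fc):
            M[j + i, j] = c
    for j in range(m):
        for i, c in enumerate(gc):
            M[j + i, n + j] = c
    return M


def _coeff_list(f) -> list:
    """Descending coefficient list (leading first) of an operator/sequence."""
    if isinstance(f, DiffOperator):
        if f.is_zero:
            return []
        return [sp.sympify(f.coeff(k)) for k in range(f.degree, -1, -1)]
    seq = [sp.sympify(c) for c in f]
    while seq and seq[0] == 0:
        seq = seq[1:]
    return seq
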