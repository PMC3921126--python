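"""Constitutive equations of spring-dashpot networks.

Any series-parallel network of springs and dashpots obeys a single linear
ODE relating total stress and total strain,

    P(D) sigma = Q(D) eps,

where P and Q are polynomials in the differentiation operator D with
coefficients that are polynomials in the element parameters.  This module
derives that equation recursively:

* a spring contributes ``sigma = E eps`` (P = 1, Q = E);
* a dashpot contributes ``sigma = eta D eps`` (P = 1, Q = eta D);
* series join (shared stress, strains add):
  ``P = P1 Q2 + P2 Q1``, ``Q = Q1 Q2``;
* parallel join (shared strain, stresses add):
  ``P = P1 P2``, ``Q = Q1 P2 + Q2 P1``.

After each join the pair is *reduced*: the generic common factor (a power of
D, arising when both summed operators lack low-order terms) is divided out.
Reduced equations satisfy three structural constraints, checked throughout:
the stress operator always has a constant term (``P.lo = 0``), the strain
operator's low order is 0 or 1, and ``Q.hi - P.hi`` is 0 or 1.

*Normalization* divides both operators by one designated leading coefficient
— here always the strain-side (Q) leading coefficient, which is well defined
because ``Q.hi >= P.hi`` in reduced form.  The remaining ("non-monic")
coefficients, ordered stress side ascending then strain side ascending, form
the coefficient map c(theta) whose injectivity is what identifiability is
about.  The *count* of non-monic coefficients does not depend on which
leading coefficient is designated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy as sp

from .networks import DASHPOT, SPRING, Leaf, Network
from .operators import (
    DiffOperator,
    GenericEvaluator,
    Shape,
    generic_gcd,
    shape_of,
)

__all__ = [
    "ConstitutiveEquation",
    "CoefficientMap",
    "leaf_equation",
    "combine_series",
    "combine_parallel",
    "derive_constitutive",
    "normalize",
    "coefficient_map",
    "param_symbols",
]


def param_symbols(net: Network) -> list[sp.Symbol]:
    """Positive parameter symbols of the network's leaves, traversal order."""
    return [sp.Symbol(leaf.param, positive=True) for leaf in net.leaves()]


@dataclass(frozen=True)
class ConstitutiveEquation:
    """The reduced (and optionally normalized) pair P(D) sigma = Q(D) eps."""

    P: DiffOperator  # acts on stress sigma
    Q: DiffOperator  # acts on strain eps
    normalized: bool = False

    @property
    def p_shape(self) -> Shape:
        return shape_of(self.P)

    @property
    def q_shape(self) -> Shape:
        return shape_of(self.Q)

    @property
    def order(self) -> int:
        """Highest derivative of the stress component (the ODE order symbol)."""
        return self.p_shape.hi

    def check_reduced_form(self) -> None:
        """Assert the structural constraints of a reduced equation."""
        ps, qs = self.p_shape, self.q_shape
        if ps.lo != 0:
            raise AssertionError(f"stress operator low order {ps.lo} != 0")
        if qs.lo not in (0, 1):
            raise AssertionError(f"strain operator low order {qs.lo} not in {{0,1}}")
        if qs.hi - ps.hi not in (0, 1):
            raise AssertionError(
                f"order gap q_hi - p_hi = {qs.hi - ps.hi} not in {{0,1}}"
            )

    @property
    def n_nonmonic(self) -> int:
        """Number of non-monic coefficients: total coefficients minus one."""
        return self.p_shape.n_coeffs + self.q_shape.n_coeffs - 1

    def equals(self, other: "ConstitutiveEquation") -> bool:
        return self.P.equals(other.P) and self.Q.equals(other.Q)

    def pretty(self) -> str:
        return f"[{self.P.pretty()}] sigma = [{self.Q.pretty()}] eps"

    def to_dict(self) -> dict:
        return {
            "stress_operator": self.P.pretty(),
            "strain_operator": self.Q.pretty(),
            "stress_shape": [self.p_shape.hi, self.p_shape.lo],
            "strain_shape": [self.q_shape.hi, self.q_shape.lo],
            "order": self.order,
            "normalized": self.normalized,
            "monic_side": "strain" if self.normalized else None,
        }


def leaf_equation(leaf: Leaf) -> ConstitutiveEquation:
    """Constitutive equation of a single element (un-normalized)."""
    sym = sp.Symbol(leaf.param, positive=True)
    if leaf.kind == SPRING:
        return ConstitutiveEquation(DiffOperator({0: 1}), DiffOperator({0: sym}))
    if leaf.kind == DASHPOT:
        return ConstitutiveEquation(DiffOperator({0: 1}), DiffOperator({1: sym}))
    raise ValueError(f"unknown leaf kind {leaf.kind!r}")


def combine_series(
    eq1: ConstitutiveEquation,
    eq2: ConstitutiveEquation,
    evaluator: GenericEvaluator | None = None,
) -> ConstitutiveEquation:
    """Join two constitutive equations in series (stress shared, strains add)."""
    P = eq1.P * eq2.Q + eq2.P * eq1.Q
    Q = eq1.Q * eq2.Q
    g = generic_gcd(eq1.Q, eq2.Q, evaluator)
    m = g.low_order
    return ConstitutiveEquation(P.shift_down(m), Q.shift_down(m))


def combine_parallel(
    eq1: ConstitutiveEquation,
    eq2: ConstitutiveEquation,
    evaluator: GenericEvaluator | None = None,
) -> ConstitutiveEquation:
    """Join two constitutive equations in parallel (strain shared, stresses add)."""
    P = eq1.P * eq2.P
    Q = eq1.Q * eq2.P + eq2.Q * eq1.P
    g = generic_gcd(eq1.P, eq2.P, evaluator)
    m = g.low_order
    return ConstitutiveEquation(P.shift_down(m), Q.shift_down(m))


def derive_constitutive(
    net: Network,
    normalized: bool = True,
    evaluator: GenericEvaluator | None = None,
) -> ConstitutiveEquation:
    """Derive the reduced constitutive equation of a network.

    Recursive fold of the leaf equations through the series/parallel
    composition rules, reducing by the generic common D factor at every
    step.  The result is invariant to flattening and child order (the join
    operations are associative and commutative).  With ``normalized=True``
    (default) the returned equation is also monic-normalized.
    """
    evaluator = evaluator or GenericEvaluator()

    def fold(node: Network) -> ConstitutiveEquation:
        if node.is_leaf:
            return leaf_equation(node)
        combine = combine_series if node.mode == "series" else combine_parallel
        eq = fold(node.children[0])
        for child in node.children[1:]:
            eq = combine(eq, fold(child), evaluator)
        return eq

    eq = fold(net)
    eq.check_reduced_form()
    return normalize(eq) if normalized else eq


def normalize(eq: ConstitutiveEquation) -> ConstitutiveEquation:
    """Divide both operators by the designated leading coefficient.

    Convention: the leading coefficient of the higher-order operator; on an
    order tie, the strain-side one.  In reduced form ``Q.hi >= P.hi`` always,
    so the designated coefficient is the strain-side leading coefficient.
    Idempotent; the non-monic coefficient count is unaffected by the
    convention choice.
    """
    lead = eq.Q.leading_coeff
    if lead == 1:
        return ConstitutiveEquation(eq.P, eq.Q, normalized=True)
    inv = sp.cancel(1 / lead)
    return ConstitutiveEquation(eq.P.scale(inv), eq.Q.scale(inv), normalized=True)


@dataclass(frozen=True)
class CoefficientMap:
    """The vector c(theta) of non-monic coefficients of a normalized equation.

    Ordering: stress-side coefficients by ascending derivative order, then
    strain-side by ascending order, omitting the monic (strain-side leading)
    one.  Entries are simplified rational functions of the parameters.
    """

    entries: tuple
    params: tuple
    labels: tuple = field(default=())

    def __len__(self) -> int:
        return len(self.entries)

    def as_matrix(self) -> sp.Matrix:
        return sp.Matrix(list(self.entries))

    def jacobian(self) -> sp.Matrix:
        return self.as_matrix().jacobian(sp.Matrix(list(self.params)))


def coefficient_map(net: Network, evaluator: GenericEvaluator | None = None) -> CoefficientMap:
    """Coefficient map c: theta -> non-monic constitutive coefficients."""
    eq = derive_constitutive(net, normalized=True, evaluator=evaluator)
    ps, qs = eq.p_shape, eq.q_shape
    entries: list[sp.Expr] = []
    labels: list[str] = []
    # entries were already cancelled during normalization
    for order in range(0, ps.hi + 1):
        entries.append(eq.P.coeff(order))
        labels.append(f"a{order}")
    for order in range(qs.lo, qs.hi):  # q_hi is the monic one, omitted
        entries.append(eq.Q.coeff(order))
        labels.append(f"b{order}")
    return CoefficientMap(
        entries=tuple(entries),
        params=tuple(param_symbols(net)),
        labels=tuple(labels),
    )
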