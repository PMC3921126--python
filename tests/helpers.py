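"""Independent cross-check utilities for the test suite.

The transfer-function oracle derives a network's constitutive equation by a
completely different route from the package's operator-composition fold: it
composes scalar compliance ratios eps/sigma = P(s)/Q(s) as rational
functions of a Laplace-like symbol s (series compliances add; parallel
stiffnesses add), cancels common factors, and reads the two polynomials off
the reduced fraction.  Agreement with the fold-based derivation on the
normalized coefficients is a strong end-to-end check.
"""

from __future__ import annotations

import sympy as sp

from springdash.networks import SPRING, Network
from springdash.operators import DiffOperator

_s = sp.Symbol("s")


def _compliance(net: Network) -> sp.Expr:
    """eps/sigma transfer ratio of the network, as a rational function of s."""
    if net.is_leaf:
        sym = sp.Symbol(net.param, positive=True)
        return 1 / sym if net.kind == SPRING else 1 / (sym * _s)
    parts = [_compliance(c) for c in net.children]
    if net.mode == "series":
        return sp.cancel(sum(parts))
    return sp.cancel(1 / sum(1 / p for p in parts))


def transfer_function_equation(net: Network) -> tuple[DiffOperator, DiffOperator]:
    """Normalized (P, Q) operator pair derived via the transfer function.

    Returns operators scaled so the strain-side (Q) leading coefficient is
    one, matching the package's normalization convention.
    """
    ratio = sp.cancel(_compliance(net))  # = P(s)/Q(s)
    p_expr, q_expr = sp.fraction(ratio)
    p_poly = sp.Poly(sp.expand(p_expr), _s)
    q_poly = sp.Poly(sp.expand(q_expr), _s)
    lead = q_poly.LC()
    P = DiffOperator(
        {deg: sp.cancel(c / lead) for deg, c in zip(
            range(p_poly.degree(), -1, -1), p_poly.all_coeffs())}
    )
    Q = DiffOperator(
        {deg: sp.cancel(c / lead) for deg, c in zip(
            range(q_poly.degree(), -1, -1), q_poly.all_coeffs())}
    )
    return P, Q
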