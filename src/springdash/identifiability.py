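"""Local and global structural identifiability decisions, with oracles.

Local identifiability of a spring-dashpot network reduces to a count: the
network is locally identifiable exactly when the number of non-monic
coefficients of its reduced, normalized constitutive equation equals the
number of element parameters.  (The coefficient count never exceeds the
parameter count, so inequality always means unidentifiable.)

Global identifiability additionally requires that the network can be built
by attaching one basic element (spring or dashpot) at a time at the bounding
nodes.  On the canonical flattened tree this is the *caterpillar/spine*
condition: every internal node has at most one internal child, recursively.

Two numerical oracles validate the symbolic verdicts independently:

* :func:`jacobian_rank_oracle` — the coefficient map is finite-to-one iff
  its Jacobian has full column rank at a generic parameter point; the rank
  is computed exactly (rational arithmetic) at random rational points.
* :func:`preimage_count_oracle` — counts distinct positive-parameter
  solutions of ``c(theta) = c(theta0)`` by multistart damped least squares
  in log-parameter space; a globally identifiable model has a unique generic
  preimage, a locally-only one has several (e.g. arm permutations).

The shape-factorization machinery (matrix factored form, Sylvester block
certificate) explains *why* the counting criterion works: a join of two
locally identifiable systems is identifiable iff the padded block matrix
mapping the unknown sub-operator coefficients to the composed coefficients
is square — and any square such matrix is generically invertible, its
determinant being a product of triangular blocks and a Sylvester resultant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import sympy as sp
from scipy.optimize import least_squares

from .constitutive import (
    ConstitutiveEquation,
    coefficient_map,
    derive_constitutive,
    param_symbols,
)
from .networks import PARALLEL, SERIES, Network, flatten
from .operators import (
    DiffOperator,
    GenericEvaluator,
    Shape,
    shape_of,
    sylvester_matrix,
)

__all__ = [
    "LocalVerdict",
    "GlobalVerdict",
    "ShapeQuadruple",
    "ShapeMatrix",
    "local_identifiability",
    "jacobian_rank_oracle",
    "globally_constructible",
    "global_identifiability",
    "preimage_count_oracle",
    "quadruple_for_join",
    "build_shape_matrix",
    "is_good_quadruple",
    "has_elementary_spine_joins",
]


# ---------------------------------------------------------------------------
# Local identifiability (coefficient counting)

@dataclass(frozen=True)
class LocalVerdict:
    status: str  # "locally_identifiable" | "unidentifiable"
    n_params: int
    n_nonmonic: int

    @property
    def identifiable(self) -> bool:
        return self.status == "locally_identifiable"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "n_params": self.n_params,
            "n_nonmonic": self.n_nonmonic,
        }


def local_identifiability(
    net: Network,
    evaluator: GenericEvaluator | None = None,
    eq: ConstitutiveEquation | None = None,
) -> LocalVerdict:
    """Decide local identifiability by the coefficient-counting criterion.

    A pre-derived (reduced, un-normalized) equation can be passed to avoid
    re-deriving it in bulk sweeps.
    """
    if eq is None:
        eq = derive_constitutive(net, normalized=False, evaluator=evaluator)
    n_params = len(list(net.leaves()))
    n_nonmonic = eq.n_nonmonic
    if n_nonmonic > n_params:
        raise AssertionError(
            "non-monic coefficient count exceeds parameter count — upstream bug"
        )
    status = "locally_identifiable" if n_nonmonic == n_params else "unidentifiable"
    return LocalVerdict(status=status, n_params=n_params, n_nonmonic=n_nonmonic)


def jacobian_rank_oracle(
    net: Network,
    seed: int = 0,
    evaluator: GenericEvaluator | None = None,
    eq: ConstitutiveEquation | None = None,
) -> int:
    """Exact generic rank of the Jacobian of the coefficient map.

    The map is finite-to-one iff this rank equals the parameter count.  The
    Jacobian is evaluated exactly at independent random integer points from
    the generic protocol; the maximum rank over draws is returned and a
    warning is emitted if the draws disagree (a non-generic sample).

    Each coefficient is ``c_i = p_i / L`` with ``p_i`` and the designated
    leading coefficient ``L`` integer-coefficient polynomials, so by the
    quotient rule the Jacobian at a point where ``L != 0`` has the same rank
    as the polynomial matrix ``[L * dp_i/dt_j - p_i * dL/dt_j]``.  That
    matrix is evaluated with exact big-integer arithmetic and its rank
    computed over the rationals — no floating point anywhere.
    """
    evaluator = evaluator or GenericEvaluator(seed)
    if eq is None:
        eq = derive_constitutive(net, normalized=False, evaluator=evaluator)
    params = param_symbols(net)
    L = eq.Q.leading_coeff
    polys = [eq.P.coeff(o) for o in range(eq.p_shape.hi + 1)]
    polys += [eq.Q.coeff(o) for o in range(eq.q_shape.lo, eq.q_shape.hi)]
    dL = [sp.diff(L, t) for t in params]
    entries = [
        L * sp.diff(p, t) - p * dLj
        for p in polys
        for t, dLj in zip(params, dL)
    ]
    fn = sp.lambdify(params, entries, modules="math")
    n_rows, n_cols = len(polys), len(params)
    ranks = []
    for _ in range(evaluator.draws):
        values = [
            evaluator.rng.randint(evaluator.LOW, evaluator.HIGH) for _ in params
        ]
        flat = fn(*values)  # exact Python integers
        M = sp.Matrix(n_rows, n_cols, [sp.Integer(v) for v in flat])
        ranks.append(M.rank())
    if len(set(ranks)) > 1:
        warnings.warn(
            f"Jacobian rank disagreed across draws: {ranks}; using the maximum"
        )
    return max(ranks)


# ---------------------------------------------------------------------------
# Global identifiability (spine condition)

@dataclass(frozen=True)
class GlobalVerdict:
    status: str  # "globally_identifiable" | "locally_only" | "unidentifiable"
    constructible: bool
    construction_order: Optional[tuple] = None
    local: Optional[LocalVerdict] = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "constructible": self.constructible,
            "construction_order": (
                list(self.construction_order) if self.construction_order else None
            ),
            "local": self.local.to_dict() if self.local else None,
        }


def globally_constructible(net: Network) -> tuple[bool, Optional[tuple]]:
    """Caterpillar/spine test: buildable one element at a time?

    On the canonical flattened tree, the network can be constructed by
    adding one spring or dashpot at a time at the bounding nodes iff every
    internal node has at most one internal (non-leaf) child, recursively.
    When true, an explicit build order is returned: starting from the
    innermost spine node, its first canonical leaf is the seed and every
    further leaf is attached with the enclosing node's join mode.
    """
    net = flatten(net)
    if net.is_leaf:
        return True, ((net.param, "seed"),)

    spine: list[Network] = []
    node = net
    while True:
        internal = [c for c in node.children if not c.is_leaf]
        if len(internal) > 1:
            return False, None
        spine.append(node)
        if not internal:
            break
        node = internal[0]

    order: list[tuple[str, str]] = []
    for depth, node in enumerate(reversed(spine)):
        leaves = [c for c in node.children if c.is_leaf]
        if depth == 0:
            order.append((leaves[0].param, "seed"))
            leaves = leaves[1:]
        for leaf in leaves:
            order.append((leaf.param, node.mode))
    return True, tuple(order)


def global_identifiability(
    net: Network, evaluator: GenericEvaluator | None = None
) -> GlobalVerdict:
    """Combine the counting criterion with the spine condition."""
    local = local_identifiability(net, evaluator)
    constructible, order = globally_constructible(net)
    if not local.identifiable:
        status = "unidentifiable"
    elif constructible:
        status = "globally_identifiable"
    else:
        status = "locally_only"
    return GlobalVerdict(
        status=status,
        constructible=constructible,
        construction_order=order,
        local=local,
    )


def has_elementary_spine_joins(net: Network) -> bool:
    """Necessary condition for global identifiability.

    A globally identifiable network admits, at every internal node, a binary
    join in which one side is a spring, a dashpot, or (series) a Maxwell /
    (parallel) a Voigt element.  On the canonical flattened tree this means
    every internal node carries at least one leaf child and at most one
    internal child.
    """
    net = flatten(net)

    def walk(node: Network) -> bool:
        if node.is_leaf:
            return True
        internal = [c for c in node.children if not c.is_leaf]
        leaves = [c for c in node.children if c.is_leaf]
        if len(internal) > 1 or not leaves:
            return False
        return all(walk(c) for c in internal)

    return walk(net)


# ---------------------------------------------------------------------------
# Preimage-count oracle

class PreimageSolveError(RuntimeError):
    """The multistart solver found no solution reaching tolerance."""


def preimage_count_oracle(
    net: Network,
    seed: int = 0,
    n_starts: int = 200,
    residual_tol: float = 1e-9,
    cluster_tol: float = 1e-4,
    max_params: int = 8,
) -> int:
    """Count distinct positive preimages of a generic coefficient vector.

    Draws a random integer parameter point theta0 (components 2..1000),
    computes the coefficient vector c0 = c(theta0), and solves
    ``c(theta) = c0`` by damped least squares in log-parameter space from
    *n_starts* starting points: theta0 itself plus points log-uniform in
    [1e-2, 1e2] per coordinate.  Converged solutions (max relative residual
    below *residual_tol*) are clustered at relative tolerance *cluster_tol*
    and the number of distinct clusters is returned.

    A globally identifiable model returns 1; a locally-only identifiable
    model returns the (finite) number of preimages the optimizer can reach,
    e.g. the arm-permutation count of a generalized Kelvin-Voigt chain.
    """
    cmap = coefficient_map(net)
    k = len(cmap.params)
    if k > max_params:
        raise ValueError(f"too many parameters for the oracle ({k} > {max_params})")
    fn = sp.lambdify(list(cmap.params), list(cmap.entries), "numpy")

    rng = np.random.default_rng(seed)
    theta0 = rng.integers(GenericEvaluator.LOW, GenericEvaluator.HIGH + 1, size=k)
    theta0 = theta0.astype(float)
    c0 = np.asarray(fn(*theta0), dtype=float)
    scale = np.maximum(np.abs(c0), 1e-12)

    def residual(x):
        # overflow/zero-division on wild optimizer excursions is expected;
        # non-finite residuals are mapped to a large penalty
        with np.errstate(all="ignore"):
            theta = np.exp(x)
            r = (np.asarray(fn(*theta), dtype=float) - c0) / scale
        return np.where(np.isfinite(r), r, 1e6)

    lo, hi = np.log(1e-2), np.log(1e2)
    starts = [np.log(theta0)]
    starts.extend(rng.uniform(lo, hi, size=k) for _ in range(max(0, n_starts - 1)))

    solutions: list[np.ndarray] = []
    for x0 in starts:
        try:
            res = least_squares(
                residual, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if np.max(np.abs(residual(res.x))) >= residual_tol:
            continue
        theta = np.exp(res.x)
        for known in solutions:
            if np.max(np.abs(theta - known) / np.abs(known)) < cluster_tol:
                break
        else:
            solutions.append(theta)
    if not solutions:
        raise PreimageSolveError(
            "no start reached the residual tolerance; the target point may be "
            "degenerate — retry with a different seed"
        )
    return len(solutions)


# ---------------------------------------------------------------------------
# Shape factorization: matrix factored form and the Sylvester certificate

@dataclass(frozen=True)
class ShapeQuadruple:
    """Shapes of a factorization problem ``f = U1*K2 + U2*K1, g = K1*K2``.

    For a series join the unknown operators U are the stress sides (P1, P2)
    and the known monic pair K the strain sides (Q1, Q2); for a parallel
    join the roles are exchanged.  A common low-order factor D**m of the
    known pair is divided out before the linear system is formed, mirroring
    the gcd reduction of the composed equation.
    """

    u1: Shape
    k1: Shape
    u2: Shape
    k2: Shape
    mode: str = SERIES

    @property
    def reduction(self) -> int:
        return min(self.k1.lo, self.k2.lo)

    @property
    def n_columns(self) -> int:
        return self.u1.n_coeffs + self.u2.n_coeffs

    @property
    def n_rows(self) -> int:
        m = self.reduction
        r1_hi, r1_lo = self.k1.hi - m, self.k1.lo - m
        r2_hi, r2_lo = self.k2.hi - m, self.k2.lo - m
        row_lo = min(self.u1.lo + r2_lo, self.u2.lo + r1_lo)
        row_hi = max(self.u1.hi + r2_hi, self.u2.hi + r1_hi)
        return row_hi - row_lo + 1

    @property
    def is_square(self) -> bool:
        return self.n_rows == self.n_columns


def quadruple_for_join(
    eq1: ConstitutiveEquation, eq2: ConstitutiveEquation, mode: str
) -> ShapeQuadruple:
    """Shape quadruple of the factorization problem posed by a join."""
    if mode == SERIES:
        return ShapeQuadruple(
            u1=eq1.p_shape, k1=eq1.q_shape, u2=eq2.p_shape, k2=eq2.q_shape,
            mode=SERIES,
        )
    if mode == PARALLEL:
        return ShapeQuadruple(
            u1=eq1.q_shape, k1=eq1.p_shape, u2=eq2.q_shape, k2=eq2.p_shape,
            mode=PARALLEL,
        )
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class ShapeMatrix:
    """Matrix factored form [M1 | M2] of a shape factorization problem.

    Column j of M1 holds the coefficients of ``D**order * R2`` (R2 = reduced
    known operator of the second system), so that M1 maps the unknown U1
    coefficients to their contribution to the composed operator
    ``f = U1*R2 + U2*R1``; likewise M2 with R1.  Rows are aligned by
    monomial degree (ascending from ``row_lo``) across both blocks.
    """

    matrix: sp.Matrix
    quadruple: ShapeQuadruple
    row_lo: int
    column_orders: tuple  # (block, derivative order) per column
    R1: DiffOperator
    R2: DiffOperator

    @property
    def is_square(self) -> bool:
        return self.matrix.rows == self.matrix.cols


def build_shape_matrix(
    q: ShapeQuadruple, K1: DiffOperator, K2: DiffOperator
) -> ShapeMatrix:
    """Assemble the padded block matrix for given known operators K1, K2."""
    if shape_of(K1) != q.k1 or shape_of(K2) != q.k2:
        raise ValueError("operators inconsistent with the quadruple's known shapes")
    m = q.reduction
    R1, R2 = K1.shift_down(m), K2.shift_down(m)
    row_lo = min(q.u1.lo + R2.low_order, q.u2.lo + R1.low_order)
    row_hi = max(q.u1.hi + R2.degree, q.u2.hi + R1.degree)
    n_rows = row_hi - row_lo + 1

    columns: list[list] = []
    orders: list[tuple[int, int]] = []
    for block, (u, R) in enumerate(((q.u1, R2), (q.u2, R1)), start=1):
        for order in range(u.lo, u.hi + 1):
            col = [sp.Integer(0)] * n_rows
            for r_order, c in R.coeffs.items():
                col[order + r_order - row_lo] = c
            columns.append(col)
            orders.append((block, order))
    M = sp.Matrix(n_rows, len(columns), lambda i, j: columns[j][i])
    return ShapeMatrix(
        matrix=M, quadruple=q, row_lo=row_lo, column_orders=tuple(orders),
        R1=R1, R2=R2,
    )


def _sample_known(
    shape: Shape, evaluator: GenericEvaluator
) -> DiffOperator:
    """Random rational operator of the given shape, monic leading coefficient."""
    coeffs = {shape.hi: sp.Integer(1)}
    for order in range(shape.lo, shape.hi):
        coeffs[order] = sp.Rational(
            evaluator.rng.randint(evaluator.LOW, evaluator.HIGH)
        )
    return DiffOperator(coeffs)


def _sylvester_block_permutation(sm: ShapeMatrix) -> Optional[tuple]:
    """Search for a column order exposing the block-triangular structure.

    The certified structure (the reason square shape matrices are generically
    invertible) is, with rows in descending degree order and after a suitable
    column permutation,

        [ L  0  0 ]
        [ *  S  0 ]
        [ *  *  U ]

    with L and U triangular with nonzero diagonals and S the Sylvester matrix
    of the reduced known operators R1, R2 (their full coefficient vectors
    after the common D**m factor has been divided out).  The determinant is
    then det(L) * resultant(R1, R2) * det(U), generically nonzero.  Rows are
    kept in degree order (either orientation, since the case analysis swaps
    the two systems without loss of generality).  Returns the column
    permutation found, or None.
    """
    M = sm.matrix
    n = M.cols
    if not sm.is_square or n > 8:
        return None
    d1, d2 = sm.R1.degree, sm.R2.degree
    s = d1 + d2
    if s > n:
        return None
    syl_candidates = (
        [sylvester_matrix(sm.R1, sm.R2), sylvester_matrix(sm.R2, sm.R1)]
        if s
        else []
    )
    a_plus_b = n - s

    def triangular_ok(block):
        k = block.rows
        if any(block[i, i] == 0 for i in range(k)):
            return False
        lower = all(block[i, j] == 0 for i in range(k) for j in range(i + 1, k))
        upper = all(block[i, j] == 0 for i in range(k) for j in range(i))
        return lower or upper

    def structure_ok(P, a):
        b = a_plus_b - a
        if a:
            if not triangular_ok(P[:a, :a]):
                return False
            if any(P[i, j] != 0 for i in range(a) for j in range(a, n)):
                return False
        if s:
            Sb = P[a : a + s, a : a + s]
            if not any(Sb == cand for cand in syl_candidates):
                return False
            if any(P[i, j] != 0 for i in range(a, a + s) for j in range(a + s, n)):
                return False
        if b and not triangular_ok(P[a + s :, a + s :]):
            return False
        return True

    # the WLOG swap in the case analysis can mirror the layout, so try the
    # rows both descending (the conventional Sylvester orientation) and
    # ascending by degree
    for R in (M[::-1, :], M):
        cols = [R[:, j] for j in range(n)]
        for perm in itertools.permutations(range(n)):
            P = sp.Matrix.hstack(*(cols[j] for j in perm))
            for a in range(a_plus_b + 1):
                if structure_ok(P, a):
                    return perm
    return None


class ShapeMatrixCertificateError(RuntimeError):
    """A square shape matrix failed its generic-invertibility certificate."""


def is_good_quadruple(
    q: ShapeQuadruple,
    evaluator: GenericEvaluator | None = None,
    check_sylvester_block: bool = True,
) -> bool:
    """Does the shape factorization problem have finitely many solutions?

    True iff the matrix factored form is square.  For square matrices the
    claim "square implies generically invertible" is certified: at every
    random rational draw of the known operators the exact determinant must
    be nonzero, and (for matrices small enough to search) a column
    permutation must expose the block-triangular form whose middle block is
    the Sylvester matrix of the reduced known operators.  A square matrix
    with vanishing determinant at all draws signals an upstream bug.
    """
    evaluator = evaluator or GenericEvaluator()
    if not q.is_square:
        return False
    zero_dets = 0
    block_seen = False
    for _ in range(evaluator.draws):
        K1 = _sample_known(q.k1, evaluator)
        K2 = _sample_known(q.k2, evaluator)
        sm = build_shape_matrix(q, K1, K2)
        if sm.matrix.det() == 0:
            zero_dets += 1
            continue
        if check_sylvester_block and not block_seen:
            if _sylvester_block_permutation(sm) is not None:
                block_seen = True
    if zero_dets == evaluator.draws:
        raise ShapeMatrixCertificateError(
            "square shape matrix had zero determinant at every draw"
        )
    if zero_dets:
        warnings.warn(
            f"shape matrix determinant vanished in {zero_dets}/{evaluator.draws} "
            "draws (non-generic samples)"
        )
    if check_sylvester_block and q.n_columns <= 8 and not block_seen:
        raise ShapeMatrixCertificateError(
            "no column permutation exposed the Sylvester block structure"
        )
    return True
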