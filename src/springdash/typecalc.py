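"""Type classification (A/B/C/D) and the identifiability tables.

Every reduced spring-dashpot constitutive equation falls into one of four
types, determined by the shapes of its stress operator P and strain
operator Q (with n = P.hi):

=====  ==========  ==========
type   Q.hi        Q.lo
=====  ==========  ==========
A      n           0
B      n + 1       1
C      n + 1       0
D      n           1
=====  ==========  ==========

Anchors: a spring is type A, a dashpot type B, a Voigt element (spring |
dashpot) type C, a Maxwell element (spring - dashpot) type D.

The *identifiability tables* give the type of a series or parallel join of
two locally identifiable typed systems, or the marker ``u`` when the join is
unidentifiable; ``u`` is absorbing.  Replacing springs by A, dashpots by B
and folding the network tree through the tables yields the typing function
tau, which decides local identifiability without ever deriving the
constitutive equation — and, when the result is ``u``, localizes the first
join at which identifiability is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .networks import SERIES, SPRING, Network
from .operators import Shape

__all__ = [
    "TypeLabel",
    "TypeTrace",
    "JoinRecord",
    "classify_shapes",
    "table_series",
    "table_parallel",
    "tau",
    "render_tables",
]


class TypeLabel(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    U = "u"

    def __str__(self) -> str:
        return self.value


_L = TypeLabel
_ORDER = (_L.A, _L.B, _L.C, _L.D, _L.U)

# Join tables: rows/columns ordered A, B, C, D, u.  Both are symmetric and
# u-absorbing.  The parallel table is anchored by parallel(A, B) = C (the
# Voigt element); the series table by series(A, B) = D (the Maxwell element).
_PARALLEL_TABLE = {
    _L.A: (_L.U, _L.C, _L.U, _L.A, _L.U),
    _L.B: (_L.C, _L.U, _L.U, _L.B, _L.U),
    _L.C: (_L.U, _L.U, _L.U, _L.C, _L.U),
    _L.D: (_L.A, _L.B, _L.C, _L.D, _L.U),
    _L.U: (_L.U, _L.U, _L.U, _L.U, _L.U),
}

_SERIES_TABLE = {
    _L.A: (_L.U, _L.D, _L.A, _L.U, _L.U),
    _L.B: (_L.D, _L.U, _L.B, _L.U, _L.U),
    _L.C: (_L.A, _L.B, _L.C, _L.D, _L.U),
    _L.D: (_L.U, _L.U, _L.D, _L.U, _L.U),
    _L.U: (_L.U, _L.U, _L.U, _L.U, _L.U),
}


def table_series(t1: TypeLabel, t2: TypeLabel) -> TypeLabel:
    """Type of the series join of two typed systems (u = unidentifiable)."""
    return _SERIES_TABLE[TypeLabel(t1)][_ORDER.index(TypeLabel(t2))]


def table_parallel(t1: TypeLabel, t2: TypeLabel) -> TypeLabel:
    """Type of the parallel join of two typed systems (u = unidentifiable)."""
    return _PARALLEL_TABLE[TypeLabel(t1)][_ORDER.index(TypeLabel(t2))]


def classify_shapes(p_shape: Shape, q_shape: Shape) -> TypeLabel:
    """Classify a reduced equation by the shapes of its P and Q operators."""
    if p_shape.lo != 0:
        raise ValueError(
            f"not a reduced equation: stress shape {p_shape} has nonzero low order"
        )
    n = p_shape.hi
    key = (q_shape.hi - n, q_shape.lo)
    mapping = {(0, 0): _L.A, (1, 1): _L.B, (1, 0): _L.C, (0, 1): _L.D}
    if key not in mapping:
        raise ValueError(
            f"shapes P={p_shape}, Q={q_shape} match no type — upstream bug"
        )
    return mapping[key]


@dataclass(frozen=True)
class JoinRecord:
    """One pairwise application of a table while folding an n-ary node."""

    path: tuple  # child-index path of the composite node
    mode: str
    step: int  # 0-based fold step within the node
    left_label: TypeLabel  # accumulated label of children[0..step]
    right_label: TypeLabel  # label of children[step + 1]
    result: TypeLabel

    def describe(self, node: Network) -> str:
        sep = "-" if self.mode == SERIES else "|"
        left = f" {sep} ".join(c.serialize() for c in node.children[: self.step + 1])
        right = node.children[self.step + 1].serialize()
        return (
            f"{self.mode} join of [{left}] (type {self.left_label}) with "
            f"[{right}] (type {self.right_label}) -> {self.result}"
        )


@dataclass
class TypeTrace:
    """Per-node type annotations and the first unidentifiable join, if any."""

    node_labels: dict = field(default_factory=dict)  # path -> TypeLabel
    joins: list = field(default_factory=list)  # list[JoinRecord]
    first_u: Optional[JoinRecord] = None

    def label_at(self, path: tuple) -> TypeLabel:
        return self.node_labels[path]


def tau(net: Network) -> tuple[TypeLabel, TypeTrace]:
    """Typing function: fold leaf types through the identifiability tables.

    Springs map to A, dashpots to B; n-ary joins are folded left-to-right
    over the canonically sorted children (the result is fold-order
    independent).  The trace labels every node and records the first join
    producing the unidentifiable marker u.
    """
    trace = TypeTrace()

    def visit(node: Network, path: tuple) -> TypeLabel:
        if node.is_leaf:
            label = _L.A if node.kind == SPRING else _L.B
            trace.node_labels[path] = label
            return label
        table = table_series if node.mode == SERIES else table_parallel
        child_labels = [
            visit(child, path + (i,)) for i, child in enumerate(node.children)
        ]
        acc = child_labels[0]
        for step, right in enumerate(child_labels[1:]):
            result = table(acc, right)
            record = JoinRecord(
                path=path,
                mode=node.mode,
                step=step,
                left_label=acc,
                right_label=right,
                result=result,
            )
            trace.joins.append(record)
            if result is _L.U and trace.first_u is None and acc is not _L.U and right is not _L.U:
                trace.first_u = record
            acc = result
        trace.node_labels[path] = acc
        return acc

    label = visit(net, ())
    return label, trace


def render_tables() -> str:
    """Render both 5x5 identifiability tables as text."""
    lines = []
    for title, table in (
        ("Parallel connection", _PARALLEL_TABLE),
        ("Series connection", _SERIES_TABLE),
    ):
        lines.append(title)
        header = "    " + "  ".join(str(t) for t in _ORDER)
        lines.append(header)
        for row in _ORDER:
            cells = "  ".join(str(c) for c in table[row])
            lines.append(f"  {row}  {cells}")
        lines.append("")
    return "\n".join(lines)
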