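"""Series-parallel spring-dashpot networks.

A viscoelastic network is a rooted series-parallel tree whose leaves are
ideal springs (Hooke's law, sigma = E*eps) and dashpots (Newtonian,
sigma = eta * d eps/dt).  Composite nodes join their children either in
series (stress shared, strains add) or in parallel (strain shared, stresses
add).

Networks are kept in a *canonical form*: composite nodes are flattened (no
series node directly under a series node, likewise for parallel), children
are sorted by a deterministic key (leaves first, then by canonical
serialization), and every leaf carries a unique parameter symbol.

The text DSL uses ``-`` for series and ``|`` for parallel, e.g. the Burgers
model is ``(E1 - n1) - (E2 | n2)``.  Chains of a single operator need no
parentheses; mixing the two operators at one level is a syntax error.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass
from typing import Iterator, Optional

import yaml

SPRING = "spring"
DASHPOT = "dashpot"
SERIES = "series"
PARALLEL = "parallel"

__all__ = [
    "Leaf",
    "Composite",
    "Network",
    "NetworkSyntaxError",
    "parse_network",
    "parse_network_file",
    "flatten",
    "count_elements",
    "enumerate_networks",
    "random_network",
    "builtin_model",
    "BUILTIN_MODELS",
    "network_to_dict",
    "network_from_dict",
    "load_network_config",
]


class NetworkSyntaxError(ValueError):
    """Raised for malformed DSL input; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Leaf:
    """A single spring or dashpot with its parameter symbol name."""

    kind: str  # SPRING or DASHPOT
    param: str

    def __post_init__(self):
        if self.kind not in (SPRING, DASHPOT):
            raise ValueError(f"unknown element kind {self.kind!r}")

    @property
    def is_leaf(self) -> bool:
        return True

    def serialize(self) -> str:
        return self.param

    def leaves(self) -> Iterator["Leaf"]:
        yield self


@dataclass(frozen=True)
class Composite:
    """A series or parallel join of two or more sub-networks."""

    mode: str  # SERIES or PARALLEL
    children: tuple  # tuple[Network, ...], length >= 2

    def __post_init__(self):
        if self.mode not in (SERIES, PARALLEL):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.children) < 2:
            raise ValueError("composite node needs at least two children")

    @property
    def is_leaf(self) -> bool:
        return False

    def serialize(self) -> str:
        sep = " - " if self.mode == SERIES else " | "
        parts = []
        for child in self.children:
            s = child.serialize()
            parts.append(s if child.is_leaf else f"({s})")
        return sep.join(parts)

    def leaves(self) -> Iterator[Leaf]:
        for child in self.children:
            yield from child.leaves()


Network = Leaf | Composite


def _canonical_key(net: Network) -> tuple:
    # leaves sort before composites; ties broken by serialization
    return (0 if net.is_leaf else 1, net.serialize())


def flatten(net: Network) -> Network:
    """Return the canonical (flattened, sorted) form of *net*.

    Series children of a series node are spliced into their parent
    (associativity), likewise for parallel; children are then sorted by the
    canonical key.  Idempotent, and the derived constitutive equation is
    unchanged because both join operations are associative and commutative.
    """
    if net.is_leaf:
        return net
    merged: list[Network] = []
    for child in net.children:
        child = flatten(child)
        if not child.is_leaf and child.mode == net.mode:
            merged.extend(child.children)
        else:
            merged.append(child)
    merged.sort(key=_canonical_key)
    return Composite(net.mode, tuple(merged))


def _validate_params(net: Network) -> None:
    seen: set[str] = set()
    for leaf in net.leaves():
        if leaf.param in seen:
            raise ValueError(f"duplicate parameter symbol {leaf.param!r}")
        seen.add(leaf.param)


def count_elements(net: Network) -> tuple[int, int]:
    """Return ``(n_springs, n_dashpots)``; the sum is the parameter count."""
    springs = dashpots = 0
    for leaf in net.leaves():
        if leaf.kind == SPRING:
            springs += 1
        else:
            dashpots += 1
    return springs, dashpots


# ---------------------------------------------------------------------------
# DSL parser

_LEAF_RE = re.compile(r"[En][A-Za-z0-9_]*")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        c = text[pos]
        if c.isspace():
            pos += 1
            continue
        m = _LEAF_RE.match(text, pos)
        if m is not None:
            tokens.append(("leaf", m.group(), pos))
            pos = m.end()
        elif c in "-|":
            tokens.append(("op", c, pos))
            pos += 1
        elif c == "(":
            tokens.append(("lp", c, pos))
            pos += 1
        elif c == ")":
            tokens.append(("rp", c, pos))
            pos += 1
        else:
            raise NetworkSyntaxError(f"unexpected character {c!r}", pos)
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], length: int):
        self.tokens = tokens
        self.i = 0
        self.length = length

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is not None:
            self.i += 1
        return tok

    def parse_expr(self) -> Network:
        terms = [self.parse_term()]
        op: Optional[str] = None
        while True:
            tok = self.peek()
            if tok is None or tok[0] == "rp":
                break
            if tok[0] != "op":
                raise NetworkSyntaxError(
                    f"expected '-' or '|' but found {tok[1]!r}", tok[2]
                )
            if op is None:
                op = tok[1]
            elif tok[1] != op:
                raise NetworkSyntaxError(
                    "mixed '-' and '|' need parentheses", tok[2]
                )
            self.next()
            terms.append(self.parse_term())
        if op is None:
            return terms[0]
        mode = SERIES if op == "-" else PARALLEL
        return Composite(mode, tuple(terms))

    def parse_term(self) -> Network:
        tok = self.next()
        if tok is None:
            raise NetworkSyntaxError("unexpected end of input", self.length)
        name, value, pos = tok
        if name == "leaf":
            kind = SPRING if value[0] == "E" else DASHPOT
            return Leaf(kind, value)
        if name == "lp":
            inner = self.parse_expr()
            closing = self.next()
            if closing is None or closing[0] != "rp":
                raise NetworkSyntaxError("unbalanced '('", pos)
            return inner
        raise NetworkSyntaxError(f"unexpected token {value!r}", pos)


def parse_network(text: str) -> Network:
    """Parse a DSL expression into a canonical network.

    Leaf tokens starting with ``E`` are springs, with ``n`` dashpots; ``-``
    joins in series, ``|`` in parallel.  The result is flattened and
    canonically sorted, so ``parse_network(net.serialize())`` reproduces any
    canonical network exactly.
    """
    if not text or not text.strip():
        raise NetworkSyntaxError("empty input", 0)
    parser = _Parser(_tokenize(text), len(text))
    net = parser.parse_expr()
    trailing = parser.peek()
    if trailing is not None:
        raise NetworkSyntaxError(f"unexpected token {trailing[1]!r}", trailing[2])
    net = flatten(net)
    _validate_params(net)
    return net


def parse_network_file(path) -> list[Network]:
    """Read a DSL file: one expression per line, ``#`` starts a comment."""
    nets = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                nets.append(parse_network(line))
    return nets


# ---------------------------------------------------------------------------
# Structured (dict / YAML / JSON) form

def network_to_dict(net: Network) -> dict:
    if net.is_leaf:
        return {"element": net.kind, "param": net.param}
    return {"join": net.mode, "children": [network_to_dict(c) for c in net.children]}


def network_from_dict(d: dict) -> Network:
    if "element" in d:
        return Leaf(d["element"], d["param"])
    if "join" not in d:
        raise ValueError("node must have 'element' or 'join'")
    children = tuple(network_from_dict(c) for c in d["children"])
    net = flatten(Composite(d["join"], children))
    _validate_params(net)
    return net


def load_network_config(path) -> Network:
    """Load a network from a YAML or JSON config mirroring the tree."""
    with open(path) as fh:
        text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    return network_from_dict(data)


# ---------------------------------------------------------------------------
# Enumeration and random generation

_MAX_ENUM = 7


def _rename_params(net: Network) -> Network:
    """Assign canonical parameter names E1.., n1.. in traversal order."""
    counters = {SPRING: 0, DASHPOT: 0}

    def walk(node: Network) -> Network:
        if node.is_leaf:
            counters[node.kind] += 1
            prefix = "E" if node.kind == SPRING else "n"
            return Leaf(node.kind, f"{prefix}{counters[node.kind]}")
        return Composite(node.mode, tuple(walk(c) for c in node.children))

    return walk(net)


def _canonical_rename(net: Network) -> Network:
    """Rename parameters in traversal order, keeping the tree canonical.

    Renaming can perturb the canonical child order (children are sorted by
    their serialization), so flatten and rename are iterated to a fixpoint.
    """
    prev = None
    for _ in range(10):
        net = flatten(_rename_params(net))
        s = net.serialize()
        if s == prev:
            break
        prev = s
    return net


def _skeletons(n: int, top_mode_forbidden: Optional[str], cache: dict) -> list[Network]:
    """Canonical networks of *n* leaves with placeholder parameter names.

    Leaf kinds are enumerated (both spring and dashpot); parameter names are
    the kind letters, so serializations act as skeleton keys.  A composite of
    mode m never has a child of mode m (canonical form).
    """
    key = (n, top_mode_forbidden)
    if key in cache:
        return cache[key]
    out: list[Network] = []
    if n == 1:
        out = [Leaf(SPRING, "E"), Leaf(DASHPOT, "n")]
    else:
        for mode in (SERIES, PARALLEL):
            if mode == top_mode_forbidden:
                continue
            pool: list[Network] = []
            for size in range(1, n):
                pool.extend(
                    (net, size)
                    for net in _skeletons(size, mode, cache)
                )
            # choose unordered multisets of >=2 children with sizes summing to n,
            # nondecreasing pool index to avoid duplicates
            def extend(start: int, remaining: int, chosen: list[Network]):
                if remaining == 0:
                    if len(chosen) >= 2:
                        kids = tuple(sorted(chosen, key=_canonical_key))
                        out.append(Composite(mode, kids))
                    return
                for idx in range(start, len(pool)):
                    net, size = pool[idx]
                    if size <= remaining:
                        extend(idx, remaining - size, chosen + [net])

            extend(0, n, [])
    # dedup defensively and order deterministically
    uniq = {net.serialize(): net for net in out}
    result = [uniq[k] for k in sorted(uniq)]
    cache[key] = result
    return result


def enumerate_networks(n_elements: int, max_elements: int = _MAX_ENUM) -> list[Network]:
    """All canonical series-parallel networks with exactly *n_elements* leaves.

    Leaf kinds (spring/dashpot) are enumerated as unordered multisets within
    the canonical form; parameters are named E1..,n1.. in traversal order.
    Deterministic order (sorted by skeleton serialization).
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if n_elements > max_elements:
        raise ValueError(
            f"enumeration size limit exceeded ({n_elements} > {max_elements})"
        )
    cache: dict = {}
    return [_canonical_rename(sk) for sk in _skeletons(n_elements, None, cache)]


def random_network(n_elements: int, seed: int) -> Network:
    """Deterministic random canonical network with exactly *n_elements* leaves.

    Sampling scheme: recursively, a block of size 1 becomes a spring or
    dashpot with probability 1/2 each; a block of size n >= 2 picks series or
    parallel uniformly and a binary split point uniformly in 1..n-1, then
    recurses on both halves.  The binary tree is then flattened to canonical
    form and parameters renamed in traversal order.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    rng = random.Random(seed)

    def build(n: int) -> Network:
        if n == 1:
            return Leaf(rng.choice((SPRING, DASHPOT)), "x")
        mode = rng.choice((SERIES, PARALLEL))
        left = rng.randint(1, n - 1)
        return Composite(mode, (build(left), build(n - left)))

    return _canonical_rename(build(n_elements))


# ---------------------------------------------------------------------------
# Built-in fixtures

def _gen_kelvin_voigt(k: int) -> Network:
    children: list[Network] = [Leaf(SPRING, "E0")]
    for i in range(1, k + 1):
        children.append(
            Composite(PARALLEL, (Leaf(SPRING, f"E{i}"), Leaf(DASHPOT, f"n{i}")))
        )
    return flatten(Composite(SERIES, tuple(children)))


def _gen_maxwell(k: int) -> Network:
    arms = tuple(
        Composite(SERIES, (Leaf(SPRING, f"E{i}"), Leaf(DASHPOT, f"n{i}")))
        for i in range(1, k + 1)
    )
    return flatten(Composite(PARALLEL, arms))


def _roscoe10() -> Network:
    # Text-level reconstruction: a Maxwell element joined in series with a
    # generalized Maxwell bank of 4 arms (10 elements total).
    maxwell = Composite(SERIES, (Leaf(SPRING, "E0"), Leaf(DASHPOT, "n0")))
    return flatten(Composite(SERIES, (maxwell, _gen_maxwell(4))))


BUILTIN_MODELS = {
    "maxwell": lambda: parse_network("E1 - n1"),
    "voigt": lambda: parse_network("E1 | n1"),
    "burgers": lambda: parse_network("(E1 - n1) - (E2 | n2)"),
    "kelvin_voigt_body": lambda: parse_network("E0 - (E1 | n1)"),
    "generalized_kelvin_voigt": _gen_kelvin_voigt,
    "generalized_maxwell": _gen_maxwell,
    "roscoe10_reconstruction": _roscoe10,
}

#: fixtures that are text-level reconstructions of figures
RECONSTRUCTION_MODELS = frozenset({"roscoe10_reconstruction"})


def builtin_model(name: str, k: Optional[int] = None) -> Network:
    """Return a named fixture network.

    ``generalized_kelvin_voigt`` and ``generalized_maxwell`` accept the
    number of arms *k* (default 3).  ``roscoe10_reconstruction`` is a
    reconstruction of a ten-element model known only from its textual
    description (Maxwell element in series with a generalized Maxwell bank).
    """
    if name not in BUILTIN_MODELS:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(BUILTIN_MODELS)}"
        )
    factory = BUILTIN_MODELS[name]
    if name in ("generalized_kelvin_voigt", "generalized_maxwell"):
        return factory(3 if k is None else k)
    if k is not None:
        raise ValueError(f"model {name!r} takes no size argument")
    return factory()
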