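import pytest

import springdash as sd

# Minimal representative networks for the four types, with disjoint
# parameter pools so pairs can be joined.
TYPE_REPS_1 = {"A": "E1", "B": "n1", "C": "E1 | n1", "D": "E1 - n1"}
TYPE_REPS_2 = {"A": "E9", "B": "n9", "C": "E9 | n9", "D": "E9 - n9"}

# Printed outcomes for the 20 join pairings of the four types:
# (Identifiable?, resulting type).
SERIES_PAIRINGS = {
    ("A", "A"): ("Not Id", "A"),
    ("A", "B"): ("Id", "D"),
    ("A", "C"): ("Id", "A"),
    ("A", "D"): ("Not Id", "D"),
    ("B", "B"): ("Not Id", "B"),
    ("B", "C"): ("Id", "B"),
    ("B", "D"): ("Not Id", "D"),
    ("C", "C"): ("Id", "C"),
    ("C", "D"): ("Id", "D"),
    ("D", "D"): ("Not Id", "D"),
}
PARALLEL_PAIRINGS = {
    ("A", "A"): ("Not Id", "A"),
    ("A", "B"): ("Id", "C"),
    ("A", "C"): ("Not Id", "C"),
    ("A", "D"): ("Id", "A"),
    ("B", "B"): ("Not Id", "B"),
    ("B", "C"): ("Not Id", "C"),
    ("B", "D"): ("Id", "B"),
    ("C", "C"): ("Not Id", "C"),
    ("C", "D"): ("Id", "C"),
    ("D", "D"): ("Id", "D"),
}


def pairing_network(t1: str, t2: str, mode: str) -> sd.Network:
    op = " - " if mode == "series" else " | "
    return sd.parse_network(f"({TYPE_REPS_1[t1]}){op}({TYPE_REPS_2[t2]})")


@pytest.fixture(scope="session")
def enumerated_by_size():
    """All canonical networks by element count, up to 6 elements."""
    return {n: sd.enumerate_networks(n) for n in range(1, 7)}


@pytest.fixture(scope="session")
def enumerated_small(enumerated_by_size):
    """Networks with up to 4 elements (cheap symbolic sweeps)."""
    return [net for n in range(1, 5) for net in enumerated_by_size[n]]
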