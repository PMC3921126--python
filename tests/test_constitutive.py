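import random

import pytest
import sympy as sp

import springdash as sd
from springdash.constitutive import (
    coefficient_map,
    combine_parallel,
    combine_series,
    derive_constitutive,
    leaf_equation,
    normalize,
)
from springdash.networks import Composite, Leaf

from .helpers import transfer_function_equation

E, E1, E2, n1, n2 = sp.symbols("E E1 E2 n1 n2", positive=True)


class TestLeafEquations:
    def test_spring_and_dashpot(self):
        eq = leaf_equation(Leaf("spring", "E"))
        assert eq.P.coeffs == {0: 1} and eq.Q.coeffs == {0: E}
        assert (eq.p_shape.hi, eq.p_shape.lo, eq.q_shape.hi, eq.q_shape.lo) == (0, 0, 0, 0)
        eq = leaf_equation(Leaf("dashpot", "n1"))
        assert eq.Q.coeffs == {1: n1}
        assert (eq.q_shape.hi, eq.q_shape.lo) == (1, 1)

    def test_unit_spring_is_identity_relation(self):
        eq = leaf_equation(Leaf("spring", "E"))
        assert eq.Q.subs({E: 1}).coeffs == eq.P.coeffs  # sigma = eps


class TestJoins:
    def test_maxwell_from_series(self):
        eq = combine_series(
            leaf_equation(Leaf("spring", "E")), leaf_equation(Leaf("dashpot", "n1"))
        )
        # eta*D + E acting on stress, E*eta*D on strain
        assert eq.P.coeffs == {1: n1, 0: E}
        assert eq.Q.coeffs == {1: E * n1}

    def test_two_springs_in_series(self):
        eq = combine_series(
            leaf_equation(Leaf("spring", "E1")), leaf_equation(Leaf("spring", "E2"))
        )
        assert eq.P.coeffs == {0: E1 + E2}
        assert eq.Q.coeffs == {0: E1 * E2}

    def test_series_of_two_maxwells_cancels_common_d(self):
        m1 = sd.parse_network("E1 - n1")
        m2 = sd.parse_network("E2 - n2")
        eq = combine_series(
            derive_constitutive(m1, normalized=False),
            derive_constitutive(m2, normalized=False),
        )
        assert (eq.p_shape.hi, eq.p_shape.lo) == (1, 0)
        assert (eq.q_shape.hi, eq.q_shape.lo) == (1, 1)

    def test_voigt_from_parallel(self):
        eq = combine_parallel(
            leaf_equation(Leaf("spring", "E")), leaf_equation(Leaf("dashpot", "n1"))
        )
        assert eq.P.coeffs == {0: 1}
        assert eq.Q.coeffs == {0: E, 1: n1}

    def test_two_dashpots_in_parallel(self):
        eq = combine_parallel(
            leaf_equation(Leaf("dashpot", "n1")), leaf_equation(Leaf("dashpot", "n2"))
        )
        assert eq.P.coeffs == {0: 1}
        assert sp.expand(eq.Q.coeff(1) - (n1 + n2)) == 0

    def test_spring_parallel_maxwell_is_type_a_shaped(self):
        eq = derive_constitutive(
            sd.parse_network("E2 | (E1 - n1)"), normalized=False
        )
        assert (eq.p_shape.hi, eq.p_shape.lo) == (1, 0)
        assert (eq.q_shape.hi, eq.q_shape.lo) == (1, 0)


class TestNormalization:
    def test_maxwell_normalized_coefficients(self):
        eq = derive_constitutive(sd.parse_network("E1 - n1"))
        assert eq.Q.coeffs == {1: 1}
        assert eq.P.coeff(1) == 1 / E1
        assert eq.P.coeff(0) == 1 / n1

    def test_voigt_normalized_coefficients(self):
        eq = derive_constitutive(sd.parse_network("E1 | n1"))
        assert eq.Q.coeff(1) == 1
        assert sp.cancel(eq.Q.coeff(0) - E1 / n1) == 0
        assert sp.cancel(eq.P.coeff(0) - 1 / n1) == 0

    def test_idempotent(self):
        eq = derive_constitutive(sd.parse_network("(E1 - n1) - (E2 | n2)"))
        again = normalize(eq)
        assert again.equals(eq) and again.normalized


class TestCoefficientMap:
    @pytest.mark.parametrize(
        "expr,length",
        [("E1 - n1", 2), ("(E1 - n1) - (E2 | n2)", 4), ("E1", 1), ("E0 - (E1 | n1)", 3)],
    )
    def test_lengths(self, expr, length):
        assert len(coefficient_map(sd.parse_network(expr))) == length

    def test_two_series_springs_single_entry(self):
        cmap = coefficient_map(sd.parse_network("E1 - E2"))
        assert len(cmap) == 1
        assert sp.cancel(cmap.entries[0] - (E1 + E2) / (E1 * E2)) == 0

    def test_count_never_exceeds_params(self, enumerated_small):
        for net in enumerated_small:
            eq = derive_constitutive(net, normalized=False)
            assert eq.n_nonmonic <= len(list(net.leaves()))


class TestDerivationInvariance:
    @pytest.mark.parametrize("seed", range(6))
    def test_child_permutation_and_flattening(self, seed):
        rng = random.Random(seed)
        net = sd.random_network(rng.randint(2, 5), seed)

        def shuffled(node):
            if node.is_leaf:
                return node
            kids = [shuffled(c) for c in node.children]
            rng.shuffle(kids)
            return Composite(node.mode, tuple(kids))

        eq1 = derive_constitutive(net)
        eq2 = derive_constitutive(shuffled(net))
        assert eq1.equals(eq2)

    def test_binary_vs_flat_burgers(self):
        binary = Composite(
            "series",
            (
                Composite("series", (Leaf("spring", "E1"), Leaf("dashpot", "n1"))),
                Composite("parallel", (Leaf("spring", "E2"), Leaf("dashpot", "n2"))),
            ),
        )
        assert derive_constitutive(binary).equals(
            derive_constitutive(sd.builtin_model("burgers"))
        )


class TestReducedFormInvariants:
    def test_enumerated_small(self, enumerated_small):
        for net in enumerated_small:
            eq = derive_constitutive(net, normalized=False)
            eq.check_reduced_form()  # raises on violation


class TestTransferFunctionOracle:
    """End-to-end cross-check against an independent derivation route."""

    @pytest.mark.parametrize(
        "expr",
        ["E1", "n1", "E1 - n1", "E1 | n1", "(E1 - n1) - (E2 | n2)",
         "E0 - (E1 | n1)", "(E1 | n1) - (E2 | n2)", "(E1 - n1) | (E2 - n2)"],
    )
    def test_named_models_agree(self, expr):
        net = sd.parse_network(expr)
        P, Q = transfer_function_equation(net)
        eq = derive_constitutive(net)
        assert eq.P.equals(P) and eq.Q.equals(Q)

    def test_enumerated_networks_agree(self, enumerated_small):
        for net in enumerated_small:
            P, Q = transfer_function_equation(net)
            eq = derive_constitutive(net)
            assert eq.P.equals(P) and eq.Q.equals(Q), net.serialize()
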