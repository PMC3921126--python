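import pytest

import springdash as sd
from springdash.constitutive import derive_constitutive
from springdash.identifiability import (
    ShapeMatrixCertificateError,
    build_shape_matrix,
    global_identifiability,
    globally_constructible,
    has_elementary_spine_joins,
    is_good_quadruple,
    jacobian_rank_oracle,
    local_identifiability,
    preimage_count_oracle,
    quadruple_for_join,
)
from springdash.operators import DiffOperator, GenericEvaluator

from .conftest import pairing_network


class TestLocalVerdicts:
    @pytest.mark.parametrize(
        "expr,params,coeffs,identifiable",
        [
            ("E1 - n1", 2, 2, True),
            ("E1 - E2", 2, 1, False),
            ("(E1 - n1) - (E2 | n2)", 4, 4, True),
            ("E0 - (E1 | n1)", 3, 3, True),
        ],
    )
    def test_counting(self, expr, params, coeffs, identifiable):
        lv = local_identifiability(sd.parse_network(expr))
        assert (lv.n_params, lv.n_nonmonic, lv.identifiable) == (
            params, coeffs, identifiable,
        )


class TestJacobianOracle:
    @pytest.mark.parametrize(
        "expr,rank",
        [("E1 - n1", 2), ("E1 - E2", 1), ("(E1 - n1) - (E2 | n2)", 4)],
    )
    def test_known_ranks(self, expr, rank):
        assert jacobian_rank_oracle(sd.parse_network(expr), seed=2) == rank

    def test_agrees_with_counting_criterion(self, enumerated_small):
        for net in enumerated_small:
            eq = derive_constitutive(net, normalized=False)
            lv = local_identifiability(net, eq=eq)
            rank = jacobian_rank_oracle(net, seed=3, eq=eq)
            assert (rank == lv.n_params) == lv.identifiable, net.serialize()


class TestGlobalConstructibility:
    def test_single_leaf(self):
        ok, order = globally_constructible(sd.parse_network("E1"))
        assert ok and order == (("E1", "seed"),)

    def test_burgers_build_order(self):
        ok, order = globally_constructible(sd.builtin_model("burgers"))
        assert ok
        steps = list(order)
        # seed inside the Voigt element, then its partner in parallel,
        # then the Maxwell pieces in series
        assert steps[0][1] == "seed"
        assert {s for s in steps[1:2]} == {(steps[1][0], "parallel")}
        assert all(mode == "series" for _, mode in steps[2:])
        assert {p for p, _ in steps} == {"E1", "n1", "E2", "n2"}

    def test_generalized_kelvin_voigt_not_constructible(self):
        ok, order = globally_constructible(
            sd.builtin_model("generalized_kelvin_voigt", 3)
        )
        assert not ok and order is None

    @pytest.mark.parametrize(
        "model,status",
        [
            ("maxwell", "globally_identifiable"),
            ("voigt", "globally_identifiable"),
            ("burgers", "globally_identifiable"),
            ("kelvin_voigt_body", "globally_identifiable"),
            ("generalized_kelvin_voigt", "locally_only"),
            ("roscoe10_reconstruction", "unidentifiable"),
        ],
    )
    def test_statuses(self, model, status):
        assert global_identifiability(sd.builtin_model(model)).status == status

    def test_globally_identifiable_networks_have_elementary_joins(
        self, enumerated_small
    ):
        for net in enumerated_small:
            gv = global_identifiability(net)
            if gv.status == "globally_identifiable":
                assert has_elementary_spine_joins(net), net.serialize()


class TestPreimageOracle:
    def test_burgers_unique_preimage(self):
        net = sd.builtin_model("burgers")
        assert preimage_count_oracle(net, seed=5, n_starts=60) == 1

    def test_voigt_chain_has_swap_preimage(self):
        net = sd.parse_network("(E1 | n1) - (E2 | n2)")
        assert preimage_count_oracle(net, seed=5, n_starts=60) == 2

    def test_generalized_kelvin_voigt_permutation_count(self):
        net = sd.builtin_model("generalized_kelvin_voigt", 3)
        assert preimage_count_oracle(net, seed=5, n_starts=200) == 6

    def test_too_many_parameters_rejected(self):
        net = sd.builtin_model("roscoe10_reconstruction")
        with pytest.raises(ValueError, match="too many"):
            preimage_count_oracle(net, seed=0)


class TestShapeFactorization:
    @staticmethod
    def _quadruple(t1, t2, mode):
        from .conftest import TYPE_REPS_1, TYPE_REPS_2

        eq1 = derive_constitutive(sd.parse_network(TYPE_REPS_1[t1]), normalized=False)
        eq2 = derive_constitutive(sd.parse_network(TYPE_REPS_2[t2]), normalized=False)
        return quadruple_for_join(eq1, eq2, mode)

    def test_maxwell_construction_square(self):
        q = self._quadruple("A", "B", "series")
        assert q.is_square and q.n_columns == 2

    def test_two_springs_not_square(self):
        q = self._quadruple("A", "A", "series")
        assert not q.is_square

    def test_column_count_is_unknown_coefficient_total(self):
        q = self._quadruple("C", "D", "series")
        sm = build_shape_matrix(
            q,
            DiffOperator({1: 1, 0: 3}),  # type C strain side, monic
            DiffOperator({1: 1}),        # type D strain side, monic
        )
        assert sm.matrix.cols == q.u1.n_coeffs + q.u2.n_coeffs

    def test_inconsistent_operators_rejected(self):
        q = self._quadruple("A", "B", "series")
        with pytest.raises(ValueError, match="inconsistent"):
            build_shape_matrix(q, DiffOperator({1: 1}), DiffOperator({1: 1}))

    @pytest.mark.parametrize(
        "t1,t2,mode,good",
        [
            ("C", "C", "series", True),
            ("D", "D", "series", False),
            ("D", "D", "parallel", True),
            ("A", "D", "parallel", True),
            ("B", "C", "parallel", False),
        ],
    )
    def test_goodness_matches_pairing_verdicts(self, t1, t2, mode, good):
        q = self._quadruple(t1, t2, mode)
        assert is_good_quadruple(q, GenericEvaluator(seed=4)) == good

    def test_goodness_equals_local_identifiability_of_join(self):
        # the matrix criterion and the counting criterion must agree on
        # every pairing of the four minimal representatives
        import itertools

        for mode in ("series", "parallel"):
            for t1, t2 in itertools.combinations_with_replacement("ABCD", 2):
                q = self._quadruple(t1, t2, mode)
                lv = local_identifiability(pairing_network(t1, t2, mode))
                assert is_good_quadruple(q, GenericEvaluator(seed=6)) == lv.identifiable
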