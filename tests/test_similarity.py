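"""Semantic, functional, GIP and integrated similarity computations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdbirw.data import AssociationNetwork, DiseaseDAG, NodeRegistry
from mdbirw.fixtures import FixtureSpec, make_association_matrix, make_dag_forest
from mdbirw.similarity import (
    GipParams,
    SemanticParams,
    SimilarityMatrix,
    build_similarity_networks,
    disease_semantic_similarity,
    disease_to_group_similarity,
    gip_kernel,
    integrate_similarity,
    metabolite_functional_similarity,
    semantic_contribution,
    semantic_value,
)
from conftest import chain_dag


class TestSemanticContribution:
    def test_disease_itself_contributes_one(self):
        assert semantic_contribution(chain_dag(), "d") == 1.0

    def test_chain_decays_per_level(self):
        dag = chain_dag("d", ("p", "g"))
        assert semantic_contribution(dag, "p") == 0.5
        assert semantic_contribution(dag, "g") == 0.25

    def test_diamond_takes_max_over_children(self):
        # g has children p (contribution 0.5) and d (contribution 1)
        dag = DiseaseDAG(
            "d",
            frozenset({"d", "p", "g"}),
            {"g": frozenset({"p", "d"}), "p": frozenset({"d"})},
        )
        assert semantic_contribution(dag, "g") == 0.5

    def test_unknown_term_raises(self):
        with pytest.raises(ValueError, match="not in DAG"):
            semantic_contribution(chain_dag(), "zzz")

    def test_contributions_never_increase_up_ancestor_chain(self):
        dag = chain_dag("d", tuple(f"a{i}" for i in range(6)))
        vals = [semantic_contribution(dag, t) for t in ("d", "a0", "a1", "a2", "a3")]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_custom_delta(self):
        dag = chain_dag("d", ("p",))
        assert semantic_contribution(dag, "p", SemanticParams(delta=0.8)) == 0.8


class TestSemanticValue:
    @pytest.mark.parametrize(
        "dag, expected",
        [
            (DiseaseDAG("d", frozenset({"d"}), {}), 1.0),
            (chain_dag("d", ("p", "g")), 1.75),
            # two direct parents contribute 0.5 each
            (
                DiseaseDAG(
                    "d",
                    frozenset({"d", "p1", "p2"}),
                    {"p1": frozenset({"d"}), "p2": frozenset({"d"})},
                ),
                2.0,
            ),
        ],
        ids=["singleton", "chain3", "two-parents"],
    )
    def test_hand_computed_sums(self, dag, expected):
        assert semantic_value(dag) == expected


class TestDiseaseSemanticSimilarity:
    def test_sibling_leaves_under_shared_parent(self):
        # both DV = 1.5; shared parent contributes 0.5 from each side
        dags = {
            "d1": chain_dag("d1", ("p",)),
            "d2": chain_dag("d2", ("p",)),
        }
        S = disease_semantic_similarity(dags, ["d1", "d2"])
        assert S.values[0, 1] == pytest.approx(1.0 / 3.0)

    def test_diagonal_is_exactly_one(self, small_forest, small_spec):
        S = disease_semantic_similarity(small_forest, [f"D{j:03d}" for j in range(small_spec.n_diseases)])
        np.testing.assert_array_equal(np.diag(S.values), 1.0)

    def test_disjoint_dags_have_zero_similarity(self):
        dags = {"d1": chain_dag("d1", ("a",)), "d2": chain_dag("d2", ("b",))}
        S = disease_semantic_similarity(dags, ["d1", "d2"])
        assert S.values[0, 1] == 0.0

    def test_missing_dag_gives_zero_row_except_diagonal(self):
        dags = {"d1": chain_dag("d1", ("p",))}
        S = disease_semantic_similarity(dags, ["d1", "nodag"])
        assert S.values[1, 1] == 1.0
        assert S.values[0, 1] == 0.0

    def test_symmetric_and_bounded(self, small_forest, small_spec):
        S = disease_semantic_similarity(small_forest, [f"D{j:03d}" for j in range(small_spec.n_diseases)])
        np.testing.assert_allclose(S.values, S.values.T, atol=1e-12)
        assert S.values.min() >= 0 and S.values.max() <= 1


class TestGroupSimilarity:
    def test_self_in_group_gives_one(self):
        S = SimilarityMatrix("disease", "semantic", np.eye(3))
        assert disease_to_group_similarity("a", {"a"}, S, ["a", "b", "c"]) == 1.0

    def test_max_over_group(self):
        vals = np.array([[1.0, 0.2, 0.7, 0.4], [0.2, 1, 0, 0], [0.7, 0, 1, 0], [0.4, 0, 0, 1]])
        S = SimilarityMatrix("disease", "semantic", vals)
        ids = ["d", "x", "y", "z"]
        assert disease_to_group_similarity("d", {"x", "y", "z"}, S, ids) == 0.7

    def test_empty_group_raises(self):
        S = SimilarityMatrix("disease", "semantic", np.eye(2))
        with pytest.raises(ValueError, match="non-empty"):
            disease_to_group_similarity("a", set(), S, ["a", "b"])


class TestFunctionalSimilarity:
    def _net(self, A):
        A = np.asarray(A, float)
        return AssociationNetwork(
            NodeRegistry("metabolite", tuple(f"m{i}" for i in range(A.shape[0]))),
            NodeRegistry("disease", tuple(f"d{j}" for j in range(A.shape[1]))),
            A,
        )

    def test_identical_singleton_groups_give_one(self):
        S_d = SimilarityMatrix("disease", "semantic", np.eye(2))
        Sm = metabolite_functional_similarity(self._net([[1, 0], [1, 0]]), S_d)
        assert Sm.values[0, 1] == 1.0

    def test_cross_group_value_by_hand(self):
        # D_i = {d1}, D_j = {d2}, S(d1,d2) = 0.4 -> (0.4 + 0.4) / 2
        vals = np.array([[1.0, 0.4], [0.4, 1.0]])
        S_d = SimilarityMatrix("disease", "semantic", vals)
        Sm = metabolite_functional_similarity(self._net([[1, 0], [0, 1]]), S_d)
        assert Sm.values[0, 1] == pytest.approx(0.4)

    def test_metabolite_without_diseases_has_zero_row(self):
        S_d = SimilarityMatrix("disease", "semantic", np.eye(2))
        Sm = metabolite_functional_similarity(self._net([[1, 0], [0, 0]]), S_d)
        assert Sm.values[1, 0] == 0.0
        assert Sm.values[1, 1] == 0.0  # degenerate diagonal left for GIP fallback

    def test_all_ones_disease_similarity_gives_all_ones(self):
        S_d = SimilarityMatrix("disease", "semantic", np.ones((3, 3)))
        A = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 1]], float)
        Sm = metabolite_functional_similarity(self._net(A), S_d)
        np.testing.assert_allclose(Sm.values, 1.0)

    def test_diagonal_one_for_associated_metabolites(self, small_network, small_forest):
        S_d = disease_semantic_similarity(small_forest, small_network.diseases.ids)
        Sm = metabolite_functional_similarity(small_network, S_d)
        np.testing.assert_array_equal(np.diag(Sm.values), 1.0)


class TestGipKernel:
    def test_identical_profiles_give_one(self):
        P = np.array([[1, 0, 1], [1, 0, 1]], float)
        K = gip_kernel(P, "metabolite")
        assert K.values[0, 1] == 1.0

    def test_two_distinct_single_hits(self):
        # mean ||IP||^2 = 1 so bandwidth = 1; distance^2 = 2 -> exp(-2)
        P = np.zeros((2, 10))
        P[0, 0] = P[1, 5] = 1.0
        K = gip_kernel(P, "metabolite")
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0))

    def test_bandwidth_is_mean_normalized(self):
        # ||IP1||^2 = 1, ||IP2||^2 = 3 -> bandwidth 1/2; distance^2 = 2 -> exp(-1)
        P = np.array([[1, 0, 0], [1, 1, 1]], float)
        assert gip_kernel(P, "metabolite").values[0, 1] == pytest.approx(np.exp(-0.5 * 2.0))

    def test_all_zero_profiles_fall_back_to_identity(self, caplog):
        with caplog.at_level("WARNING"):
            K = gip_kernel(np.zeros((3, 4)), "disease")
        np.testing.assert_array_equal(K.values, np.eye(3))
        assert any("identity" in r.message for r in caplog.records)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**24 - 1))
    def test_matches_brute_force_double_loop(self, seed):
        """Vectorized kernel equals the elementwise definition on random 6x4 profiles."""
        rng = np.random.default_rng(seed)
        P = (rng.random((6, 4)) < 0.5).astype(float)
        if P.sum() == 0:
            P[0, 0] = 1.0
        lam = 1.0 / (P**2).sum(axis=1).mean()
        expected = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                expected[i, j] = np.exp(-lam * ((P[i] - P[j]) ** 2).sum())
        np.testing.assert_allclose(gip_kernel(P, "metabolite").values, expected, atol=1e-12)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            GipParams(bandwidth_prime=0.0)


class TestIntegration:
    def test_zero_base_substitutes_gip(self):
        base = SimilarityMatrix("disease", "semantic", np.eye(2))
        gip = SimilarityMatrix("disease", "gip", np.array([[1.0, 0.3], [0.3, 1.0]]))
        out = integrate_similarity(base, gip)
        assert out.values[0, 1] == 0.3

    def test_nonzero_base_averages(self):
        base = SimilarityMatrix("disease", "semantic", np.array([[1.0, 0.6], [0.6, 1.0]]))
        gip = SimilarityMatrix("disease", "gip", np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert integrate_similarity(base, gip).values[0, 1] == pytest.approx(0.5)

    def test_diagonal_forced_to_one(self):
        base = SimilarityMatrix("disease", "semantic", np.eye(3) * 0 + np.eye(3))
        gip = SimilarityMatrix("disease", "gip", np.eye(3))
        np.testing.assert_array_equal(np.diag(integrate_similarity(base, gip).values), 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_similarity(
                SimilarityMatrix("disease", "semantic", np.eye(2)),
                SimilarityMatrix("disease", "gip", np.eye(3)),
            )


class TestIntegratedNetworks:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_outputs_symmetric_and_bounded(self, seed):
        spec = FixtureSpec(n_metabolites=10, n_diseases=6, n_blocks=2, seed=seed)
        net = make_association_matrix(spec)
        MS, DS = build_similarity_networks(net, make_dag_forest(spec))
        for M in (MS.values, DS.values):
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            assert M.min() >= 0.0 and M.max() <= 1.0 + 1e-12
            np.testing.assert_array_equal(np.diag(M), 1.0)
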