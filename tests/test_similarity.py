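import numpy as np
import pytest
from scipy.stats import spearmanr

from elcda import (DiseaseDAG, ExpressionProfiles, circ_bio_similarity,
                   compute_similarity_bundle, disease_bio_similarity,
                   disease_semantic_similarity, expression_similarity,
                   functional_similarity, gip_kernel, hetesim,
                   integrate_similarity, pathsim, semantic_contribution,
                   transition_matrix)

from conftest import hetesim_recursive, random_network, walk_count_matrix


class TestTransitionMatrix:
    def test_row_normalisation(self):
        T = transition_matrix([[1, 1], [0, 1]])
        assert np.allclose(T, [[0.5, 0.5], [0, 1]])

    def test_worked_example_row(self, toy_net):
        T = transition_matrix(toy_net.A_CD)
        assert np.allclose(T[1], [0.5, 0.5, 0.0])
        assert np.allclose(T[3], [1 / 3, 1 / 3, 1 / 3])

    def test_zero_row_stays_zero(self):
        assert np.allclose(transition_matrix([[0.0, 0.0]]), [[0.0, 0.0]])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix([[-1.0, 2.0]])


class TestPathSim:
    def test_worked_example(self, toy_net):
        assert pathsim(toy_net, "CDC")[1, 3] == 0.8

    def test_unit_diagonal(self, toy_net):
        S = pathsim(toy_net, "CDC")
        assert np.allclose(np.diag(S), 1.0)

    def test_non_palindromic_rejected(self, toy_net):
        with pytest.raises(ValueError, match="palindromic"):
            pathsim(toy_net, "CD")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_walk_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 6, 3, 4)
        M = walk_count_matrix(net, ("C", "D", "C"))
        S = pathsim(net, "CDC")
        for x in range(6):
            for y in range(6):
                denom = M[x, x] + M[y, y]
                expected = 2 * M[x, y] / denom if denom else 0.0
                assert S[x, y] == pytest.approx(expected, abs=1e-12)


class TestHeteSim:
    def test_worked_example(self, toy_net):
        assert hetesim(toy_net, "CDC")[1, 3] == pytest.approx(np.sqrt(6) / 3, abs=1e-12)

    def test_unit_diagonal_for_connected_nodes(self, toy_net):
        S = hetesim(toy_net, "CDC")
        assert np.allclose(np.diag(S), 1.0)

    def test_odd_edge_count_rejected(self, toy_net):
        with pytest.raises(ValueError, match="even"):
            hetesim(toy_net, "CDCDC"[:2])  # CD: one edge

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 6, 4, 5)
        for spec in ("CDC", "CMC", "CDMDC", "DCD", "DMCMD"):
            S = hetesim(net, spec)
            assert S.min() >= 0 and S.max() <= 1 + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("spec", ["CDC", "CMC", "DCD", "CDMDC"])
    def test_matches_recursive_definition(self, seed, spec):
        rng = np.random.default_rng(40 + seed)
        net = random_network(rng, 5, 3, 3)
        S = hetesim(net, spec)
        sizes = {"C": 5, "M": 3, "D": 3}
        k = sizes[spec[0]]
        for x in range(k):
            for y in range(k):
                assert S[x, y] == pytest.approx(
                    hetesim_recursive(net, tuple(spec), x, y), abs=1e-10)


SIMPLE_DAG = DiseaseDAG([("d1", "root"), ("d2", "root")])


class TestSemanticSimilarity:
    def test_self_contribution_is_one(self):
        assert semantic_contribution(SIMPLE_DAG, "d1")["d1"] == 1.0

    def test_parent_one_hop(self):
        assert semantic_contribution(SIMPLE_DAG, "d1")["root"] == 0.5

    def test_diamond_takes_max_path(self):
        # two routes to the top: direct (one hop) and via mid (two hops)
        dag = DiseaseDAG([("d", "top"), ("d", "mid"), ("mid", "top")])
        assert semantic_contribution(dag, "d")["top"] == 0.5

    def test_absent_disease_rejected(self):
        with pytest.raises(ValueError):
            semantic_contribution(SIMPLE_DAG, "nope")

    def test_identical_disease_similarity_is_one(self):
        SS, cov = disease_semantic_similarity(SIMPLE_DAG, ["d1", "d2"])
        assert SS[0, 0] == 1.0 and cov.all()

    def test_siblings_under_root(self):
        SS, _ = disease_semantic_similarity(SIMPLE_DAG, ["d1", "d2"])
        # shared ancestor root contributes 0.5 from each side; DV = 1.5 each
        assert SS[0, 1] == pytest.approx(1 / 3)

    def test_disjoint_components_share_nothing(self):
        dag = DiseaseDAG([("a1", "rootA"), ("b1", "rootB")])
        SS, _ = disease_semantic_similarity(dag, ["a1", "b1"])
        assert SS[0, 1] == 0.0

    def test_invariant_to_edge_ordering(self):
        edges = [("d1", "m1"), ("m1", "r"), ("d2", "m1"), ("d1", "r")]
        a, _ = disease_semantic_similarity(DiseaseDAG(edges), ["d1", "d2"])
        b, _ = disease_semantic_similarity(DiseaseDAG(edges[::-1]), ["d1", "d2"])
        assert np.allclose(a, b)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG([("a", "b"), ("b", "a")])


class TestGipKernel:
    def test_identical_columns(self):
        G = gip_kernel(np.array([[1, 1], [0, 0]]))
        assert G[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        G = gip_kernel(np.array([[1, 0], [0, 1]]))
        # beta = 2 / (1 + 1) = 1; squared distance 2
        assert G[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        MD = (rng.random((6, 8)) < 0.4).astype(int)
        G = gip_kernel(MD)
        assert np.allclose(G, G.T)
        assert np.allclose(np.diag(G), 1.0)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            gip_kernel(np.array([[0.5]]))

    def test_all_zero_profiles_fall_back_to_identity(self):
        assert np.allclose(gip_kernel(np.zeros((3, 4), dtype=int)), np.eye(4))


class TestBioCombination:
    def test_coverage_selects_semantic_else_gip(self):
        SS = np.array([[1.0, 0.7], [0.7, 1.0]])
        GD = np.array([[1.0, 0.2], [0.2, 1.0]])
        cov = np.array([[True, False], [False, True]])
        out = disease_bio_similarity(SS, GD, cov)
        assert out[0, 0] == 1.0 and out[0, 1] == 0.2

    def test_full_coverage_equals_semantic(self):
        SS, GD = np.eye(2), np.full((2, 2), 0.5)
        assert np.array_equal(disease_bio_similarity(SS, GD, np.ones((2, 2), bool)), SS)

    def test_circ_combination(self):
        SF = np.array([[1.0, 0.6], [0.6, 1.0]])
        SE = np.array([[1.0, 0.2], [0.2, 1.0]])
        cov = np.ones((2, 2), bool)
        assert circ_bio_similarity(SF, SE, cov)[0, 1] == pytest.approx(0.4)

    def test_uncovered_uses_functional(self):
        SF, SE = np.full((2, 2), 0.6), np.zeros((2, 2))
        out = circ_bio_similarity(SF, SE, np.zeros((2, 2), bool))
        assert np.array_equal(out, SF)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            disease_bio_similarity(np.eye(2), np.eye(3), np.ones((2, 2), bool))


class TestExpressionSimilarity:
    def test_identical_profiles(self):
        prof = ExpressionProfiles(["a", "b"], [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        SE, cov = expression_similarity(prof, ["a", "b"])
        assert SE[0, 1] == pytest.approx(1.0)
        assert cov.all()

    def test_reversed_profiles(self):
        prof = ExpressionProfiles(["a", "b"], [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        SE, _ = expression_similarity(prof, ["a", "b"])
        assert SE[0, 1] == pytest.approx(-1.0)

    def test_constant_profile_flagged(self):
        prof = ExpressionProfiles(["a", "b"], [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        SE, cov = expression_similarity(prof, ["a", "b"])
        assert SE[0, 1] == 0.0 and not cov[0, 1]

    def test_unprofiled_circrna_uncovered(self):
        prof = ExpressionProfiles(["a"], [[1.0, 2.0, 3.0]])
        SE, cov = expression_similarity(prof, ["a", "b"])
        assert cov[0, 0] and not cov[0, 1] and not cov[1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_spearman(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((4, 9))
        prof = ExpressionProfiles([f"c{i}" for i in range(4)], X)
        SE, _ = expression_similarity(prof, prof.circ_ids)
        expected = spearmanr(X, axis=1).statistic
        assert np.allclose(SE, expected, atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ExpressionProfiles(["a"], [[1.0, 2.0]])


class TestFunctionalSimilarity:
    def test_single_shared_disease(self):
        SD = np.eye(2)
        A = np.array([[1, 0], [1, 0]])
        assert functional_similarity(SD, A)[0, 1] == pytest.approx(1.0)

    def test_disjoint_sets_with_zero_cross_similarity(self):
        SD = np.eye(2)
        A = np.array([[1, 0], [0, 1]])
        assert functional_similarity(SD, A)[0, 1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        SD = rng.random((3, 3))
        SD = (SD + SD.T) / 2
        np.fill_diagonal(SD, 1.0)
        A = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        SF = functional_similarity(SD, A)
        for i in range(3):
            for j in range(3):
                Ni, Nj = np.nonzero(A[i])[0], np.nonzero(A[j])[0]
                total = sum(SD[d, Nj].max() for d in Ni)
                total += sum(SD[d, Ni].max() for d in Nj)
                expected = total / (len(Ni) + len(Nj))
                if i == j:
                    expected = 1.0
                assert SF[i, j] == pytest.approx(expected, abs=1e-12)

    def test_circrna_without_diseases(self):
        SF = functional_similarity(np.eye(2), np.array([[1, 0], [0, 0]]))
        assert SF[1, 0] == 0.0 and SF[1, 1] == 1.0


class TestIntegration:
    def test_identity_inputs(self):
        out = integrate_similarity(np.eye(3), np.eye(3), np.eye(3))
        assert np.allclose(out, np.eye(3))

    def test_coefficients(self):
        out = integrate_similarity(np.ones((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)))
        assert out[0, 0] == 0.5

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            integrate_similarity(np.eye(2), np.eye(2), np.eye(2), weights=(1, 1, 1))

    def test_unit_diagonal_preserved(self):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(3):
            M = rng.random((4, 4))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            mats.append(M)
        out = integrate_similarity(*mats)
        assert np.allclose(np.diag(out), 1.0)


class TestBundle:
    def test_all_matrices_symmetric_and_finite(self, small_bundle):
        for name in ("SS", "GD", "SD_bio", "SE", "SF", "SC_bio", "pathsim_C",
                     "hetesim_C", "pathsim_D", "hetesim_D", "SC", "SD", "SM"):
            M = getattr(small_bundle, name)
            assert np.isfinite(M).all(), name
            assert np.abs(M - M.T).max() < 1e-10, name

    def test_bounded_layers(self, small_bundle):
        for name in ("SS", "GD", "SF", "pathsim_C", "hetesim_C",
                     "pathsim_D", "hetesim_D"):
            M = getattr(small_bundle, name)
            assert M.min() >= -1e-12 and M.max() <= 1 + 1e-9, name
        assert small_bundle.SE.min() >= -1 - 1e-12
        assert small_bundle.SE.max() <= 1 + 1e-12

    def test_without_optional_inputs(self, small_synth):
        net = small_synth[0]
        bundle = compute_similarity_bundle(net)
        assert np.array_equal(bundle.SD_bio, bundle.GD)
        assert np.array_equal(bundle.SC_bio, bundle.SF)
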