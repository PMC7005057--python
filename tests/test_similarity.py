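import itertools

import networkx as nx
import numpy as np
import pytest

from rwrknn.core_data import AssociationMatrix, DiseaseDAG, EntityRegistry
from rwrknn.pipeline import PipelineParams, compute_similarities
from rwrknn.similarity import (
    GipParams,
    SemanticParams,
    circ_functional_similarity,
    disease_semantic_similarity,
    gip_kernel,
    integrate_circ_similarity,
    integrate_disease_similarity,
    semantic_contributions,
    semantic_value,
)
from rwrknn.synthetic import SyntheticSpec, generate_associations, generate_dags

from conftest import random_dag_edges


def brute_force_contributions(dag: DiseaseDAG, delta: float) -> dict[str, float]:
    """Independent oracle: contribution of term t is max over all root->t
    paths of delta^(path length)."""
    g = nx.DiGraph()
    g.add_node(dag.root)
    g.add_edges_from(dag.edges)
    out = {}
    for t in {dag.root} | nx.descendants(g, dag.root):
        best = max(
            delta ** (len(path) - 1)
            for path in nx.all_simple_paths(g, dag.root, t)
        ) if t != dag.root else 1.0
        out[t] = best
    return out


class TestSemanticContributions:
    def test_singleton_base_case(self):
        dag = DiseaseDAG(disease="d", edges=frozenset())
        assert semantic_contributions(dag) == {"d": 1.0}
        assert semantic_value(dag) == 1.0

    def test_chain(self, chain_dag):
        assert semantic_contributions(chain_dag) == {"d": 1.0, "t1": 0.5, "t2": 0.25}
        assert semantic_value(chain_dag) == pytest.approx(1.75)

    def test_diamond_takes_max_over_children(self, diamond_dag):
        contrib = semantic_contributions(diamond_dag)
        assert contrib["t3"] == pytest.approx(0.25)

    def test_decay_free_chain_sums_to_length(self):
        n = 6
        edges = frozenset((f"n{i}", f"n{i+1}") for i in range(n - 1))
        dag = DiseaseDAG(disease="n0", edges=edges)
        assert semantic_value(dag, SemanticParams(delta=1.0)) == pytest.approx(n)

    def test_unreachable_terms_excluded(self):
        dag = DiseaseDAG(
            disease="d",
            edges=frozenset({("d", "t1"), ("x", "y")}),
        )
        assert set(semantic_contributions(dag)) == {"d", "t1"}

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_terms = int(rng.integers(2, 13))
        dag = DiseaseDAG(
            disease="n0", edges=random_dag_edges(rng, n_terms, edge_prob=0.35)
        )
        delta = 0.5
        got = semantic_contributions(dag, SemanticParams(delta=delta))
        expected = brute_force_contributions(dag, delta)
        assert got.keys() == expected.keys()
        for t in got:
            assert got[t] == pytest.approx(expected[t], abs=1e-12)


class TestDiseaseSemanticSimilarity:
    def test_disjoint_dags_give_zero(self):
        dags = {
            "d1": DiseaseDAG(disease="d1", edges=frozenset({("d1", "a")})),
            "d2": DiseaseDAG(disease="d2", edges=frozenset({("d2", "b")})),
        }
        dss = disease_semantic_similarity(dags)
        assert dss.values[0, 1] == 0.0

    def test_diagonal_is_one(self, chain_dag):
        dss = disease_semantic_similarity({"d": chain_dag})
        assert dss.values[0, 0] == 1.0

    def test_shared_ancestor_hand_value(self):
        dags = {
            "d1": DiseaseDAG(disease="d1", edges=frozenset({("d1", "t")})),
            "d2": DiseaseDAG(disease="d2", edges=frozenset({("d2", "t")})),
        }
        dss = disease_semantic_similarity(dags)
        # shared t contributes (0.5 + 0.5) / (1.5 + 1.5)
        assert dss.values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_permutation_equivariance_under_term_relabeling(self):
        rng = np.random.default_rng(4)
        edges = random_dag_edges(rng, 8, 0.4)
        dag1 = DiseaseDAG(disease="n0", edges=edges)
        mapping = {f"n{i}": f"m{i}" for i in range(8)}
        mapping["n0"] = "n0"  # keep the root's own term
        dag2 = DiseaseDAG(
            disease="n0",
            edges=frozenset((mapping[c], mapping[p]) for c, p in edges),
        )
        other = DiseaseDAG(disease="z", edges=frozenset({("z", "q")}))
        m1 = disease_semantic_similarity({"n0": dag1, "z": other}).values
        m2 = disease_semantic_similarity({"n0": dag2, "z": other}).values
        np.testing.assert_allclose(m1, m2, atol=1e-15)


class TestGipKernel:
    def test_identical_profiles_give_one(self):
        reg = EntityRegistry(("a", "b"))
        k = gip_kernel(np.array([[1, 0, 1], [1, 0, 1]]), reg)
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_hand_value_two_orthogonal_profiles(self):
        reg = EntityRegistry(("a", "b"))
        k = gip_kernel(np.array([[1, 0], [0, 1]]), reg)
        # sigma = 1 / ((1+1)/2) = 1; squared distance 2
        assert k.values[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_monotone_nonincreasing_in_sigma_star(self):
        rng = np.random.default_rng(1)
        profiles = rng.integers(0, 2, size=(6, 9))
        profiles[0, 0] = 1  # guard against an all-zero matrix
        reg = EntityRegistry(tuple(f"e{i}" for i in range(6)))
        prev = None
        for s in (0.5, 1.0, 2.0, 4.0):
            k = gip_kernel(profiles, reg, GipParams(sigma_star=s)).values
            if prev is not None:
                assert (k <= prev + 1e-15).all()
            prev = k

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 21)), int(rng.integers(1, 21))
        profiles = rng.integers(0, 2, size=(n, m))
        if profiles.sum() == 0:
            profiles[0, 0] = 1
        reg = EntityRegistry(tuple(f"e{i}" for i in range(n)))
        got = gip_kernel(profiles, reg).values
        sigma = 1.0 / (sum(float(p @ p) for p in profiles) / n)
        for i in range(n):
            for j in range(n):
                d2 = float(((profiles[i] - profiles[j]) ** 2).sum())
                expected = 1.0 if i == j else np.exp(-sigma * d2)
                assert got[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_profiles_error(self):
        reg = EntityRegistry(("a", "b"))
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(np.zeros((2, 3)), reg)


class TestIntegration:
    def _sims(self, primary, gip, role_a, role_b):
        reg = EntityRegistry(("x", "y"))
        from rwrknn.core_data import SimilarityMatrix

        return (
            SimilarityMatrix(np.array(primary), reg, role_a),
            SimilarityMatrix(np.array(gip), reg, role_b),
        )

    def test_zero_branch_uses_gip(self):
        dss, dgs = self._sims([[1, 0], [0, 1]], [[1, 0.4], [0.4, 1]], "DSS", "DGS")
        sd = integrate_disease_similarity(dss, dgs)
        assert sd.values[0, 1] == pytest.approx(0.4)

    def test_mean_branch(self):
        dss, dgs = self._sims([[1, 0.6], [0.6, 1]], [[1, 0.2], [0.2, 1]], "DSS", "DGS")
        sd = integrate_disease_similarity(dss, dgs)
        assert sd.values[0, 1] == pytest.approx(0.4)

    def test_equal_matrices_are_a_fixed_point(self):
        dss, dgs = self._sims([[1, 0.3], [0.3, 1]], [[1, 0.3], [0.3, 1]], "DSS", "DGS")
        sd = integrate_disease_similarity(dss, dgs)
        np.testing.assert_allclose(sd.values, dss.values)

    def test_circ_variant_mean_and_zero_branches(self):
        cfs, cgs = self._sims([[1, 0.3], [0.3, 1]], [[1, 0.5], [0.5, 1]], "CFS", "CGS")
        sc = integrate_circ_similarity(cfs, cgs)
        assert sc.values[0, 1] == pytest.approx(0.4)
        cfs, cgs = self._sims([[1, 0], [0, 1]], [[1, 0.7], [0.7, 1]], "CFS", "CGS")
        assert integrate_circ_similarity(cfs, cgs).values[0, 1] == pytest.approx(0.7)

    def test_registry_mismatch_errors(self):
        from rwrknn.core_data import SimilarityMatrix

        a = SimilarityMatrix(np.eye(2), EntityRegistry(("a", "b")), "DSS")
        b = SimilarityMatrix(np.eye(2), EntityRegistry(("x", "y")), "DGS")
        with pytest.raises(ValueError, match="registr"):
            integrate_disease_similarity(a, b)


def make_dss(values, names):
    from rwrknn.core_data import SimilarityMatrix

    return SimilarityMatrix(np.array(values, dtype=float), EntityRegistry(names), "DSS")


class TestCircFunctionalSimilarity:
    def test_identical_singleton_sets(self):
        assoc = AssociationMatrix(
            np.array([[1], [1]]), EntityRegistry(("u", "v")), EntityRegistry(("d1",))
        )
        cfs = circ_functional_similarity(assoc, make_dss([[1.0]], ("d1",)))
        assert cfs.values[0, 1] == pytest.approx(1.0)

    def test_distinct_singletons_use_cross_similarity(self):
        assoc = AssociationMatrix(
            np.array([[1, 0], [0, 1]]),
            EntityRegistry(("u", "v")),
            EntityRegistry(("d1", "d2")),
        )
        dss = make_dss([[1, 0.5], [0.5, 1]], ("d1", "d2"))
        cfs = circ_functional_similarity(assoc, dss)
        assert cfs.values[0, 1] == pytest.approx(0.5)

    def test_best_match_average_hand_value(self):
        # Du={d1}, Dv={d2,d3}; DSS(d1,d2)=0.6, DSS(d1,d3)=0.2
        assoc = AssociationMatrix(
            np.array([[1, 0, 0], [0, 1, 1]]),
            EntityRegistry(("u", "v")),
            EntityRegistry(("d1", "d2", "d3")),
        )
        dss = make_dss(
            [[1, 0.6, 0.2], [0.6, 1, 0.9], [0.2, 0.9, 1]], ("d1", "d2", "d3")
        )
        cfs = circ_functional_similarity(assoc, dss)
        assert cfs.values[0, 1] == pytest.approx((0.6 + 0.6 + 0.2) / 3, abs=1e-12)

    def test_empty_disease_set_gives_zero_off_diagonal(self, tiny_assoc):
        dss = make_dss(np.eye(3), ("d1", "d2", "d3"))
        cfs = circ_functional_similarity(tiny_assoc, dss)
        assert cfs.values[2, 0] == 0.0 and cfs.values[2, 1] == 0.0
        assert cfs.values[2, 2] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_single_disease_circs_reduce_to_dss(self, seed):
        # every circRNA maps to exactly one disease -> CFS == DSS restricted
        rng = np.random.default_rng(seed)
        n_c, n_d = 6, 4
        spec = SyntheticSpec(n_disease=n_d, rng_seed=seed)
        dags = {
            d: dag
            for d, dag in generate_dags(spec).items()
        }
        dss = disease_semantic_similarity(dags)
        assignment = rng.integers(0, n_d, size=n_c)
        values = np.zeros((n_c, n_d), dtype=np.int8)
        values[np.arange(n_c), assignment] = 1
        assoc = AssociationMatrix(
            values,
            EntityRegistry(tuple(f"c{i}" for i in range(n_c))),
            EntityRegistry(tuple(dags)),
        )
        cfs = circ_functional_similarity(assoc, dss)
        for i, j in itertools.combinations(range(n_c), 2):
            assert cfs.values[i, j] == pytest.approx(
                dss.values[assignment[i], assignment[j]], abs=1e-12
            )


class TestSixMatrixInvariants:
    def test_symmetric_unit_diagonal_in_unit_interval(self):
        spec = SyntheticSpec(n_circ=25, n_disease=10, n_blocks=3, rng_seed=11)
        sims = compute_similarities(
            generate_associations(spec), generate_dags(spec), PipelineParams()
        )
        assert set(sims) == {"DSS", "DGS", "SD", "CFS", "CGS", "SC"}
        for role, sim in sims.items():
            v = sim.values
            np.testing.assert_allclose(v, v.T, atol=1e-12, err_msg=role)
            assert v.min() >= -1e-12 and v.max() <= 1 + 1e-12, role
            np.testing.assert_allclose(np.diag(v), 1.0, atol=1e-12, err_msg=role)
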