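import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from relapsegrn.config import PipelineConfig
from relapsegrn.ontology import GoDag
from relapsegrn.semsim import (
    DEFAULT_WEIGHTS,
    WangSimilarity,
    ecdf_table,
    gene_pair_sim,
    homogeneity_test,
    ks_dminus,
    wang_term_sim,
)
from relapsegrn.simulate import simulate_go


def brute_force_svalues(dag: GoDag, term: str, weights=DEFAULT_WEIGHTS) -> dict:
    """S-values via explicit enumeration of every child->parent path."""
    s = {term: 1.0}
    for anc in dag.ancestors(term) - {term}:
        best = 0.0
        for path in nx.all_simple_paths(dag.graph, term, anc):
            w = 1.0
            for u, v in zip(path, path[1:]):
                w *= weights[dag.graph.edges[u, v]["relation"]]
            best = max(best, w)
        s[anc] = best
    return s


def brute_force_term_sim(dag: GoDag, t1: str, t2: str) -> float:
    sa = brute_force_svalues(dag, t1)
    sb = brute_force_svalues(dag, t2)
    common = sa.keys() & sb.keys()
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def random_dag(rng, n_terms: int) -> GoDag:
    """Random rooted DAG with mixed is_a/part_of edges, <= n_terms terms."""
    g = nx.DiGraph()
    g.add_node("t0", namespace="bp")
    for i in range(1, n_terms):
        node = f"t{i}"
        n_parents = int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            g.add_edge(node, f"t{p}", relation=rel)
        g.nodes[node]["namespace"] = "bp"
    return GoDag(graph=g)


class TestWangTermSim:
    def test_identity_is_exactly_one(self, small_dag):
        assert wang_term_sim(small_dag, "c", "c") == 1.0

    def test_parent_child_recursion_value(self):
        # B is_a A and nothing else: SV(B) = 1 + 0.8, SV(A) = 1, common = {A}
        g = nx.DiGraph()
        g.add_edge("B", "A", relation="is_a")
        g.nodes["A"]["namespace"] = "bp"
        g.nodes["B"]["namespace"] = "bp"
        dag = GoDag(graph=g)
        assert wang_term_sim(dag, "A", "B") == pytest.approx((1 + 0.8) / (1 + 1.8))

    def test_siblings_beat_root_only_pairs(self, small_dag):
        # c,d share parent a; c,e share only the root
        assert wang_term_sim(small_dag, "c", "d") > wang_term_sim(small_dag, "c", "e")

    def test_symmetric_and_bounded(self, small_dag):
        for t1, t2 in itertools.combinations(["a", "b", "c", "d", "e", "f"], 2):
            s12 = wang_term_sim(small_dag, t1, t2)
            s21 = wang_term_sim(small_dag, t2, t1)
            assert s12 == pytest.approx(s21)
            assert 0.0 <= s12 < 1.0  # equals 1 only for identical terms

    def test_cross_namespace_scores_zero(self, small_dag):
        g = small_dag.graph.copy()
        g.add_node("mf_root", namespace="molecular_function")
        g.add_edge("mf_x", "mf_root", relation="is_a")
        g.nodes["mf_x"]["namespace"] = "molecular_function"
        dag = GoDag(graph=g)
        assert wang_term_sim(dag, "c", "mf_x") == 0.0

    def test_dp_matches_path_enumeration_on_random_dags(self):
        rng = np.random.default_rng(101)
        for _ in range(10):
            dag = random_dag(rng, int(rng.integers(8, 31)))
            sim = WangSimilarity(dag)
            terms = list(dag.graph)
            for _ in range(15):
                t1, t2 = rng.choice(terms, 2, replace=True)
                assert sim.term_sim(str(t1), str(t2)) == pytest.approx(
                    brute_force_term_sim(dag, str(t1), str(t2)), abs=1e-12
                )


class TestGenePairSim:
    def test_identical_annotation_sets(self, small_dag):
        annot = {"g1": {"c", "e"}, "g2": {"c", "e"}}
        assert gene_pair_sim(annot, small_dag, "g1", "g2") == pytest.approx(1.0)

    def test_symmetry(self, small_dag):
        annot = {"g1": {"c", "d"}, "g2": {"e"}}
        assert gene_pair_sim(annot, small_dag, "g1", "g2") == pytest.approx(
            gene_pair_sim(annot, small_dag, "g2", "g1")
        )

    def test_single_term_genes_reduce_to_term_sim(self, small_dag):
        annot = {"g1": {"c"}, "g2": {"e"}}
        assert gene_pair_sim(annot, small_dag, "g1", "g2") == pytest.approx(
            wang_term_sim(small_dag, "c", "e")
        )

    def test_unannotated_gene_errors(self, small_dag):
        with pytest.raises(ValueError, match="g2"):
            gene_pair_sim({"g1": {"c"}}, small_dag, "g1", "g2")


class TestKsDminus:
    def test_matches_scipy_one_sided_statistic(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 40))
            y = rng.normal(size=rng.integers(3, 200))
            expect = stats.ks_2samp(x, y, alternative="less").statistic
            assert ks_dminus(x, np.sort(y)) == pytest.approx(expect, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(18)
        x, y = rng.normal(size=30), rng.normal(size=50)
        d1 = ks_dminus(x, np.sort(y))
        f = lambda v: np.exp(3 * v) + 1  # strictly increasing
        d2 = ks_dminus(f(x), np.sort(f(y)))
        assert d1 == pytest.approx(d2, abs=1e-12)


@pytest.fixture(scope="module")
def go_world():
    dag, annot, truth = simulate_go(300, 12, seed=3)
    return dag, annot, truth


class TestHomogeneityTest:
    def test_planted_module_rejects(self, go_world):
        dag, annot, truth = go_world
        rep = homogeneity_test(
            truth.homogeneous_module, annot, dag, set(annot),
            PipelineConfig(), seed=11
        )
        assert rep.pvalue <= 0.05
        assert rep.ks_statistic > 0.3

    def test_bookkeeping_minimal_case(self, go_world):
        dag, annot, _ = go_world
        genes = sorted(annot)[:2]
        cfg = PipelineConfig(n_random_sets=1)
        rep = homogeneity_test(set(genes), annot, dag, set(annot), cfg, seed=5)
        assert len(rep.grn_scores) == 1  # one pair
        assert rep.n_random_sets == 1
        assert len(rep.null_scores) == 1
        assert len(rep.null_statistics) == 1

    def test_deterministic_under_seed(self, go_world):
        dag, annot, truth = go_world
        cfg = PipelineConfig(n_random_sets=20)
        r1 = homogeneity_test(truth.homogeneous_module, annot, dag, set(annot), cfg, seed=9)
        r2 = homogeneity_test(truth.homogeneous_module, annot, dag, set(annot), cfg, seed=9)
        np.testing.assert_array_equal(r1.null_scores, r2.null_scores)
        assert r1.pvalue == r2.pvalue
        t1, t2 = ecdf_table(r1), ecdf_table(r2)
        assert t1.equals(t2)

    def test_annotation_count_matched_null_mode(self, go_world):
        """Matched mode draws null genes with the set's annotation counts."""
        dag, annot, truth = go_world
        cfg = PipelineConfig(n_random_sets=5, semsim_match_annotation_counts=True)
        rep = homogeneity_test(
            truth.homogeneous_module, annot, dag, set(annot), cfg, seed=4
        )
        n_pairs = len(rep.grn_scores)
        assert len(rep.null_scores) == 5 * n_pairs
        assert 0 < rep.pvalue <= 1

    def test_too_few_annotated_genes_errors(self, go_world):
        dag, annot, _ = go_world
        with pytest.raises(ValueError, match=">= 2"):
            homogeneity_test({"g0000"}, annot, dag, set(annot), PipelineConfig(), seed=1)

    def test_universe_smaller_than_set_errors(self, go_world):
        dag, annot, truth = go_world
        module = sorted(truth.homogeneous_module)
        with pytest.raises(ValueError):
            homogeneity_test(
                set(module), annot, dag, set(module[:3]), PipelineConfig(), seed=1
            )

    def test_ecdf_table_properties(self, go_world):
        dag, annot, truth = go_world
        rep = homogeneity_test(
            truth.homogeneous_module, annot, dag, set(annot),
            PipelineConfig(n_random_sets=20), seed=2
        )
        tab = ecdf_table(rep)
        assert tab["ecdf_grn"].iloc[-1] == 1.0
        assert tab["ecdf_random"].iloc[-1] == 1.0
        assert (tab["ecdf_grn"].diff().dropna() >= 0).all()
        # homogeneous set: its ECDF lies below (scores shifted right)
        assert tab["ecdf_grn"].mean() < tab["ecdf_random"].mean()
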