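import numpy as np
import pytest

from rwhn.errors import EmptyUniverse, UnknownTerm
from rwhn.io_formats import AnnotationLibrary, OntologyDAG, PPINetwork, SiteID
from rwhn.netbuild import (
    Adjacency,
    ModuleAssignment,
    assemble_multilayer,
    build_function_subnetwork,
    build_protein_subnetwork,
    build_site_subnetwork,
    detect_modules,
    enrich_modules,
    filter_function_terms,
    hypergeometric_enrichment,
)
from rwhn.preprocess import ClusterAssignment

from conftest import make_quant, run_study_pipeline


def assignment_for(qt, labels):
    return ClusterAssignment({s: c for s, c in zip(qt.sites, labels)})


class TestSiteSubnetwork:
    def test_same_cluster_identical_profiles_linked(self):
        qt = make_quant([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        adj = build_site_subnetwork(qt, assignment_for(qt, [1, 1]))
        assert adj.matrix[0, 1] == 1.0 and adj.is_symmetric()

    def test_cross_cluster_profiles_never_linked(self):
        qt = make_quant([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        adj = build_site_subnetwork(qt, assignment_for(qt, [1, 2]))
        assert adj.matrix.sum() == 0

    def test_correlation_below_threshold_not_linked(self):
        qt = make_quant([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 6.0]])
        r2 = np.corrcoef(qt.values)[0, 1] ** 2
        assert r2 < 0.99  # ≈ 0.878 by direct computation
        adj = build_site_subnetwork(qt, assignment_for(qt, [1, 1]))
        assert adj.matrix.sum() == 0
        # plain-r mode passes the same pair at a 0.93 threshold
        adj_r = build_site_subnetwork(
            qt, assignment_for(qt, [1, 1]), threshold=0.93, squared=False
        )
        assert adj_r.matrix[0, 1] == 1.0

    def test_constant_profile_has_no_edges_and_warns(self):
        qt = make_quant([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            adj = build_site_subnetwork(qt, assignment_for(qt, [1, 1, 1]))
        assert adj.matrix.sum() == 0

    def test_label_permutation_leaves_edges_unchanged(self):
        rng = np.random.default_rng(0)
        qt = make_quant(rng.random((10, 5)))
        labels = [1, 1, 2, 2, 3, 3, 1, 2, 3, 1]
        relabeled = [{1: 3, 2: 1, 3: 2}[c] for c in labels]
        a = build_site_subnetwork(qt, assignment_for(qt, labels), threshold=0.2)
        b = build_site_subnetwork(qt, assignment_for(qt, relabeled), threshold=0.2)
        assert np.array_equal(a.matrix, b.matrix)


class TestProteinSubnetwork:
    @pytest.fixture
    def ppi(self):
        net = PPINetwork()
        net.add_edge("A", "B", 0.9)  # B is a direct interactor of data protein A
        net.add_edge("B", "C", 0.9)  # C is two hops away
        net.add_edge("B", "D", 0.8)
        net.add_edge("D", "A", 0.7)
        return net

    def test_first_neighborhood_rule(self, ppi):
        adj = build_protein_subnetwork(ppi, {"A"})
        assert set(adj.row_nodes) == {"A", "B", "D"}  # C excluded

    def test_isolated_data_protein_retained(self, ppi):
        adj = build_protein_subnetwork(ppi, {"A", "Z"})
        assert "Z" in adj.row_nodes
        assert adj.matrix[adj.row_nodes.index("Z")].sum() == 0

    def test_edges_among_interactors_kept(self, ppi):
        adj = build_protein_subnetwork(ppi, {"A"})
        i, j = adj.row_nodes.index("B"), adj.row_nodes.index("D")
        assert adj.matrix[i, j] == 1.0


class TestModules:
    def cliques_adjacency(self):
        nodes = [f"X{i}" for i in range(5)] + [f"Y{i}" for i in range(5)]
        A = np.zeros((10, 10))
        A[:5, :5] = 1 - np.eye(5)
        A[5:, 5:] = 1 - np.eye(5)
        return Adjacency(nodes, nodes, A)

    def test_two_cliques_two_modules(self):
        modules = detect_modules(self.cliques_adjacency(), seed=0)
        groups = {}
        for p, m in modules.modules.items():
            groups.setdefault(m, set()).add(p)
        assert sorted(map(sorted, groups.values())) == [
            [f"X{i}" for i in range(5)],
            [f"Y{i}" for i in range(5)],
        ]

    def test_deterministic_given_seed(self, planted_pipeline):
        _, _, net, _ = planted_pipeline
        adj = Adjacency(net.proteins, net.proteins, net.a_pp)
        assert detect_modules(adj, seed=3).modules == detect_modules(adj, seed=3).modules


class TestEnrichment:
    UNIVERSE = {f"g{i}" for i in range(1, 21)}
    LIB = AnnotationLibrary(
        {
            "T1": frozenset({"g1", "g2", "g3", "g4", "g5"}),
            "T2": frozenset({"g10", "g11"}),
        }
    )

    def test_closed_form_hypergeometric(self):
        modules = ModuleAssignment({f"g{i}": 0 for i in range(1, 6)})
        records, pf = enrich_modules(modules, self.LIB, self.UNIVERSE)
        assert len(records) == 1
        rec = records[0]
        # drawing all 5 annotated genes in 5 draws from 20: 1 / C(20,5)
        assert rec.p == pytest.approx(1 / 15504, rel=1e-12)
        assert pf["T1"] == {f"g{i}" for i in range(1, 6)}

    def test_zero_overlap_term_skipped(self):
        result = hypergeometric_enrichment({"g1"}, self.LIB, self.UNIVERSE, alpha=1.1)
        assert [r[0] for r in result] == ["T1"]

    def test_bh_adjustment_hand_computed(self):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_empty_universe(self):
        with pytest.raises(EmptyUniverse):
            hypergeometric_enrichment({"g1"}, self.LIB, set())


class TestFilterFunctionTerms:
    def setup_method(self):
        # A sits under ten parents (a wide diamond) so the parent/child pair
        # (A, B) clears the 0.9 redundancy cutoff; C is an unrelated shallow
        # term. Sibling or simple-chain pairs cannot exceed 0.9 with the
        # standard 0.8 is_a factor.
        edges = [(f"P{i}", "R", "is_a") for i in range(10)]
        edges += [("A", f"P{i}", "is_a") for i in range(10)]
        edges += [("B", "A", "is_a"), ("C", "R", "is_a")]
        self.dag = OntologyDAG(edges)
        self.universe = {f"g{i}" for i in range(100)}

    def test_high_frequency_term_removed(self):
        lib = AnnotationLibrary(
            {"A": frozenset(f"g{i}" for i in range(6)), "C": frozenset({"g0"})}
        )
        kept = filter_function_terms({"A", "C"}, self.dag, lib, self.universe)
        assert kept == {"C"}  # A annotated to 6% > 5%

    def test_redundant_pair_keeps_rarer_term(self):
        from rwhn.semsim import wang_similarity

        lib = AnnotationLibrary(
            {"A": frozenset({"g0", "g1", "g2"}), "B": frozenset({"g0"})}
        )
        assert wang_similarity(self.dag, "A", "B") > 0.9
        kept = filter_function_terms({"A", "B"}, self.dag, lib, self.universe)
        assert kept == {"B"}  # B has frequency 1%, A 3% (propagated)

    def test_no_cutoff_hit_identity(self):
        lib = AnnotationLibrary(
            {"A": frozenset({"g0"}), "C": frozenset({"g1"})}
        )
        assert filter_function_terms({"A", "C"}, self.dag, lib, self.universe) == {
            "A",
            "C",
        }

    def test_unknown_term_rejected(self):
        lib = AnnotationLibrary({"A": frozenset({"g0"})})
        with pytest.raises(UnknownTerm):
            filter_function_terms({"ZZ"}, self.dag, lib, self.universe)


class TestFunctionSubnetwork:
    def test_kegg_profile_threshold_strict(self):
        lib = AnnotationLibrary(
            {
                "K1": frozenset({"a", "b", "c", "d"}),
                "K2": frozenset({"a", "b", "c", "x"}),  # overlap 3/4 = 0.75
                "K3": frozenset({"p", "q"}),
            }
        )
        adj = build_function_subnetwork({"K1", "K2", "K3"}, "kegg", lib)
        i, j = adj.row_nodes.index("K1"), adj.row_nodes.index("K2")
        assert adj.matrix[i, j] == 1.0
        assert np.all(np.diag(adj.matrix) == 0)  # no self-edges
        assert adj.matrix.sum() == 2  # only the K1-K2 pair

    def test_go_wang_threshold(self):
        # chain of depth 4 below the root: sibling leaves score ≈ 0.7025
        edges = [("L1", "D3", "is_a"), ("L2", "D3", "is_a")]
        edges += [("D3", "D2", "is_a"), ("D2", "D1", "is_a"), ("D1", "R", "is_a")]
        edges += [("S1", "R", "is_a"), ("S2", "R", "is_a")]  # shallow: ≈ 0.444
        dag = OntologyDAG(edges)
        adj = build_function_subnetwork({"L1", "L2", "S1", "S2"}, "go", dag)
        idx = {t: i for i, t in enumerate(adj.row_nodes)}
        assert adj.matrix[idx["L1"], idx["L2"]] == 1.0
        assert adj.matrix[idx["S1"], idx["S2"]] == 0.0


class TestAssemble:
    def test_full_matrix_symmetric(self, planted_pipeline):
        _, _, net, _ = planted_pipeline
        full = net.full_matrix()
        assert np.array_equal(full, full.T)
        assert full.shape == (net.n_nodes, net.n_nodes)

    def test_each_site_has_exactly_one_host_edge(self, planted_pipeline):
        _, _, net, _ = planted_pipeline
        assert np.array_equal(net.a_rp.sum(axis=1), np.ones(len(net.sites)))
        for i, site in enumerate(net.sites):
            host = net.proteins[int(net.a_rp[i].argmax())]
            assert host == site.protein

    def test_blocks_binary_and_hollow_diagonals(self, planted_pipeline):
        _, _, net, _ = planted_pipeline
        for block in (net.a_rr, net.a_pp, net.a_ff, net.a_rp, net.a_pf):
            assert set(np.unique(block)) <= {0.0, 1.0}
        for block in (net.a_rr, net.a_pp, net.a_ff):
            assert np.all(np.diag(block) == 0)

    def test_function_layer_only_enriched_terms(self, planted_study, planted_pipeline):
        _, _, net, _ = planted_pipeline
        assert set(net.functions) <= set(planted_study.lib.terms)
        # planted terms survive enrichment + GO filtering
        assert set(planted_study.truth.values()) <= set(net.functions)
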