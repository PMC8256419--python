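import numpy as np
import pytest

from rwhn.core import (
    RWHNParams,
    build_transition_matrix,
    extract_function_ranking,
    make_initial_vector,
    random_walk,
    run_rwhn,
)
from rwhn.errors import EmptySeeds, NoConvergence
from rwhn.io_formats import SiteID
from rwhn.netbuild import MultilayerNetwork
from rwhn.synthetic import random_multilayer

from conftest import match_clusters


def tiny_network():
    """Two sites on one protein linked to one function term.

    s1–s2 site edge; both sites on p1; p1 annotated to f1; no intra-layer
    protein or function edges.
    """
    s1, s2 = SiteID("P1", 10, "S"), SiteID("P1", 20, "T")
    return MultilayerNetwork(
        sites=[s1, s2],
        proteins=["P1"],
        functions=["F1"],
        a_rr=np.array([[0.0, 1.0], [1.0, 0.0]]),
        a_pp=np.zeros((1, 1)),
        a_ff=np.zeros((1, 1)),
        a_rp=np.array([[1.0], [1.0]]),
        a_pf=np.array([[1.0]]),
    )


def direct_solve(M, p0, r):
    """Linear-algebra oracle: p = r (I − (1−r) Mᵀ)⁻¹ p0."""
    n = len(p0)
    return r * np.linalg.solve(np.eye(n) - (1 - r) * M.matrix.T, p0)


class TestTransitionMatrix:
    def test_site_row_splits_lambda_between_layers(self):
        M = build_transition_matrix(tiny_network(), lambda_=0.5).matrix
        # row for s1: one site neighbor (s2), one host (p1)
        assert M[0, 1] == pytest.approx(0.5)
        assert M[0, 2] == pytest.approx(0.5)

    def test_site_without_intra_edges_sends_all_mass_to_host(self):
        net = tiny_network()
        net.a_rr[:] = 0.0
        M = build_transition_matrix(net, lambda_=0.5).matrix
        assert M[0, 2] == pytest.approx(1.0) and M[0, :2].sum() == 0.0

    def test_protein_with_both_bipartite_layers_splits_half(self):
        M = build_transition_matrix(tiny_network(), lambda_=0.6).matrix
        # p1 has no intra edges: half the mass to sites, half to the function
        assert M[2, 0] == pytest.approx(0.25)
        assert M[2, 1] == pytest.approx(0.25)
        assert M[2, 3] == pytest.approx(0.5)

    def test_degree_proportional_split_option(self):
        M = build_transition_matrix(
            tiny_network(), lambda_=0.6, protein_split="degree"
        ).matrix
        # p1 reaches 2 sites and 1 function: weights 2/3 and 1/3
        assert M[2, :2].sum() == pytest.approx(2 / 3)
        assert M[2, 3] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_rows_with_edges_sum_to_one(self, seed):
        net, _ = random_multilayer(
            n_sites=10, n_proteins=15, n_functions=6, edge_density=0.2, seed=seed
        )
        M = build_transition_matrix(net, lambda_=0.7).matrix
        sums = M.sum(axis=1)
        has_edge = net.full_matrix().sum(axis=1) > 0
        assert np.allclose(sums[has_edge], 1.0, atol=1e-12)
        assert np.all(sums[~has_edge] == 0.0)


class TestInitialVector:
    def test_seed_mass_uniform_and_nonseeds_zero(self):
        net = tiny_network()
        p0 = make_initial_vector(net, {net.sites[0]}, eta_p=0.0, eta_f=0.0)
        assert p0[0] == 1.0 and p0[1] == 0.0 and p0[2:].sum() == 0.0
        both = make_initial_vector(net, set(net.sites), eta_p=0.0, eta_f=0.0)
        assert both[0] == both[1] == pytest.approx(0.5)

    @pytest.mark.parametrize("eta_p", [0.0, 0.3, 0.7, 1.0])
    @pytest.mark.parametrize("eta_f", [0.0, 0.3, 1.0])
    def test_normalized_for_any_layer_weights(self, eta_p, eta_f):
        net, clusters = random_multilayer(seed=3)
        seeds = set(clusters.sites_in(1))
        p0 = make_initial_vector(net, seeds, eta_p, eta_f)
        assert p0.sum() == pytest.approx(1.0, abs=1e-12)
        site_block = p0[: len(net.sites)]
        seeded = np.array([s in seeds for s in net.sites])
        assert np.all(site_block[~seeded] == 0.0)

    def test_empty_seeds_rejected(self):
        with pytest.raises(EmptySeeds):
            make_initial_vector(tiny_network(), set())


class TestRandomWalk:
    def test_restart_only_limit_returns_p0(self):
        net, clusters = random_multilayer(seed=1)
        M = build_transition_matrix(net, 0.7)
        p0 = make_initial_vector(net, set(clusters.sites_in(1)), 0.7, 0.3)
        assert np.array_equal(random_walk(M, p0, r=1.0), p0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_linear_solve(self, seed):
        net, clusters = random_multilayer(
            n_sites=15, n_proteins=25, n_functions=10, seed=seed
        )
        M = build_transition_matrix(net, 0.7)
        p0 = make_initial_vector(net, set(clusters.sites_in(1)), 0.7, 0.3)
        iterative = random_walk(M, p0, r=0.7, tol=1e-12)
        assert np.abs(iterative - direct_solve(M, p0, 0.7)).max() < 1e-8

    def test_probability_conserved_without_isolated_nodes(self):
        net, clusters = random_multilayer(edge_density=0.5, seed=2)
        M = build_transition_matrix(net, 0.7)
        assert np.all(M.matrix.sum(axis=1) > 0)  # no isolated nodes
        p0 = make_initial_vector(net, set(clusters.sites_in(2)), 0.7, 0.3)
        p = random_walk(M, p0, r=0.7)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_linearity_of_steady_state(self):
        net, clusters = random_multilayer(seed=4)
        M = build_transition_matrix(net, 0.7)
        p0 = make_initial_vector(net, set(clusters.sites_in(1)), 0.7, 0.3)
        a = random_walk(M, p0, 0.7, tol=1e-13)
        b = random_walk(M, 2.0 * p0, 0.7, tol=1e-13)
        assert np.allclose(b, 2.0 * a, atol=1e-9)

    def test_no_convergence_reported_with_residual(self):
        net, clusters = random_multilayer(seed=5)
        M = build_transition_matrix(net, 0.7)
        p0 = make_initial_vector(net, set(clusters.sites_in(1)), 0.7, 0.3)
        with pytest.raises(NoConvergence) as exc:
            random_walk(M, p0, r=0.01, tol=1e-10, max_iter=2)
        assert exc.value.residual > 0


def ranking_fixture(n_terms, n_clusters, perturb):
    """Steady states over a function-only scoring problem."""
    rng = np.random.default_rng(0)
    net, _ = random_multilayer(n_sites=4, n_proteins=4, n_functions=n_terms, seed=9)
    steady = {}
    base = rng.random(n_terms)
    for c in range(1, n_clusters + 1):
        probs = base.copy()
        if perturb:
            probs += rng.random(n_terms) * 0.5
        steady[c] = np.concatenate([np.zeros(8), probs])
    return net, steady


class TestExtraction:
    def test_top_fraction_ceiling_count(self):
        net, steady = ranking_fixture(100, 3, perturb=True)
        result = extract_function_ranking(steady, net, top_fraction=0.05)
        assert all(len(result.retained[c]) == 5 for c in result.clusters)

    def test_constant_rank_terms_removed_before_cut(self):
        net, steady = ranking_fixture(10, 3, perturb=True)
        # force one term to rank first everywhere
        for c in steady:
            steady[c][8] = 10.0
        result = extract_function_ranking(steady, net, top_fraction=0.5)
        constant = net.functions[0]
        assert constant in result.constant_terms
        for c in result.clusters:
            assert constant not in result.retained[c]
            # cut applies to the remaining 9 terms: ceil(0.5 * 9) = 5
            assert len(result.retained[c]) == 5

    def test_single_cluster_skips_constant_rank_removal(self):
        net, steady = ranking_fixture(10, 1, perturb=False)
        result = extract_function_ranking(steady, net, top_fraction=0.2)
        assert result.constant_terms == set()
        assert len(result.retained[1]) == 2

    def test_ties_broken_by_term_id(self):
        net, steady = ranking_fixture(10, 1, perturb=False)
        steady[1][8:] = 0.25  # all equal
        result = extract_function_ranking(steady, net, top_fraction=1.0)
        terms = [t for t, _, _ in result.rankings[1]]
        assert terms == sorted(terms)


class TestRunRWHN:
    def test_planted_term_tops_each_seeding_cluster(
        self, planted_study, planted_pipeline
    ):
        _, clusters, _, result = planted_pipeline
        mapping = match_clusters(planted_study, clusters)
        planted = set(planted_study.truth.values())
        for c in result.clusters:
            own = planted_study.truth[mapping[c]]
            assert own in result.retained[c]
            own_rank = result.rank_of(c, own)
            for other in planted - {own}:
                assert own_rank < result.rank_of(c, other)

    def test_node_relabeling_leaves_ranking_unchanged(self):
        net, clusters = random_multilayer(
            n_sites=12, n_proteins=18, n_functions=9, edge_density=0.25, seed=6
        )
        base = run_rwhn(net, clusters, RWHNParams())

        rng = np.random.default_rng(1)
        perm_r = rng.permutation(len(net.sites))
        perm_p = rng.permutation(len(net.proteins))
        perm_f = rng.permutation(len(net.functions))
        shuffled = MultilayerNetwork(
            [net.sites[i] for i in perm_r],
            [net.proteins[i] for i in perm_p],
            [net.functions[i] for i in perm_f],
            net.a_rr[np.ix_(perm_r, perm_r)],
            net.a_pp[np.ix_(perm_p, perm_p)],
            net.a_ff[np.ix_(perm_f, perm_f)],
            net.a_rp[np.ix_(perm_r, perm_p)],
            net.a_pf[np.ix_(perm_p, perm_f)],
        )
        got = run_rwhn(shuffled, clusters, RWHNParams())
        for c in base.clusters:
            assert dict(
                (t, r) for t, _, r in base.rankings[c]
            ) == dict((t, r) for t, _, r in got.rankings[c])

    def test_bit_identical_across_runs(self, planted_pipeline):
        _, clusters, net, result = planted_pipeline
        again = run_rwhn(net, clusters, RWHNParams())
        assert again.rankings == result.rankings
        assert again.retained == result.retained

    def test_cluster_without_network_sites_rejected(self):
        from rwhn.preprocess import ClusterAssignment

        net, clusters = random_multilayer(seed=7)
        labels = dict(clusters.labels)
        labels[SiteID("ZZ", 5, "S")] = 99  # cluster 99 has no network sites
        with pytest.raises(EmptySeeds):
            run_rwhn(net, ClusterAssignment(labels), RWHNParams())
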