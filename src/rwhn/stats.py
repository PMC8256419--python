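"""Permutation-based significance, ORA baseline, and ranking comparison.

The permutation control asks whether a term's rank for a given seed cluster
could have arisen from network topology alone: node labels are shuffled
independently within each layer and applied consistently to the intra-layer
and bipartite blocks, so the permuted network is isomorphic to the original
(every subnetwork and bipartite edge is maintained) but which site seeds
where — and which term sits at which topological position — is random. The
walk is re-run on each permuted network. The primary significance measure
is the add-one empirical p-value of the observed rank against the null
ranks, BH-adjusted across terms within each cluster; a Mann–Whitney U
comparison is additionally reported when observed ranks exist for two or
more clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import RWHNParams, run_rwhn
from .errors import BadPermCount, EmptyCluster, ItemMismatch
from .io_formats import AnnotationLibrary
from .netbuild import MultilayerNetwork, hypergeometric_enrichment
from .preprocess import ClusterAssignment


def permute_multilayer(net: MultilayerNetwork, seed: int) -> MultilayerNetwork:
    """Shuffle node labels within each layer, consistently across blocks.

    An independent random permutation per layer is applied to both indices
    of the intra-layer adjacency and the matching index of each bipartite
    block, producing a network isomorphic to the input: every subnetwork and
    every bipartite edge is maintained, but the correspondence between node
    identities (which sites seed a cluster, which term is which) and
    topological positions is randomized. Layer sizes, degree multisets and
    all per-block edge counts are preserved. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = net.copy()
    p_r = rng.permutation(len(net.sites))
    p_p = rng.permutation(len(net.proteins))
    p_f = rng.permutation(len(net.functions))
    out.a_rr = net.a_rr[np.ix_(p_r, p_r)]
    out.a_pp = net.a_pp[np.ix_(p_p, p_p)]
    out.a_ff = net.a_ff[np.ix_(p_f, p_f)]
    out.a_rp = net.a_rp[np.ix_(p_r, p_p)]
    out.a_pf = net.a_pf[np.ix_(p_p, p_f)]
    return out


@dataclass
class PermStats:
    """Observed vs null ranks with empirical and adjusted p-values.

    Keys of the per-term dicts are (cluster, term). ``null_ranks`` holds one
    rank per permutation; ``pvals`` the add-one empirical p; ``qvals`` the
    BH adjustment across terms within the cluster. ``mwu_pvals`` /
    ``mwu_qvals`` (per term, across clusters) are present only when observed
    ranks exist for ≥2 clusters.
    """

    clusters: list
    terms: list
    n_perm: int
    observed: dict
    null_ranks: dict
    pvals: dict
    qvals: dict
    observed_prob: dict = field(default_factory=dict)
    mwu_pvals: dict = field(default_factory=dict)
    mwu_qvals: dict = field(default_factory=dict)

    def null_density(self, cluster, term: str):
        """Gaussian KDE (Silverman bandwidth) over the null ranks; reporting only."""
        ranks = np.asarray(self.null_ranks[(cluster, term)], dtype=float)
        if np.ptp(ranks) == 0:
            ranks = ranks + np.linspace(-0.5, 0.5, len(ranks))
        return sps.gaussian_kde(ranks, bw_method="silverman")

    def to_rows(self) -> list[dict]:
        rows = []
        for (c, t), p in self.pvals.items():
            rows.append(
                {
                    "seed_cluster": c,
                    "term_id": t,
                    "observed_rank": self.observed[(c, t)],
                    "median_null_rank": float(np.median(self.null_ranks[(c, t)])),
                    "empirical_p": p,
                    "adjusted_p": self.qvals[(c, t)],
                    "mwu_adjusted_p": self.mwu_qvals.get(t, float("nan")),
                }
            )
        return rows


def permutation_significance(
    net: MultilayerNetwork,
    clusters: ClusterAssignment,
    params: RWHNParams = RWHNParams(),
    n_perm: int = 100,
    seed: int = 0,
) -> PermStats:
    """Permutation null for per-cluster term ranks.

    Runs the walk on ``n_perm`` independently permuted networks. For each
    (cluster, term) the add-one empirical p is

        (1 + #{null steady-state probability ≥ observed}) / (n_perm + 1)

    — never exactly 0 and exactly uniform under the exchangeable null. The
    continuous visiting probability is the comparison statistic (it orders
    terms identically to the rank within any single network but is free of
    the integer-rank collisions across networks that would make a
    rank-count p conservative); null *ranks* are kept alongside for
    reporting and KDE. BH adjustment across terms within each cluster is
    reported as ``qvals``. With ≥2 clusters, a two-sided Mann–Whitney U of
    the observed ranks (one per cluster) against the pooled null ranks is
    additionally reported per term, BH-adjusted across terms.
    """
    if n_perm < 1:
        raise BadPermCount(f"n_perm must be >= 1, got {n_perm}")
    observed_result = run_rwhn(net, clusters, params)
    cluster_ids = observed_result.clusters
    terms = list(net.functions)
    obs = {
        (c, t): observed_result.rank_of(c, t) for c in cluster_ids for t in terms
    }
    obs_prob = {
        (c, t): p
        for c in cluster_ids
        for t, p, _ in observed_result.rankings[c]
    }
    null: dict = {(c, t): np.empty(n_perm, dtype=int) for c in cluster_ids for t in terms}
    null_prob: dict = {(c, t): np.empty(n_perm) for c in cluster_ids for t in terms}
    child_seeds = np.random.SeedSequence(seed).generate_state(n_perm) % (2**31)
    for b in range(n_perm):
        perm_net = permute_multilayer(net, int(child_seeds[b]))
        perm_result = run_rwhn(perm_net, clusters, params)
        for c in cluster_ids:
            for t, p, rank in perm_result.rankings[c]:
                null[(c, t)][b] = rank
                null_prob[(c, t)][b] = p

    pvals: dict = {}
    qvals: dict = {}
    for c in cluster_ids:
        ps = []
        for t in terms:
            p = (1 + int(np.sum(null_prob[(c, t)] >= obs_prob[(c, t)]))) / (
                n_perm + 1
            )
            pvals[(c, t)] = p
            ps.append(p)
        if ps:
            _, qs, _, _ = multipletests(ps, method="fdr_bh")
            for t, q in zip(terms, qs):
                qvals[(c, t)] = float(q)

    mwu_p: dict = {}
    mwu_q: dict = {}
    if len(cluster_ids) >= 2 and terms:
        ps = []
        for t in terms:
            obs_sample = [obs[(c, t)] for c in cluster_ids]
            null_sample = np.concatenate([null[(c, t)] for c in cluster_ids])
            try:
                _, p = sps.mannwhitneyu(obs_sample, null_sample, alternative="two-sided")
            except ValueError:  # all values identical
                p = 1.0
            mwu_p[t] = float(p)
            ps.append(float(p))
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
        for t, q in zip(terms, qs):
            mwu_q[t] = float(q)

    return PermStats(
        cluster_ids, terms, n_perm, obs, null, pvals, qvals, obs_prob, mwu_p, mwu_q
    )


def ora(
    cluster_proteins: set[str],
    lib: AnnotationLibrary,
    universe: set[str],
    alpha: float = 0.05,
) -> list[tuple[str, int, int, float, float]]:
    """Over-representation baseline: hypergeometric + BH on one protein list.

    Returns (term, overlap, term_size, p, q) for terms with q < ``alpha``,
    sorted by p. The gene-centric comparison point for the walk-based
    rankings.
    """
    if not cluster_proteins:
        raise EmptyCluster("empty protein set for ORA")
    return hypergeometric_enrichment(set(cluster_proteins), lib, universe, alpha)


def weighted_tau(rank_a: dict, rank_b: dict) -> float:
    """Hyperbolically weighted Kendall correlation of two rankings.

    ``rank_a`` / ``rank_b`` map the same items to ranks (1 = best). Pair
    (i, j) carries additive weight (1/r_i + 1/r_j), so exchanges near the
    top of the ranking weigh more; the weights are averaged over the two
    rankings, matching the symmetric estimator of Vigna (2015). Returns a
    value in [−1, 1]; identical rankings give 1.
    """
    if set(rank_a) != set(rank_b):
        raise ItemMismatch("rankings cover different item sets")
    items = sorted(rank_a)
    if len(items) < 2:
        return 1.0
    ra = np.array([rank_a[i] for i in items], dtype=float)
    rb = np.array([rank_b[i] for i in items], dtype=float)

    def one_sided(ranks: np.ndarray) -> tuple[float, float]:
        num = 0.0
        den = 0.0
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                wgt = 1.0 / ranks[i] + 1.0 / ranks[j]
                num += wgt * np.sign(ra[i] - ra[j]) * np.sign(rb[i] - rb[j])
                den += wgt
        return num, den

    na, da = one_sided(ra)
    nb, db = one_sided(rb)
    return 0.5 * (na / da + nb / db)


def ranking_to_rankmap(result, cluster) -> dict:
    """Extract a term → rank dict for one seed cluster of a RankedResult."""
    return {t: r for t, _, r in result.rankings[cluster]}
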