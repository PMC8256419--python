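"""Random walk with restart on the three-layer heterogeneous network.

A walker starts on the phosphosites of one regulation cluster and diffuses
through site–site, protein–protein and function–function edges, hopping
between layers through the bipartite site–protein and protein–function
blocks. At each step a fraction ``r`` of probability teleports back to the
seeds. Function nodes are ranked by their steady-state visiting probability;
terms ranked identically for every seed cluster carry no cluster-specific
signal and are removed before the top-fraction cut.

Transition rule (per row of the transition matrix M): probability mass λ
goes to cross-layer moves and 1−λ to intra-layer moves, each uniformly over
the corresponding neighbors. Protein nodes adjacent to both the site and the
function layer split the cross-layer mass λ/2 per layer (or proportionally
to bipartite degree with ``protein_split="degree"``). When a node has no
intra-layer edges its whole mass crosses layers, and vice versa; fully
isolated nodes keep an all-zero row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySeeds, NoConvergence
from .io_formats import SiteID
from .netbuild import MultilayerNetwork
from .preprocess import ClusterAssignment


@dataclass
class RWHNParams:
    """Tunable parameters of the walk, with the method's defaults.

    lambda_ — inter-layer transition probability; r — restart probability;
    eta_p, eta_f — initial-probability weights of the protein and function
    layers; top_fraction — fraction of ranked functions retained.
    """

    lambda_: float = 0.7
    r: float = 0.7
    eta_p: float = 0.7
    eta_f: float = 0.3
    tol: float = 1e-10
    max_iter: int = 10000
    top_fraction: float = 0.05
    protein_split: str = "half"  # or "degree"

    def __post_init__(self):
        if not 0.0 < self.lambda_ < 1.0:
            raise ValueError("lambda_ must be in (0,1)")
        if not 0.0 < self.r <= 1.0:
            raise ValueError("r must be in (0,1]")
        for name in ("eta_p", "eta_f"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0,1]")
        if self.protein_split not in ("half", "degree"):
            raise ValueError("protein_split must be 'half' or 'degree'")


@dataclass
class TransitionMatrix:
    """Row-stochastic block transition matrix over [sites; proteins; functions].

    Rows of nodes with at least one edge sum to 1 (±1e-12); isolated nodes
    keep all-zero rows.
    """

    matrix: np.ndarray
    n_sites: int
    n_proteins: int
    n_functions: int

    @property
    def n_nodes(self) -> int:
        return self.n_sites + self.n_proteins + self.n_functions

    @property
    def function_slice(self) -> slice:
        return slice(self.n_sites + self.n_proteins, self.n_nodes)


def _rownorm(block: np.ndarray) -> np.ndarray:
    """Row-normalize, leaving all-zero rows untouched."""
    s = block.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, block / s, 0.0)
    return out


def build_transition_matrix(
    net: MultilayerNetwork, lambda_: float = 0.7, protein_split: str = "half"
) -> TransitionMatrix:
    """Assemble the row-stochastic transition matrix with inter-layer mass λ."""
    n_r, n_p, n_f = len(net.sites), len(net.proteins), len(net.functions)
    n = n_r + n_p + n_f
    M = np.zeros((n, n))
    sl_r, sl_p, sl_f = (
        slice(0, n_r),
        slice(n_r, n_r + n_p),
        slice(n_r + n_p, n),
    )

    rr, pp, ff = _rownorm(net.a_rr), _rownorm(net.a_pp), _rownorm(net.a_ff)
    rp, pf = _rownorm(net.a_rp), _rownorm(net.a_pf)
    pr, fp = _rownorm(net.a_rp.T), _rownorm(net.a_pf.T)

    deg_intra_r = net.a_rr.sum(axis=1)
    deg_cross_r = net.a_rp.sum(axis=1)
    for i in range(n_r):
        has_intra, has_cross = deg_intra_r[i] > 0, deg_cross_r[i] > 0
        if has_intra and has_cross:
            M[i, sl_r] = (1 - lambda_) * rr[i]
            M[i, sl_p] = lambda_ * rp[i]
        elif has_cross:
            M[i, sl_p] = rp[i]
        elif has_intra:
            M[i, sl_r] = rr[i]

    deg_intra_p = net.a_pp.sum(axis=1)
    deg_to_sites = net.a_rp.T.sum(axis=1)
    deg_to_funcs = net.a_pf.sum(axis=1)
    for i in range(n_p):
        row = n_r + i
        has_intra = deg_intra_p[i] > 0
        to_r, to_f = deg_to_sites[i] > 0, deg_to_funcs[i] > 0
        if to_r and to_f:
            if protein_split == "half":
                w_r = w_f = 0.5
            else:
                total = deg_to_sites[i] + deg_to_funcs[i]
                w_r, w_f = deg_to_sites[i] / total, deg_to_funcs[i] / total
        else:
            w_r, w_f = float(to_r), float(to_f)
        cross = lambda_ if has_intra else 1.0
        if not (to_r or to_f):
            cross = 0.0
        if has_intra:
            M[row, sl_p] = (1.0 - cross) * pp[i]
        if to_r:
            M[row, sl_r] = cross * w_r * pr[i]
        if to_f:
            M[row, sl_f] = cross * w_f * pf[i]

    deg_intra_f = net.a_ff.sum(axis=1)
    deg_cross_f = net.a_pf.T.sum(axis=1)
    for i in range(n_f):
        row = n_r + n_p + i
        has_intra, has_cross = deg_intra_f[i] > 0, deg_cross_f[i] > 0
        if has_intra and has_cross:
            M[row, sl_f] = (1 - lambda_) * ff[i]
            M[row, sl_p] = lambda_ * fp[i]
        elif has_cross:
            M[row, sl_p] = fp[i]
        elif has_intra:
            M[row, sl_f] = ff[i]

    return TransitionMatrix(M, n_r, n_p, n_f)


def make_initial_vector(
    net: MultilayerNetwork,
    seeds: set[SiteID],
    eta_p: float = 0.7,
    eta_f: float = 0.3,
) -> np.ndarray:
    """Initial probability vector: uniform mass 1 over the seed sites, mass
    η_P spread over proteins and η_F over functions, then normalized to 1.

    Non-seed sites start at exactly 0.
    """
    if not seeds:
        raise EmptySeeds("seed set is empty")
    site_idx = {s: i for i, s in enumerate(net.sites)}
    missing = [s for s in seeds if s not in site_idx]
    if missing:
        raise EmptySeeds(f"seeds not in site layer: {missing[:3]}")
    n_r, n_p, n_f = len(net.sites), len(net.proteins), len(net.functions)
    p0 = np.zeros(n_r + n_p + n_f)
    for s in seeds:
        p0[site_idx[s]] = 1.0 / len(seeds)
    if n_p:
        p0[n_r : n_r + n_p] = eta_p / n_p
    if n_f:
        p0[n_r + n_p :] = eta_f / n_f
    return p0 / p0.sum()


def random_walk(
    M: TransitionMatrix | np.ndarray,
    p0: np.ndarray,
    r: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> np.ndarray:
    """Iterate p ← (1−r)·Mᵀ·p + r·p0 to the steady state (L1 criterion).

    Raises :class:`NoConvergence` (with the final residual) if ``max_iter``
    is exhausted. With r=1 the result is exactly p0.
    """
    mat = M.matrix if isinstance(M, TransitionMatrix) else np.asarray(M)
    if r == 1.0:
        return p0.copy()
    mt = mat.T.copy()  # contiguous for the repeated matvec
    p = p0.copy()
    restart = r * p0
    residual = np.inf
    for _ in range(max_iter):
        p_next = (1.0 - r) * (mt @ p) + restart
        residual = float(np.abs(p_next - p).sum())
        if residual < tol:
            return p_next
        p = p_next
    raise NoConvergence(residual, max_iter)


@dataclass
class RankedResult:
    """Per-seed-cluster rankings of function terms.

    ``rankings[c]`` is the full list of (term, steady-state probability,
    rank) sorted by rank; ``retained[c]`` the ordered terms surviving
    constant-rank removal and the top-fraction cut. ``constant_terms`` are
    the terms ranked identically across every cluster (empty with a single
    cluster).
    """

    clusters: list
    rankings: dict
    retained: dict
    constant_terms: set = field(default_factory=set)

    def rank_of(self, cluster, term: str) -> int:
        for t, _, rank in self.rankings[cluster]:
            if t == term:
                return rank
        raise KeyError(term)


def extract_function_ranking(
    steady_states: dict,
    net: MultilayerNetwork,
    top_fraction: float = 0.05,
) -> RankedResult:
    """Rank function nodes per seed cluster and apply the retention rules.

    Probabilities are restricted to the function block and ranked in
    descending order (ties broken by term ID). With ≥2 clusters, terms whose
    integer rank is identical for every cluster are removed; the top
    ``ceil(top_fraction × n_remaining)`` terms per cluster are retained.
    """
    clusters = list(steady_states)
    n_r, n_p = len(net.sites), len(net.proteins)
    rankings: dict = {}
    rank_maps: dict = {}
    for c in clusters:
        probs = np.asarray(steady_states[c])[n_r + n_p :]
        order = sorted(
            zip(net.functions, probs), key=lambda tp: (-tp[1], tp[0])
        )
        rankings[c] = [(t, float(p), i + 1) for i, (t, p) in enumerate(order)]
        rank_maps[c] = {t: i + 1 for i, (t, p) in enumerate(order)}

    constant: set[str] = set()
    if len(clusters) >= 2 and net.functions:
        for t in net.functions:
            ranks = {rank_maps[c][t] for c in clusters}
            if len(ranks) == 1:
                constant.add(t)

    retained: dict = {}
    for c in clusters:
        remaining = [row for row in rankings[c] if row[0] not in constant]
        n_keep = math.ceil(top_fraction * len(remaining)) if remaining else 0
        retained[c] = [t for t, _, _ in remaining[:n_keep]]
    return RankedResult(clusters, rankings, retained, constant)


def run_rwhn(
    net: MultilayerNetwork,
    clusters: ClusterAssignment,
    params: RWHNParams = RWHNParams(),
) -> RankedResult:
    """Run the walk once per regulation cluster and rank function terms.

    All clusters share one transition matrix; the seed set of cluster c is
    its sites present in the network. Fully deterministic.
    """
    M = build_transition_matrix(net, params.lambda_, params.protein_split)
    in_net = set(net.sites)
    steady: dict = {}
    for c in clusters.cluster_ids():
        seeds = {s for s in clusters.sites_in(c) if s in in_net}
        if not seeds:
            raise EmptySeeds(f"cluster {c} has no sites in the network")
        p0 = make_initial_vector(net, seeds, params.eta_p, params.eta_f)
        steady[c] = random_walk(M, p0, params.r, params.tol, params.max_iter)
    return extract_function_ranking(steady, net, params.top_fraction)
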