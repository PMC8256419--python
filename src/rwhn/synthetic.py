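"""Self-contained synthetic studies with planted cluster → function truth.

The generator emulates a SILAC-style time-course phosphoproteomics
experiment over a signaling network: each regulation cluster follows one of
five temporal archetypes (early transient, sustained, late, decreasing,
cycling) on a log2-ratio scale; the sites of a cluster live on a dedicated
group of host proteins that form a dense interaction module; each module is
annotated to one distinctive ("planted") function term, while decoy terms
annotate background modules. Running the full pipeline on such a study
should recover each cluster's planted term in its retained list — the
ground truth is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BadConfig
from .io_formats import (
    AnnotationLibrary,
    OntologyDAG,
    PPINetwork,
    QuantTable,
    SiteID,
)
from .preprocess import ClusterAssignment

# Temporal archetypes on the log2-ratio scale over 8 time points.
# Amplitudes of ±2 (4-fold) keep the sites comfortably "regulated".
_T = np.linspace(0.0, 1.0, 8)
ARCHETYPES: dict[str, np.ndarray] = {
    "early_transient": 2.0 * (np.exp(-((_T - 0.15) ** 2) / 0.008)),
    "sustained": 2.0 * (1.0 - np.exp(-_T / 0.15)),
    "late": 2.0 * np.exp(-((_T - 0.9) ** 2) / 0.05),
    "decreasing": -2.0 * (1.0 - np.exp(-_T / 0.3)),
    "cycling": 1.8 * np.sin(2.0 * np.pi * 1.5 * _T),
}
_ARCHETYPE_ORDER = list(ARCHETYPES)
_RESIDUES = "STY"


@dataclass
class SyntheticStudy:
    """A generated study plus its planted ground truth.

    ``truth`` maps the cluster index (1-based, in archetype order) to its
    distinctive term; ``archetypes`` maps it to the temporal shape name;
    ``true_labels`` holds the planted site → cluster assignment.
    """

    quant: QuantTable
    ppi: PPINetwork
    lib: AnnotationLibrary
    dag: OntologyDAG
    truth: dict[int, str]
    archetypes: dict[int, str]
    true_labels: dict[SiteID, int]

    def true_assignment(self) -> ClusterAssignment:
        return ClusterAssignment(dict(self.true_labels))


def _term_id(n: int) -> str:
    return f"GO:{n:07d}"


def _make_sites(
    rng: np.random.Generator, proteins: list[str], n_sites: int
) -> list[SiteID]:
    """Distribute n_sites round-robin over proteins with unique positions."""
    sites = []
    used: dict[str, set[int]] = {p: set() for p in proteins}
    for i in range(n_sites):
        prot = proteins[i % len(proteins)]
        while True:
            pos = int(rng.integers(1, 2000))
            if pos not in used[prot]:
                used[prot].add(pos)
                break
        sites.append(SiteID(prot, pos, _RESIDUES[int(rng.integers(3))]))
    return sites


def generate_planted_study(
    n_clusters: int = 3,
    sites_per_cluster: int = 30,
    n_background_proteins: int = 350,
    n_decoy_terms: int = 12,
    noise_sd: float = 0.25,
    seed: int = 0,
    missing_fraction: float = 0.1,
) -> SyntheticStudy:
    """Generate a planted study (quant + PPI + GMT + ontology + truth).

    Each of the ``n_clusters`` clusters (max 5, one archetype each) has
    ``sites_per_cluster`` sites on a dedicated dense protein module wired to
    that cluster's distinctive term. Background proteins are interactors of
    the phosphoproteins (mirroring a STRING first-neighborhood) and host
    decoy modules annotated to decoy terms. ``missing_fraction`` of sites
    get one missing cell (left-censored, exercising the imputation path).
    Deterministic given ``seed``.
    """
    if n_clusters < 2 or n_clusters > len(ARCHETYPES):
        raise BadConfig(f"n_clusters must be in [2, {len(ARCHETYPES)}]")
    if sites_per_cluster < 3:
        raise BadConfig("sites_per_cluster must be >= 3")
    if n_background_proteins < 8 * n_decoy_terms:
        raise BadConfig(
            "need >= 8 background proteins per decoy term "
            f"({n_background_proteins} < {8 * n_decoy_terms})"
        )
    rng = np.random.default_rng(seed)
    n_timepoints = len(_T)
    conditions = [f"t{i}" for i in range(n_timepoints)]

    # --- quant table -----------------------------------------------------
    sites: list[SiteID] = []
    true_labels: dict[SiteID, int] = {}
    archetypes: dict[int, str] = {}
    cluster_proteins: dict[int, list[str]] = {}
    values_rows: list[np.ndarray] = []
    for c in range(1, n_clusters + 1):
        name = _ARCHETYPE_ORDER[c - 1]
        archetypes[c] = name
        n_prot = max(4, sites_per_cluster // 2)
        prots = [f"C{c}P{i + 1}" for i in range(n_prot)]
        cluster_proteins[c] = prots
        c_sites = _make_sites(rng, prots, sites_per_cluster)
        base = ARCHETYPES[name]
        for s in c_sites:
            log2 = base + rng.normal(0.0, noise_sd, n_timepoints)
            sites.append(s)
            true_labels[s] = c
            values_rows.append(2.0 ** log2)
    values = np.vstack(values_rows)

    # knock out one low-intensity cell for a fraction of sites
    n_censor = int(round(missing_fraction * len(sites)))
    censored_rows = rng.choice(len(sites), size=n_censor, replace=False)
    for i in censored_rows:
        j = int(np.argmin(values[i]))
        values[i, j] = np.nan
    quant = QuantTable(sites, conditions, values)

    # --- PPI --------------------------------------------------------------
    ppi = PPINetwork()
    background = [f"BG{i + 1}" for i in range(n_background_proteins)]

    def dense_module(prots: list[str], p_edge: float = 0.9) -> None:
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                if rng.random() < p_edge:
                    ppi.add_edge(prots[i], prots[j], float(rng.uniform(0.401, 1.0)))

    all_cluster_prots = [p for c in range(1, n_clusters + 1) for p in cluster_proteins[c]]
    for c in range(1, n_clusters + 1):
        # near-clique: a signaling module's internal wiring must dominate the
        # background tethers or module detection cannot resolve it
        dense_module(cluster_proteins[c], p_edge=0.95)

    # every background protein interacts weakly with one phosphoprotein, so
    # the whole background is part of the first neighborhood (as a STRING
    # pull of "all interactors" would be)
    for bg in background:
        anchor = all_cluster_prots[int(rng.integers(len(all_cluster_prots)))]
        ppi.add_edge(bg, anchor, float(rng.uniform(0.401, 0.6)))

    decoy_modules: list[list[str]] = []
    cursor = 0
    for _ in range(n_decoy_terms):
        group = background[cursor : cursor + 8]
        cursor += 8
        decoy_modules.append(group)
        dense_module(group)
    rest = background[cursor:]
    for i in range(len(rest)):
        for j in range(i + 1, len(rest)):
            if rng.random() < 0.02:
                ppi.add_edge(rest[i], rest[j], float(rng.uniform(0.401, 1.0)))

    # --- ontology + annotations -------------------------------------------
    root = _term_id(1)
    branches = [_term_id(10 + b) for b in range(3)]
    edges = [(b, root, "is_a") for b in branches]
    names = {root: "biological_process"}
    for b, bid in enumerate(branches):
        names[bid] = f"branch {b + 1}"
    terms: dict[str, frozenset[str]] = {}
    truth: dict[int, str] = {}
    for c in range(1, n_clusters + 1):
        tid = _term_id(100 + c)
        truth[c] = tid
        names[tid] = f"planted process cluster {c}"
        edges.append((tid, branches[c % len(branches)], "is_a"))
        terms[tid] = frozenset(cluster_proteins[c])
    # decoy terms come in sibling pairs at ontology depth 4, deep enough for
    # the pair to clear the 0.7 function-layer similarity threshold while
    # staying under the 0.9 redundancy cutoff
    for d, group in enumerate(decoy_modules):
        tid = _term_id(200 + d)
        names[tid] = f"decoy process {d + 1}"
        pair = d // 2
        chain_parent = branches[pair % len(branches)]
        for depth in range(2):  # two intermediate nodes below the branch
            mid = _term_id(300 + 10 * pair + depth)
            if mid not in names:
                names[mid] = f"decoy family {pair + 1} level {depth + 2}"
                edges.append((mid, chain_parent, "is_a"))
            chain_parent = mid
        rel = "is_a" if rng.random() < 0.7 else "part_of"
        edges.append((tid, chain_parent, rel))
        terms[tid] = frozenset(group)
    dag = OntologyDAG(edges, terms=[root, *branches, *terms], names=names)
    universe = frozenset(
        p for prots in cluster_proteins.values() for p in prots
    ) | frozenset(background)
    lib = AnnotationLibrary(terms, names={t: names[t] for t in terms}, universe=universe)

    return SyntheticStudy(quant, ppi, lib, dag, truth, archetypes, true_labels)


def generate_validation_like_dataset(
    seed: int = 0, noise_sd: float = 0.15
) -> tuple[QuantTable, ClusterAssignment]:
    """A small MAPK/ERK-style time course: 19 sites on 8 proteins, 5 clusters.

    The layout mirrors a canonical growth-factor cascade (receptor, adaptor,
    exchange factor, three kinase tiers, effector) with each site following
    one of the five temporal archetypes; values are generated, not measured.
    """
    rng = np.random.default_rng(seed)
    layout = [  # (protein, n_sites, cluster index 1..5)
        ("RTK1", 4, [1, 1, 2, 3]),
        ("ADAP1", 1, [1]),
        ("GEF1", 2, [1, 4]),
        ("KIN1", 4, [2, 4, 5, 5]),
        ("KIN2", 2, [2, 3]),
        ("KIN3", 2, [3, 5]),
        ("KIN4", 2, [2, 4]),
        ("EFF1", 2, [3, 5]),
    ]
    conditions = [f"t{i}" for i in range(len(_T))]
    sites: list[SiteID] = []
    labels: dict[SiteID, int] = {}
    rows: list[np.ndarray] = []
    for prot, n, cls in layout:
        positions = rng.choice(np.arange(1, 1500), size=n, replace=False)
        for pos, c in zip(positions, cls):
            site = SiteID(prot, int(pos), _RESIDUES[int(rng.integers(3))])
            sites.append(site)
            labels[site] = c
            base = ARCHETYPES[_ARCHETYPE_ORDER[c - 1]]
            rows.append(2.0 ** (base + rng.normal(0.0, noise_sd, len(_T))))
    qt = QuantTable(sites, conditions, np.vstack(rows))
    return qt, ClusterAssignment(labels)


def random_multilayer(
    n_sites: int = 12,
    n_proteins: int = 20,
    n_functions: int = 8,
    n_clusters: int = 3,
    edge_density: float = 0.15,
    seed: int = 0,
):
    """A structureless random multilayer network with no planted signal.

    Intra-layer blocks are Erdős–Rényi at ``edge_density``; every site gets
    one random host protein; every function term annotates a random protein
    subset (at least one). Sites are split round-robin into ``n_clusters``
    seed clusters unrelated to any structure. The distribution is invariant
    under within-layer node relabeling, which makes these networks the
    exchangeable null for the permutation control.

    Returns (MultilayerNetwork, ClusterAssignment).
    """
    from .netbuild import MultilayerNetwork

    if min(n_sites, n_proteins, n_functions) < 1 or n_clusters < 1:
        raise BadConfig("all sizes must be >= 1")
    rng = np.random.default_rng(seed)

    def er(n: int) -> np.ndarray:
        a = (rng.random((n, n)) < edge_density).astype(float)
        a = np.triu(a, 1)
        return a + a.T

    sites = _make_sites(rng, [f"RP{i + 1}" for i in range(n_proteins)], n_sites)
    # unique (protein, position) guaranteed per protein by _make_sites only
    # within one call, which draws over all proteins here
    proteins = [f"RP{i + 1}" for i in range(n_proteins)]
    functions = [_term_id(900 + i) for i in range(n_functions)]
    a_rp = np.zeros((n_sites, n_proteins))
    prot_idx = {p: i for i, p in enumerate(proteins)}
    for i, s in enumerate(sites):
        a_rp[i, prot_idx[s.protein]] = 1.0
    a_pf = np.zeros((n_proteins, n_functions))
    for j in range(n_functions):
        size = max(1, int(rng.binomial(n_proteins, edge_density)))
        rows = rng.choice(n_proteins, size=size, replace=False)
        a_pf[rows, j] = 1.0
    net = MultilayerNetwork(
        sites, proteins, functions, er(n_sites), er(n_proteins), er(n_functions),
        a_rp, a_pf,
    )
    labels = {s: (i % n_clusters) + 1 for i, s in enumerate(sites)}
    return net, ClusterAssignment(labels)


def generate_toy_ontology(
    n_terms: int, max_depth: int = 4, seed: int = 0
) -> tuple[OntologyDAG, AnnotationLibrary]:
    """A random rooted acyclic ontology with per-term gene annotations.

    Term 1 is the root; every later term attaches to one or two existing
    terms of depth < ``max_depth`` via is_a (70%) or part_of (30%) edges, so
    every term reaches the root. Genes are drawn from a pool of 3×n_terms.
    """
    if n_terms < 2:
        raise BadConfig("n_terms must be >= 2")
    rng = np.random.default_rng(seed)
    ids = [_term_id(i + 1) for i in range(n_terms)]
    depth = {ids[0]: 0}
    edges: list[tuple[str, str, str]] = []
    for i in range(1, n_terms):
        eligible = [t for t in ids[:i] if depth[t] < max_depth]
        if not eligible:
            eligible = [ids[0]]
        n_parents = 1 if len(eligible) == 1 or rng.random() < 0.7 else 2
        parents = rng.choice(len(eligible), size=n_parents, replace=False)
        depth[ids[i]] = min(depth[eligible[p]] for p in parents) + 1
        for p in parents:
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((ids[i], eligible[p], rel))
    names = {t: f"toy term {i + 1}" for i, t in enumerate(ids)}
    dag = OntologyDAG(edges, terms=ids, names=names)
    pool = [f"G{i + 1}" for i in range(3 * n_terms)]
    terms = {
        t: frozenset(
            pool[g] for g in rng.choice(len(pool), size=int(rng.integers(1, 6)), replace=False)
        )
        for t in ids
    }
    lib = AnnotationLibrary(terms, names=names, universe=frozenset(pool))
    return dag, lib
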