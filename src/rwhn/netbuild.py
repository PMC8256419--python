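"""Construction of the three-layer (site / protein / function) network.

The full network is the symmetric block matrix

    | A_RR  A_RP  0    |
    | A_PR  A_PP  A_PF |
    | 0     A_FP  A_FF |

with binary entries throughout. The five blocks come from:

* ``A_RR`` — sites in the same regulation cluster whose quantitative
  profiles correlate at r² ≥ 0.99;
* ``A_PP`` — the STRING-derived interaction subgraph induced on the
  phosphorylated proteins plus their direct interactors;
* ``A_FF`` — function terms with pairwise similarity > 0.7 (Wang for GO,
  annotation-profile overlap for pathway collections);
* ``A_RP`` — each site linked to its single host protein;
* ``A_PF`` — terms enriched (hypergeometric + BH, q < 0.05) in Louvain
  modules of the protein layer, linked to the module proteins annotated to
  them; over-broad (>5% annotation frequency) and semantically redundant
  (Wang > 0.9) GO terms are removed first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyUniverse, MissingData, OrphanSite, UnknownTerm
from .io_formats import AnnotationLibrary, OntologyDAG, PPINetwork, QuantTable, SiteID
from .preprocess import ClusterAssignment
from .semsim import (
    DEFAULT_CONTRIBUTION,
    SemanticContribution,
    annotation_profile_similarity,
    term_frequency,
    wang_similarity,
)


@dataclass
class Adjacency:
    """A (possibly rectangular) binary adjacency block with ordered node IDs."""

    row_nodes: list
    col_nodes: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.row_nodes), len(self.col_nodes)):
            raise ValueError("matrix shape inconsistent with node lists")

    @property
    def n_edges(self) -> int:
        m = int(self.matrix.sum())
        return m // 2 if self.row_nodes == self.col_nodes else m

    def is_symmetric(self) -> bool:
        return self.matrix.shape[0] == self.matrix.shape[1] and np.array_equal(
            self.matrix, self.matrix.T
        )


@dataclass
class ModuleAssignment:
    """Louvain module index (0-based) for every protein-layer node."""

    modules: dict[str, int]

    def module_ids(self) -> list[int]:
        return sorted(set(self.modules.values()))

    def members(self, module: int) -> set[str]:
        return {p for p, m in self.modules.items() if m == module}


@dataclass
class EnrichmentRecord:
    module: int
    term: str
    overlap: int
    term_size: int
    p: float
    q: float


@dataclass
class MultilayerNetwork:
    """Three ordered node lists plus the five binary adjacency blocks."""

    sites: list[SiteID]
    proteins: list[str]
    functions: list[str]
    a_rr: np.ndarray
    a_pp: np.ndarray
    a_ff: np.ndarray
    a_rp: np.ndarray
    a_pf: np.ndarray
    term_names: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.sites) + len(self.proteins) + len(self.functions)

    def full_matrix(self) -> np.ndarray:
        """The symmetric block adjacency over [sites; proteins; functions]."""
        n_r, n_p, n_f = len(self.sites), len(self.proteins), len(self.functions)
        full = np.zeros((self.n_nodes, self.n_nodes))
        full[:n_r, :n_r] = self.a_rr
        full[n_r : n_r + n_p, n_r : n_r + n_p] = self.a_pp
        full[n_r + n_p :, n_r + n_p :] = self.a_ff
        full[:n_r, n_r : n_r + n_p] = self.a_rp
        full[n_r : n_r + n_p, :n_r] = self.a_rp.T
        full[n_r : n_r + n_p, n_r + n_p :] = self.a_pf
        full[n_r + n_p :, n_r : n_r + n_p] = self.a_pf.T
        return full

    def copy(self) -> "MultilayerNetwork":
        return MultilayerNetwork(
            list(self.sites),
            list(self.proteins),
            list(self.functions),
            self.a_rr.copy(),
            self.a_pp.copy(),
            self.a_ff.copy(),
            self.a_rp.copy(),
            self.a_pf.copy(),
            dict(self.term_names),
        )

    def summary(self) -> dict:
        """Per-block node/edge counts (for run manifests)."""
        return {
            "site_site": {"nodes": len(self.sites), "edges": int(self.a_rr.sum()) // 2},
            "protein_protein": {
                "nodes": len(self.proteins),
                "edges": int(self.a_pp.sum()) // 2,
            },
            "function_function": {
                "nodes": len(self.functions),
                "edges": int(self.a_ff.sum()) // 2,
            },
            "site_protein": {"edges": int(self.a_rp.sum())},
            "protein_function": {"edges": int(self.a_pf.sum())},
        }


# ---------------------------------------------------------------------------
# subnetworks
# ---------------------------------------------------------------------------


def build_site_subnetwork(
    qt: QuantTable,
    clusters: ClusterAssignment,
    threshold: float = 0.99,
    squared: bool = True,
) -> Adjacency:
    """Site–site edges between same-cluster sites with r² ≥ ``threshold``.

    With ``squared=False`` the threshold applies to the plain Pearson r.
    Constant (zero-variance) profiles correlate with nothing and are
    reported via a warning.
    """
    if qt.mask.any():
        raise MissingData("site subnetwork requires a complete matrix")
    n = qt.n_sites
    A = np.zeros((n, n))
    if n >= 2:
        sd = qt.values.std(axis=1)
        constant = np.flatnonzero(sd == 0)
        if len(constant):
            warnings.warn(
                f"{len(constant)} constant profile(s) have no site-layer edges",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(qt.values)
        labels = np.array([clusters.labels[s] for s in qt.sites])
        stat = corr ** 2 if squared else corr
        same = labels[:, None] == labels[None, :]
        ok = same & (stat >= threshold) & ~np.isnan(stat)
        np.fill_diagonal(ok, False)
        ok[constant, :] = False
        ok[:, constant] = False
        A[ok] = 1.0
    return Adjacency(list(qt.sites), list(qt.sites), A)


def build_protein_subnetwork(ppi: PPINetwork, data_proteins: set[str]) -> Adjacency:
    """Protein layer: data proteins plus their direct interactors.

    The node set is the phosphoproteome's proteins together with every
    first neighbor in the (already score-filtered) interaction network; all
    interaction edges with both endpoints inside the node set are kept, so
    modules among interactors stay intact. Data proteins without any
    interaction remain as isolated nodes.
    """
    nodes: set[str] = set(data_proteins)
    for p in data_proteins:
        nodes |= ppi.neighbors(p)
    order = sorted(nodes)
    idx = {p: i for i, p in enumerate(order)}
    A = np.zeros((len(order), len(order)))
    for a, b in ppi.graph.edges():
        if a in idx and b in idx:
            A[idx[a], idx[b]] = 1.0
            A[idx[b], idx[a]] = 1.0
    return Adjacency(order, order, A)


def detect_modules(
    app: Adjacency, resolution: float = 1.0, seed: int = 0
) -> ModuleAssignment:
    """Louvain modules of the protein subnetwork (deterministic given seed).

    Modules are renumbered by their lexicographically smallest member so the
    numbering does not depend on the partition's internal order.
    """
    if not app.is_symmetric():
        raise ValueError("protein adjacency must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(app.row_nodes)
    rows, cols = np.nonzero(app.matrix)
    g.add_edges_from(
        (app.row_nodes[i], app.col_nodes[j]) for i, j in zip(rows, cols) if i < j
    )
    communities = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    modules = {p: m for m, members in enumerate(communities) for p in members}
    return ModuleAssignment(modules)


def hypergeometric_enrichment(
    query: set[str],
    lib: AnnotationLibrary,
    universe: set[str],
    alpha: float = 0.05,
) -> list[tuple[str, int, int, float, float]]:
    """Upper-tail hypergeometric enrichment of library terms in ``query``.

    Returns (term, overlap, term_size, p, q) for terms with q < ``alpha``,
    sorted by p then term ID. Shared by module enrichment and the ORA
    baseline. Terms with zero overlap are skipped (p would be 1).
    """
    if not universe:
        raise EmptyUniverse("empty gene universe")
    universe = set(universe)
    n_query = len(query & universe)
    rows: list[tuple[str, int, int, float]] = []
    for term in sorted(lib.terms):
        genes = lib.genes_of(term) & universe
        k = len(genes & query)
        if k == 0 or not genes:
            continue
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(genes), n_query))
        rows.append((term, k, len(genes), p))
    if not rows:
        return []
    _, qvals, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    out = [
        (term, k, K, p, float(q))
        for (term, k, K, p), q in zip(rows, qvals)
        if q < alpha
    ]
    out.sort(key=lambda r: (r[3], r[0]))
    return out


def enrich_modules(
    modules: ModuleAssignment,
    lib: AnnotationLibrary,
    universe: set[str],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentRecord], dict[str, set[str]]]:
    """Per-module hypergeometric enrichment with BH correction within module.

    Returns the retained records (q < ``alpha``) and a map term → proteins
    carrying a protein–function edge: a module's retained term connects to
    the module proteins annotated to it (unioned over modules when a term
    is enriched in several).
    """
    records: list[EnrichmentRecord] = []
    pf_edges: dict[str, set[str]] = {}
    for module in modules.module_ids():
        members = modules.members(module)
        for term, k, K, p, q in hypergeometric_enrichment(members, lib, universe, alpha):
            records.append(EnrichmentRecord(module, term, k, K, p, q))
            annotated = lib.genes_of(term) & members
            pf_edges.setdefault(term, set()).update(annotated)
    return records, pf_edges


def filter_function_terms(
    terms: set[str],
    dag: OntologyDAG,
    lib: AnnotationLibrary,
    universe: set[str],
    freq_cutoff: float = 0.05,
    redundancy_cutoff: float = 0.9,
    w: SemanticContribution = DEFAULT_CONTRIBUTION,
) -> set[str]:
    """Drop over-broad and semantically redundant GO terms.

    A term annotated (after child→ancestor propagation) to more than
    ``freq_cutoff`` of universe genes is removed; then, for every pair with
    Wang similarity > ``redundancy_cutoff``, the higher-frequency (less
    specific) term is removed, ties broken toward the lexicographically
    smaller ID.
    """
    for t in terms:
        if t not in dag:
            raise UnknownTerm(f"term {t!r} not in ontology")
    freq = {t: term_frequency(lib, dag, t, frozenset(universe)) for t in terms}
    survivors = {t for t in terms if freq[t] <= freq_cutoff}
    ordered = sorted(survivors)
    removed: set[str] = set()
    for i, t1 in enumerate(ordered):
        if t1 in removed:
            continue
        for t2 in ordered[i + 1 :]:
            if t2 in removed:
                continue
            if wang_similarity(dag, t1, t2, w) > redundancy_cutoff:
                # keep the rarer (more specific) term
                drop = t2 if freq[t2] > freq[t1] else t1 if freq[t1] > freq[t2] else t2
                removed.add(drop)
                if drop == t1:
                    break
    return survivors - removed


def build_function_subnetwork(
    terms: set[str],
    mode: str,
    dag_or_lib,
    threshold: float = 0.7,
    metric: str = "overlap",
    w: SemanticContribution = DEFAULT_CONTRIBUTION,
) -> Adjacency:
    """Function–function edges between terms with similarity strictly > threshold.

    GO mode uses Wang similarity on the ontology; KEGG mode uses
    annotation-profile similarity on the library. The diagonal is excluded.
    """
    order = sorted(terms)
    n = len(order)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "go":
                sim = wang_similarity(dag_or_lib, order[i], order[j], w)
            elif mode == "kegg":
                sim = annotation_profile_similarity(dag_or_lib, order[i], order[j], metric)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if sim > threshold:
                A[i, j] = A[j, i] = 1.0
    return Adjacency(order, order, A)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_multilayer(
    qt: QuantTable,
    clusters: ClusterAssignment,
    ppi: PPINetwork,
    lib: AnnotationLibrary,
    dag: OntologyDAG | None = None,
    *,
    mode: str = "go",
    corr_threshold: float = 0.99,
    corr_squared: bool = True,
    funsim_threshold: float = 0.7,
    freq_cutoff: float = 0.05,
    redundancy_cutoff: float = 0.9,
    alpha: float = 0.05,
    resolution: float = 1.0,
    kegg_metric: str = "overlap",
    seed: int = 0,
) -> MultilayerNetwork:
    """Build all five blocks and assemble the multilayer network.

    The function layer is the union over protein modules of enriched terms
    (q < ``alpha``), GO-filtered for frequency and redundancy when a DAG is
    supplied in go mode. Every site gets exactly one site–protein edge (to
    its host protein); :class:`OrphanSite` is raised if a host protein is
    somehow absent from the protein layer.
    """
    if mode == "go" and dag is None:
        raise ValueError("go mode requires an ontology DAG")
    a_rr = build_site_subnetwork(qt, clusters, corr_threshold, corr_squared)
    data_proteins = qt.proteins()
    a_pp = build_protein_subnetwork(ppi, data_proteins)
    modules = detect_modules(a_pp, resolution, seed)
    universe = set(lib.effective_universe()) | set(a_pp.row_nodes)
    records, pf_edges = enrich_modules(modules, lib, universe, alpha)
    terms = set(pf_edges)
    if mode == "go" and terms:
        terms = filter_function_terms(
            terms, dag, lib, universe, freq_cutoff, redundancy_cutoff
        )
    a_ff = build_function_subnetwork(
        terms, mode, dag if mode == "go" else lib, funsim_threshold, kegg_metric
    )
    functions = a_ff.row_nodes

    prot_idx = {p: i for i, p in enumerate(a_pp.row_nodes)}
    a_rp = np.zeros((qt.n_sites, len(prot_idx)))
    for i, site in enumerate(qt.sites):
        if site.protein not in prot_idx:
            raise OrphanSite(f"host protein of {site} missing from protein layer")
        a_rp[i, prot_idx[site.protein]] = 1.0

    fun_idx = {t: j for j, t in enumerate(functions)}
    a_pf = np.zeros((len(prot_idx), len(functions)))
    for term, prots in pf_edges.items():
        if term not in fun_idx:
            continue
        for p in prots:
            a_pf[prot_idx[p], fun_idx[term]] = 1.0

    names = {t: lib.name_of(t) for t in functions}
    if dag is not None:
        names.update({t: dag.name_of(t) for t in functions if t in dag})
    return MultilayerNetwork(
        list(qt.sites),
        list(a_pp.row_nodes),
        list(functions),
        a_rr.matrix,
        a_pp.matrix,
        a_ff.matrix,
        a_rp,
        a_pf,
        names,
    )
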