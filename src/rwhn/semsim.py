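"""Term–term similarity machinery for the function layer.

Two similarity notions are used to wire the function–function subnetwork:

* **Wang semantic similarity** for GO terms — each term's *semantic value*
  aggregates weighted contributions of its ancestors, where a contribution
  decays along each is_a (factor 0.8) or part_of (factor 0.6) edge and the
  best path wins; similarity is the shared contribution mass over the total.
* **Annotation-profile similarity** for pathway collections — the overlap
  coefficient (default) or Jaccard index of two terms' member gene sets.

The module also computes propagated annotation frequencies (a gene annotated
to a term counts toward every ancestor), used to filter over-broad terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import UnknownTerm
from .io_formats import AnnotationLibrary, OntologyDAG


@dataclass(frozen=True)
class SemanticContribution:
    """Per-relation decay factors for Wang S-values, each strictly in (0,1)."""

    weights: dict = field(
        default_factory=lambda: {"is_a": 0.8, "part_of": 0.6}
    )

    def __post_init__(self):
        for rel, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"factor for {rel!r} must be in (0,1), got {w}")

    def factor(self, relation: str) -> float:
        return self.weights[relation]


DEFAULT_CONTRIBUTION = SemanticContribution()


def s_values(
    dag: OntologyDAG, term: str, w: SemanticContribution = DEFAULT_CONTRIBUTION
) -> dict[str, float]:
    """Wang S-values of ``term``: its own contribution (1.0) plus the maximal
    decayed contribution of every ancestor.

    S(term) = 1; S(parent) = max over children c in the ancestor closure of
    factor(relation) * S(c). Computed by dynamic programming in topological
    order over the ancestor sub-DAG (edges run child → parent, so children
    settle before parents).
    """
    if term not in dag:
        raise UnknownTerm(f"term {term!r} not in ontology")
    closure = dag.ancestors(term) | {term}
    sub = dag.graph.subgraph(closure)
    s: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node not in s:
            continue
        for _, parent, data in sub.out_edges(node, data=True):
            cand = w.factor(data["relation"]) * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return s


def wang_similarity(
    dag: OntologyDAG,
    t1: str,
    t2: str,
    w: SemanticContribution = DEFAULT_CONTRIBUTION,
) -> float:
    """Wang semantic similarity of two ontology terms, in [0, 1].

    sim = Σ_{t ∈ T1 ∩ T2} (S1(t) + S2(t)) / (SV(t1) + SV(t2)), where T_i is
    the ancestor closure of t_i and SV the sum of its S-values. Terms with
    disjoint ancestries (different roots) score 0; sim(t, t) = 1.
    """
    s1 = s_values(dag, t1, w)
    s2 = s_values(dag, t2, w)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    shared = sum(s1[t] + s2[t] for t in common)
    total = sum(s1.values()) + sum(s2.values())
    return shared / total


def annotation_profile_similarity(
    lib: AnnotationLibrary, t1: str, t2: str, metric: str = "overlap"
) -> float:
    """Similarity of two terms' annotation gene sets.

    ``overlap`` = |A∩B| / min(|A|,|B|) (default), ``jaccard`` = |A∩B| / |A∪B|.
    """
    for t in (t1, t2):
        if t not in lib.terms:
            raise UnknownTerm(f"term {t!r} not in annotation library")
    a, b = lib.genes_of(t1), lib.genes_of(t2)
    inter = len(a & b)
    if inter == 0:
        return 0.0
    if metric == "overlap":
        return inter / min(len(a), len(b))
    if metric == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown metric {metric!r}")


def propagated_annotations(
    lib: AnnotationLibrary, dag: OntologyDAG
) -> dict[str, frozenset[str]]:
    """Annotation sets propagated child → ancestor over the ontology.

    A gene annotated to a term is counted for the term and all its ancestors
    (the true-path rule). Terms absent from the library but present in the
    DAG receive the union of their descendants' genes.
    """
    out: dict[str, set[str]] = {t: set() for t in dag.terms}
    for term, genes in lib.terms.items():
        if term not in dag:
            continue
        out[term] |= genes
        for anc in dag.ancestors(term):
            out[anc] |= genes
    return {t: frozenset(g) for t, g in out.items()}


def term_frequency(
    lib: AnnotationLibrary,
    dag: OntologyDAG,
    term: str,
    universe: frozenset[str] | set[str],
) -> float:
    """Fraction of universe genes annotated to ``term`` or any descendant."""
    if term not in dag:
        raise UnknownTerm(f"term {term!r} not in ontology")
    genes: set[str] = set(lib.terms.get(term, frozenset()))
    for child in dag.descendants(term):
        genes |= lib.terms.get(child, frozenset())
    if not universe:
        return 0.0
    return len(genes & set(universe)) / len(universe)
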