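"""Readers and writers for the external formats the tool touches.

All downstream modules consume only the domain types defined here:

* :class:`SiteID` / :class:`QuantTable` — phosphosite quantification,
* :class:`PPINetwork` — a score-filtered protein interaction network,
* :class:`AnnotationLibrary` — GMT term → gene-set collections,
* :class:`OntologyDAG` — the GO DAG restricted to is_a / part_of.

Conventions: positions are 1-based, residue letters are upper-cased on read,
missing quant cells are encoded as empty string / ``NA`` / ``NaN``
(case-insensitive) and carried as ``numpy.nan`` behind an explicit mask.
Gene/protein identifier namespaces are the caller's responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .errors import (
    CycleDetected,
    DuplicateSite,
    EmptyTerm,
    ParseError,
)

_RESIDUES = frozenset("STY")
_NA_STRINGS = frozenset({"", "na", "nan"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SiteID:
    """A phosphorylation site: a serine/threonine/tyrosine on a protein.

    Ordering is lexicographic on (protein, position, residue), which gives
    deterministic node orderings throughout the package.
    """

    protein: str
    position: int
    residue: str

    def __post_init__(self):
        if self.residue not in _RESIDUES:
            raise ParseError(
                f"residue must be one of S/T/Y, got {self.residue!r}"
            )
        if self.position < 1:
            raise ParseError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:  # e.g. EGFR_Y1197
        return f"{self.protein}_{self.residue}{self.position}"

    @classmethod
    def parse(cls, label: str) -> "SiteID":
        """Inverse of ``str(site)``: ``PROT_Y123`` → SiteID."""
        try:
            prot, tail = label.rsplit("_", 1)
            return cls(prot, int(tail[1:]), tail[0].upper())
        except (ValueError, IndexError) as exc:
            raise ParseError(f"cannot parse site label {label!r}") from exc


@dataclass
class QuantTable:
    """Phosphosite × condition matrix of (SILAC-style) ratios.

    ``values`` holds floats with ``nan`` where the measurement is missing;
    ``mask`` (derived) is True at missing cells. Row order is meaningful and
    preserved by every operation.
    """

    sites: list[SiteID]
    conditions: list[str]
    values: np.ndarray  # shape (n_sites, n_conditions), float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.conditions)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.sites)}, {len(self.conditions)})"
            )
        keys = {(s.protein, s.position) for s in self.sites}
        if len(keys) != len(self.sites):
            raise DuplicateSite("duplicate (accession, position) in table")

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "QuantTable":
        return QuantTable(list(self.sites), list(self.conditions), self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[str(s) for s in self.sites], columns=self.conditions
        )

    def proteins(self) -> set[str]:
        return {s.protein for s in self.sites}


@dataclass
class PPINetwork:
    """Undirected protein–protein interaction network with [0,1] edge scores."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            return  # self-loops never stored
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0,1]")
        prev = self.graph.edges.get((a, b), {}).get("score", -1.0)
        if score > prev:
            self.graph.add_edge(a, b, score=score)

    def score(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["score"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, protein: str) -> set[str]:
        if protein not in self.graph:
            return set()
        return set(self.graph.neighbors(protein))


@dataclass
class AnnotationLibrary:
    """Term → gene-set collection (a GMT file in memory).

    ``names`` maps term IDs to human-readable descriptions; ``universe`` is the
    optional background gene set used for enrichment (defaults to the union of
    all annotated genes when not provided).
    """

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self):
        for t, genes in self.terms.items():
            if not genes:
                raise EmptyTerm(f"term {t!r} has an empty gene set")

    def genes_of(self, term: str) -> frozenset[str]:
        return self.terms[term]

    def name_of(self, term: str) -> str:
        return self.names.get(term, term)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def effective_universe(self) -> frozenset[str]:
        return self.universe if self.universe is not None else self.all_genes()


class OntologyDAG:
    """An ontology restricted to is_a / part_of, stored child → parent.

    The graph is a :class:`networkx.MultiDiGraph` whose edges run from child
    to parent with a ``relation`` key in ``{"is_a", "part_of"}``. Construction
    verifies acyclicity.
    """

    RELATIONS = ("is_a", "part_of")

    def __init__(
        self,
        edges: Iterable[tuple[str, str, str]],
        terms: Iterable[str] = (),
        names: Mapping[str, str] | None = None,
    ):
        g = nx.MultiDiGraph()
        g.add_nodes_from(terms)
        for child, parent, rel in edges:
            if rel not in self.RELATIONS:
                continue
            g.add_edge(child, parent, relation=rel)
        if not nx.is_directed_acyclic_graph(g):
            raise CycleDetected("ontology relations form a cycle")
        self.graph = g
        self.names = dict(names or {})

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs of ``term``."""
        return [
            (p, d["relation"]) for _, p, d in self.graph.out_edges(term, data=True)
        ]

    def children(self, term: str) -> set[str]:
        return {c for c, _ in self.graph.in_edges(term)}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All terms below ``term`` (excluding itself)."""
        return nx.ancestors(self.graph, term)

    def name_of(self, term: str) -> str:
        return self.names.get(term, term)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _is_missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return isinstance(cell, str) and cell.strip().lower() in _NA_STRINGS


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_quant_table(
    path: str | Path,
    id_columns: Sequence[str] = ("protein", "residue", "position"),
    condition_columns: Sequence[str] | None = None,
) -> QuantTable:
    """Read a delimited phosphosite quantification table.

    ``id_columns`` names the accession, residue and position columns, in that
    order. ``condition_columns`` defaults to every remaining column. Missing
    ratios may be empty, ``NA`` or ``NaN`` (case-insensitive).

    Raises :class:`DuplicateSite` on repeated (accession, position) and
    :class:`ParseError` on malformed residue/position/ratio fields.
    """
    path = Path(path)
    if len(id_columns) != 3:
        raise ParseError("id_columns must name (accession, residue, position)")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in id_columns:
        if col not in df.columns:
            raise ParseError(f"missing id column {col!r} in {path.name}")
    acc_col, res_col, pos_col = id_columns
    if condition_columns is None:
        condition_columns = [c for c in df.columns if c not in id_columns]
    else:
        for col in condition_columns:
            if col not in df.columns:
                raise ParseError(f"missing condition column {col!r}")
    if not condition_columns:
        raise ParseError("no condition columns")

    sites: list[SiteID] = []
    seen: set[tuple[str, int]] = set()
    values = np.empty((len(df), len(condition_columns)))
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            pos = int(rec[pos_col])
        except ValueError as exc:
            raise ParseError(
                f"bad position {rec[pos_col]!r} at row {i + 1}"
            ) from exc
        site = SiteID(rec[acc_col].strip(), pos, rec[res_col].strip().upper())
        key = (site.protein, site.position)
        if key in seen:
            raise DuplicateSite(f"duplicate site {site} at row {i + 1}")
        seen.add(key)
        sites.append(site)
        for j, col in enumerate(condition_columns):
            cell = rec[col]
            if _is_missing(cell):
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"bad ratio {cell!r} in column {col!r}, row {i + 1}"
                    ) from exc
    return QuantTable(sites, list(condition_columns), values)


def write_quant_table(qt: QuantTable, path: str | Path) -> None:
    """Serialize a quant table; inverse of :func:`read_quant_table`."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["protein", "residue", "position", *qt.conditions]) + "\n")
        for site, row in zip(qt.sites, qt.values):
            cells = ["" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(
                sep.join([site.protein, site.residue, str(site.position), *cells])
                + "\n"
            )


def read_ppi_edges(
    path: str | Path,
    channel: str = "experimental",
    threshold: float = 0.4,
) -> PPINetwork:
    """Read a STRING-dialect protein-links flat file.

    Scores are integers on a 0–1000 scale; the named ``channel`` column is
    divided by 1000 and edges are kept only when the scaled score is
    *strictly greater* than ``threshold``. Self-loops are dropped and
    duplicate pairs merged keeping the maximum score. A headerless
    three-column file is accepted (third column = score).
    """
    path = Path(path)
    net = PPINetwork()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return net
    first = lines[0].replace(",", " ").split()
    score_idx = 2
    start = 0
    header_like = len(first) >= 3 and not first[2].lstrip("+-").isdigit()
    if header_like:
        start = 1
        if channel in first:
            score_idx = first.index(channel)
        elif "score" in first:
            score_idx = first.index("score")
        elif len(first) == 3:
            score_idx = 2
        else:
            raise ParseError(
                f"channel {channel!r} not found in header of {path.name}"
            )
    for ln in lines[start:]:
        fields = ln.replace(",", " ").split()
        if len(fields) <= score_idx:
            raise ParseError(f"short line in {path.name}: {ln!r}")
        a, b, raw = fields[0], fields[1], fields[score_idx]
        try:
            score = int(raw) / 1000.0
        except ValueError as exc:
            raise ParseError(f"non-numeric score {raw!r} in {path.name}") from exc
        if a == b:
            continue
        if score > threshold:
            net.add_edge(a, b, score)
    return net


def write_ppi_edges(net: PPINetwork, path: str | Path, channel: str = "experimental") -> None:
    """Write a STRING-dialect flat file (scores re-scaled to 0–1000)."""
    with open(path, "w") as fh:
        fh.write(f"protein1 protein2 {channel}\n")
        for a, b, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{a} {b} {int(round(data['score'] * 1000))}\n")


def read_gmt(path: str | Path) -> AnnotationLibrary:
    """Read a GMT annotation library (term, description, genes...)."""
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 2:
                raise ParseError(f"GMT line {i + 1} has fewer than 2 fields")
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g.strip())
            if not genes:
                raise EmptyTerm(f"term {term!r} (line {i + 1}) lists no genes")
            terms[term] = genes
            names[term] = desc
    return AnnotationLibrary(terms, names)


def write_gmt(lib: AnnotationLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(lib.terms):
            genes = sorted(lib.terms[term])
            fh.write("\t".join([term, lib.name_of(term), *genes]) + "\n")


def read_obo(path: str | Path) -> OntologyDAG:
    """Read an OBO 1.2 ontology, keeping is_a/part_of and dropping obsoletes.

    Raises :class:`CycleDetected` if the retained relations form a cycle.
    """
    g = obonet.read_obo(path, ignore_obsolete=True)
    edges: list[tuple[str, str, str]] = []
    names: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        if "name" in data:
            names[node] = data["name"]
    # obonet stores edges child -> parent keyed by relation type
    for child, parent, rel in g.edges(keys=True):
        if rel in OntologyDAG.RELATIONS:
            edges.append((child, parent, rel))
    return OntologyDAG(edges, terms=g.nodes, names=names)


def write_obo(dag: OntologyDAG, path: str | Path, ontology_name: str = "toy") -> None:
    """Write an OBO 1.2 file; inverse of :func:`read_obo` for our DAGs."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n")
        for term in sorted(dag.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.name_of(term)}\n")
            for parent, rel in sorted(dag.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


# ---------------------------------------------------------------------------
# rankings output
# ---------------------------------------------------------------------------

RANKING_COLUMNS = (
    "seed_cluster",
    "term_id",
    "term_name",
    "steady_state_probability",
    "rank",
    "retained_flag",
)


def write_rankings(result, path: str | Path, term_names: Mapping[str, str] | None = None) -> None:
    """Write a RankedResult as TSV.

    One row per (seed cluster, function term), grouped by cluster in input
    order; probabilities serialized at full precision (``repr``). Clusters
    whose retained set is empty still emit all their rows with
    ``retained_flag`` false.
    """
    term_names = term_names or {}
    with open(path, "w") as fh:
        fh.write("\t".join(RANKING_COLUMNS) + "\n")
        for cluster in result.clusters:
            retained = set(result.retained[cluster])
            for term, prob, rank in result.rankings[cluster]:
                fh.write(
                    "\t".join(
                        [
                            str(cluster),
                            term,
                            term_names.get(term, term),
                            repr(float(prob)),
                            str(rank),
                            str(term in retained),
                        ]
                    )
                    + "\n"
                )


def read_rankings(path: str | Path):
    """Round-trip reader for :func:`write_rankings` output."""
    from .core import RankedResult  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"seed_cluster": str})
    clusters: list = []
    rankings: dict = {}
    retained: dict = {}
    for cl, grp in df.groupby("seed_cluster", sort=False):
        key: object = int(cl) if str(cl).isdigit() else cl
        clusters.append(key)
        rankings[key] = [
            (r.term_id, float(r.steady_state_probability), int(r.rank))
            for r in grp.itertuples(index=False)
        ]
        retained[key] = [
            r.term_id
            for r in grp.itertuples(index=False)
            if str(r.retained_flag) == "True"
        ]
    return RankedResult(clusters=clusters, rankings=rankings, retained=retained)
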