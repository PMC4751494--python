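"""Hypergeometric gene-set enrichment and ontology-tree induction.

For a query gene list (e.g. the up-regulated genes of a contrast) and a
gene-set collection (GO terms, KEGG pathways in GMT form), each term is
scored by the right tail of the hypergeometric distribution -- the
probability of drawing at least the observed overlap k when n query
genes are sampled from a universe of N genes of which K belong to the
term -- followed by Benjamini-Hochberg correction across all tested
terms. Enriched terms plus all their ontology ancestors are then
assembled into a directed tree/DAG whose nodes are labelled by the
direction of the gene list they came from (up / down / ambiguous when
enriched in both / ancestor-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import GeneSetCollection, OntologyEdges

__all__ = [
    "EnrichmentRecord",
    "GoTree",
    "hypergeom_right_tail",
    "enrich",
    "build_go_tree",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    description: str
    k: int  # query genes in the set
    K: int  # set size within the universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    fdr: float

    @property
    def fold_enrichment(self) -> float:
        return (self.k / self.n) / (self.K / self.N)

    @property
    def genes_ratio(self) -> str:
        return f"{self.k}/{self.K}"


def hypergeom_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n) (right-sided test)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible parameters K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"infeasible overlap k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
    min_set_size: int = 2,
) -> list[EnrichmentRecord]:
    """Right-sided hypergeometric enrichment of ``query`` against every
    set of ``collection`` within ``universe``.

    Gene sets are intersected with the universe first; the query must be
    a subset of the universe. Sets with fewer than ``min_set_size``
    universe genes are skipped (single-gene hits are degenerate).
    Records are BH-adjusted jointly and returned sorted by p-value
    (ties by term id); ``fdr < alpha`` is the conventional significance
    call, left to the caller.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene set")
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(query)
    rows: list[tuple[str, str, int, int]] = []
    for term in collection.terms():
        genes = collection.genes_of(term) & universe
        K = len(genes)
        if K < min_set_size:
            continue
        k = len(genes & query)
        rows.append((term, collection.description_of(term), k, K))
    if not rows:
        return []
    pvals = [hypergeom_right_tail(k, K, n, N) for _, _, k, K in rows]
    fdrs = bh_adjust(pvals)
    records = [
        EnrichmentRecord(term, desc, k, K, n, N, float(p), float(q))
        for (term, desc, k, K), p, q in zip(rows, pvals, fdrs)
    ]
    records.sort(key=lambda r: (r.p_value, r.term))
    return records


ANCESTOR_ONLY = "ancestor-only"
AMBIGUOUS = "ambiguous"


@dataclass
class GoTree:
    """Ontology subgraph induced by enriched terms and their ancestors.

    ``graph`` has child -> parent edges; every node carries a ``label``
    attribute in {up, down, ambiguous, ancestor-only}.
    """

    graph: nx.DiGraph

    @property
    def labels(self) -> dict[str, str]:
        return {n: d["label"] for n, d in self.graph.nodes(data=True)}

    def nodes_with_label(self, label: str) -> set[str]:
        return {n for n, l in self.labels.items() if l == label}

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_dot(self) -> str:
        colors = {"up": "red", "down": "blue", AMBIGUOUS: "purple",
                  ANCESTOR_ONLY: "gray"}
        lines = ["digraph go_tree {"]
        for node, label in sorted(self.labels.items()):
            lines.append(
                f'  "{node}" [label="{node}", color={colors[label]}];'
            )
        for child, parent in sorted(self.graph.edges()):
            lines.append(f'  "{child}" -> "{parent}";')
        lines.append("}")
        return "\n".join(lines)


def build_go_tree(
    enriched_up: Iterable[str],
    enriched_down: Iterable[str],
    ontology: OntologyEdges,
) -> GoTree:
    """Induce the labelled ancestor-closed ontology subgraph.

    A term enriched only in the up analysis is labelled 'up', only in
    the down analysis 'down', in both 'ambiguous'; ancestors pulled in
    for connectivity are 'ancestor-only'.
    """
    up = set(enriched_up)
    down = set(enriched_down)
    known = ontology.terms()
    missing = (up | down) - known
    if missing:
        raise KeyError(
            f"terms absent from the ontology: {sorted(missing)[:5]}"
        )
    nodes = set(up | down)
    for term in up | down:
        nodes |= ontology.ancestors(term)
    full = ontology.to_graph()
    sub = nx.DiGraph(full.subgraph(nodes).copy())
    for node in sub.nodes:
        if node in up and node in down:
            label = AMBIGUOUS
        elif node in up:
            label = "up"
        elif node in down:
            label = "down"
        else:
            label = ANCESTOR_ONLY
        sub.nodes[node]["label"] = label
    return GoTree(sub)
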