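"""Readers and writers for the external formats the pipeline touches.

Formats: count-matrix TSV (+ sample metadata TSV), FASTA, GMT gene-set
collections, ontology parent-edge TSV, GraphML/SIF network export, and
the differential-expression result table. All readers validate and raise
:class:`~mirnet.matrix.FormatError` with the offending record named.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .matrix import CountMatrix, FormatError

__all__ = [
    "SequenceRecord",
    "GeneSetCollection",
    "OntologyEdges",
    "read_count_table",
    "write_count_table",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_ontology",
    "write_ontology",
    "write_network",
    "write_de_table",
    "read_de_table",
]

_VALID_BASES = set("ACGUTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA/DNA sequence; 'T' is mapped to 'U' at parse time so
    seed matching downstream is alphabet-agnostic."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r} has non-nucleotide characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneSetCollection:
    """term id -> (description, frozenset of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {term!r} is empty")

    def terms(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def description_of(self, term: str) -> str:
        return self.sets[term][0]


@dataclass
class OntologyEdges:
    """child term -> set of parent terms; acyclic with a single root."""

    edges: dict[str, set[str]]

    def __post_init__(self) -> None:
        g = self.to_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"ontology contains a cycle: {cycle}")

    def to_graph(self) -> nx.DiGraph:
        """Directed graph with child -> parent edges."""
        g = nx.DiGraph()
        for child, parents in self.edges.items():
            g.add_node(child)
            for p in parents:
                g.add_edge(child, p)
        return g

    def roots(self) -> list[str]:
        g = self.to_graph()
        return sorted(n for n in g.nodes if g.out_degree(n) == 0)

    def terms(self) -> set[str]:
        out = set(self.edges)
        for parents in self.edges.values():
            out |= parents
        return out

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following child -> parent edges."""
        g = self.to_graph()
        if term not in g:
            raise KeyError(f"term {term!r} not in ontology")
        return nx.descendants(g, term)


# ---------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------

def read_count_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> CountMatrix:
    """Read a tab-separated feature x sample count table.

    First column holds feature ids; the header row holds sample ids;
    lines starting with '#' are ignored. ``metadata_path`` points to a
    two-column sample<TAB>group TSV and must cover every sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        raise FormatError(f"{path}: non-numeric entries in count table")
    groups = None
    if metadata_path is not None:
        meta = pd.read_csv(
            metadata_path, sep="\t", header=None, names=["sample", "group"],
            comment="#", dtype=str,
        )
        if meta["sample"].duplicated().any():
            dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
            raise FormatError(f"{metadata_path}: duplicate sample {dup!r}")
        groups = dict(zip(meta["sample"], meta["group"]))
        missing = [s for s in df.columns if s not in groups]
        if missing:
            raise FormatError(
                f"{path}: samples absent from metadata: {missing}"
            )
    return CountMatrix(df, groups=groups)


def write_count_table(
    matrix: CountMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature")
    if metadata_path is not None:
        if matrix.groups is None:
            raise ValueError("matrix has no group metadata to write")
        with open(metadata_path, "w") as fh:
            for s in matrix.samples:
                fh.write(f"{s}\t{matrix.groups[s]}\n")


# ---------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; DNA 'T' is unified to RNA 'U'."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper().replace("T", "U"))
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------
# GMT and ontology
# ---------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description "
                    f"and >=1 gene ({len(fields)} fields)"
                )
            term, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, frozenset(genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_ontology(path: str | Path) -> OntologyEdges:
    """Read child<TAB>parent edge list."""
    edges: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected child<TAB>parent, got {line!r}"
                )
            child, parent = fields
            edges.setdefault(child, set()).add(parent)
    return OntologyEdges(edges)


def write_ontology(ontology: OntologyEdges, path: str | Path) -> None:
    with open(path, "w") as fh:
        for child in sorted(ontology.edges):
            for parent in sorted(ontology.edges[child]):
                fh.write(f"{child}\t{parent}\n")


# ---------------------------------------------------------------------
# network and DE-table export
# ---------------------------------------------------------------------

def write_network(network, path: str | Path, format: str = "graphml") -> None:
    """Export a regulatory network as GraphML or SIF.

    GraphML nodes carry ``kind`` (miRNA | gene); edges carry
    ``site_type``, ``mirna_direction`` and ``gene_direction``.
    SIF lines read ``mirna<TAB>targets<TAB>gene``.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    if format == "graphml":
        nx.write_graphml(graph, str(path))
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in graph.edges():
                fh.write(f"{u}\ttargets\t{v}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


_DE_COLUMNS = ["feature", "fold_change", "log2fc", "p_value", "fdr", "status"]


def write_de_table(records, path: str | Path) -> None:
    """Write DE records as TSV; fold changes printed to 2 decimals, as
    in published DE miRNA tables."""
    with open(path, "w") as fh:
        fh.write("\t".join(_DE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.feature}\t{r.fold_change:.2f}\t{r.log2fc:.4f}\t"
                f"{r.p_value:.6g}\t{r.fdr:.6g}\t{r.status}\n"
            )


def read_de_table(path: str | Path):
    """Read a DE-result TSV back into records (inverse of write_de_table)."""
    from .de import DERecord  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    missing = set(_DE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: DE table missing columns {sorted(missing)}")
    return [
        DERecord(
            feature=str(row.feature),
            fold_change=float(row.fold_change),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            fdr=float(row.fdr),
            status=str(row.status),
        )
        for row in df.itertuples()
    ]
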