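"""Seed-match target prediction and the inverse-correlation
miRNA -> mRNA regulatory network.

Canonical miRNA target sites are matches in a 3'UTR to the reverse
complement of the miRNA seed (nucleotides 2-8 of the mature sequence,
5'->3'):

* 8mer      -- reverse complement of the full 7-nt seed followed by 'A'
* 7mer-m8   -- reverse complement of the full 7-nt seed alone
* 7mer-A1   -- reverse complement of seed nucleotides 2-7 followed by 'A'

Predicted pairs are integrated with expression results: a pair enters
the network only when the miRNA and gene change in opposite directions
(a repressor signature) and the miRNA is not low-abundance (normalized
counts below a floor in both groups). The network itself is a strictly
bipartite directed graph from a small core of the most strongly
regulated miRNAs to their admissible targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .de import DERecord, DOWN, UP
from .io import SequenceRecord

__all__ = [
    "SITE_TYPES",
    "SeedSite",
    "TargetPair",
    "RegulatoryNetwork",
    "seed_of",
    "reverse_complement",
    "find_seed_sites",
    "predict_targets",
    "integrate_pairs",
    "select_core_mirnas",
    "build_network",
]

# strongest first
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}
_SITE_SPAN = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7}

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement on the RNA alphabet ('T' accepted as 'U')."""
    return seq.upper().replace("T", "U").translate(_RNA_COMPLEMENT)[::-1]


def seed_of(mirna_sequence: str) -> str:
    """Seed = nucleotides 2-8 (1-based, inclusive) of the mature miRNA."""
    seq = mirna_sequence.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(
            f"mature miRNA must be >=8 nt to have a seed (got {len(seq)})"
        )
    return seq[1:8]


@dataclass(frozen=True)
class SeedSite:
    """One canonical site occurrence; coordinates are 0-based half-open
    on the provided (sense-strand) UTR sequence."""

    mirna: str
    gene: str
    utr_start: int
    utr_end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.utr_end - self.utr_start != _SITE_SPAN[self.site_type]:
            raise ValueError(
                f"{self.site_type} site must span "
                f"{_SITE_SPAN[self.site_type]} nt"
            )


def find_seed_sites(
    mirna: SequenceRecord, utr: SequenceRecord
) -> list[SeedSite]:
    """All canonical seed sites of ``mirna`` in ``utr``.

    Matches are classified at their strongest type: an m8 match
    (reverse complement of the full seed) followed by 'A' is an 8mer,
    otherwise a 7mer-m8; a 7mer-A1 (reverse complement of seed 2-7 plus
    'A') is only reported where it does not overlap a stronger site.
    Sites are returned in UTR order.
    """
    seed = seed_of(mirna.sequence)
    utr_seq = utr.sequence.upper().replace("T", "U")
    m7 = reverse_complement(seed)            # matches seed positions 2-8
    a1 = reverse_complement(seed[:6]) + "A"  # seed positions 2-7 + A
    sites: list[SeedSite] = []
    covered: list[tuple[int, int]] = []

    start = utr_seq.find(m7)
    while start != -1:
        end = start + 7
        if end < len(utr_seq) and utr_seq[end] == "A":
            site = SeedSite(mirna.id, utr.id, start, end + 1, "8mer")
        else:
            site = SeedSite(mirna.id, utr.id, start, end, "7mer-m8")
        sites.append(site)
        covered.append((site.utr_start, site.utr_end))
        start = utr_seq.find(m7, start + 1)

    start = utr_seq.find(a1)
    while start != -1:
        end = start + 7
        overlaps = any(start < ce and s < end for s, ce in covered)
        if not overlaps:
            sites.append(SeedSite(mirna.id, utr.id, start, end, "7mer-A1"))
        start = utr_seq.find(a1, start + 1)

    sites.sort(key=lambda s: (s.utr_start, _SITE_RANK[s.site_type]))
    return sites


@dataclass
class TargetPair:
    """A (miRNA, gene) pair supported by >=1 seed site, annotated with
    expression direction once integrated."""

    mirna: str
    gene: str
    best_site_type: str
    n_sites: int
    sites: list[SeedSite] = field(default_factory=list)
    mirna_status: str | None = None
    gene_status: str | None = None
    mirna_fold: float | None = None
    gene_fold: float | None = None


def predict_targets(
    mirnas: Sequence[SequenceRecord], utrs: Sequence[SequenceRecord]
) -> list[TargetPair]:
    """Scan every miRNA against every UTR; one pair per (miRNA, gene)
    with at least one canonical site."""
    if not mirnas or not utrs:
        raise ValueError("need at least one miRNA and one UTR")
    pairs: list[TargetPair] = []
    for mir in mirnas:
        for utr in utrs:
            sites = find_seed_sites(mir, utr)
            if not sites:
                continue
            best = min(sites, key=lambda s: _SITE_RANK[s.site_type])
            pairs.append(
                TargetPair(
                    mirna=mir.id,
                    gene=utr.id,
                    best_site_type=best.site_type,
                    n_sites=len(sites),
                    sites=sites,
                )
            )
    return pairs


def integrate_pairs(
    pairs: Iterable[TargetPair],
    mirna_de: Sequence[DERecord],
    gene_de: Sequence[DERecord],
    mirna_abundance: pd.DataFrame | None = None,
    min_abundance: float = 100.0,
) -> list[TargetPair]:
    """Keep the predicted pairs consistent with repression.

    A pair is admissible iff the miRNA and the gene have opposite DE
    status (miRNA up & gene down, or miRNA down & gene up), and the
    miRNA is not low-abundance. ``mirna_abundance`` is a feature x group
    table of group-mean normalized counts; a miRNA is dropped when its
    mean is below ``min_abundance`` in BOTH groups (strict '<').
    """
    mir_status = {r.feature: r for r in mirna_de}
    gene_status = {r.feature: r for r in gene_de}
    kept: list[TargetPair] = []
    for pair in pairs:
        if pair.mirna not in mir_status:
            raise KeyError(f"miRNA {pair.mirna!r} missing from DE results")
        if pair.gene not in gene_status:
            raise KeyError(f"gene {pair.gene!r} missing from DE results")
        mrec, grec = mir_status[pair.mirna], gene_status[pair.gene]
        inverse = {mrec.status, grec.status} == {UP, DOWN}
        if not inverse:
            continue
        if mirna_abundance is not None:
            if pair.mirna not in mirna_abundance.index:
                raise KeyError(
                    f"miRNA {pair.mirna!r} missing from abundance table"
                )
            means = mirna_abundance.loc[pair.mirna]
            if bool((means < min_abundance).all()):
                continue
        pair.mirna_status, pair.gene_status = mrec.status, grec.status
        pair.mirna_fold, pair.gene_fold = mrec.fold_change, grec.fold_change
        kept.append(pair)
    return kept


def select_core_mirnas(
    de: Sequence[DERecord],
    k: int = 15,
    direction: str = UP,
    allowed: Iterable[str] | None = None,
) -> list[str]:
    """The k most strongly regulated DE miRNAs in one direction.

    Sorted by fold change (largest first for up, smallest first for
    down); ties broken by smaller p-value, then id. ``allowed``
    restricts candidates (e.g. to miRNAs surviving the abundance
    filter). Returns fewer than k when fewer qualify.
    """
    if direction not in (UP, DOWN):
        raise ValueError("direction must be 'up' or 'down'")
    pool = [r for r in de if r.status == direction]
    if allowed is not None:
        allowed = set(allowed)
        pool = [r for r in pool if r.feature in allowed]
    sign = -1.0 if direction == UP else 1.0
    pool.sort(key=lambda r: (sign * r.fold_change, r.p_value, r.feature))
    return [r.feature for r in pool[:k]]


@dataclass
class RegulatoryNetwork:
    """Bipartite directed miRNA -> gene graph with edge provenance."""

    graph: nx.DiGraph

    @property
    def mirnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "miRNA"}

    @property
    def genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "gene"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_distribution(self) -> dict[str, int]:
        return {n: int(d) for n, d in self.graph.degree()}

    def summary(self) -> str:
        degs = [d for _, d in self.graph.degree()]
        lines = [
            "miRNA -> gene regulatory network",
            "=" * 40,
            f"core miRNAs: {len(self.mirnas)}",
            f"target genes: {len(self.genes)}",
            f"edges: {self.n_edges}",
        ]
        if degs:
            lines.append(
                f"degree: max {max(degs)}, mean {sum(degs) / len(degs):.2f}"
            )
        return "\n".join(lines)

    def audit(
        self,
        mirna_seqs: Mapping[str, SequenceRecord] | None = None,
        utr_seqs: Mapping[str, SequenceRecord] | None = None,
    ) -> None:
        """Re-validate every structural guarantee; raises on violation.

        Checks bipartiteness, inverse expression directions on every
        edge and (when sequences are supplied) re-scans each edge's UTR
        for a seed site of the recorded type's strength or better.
        """
        for u, v, d in self.graph.edges(data=True):
            if self.graph.nodes[u]["kind"] != "miRNA" or \
               self.graph.nodes[v]["kind"] != "gene":
                raise AssertionError(f"edge {u}->{v} violates bipartiteness")
            dirs = {d["mirna_direction"], d["gene_direction"]}
            if dirs != {UP, DOWN}:
                raise AssertionError(
                    f"edge {u}->{v} directions not inverse: {dirs}"
                )
            if mirna_seqs is not None and utr_seqs is not None:
                sites = find_seed_sites(mirna_seqs[u], utr_seqs[v])
                if not sites:
                    raise AssertionError(
                        f"edge {u}->{v} has no re-detectable seed site"
                    )


def build_network(
    core: Iterable[str], admissible: Sequence[TargetPair]
) -> RegulatoryNetwork:
    """Assemble the bipartite network of core miRNAs and their
    admissible targets; isolated core miRNAs stay as degree-0 nodes."""
    core = list(dict.fromkeys(core))
    g = nx.DiGraph()
    for m in core:
        g.add_node(m, kind="miRNA")
    for pair in admissible:
        if pair.mirna not in core:
            continue
        if pair.mirna_status is None or pair.gene_status is None:
            raise ValueError(
                f"pair {pair.mirna}->{pair.gene} lacks expression status; "
                "run integrate_pairs first"
            )
        g.add_node(pair.gene, kind="gene")
        g.add_edge(
            pair.mirna,
            pair.gene,
            site_type=pair.best_site_type,
            n_sites=pair.n_sites,
            mirna_direction=pair.mirna_status,
            gene_direction=pair.gene_status,
        )
    return RegulatoryNetwork(g)
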