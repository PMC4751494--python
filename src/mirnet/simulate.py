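"""Synthetic data with the statistical structure the pipeline assumes.

Generates, under one seeded configuration:

* miRNA and mRNA count matrices: negative-binomial counts
  (Var = mu + phi * mu^2; phi = 0 falls back to Poisson) for a small
  two-group design (default 3 vs 3), with a configurable fraction of
  features given a planted fold change, split evenly between directions;
* mature miRNA and 3'UTR sequences in which every planted regulatory
  pair has a canonical seed site of a prescribed type, while every
  non-target UTR is guaranteed site-free for every simulated miRNA
  (so target-prediction precision/recall on synthetic data is exact);
* a multi-cell-type expression panel with per-platform monotone
  power/scale distortions (raw values differ by platform, within-sample
  abundance ranks do not);
* a small rooted ontology DAG with ancestor-propagated gene annotations
  and the matching GMT collection.

Ground-truth labels (true DE directions, log fold changes, planted
pairs) are returned alongside for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    OntologyEdges,
    SequenceRecord,
    write_count_table,
    write_fasta,
    write_gmt,
    write_ontology,
)
from .matrix import CountMatrix
from .network import SITE_TYPES, find_seed_sites, reverse_complement, seed_of

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CellTypePanel",
    "simulate_counts",
    "simulate_sequences",
    "simulate_celltype_panel",
    "simulate_ontology",
    "write_ground_truth",
]

_BASES = np.array(list("ACGU"))
_CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for all generators.

    Defaults emulate a small clinical RNA-seq contrast: 3 vs 3
    replicates, moderately overdispersed counts (phi = 0.1), 20% of
    features perturbed four-fold, ~200 nt UTRs with one planted site
    per regulatory pair.
    """

    n_mirna: int = 60
    n_gene: int = 120
    n_per_group: int = 3
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    frac_de: float = 0.2
    fc_de: float = 4.0
    seed: int = 0
    utr_length: int = 200
    n_planted_sites_per_target: int = 1
    n_celltypes: int = 4
    platform_shift: float = 0.3
    group_labels: tuple[str, str] = ("case", "control")

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_gene", "n_per_group", "utr_length",
                     "n_planted_sites_per_target", "n_celltypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.fc_de <= 0:
            raise ValueError("fc_de must be positive")


@dataclass
class GroundTruth:
    """Planted-effect labels; directions are 'up'/'down' for the first
    (case) group relative to the second."""

    de_mirnas: dict[str, str]
    de_genes: dict[str, str]
    true_pairs: set[tuple[str, str, str]]  # (mirna, gene, site_type)
    true_logfc: dict[str, float]

    def pairs_of_gene(self, gene: str) -> list[tuple[str, str, str]]:
        return [p for p in self.true_pairs if p[1] == gene]


# ---------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _split_directions(ids: list[str]) -> dict[str, str]:
    # even split, first half up
    half = math.ceil(len(ids) / 2)
    return {f: ("up" if i < half else "down") for i, f in enumerate(ids)}


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Two-group NB count matrices for miRNAs and genes plus truth.

    DE features have their case-group mean multiplied (up) or divided
    (down) by ``fc_de``; planted regulatory pairs link DE miRNAs to DE
    genes of the opposite direction, cycling through the canonical site
    types.
    """
    rng = np.random.default_rng([config.seed, 0])
    mirna_ids = [f"mir-{i:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"gene-{i:04d}" for i in range(config.n_gene)]
    g1, g2 = config.group_labels
    samples = [f"{g1}_{i + 1}" for i in range(config.n_per_group)] + \
              [f"{g2}_{i + 1}" for i in range(config.n_per_group)]
    groups = {s: (g1 if s.startswith(f"{g1}_") else g2) for s in samples}

    n_de_mir = int(round(config.frac_de * config.n_mirna))
    n_de_gene = int(round(config.frac_de * config.n_gene))
    de_mirnas = _split_directions(mirna_ids[:n_de_mir])
    de_genes = _split_directions(gene_ids[:n_de_gene])

    def build(ids: list[str], de: dict[str, str]) -> tuple[pd.DataFrame, dict]:
        n = len(ids)
        case_mean = np.full(n, config.baseline_mean)
        ctrl_mean = np.full(n, config.baseline_mean)
        logfc = {}
        for i, f in enumerate(ids):
            if f in de:
                if de[f] == "up":
                    case_mean[i] *= config.fc_de
                else:
                    case_mean[i] /= config.fc_de
            logfc[f] = float(np.log2(case_mean[i] / ctrl_mean[i]))
        cols = {}
        for s in samples:
            mean = case_mean if groups[s] == g1 else ctrl_mean
            cols[s] = _nb_draw(rng, mean, config.dispersion)
        return pd.DataFrame(cols, index=ids), logfc

    mir_df, mir_logfc = build(mirna_ids, de_mirnas)
    gene_df, gene_logfc = build(gene_ids, de_genes)

    ann_mir = pd.DataFrame(
        {"chromosome": rng.choice(_CHROMOSOMES, size=len(mirna_ids))},
        index=mirna_ids,
    )
    ann_gene = pd.DataFrame(
        {"chromosome": rng.choice(_CHROMOSOMES, size=len(gene_ids))},
        index=gene_ids,
    )
    mirna_mat = CountMatrix(mir_df, groups=groups, feature_annotations=ann_mir)
    gene_mat = CountMatrix(gene_df, groups=groups, feature_annotations=ann_gene)

    # pair every DE gene with an opposite-direction DE miRNA, if any
    true_pairs: set[tuple[str, str, str]] = set()
    by_dir = {"up": [m for m, d in de_mirnas.items() if d == "up"],
              "down": [m for m, d in de_mirnas.items() if d == "down"]}
    counters = {"up": 0, "down": 0}
    for j, (gene, gdir) in enumerate(sorted(de_genes.items())):
        want = "down" if gdir == "up" else "up"
        pool = by_dir[want]
        if not pool:
            continue
        mir = pool[counters[want] % len(pool)]
        counters[want] += 1
        site_type = SITE_TYPES[j % len(SITE_TYPES)]
        true_pairs.add((mir, gene, site_type))

    truth = GroundTruth(
        de_mirnas=de_mirnas,
        de_genes=de_genes,
        true_pairs=true_pairs,
        true_logfc={**mir_logfc, **gene_logfc},
    )
    return mirna_mat, gene_mat, truth


# ---------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------

def _site_patterns(seed: str) -> dict[str, str]:
    m7 = reverse_complement(seed)
    return {
        "8mer": m7 + "A",
        "7mer-m8": m7,
        "7mer-A1": reverse_complement(seed[:6]) + "A",
    }


def _patterns_conflict(a: dict[str, str], b: dict[str, str]) -> bool:
    # a site pattern of one miRNA embedded in another's would make a
    # planted site double-count; forbid cross containment outright
    for x in a.values():
        for y in b.values():
            if x in y or y in x:
                return True
    return False


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _scan_all(utr: SequenceRecord, mirnas: list[SequenceRecord],
              protect: list[tuple[int, int]]):
    """Sites of any miRNA in the UTR that lie outside protected spans."""
    hits = []
    for mir in mirnas:
        for site in find_seed_sites(mir, utr):
            inside = any(site.utr_start >= s and site.utr_end <= e
                         for s, e in protect)
            if not inside:
                hits.append(site)
    return hits


def _scrub(
    rng: np.random.Generator,
    seq: str,
    gene: str,
    mirnas: list[SequenceRecord],
    protect: list[tuple[int, int]],
    max_rounds: int = 300,
) -> str:
    """Mutate single bases until no unprotected canonical site remains."""
    protected = set()
    for s, e in protect:
        protected.update(range(s, e))
    for _ in range(max_rounds):
        hits = _scan_all(SequenceRecord(gene, seq), mirnas, protect)
        if not hits:
            return seq
        site = hits[0]
        positions = [i for i in range(site.utr_start, site.utr_end)
                     if i not in protected]
        if not positions:  # pattern butts against a planted span
            raise RuntimeError(
                f"cannot scrub site overlapping a planted span in {gene}"
            )
        pos = int(rng.choice(positions))
        new = str(rng.choice(_BASES[_BASES != seq[pos]]))
        seq = seq[:pos] + new + seq[pos + 1:]
    raise RuntimeError(f"could not scrub UTR of {gene} site-free")


def simulate_sequences(
    config: SimulationConfig,
    truth: GroundTruth,
    mirna_length: int = 21,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Mature miRNA sequences and 3'UTRs honouring the planted pairs.

    Every (miRNA, gene, site_type) in ``truth.true_pairs`` yields
    ``n_planted_sites_per_target`` sites of exactly that type in the
    gene's UTR; all other UTR positions -- and all non-target UTRs --
    are scrubbed free of canonical sites for every simulated miRNA.
    miRNA seed regions are rejection-sampled so that no miRNA's site
    pattern contains another's, which keeps planted sites unambiguous.
    """
    if config.utr_length < 8:
        raise ValueError("utr_length must be >= 8 to host a seed site")
    if mirna_length < 19:
        raise ValueError("mature miRNA sequences must be >= 19 nt")
    rng = np.random.default_rng([config.seed, 1])

    mirna_ids = [f"mir-{i:04d}" for i in range(config.n_mirna)]

    mirnas: list[SequenceRecord] = []
    patterns: list[dict[str, str]] = []
    for mid in mirna_ids:
        for _ in range(1000):
            seq = _random_seq(rng, mirna_length)
            pats = _site_patterns(seed_of(seq))
            if pats["7mer-m8"] == pats["7mer-A1"]:
                continue  # degenerate homopolymer-like seed
            if not any(_patterns_conflict(pats, p) for p in patterns):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw non-conflicting miRNA seeds")
        mirnas.append(SequenceRecord(mid, seq))
        patterns.append(pats)
    by_id = {m.id: m for m in mirnas}

    utrs: list[SequenceRecord] = []
    gene_ids = [f"gene-{i:04d}" for i in range(config.n_gene)]
    for gene in gene_ids:
        pairs = truth.pairs_of_gene(gene)
        seq = _random_seq(rng, config.utr_length)
        planted: list[tuple[int, int]] = []
        for mir, _, site_type in pairs:
            if site_type not in SITE_TYPES:
                raise ValueError(f"unknown site type {site_type!r}")
            pattern = _site_patterns(seed_of(by_id[mir].sequence))[site_type]
            span = len(pattern)
            if site_type == "7mer-m8":
                # avoid an accidental 8mer: force a non-A right flank
                pattern_full, extra = pattern, 1
            else:
                pattern_full, extra = pattern, 0
            for _ in range(config.n_planted_sites_per_target):
                for _ in range(500):
                    start = int(rng.integers(0, config.utr_length - span - extra + 1))
                    window = (start, start + span + extra)
                    if not any(s < window[1] and window[0] < e
                               for s, e in planted):
                        break
                else:
                    raise RuntimeError(
                        f"UTR of {gene} too short for all planted sites"
                    )
                seq = seq[:start] + pattern_full + seq[start + span:]
                if extra:
                    flank_pos = start + span
                    if flank_pos < len(seq) and seq[flank_pos] == "A":
                        repl = str(rng.choice(_BASES[_BASES != "A"]))
                        seq = seq[:flank_pos] + repl + seq[flank_pos + 1:]
                    planted.append((start, start + span + 1))
                else:
                    planted.append((start, start + span))
        seq = _scrub(rng, seq, gene, mirnas, planted)
        utrs.append(SequenceRecord(gene, seq))
    return mirnas, utrs


# ---------------------------------------------------------------------
# multi-cell-type panel
# ---------------------------------------------------------------------

@dataclass
class CellTypePanel:
    """Expression panel across cell types with platform labels.

    ``matrices`` hold the platform-distorted values the pipeline sees;
    ``undistorted`` the latent values; both share features and columns.
    """

    cell_types: list[str]
    platforms: dict[str, str]
    matrices: dict[str, pd.DataFrame]
    undistorted: dict[str, pd.DataFrame]
    true_order: dict[str, list[str]]  # cell type -> descending feature order


def simulate_celltype_panel(config: SimulationConfig) -> CellTypePanel:
    """Cell types with distinct latent abundance rankings, measured on
    alternating platforms with monotone power/scale distortions.

    Each cell type's latent per-feature abundance is log-normal (its
    descending order is that cell type's true ranking); replicates add
    NB noise. The platform transform x -> scale * x^gamma with
    gamma = 1 + platform_shift * delta_p (delta in (-0.5, 0.5]) is
    strictly increasing, so within-sample ranks are preserved exactly;
    platform_shift = 0 is the identity.
    """
    if config.n_celltypes < 2:
        raise ValueError("need at least two cell types")
    rng = np.random.default_rng([config.seed, 2])
    features = [f"mir-{i:04d}" for i in range(config.n_mirna)]
    cell_types = [f"celltype_{i}" for i in range(config.n_celltypes)]
    platforms = {c: f"platform_{i % 2}" for i, c in enumerate(cell_types)}
    plat_delta = {"platform_0": 0.5, "platform_1": -0.25}
    plat_scale = {"platform_0": 1.0, "platform_1": 3.0}

    matrices, undistorted, true_order = {}, {}, {}
    for ct in cell_types:
        latent = np.exp(rng.normal(np.log(config.baseline_mean), 1.5,
                                   size=config.n_mirna))
        order = [features[i] for i in np.argsort(-latent, kind="stable")]
        cols = {}
        for r in range(config.n_per_group):
            cols[f"{ct}_rep{r + 1}"] = _nb_draw(rng, latent, config.dispersion)
        raw = pd.DataFrame(cols, index=features).astype(float)
        plat = platforms[ct]
        gamma = 1.0 + config.platform_shift * plat_delta[plat]
        scale = 1.0 + config.platform_shift * (plat_scale[plat] - 1.0)
        undistorted[ct] = raw
        matrices[ct] = scale * raw.pow(gamma)
        true_order[ct] = order
    return CellTypePanel(cell_types, platforms, matrices, undistorted,
                         true_order)


# ---------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------

def simulate_ontology(
    n_terms: int, n_genes: int, seed: int = 0
) -> tuple[OntologyEdges, GeneSetCollection]:
    """A rooted random DAG of terms with ancestor-propagated annotations.

    Term 0 is the unique root; every later term picks one or two
    earlier terms as parents (guaranteeing acyclicity and a single
    root). Each term receives at least one directly annotated gene, and
    a term's gene set is its direct genes plus the union of its
    descendants' sets, so child sets are always subsets of parent sets.
    """
    if n_terms < 2:
        raise ValueError("need at least two terms")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng([seed, 3])
    terms = [f"TERM:{i:04d}" for i in range(n_terms)]
    genes = [f"gene-{i:04d}" for i in range(n_genes)]
    edges: dict[str, set[str]] = {}
    children: dict[str, list[str]] = {t: [] for t in terms}
    for i in range(1, n_terms):
        n_parents = 1 if i == 1 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        edges[terms[i]] = {terms[int(p)] for p in parents}
        for p in parents:
            children[terms[int(p)]].append(terms[i])

    direct: dict[str, set[str]] = {}
    for t in terms:
        size = int(rng.integers(1, max(2, n_genes // n_terms + 2)))
        direct[t] = set(rng.choice(genes, size=min(size, n_genes),
                                   replace=False))

    annotated: dict[str, set[str]] = {}

    def gather(term: str) -> set[str]:
        if term not in annotated:
            out = set(direct[term])
            for ch in children[term]:
                out |= gather(ch)
            annotated[term] = out
        return annotated[term]

    sets = {
        t: (f"synthetic term {t}", frozenset(gather(t))) for t in terms
    }
    return OntologyEdges(edges), GeneSetCollection(sets)


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """TSV with one line per planted fact."""
    with open(path, "w") as fh:
        fh.write("kind\tid\tdirection_or_site\tpartner\tlog2fc\n")
        for mid, d in sorted(truth.de_mirnas.items()):
            fh.write(f"de_mirna\t{mid}\t{d}\t\t{truth.true_logfc[mid]:.4f}\n")
        for gid, d in sorted(truth.de_genes.items()):
            fh.write(f"de_gene\t{gid}\t{d}\t\t{truth.true_logfc[gid]:.4f}\n")
        for mir, gene, st in sorted(truth.true_pairs):
            fh.write(f"pair\t{mir}\t{st}\t{gene}\t\n")


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate one full synthetic dataset and write every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirna_mat, gene_mat, truth = simulate_counts(config)
    mirnas, utrs = simulate_sequences(config, truth)
    ontology, collection = simulate_ontology(
        n_terms=12, n_genes=config.n_gene, seed=config.seed
    )
    paths = {
        "mirna_counts": outdir / "mirna_counts.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "metadata": outdir / "samples.tsv",
        "mirna_fasta": outdir / "mirna.fa",
        "utr_fasta": outdir / "utrs.fa",
        "gmt": outdir / "terms.gmt",
        "ontology": outdir / "ontology.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_count_table(mirna_mat, paths["mirna_counts"], paths["metadata"])
    write_count_table(gene_mat, paths["gene_counts"])
    write_fasta(mirnas, paths["mirna_fasta"])
    write_fasta(utrs, paths["utr_fasta"])
    write_gmt(collection, paths["gmt"])
    write_ontology(ontology, paths["ontology"])
    write_ground_truth(truth, paths["truth"])
    return paths
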