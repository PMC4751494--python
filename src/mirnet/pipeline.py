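"""End-to-end orchestration: normalize -> DE -> specificity ->
enrichment -> network, from a single configuration, with a per-stage
run manifest and a fully synthetic demo mode."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import (
    DEConfig,
    DifferentialExpression,
    DOWN,
    UP,
)
from .enrichment import build_go_tree, enrich
from .io import (
    read_count_table,
    read_de_table,
    read_fasta,
    read_gmt,
    read_ontology,
    write_de_table,
    write_network,
)
from .network import (
    build_network,
    integrate_pairs,
    predict_targets,
    select_core_mirnas,
)
from .specificity import (
    SpecificityCriteria,
    abundance_rank_profile,
    compare_rank_profiles,
    define_specific_set,
    directional_overlap,
    quantile_normalize,
)
from .simulate import SimulationConfig, write_dataset

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "demo"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run.

    Any optional input left as None causes its stage to be skipped with
    a warning in the manifest (e.g. no cell-type panels -> no
    specificity stage).
    """

    output_dir: str
    mirna_counts: str
    metadata: str
    mrna_counts: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    gmt: str | None = None
    ontology: str | None = None
    comparison_de: str | None = None  # DE table of a second contrast
    panels: list[str] = field(default_factory=list)
    mirna_alpha: float = 0.01
    mrna_alpha: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    enrichment_alpha: float = 0.05
    min_abundance: float = 100.0
    top_k: int = 15
    rank_window: int = 10
    min_similar: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def mirna_de_config(self) -> DEConfig:
        return DEConfig(alpha=self.mirna_alpha, fc_up=self.fc_up,
                        fc_down=self.fc_down)

    def mrna_de_config(self) -> DEConfig:
        return DEConfig(alpha=self.mrna_alpha, fc_up=self.fc_up,
                        fc_down=self.fc_down)


@dataclass
class RunManifest:
    """Per-stage record of what ran, with what inputs, and what came out."""

    seed: int
    version: str = __version__
    started: float = field(default_factory=time.time)
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, **info) -> None:
        self.stages[stage] = {"status": status, **info}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage whose inputs are present, in order.

    A stage failure aborts the run with the stage named; outputs of
    earlier stages are retained on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)

    # -- differential expression -------------------------------------
    stage = "de_mirna"
    try:
        mirna_mat = read_count_table(config.mirna_counts, config.metadata)
        mirna_res = DifferentialExpression(
            mirna_mat, config.mirna_de_config()
        ).fit()
        de_path = out / "de_mirna.tsv"
        write_de_table(mirna_res.records, de_path)
        manifest.record(
            stage, "ok",
            features=len(mirna_res.records),
            up=mirna_res.n_up, down=mirna_res.n_down,
            dispersion=mirna_res.dispersion,
            outputs=[str(de_path)],
        )
    except Exception as exc:
        manifest.record(stage, "failed", error=str(exc))
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    mrna_res = None
    stage = "de_mrna"
    if config.mrna_counts:
        try:
            mrna_mat = read_count_table(config.mrna_counts, config.metadata)
            mrna_res = DifferentialExpression(
                mrna_mat, config.mrna_de_config()
            ).fit()
            de_path = out / "de_mrna.tsv"
            write_de_table(mrna_res.records, de_path)
            manifest.record(
                stage, "ok",
                features=len(mrna_res.records),
                up=mrna_res.n_up, down=mrna_res.n_down,
                dispersion=mrna_res.dispersion,
                outputs=[str(de_path)],
            )
        except Exception as exc:
            manifest.record(stage, "failed", error=str(exc))
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    else:
        manifest.record(stage, "skipped", reason="no mRNA counts provided")

    # -- specificity ---------------------------------------------------
    stage = "specificity"
    overlaps = []
    rank_reports = []
    if config.comparison_de or config.panels:
        try:
            if config.comparison_de:
                other = read_de_table(config.comparison_de)
                overlaps.append(
                    directional_overlap(mirna_res.records, other)
                )
            if config.panels:
                frames = [pd.read_csv(p, sep="\t", index_col=0, comment="#")
                          for p in config.panels]
                qn = quantile_normalize(
                    frames + [mirna_res.normalized.data]
                )
                own_cols = [c for c in qn.columns
                            if c in mirna_res.normalized.data.columns]
                own_profile = abundance_rank_profile(
                    qn[own_cols].mean(axis=1), id="primary"
                )
                for col in qn.columns:
                    if col in own_cols:
                        continue
                    prof = abundance_rank_profile(qn[col], id=col)
                    rank_reports.append(
                        compare_rank_profiles(own_profile, prof,
                                              window=config.rank_window)
                    )
            criteria = SpecificityCriteria(window=config.rank_window,
                                           min_similar=config.min_similar)
            specific = define_specific_set(
                mirna_res.records, overlaps, rank_reports, criteria
            )
            spec_path = out / "specific_mirnas.txt"
            spec_path.write_text("\n".join(sorted(specific)) + "\n")
            manifest.record(
                stage, "ok",
                de_mirnas=mirna_res.n_up + mirna_res.n_down,
                specific=len(specific),
                overlaps=[{"up": r.n_up_overlap, "down": r.n_down_overlap}
                          for r in overlaps],
                outputs=[str(spec_path)],
            )
        except Exception as exc:
            manifest.record(stage, "failed", error=str(exc))
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    else:
        manifest.record(stage, "skipped",
                        reason="no comparison contrast or panels provided")

    # -- enrichment ----------------------------------------------------
    stage = "enrichment"
    if config.gmt and mrna_res is not None:
        try:
            collection = read_gmt(config.gmt)
            universe = {r.feature for r in mrna_res.records}
            up_genes = mrna_res.features_with_status(UP)
            down_genes = mrna_res.features_with_status(DOWN)
            sig_up, sig_down = [], []
            outputs = []
            for name, genes, bucket in (
                ("up", up_genes, sig_up), ("down", down_genes, sig_down)
            ):
                if not genes:
                    continue
                records = enrich(genes, collection, universe,
                                 alpha=config.enrichment_alpha)
                bucket.extend(
                    r.term for r in records if r.fdr < config.enrichment_alpha
                )
                path = out / f"enrichment_{name}.tsv"
                pd.DataFrame(
                    [(r.term, r.description, r.k, r.K, r.n, r.N,
                      r.p_value, r.fdr) for r in records],
                    columns=["term", "description", "k", "K", "n", "N",
                             "p_value", "fdr"],
                ).to_csv(path, sep="\t", index=False)
                outputs.append(str(path))
            info = {"significant_up": len(sig_up),
                    "significant_down": len(sig_down)}
            if config.ontology and (sig_up or sig_down):
                ontology = read_ontology(config.ontology)
                tree = build_go_tree(sig_up, sig_down, ontology)
                tree_path = out / "go_tree.graphml"
                tree.to_graphml(tree_path)
                (out / "go_tree.dot").write_text(tree.to_dot() + "\n")
                outputs += [str(tree_path), str(out / "go_tree.dot")]
                info["tree_nodes"] = tree.graph.number_of_nodes()
            manifest.record(stage, "ok", outputs=outputs, **info)
        except Exception as exc:
            manifest.record(stage, "failed", error=str(exc))
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    else:
        manifest.record(stage, "skipped",
                        reason="no gene sets or no mRNA contrast")

    # -- network -------------------------------------------------------
    stage = "network"
    if config.mirna_fasta and config.utr_fasta and mrna_res is not None:
        try:
            mirnas = read_fasta(config.mirna_fasta)
            utrs = read_fasta(config.utr_fasta)
            pairs = predict_targets(mirnas, utrs)
            known_mirnas = {r.feature for r in mirna_res.records}
            known_genes = {r.feature for r in mrna_res.records}
            pairs = [p for p in pairs
                     if p.mirna in known_mirnas and p.gene in known_genes]
            abundance = mirna_res.normalized.group_means()
            admissible = integrate_pairs(
                pairs, mirna_res.records, mrna_res.records,
                mirna_abundance=abundance,
                min_abundance=config.min_abundance,
            )
            abundant = set(
                abundance.index[(abundance >= config.min_abundance).any(axis=1)]
            )
            outputs = []
            edge_total = 0
            for direction in (UP, DOWN):
                core = select_core_mirnas(
                    mirna_res.records, k=config.top_k,
                    direction=direction, allowed=abundant,
                )
                net = build_network(core, admissible)
                net.audit()
                base = out / f"network_{direction}"
                write_network(net, f"{base}.graphml", "graphml")
                write_network(net, f"{base}.sif", "sif")
                outputs += [f"{base}.graphml", f"{base}.sif"]
                edge_total += net.n_edges
            manifest.record(
                stage, "ok",
                predicted_pairs=len(pairs),
                admissible_pairs=len(admissible),
                edges=edge_total,
                outputs=outputs,
            )
        except Exception as exc:
            manifest.record(stage, "failed", error=str(exc))
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    else:
        manifest.record(stage, "skipped",
                        reason="no sequences or no mRNA contrast")

    manifest.to_json(out / "manifest.json")
    return manifest


def demo(seed: int = 7, output_dir: str | Path = "mirnet_demo",
         sim: SimulationConfig | None = None) -> tuple[RunManifest, dict]:
    """Generate a synthetic dataset, run the full pipeline on it and
    report how well the planted truth was recovered.

    Returns the run manifest and a recovery report with DE power /
    false-direction counts and network pair precision / recall.
    """
    from .simulate import simulate_counts

    outdir = Path(output_dir)
    datadir = outdir / "data"
    sim = sim or SimulationConfig(seed=seed)
    if sim.seed != seed:
        sim = SimulationConfig(**{**asdict_config(sim), "seed": seed})
    paths = write_dataset(sim, datadir)

    config = PipelineConfig(
        output_dir=str(outdir / "results"),
        mirna_counts=str(paths["mirna_counts"]),
        metadata=str(paths["metadata"]),
        mrna_counts=str(paths["gene_counts"]),
        mirna_fasta=str(paths["mirna_fasta"]),
        utr_fasta=str(paths["utr_fasta"]),
        gmt=str(paths["gmt"]),
        ontology=str(paths["ontology"]),
        min_abundance=100.0,
        top_k=15,
        seed=seed,
    )
    manifest = run_pipeline(config)

    # recovery report against the planted truth
    _, _, truth = simulate_counts(sim)
    de = read_de_table(Path(config.output_dir) / "de_mirna.tsv")
    detected = {r.feature: r.status for r in de
                if r.status in (UP, DOWN)}
    correct = sum(1 for f, d in truth.de_mirnas.items()
                  if detected.get(f) == d)
    wrong = sum(1 for f, d in truth.de_mirnas.items()
                if f in detected and detected[f] != d)
    edges = set()
    for direction in (UP, DOWN):
        import networkx as nx

        g = nx.read_graphml(
            Path(config.output_dir) / f"network_{direction}.graphml"
        )
        edges |= set(g.edges())
    true_edges = {(m, g) for m, g, _ in truth.true_pairs}
    tp = len(edges & true_edges)
    report = {
        "planted_de_mirnas": len(truth.de_mirnas),
        "detected_correct_direction": correct,
        "detected_wrong_direction": wrong,
        "de_power": correct / len(truth.de_mirnas) if truth.de_mirnas else 0.0,
        "planted_pairs": len(true_edges),
        "recovered_edges": len(edges),
        "edge_precision": tp / len(edges) if edges else 1.0,
        "edge_recall": tp / len(true_edges) if true_edges else 0.0,
    }
    with open(outdir / "recovery_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return manifest, report


def asdict_config(sim: SimulationConfig) -> dict:
    from dataclasses import asdict as _asdict

    return _asdict(sim)
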