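# mirnet

Integrated miRNA–mRNA analysis for count-based expression studies:
differential expression of small-RNA and mRNA sequencing counts,
cross-cell-type specificity of the resulting miRNA signatures,
hypergeometric functional enrichment with an ontology-tree summary, and
construction of an inverse-correlation miRNA→mRNA regulatory network
from canonical seed-match target prediction.

The package is aimed at the common clinical design in which a handful of
case and control samples (e.g. ossified vs normal posterior longitudinal
ligament primary cells, n = 3 per group) are profiled on both a
small-RNA and an mRNA assay, and the question is which miRNAs are
specifically dysregulated in the condition and which genes they
plausibly repress.

## The statistics at the core

**Differential expression.** Libraries are rescaled by TMM (trimmed mean
of M-values: doubly trimmed, precision-weighted mean of per-feature
log-ratios against a reference library, factors normalised to unit
geometric mean). A common negative-binomial dispersion φ with
Var(Y) = μ + φμ² is estimated by pooled method of moments on
library-size-equalised counts. Each feature is then tested by
conditioning on its total count t across both groups: under the null the
split (a, t−a) follows the conditional law of two NB group sums with
means proportional to the effective library sizes (a group sum of n
replicates has dispersion φ/n), and the two-sided p-value sums the
probabilities of all splits no more likely than the one observed. At
φ = 0 this is exactly the conditional binomial test. P-values are
Benjamini–Hochberg adjusted, and features are called up/down when
fold change ≥ 2 (or ≤ 0.5) **and** FDR ≤ α (α = 0.01 for miRNA, 0.05 for
mRNA by default; thresholds inclusive).

**Specificity.** Panels from different platforms are joined on shared
feature ids, quantile-normalised (columns forced onto the common
distribution of order-statistic means), and summarised as rank-abundance
profiles: each feature's share of total miRNA abundance, ranked from the
most abundant down. A DE miRNA is *condition-specific* when it neither
overlaps directionally with a comparison contrast (same-direction Venn
intersection) nor keeps a similar abundance rank in other cell types.

**Enrichment.** For query set of size n in a universe of size N, a term
with K universe genes and overlap k scores p = P[X ≥ k],
X ~ Hypergeometric(N, K, n), BH-corrected across all terms; enriched
terms plus their ontology ancestors form a directed tree labelled
up / down / ambiguous / ancestor-only.

**Network.** The seed of a mature miRNA is nucleotides 2–8 (5′→3′).
Canonical sites in a 3′UTR are the reverse complement of the seed
followed by A (8mer), alone (7mer-m8), or the reverse complement of seed
nucleotides 2–7 followed by A (7mer-A1); overlaps resolve to the
strongest type. A predicted pair enters the network only if the miRNA
and gene changed in *opposite* directions and the miRNA's group-mean
normalized count is not below 100 in both groups; the network links the
top-15 most strongly regulated miRNAs per direction to their admissible
targets.

## Worked example

The synthetic demo generates a full study — NB counts for 60 miRNAs and
120 genes (3 vs 3, dispersion 0.1, 20% of features perturbed four-fold),
miRNA/3′UTR sequences with seed sites planted for every true regulatory
pair, a random ontology — runs every stage, and scores the result
against the planted truth:

```bash
mirnet demo --seed 7 --out demo_run
```

```
{
  "planted_de_mirnas": 12,
  "detected_correct_direction": 12,
  "detected_wrong_direction": 0,
  "de_power": 1.0,
  "planted_pairs": 24,
  "recovered_edges": 24,
  "edge_precision": 1.0,
  "edge_recall": 1.0
}
```

All 12 planted DE miRNAs are recovered in the correct direction and the
network contains exactly the 24 planted miRNA→gene pairs — no spurious
edges (precision 1.0), none missed (recall 1.0). The same fit through
the library API:

```python
from mirnet import DifferentialExpression, DEConfig
from mirnet.simulate import SimulationConfig, simulate_counts

counts, _, truth = simulate_counts(SimulationConfig(seed=7))
results = DifferentialExpression(counts, DEConfig(alpha=0.01)).fit()
print(results.summary(top=5))
```

```
Differential expression (conditional exact NB test)
=======================================================
contrast:        case / control
features tested: 60
common dispersion phi: 0.0782
thresholds: fold >= 2.0 or <= 0.5, fdr <= 0.01
up-regulated:    7
down-regulated:  7

          fold_change  log2fc  p_value      fdr status
feature
mir-0011        0.168   -2.58 7.58e-12 4.55e-10   down
mir-0000         5.04    2.33 3.24e-11 9.72e-10     up
mir-0001         4.94    2.31 7.73e-11 1.55e-09     up
mir-0010        0.205   -2.29 3.17e-10 4.76e-09   down
mir-0003         4.59     2.2 4.47e-10 5.37e-09     up
```

The estimated common dispersion (0.078) is close to the generating value
(0.1), and the strongest calls are planted features with fold-change
estimates near the true four-fold effect.

Other entry points: `mirnet de`, `mirnet specificity`, `mirnet enrich`,
`mirnet network`, and `mirnet run --config config.yaml` for a full
configured pipeline (see `mirnet --help`).

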