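# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, in the order the pipeline runs them.

## Count model and differential expression

Counts are modelled feature-wise as negative binomial with mean μ and
common dispersion φ, Var(Y) = μ + φμ²; φ = 0 degenerates to Poisson.
A single (common) dispersion shared across features is deliberate: with
3 replicates per group, per-feature (tagwise) dispersion estimates are
too noisy to help, and the common estimate keeps the test fully
transparent. Trended/tagwise shrinkage as found in mature DE packages is
intentionally out of scope.

**TMM normalization.** The reference library is the sample whose 75th
percentile of counts/library-size is closest to the mean such
percentile. For each sample, per-feature log2 ratios M against the
reference (library-size scaled, positive counts only) are trimmed 30%
on M and 5% on average abundance A, then averaged with inverse
delta-method variance weights (N−x)/(Nx) + (N_r−x_r)/(N_r x_r). Factors
are rescaled to unit geometric mean, so scale common to all libraries
lives in the library size, not the factors. Effective library size =
raw library size × factor.

**Dispersion estimation.** Counts are equalised to the geometric-mean
effective library size. For every feature in every group with ≥ 2
replicates, the moment identities E[v − m] = φμ² and E[m² − v/n] = μ²
(m, v the replicate sample mean/variance) are pooled as
φ̂ = Σ(v − m) / Σ(m² − v/n), clamped at 0. The −v/n term removes the
small-n upward bias of m² as an estimate of μ²; features with equalised
mean < 1 are excluded as uninformative. Simulation recovery: data
generated at φ = 0.1 yields estimates within [0.05, 0.2] at 2000
features, and Poisson data estimates < 0.02.

**Exact test.** Per feature, condition on the total t = a + b of the two
group sums. Group sums of n i.i.d. NB(μ, φ) replicates are NB with
dispersion φ/n, so the conditional null probability of the split k is
proportional to f_A(k)·f_B(t−k), where f_A, f_B are NB pmfs with means
t·S_A/(S_A+S_B) and t·S_B/(S_A+S_B) (S_g the group's summed effective
library size) and dispersions φ/n_A, φ/n_B. Two-sided p-value =
Σ probabilities of all splits no more likely than the observed one
(minimum-likelihood method), ties included via a 1e-10 log-space
tolerance, capped at 1. t = 0 returns p = 1. Dispersion below 1e-12 uses
the exact conditional binomial branch (and avoids overflow of n/φ). The
whole computation is in log space; the φ = 0 branch reproduces exact
rational binomial enumeration to < 1e-12 for all totals ≤ 50.

**Classification.** Fold change = (mean_A + c) / (mean_B + c) on
TMM-scaled counts-per-million, pseudocount c = 0.5. The pseudocount
keeps fold changes finite when one group is all zeros — published
small-RNA tables contain very large finite fold changes (e.g. 630.71),
which implies such zero-handling, and 0.5 normalized counts is the
conventional choice. Calls are up when fold ≥ 2 and FDR ≤ α, down when
fold ≤ 0.5 and FDR ≤ α; thresholds are inclusive because published
tables label a printed fold of exactly 0.50 as down-regulated. The
significance column is the BH-adjusted p by default (α = 0.01 for
miRNA, 0.05 for mRNA); filtering on the raw p instead is a
configuration switch, since study write-ups mix both conventions.

**TPM.** For small-RNA data, value = count / total clean reads × 10⁶.
Clean totals are supplied per sample and must be at least the mapped
totals; omitted, they default to mapped totals. Column sums then obey
the exact identity (mapped/clean)×10⁶.

## Specificity analysis

"Similar expression behaviour in other cell types" is made operational
in two ways:

1. **Directional overlap** — the same-direction intersection of DE sets
   from two contrasts. A feature up in the primary contrast and up in
   the comparison contrast is *not* condition-specific.
2. **Rank similarity** — features are ranked by share of total
   abundance within each sample/cell type (ties broken lexicographically
   by feature id so all outputs are deterministic); a feature is
   rank-similar between two profiles when |Δrank| ≤ R, default R = 10.
   The threshold is a judgement call — the underlying notion of
   "similar rank place" has no canonical quantification — so R and the
   number of cell types required (min_similar) are configuration, and
   the rank criterion is off unless requested.

Cross-platform panels are joined by exact feature id (an optional
old→new alias table handles annotation-release drift; full release
history tracking is out of scope) and quantile-normalised: every column
is replaced by the across-column mean of order statistics, tied values
receiving the mean of the quantile means their span covers. This makes
column distributions identical (hence equal means) and is idempotent on
tie-free data; with ties, re-application can drift in the last decimals
because tie spans are re-averaged. Features missing from a platform are
dropped from joint analyses rather than imputed.

Hierarchical clustering is average linkage on euclidean or
1−correlation distances, with optional per-item median centering (the
classic expression heat-map preprocessing); average linkage guarantees
monotone merge heights, asserted in tests. Trees export to Newick with
branch lengths from merge-height differences.

## Enrichment and the ontology tree

Right-tail hypergeometric p-values are computed with the survival
function of the standard library distribution (log-space internally)
and verified against exact rational enumeration for every parameter
combination with N ≤ 25. The universe is the set of features *tested*
for DE, not the genome: enrichment should measure composition of the
significant list relative to what could have been called, and the
assayed universe is the defensible default. Terms with fewer than 2
universe genes are skipped (single-gene sets make degenerate "hits");
the floor is configurable. Up- and down-gene queries are tested and
BH-corrected separately, as the two directions are reported separately.
Pathway collections are just another GMT — no separate code path.

The ontology tree is the subgraph induced by the enriched terms plus
all their ancestors (child→parent edges), each node labelled up, down,
ambiguous (enriched in both directions) or ancestor-only. No
ancestry-aware p-value correction (elim/weight) is attempted.

## Target prediction and the network

Only the three canonical seed-site types are matched (8mer, 7mer-m8,
7mer-A1); 6mer sites are excluded by default as weak. Site coordinates
are 0-based half-open on the supplied sense-strand UTR. Overlapping
matches resolve to the strongest type — in particular, every 8mer
contains its own 7mer-A1 at offset 1, which is suppressed. Context
scoring (conservation, AU content, 3′ pairing) is out of scope: the
pipeline treats site presence as a binary gate and lets expression do
the ranking.

"Inverse correlation" between a miRNA and its predicted target is
operationalised as *opposite DE status*, not a per-sample correlation
coefficient: with 3 samples per group, sample-level correlations are
far too unstable to filter on, whereas opposite significant calls are
exactly the repressor signature the integration is after. Low-abundance
miRNAs are removed when their group-mean normalized count is below 100
in *both* groups (strict <, so 100 in either group survives); group
mean is the aggregate, as a per-sample reading would make the filter
depend on n. Core miRNAs are the top k = 15 per direction by fold
change (ties by smaller p, then id), k configurable. Every network
passes an internal audit that re-checks bipartiteness, inverse
directions on every edge, and (when sequences are supplied) re-scans
each edge's UTR for a site.

## Synthetic data

The generator emulates the study conditions the pipeline targets:
3 vs 3 replicates, NB counts at baseline mean 200 with dispersion 0.1,
20% of features differentially expressed at four-fold (split evenly
between directions), 21-nt miRNAs, 200-nt UTRs with one planted site
per regulatory pair, four cell types on two platforms, and a ~12-term
random rooted ontology DAG. Defaults were chosen once as a realistic
small clinical RNA-seq contrast; no public library-size or dispersion
estimates exist for the motivating data, so they aim at testability,
not at reproducing any particular accession.

Non-target UTRs are *guaranteed* site-free, not just unlikely to have
sites: UTRs are scrubbed by mutating single bases inside any canonical
site of any simulated miRNA until none remain (planted spans
protected). miRNA seeds are rejection-sampled so that no miRNA's site
pattern is a substring of another's, which keeps planted sites
unambiguous. Consequently target-prediction precision and recall on
synthetic data are exact, which is what makes the network recovery
tests sharp. Planted 7mer-m8 sites force a non-A right flank so they
cannot silently upgrade to 8mers.

What the generator does **not** emulate: read-level artefacts (adapter
trimming, alignment ambiguity, multimapping), per-sample library-size
variation beyond sampling noise, feature-specific baseline abundance in
the DE matrices (all features share the baseline mean, so fold-change
recovery is not confounded with abundance), correlated features, UTR
isoforms, and non-canonical or conserved-context target sites. Passing
tests therefore demonstrate correctness of the statistical machinery
under its own model assumptions — not robustness to the full messiness
of real sequencing data.

Determinism: every generator draws from a generator seeded by
(config.seed, stage-offset); identical configurations give bit-identical
outputs.

## Problem sizes used in checks

The standing verification suite uses 2000-feature null simulations and
1000-feature planted-effect simulations for calibration and power, the
default 60-miRNA/120-gene configuration for end-to-end network
recovery, exhaustive oracle grids for totals ≤ 50 (conditional test)
and N ≤ 25 (hypergeometric), and 100 random draws for the seed-site
scanner. These sizes give stable stochastic estimates (binomial SE of
the null exceedance fraction at 2000 features is ≈ 0.005) while keeping
the whole suite fast.

## Known limitations

* The DE stage is a documented simplification of the quantile-adjusted
  conditional ML / tagwise-shrinkage machinery of mature count-DE
  packages; p-values agree in spirit, not to the digit.
* The exact test enumerates all t+1 splits of the conditioned total;
  for extremely deep libraries (t ≫ 10⁶ per feature) this is slow and a
  normal approximation would be preferable.
* Quantile normalization with heavy ties (many zero counts) compresses
  the low tail; rank-based downstream steps are unaffected, but
  absolute normalized values at the bottom of the distribution carry
  little information.
* The specificity criteria expose thresholds (R, min_similar) that the
  underlying concept does not pin down; published specific-set sizes
  from comparable studies are not exactly recoverable without their
  original panel data, and the package does not claim to reproduce
  them.
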