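"""Normalization and two-group differential expression for count data.

The testing model is the classic exact negative-binomial strategy for
small replicated RNA-seq designs: libraries are rescaled by TMM (trimmed
mean of M-values), a common dispersion phi (Var = mu + phi * mu^2) is
estimated by method of moments on library-size-equalized counts, and each
feature is tested by conditioning on its total count across both groups
and asking how extreme the observed split is under the null NB
convolution. P-values are Benjamini-Hochberg adjusted and features are
classified up / down / not significant by joint fold-change and FDR
thresholds (defaults: fold >= 2 or <= 0.5 at FDR <= 0.01, thresholds
inclusive).

The object-oriented entry point is :class:`DifferentialExpression`, whose
``fit()`` returns a :class:`DEResults`; :func:`run_de` is the equivalent
functional surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom

from .matrix import CountMatrix, NormalizedMatrix

__all__ = [
    "DEConfig",
    "DERecord",
    "DifferentialExpression",
    "DEResults",
    "compute_tpm",
    "chromosome_distribution",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_nb_test",
    "bh_adjust",
    "classify_status",
    "normalize_status",
    "run_de",
    "UP",
    "DOWN",
    "NOT_SIGNIFICANT",
]

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"

_STATUS_ALIASES = {
    "up": UP,
    "up-regulated": UP,
    "upregulated": UP,
    "down": DOWN,
    "down-regulated": DOWN,
    "downregulated": DOWN,
    "not_significant": NOT_SIGNIFICANT,
    "not significant": NOT_SIGNIFICANT,
    "ns": NOT_SIGNIFICANT,
}


def normalize_status(label: str) -> str:
    """Map a free-form regulation label ('Up-regulated', 'NS', ...) to the
    canonical {up, down, not_significant}."""
    key = label.strip().lower()
    if key not in _STATUS_ALIASES:
        raise ValueError(f"unrecognised regulation status {label!r}")
    return _STATUS_ALIASES[key]


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and options for the DE classification.

    alpha is applied to the BH-adjusted p-value by default
    (``filter_on='fdr'``); set ``filter_on='p'`` to threshold the raw
    p-value instead. Small-RNA contrasts conventionally use alpha=0.01,
    mRNA contrasts 0.05. The pseudocount (normalized-count units) keeps
    fold changes finite when one group is all zero.
    """

    alpha: float = 0.01
    fc_up: float = 2.0
    fc_down: float = 0.5
    pseudocount: float = 0.5
    dispersion_mode: str = "estimate"  # or "fixed"
    dispersion: float = 0.0  # used when dispersion_mode == "fixed"
    filter_on: str = "fdr"  # or "p"
    numerator: str | None = None  # group on top of the fold change
    denominator: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_up <= 0 or self.fc_down <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.dispersion_mode not in ("estimate", "fixed"):
            raise ValueError("dispersion_mode must be 'estimate' or 'fixed'")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.filter_on not in ("fdr", "p"):
            raise ValueError("filter_on must be 'fdr' or 'p'")


@dataclass(frozen=True)
class DERecord:
    feature: str
    fold_change: float
    log2fc: float
    p_value: float
    fdr: float
    status: str


# ---------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------

def compute_tpm(
    matrix: CountMatrix, clean_totals: pd.Series | dict | None = None
) -> NormalizedMatrix:
    """Reads-per-million scaling against total clean reads.

    value[i, s] = counts[i, s] / clean_totals[s] * 1e6. When
    ``clean_totals`` is omitted the per-sample mapped totals are used
    (every clean read mapped). Column sums then equal
    (mapped total / clean total) * 1e6 and can never exceed 1e6.
    """
    mapped = matrix.library_sizes()
    if clean_totals is None:
        totals = mapped.astype(float)
    else:
        totals = pd.Series(clean_totals, dtype=float).reindex(matrix.samples)
        if totals.isna().any():
            missing = totals.index[totals.isna()].tolist()
            raise ValueError(f"clean totals missing for samples {missing}")
    if (totals <= 0).any():
        raise ValueError("clean totals must be positive for every sample")
    if (totals < mapped - 1e-9).any():
        bad = totals.index[(totals < mapped - 1e-9)].tolist()
        raise ValueError(
            f"clean totals below mapped read totals for samples {bad}"
        )
    values = matrix.data.div(totals, axis=1) * 1e6
    return NormalizedMatrix(
        values,
        groups=matrix.groups,
        feature_annotations=matrix.feature_annotations,
        normalization="tpm",
        clean_totals=totals,
    )


def chromosome_distribution(
    matrix: CountMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fraction of mapped reads on each chromosome, per sample.

    Requires ``feature_annotations['chromosome']``. Returns the
    chromosome x sample fraction table (columns sum to 1) and, when the
    matrix carries groups, the per-group average of those fractions.
    """
    ann = matrix.feature_annotations
    if ann is None or "chromosome" not in ann.columns:
        raise ValueError("matrix has no chromosome annotations")
    chrom = ann["chromosome"].reindex(matrix.data.index).dropna()
    if chrom.empty:
        raise ValueError("no features carry a chromosome annotation")
    counts = matrix.data.loc[chrom.index]
    per_chrom = counts.groupby(chrom).sum()
    totals = per_chrom.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero annotated reads: {bad}")
    frac = per_chrom.div(totals, axis=1)
    group_avg = None
    if matrix.groups is not None:
        group_avg = pd.DataFrame(
            {g: frac[matrix.samples_of(g)].mean(axis=1)
             for g in matrix.group_labels()}
        )
    return frac, group_avg


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (Robinson-Oshlack).

    The reference sample is the one whose 75th percentile of
    counts/library-size is closest to the mean such percentile. For each
    sample, log2 ratios M against the reference are doubly trimmed (30%
    on M, 5% on average abundance A) and averaged with inverse
    approximate-variance weights; factors are rescaled to unit geometric
    mean so that scale shared by all libraries is absorbed into library
    size.
    """
    data = matrix.data.to_numpy(dtype=float)
    if data.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    libsize = data.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("every sample needs a positive library size")
    props = data / libsize
    uq = np.array([np.quantile(props[:, j][data[:, j] > 0], 0.75)
                   if (data[:, j] > 0).any() else 0.0
                   for j in range(data.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(data.shape[1])
    xr, nr = data[:, ref], libsize[ref]
    for j in range(data.shape[1]):
        if j == ref:
            continue
        x, n = data[:, j], libsize[j]
        keep = (x > 0) & (xr > 0)
        if not keep.any():
            raise ValueError(
                f"sample {matrix.samples[j]!r} shares no expressed features "
                "with the TMM reference"
            )
        p, pr = x[keep] / n, xr[keep] / nr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        # asymptotic delta-method variance of M
        w = (n - x[keep]) / (n * x[keep]) + (nr - xr[keep]) / (nr * xr[keep])
        k = m.size
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        lo_m, hi_m = np.floor(k * trim_m), np.ceil(k * (1 - trim_m))
        lo_a, hi_a = np.floor(k * trim_a), np.ceil(k * (1 - trim_a))
        sel = (rank_m >= lo_m) & (rank_m < hi_m) & \
              (rank_a >= lo_a) & (rank_a < hi_a)
        if not sel.any():
            sel = np.ones(k, dtype=bool)
        wsel = 1.0 / w[sel]
        factors[j] = 2 ** (np.sum(wsel * m[sel]) / np.sum(wsel))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.samples, name="tmm_factor")


# ---------------------------------------------------------------------
# dispersion and the exact test
# ---------------------------------------------------------------------

def estimate_common_dispersion(
    matrix: CountMatrix,
    effective_libsize: pd.Series | None = None,
    min_mean: float = 1.0,
) -> float:
    """Method-of-moments common dispersion on equalized libraries.

    Counts are rescaled to a common (geometric-mean) effective library
    size; within each replicated group the relation Var = mu + phi*mu^2
    gives per-feature moment equations that are pooled as
    phi_hat = sum(v - m) / sum(m^2 - v/n), clamped at zero. The
    denominator correction (- v/n) removes the upward bias of m^2 as an
    estimate of mu^2 at small n.
    """
    if matrix.groups is None:
        raise ValueError("dispersion estimation needs group metadata")
    sizes = (
        matrix.library_sizes().astype(float)
        if effective_libsize is None
        else pd.Series(effective_libsize, dtype=float).reindex(matrix.samples)
    )
    common = np.exp(np.mean(np.log(sizes)))
    eq = matrix.data.mul(common / sizes, axis=1)

    num = 0.0
    den = 0.0
    any_replicated = False
    for g in matrix.group_labels():
        cols = matrix.samples_of(g)
        n = len(cols)
        if n < 2:
            continue
        any_replicated = True
        sub = eq[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m >= min_mean
        num += float(np.sum(v[keep] - m[keep]))
        den += float(np.sum(m[keep] ** 2 - v[keep] / n))
    if not any_replicated:
        raise ValueError(
            "no group has >=2 replicates; use dispersion_mode='fixed'"
        )
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def exact_nb_test(
    count_a: float,
    count_b: float,
    size_a: float,
    size_b: float,
    dispersion: float,
    n_a: int = 1,
    n_b: int = 1,
) -> float:
    """Two-sided conditional exact test for a two-group count split.

    Conditions on the total t = count_a + count_b. Under the null the
    group sums are NB with means proportional to the effective library
    sizes; the group sum of n replicates with per-sample dispersion phi
    has dispersion phi/n. The two-sided p-value sums the probabilities of
    every split (k, t-k) no more likely than the observed one
    (minimum-likelihood method), capped at 1. phi = 0 reduces exactly to
    the conditional binomial (Poisson) test.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if size_a <= 0 or size_b <= 0:
        raise ValueError("effective library sizes must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    a = int(round(count_a))
    t = int(round(count_a + count_b))
    if t == 0:
        return 1.0
    p_a = size_a / (size_a + size_b)
    k = np.arange(t + 1)
    if dispersion < 1e-12:  # Poisson limit; avoids overflow of n/phi
        logp = binom.logpmf(k, t, p_a)
    else:
        mu_a = t * p_a
        mu_b = t - mu_a
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        logp = (
            nbinom.logpmf(k, r_a, r_a / (r_a + mu_a))
            + nbinom.logpmf(t - k, r_b, r_b / (r_b + mu_b))
        )
        logp -= logsumexp(logp)
    obs = logp[a]
    tail = logp[logp <= obs + 1e-10]
    return float(min(np.exp(logsumexp(tail)), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def classify_status(fold_change: float, stat: float, config: DEConfig) -> str:
    """Joint fold/significance call; thresholds are inclusive."""
    if stat <= config.alpha:
        if fold_change >= config.fc_up:
            return UP
        if fold_change <= config.fc_down:
            return DOWN
    return NOT_SIGNIFICANT


# ---------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------

class DifferentialExpression:
    """Two-group exact NB differential-expression model.

    Parameters
    ----------
    counts
        Raw count matrix with exactly two groups in its metadata.
    config
        Thresholds and options; defaults to :class:`DEConfig()`.

    Examples
    --------
    >>> model = DifferentialExpression(counts, DEConfig(alpha=0.01))
    >>> res = model.fit()
    >>> res.summary()  # doctest: +SKIP
    """

    def __init__(self, counts: CountMatrix, config: DEConfig | None = None):
        if counts.groups is None:
            raise ValueError("count matrix needs sample -> group metadata")
        labels = counts.group_labels()
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, found {labels}")
        self.counts = counts
        self.config = config or DEConfig()
        num = self.config.numerator or labels[0]
        den = self.config.denominator or (
            labels[1] if num == labels[0] else labels[0]
        )
        if {num, den} != set(labels):
            raise ValueError(
                f"numerator/denominator {num, den} do not match groups {labels}"
            )
        self.group_a, self.group_b = num, den

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        groups: dict[str, str],
        config: DEConfig | None = None,
    ) -> "DifferentialExpression":
        return cls(CountMatrix(data, groups=groups), config)

    def fit(self) -> "DEResults":
        cfg = self.config
        mat = self.counts
        cols_a = mat.samples_of(self.group_a)
        cols_b = mat.samples_of(self.group_b)
        if not cols_a or not cols_b:
            raise ValueError("each group needs at least one sample")

        factors = tmm_factors(mat)
        eff = mat.library_sizes().astype(float) * factors
        if cfg.dispersion_mode == "fixed":
            phi = cfg.dispersion
        else:
            phi = estimate_common_dispersion(mat, effective_libsize=eff)

        a_counts = mat.data[cols_a].sum(axis=1).to_numpy()
        b_counts = mat.data[cols_b].sum(axis=1).to_numpy()
        size_a = float(eff[cols_a].sum())
        size_b = float(eff[cols_b].sum())
        pvals = np.array([
            exact_nb_test(a, b, size_a, size_b, phi,
                          n_a=len(cols_a), n_b=len(cols_b))
            for a, b in zip(a_counts, b_counts)
        ])
        fdr = bh_adjust(pvals)

        # fold changes on effective-library CPM with a pseudocount
        cpm = mat.data.div(eff, axis=1) * 1e6
        mean_a = cpm[cols_a].mean(axis=1).to_numpy()
        mean_b = cpm[cols_b].mean(axis=1).to_numpy()
        fold = (mean_a + cfg.pseudocount) / (mean_b + cfg.pseudocount)
        log2fc = np.log2(fold)

        stat = fdr if cfg.filter_on == "fdr" else pvals
        records = [
            DERecord(
                feature=f,
                fold_change=float(fc),
                log2fc=float(lfc),
                p_value=float(p),
                fdr=float(q),
                status=classify_status(float(fc), float(s), cfg),
            )
            for f, fc, lfc, p, q, s in zip(
                mat.features, fold, log2fc, pvals, fdr, stat
            )
        ]
        normalized = NormalizedMatrix(
            cpm, groups=mat.groups,
            feature_annotations=mat.feature_annotations,
            normalization="tmm", clean_totals=None,
        )
        return DEResults(
            model=self,
            records=records,
            dispersion=phi,
            tmm=factors,
            effective_libsize=eff,
            normalized=normalized,
        )


@dataclass
class DEResults:
    """Fitted differential-expression results.

    Carries one :class:`DERecord` per feature (fold change =
    numerator-group over denominator-group mean of TMM-scaled CPM, with
    pseudocount), the common dispersion estimate, TMM factors and the
    normalized matrix used for fold changes.
    """

    model: DifferentialExpression
    records: list[DERecord]
    dispersion: float
    tmm: pd.Series
    effective_libsize: pd.Series
    normalized: NormalizedMatrix

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.feature, r.fold_change, r.log2fc, r.p_value, r.fdr, r.status)
                for r in self.records
            ],
            columns=["feature", "fold_change", "log2fc", "p_value", "fdr",
                     "status"],
        ).set_index("feature")

    def features_with_status(self, status: str) -> set[str]:
        return {r.feature for r in self.records if r.status == status}

    @property
    def n_up(self) -> int:
        return len(self.features_with_status(UP))

    @property
    def n_down(self) -> int:
        return len(self.features_with_status(DOWN))

    def summary(self, top: int = 10) -> str:
        cfg = self.model.config
        df = self.frame.sort_values("p_value")
        lines = [
            "Differential expression (conditional exact NB test)",
            "=" * 55,
            f"contrast:        {self.model.group_a} / {self.model.group_b}",
            f"features tested: {len(self.records)}",
            f"common dispersion phi: {self.dispersion:.4f}",
            f"thresholds: fold >= {cfg.fc_up} or <= {cfg.fc_down}, "
            f"{cfg.filter_on} <= {cfg.alpha}",
            f"up-regulated:    {self.n_up}",
            f"down-regulated:  {self.n_down}",
            "",
            df.head(top).to_string(
                float_format=lambda v: f"{v:.3g}"
            ),
        ]
        return "\n".join(lines)


def run_de(matrix: CountMatrix, config: DEConfig | None = None) -> list[DERecord]:
    """Functional one-shot surface over :class:`DifferentialExpression`."""
    return DifferentialExpression(matrix, config).fit().records
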