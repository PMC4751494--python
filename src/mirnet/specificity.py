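"""Cross-cell-type specificity analysis.

A condition's differentially expressed miRNAs are only informative if
they are not simply a signature of some related cell state (e.g. the
osteogenic differentiation of mesenchymal stem cells, for an ossification
phenotype). This module harmonizes expression panels from different
platforms by quantile normalization, clusters them, builds per-sample
rank-abundance profiles (share of total miRNA expression, ranked from the
most abundant down), and classifies DE features as condition-specific
when they neither overlap directionally with another contrast nor keep a
similar abundance rank in other cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .de import DOWN, UP, normalize_status

__all__ = [
    "RankProfile",
    "OverlapReport",
    "SpecificityCriteria",
    "Dendrogram",
    "quantile_normalize",
    "hierarchical_cluster",
    "abundance_rank_profile",
    "topk_share",
    "compare_rank_profiles",
    "directional_overlap",
    "define_specific_set",
    "apply_alias_map",
]


# ---------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------

def quantile_normalize(
    panel: pd.DataFrame | Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Classic quantile normalization across all columns of a panel.

    Multiple matrices are first joined on their shared feature ids (an
    exact-id join; apply :func:`apply_alias_map` beforehand if ids need
    harmonizing). Every column is then forced onto the common
    distribution of across-column order-statistic means; tied values
    receive the mean of the quantile means their span covers, so the
    result is deterministic and idempotent.
    """
    frames = [panel] if isinstance(panel, pd.DataFrame) else list(panel)
    if not frames:
        raise ValueError("empty panel")
    shared = reduce(lambda a, b: a.intersection(b), (f.index for f in frames))
    if len(shared) == 0:
        raise ValueError("panels share no feature ids")
    shared = sorted(shared)
    parts = []
    for i, f in enumerate(frames):
        part = f.loc[shared]
        if len(frames) > 1:
            part = part.add_prefix(f"p{i}:") if _dup_cols(frames) else part
        parts.append(part)
    joined = pd.concat(parts, axis=1).astype(float)
    if joined.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 columns")

    values = joined.to_numpy()
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = mean_sorted
        # ties: average the quantile means spanned by each tied value
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=joined.index, columns=joined.columns)


def _dup_cols(frames: Sequence[pd.DataFrame]) -> bool:
    seen: set[str] = set()
    for f in frames:
        for c in f.columns:
            if c in seen:
                return True
            seen.add(c)
    return False


def apply_alias_map(df: pd.DataFrame, alias: Mapping[str, str]) -> pd.DataFrame:
    """Rename feature ids by an old_id -> new_id alias table (e.g. to
    bring several miRNA annotation releases onto one naming); unmapped
    ids are kept. Collisions after mapping raise."""
    renamed = df.rename(index=lambda f: alias.get(f, f))
    if renamed.index.has_duplicates:
        dups = renamed.index[renamed.index.duplicated()].unique().tolist()
        raise ValueError(f"alias mapping collides on ids {dups[:5]}")
    return renamed


# ---------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------

@dataclass
class Dendrogram:
    """An average-linkage tree over items (features or samples)."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def has_inversions(self) -> bool:
        h = self.heights
        return bool(np.any(np.diff(h) < -1e-10))

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = sch.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "samples",
    center: str = "none",
    metric: str = "euclidean",
) -> Dendrogram:
    """Average-linkage agglomerative clustering.

    ``axis`` picks whether rows ('features') or columns ('samples') are
    clustered; ``center='median'`` subtracts each item's median first
    (the classic gene-expression heat-map preprocessing). Rows with
    missing values are excluded before clustering. Average linkage has
    no height inversions, so the returned tree's merge heights are
    non-decreasing.
    """
    if axis not in ("features", "samples"):
        raise ValueError("axis must be 'features' or 'samples'")
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    if center not in ("none", "median"):
        raise ValueError("center must be 'none' or 'median'")
    df = matrix.dropna(axis=0)
    items = df if axis == "features" else df.T
    if items.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    values = items.to_numpy(dtype=float)
    if center == "median":
        values = values - np.median(values, axis=1, keepdims=True)
    z = sch.linkage(pdist(values, metric=metric), method="average")
    return Dendrogram(z, [str(i) for i in items.index])


def median_center(df: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's median (utility mirroring the clustering
    preprocessing)."""
    return df.sub(df.median(axis=1), axis=0)


# ---------------------------------------------------------------------
# rank-abundance profiles
# ---------------------------------------------------------------------

@dataclass
class RankProfile:
    """Descending abundance shares for one sample or cell type.

    ``entries`` holds (feature, share of total abundance) sorted by
    decreasing share, ties broken lexicographically by feature id;
    ``ranks`` maps feature -> 1-based rank in that order.
    """

    id: str
    entries: list[tuple[str, float]]
    ranks: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.ranks = {f: i + 1 for i, (f, _) in enumerate(self.entries)}

    @property
    def shares(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


def abundance_rank_profile(column: pd.Series, id: str | None = None) -> RankProfile:
    """Profile a single sample/cell type: share of total abundance per
    feature, ranked from the most abundant down."""
    total = float(column.sum())
    if total <= 0:
        raise ValueError("column has no positive abundance")
    if (column < 0).any():
        raise ValueError("abundances must be non-negative")
    shares = (column / total).sort_index()
    ordered = sorted(shares.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankProfile(id or str(column.name), ordered)


def topk_share(profile: RankProfile, k: int) -> float:
    """Cumulative share of the k most abundant features (e.g. the top
    dozen miRNAs of a ligament-cell profile carrying ~80% of all miRNA
    reads)."""
    if not 1 <= k <= len(profile):
        raise ValueError(f"k must lie in [1, {len(profile)}]")
    return float(profile.shares[:k].sum())


def compare_rank_profiles(
    profile_a: RankProfile, profile_b: RankProfile, window: int = 10
) -> pd.DataFrame:
    """Per-feature rank shift between two profiles.

    Restricted to the shared feature universe; a feature is 'similar'
    when |rank_a - rank_b| <= window.
    """
    common = sorted(set(profile_a.ranks) & set(profile_b.ranks))
    if not common:
        raise ValueError("profiles share no features")
    rows = []
    for f in common:
        ra, rb = profile_a.ranks[f], profile_b.ranks[f]
        shift = abs(ra - rb)
        rows.append((f, ra, rb, shift, shift <= window))
    return pd.DataFrame(
        rows, columns=["feature", "rank_a", "rank_b", "shift", "similar"]
    ).set_index("feature")


# ---------------------------------------------------------------------
# directional overlap and the specific set
# ---------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Directional DE overlap between a primary and a comparison
    contrast (the two-circle Venn, split by direction)."""

    up_overlap: frozenset[str]
    down_overlap: frozenset[str]
    specific_up: frozenset[str]
    specific_down: frozenset[str]

    @property
    def n_up_overlap(self) -> int:
        return len(self.up_overlap)

    @property
    def n_down_overlap(self) -> int:
        return len(self.down_overlap)

    @property
    def overlapping(self) -> frozenset[str]:
        return self.up_overlap | self.down_overlap


def _status_sets(de) -> tuple[set[str], set[str]]:
    if isinstance(de, Mapping):
        items = [(f, normalize_status(s)) for f, s in de.items()]
    else:
        items = [(r.feature, r.status) for r in de]
    up = {f for f, s in items if s == UP}
    down = {f for f, s in items if s == DOWN}
    return up, down


def directional_overlap(de_a, de_b) -> OverlapReport:
    """Same-direction DE intersection of two contrasts.

    Accepts lists of DE records or feature -> status mappings (labels
    like 'Up-regulated' are normalized). The 'specific' sets are the
    primary contrast's DE features that do not overlap directionally.
    """
    up_a, down_a = _status_sets(de_a)
    up_b, down_b = _status_sets(de_b)
    up_overlap = up_a & up_b
    down_overlap = down_a & down_b
    return OverlapReport(
        up_overlap=frozenset(up_overlap),
        down_overlap=frozenset(down_overlap),
        specific_up=frozenset(up_a - up_overlap),
        specific_down=frozenset(down_a - down_overlap),
    )


@dataclass(frozen=True)
class SpecificityCriteria:
    """window: rank-distance threshold for 'similar rank place';
    min_similar: drop a DE feature that is rank-similar in at least this
    many other cell types (None disables the rank criterion)."""

    window: int = 10
    min_similar: int | None = None


def define_specific_set(
    de,
    overlaps: Iterable[OverlapReport] = (),
    rank_reports: Iterable[pd.DataFrame] = (),
    criteria: SpecificityCriteria = SpecificityCriteria(),
) -> set[str]:
    """Condition-specific DE features.

    Starts from all DE features of the primary contrast, removes any
    that overlap directionally in ANY comparison contrast, and (when
    ``criteria.min_similar`` is set) any that keep a similar abundance
    rank in at least that many other cell types.
    """
    up, down = _status_sets(de)
    specific = up | down
    for rep in overlaps:
        specific -= rep.overlapping
    if criteria.min_similar is not None:
        similar_counts: dict[str, int] = {}
        for rep in rank_reports:
            sim = rep.index[rep["similar"]]
            for f in sim:
                similar_counts[f] = similar_counts.get(f, 0) + 1
        specific -= {
            f for f, c in similar_counts.items() if c >= criteria.min_similar
        }
    return specific
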