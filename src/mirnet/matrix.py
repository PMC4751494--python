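"""Core in-memory containers for expression matrices.

The whole pipeline operates on a feature x sample count matrix with a
sample -> group map (here the condition contrast is OPLL vs PLL: ossified
vs normal posterior longitudinal ligament primary cells, n = 3 per group,
but nothing is specific to that study design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "NormalizedMatrix", "FormatError"]


class FormatError(ValueError):
    """Malformed external input (duplicate ids, negative counts, ...)."""


@dataclass
class CountMatrix:
    """Feature x sample expression matrix with sample grouping.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample.
        Raw matrices hold non-negative integers; normalized matrices
        (see :class:`NormalizedMatrix`) hold non-negative reals.
    groups
        Optional map sample id -> group label. Required for any
        group-wise operation (differential testing, group means).
    feature_annotations
        Optional DataFrame indexed by feature id; recognised columns are
        ``chromosome`` and ``symbol``.
    """

    data: pd.DataFrame
    groups: dict[str, str] | None = None
    feature_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self, require_int: bool = False) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if vals.size and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if require_int and vals.size and not np.allclose(vals, np.round(vals)):
            raise FormatError("raw counts must be integers")
        if self.groups is not None:
            missing = [s for s in cols if s not in self.groups]
            if missing:
                raise FormatError(f"samples without group label: {missing}")

    # -- convenience ---------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-sample order."""
        if self.groups is None:
            raise ValueError("matrix has no group metadata")
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("matrix has no group metadata")
        return [s for s in self.samples if self.groups[s] == group]

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def group_means(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-feature mean over the samples of each group."""
        vals = self.data if values is None else values
        return pd.DataFrame(
            {g: vals[self.samples_of(g)].mean(axis=1) for g in self.group_labels()}
        )


@dataclass
class NormalizedMatrix(CountMatrix):
    """A :class:`CountMatrix` after normalization.

    ``normalization`` records the method ('tpm' or 'tmm'); ``clean_totals``
    holds the per-sample total clean-read counts used for TPM scaling.
    """

    normalization: str = "tpm"
    clean_totals: pd.Series | None = None
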