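"""Trimmed-column-mean normalization of expression count matrices.

Samples are equalized so that the trimmed mean (discarding the lowest and
highest 5% of values by rank) of the non-mitochondrial genes is the same in
every column. Mitochondrially encoded transcripts are excluded from the size
factors but are scaled by them, i.e. they are normalized *to* the trimmed mean
of the nuclear transcripts rather than contributing to it — mtDNA transcripts
are so abundant that letting them into the trim window would let a handful of
genes drive the factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TRIM_FRACTION = 0.05


@dataclass
class CountMatrix:
    """Genes-by-samples expression matrix with a per-gene mitochondrial flag.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``is_mito`` is a boolean Series on the same gene index.
    """

    values: pd.DataFrame
    is_mito: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < 0).any():
            r, c = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        self.is_mito = self.is_mito.reindex(self.values.index)
        if self.is_mito.isna().any():
            missing = self.is_mito.index[self.is_mito.isna()].tolist()
            raise ValueError(f"is_mito flag missing for genes: {missing[:5]}")
        self.is_mito = self.is_mito.astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class NormalizedMatrix:
    """Scaled matrix plus the per-sample size factors that produced it."""

    values: pd.DataFrame
    is_mito: pd.Series
    size_factors: pd.Series
    trim_fraction: float
    target: float = field(default=float("nan"))


def trimmed_mean(values, trim_fraction: float = DEFAULT_TRIM_FRACTION) -> float:
    """Mean after dropping ``floor(trim_fraction * n)`` values from each end.

    Values are ranked (ties kept in sorted order, zeros participate), so the
    trim is by count rank, not by value percentile.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("trimmed_mean expects a 1-D sequence")
    n = x.size
    if n == 0:
        raise ValueError("trimmed_mean of empty sequence")
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    k = math.floor(trim_fraction * n)
    xs = np.sort(x)
    return float(xs[k : n - k].mean())


def compute_size_factors(
    matrix: CountMatrix, trim_fraction: float = DEFAULT_TRIM_FRACTION
) -> pd.Series:
    """Per-sample multiplicative factors equalizing non-mito trimmed means.

    ``factor_s = target / trimmed_mean(column s over non-mito genes)`` with
    ``target`` the across-sample mean of the per-sample trimmed means, so
    multiplying each column by its factor makes all trimmed means equal.
    """
    nonmito = matrix.values.loc[~matrix.is_mito]
    if nonmito.shape[0] == 0:
        raise ValueError("no non-mitochondrial genes to normalize against")
    tms = nonmito.apply(lambda col: trimmed_mean(col.to_numpy(), trim_fraction), axis=0)
    zero = tms.index[tms == 0].tolist()
    if zero:
        raise ValueError(f"trimmed mean is zero for samples: {zero}")
    target = float(tms.mean())
    factors = target / tms
    factors.name = "size_factor"
    return factors


def normalize(
    matrix: CountMatrix, trim_fraction: float = DEFAULT_TRIM_FRACTION
) -> NormalizedMatrix:
    """Scale every row (mitochondrial included) by non-mito-derived factors."""
    if matrix.is_mito.all():
        raise ValueError("all genes are flagged mitochondrial; nothing to normalize to")
    factors = compute_size_factors(matrix, trim_fraction)
    nonmito = matrix.values.loc[~matrix.is_mito]
    target = float(
        nonmito.apply(lambda col: trimmed_mean(col.to_numpy(), trim_fraction), axis=0).mean()
    )
    scaled = matrix.values.mul(factors, axis=1)
    return NormalizedMatrix(
        values=scaled,
        is_mito=matrix.is_mito.copy(),
        size_factors=factors,
        trim_fraction=trim_fraction,
        target=target,
    )
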