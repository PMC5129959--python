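"""Count normalization for mixed-biotype small/large RNA expression matrices.

The analysis works on the log-CPM scale, ``log2((count + 0.5) / millions of
library reads)``, after removing features with insufficient read support and
flattening intensity-dependent between-sample biases with cyclic loess.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

BIOTYPES = ("coding", "lncRNA", "miRNA", "piRNA", "snRNA", "snoRNA")

#: matrix scale states, in pipeline order
SCALE_RAW = "raw"
SCALE_LOG_CPM = "log_cpm"
SCALE_LOESS = "loess_normalized"


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with per-feature biotypes.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids. Raw
        matrices hold non-negative integer read counts.
    biotype
        Series mapping each feature id to one of :data:`BIOTYPES`.
    lib_sizes
        Total library read count per sample. Computed from the column sums
        at construction when omitted, and deliberately carried unchanged
        through feature filtering so that CPM always refers to the full
        library depth.
    scale
        One of ``raw``, ``log_cpm`` or ``loess_normalized``.
    """

    values: pd.DataFrame
    biotype: pd.Series
    lib_sizes: pd.Series = None
    scale: str = SCALE_RAW

    def __post_init__(self) -> None:
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()].tolist()
            raise ValueError(f"features without biotype annotation: {missing[:5]}")
        unknown = set(self.biotype.unique()) - set(BIOTYPES)
        if unknown:
            raise ValueError(f"unknown biotypes: {sorted(unknown)}")
        if self.lib_sizes is None:
            if self.scale != SCALE_RAW:
                raise ValueError("lib_sizes required for non-raw matrices")
            self.lib_sizes = self.values.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, dtype=float).reindex(
                self.values.columns
            )
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if self.scale == SCALE_RAW and (self.values.values < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_biotype(self, *biotypes: str) -> "ExpressionMatrix":
        keep = self.biotype.isin(biotypes)
        return replace(
            self, values=self.values.loc[keep], biotype=self.biotype.loc[keep]
        )

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "biotype", self.biotype)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path, scale: str = SCALE_RAW, lib_sizes=None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        biotype = df.pop("biotype")
        return cls(values=df, biotype=biotype, lib_sizes=lib_sizes, scale=scale)


def log_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transform raw counts to log2 counts-per-million with a 0.5 offset.

    value' = log2((count + 0.5) / (lib_size / 1e6)). Library sizes are the
    per-sample totals recorded on the matrix, so the transform is invariant
    to jointly rescaling counts and library sizes.
    """
    if matrix.scale != SCALE_RAW:
        raise ValueError(f"log_cpm expects a raw matrix, got scale={matrix.scale!r}")
    per_million = matrix.lib_sizes / 1e6
    out = np.log2((matrix.values + 0.5).divide(per_million, axis=1))
    return replace(matrix, values=out, scale=SCALE_LOG_CPM)


def _ma_loess_adjust(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Loess trend of M = x - y against A = (x + y)/2, evaluated per feature."""
    m = x - y
    a = 0.5 * (x + y)
    fitted = lowess(
        m, a, frac=span, it=2, return_sorted=False, delta=0.005 * np.ptp(a)
    )
    return fitted


def cyclic_loess_normalize(
    matrix: ExpressionMatrix, span: float = 0.7, cycles: int = 3
) -> ExpressionMatrix:
    """Pairwise cyclic loess normalization of a log-CPM matrix.

    For every ordered sample pair an M-versus-A loess trend is estimated and
    half of it is subtracted from one member and added to the other, so a
    pair of identical samples is left untouched. The full sweep over pairs is
    repeated ``cycles`` times.
    """
    if matrix.scale != SCALE_LOG_CPM:
        raise ValueError("cyclic loess operates on the log_cpm scale")
    vals = matrix.values.to_numpy(dtype=float).copy()
    n = vals.shape[1]
    if n < 2:
        raise ValueError("cyclic loess needs at least 2 samples")
    for _ in range(cycles):
        for i in range(n - 1):
            for j in range(i + 1, n):
                trend = _ma_loess_adjust(vals[:, i], vals[:, j], span)
                vals[:, i] -= trend / 2.0
                vals[:, j] += trend / 2.0
    out = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=out, scale=SCALE_LOESS)


def filter_min_reads(matrix: ExpressionMatrix, threshold: int = 100) -> ExpressionMatrix:
    """Keep features with strictly more than ``threshold`` reads summed over all samples.

    The default reproduces the ">100 supporting reads among all samples"
    inclusion rule; a feature whose row sum equals the threshold is removed.
    Library sizes are preserved.
    """
    if matrix.scale != SCALE_RAW:
        raise ValueError("read-support filtering applies to raw counts")
    keep = matrix.values.sum(axis=1) > threshold
    return replace(
        matrix, values=matrix.values.loc[keep], biotype=matrix.biotype.loc[keep]
    )


def collapse_features(
    matrix: ExpressionMatrix, collapse_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Sum raw counts of features mapped to the same group (isomiR collapsing).

    Every feature must be mapped; group ids become the new feature ids. All
    features collapsed together must share a biotype.
    """
    if matrix.scale != SCALE_RAW:
        raise ValueError("collapsing applies to raw counts")
    missing = [f for f in matrix.feature_ids if f not in collapse_map]
    if missing:
        raise ValueError(f"collapse_map missing features: {missing[:5]}")
    groups = pd.Series(
        [collapse_map[f] for f in matrix.feature_ids], index=matrix.feature_ids
    )
    collapsed = matrix.values.groupby(groups).sum()
    biotype = matrix.biotype.groupby(groups).agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else None
    )
    if biotype.isna().any():
        bad = biotype.index[biotype.isna()].tolist()
        raise ValueError(f"collapse groups mixing biotypes: {bad[:5]}")
    return replace(matrix, values=collapsed, biotype=biotype)
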