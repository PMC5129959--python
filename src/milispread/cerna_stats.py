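"""Global competing-endogenous-RNA (ceRNA) network statistics.

The ceRNA hypothesis: circRNAs, lncRNAs and mRNAs mutually titrate shared
miRNAs away from their targets, so the bulk abundance of the long RNA classes
relative to miRNAs indexes how much regulatory miRNA activity remains
unbound. This module computes per-sample class-abundance statistics — the
circRNA index (back-splice events over all splice events), the lncRNA/coding
median-expression ratio, and miRNA totals normalized to snRNA or snoRNA — and
compares them between the miliary and non-miliary spread types with Student's
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import SCALE_LOESS, SCALE_LOG_CPM, SCALE_RAW, ExpressionMatrix

SOLID_ORIGINS = ("P", "M")
ASCITES_ORIGINS = ("A", "S")


@dataclass
class SpliceJunctionCounts:
    """Per-sample totals of back-splice and linear splice-junction events."""

    counts: pd.DataFrame  # index: sample_id; columns: back_splice_events, linear_splice_events

    def __post_init__(self) -> None:
        needed = {"back_splice_events", "linear_splice_events"}
        if not needed <= set(self.counts.columns):
            raise ValueError(f"junction table needs columns {sorted(needed)}")
        if (self.counts[list(needed)] < 0).any().any():
            raise ValueError("junction event counts must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "SpliceJunctionCounts":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


def circ_index(junctions: SpliceJunctionCounts) -> pd.Series:
    """Back-splice events divided by all (back + linear) splice events, per sample."""
    back = junctions.counts["back_splice_events"].astype(float)
    linear = junctions.counts["linear_splice_events"].astype(float)
    total = back + linear
    if (total <= 0).any():
        bad = total.index[total <= 0].tolist()
        raise ValueError(f"samples without splice events: {bad[:5]}")
    return (back / total).rename("circ_index")


def nc_coding_ratio(matrix: ExpressionMatrix, linear_scale: bool = True) -> pd.Series:
    """Per-sample ratio of median lncRNA to median coding-RNA expression.

    Medians are taken on the linear (2**log) scale by default so that the
    ratio reads as an abundance ratio; set ``linear_scale=False`` to use the
    log-scale medians directly.
    """
    if matrix.scale not in (SCALE_LOG_CPM, SCALE_LOESS):
        raise ValueError("nc_coding_ratio expects normalized log expression")
    for bt in ("lncRNA", "coding"):
        if not (matrix.biotype == bt).any():
            raise ValueError(f"no {bt} features in matrix")
    lnc = matrix.values.loc[matrix.biotype == "lncRNA"]
    cod = matrix.values.loc[matrix.biotype == "coding"]
    if linear_scale:
        lnc, cod = 2.0**lnc, 2.0**cod
    return (lnc.median(axis=0) / cod.median(axis=0)).rename("nc_coding_ratio")


def mir_abundance_ratios(matrix: ExpressionMatrix) -> pd.DataFrame:
    """miRNA totals and miRNA/long-RNA ratios normalized to snRNA or snoRNA.

    Operates on raw counts. Long linear RNA = coding + lncRNA (circRNAs are
    junction-level objects and do not enter the count matrix). All four
    ratios are invariant to global per-sample scaling; the miRNA/long-RNA
    ratio is algebraically identical under the two normalizers whenever both
    are positive, and both are still reported as in the source analysis.
    """
    if matrix.scale != SCALE_RAW:
        raise ValueError("abundance ratios are computed from raw counts")
    totals = {
        bt: matrix.values.loc[matrix.biotype == bt].sum(axis=0).astype(float)
        for bt in ("miRNA", "snRNA", "snoRNA", "coding", "lncRNA")
    }
    for norm in ("snRNA", "snoRNA"):
        if not (matrix.biotype == norm).any():
            raise ValueError(f"no {norm} features in matrix")
        if (totals[norm] <= 0).any():
            raise ValueError(f"zero total {norm} counts in some sample")
    long_linear = totals["coding"] + totals["lncRNA"]
    mir_sn = totals["miRNA"] / totals["snRNA"]
    mir_sno = totals["miRNA"] / totals["snoRNA"]
    return pd.DataFrame(
        {
            "mir_sn_ratio": mir_sn,
            "mir_sno_ratio": mir_sno,
            "mir_long_ratio_sn": mir_sn / (long_linear / totals["snRNA"]),
            "mir_long_ratio_sno": mir_sno / (long_linear / totals["snoRNA"]),
        }
    )


def compare_groups(
    values: pd.Series, groups: Mapping[str, str]
) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance, two-sided).

    ``groups`` maps sample id to a label; exactly two labels are required.
    Returns (t, p) with t computed for the first label minus the second, in
    sorted label order.
    """
    labels = pd.Series({s: groups[s] for s in values.index})
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 group labels, got {uniq}")
    a = values[labels == uniq[0]].to_numpy(dtype=float)
    b = values[labels == uniq[1]].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def mean_expression_by_spread(
    matrix: ExpressionMatrix, annotations: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene mean expression by tissue class and spread type, with paired tests.

    ``annotations`` must carry ``tissue_origin`` (P/M/A/S) and ``spread_type``
    (miliary/non_miliary) per sample. For each gene, expression is averaged
    over the samples of one tissue class (solid = P+M, ascites = A+S) and one
    spread type. For each tissue class and biotype (coding, lncRNA) a paired
    two-sided t-test across genes compares non-miliary minus miliary means.

    Returns (means, comparisons): ``means`` has one row per gene, tissue
    class and spread type; ``comparisons`` one row per tissue class and
    biotype with mean_diff, t and p.
    """
    if matrix.scale not in (SCALE_LOG_CPM, SCALE_LOESS):
        raise ValueError("expects normalized log expression")
    ann = annotations.loc[list(matrix.sample_ids)]
    tissue_class = ann["tissue_origin"].map(
        {**{o: "solid" for o in SOLID_ORIGINS}, **{o: "ascites" for o in ASCITES_ORIGINS}}
    )
    rows = []
    mean_frames = {}
    for tclass in ("solid", "ascites"):
        for spread in ("miliary", "non_miliary"):
            cols = matrix.sample_ids[
                (tissue_class == tclass) & (ann["spread_type"] == spread)
            ]
            if len(cols) == 0:
                raise ValueError(f"no samples for {tclass}/{spread}")
            mean_frames[(tclass, spread)] = matrix.values[cols].mean(axis=1)
    means = pd.concat(
        [
            pd.DataFrame(
                {
                    "feature_id": s.index,
                    "tissue_class": tclass,
                    "spread_type": spread,
                    "mean_expression": s.values,
                }
            )
            for (tclass, spread), s in mean_frames.items()
        ],
        ignore_index=True,
    )
    for tclass in ("solid", "ascites"):
        diff = mean_frames[(tclass, "non_miliary")] - mean_frames[(tclass, "miliary")]
        for bt in ("coding", "lncRNA"):
            d = diff[matrix.biotype == bt]
            if len(d) < 2:
                raise ValueError(f"not enough {bt} features for paired test")
            t, p = stats.ttest_1samp(d, 0.0)
            rows.append(
                {
                    "tissue_class": tclass,
                    "biotype": bt,
                    "mean_diff": float(d.mean()),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return means, pd.DataFrame(rows)


def cerna_sample_stats(
    matrix_raw: ExpressionMatrix,
    matrix_norm: ExpressionMatrix,
    junctions: SpliceJunctionCounts,
) -> pd.DataFrame:
    """Assemble the per-sample ceRNA statistics table."""
    out = mir_abundance_ratios(matrix_raw)
    out.insert(0, "circ_index", circ_index(junctions).reindex(out.index))
    out.insert(1, "nc_coding_ratio", nc_coding_ratio(matrix_norm).reindex(out.index))
    return out
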