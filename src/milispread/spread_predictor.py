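"""The 13 small-RNA tumor-spread predictor.

A deliberately simple, non-model-driven score: per sample, the median
expression of the miliary-up sRNAs minus the median expression of the
non-miliary-up sRNAs. Higher values indicate a more miliary-like sample;
cohort-level median dichotomization turns scores into spread-type calls.
Signature members are selected as sRNAs deregulated between the spread types
in primary ovarian (P) tumor samples only, and in no other supplied
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

#: shipped default: 3 sRNAs higher in miliary, 10 higher in non-miliary
DEFAULT_UP_MILIARY = ("miR-760", "novel_miR-1003", "novel_miR-2508")
DEFAULT_UP_NON_MILIARY = (
    "miR-1254",
    "novel_miR-804",
    "novel_miR-1628",
    "novel_miR-1927",
    "novel_miR-2353",
    "novel_miR-2916",
    "novel_miR-3475",
    "novel_miR-3784",
    "piRno_hsa_009295",
    "novel_piRn9_chr19_12817301",
)


@dataclass(frozen=True)
class SpreadSignature:
    """Named miliary-up and non-miliary-up sRNA lists defining the score."""

    up_ids: tuple
    down_ids: tuple

    def __post_init__(self) -> None:
        up, down = tuple(self.up_ids), tuple(self.down_ids)
        object.__setattr__(self, "up_ids", up)
        object.__setattr__(self, "down_ids", down)
        if not up or not down:
            raise ValueError("both signature halves must be non-empty")
        if set(up) & set(down):
            raise ValueError("signature halves must be disjoint")

    @property
    def members(self) -> tuple:
        return self.up_ids + self.down_ids

    @classmethod
    def default(cls) -> "SpreadSignature":
        return cls(DEFAULT_UP_MILIARY, DEFAULT_UP_NON_MILIARY)

    @classmethod
    def from_tsv(cls, path) -> "SpreadSignature":
        df = pd.read_csv(path, sep="\t")
        up = df.loc[df["direction"] == "up_miliary", "id"]
        down = df.loc[df["direction"] == "up_non_miliary", "id"]
        return cls(tuple(up), tuple(down))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "id": self.members,
                "direction": ["up_miliary"] * len(self.up_ids)
                + ["up_non_miliary"] * len(self.down_ids),
            }
        ).to_csv(path, sep="\t", index=False)


def score(
    expr: Mapping[str, float] | pd.Series,
    signature: SpreadSignature,
    min_coverage: float = 1.0,
) -> float:
    """median(up-miliary members) - median(up-non-miliary members) for one sample.

    ``expr`` holds consistently normalized log expression (or -dCq) for the
    signature members. By default every member must be present; lowering
    ``min_coverage`` (e.g. to 0.75) tolerates missing members.
    """
    expr = pd.Series(expr, dtype=float)
    up = expr.reindex(signature.up_ids).dropna()
    down = expr.reindex(signature.down_ids).dropna()
    for have, want in ((up, signature.up_ids), (down, signature.down_ids)):
        if len(have) < min_coverage * len(want) or len(have) == 0:
            missing = sorted(set(want) - set(have.index))
            raise ValueError(f"signature members missing from sample: {missing}")
    return float(up.median() - down.median())


def score_samples(
    matrix_values: pd.DataFrame,
    signature: SpreadSignature,
    min_coverage: float = 1.0,
) -> pd.Series:
    """Score every column (sample) of a features x samples expression table."""
    return pd.Series(
        {
            s: score(matrix_values[s], signature, min_coverage)
            for s in matrix_values.columns
        },
        name="score",
    )


def dichotomize(scores: pd.Series) -> pd.Series:
    """Median split: score above the cohort median is called miliary.

    Scores at or below the median (ties included) are called non-miliary.
    Refuses all-identical score vectors, which carry no ordering information.
    """
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if scores.nunique() == 1:
        raise ValueError("all predictor values identical; median split undefined")
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "miliary", "non_miliary"),
        index=scores.index,
        name="call",
    )


def select_signature(
    de_by_origin: Dict[str, pd.DataFrame],
    primary_origin: str = "P",
    fdr_cutoff: float = 0.05,
    min_per_direction: int = 2,
) -> SpreadSignature:
    """Select signature members from per-tissue-origin differential results.

    Members are sRNAs significant (FDR < ``fdr_cutoff``) in the miliary vs
    non-miliary comparison restricted to ``primary_origin`` samples and not
    significant in any other supplied comparison. Direction partitions the
    members: log_fc > 0 (higher in miliary, with groups coded miliary = 1)
    goes to ``up_ids``, the rest to ``down_ids``.
    """
    if primary_origin not in de_by_origin:
        raise ValueError(f"no differential results for origin {primary_origin!r}")
    primary = de_by_origin[primary_origin]
    candidates = primary[primary["fdr"] < fdr_cutoff]
    if candidates.empty:
        raise ValueError("no significant sRNAs in the primary-tumor comparison")
    keep = pd.Series(True, index=candidates.index)
    for origin, table in de_by_origin.items():
        if origin == primary_origin:
            continue
        sig_elsewhere = table.index[table["fdr"] < fdr_cutoff]
        keep &= ~candidates.index.isin(sig_elsewhere)
    selected = candidates[keep]
    up = tuple(selected.index[selected["log_fc"] > 0])
    down = tuple(selected.index[selected["log_fc"] <= 0])
    if len(up) < min_per_direction or len(down) < min_per_direction:
        raise ValueError(
            "too few primary-tumor-specific sRNAs per direction "
            f"(up={len(up)}, down={len(down)}, need {min_per_direction})"
        )
    return SpreadSignature(up, down)
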