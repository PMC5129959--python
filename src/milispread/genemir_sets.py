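"""Joint gene-set / miR-set ("gene-miR set") deregulation analysis.

A gene-miR set couples a gene set with the miRNAs whose experimentally
verified targets are over-represented in it (one-sided Fisher's exact test,
p < 0.05). Both halves are then tested for coordinate deregulation with a
competitive permutation test of the mean member t-statistic, the two p-values
are combined with Fisher's method (chi-squared, 4 df), combined p-values are
BH-corrected across sets, and direction concordance is summarized: because
miRNAs predominantly repress their targets, genuinely coupled sets are
expected to move in opposite directions (gene sets down where the miR sets
are up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr

_P_FLOOR = 1e-300


@dataclass
class TargetInteractionTable:
    """miRNA -> target-gene interactions (unique pairs, evidence-flagged)."""

    pairs: pd.DataFrame  # columns: mirna_id, gene_id, evidence

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id"}
        if not required <= set(self.pairs.columns):
            raise ValueError("target table needs mirna_id and gene_id columns")
        if "evidence" not in self.pairs.columns:
            self.pairs = self.pairs.assign(evidence="verified")
        self.pairs = self.pairs.drop_duplicates(["mirna_id", "gene_id"])

    def verified(self) -> "TargetInteractionTable":
        return TargetInteractionTable(self.pairs[self.pairs["evidence"] == "verified"])

    def targets_of(self, mirna_id: str) -> set:
        return set(self.pairs.loc[self.pairs["mirna_id"] == mirna_id, "gene_id"])

    @property
    def mirna_ids(self) -> List[str]:
        return sorted(self.pairs["mirna_id"].unique())

    def gene_universe(self) -> set:
        return set(self.pairs["gene_id"])

    @classmethod
    def from_tsv(cls, path) -> "TargetInteractionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


@dataclass
class GeneMiRSet:
    """A gene set, its assigned miR set, and their (combined) deregulation p-values."""

    set_id: str
    genes: List[str]
    mirs: Dict[str, float]  # miRNA id -> Fisher assignment p (< 0.05)
    p_gene: Optional[float] = None
    p_mir: Optional[float] = None
    dir_gene: Optional[str] = None
    dir_mir: Optional[str] = None
    p_combined: Optional[float] = None
    q_combined: Optional[float] = None


@dataclass
class ConcordanceCurve:
    """Directional concordance of gene-miR sets along a significance-cutoff grid."""

    cutoffs: np.ndarray
    pct_opposite: np.ndarray  # % of sets below cutoff with dir_gene != dir_mir
    pct_gene_down_mir_up: np.ndarray  # % of the opposite-direction subset
    n_below: np.ndarray
    n_significant: int  # sets with q_combined < 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "n_below": self.n_below,
                "pct_opposite": self.pct_opposite,
                "pct_gene_down_mir_up": self.pct_gene_down_mir_up,
            }
        )


def enrichment_pvalue(
    n_set_targeted: int, n_universe_targeted: int, set_size: int, universe_size: int
) -> float:
    """One-sided Fisher's exact p for target enrichment in a gene set.

    The 2x2 table is (in-set targeted, in-set non-targeted) vs (out-of-set
    targeted, out-of-set non-targeted); the enrichment tail equals the upper
    hypergeometric tail P(X >= k), X ~ Hypergeom(N, K, n).
    """
    if not 0 <= n_set_targeted <= min(set_size, n_universe_targeted):
        raise ValueError("inconsistent 2x2 table margins")
    if set_size > universe_size or n_universe_targeted > universe_size:
        raise ValueError("set and target counts cannot exceed the universe")
    return float(
        stats.hypergeom.sf(
            n_set_targeted - 1, universe_size, n_universe_targeted, set_size
        )
    )


def assign_mirs_to_gene_set(
    gene_set: Sequence[str],
    targets: TargetInteractionTable,
    universe: Sequence[str],
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Assign miRNAs whose targets are enriched in the gene set.

    For each miRNA the 2x2 table (in-set targeted / in-set non-targeted /
    out-of-set targeted / out-of-set non-targeted) is tested with a one-sided
    Fisher's exact test for enrichment, i.e. the upper hypergeometric tail
    P(X >= k) with X ~ Hypergeom(N=|universe|, K=targets in universe,
    n=|set|). miRNAs with p < ``alpha`` form the miR set.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set <= universe:
        raise ValueError("gene set must be contained in the universe")
    n_universe = len(universe)
    n_set = len(gene_set)
    assigned: Dict[str, float] = {}
    grouped = targets.pairs.groupby("mirna_id")["gene_id"]
    for mirna, genes in grouped:
        tg = set(genes) & universe
        big_k = len(tg)
        if big_k == 0:
            continue
        k = len(tg & gene_set)
        p = enrichment_pvalue(k, big_k, n_set, n_universe)
        if p < alpha:
            assigned[mirna] = p
    return assigned


def set_deregulation_test(
    stats_table: pd.DataFrame,
    members: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, str]:
    """Competitive permutation test of the mean member statistic.

    The observed score is the mean t-statistic over the member features; the
    null draws ``n_perm`` random feature sets of the same size from all
    scored features. The two-sided p uses the add-one permutation estimator.
    Direction is the sign of the observed score, with an exact zero labeled
    "up".
    """
    members = list(members)
    if not members:
        raise ValueError("empty member list")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    missing = [m for m in members if m not in stats_table.index]
    if missing:
        raise ValueError(f"members absent from statistics table: {missing[:5]}")
    values = stats_table["statistic"].to_numpy(dtype=float)
    observed = float(stats_table.loc[members, "statistic"].mean())
    rng = np.random.default_rng(seed)
    k = min(len(members), len(values))
    # without-replacement draws via random-key argpartition, chunked for memory
    null = np.empty(n_perm)
    chunk = max(1, int(2e6 // max(len(values), 1)))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        keys = rng.random((stop - start, len(values)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[start:stop] = values[idx].mean(axis=1)
    centered = null - null.mean()
    obs_centered = observed - null.mean()
    # ties (within float jitter) count as at-least-as-extreme
    eps = 1e-9 * max(1.0, float(np.abs(values).max(initial=0.0)))
    p = (1.0 + np.sum(np.abs(centered) >= abs(obs_centered) - eps)) / (n_perm + 1.0)
    direction = "up" if observed >= 0 else "down"
    return float(min(p, 1.0)), direction


def combine_gene_mir_pvalues(p_gene: float, p_mir: float) -> float:
    """Fisher's method: -2(ln p_gene + ln p_mir) referred to chi-squared, 4 df."""
    ps = []
    for p in (p_gene, p_mir):
        if not 0 <= p <= 1:
            raise ValueError("p-values must lie in [0, 1]")
        if p == 0:
            warnings.warn("zero p-value clipped for Fisher combination", stacklevel=2)
            p = _P_FLOOR
        ps.append(p)
    statistic = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(statistic, df=4))


def build_gene_mir_sets(
    gene_sets: Dict[str, Sequence[str]],
    targets: TargetInteractionTable,
    stats_genes: pd.DataFrame,
    stats_mirs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    universe: Optional[Sequence[str]] = None,
) -> List[GeneMiRSet]:
    """Full gene-miR set pipeline for one two-group comparison.

    Assigns miR sets by Fisher enrichment, tests gene and miR halves with the
    competitive permutation test against ``stats_genes`` / ``stats_mirs``,
    combines the two p-values (Fisher, 4 df) and BH-corrects the combined
    p-values across all sets that received a miR set. The gene universe
    defaults to genes present in both the target table and the gene
    statistics (the analyzed transcriptome).
    """
    if universe is None:
        universe = sorted(targets.gene_universe() & set(stats_genes.index))
    universe = list(universe)
    results: List[GeneMiRSet] = []
    rng = np.random.default_rng(seed)
    for set_id, genes in gene_sets.items():
        genes_in = [g for g in genes if g in universe]
        if not genes_in:
            continue
        mirs = assign_mirs_to_gene_set(genes_in, targets, universe)
        gms = GeneMiRSet(set_id=set_id, genes=list(genes_in), mirs=mirs)
        gene_members = [g for g in genes_in if g in stats_genes.index]
        if gene_members:
            gms.p_gene, gms.dir_gene = set_deregulation_test(
                stats_genes, gene_members, n_perm, int(rng.integers(2**31))
            )
        mir_members = [m for m in mirs if m in stats_mirs.index]
        if mir_members:
            gms.p_mir, gms.dir_mir = set_deregulation_test(
                stats_mirs, mir_members, n_perm, int(rng.integers(2**31))
            )
        if gms.p_gene is not None and gms.p_mir is not None:
            gms.p_combined = combine_gene_mir_pvalues(gms.p_gene, gms.p_mir)
        results.append(gms)
    with_combined = [g for g in results if g.p_combined is not None]
    if with_combined:
        q = bh_fdr([g.p_combined for g in with_combined])
        for gms, qi in zip(with_combined, q):
            gms.q_combined = float(qi)
    return results


def concordance_summary(
    sets: Sequence[GeneMiRSet], cutoff_grid: Sequence[float]
) -> ConcordanceCurve:
    """Direction concordance among sets significant at each cutoff.

    At each cutoff c, among sets with q_combined < c: the percentage with
    gene and miR sets deregulated in opposite directions, and — within that
    inversely deregulated subset — the percentage with the gene set down and
    the miR set up. Empty strata yield NaN, not zero.
    """
    cutoffs = np.asarray(list(cutoff_grid), dtype=float)
    if cutoffs.size == 0:
        raise ValueError("empty cutoff grid")
    scored = [s for s in sets if s.q_combined is not None]
    q = np.array([s.q_combined for s in scored])
    opposite = np.array([s.dir_gene != s.dir_mir for s in scored], dtype=bool)
    gene_down_mir_up = np.array(
        [s.dir_gene == "down" and s.dir_mir == "up" for s in scored], dtype=bool
    )
    pct_opp = np.full(cutoffs.shape, np.nan)
    pct_gdmu = np.full(cutoffs.shape, np.nan)
    n_below = np.zeros(cutoffs.shape, dtype=int)
    for i, c in enumerate(cutoffs):
        below = q < c
        n_below[i] = below.sum()
        if n_below[i]:
            pct_opp[i] = 100.0 * opposite[below].mean()
            n_opp = (below & opposite).sum()
            if n_opp:
                pct_gdmu[i] = 100.0 * gene_down_mir_up[below & opposite].sum() / n_opp
    n_significant = int((q < 0.05).sum())
    return ConcordanceCurve(cutoffs, pct_opp, pct_gdmu, n_below, n_significant)


def gene_mir_sets_to_frame(sets: Sequence[GeneMiRSet]) -> pd.DataFrame:
    """Tabular export: one row per gene-miR set."""
    return pd.DataFrame(
        {
            "set_id": [s.set_id for s in sets],
            "n_genes": [len(s.genes) for s in sets],
            "n_mirs": [len(s.mirs) for s in sets],
            "p_gene": [s.p_gene for s in sets],
            "p_mir": [s.p_mir for s in sets],
            "dir_gene": [s.dir_gene for s in sets],
            "dir_mir": [s.dir_mir for s in sets],
            "p_combined": [s.p_combined for s in sets],
            "q_combined": [s.q_combined for s in sets],
        }
    ).set_index("set_id")
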