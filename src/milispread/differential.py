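"""Per-feature two-group differential expression with an optional confounder.

Each feature is fitted with an ordinary least-squares linear model
``expression ~ group + confounder`` on the normalized log scale; the reported
statistic is the t-value of the group coefficient. Without a confounder this
reduces exactly to the pooled-variance two-sample t-test. Multiplicity is
handled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import SCALE_LOESS, SCALE_LOG_CPM, ExpressionMatrix

DE_COLUMNS = ["log_fc", "statistic", "p", "fdr", "direction"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_feature_stats(
    matrix: ExpressionMatrix,
    group: Mapping[str, int],
    confounder: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Group-coefficient t statistics for every feature.

    Parameters
    ----------
    matrix
        Normalized matrix (``log_cpm`` or ``loess_normalized``).
    group
        Maps each sample id to 0 or 1; ``log_fc`` is group-1 minus group-0.
    confounder
        Optional categorical covariate per sample (e.g. tissue origin),
        entered as dummy columns alongside the group indicator.

    Returns
    -------
    DataFrame indexed by feature id with columns log_fc, statistic, p, fdr
    and direction ("up" for log_fc >= 0, "down" otherwise).
    """
    if matrix.scale not in (SCALE_LOG_CPM, SCALE_LOESS):
        raise ValueError("differential testing expects normalized log expression")
    samples = list(matrix.sample_ids)
    g = np.array([group[s] for s in samples], dtype=float)
    if set(np.unique(g)) != {0.0, 1.0}:
        raise ValueError("group must take both values 0 and 1")
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per group")

    cols = [np.ones_like(g), g]
    if confounder is not None:
        levels = pd.Categorical([confounder[s] for s in samples])
        dummies = pd.get_dummies(levels, drop_first=True).to_numpy(dtype=float)
        cols.extend(dummies.T)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("confounder is collinear with the group indicator")

    y = matrix.values.to_numpy(dtype=float).T  # samples x features
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    if df <= 0:
        raise ValueError("model has no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    log_fc = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero residual variance: t is 0 for a zero effect, +/-inf otherwise
        t = np.where(se > 0, log_fc / se, np.sign(log_fc) * np.inf)
        t = np.where((se == 0) & (log_fc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {
            "log_fc": log_fc,
            "statistic": t,
            "p": p,
            "fdr": bh_fdr(p),
            "direction": np.where(log_fc >= 0, "up", "down"),
        },
        index=matrix.feature_ids,
    )
    return out
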