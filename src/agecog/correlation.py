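"""Gene-wise Pearson correlation of expression with behavior.

Correlations are restricted to aged animals to remove age as a
confound. Significance runs through the t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of
freedom, two-tailed; equivalently a gene is significant iff
``|r| >= critical_r(alpha, n)``, the analytic critical value obtained
by inverting the transform at the two-tailed critical t. At
alpha = 0.025 and n = 20 the critical value is 0.499.

Sign semantics depend on the measure: for trials-to-criterion (TTC,
higher = worse), a positive r means higher expression in impaired
animals; for the water-maze discrimination index (higher = better), a
positive r means higher expression in better learners.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BEHAVIOR_MEASURES, NormalizedMatrix

__all__ = [
    "critical_r",
    "correlate_genes",
    "partition_by_sign",
    "behavior_correlation_table",
]


def critical_r(alpha: float, n: int) -> float:
    """Smallest |r| reaching two-tailed significance ``alpha`` at sample size ``n``.

    Computed by inverting the t transform at the two-tailed critical t
    with ``n - 2`` degrees of freedom:
    ``r_c = t_c / sqrt(t_c^2 + n - 2)``.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    df = n - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for Pearson r via the t transform, df = n - 2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    # |r| = 1 gives infinite t: p is exactly 0 in the limit
    p = np.where(np.isinf(t), 0.0, p)
    return p


def correlate_genes(
    expr: NormalizedMatrix,
    scores: pd.Series,
    alpha: float = 0.025,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with a behavioral score.

    ``scores`` is indexed by sample id; samples with missing scores are
    dropped (pairwise complete). Statistics run on the log2 scale.
    Returns a DataFrame indexed by gene with columns ``r``,
    ``p_value``, ``n`` and ``significant``; genes with zero variance
    get NaN r and are never significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    scores = scores.dropna()
    common = [s for s in expr.sample_ids if s in scores.index]
    if len(common) < 3:
        raise ValueError(f"need >= 3 samples with scores, have {len(common)}")
    y = scores.loc[common].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("behavioral scores are constant; correlation undefined")
    x = expr.log2()[common].to_numpy()
    n = len(common)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = (xc**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / np.sqrt(x_ss * (yc**2).sum())
    constant = x_ss == 0
    r[constant] = np.nan
    p = np.full_like(r, np.nan)
    ok = ~constant
    p[ok] = _pearson_p(r[ok], n)

    result = pd.DataFrame(
        {
            "r": r,
            "p_value": p,
            "n": n,
            "significant": (p < alpha) & ok,
        },
        index=expr.gene_ids,
    )
    result.index.name = "gene_id"
    return result


def partition_by_sign(results: pd.DataFrame) -> tuple[int, int]:
    """Counts of significant genes with positive and negative r.

    Returns ``(n_positive, n_negative)``. The positive share (what
    fraction of significant genes rises with the measure) is
    ``n_positive / (n_positive + n_negative)``.
    """
    sig = results.loc[results["significant"]]
    n_pos = int((sig["r"] > 0).sum())
    n_neg = int((sig["r"] < 0).sum())
    return n_pos, n_neg


def behavior_correlation_table(
    samples: pd.DataFrame,
    measures: list[str] | None = None,
    aged_only: bool = True,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among behavioral measures.

    Uses pairwise-complete observations over aged animals (by
    default). Returns ``(r, p)`` DataFrames; cells with fewer than 3
    complete pairs are NaN. Significance at the returned p can be
    compared against ``alpha`` (conventionally starred at p < 0.05).
    """
    measures = measures or BEHAVIOR_MEASURES
    table = samples.loc[samples["age_group"] == "aged"] if aged_only else samples
    k = len(measures)
    r_mat = pd.DataFrame(np.eye(k), index=measures, columns=measures)
    p_mat = pd.DataFrame(np.zeros((k, k)), index=measures, columns=measures)
    for i, a in enumerate(measures):
        for j, b in enumerate(measures):
            if j <= i:
                continue
            pair = table[[a, b]].dropna()
            if len(pair) < 3:
                r_val, p_val = np.nan, np.nan
            else:
                r_val, p_val = stats.pearsonr(pair[a], pair[b])
            r_mat.loc[a, b] = r_mat.loc[b, a] = r_val
            p_mat.loc[a, b] = p_mat.loc[b, a] = p_val
    return r_mat, p_mat
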