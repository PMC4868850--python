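"""Cross-study directional concordance and the expected-direction FDR.

Given a prior study's gene list with expected directions of change,
this module (1) restricts the list to genes detected in the current
dataset (case-insensitive symbol matching, e.g. human SST to rat Sst),
(2) scores directional agreement of fold-change signs, (3) tests the
agreement against a 50:50 chance split with a 1-df chi-square
goodness-of-fit, (4) runs per-gene one-tailed two-sample t-tests in
the prior-specified direction, and (5) computes the expected-direction
false discovery rate

    FDR = (T * alpha) / n_sig

where T is the number of genes tested, alpha the per-gene one-tailed
level, and n_sig the number of genes significant in the predicted
direction. With T = 318 matched genes and 60 significant at
alpha = 0.05 this gives 0.27; with T = 26 and 16 significant, 0.08.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, DirectionSet, NormalizedMatrix

__all__ = [
    "ConcordanceReport",
    "match_genes",
    "direction_agreement",
    "chi_square_direction",
    "directed_tests",
    "expected_direction_fdr",
]

logger = logging.getLogger(__name__)


def expected_direction_fdr(T: int, alpha: float, n_sig: int) -> float:
    """Expected-direction FDR: (T * alpha) / n_sig.

    ``T * alpha`` genes are expected to reach one-tailed significance
    in the predicted direction by chance alone; dividing by the number
    observed gives the estimated false-discovery fraction. Undefined
    (NaN) when ``n_sig`` is zero.
    """
    if T < 0 or n_sig < 0:
        raise ValueError("T and n_sig must be nonnegative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_sig == 0:
        return float("nan")
    return (T * alpha) / n_sig


def match_genes(
    prior: DirectionSet, detected: CountMatrix | NormalizedMatrix
) -> DirectionSet:
    """Restrict a prior direction list to genes present in the data.

    Matching is by case-folded symbol; the matched set keeps the
    data's own gene identifiers for downstream lookups.
    """
    by_folded = {}
    for gene in detected.gene_ids:
        by_folded.setdefault(gene.casefold(), gene)
    entries: dict[str, int] = {}
    display: dict[str, str] = {}
    for key, direction in prior.entries.items():
        if key in by_folded:
            entries[key] = direction
            display[key] = by_folded[key]
    if not entries:
        logger.warning("no genes of prior set %r detected", prior.name)
    return DirectionSet(name=prior.name, entries=entries, display=display)


def _group_means(
    expr: NormalizedMatrix,
    samples: pd.DataFrame,
    group_col: str,
    baseline: str,
    contrast: str,
):
    base_ids = samples.loc[samples[group_col] == baseline, "sample_id"].tolist()
    con_ids = samples.loc[samples[group_col] == contrast, "sample_id"].tolist()
    if not base_ids or not con_ids:
        raise ValueError("both groups must be non-empty")
    return base_ids, con_ids


def direction_agreement(
    matched: DirectionSet,
    expr: NormalizedMatrix,
    samples: pd.DataFrame,
    group_col: str = "age_group",
    baseline: str = "young",
    contrast: str = "aged",
) -> tuple[int, int]:
    """Count genes whose fold-change sign matches the prior direction.

    Observed direction is the sign of (contrast mean - baseline mean)
    on the linear scale. A gene with exactly equal means cannot agree
    with a +/-1 prediction and counts as disagreeing. Returns
    ``(n_same, percent_same)`` with the percent rounded to the nearest
    integer.
    """
    if len(matched) == 0:
        raise ValueError("matched set is empty")
    base_ids, con_ids = _group_means(expr, samples, group_col, baseline, contrast)
    linear = expr.linear()
    n_same = 0
    for key, predicted in matched.entries.items():
        gene = matched.display[key]
        diff = linear.loc[gene, con_ids].mean() - linear.loc[gene, base_ids].mean()
        if diff == 0:
            logger.warning("gene %s has exactly equal group means", gene)
            continue
        if int(np.sign(diff)) == predicted:
            n_same += 1
    percent = int(round(100.0 * n_same / len(matched)))
    return n_same, percent


def chi_square_direction(n_same: int, T: int) -> tuple[float, float]:
    """1-df goodness-of-fit of the concordant/discordant split vs 50:50.

    Plain Pearson statistic without continuity correction:
    ``chi2 = 2 * (n_same - T/2)^2 / (T/2)``; p from the chi-square
    distribution with one degree of freedom.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= n_same <= T:
        raise ValueError("n_same must lie in [0, T]")
    expected = T / 2.0
    chi2 = (n_same - expected) ** 2 / expected + ((T - n_same) - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), p


@dataclass
class ConcordanceReport:
    """Full cross-study comparison summary.

    ``fdr`` is NaN when no gene reached directed significance.
    ``sig_genes`` lists significant genes with their signed fold
    changes (linear-ratio convention: ratios below one reported as the
    negative reciprocal).
    """

    T: int
    n_same: int
    percent_same: int
    chi2: float
    chi2_p: float
    alpha: float
    n_sig: int
    n_sig_up: int
    n_sig_down: int
    expected_sig: float
    fdr: float
    sig_genes: pd.DataFrame = field(default_factory=pd.DataFrame)


def directed_tests(
    matched: DirectionSet,
    expr: NormalizedMatrix,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "age_group",
    baseline: str = "young",
    contrast: str = "aged",
    welch: bool = False,
) -> ConcordanceReport:
    """One-tailed t-tests in the prior-specified direction, plus the FDR.

    Per matched gene, a two-sample t-test (pooled by default) of
    contrast vs baseline on the log2 scale, with the one-tailed p taken
    in the predicted direction. Genes with zero variance in both
    groups stay in T (T is the number of genes *tested*, the matched
    count) but can never be significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if len(matched) == 0:
        raise ValueError("matched set is empty")
    base_ids, con_ids = _group_means(expr, samples, group_col, baseline, contrast)
    if len(base_ids) < 2 or len(con_ids) < 2:
        raise ValueError("both groups need >= 2 samples")
    log_values = expr.log2()
    linear = expr.linear()

    from .de import signed_fold  # local import avoids a cycle at module load

    rows = []
    for key, predicted in matched.entries.items():
        gene = matched.display[key]
        a = log_values.loc[gene, base_ids].to_numpy(dtype=float)
        b = log_values.loc[gene, con_ids].to_numpy(dtype=float)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            logger.warning("gene %s untestable (zero variance in both groups)", gene)
            rows.append((gene, predicted, np.nan, np.nan, np.nan))
            continue
        t_stat, _ = stats.ttest_ind(b, a, equal_var=not welch)
        # one-tailed p in the predicted direction
        df = (
            len(a) + len(b) - 2
            if not welch
            else stats.ttest_ind(b, a, equal_var=False).df
        )
        p_one = (
            float(stats.t.sf(t_stat, df))
            if predicted > 0
            else float(stats.t.cdf(t_stat, df))
        )
        fold = signed_fold(
            float(linear.loc[gene, base_ids].mean()),
            float(linear.loc[gene, con_ids].mean()),
        )
        rows.append((gene, predicted, float(t_stat), p_one, fold))

    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "predicted", "t", "p_one_tailed", "fold_change"]
    )
    sig_mask = per_gene["p_one_tailed"] < alpha
    n_sig = int(sig_mask.sum())
    n_sig_up = int((sig_mask & (per_gene["predicted"] > 0)).sum())
    n_sig_down = int((sig_mask & (per_gene["predicted"] < 0)).sum())

    n_same, percent_same = direction_agreement(
        matched, expr, samples, group_col=group_col, baseline=baseline, contrast=contrast
    )
    chi2, chi2_p = chi_square_direction(n_same, len(matched))
    T = len(matched)
    fdr = expected_direction_fdr(T, alpha, n_sig) if n_sig > 0 else float("nan")

    return ConcordanceReport(
        T=T,
        n_same=n_same,
        percent_same=percent_same,
        chi2=chi2,
        chi2_p=chi2_p,
        alpha=alpha,
        n_sig=n_sig,
        n_sig_up=n_sig_up,
        n_sig_down=n_sig_down,
        expected_sig=T * alpha,
        fdr=fdr,
        sig_genes=per_gene.loc[sig_mask].reset_index(drop=True),
    )
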