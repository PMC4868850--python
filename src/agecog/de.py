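"""Age-effect screening, fold changes, cross-region overlap, GO enrichment.

The screen is a per-gene one-way ANOVA between young and aged groups at
an uncorrected threshold (default p < 0.025); with two groups the F
statistic is exactly the square of the pooled two-sample t. Direction
and fold change are computed on the linear (normalized, non-log) scale,
with the signed convention used in aging-transcriptomics tables: a
ratio of 0.84 is reported as -1.19 rather than 0.84.

No multiple-testing correction is applied to the screen itself — the
design relies on gene-set enrichment over the screened lists, here a
one-sided hypergeometric over-representation test with
Benjamini-Hochberg adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GoAnnotation, NormalizedMatrix

__all__ = [
    "age_screen",
    "fold_change",
    "signed_fold",
    "region_overlap",
    "OverlapSummary",
    "go_enrichment",
]


def _group_columns(samples: pd.DataFrame, group_col: str, levels) -> dict[str, list[str]]:
    out = {}
    for level in levels:
        ids = samples.loc[samples[group_col] == level, "sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"group {level!r} has fewer than 2 samples")
        out[level] = ids
    return out


def signed_fold(mean_a: float, mean_b: float) -> float:
    """Signed ratio of means, b relative to a.

    Ratios >= 1 are reported as the ratio itself; ratios < 1 as the
    negative reciprocal (0.84 -> -1.19). Undefined (NaN) when either
    mean is zero or negative.
    """
    if mean_a <= 0 or mean_b <= 0:
        return float("nan")
    ratio = mean_b / mean_a
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


def fold_change(
    expr: NormalizedMatrix,
    samples: pd.DataFrame,
    gene: str,
    group_col: str = "age_group",
    baseline: str = "young",
    contrast: str = "aged",
) -> float:
    """Signed fold change of one gene, contrast group over baseline group."""
    linear = expr.linear()
    groups = _group_columns(samples, group_col, [baseline, contrast])
    mean_base = float(linear.loc[gene, groups[baseline]].mean())
    mean_con = float(linear.loc[gene, groups[contrast]].mean())
    return signed_fold(mean_base, mean_con)


def age_screen(
    expr: NormalizedMatrix,
    samples: pd.DataFrame,
    alpha: float = 0.025,
    group_col: str = "age_group",
    baseline: str = "young",
    contrast: str = "aged",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA between two groups.

    Statistics run on the log2(normalized + 1) scale; direction and
    fold change on the linear scale. Returns a DataFrame indexed by
    gene with columns ``statistic`` (F), ``p_value``, ``direction``
    (+1 if the contrast-group mean exceeds the baseline mean),
    ``fold_change`` (signed convention) and ``significant``.

    With ``welch=True`` the unequal-variance Welch test replaces the
    pooled ANOVA (sensitivity analysis; F is then the squared Welch t).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    groups = _group_columns(samples, group_col, [baseline, contrast])
    log_values = expr.log2()
    linear = expr.linear()

    a = log_values[groups[baseline]].to_numpy()
    b = log_values[groups[contrast]].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            t = (m2 - m1) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            t = (m2 - m1) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
            df = np.full_like(t, float(n1 + n2 - 2))
        f_stat = t**2
        p = stats.f.sf(f_stat, 1, df)

    lin_base = linear[groups[baseline]].to_numpy().mean(axis=1)
    lin_con = linear[groups[contrast]].to_numpy().mean(axis=1)
    direction = np.where(lin_con >= lin_base, 1, -1)
    folds = np.array(
        [signed_fold(x, y) for x, y in zip(lin_base, lin_con)]
    )

    result = pd.DataFrame(
        {
            "statistic": f_stat,
            "p_value": p,
            "direction": direction,
            "fold_change": folds,
            "significant": p < alpha,
        },
        index=log_values.index,
    )
    result.index.name = "gene_id"
    # constant genes have undefined statistics, never significant
    result.loc[~np.isfinite(result["p_value"]), "significant"] = False
    return result


@dataclass
class OverlapSummary:
    """Per-region directional counts and pairwise directional overlaps."""

    per_region: pd.DataFrame  # index region, columns up/down
    pairwise: pd.DataFrame  # region_a, region_b, direction, overlap


def region_overlap(results: dict[str, pd.DataFrame]) -> OverlapSummary:
    """Count significant up/down genes per region and shared across pairs.

    For each ordered pair the gene universes are intersected first, so
    overlap counts never exceed either region's marginal count.
    """
    per_region = pd.DataFrame(
        {
            region: {
                "up": int(((df["significant"]) & (df["direction"] > 0)).sum()),
                "down": int(((df["significant"]) & (df["direction"] < 0)).sum()),
            }
            for region, df in results.items()
        }
    ).T
    per_region.index.name = "region"

    rows = []
    regions = list(results)
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            common = results[ra].index.intersection(results[rb].index)
            da = results[ra].loc[common]
            db = results[rb].loc[common]
            for direction, label in ((1, "up"), (-1, "down")):
                both = (
                    da["significant"]
                    & db["significant"]
                    & (da["direction"] == direction)
                    & (db["direction"] == direction)
                )
                rows.append(
                    {
                        "region_a": ra,
                        "region_b": rb,
                        "direction": label,
                        "overlap": int(both.sum()),
                    }
                )
    return OverlapSummary(
        per_region=per_region,
        pairwise=pd.DataFrame(rows, columns=["region_a", "region_b", "direction", "overlap"]),
    )


def go_enrichment(
    gene_set,
    universe,
    anno: GoAnnotation,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    Tests every GO term with at least one hit in ``gene_set`` against
    the annotated ``universe``; p is the upper-tail hypergeometric
    probability of at least the observed number of hits. Returns a
    DataFrame sorted by adjusted q with columns term, term_size, hits,
    p_value, q_value, significant (q < ``q_cut``).
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of universe")
    if not gene_set:
        return pd.DataFrame(
            columns=["term", "term_size", "hits", "p_value", "q_value", "significant"]
        )

    term_members: dict[str, set[str]] = {}
    for gene in universe:
        for term in anno.terms.get(gene, ()):  # genes without terms contribute nothing
            term_members.setdefault(term, set()).add(gene)

    n_universe = len(universe)
    n_draws = len(gene_set)
    rows = []
    for term, members in term_members.items():
        hits = len(members & gene_set)
        if hits == 0:
            continue
        p = float(stats.hypergeom.sf(hits - 1, n_universe, len(members), n_draws))
        rows.append({"term": term, "term_size": len(members), "hits": hits, "p_value": p})
    if not rows:
        return pd.DataFrame(
            columns=["term", "term_size", "hits", "p_value", "q_value", "significant"]
        )
    result = pd.DataFrame(rows)
    _, q, _, _ = multipletests(result["p_value"], method="fdr_bh")
    result["q_value"] = q
    result["significant"] = result["q_value"] < q_cut
    return result.sort_values(["q_value", "p_value"]).reset_index(drop=True)
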