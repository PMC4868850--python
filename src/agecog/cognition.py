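"""Behavioral score arithmetic and the expression-behavior composite.

Three pieces: the water-maze discrimination index (G - O)/(G + O); the
mean-split classification of aged animals into aged-impaired (AI,
set-shift TTC strictly above the aged mean) and aged-unimpaired (AU);
and the composite index score — per-animal average of gene-wise
z-scored expression over a gene set, correlated against the
standardized TTC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NormalizedMatrix

__all__ = ["discrimination_index", "mean_split", "index_score"]

logger = logging.getLogger(__name__)


def discrimination_index(G: float, O: float) -> float:
    """(G - O)/(G + O) for percent time in goal and opposite quadrants.

    Returns NaN when no time was spent in either quadrant.
    """
    if G < 0 or O < 0:
        raise ValueError("quadrant times must be nonnegative percents")
    if G + O > 100:
        raise ValueError("goal + opposite quadrant time exceeds 100%")
    if G + O == 0:
        return float("nan")
    return (G - O) / (G + O)


def mean_split(aged_ttc: pd.Series) -> pd.DataFrame:
    """Classify aged animals as AI (TTC > mean) or AU.

    The split point is the arithmetic mean of the aged TTC scores; an
    animal exactly at the mean is AU (impairment reads as *delayed*
    shifting, strictly above the mean). Returns a DataFrame indexed
    like the input with columns ``ttc``, ``label`` and ``split_mean``.
    """
    aged_ttc = aged_ttc.dropna()
    if len(aged_ttc) < 2:
        raise ValueError("need >= 2 aged animals for a mean split")
    split = float(aged_ttc.mean())
    labels = np.where(aged_ttc > split, "AI", "AU")
    return pd.DataFrame(
        {"ttc": aged_ttc, "label": labels, "split_mean": split}, index=aged_ttc.index
    )


def index_score(
    expr: NormalizedMatrix,
    gene_set,
    scores: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Composite gene-set expression index vs a behavioral score.

    Expression of each gene in ``gene_set`` is z-scored across the
    animals carrying a score (the same subset used for the
    correlation); the z-scores are averaged within each animal
    (``mean_z``), and Pearson r between ``mean_z`` and the
    standardized score (``behavior_z``) is returned.

    Zero-variance genes are excluded with a warning; an empty
    effective set is an error. Returns ``(per_animal, r)`` where
    ``per_animal`` has columns ``mean_z`` and ``behavior_z`` indexed by
    sample id.
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in expr.values.index]
    if missing:
        raise ValueError(f"gene(s) not in expression matrix: {missing[:5]}")
    scores = scores.dropna()
    animals = [s for s in expr.sample_ids if s in scores.index]
    if len(animals) < 3:
        raise ValueError(f"need >= 3 animals with scores, have {len(animals)}")

    block = expr.log2().loc[gene_set, animals]
    sd = block.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "index_score excluded %d zero-variance gene(s)", int(constant.sum())
        )
        block = block.loc[~constant]
        sd = sd[~constant]
    if block.empty:
        raise ValueError("no gene in the set has variance across the chosen animals")

    z = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)
    mean_z = z.mean(axis=0)
    y = scores.loc[animals]
    behavior_z = (y - y.mean()) / y.std(ddof=1)
    r, _ = stats.pearsonr(mean_z, behavior_z)
    per_animal = pd.DataFrame({"mean_z": mean_z, "behavior_z": behavior_z})
    per_animal.index.name = "sample_id"
    return per_animal, float(r)
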