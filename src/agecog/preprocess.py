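"""Gene filtering, median-of-ratios normalization, standardization, spike-in QC.

The normalization is the classic median-of-ratios scheme: each
sample's size factor is the median, over genes expressed in every
sample, of the ratio of that sample's count to the gene's geometric
mean across samples. Filtering removes genes with low counts
("5 or less" on the chosen per-gene summary) and genes without any GO
annotation, mirroring the screening universe used for enrichment-based
aging studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, GoAnnotation, NormalizedMatrix

__all__ = [
    "QcReport",
    "filter_low_counts",
    "filter_go_annotated",
    "size_factors",
    "normalize",
    "zscore_rows",
    "spikein_qc",
]

logger = logging.getLogger(__name__)

_MODES = {"mean", "sum", "max"}


@dataclass(frozen=True)
class QcReport:
    """Spike-in linearity report; passes iff R^2 > 0.9 and >= 60 detected."""

    r_squared: float
    n_detected: int
    passed: bool
    slope: float = float("nan")
    intercept: float = float("nan")


def filter_low_counts(
    counts: CountMatrix, threshold: int = 5, mode: str = "mean"
) -> CountMatrix:
    """Drop genes whose per-gene count summary is ``threshold`` or less.

    ``mode`` selects the summary across samples: ``mean`` (default),
    ``sum`` or ``max``. The boundary is inclusive — a gene at exactly
    the threshold is removed. An empty result is permitted (logged).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")
    summary = getattr(counts.counts, mode)(axis=1)
    keep = summary > threshold
    if not keep.any():
        logger.warning("low-count filter removed every gene")
    return CountMatrix(counts.counts.loc[keep])


def filter_go_annotated(counts: CountMatrix, anno: GoAnnotation) -> CountMatrix:
    """Keep only genes annotated with at least one GO term."""
    keep = [g for g in counts.gene_ids if anno.annotated(g)]
    if not keep:
        logger.warning("GO filter removed every gene")
    return CountMatrix(counts.counts.loc[keep])


def _lower_median(values: np.ndarray) -> float:
    ordered = np.sort(values)
    return float(ordered[(len(ordered) - 1) // 2])


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Only genes with nonzero counts in every sample enter the reference
    (their geometric mean is well defined). For an even number of
    reference genes the lower median is taken.
    """
    values = counts.counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors undefined"
        )
    ref = values[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref) - log_geomean[:, None]
    factors = np.array([
        np.exp(_lower_median(log_ratios[:, j])) for j in range(values.shape[1])
    ])
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize(counts: CountMatrix, log2: bool = True) -> NormalizedMatrix:
    """Divide each sample by its size factor; optionally log2(x + 1)."""
    factors = size_factors(counts)
    values = counts.counts.astype(float).div(factors, axis=1)
    if log2:
        values = np.log2(values + 1.0)
    return NormalizedMatrix(values=values, size_factors=factors, log_transformed=log2)


def zscore_rows(matrix: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene to mean 0, SD 1 (ddof=1) across samples.

    Zero-variance rows cannot be standardized; they are excluded with a
    warning rather than propagating NaN. Idempotent on its output.
    """
    frame = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    sd = frame.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "zscore_rows excluded %d zero-variance gene(s)", int(constant.sum())
        )
    frame = frame.loc[~constant]
    return frame.sub(frame.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def spikein_qc(
    table: pd.DataFrame, min_r_squared: float = 0.9, min_detected: int = 60
) -> QcReport:
    """Spike-in linearity check.

    Least-squares fit of ``log10(observed + 1)`` on ``log10(expected)``
    over all transcripts; ``n_detected`` counts transcripts with a
    nonzero observed count. The gates are strict as written: R^2 must
    exceed 0.9 and at least 60 transcripts must be detected.
    """
    expected = table["expected_concentration"].to_numpy(dtype=float)
    observed = table["observed_count"].to_numpy(dtype=float)
    if (observed > 0).sum() < 2:
        raise ValueError("need at least 2 detected transcripts for the QC fit")
    x = np.log10(expected)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all expected concentrations equal")
    y = np.log10(observed + 1.0)
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    n_detected = int((observed > 0).sum())
    passed = (r2 > min_r_squared) and (n_detected >= min_detected)
    return QcReport(
        r_squared=r2,
        n_detected=n_detected,
        passed=passed,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
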