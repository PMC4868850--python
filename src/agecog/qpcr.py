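"""Relative quantification of qPCR CT values by the ddCT method.

Per sample and target gene: dCT = CT_target - CT_reference;
ddCT = dCT - mean dCT of the control group; fold = 2^(-ddCT). The
reference gene cancels plate offsets, and referencing to the control
mean makes the control group's geometric-mean fold exactly 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import validate_ct_table

__all__ = ["delta_delta_ct", "group_compare"]

logger = logging.getLogger(__name__)


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str = "Gapdh",
    control_group: str = "control",
) -> pd.DataFrame:
    """ddCT relative expression for every sample and target gene.

    Technical replicates (repeated rows for the same sample and gene)
    are averaged before dCT. Samples missing the reference gene are
    excluded with a warning. Returns a DataFrame with columns
    sample_id, group, gene, delta_ct, delta_delta_ct, fold.
    """
    ct = validate_ct_table(ct)
    mean_ct = (
        ct.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = mean_ct.loc[mean_ct["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = mean_ct.loc[mean_ct["gene"] != reference_gene].copy()

    have_ref = targets["sample_id"].isin(ref.index)
    if (~have_ref).any():
        dropped = sorted(targets.loc[~have_ref, "sample_id"].unique())
        logger.warning("samples missing reference %r excluded: %s", reference_gene, dropped)
        targets = targets.loc[have_ref]
    if targets.empty:
        raise ValueError("no target-gene measurements with a reference CT")

    targets["delta_ct"] = targets["ct"] - targets["sample_id"].map(ref).to_numpy()
    control = targets.loc[targets["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    control_mean = control.groupby("gene")["delta_ct"].mean()
    unseen = set(targets["gene"]) - set(control_mean.index)
    if unseen:
        raise ValueError(f"gene(s) absent from the control group: {sorted(unseen)}")
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["gene"].map(control_mean).to_numpy()
    targets["fold"] = np.power(2.0, -targets["delta_delta_ct"])
    return targets[
        ["sample_id", "group", "gene", "delta_ct", "delta_delta_ct", "fold"]
    ].reset_index(drop=True)


def group_compare(
    rel: pd.DataFrame,
    groups: tuple[str, str],
    gene: str | None = None,
    value: str = "delta_delta_ct",
    tails: str = "two",
) -> tuple[float, float]:
    """Two-sample t-test of relative expression between two groups.

    ``value`` selects the tested scale: ``delta_delta_ct`` (default;
    log2 scale, better suited to a t-test) or ``fold``. ``tails`` is
    ``two``, ``greater`` (second group higher) or ``less``. Returns
    ``(t, p)`` with t signed as second group minus first.
    """
    if value not in ("delta_delta_ct", "fold"):
        raise ValueError("value must be 'delta_delta_ct' or 'fold'")
    if tails not in ("two", "greater", "less"):
        raise ValueError("tails must be 'two', 'greater' or 'less'")
    data = rel if gene is None else rel.loc[rel["gene"] == gene]
    a = data.loc[data["group"] == groups[0], value].to_numpy(dtype=float)
    b = data.loc[data["group"] == groups[1], value].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate variance in both groups")
    sign = -1.0 if value == "delta_delta_ct" else 1.0
    # on the ddCT scale lower values mean higher expression; flip so a
    # positive t always means higher expression in the second group
    t_stat, p_two = stats.ttest_ind(sign * b, sign * a, equal_var=True)
    df = len(a) + len(b) - 2
    if tails == "two":
        return float(t_stat), float(p_two)
    if tails == "greater":
        return float(t_stat), float(stats.t.sf(t_stat, df))
    return float(t_stat), float(stats.t.cdf(t_stat, df))
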