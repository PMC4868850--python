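"""Synthetic data with planted ground truth for pipeline validation.

The generator emulates the statistical structure of a bulk RNA-seq
aging study in rat cortex: negative-binomial gene counts for ~15,000
genes over 11 young and 20 aged animals, a planted subset of genes with
age-related log2-fold shifts, a planted subset whose expression tracks
each aged animal's set-shift trials-to-criterion (TTC), aged TTC drawn
from an impaired/unimpaired two-component mixture, and water-maze
scores. Spike-in and qPCR CT fixtures cover the QC and validation arms.

Counts are negative binomial with gene-level baseline means drawn
log-normally; variance is mu + dispersion * mu^2. Behavior-correlated
genes receive an additive term beta * z(TTC) on the log2 mean of aged
animals, with beta solved from a delta-method noise approximation so
the realized expression/TTC Pearson correlation sits near the requested
target. All randomness flows from a single seed; identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, validate_ct_table, validate_sample_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_counts",
    "generate_behavior",
    "generate_spikein",
    "generate_qpcr",
]

_LN2 = np.log(2.0)

#: spread of gene baseline log2 means around ``mean_log_expr``
_BASE_LOG_SD = 1.5
#: share of planted behavior genes with a positive TTC correlation
_FRAC_BEHAVIOR_POSITIVE = 0.73
#: criterion floor: eight consecutive correct trials
_TTC_FLOOR = 8.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design this package targets: 11 young and
    20 aged animals, ~15,000 GO-annotated genes, several hundred
    age-responsive genes (half up, half down), several hundred genes
    correlated with set-shift TTC, and aged TTC from an AI/AU mixture
    whose expected mean sits near the low 50s.
    """

    n_young: int = 11
    n_aged: int = 20
    n_genes: int = 15000
    n_age_de: int = 700
    age_lfc: float = 1.0
    frac_age_up: float = 0.5
    n_behavior_genes: int = 400
    behavior_r: float = 0.6
    nb_dispersion: float = 0.1
    mean_log_expr: float = 5.0
    libsize_spread: float = 0.2
    ttc_young_mean: float = 25.0
    ttc_au_mean: float = 30.0
    ttc_ai_mean: float = 78.0
    ttc_sd: float = 10.0
    frac_aged_impaired: float = 0.45
    seed: int = 0
    region: str = "mPFC"
    integerize_ttc: bool = False

    def validate(self) -> None:
        def _positive(name):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

        for name in ("n_young", "n_aged", "n_genes", "nb_dispersion", "ttc_sd"):
            _positive(name)
        for name in ("n_age_de", "n_behavior_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_age_de + self.n_behavior_genes > self.n_genes:
            raise ValueError(
                "n_age_de + n_behavior_genes exceeds n_genes "
                f"({self.n_age_de} + {self.n_behavior_genes} > {self.n_genes})"
            )
        for name in ("frac_age_up", "frac_aged_impaired"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not -1.0 < self.behavior_r < 1.0:
            raise ValueError(f"behavior_r must lie in (-1, 1), got {self.behavior_r}")
        if self.libsize_spread < 0:
            raise ValueError("libsize_spread must be nonnegative")

    def replace(self, **kwargs) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)


@dataclass
class GroundTruth:
    """Planted truth of a simulated dataset, for recovery tests.

    ``age_de_genes`` and ``behavior_genes`` map gene ids to the planted
    sign (+1 up with age / positively correlated with TTC). The two
    sets are disjoint by construction.
    """

    age_de_genes: dict[str, int] = field(default_factory=dict)
    behavior_genes: dict[str, int] = field(default_factory=dict)
    true_size_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    ttc_class: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self):
        overlap = set(self.age_de_genes) & set(self.behavior_genes)
        if overlap:
            raise ValueError(f"planted gene sets overlap: {sorted(overlap)[:3]}")
        if (self.true_size_factors <= 0).any():
            raise ValueError("true size factors must be positive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent child streams so generate_behavior(config) returns the
    # same table whether called alone or from generate_counts
    return np.random.default_rng([int(seed), stream])


def _truncated_normal(rng, mean, sd, size, floor):
    draws = rng.normal(mean, sd, size=size)
    return np.maximum(draws, floor)


def generate_behavior(config: SimulationConfig) -> pd.DataFrame:
    """Per-animal behavioral scores with a latent AI/AU label.

    Young set-shift TTC is Normal(ttc_young_mean, ttc_sd) floored at 8
    (the task criterion is eight consecutive correct trials); aged TTC
    is a mixture of unimpaired (AU) and impaired (AI) components with
    mixing weight ``frac_aged_impaired``. Water-maze scores are drawn
    so that spatial escape distance and the discrimination index are
    negatively related, as seen in aged cohorts.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    n_y, n_a = config.n_young, config.n_aged

    young_ids = [f"Y{i + 1:02d}" for i in range(n_y)]
    aged_ids = [f"A{i + 1:02d}" for i in range(n_a)]

    ttc_young = _truncated_normal(
        rng, config.ttc_young_mean, config.ttc_sd, n_y, _TTC_FLOOR
    )
    impaired = rng.random(n_a) < config.frac_aged_impaired
    means = np.where(impaired, config.ttc_ai_mean, config.ttc_au_mean)
    ttc_aged = np.maximum(rng.normal(means, config.ttc_sd), _TTC_FLOOR)

    visual_young = _truncated_normal(rng, 30.0, 12.0, n_y, _TTC_FLOOR)
    visual_aged = _truncated_normal(rng, 38.0, 12.0, n_a, _TTC_FLOOR)

    di = np.clip(
        np.concatenate(
            [rng.normal(0.30, 0.18, n_y), rng.normal(0.22, 0.22, n_a)]
        ),
        -1.0,
        1.0,
    )
    # longer spatial escape distance goes with worse discrimination
    spatial_block5 = np.maximum(400.0 - 300.0 * di + rng.normal(0, 80.0, n_y + n_a), 50.0)
    cue_block5 = np.maximum(
        np.concatenate(
            [rng.normal(250.0, 60.0, n_y), rng.normal(310.0, 60.0, n_a)]
        ),
        50.0,
    )
    crossings = np.maximum(
        np.concatenate([rng.normal(4.0, 1.5, n_y), rng.normal(2.8, 1.5, n_a)]),
        0.0,
    )

    ttc = np.concatenate([ttc_young, ttc_aged])
    visual = np.concatenate([visual_young, visual_aged])
    if config.integerize_ttc:
        ttc = np.maximum(np.rint(ttc), _TTC_FLOOR)
        visual = np.maximum(np.rint(visual), _TTC_FLOOR)

    table = pd.DataFrame(
        {
            "sample_id": young_ids + aged_ids,
            "animal_id": young_ids + aged_ids,
            "region": config.region,
            "age_group": ["young"] * n_y + ["aged"] * n_a,
            "set_shift_ttc": ttc,
            "visual_ttc": visual,
            "cue_block5": cue_block5,
            "spatial_block5": spatial_block5,
            "crossings": crossings,
            "discrimination_index": di,
            "ttc_class": ["young"] * n_y
            + ["AI" if flag else "AU" for flag in impaired],
        }
    )
    return validate_sample_table(table)


def _solve_behavior_beta(mu: np.ndarray, dispersion: float, target_r: float) -> np.ndarray:
    """Per-gene slope on z(TTC) that yields the target log2-scale correlation.

    Delta method: var(log2 NB(mu, phi)) ~ (1/mu + phi) / ln(2)^2. With
    signal variance beta^2 on the log2 scale, the expected correlation
    is beta / sqrt(beta^2 + sigma^2), so beta = sigma * r / sqrt(1-r^2).
    """
    sigma = np.sqrt(1.0 / np.maximum(mu, 1e-9) + dispersion) / _LN2
    return sigma * abs(target_r) / np.sqrt(1.0 - target_r**2)


def generate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a count matrix, its sample table, and the planted truth.

    Returns
    -------
    (CountMatrix, SampleTable, GroundTruth)
        Counts are genes x samples nonnegative integers. The sample
        table is the one :func:`generate_behavior` produces for the
        same config. Ground truth records planted age genes (with
        sign), behavior-correlated genes (with sign), true size factors
        and the latent AI/AU class of each aged animal.
    """
    config.validate()
    samples = generate_behavior(config)
    rng = _rng(config.seed, 2)

    n_y, n_a = config.n_young, config.n_aged
    n_samples = n_y + n_a
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]

    base_log2 = rng.normal(config.mean_log_expr, _BASE_LOG_SD, config.n_genes)

    planted = rng.choice(
        config.n_genes, size=config.n_age_de + config.n_behavior_genes, replace=False
    )
    age_idx = planted[: config.n_age_de]
    beh_idx = planted[config.n_age_de :]

    n_up = int(round(config.frac_age_up * config.n_age_de))
    age_signs = np.concatenate(
        [np.ones(n_up, dtype=int), -np.ones(config.n_age_de - n_up, dtype=int)]
    )
    rng.shuffle(age_signs)
    n_pos = int(round(_FRAC_BEHAVIOR_POSITIVE * config.n_behavior_genes))
    beh_signs = np.concatenate(
        [np.ones(n_pos, dtype=int), -np.ones(config.n_behavior_genes - n_pos, dtype=int)]
    )
    rng.shuffle(beh_signs)

    log2_mu = np.tile(base_log2[:, None], (1, n_samples))
    aged_cols = np.arange(n_y, n_samples)

    # planted age effect: aged group shifted by +/- age_lfc on log2 scale
    if config.n_age_de:
        log2_mu[np.ix_(age_idx, aged_cols)] += (age_signs * config.age_lfc)[:, None]

    # planted behavior correlation, aged animals only
    if config.n_behavior_genes:
        ttc_aged = samples.loc[samples["age_group"] == "aged", "set_shift_ttc"].to_numpy()
        z_ttc = (ttc_aged - ttc_aged.mean()) / ttc_aged.std(ddof=1)
        beta = _solve_behavior_beta(
            np.power(2.0, base_log2[beh_idx]), config.nb_dispersion, config.behavior_r
        )
        log2_mu[np.ix_(beh_idx, aged_cols)] += (beh_signs * beta)[:, None] * z_ttc[None, :]

    if config.libsize_spread > 0:
        log_sf = rng.normal(0.0, config.libsize_spread, n_samples)
        log_sf -= log_sf.mean()  # geometric mean 1
        size_factors = np.exp(log_sf)
    else:
        size_factors = np.ones(n_samples)

    mu = np.power(2.0, log2_mu) * size_factors[None, :]
    phi = config.nb_dispersion
    # NB(mean mu, var mu + phi mu^2): shape n = 1/phi, p = n / (n + mu)
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"].tolist())
    )
    aged_samples = samples.loc[samples["age_group"] == "aged"]
    truth = GroundTruth(
        age_de_genes={gene_ids[i]: int(s) for i, s in zip(age_idx, age_signs)},
        behavior_genes={gene_ids[i]: int(s) for i, s in zip(beh_idx, beh_signs)},
        true_size_factors=pd.Series(size_factors, index=samples["sample_id"].tolist()),
        ttc_class=pd.Series(
            aged_samples["ttc_class"].to_numpy(), index=aged_samples["sample_id"].to_numpy()
        ),
    )
    return matrix, samples, truth


def generate_spikein(
    n_transcripts: int = 92,
    noise_sd: float = 0.15,
    seed: int = 0,
    slope: float = 1.0,
    intercept: float = 2.5,
) -> pd.DataFrame:
    """Spike-in table with known concentrations spanning six decades.

    Observed counts are generated as ``10**(intercept + slope *
    log10(expected) + eps) - 1`` with ``eps ~ Normal(0, noise_sd)`` and
    clipping at zero, so the downstream QC regression of
    ``log10(observed + 1)`` on ``log10(expected)`` is exactly linear
    when ``noise_sd`` is zero.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng([int(seed), 3])
    if n_transcripts == 1:
        log_expected = np.array([0.0])
    else:
        log_expected = np.linspace(-2.0, 4.0, n_transcripts)
    eps = rng.normal(0.0, noise_sd, n_transcripts) if noise_sd > 0 else 0.0
    observed = np.maximum(
        np.power(10.0, intercept + slope * log_expected + eps) - 1.0, 0.0
    )
    return pd.DataFrame(
        {
            "transcript_id": [f"ERCC-{i + 1:05d}" for i in range(n_transcripts)],
            "expected_concentration": np.power(10.0, log_expected),
            "observed_count": observed,
        }
    )


def generate_qpcr(
    fold_changes: dict[str, float],
    n_per_group: int = 6,
    ct_sd: float = 0.1,
    seed: int = 0,
    reference_gene: str = "Gapdh",
    groups: tuple[str, str] = ("control", "treated"),
) -> pd.DataFrame:
    """CT table for a two-group qPCR experiment with known fold changes.

    ``fold_changes`` maps gene symbols to the treated/control
    expression ratio; the reference gene must be present with fold 1.
    CT = baseline - log2(expression) + noise, so a 2-fold increase
    lowers the target CT by one cycle.
    """
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive, got {fold}")
    if reference_gene not in fold_changes:
        raise ValueError(f"reference gene {reference_gene!r} missing from fold_changes")
    if abs(fold_changes[reference_gene] - 1.0) > 1e-12:
        raise ValueError("reference gene must have fold change 1")
    if ct_sd < 0:
        raise ValueError("ct_sd must be nonnegative")

    rng = np.random.default_rng([int(seed), 4])
    genes = list(fold_changes)
    baselines = {g: rng.uniform(20.0, 30.0) for g in genes}
    rows = []
    for group_i, group in enumerate(groups):
        for k in range(n_per_group):
            sample = f"{group}{k + 1:02d}"
            for gene in genes:
                expr = fold_changes[gene] if group_i == 1 else 1.0
                noise = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "gene": gene,
                        "ct": baselines[gene] - np.log2(expr) + noise,
                    }
                )
    return validate_ct_table(pd.DataFrame(rows), reference_gene=reference_gene)
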