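"""Core in-memory containers shared by every pipeline stage.

All tabular data ride on :class:`pandas.DataFrame`; the thin wrapper
classes here exist to enforce the invariants each stage relies on
(unique identifiers, nonnegative integral counts, positive size
factors, ±1 directions) at construction time, so downstream code never
has to re-validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CountMatrix",
    "NormalizedMatrix",
    "DirectionSet",
    "GoAnnotation",
    "SAMPLE_COLUMNS",
    "BEHAVIOR_MEASURES",
    "validate_sample_table",
    "validate_spikein_table",
    "validate_ct_table",
]


class FormatError(ValueError):
    """A file or table violates the expected dialect or an invariant."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and sample
        identifiers as columns. Values must be nonnegative integers
        (integer dtype, or floats that are exactly integral).
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                i, j = np.argwhere(values != np.floor(values))[0]
                raise FormatError(
                    f"non-integer count at gene {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"CountMatrix({g} genes x {s} samples)"


@dataclass
class NormalizedMatrix:
    """Size-factor normalized expression values.

    ``values`` holds ``count / size_factor`` per sample, optionally
    transformed to ``log2(x + 1)`` when ``log_transformed`` is True.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    log_transformed: bool = False

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            bad = self.size_factors.index[self.size_factors <= 0][0]
            raise ValueError(f"non-positive size factor for sample {bad!r}")
        if list(self.size_factors.index) != list(self.values.columns):
            raise ValueError("size factor index does not match sample columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def linear(self) -> pd.DataFrame:
        """Normalized values on the linear scale (undo the log transform)."""
        if self.log_transformed:
            return np.power(2.0, self.values) - 1.0
        return self.values

    def log2(self) -> pd.DataFrame:
        """Normalized values as log2(x + 1)."""
        if self.log_transformed:
            return self.values
        return np.log2(self.values + 1.0)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "sample_id",
    "animal_id",
    "region",
    "age_group",
    "set_shift_ttc",
    "visual_ttc",
    "cue_block5",
    "spatial_block5",
    "crossings",
    "discrimination_index",
]

#: behavioral measures used for the pairwise correlation table
BEHAVIOR_MEASURES = [
    "set_shift_ttc",
    "visual_ttc",
    "cue_block5",
    "spatial_block5",
    "crossings",
    "discrimination_index",
]

_REGIONS = {"mPFC", "CA1", "WM"}
_AGE_GROUPS = {"young", "aged"}


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate per-animal metadata; returns the (possibly coerced) table.

    Missing behavioral values stay as NaN and are never filled with
    zero. Extra columns (e.g. a latent impairment label from the
    simulator) are preserved.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    bad_region = set(table["region"].dropna()) - _REGIONS
    if bad_region:
        raise FormatError(f"unknown region value(s) {sorted(bad_region)}")
    bad_age = set(table["age_group"].dropna()) - _AGE_GROUPS
    if bad_age:
        raise FormatError(f"unknown age_group value(s) {sorted(bad_age)}")
    di = table["discrimination_index"].dropna()
    if ((di < -1) | (di > 1)).any():
        raise FormatError("discrimination_index outside [-1, 1]")
    ttc = table["set_shift_ttc"].dropna()
    if (ttc < 8).any():
        raise FormatError("set_shift_ttc below the criterion floor of 8")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# prior-study direction lists and GO annotation
# ---------------------------------------------------------------------------


@dataclass
class DirectionSet:
    """A prior study's gene list with an expected direction per gene.

    ``entries`` maps case-folded gene symbols to +1 (predicted to
    increase in the named contrast) or -1 (predicted to decrease).
    ``display`` preserves the original capitalization for reporting.
    """

    name: str
    entries: dict[str, int] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sym, d in self.entries.items():
            if d not in (+1, -1):
                raise ValueError(f"direction for {sym!r} must be +1 or -1, got {d!r}")
        for sym in self.entries:
            self.display.setdefault(sym, sym)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self.entries

    def direction(self, symbol: str) -> int:
        return self.entries[symbol.casefold()]

    @classmethod
    def from_pairs(cls, name: str, pairs) -> "DirectionSet":
        entries: dict[str, int] = {}
        display: dict[str, str] = {}
        for symbol, direction in pairs:
            key = symbol.casefold()
            if key in entries and entries[key] != direction:
                raise FormatError(
                    f"conflicting directions for symbol {symbol!r}"
                )
            entries[key] = direction
            display.setdefault(key, symbol)
        return cls(name=name, entries=entries, display=display)


@dataclass
class GoAnnotation:
    """gene id -> set of GO term ids."""

    terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def annotated(self, gene_id: str) -> bool:
        return bool(self.terms.get(gene_id))

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out


# ---------------------------------------------------------------------------
# spike-in and qPCR tables
# ---------------------------------------------------------------------------


def validate_spikein_table(table: pd.DataFrame) -> pd.DataFrame:
    """Spike-in table: transcript_id, expected_concentration (>0), observed_count (>=0)."""
    required = ["transcript_id", "expected_concentration", "observed_count"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"spike-in table missing columns: {missing}")
    if (table["expected_concentration"] <= 0).any():
        raise FormatError("expected_concentration must be positive")
    if (table["observed_count"] < 0).any():
        raise FormatError("observed_count must be nonnegative")
    return table.reset_index(drop=True)


def validate_ct_table(table: pd.DataFrame, reference_gene: str | None = None) -> pd.DataFrame:
    """qPCR CT table: sample_id, group, gene, ct (finite cycles)."""
    required = ["sample_id", "group", "gene", "ct"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"CT table missing columns: {missing}")
    if not np.isfinite(table["ct"].to_numpy(dtype=float)).all():
        raise FormatError("non-finite CT value")
    if reference_gene is not None:
        with_ref = set(table.loc[table["gene"] == reference_gene, "sample_id"])
        all_samples = set(table["sample_id"])
        if all_samples - with_ref:
            missing_ref = sorted(all_samples - with_ref)[0]
            raise FormatError(
                f"reference gene {reference_gene!r} missing for sample {missing_ref!r}"
            )
    return table.reset_index(drop=True)
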