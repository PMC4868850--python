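"""Readers and writers for every tabular artifact the pipeline touches.

Formats are deliberately plain: tab-separated count matrices (genes in
rows, header of sample ids), CSV for sample metadata, direction lists,
spike-in and CT tables, and either two-column TSV or GMT for GO maps.
Every reader validates fully before returning, so a successfully loaded
object always satisfies its type's invariants.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    DirectionSet,
    FormatError,
    GoAnnotation,
    validate_ct_table,
    validate_sample_table,
    validate_spikein_table,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_direction_set",
    "write_direction_set",
    "read_go_map",
    "write_go_map",
    "read_spikein",
    "write_spikein",
    "read_ct_table",
    "write_ct_table",
]

_UP_TOKENS = {"up", "+1", "1", "increased", "increase", "increasing"}
_DOWN_TOKENS = {"down", "-1", "decreased", "decrease", "decreasing"}


def read_counts(path) -> CountMatrix:
    """Read a tab-separated genes x samples count matrix.

    The first row is a header of sample ids; the first column holds
    gene ids. Raises :class:`FormatError` with a line number for ragged
    rows, and names the offending cell for negative or non-integer
    counts.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty counts file")
    header = rows[0]
    ncol = len(header)
    samples = header[1:]
    gene_ids: list[str] = []
    data: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != ncol:
            raise FormatError(
                f"{path}:{lineno}: expected {ncol} fields, found {len(row)}"
            )
        gene_ids.append(row[0])
        parsed: list[int] = []
        for sample, cell in zip(samples, row[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {cell!r} "
                    f"(gene {row[0]!r}, sample {sample!r})"
                ) from None
            if value != int(value):
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"(gene {row[0]!r}, sample {sample!r})"
                )
            if value < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative count {cell!r} "
                    f"(gene {row[0]!r}, sample {sample!r})"
                )
            parsed.append(int(value))
        data.append(parsed)
    frame = pd.DataFrame(data, index=gene_ids, columns=samples, dtype=np.int64)
    return CountMatrix(frame)


def write_counts(matrix: CountMatrix, path) -> None:
    frame = matrix.counts.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    """Read and validate a per-animal metadata CSV.

    Empty cells become NaN (missing), never zero.
    """
    table = pd.read_csv(path)
    return validate_sample_table(table)


def write_samples(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def _parse_direction(token: str, context: str) -> int:
    folded = token.strip().casefold()
    if folded in _UP_TOKENS:
        return +1
    if folded in _DOWN_TOKENS:
        return -1
    raise FormatError(f"{context}: unknown direction token {token!r}")


def read_direction_set(path, name: str | None = None) -> DirectionSet:
    """Read a two-column CSV of (gene symbol, direction).

    Direction tokens ``up``/``down``, ``+1``/``-1`` and
    ``increased``/``decreased`` are accepted, case-insensitively. A
    header row is skipped if its second field is not a direction token.
    Symbols are matched case-insensitively downstream; a symbol listed
    twice with conflicting directions is an error.
    """
    path = Path(path)
    pairs: list[tuple[str, int]] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            token = row[1].strip().casefold()
            if lineno == 1 and token not in (_UP_TOKENS | _DOWN_TOKENS):
                continue  # header
            pairs.append((row[0].strip(), _parse_direction(row[1], f"{path}:{lineno}")))
    return DirectionSet.from_pairs(name or path.stem, pairs)


def write_direction_set(ds: DirectionSet, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["symbol", "direction"])
        for key, direction in ds.entries.items():
            writer.writerow([ds.display[key], "up" if direction > 0 else "down"])


def read_go_map(path) -> GoAnnotation:
    """Read a gene -> GO term map.

    Two dialects are auto-detected per file: two-column TSV
    ``gene_id<TAB>term`` (one pair per line), or GMT
    ``term<TAB>description<TAB>gene1<TAB>gene2...``. A file where any
    line has three or more fields is treated as GMT.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    rows = [ln.split("\t") for ln in lines if ln.strip()]
    if not rows:
        return GoAnnotation({})
    is_gmt = any(len(r) >= 3 for r in rows)
    terms: dict[str, set[str]] = {}
    for lineno, row in enumerate(rows, start=1):
        if is_gmt:
            if len(row) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                )
            term = row[0].strip()
            for gene in row[2:]:
                gene = gene.strip()
                if gene:
                    terms.setdefault(gene, set()).add(term)
        else:
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene, term = row[0].strip(), row[1].strip()
            if not gene or not term:
                raise FormatError(f"{path}:{lineno}: empty gene or term field")
            terms.setdefault(gene, set()).add(term)
    return GoAnnotation({g: frozenset(ts) for g, ts in terms.items()})


def write_go_map(anno: GoAnnotation, path) -> None:
    with Path(path).open("w") as fh:
        for gene in anno.terms:
            for term in sorted(anno.terms[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_spikein(path) -> pd.DataFrame:
    return validate_spikein_table(pd.read_csv(path))


def write_spikein(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_ct_table(path, reference_gene: str | None = None) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path), reference_gene=reference_gene)


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
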