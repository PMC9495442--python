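"""Readers and writers for the plain-text interchange formats.

OTU tables travel as TSV (first column OTU id, one column per sample,
optional trailing ``taxonomy`` column — the classic QIIME flat layout);
function and design tables travel as CSV with samples as rows.  Sample
matching everywhere is by exact id string, never by column order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import tags_from_groups
from .tables import FunctionTable, OtuTable, SampleDesign, ValidationError

TAXONOMY_COLUMN = "taxonomy"


def read_otu_table(path: str | Path, dialect: str = "tsv") -> OtuTable:
    """Read a taxa x samples count table.

    Raises :class:`ValidationError` for negative, missing or non-numeric
    counts, duplicate OTU ids, or samples whose total count is zero.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    raw = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    taxonomy = None
    if TAXONOMY_COLUMN in raw.columns:
        taxonomy = raw.pop(TAXONOMY_COLUMN)
    counts = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            counts[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric count in sample {col!r}, OTU row(s) {list(bad[:5])}"
            ) from exc
        if counts[col].isna().any():
            bad = counts.index[counts[col].isna()]
            raise ValidationError(
                f"missing count in sample {col!r}, OTU row(s) {list(bad[:5])}"
            )
    table = OtuTable(counts, taxonomy=taxonomy)
    table.require_positive_totals()
    return table


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = table.counts.copy()
    out.index.name = out.index.name or "OTU_ID"
    if table.taxonomy is not None:
        out[TAXONOMY_COLUMN] = table.taxonomy
    out.to_csv(path, sep=sep)


def read_function_table(
    path: str | Path,
    group_map: Mapping[str, str] | None = None,
    dialect: str = "csv",
) -> FunctionTable:
    """Read a samples x functions table and attach C/N/P/other tags.

    ``group_map`` may cover any subset of the columns; unmapped columns
    fall back to the package defaults and finally to ``"other"``.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    values = pd.read_csv(path, sep=sep, header=0, index_col=0)
    values.index = values.index.astype(str)
    tags = pd.Series(tags_from_groups(values.columns, group_map))
    return FunctionTable(values, tags)


def write_function_table(
    table: FunctionTable, path: str | Path, dialect: str = "csv"
) -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = table.values.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep=sep)


def read_design(path: str | Path, dialect: str = "csv") -> SampleDesign:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    frame = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    return SampleDesign(frame)


def write_design(design: SampleDesign, path: str | Path, dialect: str = "csv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = design.frame.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep=sep)
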