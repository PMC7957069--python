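"""Readers and writers for the pipeline's tabular formats.

Everything is plain TSV with a header row; floats are serialized at 10
significant digits so a write-then-read round trip is bit-stable and the
outputs diff cleanly between runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    FractionMatrix,
    MafTable,
    SignatureMatrix,
    ValidationError,
)

logger = logging.getLogger("tmescore")

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """A file could not be parsed into the expected table."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if frame.columns.empty and frame.empty:
        raise ParseError(f"{path}: empty table or missing header row")
    frame.index.name = None
    frame.columns.name = None
    return frame


def _coerce_numeric(frame: pd.DataFrame, path) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~frame.isna()
    if bad.any().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    if out.isna().any().any():
        row = out.index[out.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {row!r}")
    return out


def read_expression(path, orientation: str = "genes-by-samples",
                    scale: str = "linear") -> ExpressionMatrix:
    """Read an expression matrix from TSV.

    ``orientation`` is ``"genes-by-samples"`` (canonical; first column gene
    ids) or ``"samples-by-genes"`` (transposed on read).
    """
    frame = _coerce_numeric(_read_tsv(path), path)
    if orientation == "samples-by-genes":
        frame = frame.T
    elif orientation != "genes-by-samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        return ExpressionMatrix(frame, scale=scale)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                       index_label="gene_id")


def read_signature(path) -> SignatureMatrix:
    frame = _coerce_numeric(_read_tsv(path), path)
    try:
        return SignatureMatrix(frame)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_signature(signature: SignatureMatrix, path) -> None:
    signature.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                          index_label="gene_id")


def read_fractions(path) -> FractionMatrix:
    frame = _coerce_numeric(_read_tsv(path), path)
    # renormalize away serialization rounding before the simplex check
    frame = frame.div(frame.sum(axis=1), axis=0)
    try:
        return FractionMatrix(frame)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fractions(fractions: FractionMatrix, path) -> None:
    fractions.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                          index_label="sample_id")


def read_clinical(path) -> ClinicalTable:
    frame = _read_tsv(path)
    try:
        return ClinicalTable(frame)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                         index_label="sample_id")


# Accepted (case-insensitive) MAF column names -> canonical names.
_MAF_ALIASES = {
    "tumor_sample_barcode": "sample_id",
    "sample_id": "sample_id",
    "hugo_symbol": "hugo_symbol",
    "variant_classification": "variant_classification",
    "t_alt_count": "t_alt_count",
    "t_depth": "t_depth",
}


def read_maf(path) -> MafTable:
    """Read a MAF-format mutation table.

    Standard column names are matched case-insensitively. Rows with
    ``t_depth == 0`` (no coverage, VAF undefined) are dropped with a
    logged count.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    rename = {}
    for col in frame.columns:
        canon = _MAF_ALIASES.get(col.lower())
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    frame = frame.rename(columns=rename)
    missing = [c for c in MafTable.COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: MAF lacks required column(s) {missing}")
    frame = frame[list(MafTable.COLUMNS)].copy()
    for col in ("t_alt_count", "t_depth"):
        frame[col] = pd.to_numeric(frame[col], errors="raise").astype(int)
    zero = frame["t_depth"] == 0
    if zero.any():
        logger.warning("read_maf: dropped %d row(s) with t_depth == 0", int(zero.sum()))
        frame = frame[~zero].reset_index(drop=True)
    try:
        return MafTable(frame.reset_index(drop=True))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_maf(maf: MafTable, path) -> None:
    out = maf.data.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "hugo_symbol": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path, index_label=None) -> None:
    """Write a generic result table with the package's float convention."""
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                 index=index_label is not None, index_label=index_label)
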