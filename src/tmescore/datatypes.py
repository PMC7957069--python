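"""In-memory containers for the pipeline's tabular data.

All containers wrap a :class:`pandas.DataFrame` and validate their
invariants on construction. They are deliberately thin: downstream code
works with the underlying frame via ``.data``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "SignatureMatrix",
    "FractionMatrix",
    "ClinicalTable",
    "MafTable",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values.

    Parameters
    ----------
    data
        Frame with gene ids as index and sample ids as columns. Values are
        non-negative normalized abundances (TPM/FPKM-like) when
        ``scale == "linear"``, or ``log2(x + 1)`` transformed values when
        ``scale == "log2p1"``.
    scale
        Either ``"linear"`` or ``"log2p1"``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2p1"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale == "linear" and (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)][0]
            raise ValidationError(
                f"negative value under linear scale (first offending gene: {bad})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2p1(self) -> "ExpressionMatrix":
        """Return a ``log2(x + 1)``-scale copy (identity if already there)."""
        if self.scale == "log2p1":
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), scale="log2p1")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], scale=self.scale)


@dataclass
class SignatureMatrix:
    """Marker-gene expression basis over immune cell types (genes x types).

    The deconvolution step regresses each bulk sample on the columns of
    this matrix. Full column rank is required for identifiability.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "marker gene")
        _check_unique(self.data.columns, "cell type")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValidationError("signature matrix must be finite and non-negative")
        if np.linalg.matrix_rank(values) < self.data.shape[1]:
            raise ValidationError("signature matrix is column-rank deficient")

    @property
    def marker_genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class FractionMatrix:
    """Per-sample immune cell-type proportions (samples x cell types).

    Each row lies on the probability simplex: entries are non-negative and
    sum to 1 within 1e-9.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "cell type")
        values = self.data.to_numpy(dtype=float)
        if (values < -1e-12).any():
            raise ValidationError("fractions must be non-negative")
        sums = values.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            bad = self.data.index[np.abs(sums - 1.0).argmax()]
            raise ValidationError(f"fraction row does not sum to 1 (sample {bad})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ClinicalTable:
    """Sample-level clinical annotation with overall survival.

    Required columns: ``os_time`` (days, >= 0) and ``os_event`` (0/1).
    Optional: ``stage`` (I-IV), ``msi_status`` (MSI-H / MSI-L / MSS),
    ``response_score`` (TIDE-like, lower = better predicted response to
    checkpoint inhibition) and ``responder`` (0/1).
    """

    data: pd.DataFrame

    REQUIRED = ("os_time", "os_event")
    OPTIONAL = ("stage", "msi_status", "response_score", "responder")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValidationError(f"clinical table lacks required column {col!r}")
        os_time = self.data["os_time"].to_numpy(dtype=float)
        if not np.isfinite(os_time).all() or (os_time < 0).any():
            raise ValidationError("os_time must be finite and non-negative")
        events = self.data["os_event"].to_numpy()
        if not np.isin(events, (0, 1)).all():
            raise ValidationError("os_event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned(self, sample_ids) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"clinical table missing sample(s): {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])


#: Variant classifications counted as protein-altering for TMB.
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)


@dataclass
class MafTable:
    """Per-mutation somatic records (MAF-format subset).

    One row per called mutation with the sample, gene symbol, variant
    classification and alt/total read counts; VAF = t_alt_count / t_depth.
    Genomic coordinates are never interpreted here.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = (
        "sample_id",
        "hugo_symbol",
        "variant_classification",
        "t_alt_count",
        "t_depth",
    )

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.data.columns:
                raise ValidationError(f"MAF table lacks required column {col!r}")
        alt = self.data["t_alt_count"].to_numpy()
        depth = self.data["t_depth"].to_numpy()
        if len(self.data) and ((alt < 0).any() or (depth < alt).any()):
            raise ValidationError("require 0 <= t_alt_count <= t_depth")
        if len(self.data) and (depth <= 0).any():
            raise ValidationError("rows with t_depth == 0 must be dropped before use")

    @property
    def vaf(self) -> pd.Series:
        """Variant allele fraction per retained mutation row."""
        return self.data["t_alt_count"] / self.data["t_depth"]

    def nonsilent(self) -> pd.DataFrame:
        return self.data[self.data["variant_classification"].isin(NONSILENT_CLASSES)]
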