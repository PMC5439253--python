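"""Expression matrix container, I/O, filtering and transforms.

Expression values arrive as FPKM (fragments per kilobase of transcript per
million mapped reads), genes in rows and samples in columns.  The standard
preprocessing path is: drop genes that are zero in every sample, then
``log2(FPKM + pseudocount)`` with a small pseudocount so zeros stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Scale = Literal["fpkm", "log2"]

DEFAULT_PSEUDOCOUNT = 0.001


class ExpressionError(ValueError):
    """Invalid expression matrix or operation called out of contract."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with an explicit scale.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with sample identifiers as
        columns. Gene identifiers may follow the ``Symbol|Entrez`` dialect;
        they are treated as opaque strings.
    scale
        ``"fpkm"`` for non-negative linear-scale values, ``"log2"`` for
        log2-transformed values (finite, may be negative).
    """

    data: pd.DataFrame
    scale: Scale = "fpkm"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        dup_g = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_g):
            raise ExpressionError(f"duplicate gene id(s): {', '.join(dup_g)}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_s):
            raise ExpressionError(f"duplicate sample id(s): {', '.join(dup_s)}")
        values = self.data.to_numpy(dtype=float)
        if self.scale == "fpkm":
            if np.any(values < 0):
                raise ExpressionError("FPKM-scale values must be non-negative")
        elif self.scale == "log2":
            if not np.all(np.isfinite(values)):
                raise ExpressionError("log2-scale values must be finite")
        else:
            raise ExpressionError(f"unknown scale {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression_tsv(path: str | Path, scale: Scale = "fpkm") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids).

    Gzip input is handled transparently by extension. Row and column order of
    the file are preserved. Raises :class:`ExpressionError` on duplicate
    identifiers and a parse error naming the offending cell for non-numeric
    values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        numeric = df.astype(float)
    except ValueError:
        # locate the first bad cell for the error message
        for j, col in enumerate(df.columns):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ExpressionError(
                    f"non-numeric value {df.iloc[i, j]!r} at gene "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(numeric, scale=scale)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the same TSV dialect ``read_expression_tsv`` reads."""
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def drop_all_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose FPKM is zero in every sample.

    Applied on the FPKM scale before the log transform; gene order of the
    survivors is preserved and the sample set is untouched.
    """
    if m.scale != "fpkm":
        raise ExpressionError("zero-filter operates on FPKM-scale matrices")
    keep = (m.values != 0).any(axis=1)
    return ExpressionMatrix(m.data.loc[keep], scale="fpkm")


def log2_transform(
    m: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ExpressionMatrix:
    """Return ``log2(v + pseudocount)`` elementwise, flagging the result log2.

    The pseudocount (default 0.001) keeps zero FPKM values finite:
    ``log2(0.001) = -9.9658...``.
    """
    if m.scale != "fpkm":
        raise ExpressionError("log2_transform expects an FPKM-scale matrix")
    if np.any(m.values < 0):
        raise ExpressionError("negative values are not valid FPKM input")
    out = np.log2(m.values + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale="log2"
    )


def align_samples(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared samples in lexicographic order.

    Pairwise correlation between the two assays requires a common, identically
    ordered sample axis; fewer than 3 shared samples is an error because a
    correlation over <3 points is meaningless.
    """
    shared = sorted(set(a.sample_ids) & set(b.sample_ids))
    if len(shared) < 3:
        raise ExpressionError(
            f"only {len(shared)} shared sample(s); need at least 3 for correlation"
        )
    return (
        ExpressionMatrix(a.data[shared], scale=a.scale),
        ExpressionMatrix(b.data[shared], scale=b.scale),
    )


def preprocess(
    m: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ExpressionMatrix:
    """Zero-filter then log2-transform, the canonical FPKM preprocessing path."""
    return log2_transform(drop_all_zero_genes(m), pseudocount=pseudocount)
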