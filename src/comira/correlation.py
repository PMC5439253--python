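"""miRNA-mRNA Pearson anti-correlation screen.

miRNAs typically repress their targets, so a strongly negative expression
correlation between a miRNA and an mRNA flags a candidate regulatory pair.
The screen computes the full mRNA x miRNA Pearson matrix on log2 expression
and keeps pairs with r strictly below a cutoff (default -0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

DEFAULT_PAIR_CUTOFF = -0.5


@dataclass(frozen=True)
class CorrelationPair:
    """A screened (miRNA, gene) pair with its Pearson coefficient."""

    mirna: str
    gene: str
    r: float


@dataclass
class CorrelationMatrix:
    """Pearson coefficients, mRNAs in rows and miRNAs in columns.

    Entries are in [-1, 1]; NaN marks an undefined correlation (a
    zero-variance profile on either side).
    """

    row_ids: list[str]
    col_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("correlation matrix shape does not match id lists")
        finite = self.r[np.isfinite(self.r)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("Pearson coefficients must lie in [-1, 1]")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length vectors.

    Returns NaN (with a warning) when either vector has zero variance, where
    the coefficient is undefined; this is never silently coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        warnings.warn("zero-variance vector: Pearson correlation undefined")
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-scale each row; flag zero-variance rows."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    degenerate = norms == 0.0
    safe = np.where(degenerate, 1.0, norms)
    return centered / safe[:, None], degenerate


def cross_correlation_matrix(
    mrna: ExpressionMatrix, mirna: ExpressionMatrix
) -> CorrelationMatrix:
    """All mRNA x miRNA Pearson coefficients as one blocked matrix product.

    Both matrices must be log2 scale with identical sample order. Equivalent
    to calling :func:`pearson` per pair (within ~1e-12), but a single matmul.
    Zero-variance profiles produce NaN columns/rows with a warning.
    """
    if mrna.scale != "log2" or mirna.scale != "log2":
        raise ValueError("correlate log2-scale matrices (run preprocessing first)")
    if mrna.sample_ids != mirna.sample_ids:
        raise ValueError("sample ids differ or are ordered differently; align first")
    zm, bad_m = _standardize_rows(mrna.values)
    zi, bad_i = _standardize_rows(mirna.values)
    n_bad = int(bad_m.sum() + bad_i.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} zero-variance profile(s); their correlations are undefined (NaN)"
        )
    r = np.clip(zm @ zi.T, -1.0, 1.0)
    r[bad_m, :] = np.nan
    r[:, bad_i] = np.nan
    return CorrelationMatrix(list(mrna.gene_ids), list(mirna.gene_ids), r)


def screen_negative_pairs(
    c: CorrelationMatrix, cutoff: float = DEFAULT_PAIR_CUTOFF
) -> list[CorrelationPair]:
    """Pairs with r strictly below ``cutoff``, deterministically ordered.

    Sorted ascending by r, ties broken lexicographically by (miRNA, gene).
    NaN entries (undefined correlations) never pass the screen.
    """
    with np.errstate(invalid="ignore"):
        rows, cols = np.nonzero(c.r < cutoff)
    pairs = [
        CorrelationPair(c.col_ids[j], c.row_ids[i], float(c.r[i, j]))
        for i, j in zip(rows, cols)
    ]
    pairs.sort(key=lambda p: (p.r, p.mirna, p.gene))
    return pairs


def pairs_to_frame(pairs: list[CorrelationPair]) -> pd.DataFrame:
    """Tabulate screened pairs: rank, miRNA, gene, display and full-precision r."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(pairs) + 1),
            "miRNA": [p.mirna for p in pairs],
            "gene": [p.gene for p in pairs],
            "correlation": [f"{p.r:.2f}" for p in pairs],
            "correlation_full": [repr(p.r) for p in pairs],
        }
    )


def write_pair_table(pairs: list[CorrelationPair], path: str | Path) -> None:
    """Write the screened pairs as TSV (header always present)."""
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
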