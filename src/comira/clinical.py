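"""Clinical association of a dichotomized expression marker.

Patients are split into high/low expression groups at the median, each
categorical clinical feature is cross-tabulated against the groups, and
association is tested with a chi-square test (Yates continuity correction
for 2x2 tables, plain Pearson chi-square otherwise). Overall survival is
itself dichotomized at its median before cross-tabulation; no survival
regression is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class ClinicalError(ValueError):
    pass


@dataclass
class ClinicalRecord:
    """One patient: categorical features plus optional survival time (days)."""

    patient_id: str
    features: dict[str, str | None] = field(default_factory=dict)
    survival_days: float | None = None

    def __post_init__(self) -> None:
        if self.survival_days is not None and self.survival_days < 0:
            raise ClinicalError("survival_days must be non-negative")


@dataclass
class ContingencyTable:
    """r x c integer counts: feature categories (rows) x expression groups."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ClinicalError("counts shape does not match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ClinicalError("need at least 2 rows and 2 columns")
        if np.any(self.counts < 0) or self.counts.sum() < 1:
            raise ClinicalError("counts must be non-negative with total >= 1")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    correction_applied: bool


def dichotomize_expression(
    values: dict[str, float], rule: str = "median"
) -> dict[str, str]:
    """Median split: high iff value > median, ties go low.

    With all values identical everything is "low" (warned) — a degenerate
    marker, not an error.
    """
    if rule != "median":
        raise ClinicalError(f"unknown split rule {rule!r}")
    if len(values) < 2:
        raise ClinicalError("need at least 2 patients")
    arr = np.array(list(values.values()), dtype=float)
    med = float(np.median(arr))
    if np.all(arr == arr[0]):
        warnings.warn("all expression values identical; every patient is 'low'")
    return {p: ("high" if v > med else "low") for p, v in values.items()}


def survival_median_split(records: list[ClinicalRecord]) -> dict[str, str]:
    """Group patients by survival <= median vs > median of non-missing times."""
    days = {r.patient_id: r.survival_days for r in records if r.survival_days is not None}
    if len(days) < 2:
        raise ClinicalError("need at least 2 records with survival data")
    med = float(np.median(list(days.values())))
    return {p: ("le_median" if d <= med else "gt_median") for p, d in days.items()}


def build_contingency(
    feature: dict[str, str | None],
    groups: dict[str, str],
    row_order: list[str] | None = None,
    col_order: list[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate a clinical feature against expression groups.

    Counts run over patients present in both maps with a non-missing feature
    value (None = missing, dropped pairwise — this is why row totals differ
    across features). Row/column orders default to first-appearance order.
    """
    shared = [p for p in feature if p in groups and feature[p] is not None]
    if not shared:
        raise ClinicalError("no patients with both feature and group")
    if row_order is None:
        row_order = list(dict.fromkeys(feature[p] for p in shared))
    if col_order is None:
        col_order = list(dict.fromkeys(groups[p] for p in shared))
    counts = np.zeros((len(row_order), len(col_order)), dtype=int)
    ri = {c: i for i, c in enumerate(row_order)}
    ci = {c: i for i, c in enumerate(col_order)}
    for p in shared:
        counts[ri[feature[p]], ci[groups[p]]] += 1
    table = ContingencyTable(row_order, col_order, counts)
    if np.any(table.counts.sum(axis=1) == 0) or np.any(table.counts.sum(axis=0) == 0):
        raise ClinicalError("degenerate margin: a row or column total is zero")
    return table


def chi_square_test(t: ContingencyTable) -> ChiSquareResult:
    """Chi-square test of independence on a contingency table.

    2x2 tables get the Yates continuity correction — the statistic is
    ``N (max(|ad-bc| - N/2, 0))^2 / (r1 r2 c1 c2)`` — larger tables the
    uncorrected Pearson statistic with df=(r-1)(c-1).
    """
    if np.any(t.counts.sum(axis=1) == 0) or np.any(t.counts.sum(axis=0) == 0):
        raise ClinicalError("zero margin: chi-square test undefined")
    is_2x2 = t.counts.shape == (2, 2)
    stat, p, df, _ = stats.chi2_contingency(t.counts, correction=is_2x2)
    return ChiSquareResult(float(stat), int(df), float(p), is_2x2)


def read_clinical_tsv(path: str | Path, survival_column: str = "survival_days") -> list[ClinicalRecord]:
    """Read a one-row-per-patient TSV; empty cells are missing values."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("patient_id")
    records = []
    for pid, row in df.iterrows():
        feats = {
            k: (None if pd.isna(v) else str(v))
            for k, v in row.items()
            if k != survival_column
        }
        surv = row.get(survival_column)
        records.append(
            ClinicalRecord(
                str(pid),
                feats,
                None if surv is None or pd.isna(surv) else float(surv),
            )
        )
    return records


def write_clinical_tsv(records: list[ClinicalRecord], path: str | Path) -> None:
    feature_names = sorted({k for r in records for k in r.features})
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id}
        row.update({k: r.features.get(k) for k in feature_names})
        row["survival_days"] = r.survival_days
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def association_table(
    tables: dict[str, ContingencyTable],
) -> pd.DataFrame:
    """Summarize feature tables and chi-square p-values, one row per category.

    Columns: feature, category, N (row total), one column per expression
    group, and the feature-level p-value (repeated on its first row only,
    mirroring the usual clinical-relevance table layout).
    """
    rows = []
    for feat, tab in tables.items():
        res = chi_square_test(tab)
        for i, cat in enumerate(tab.row_labels):
            rows.append(
                {
                    "feature": feat,
                    "category": cat,
                    "N": int(tab.counts[i].sum()),
                    **{g: int(tab.counts[i, j]) for j, g in enumerate(tab.col_labels)},
                    "p_value": res.p_value if i == 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
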