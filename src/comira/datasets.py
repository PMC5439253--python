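"""Bundled reference tables.

``MIR200C_CLINICAL_TABLES`` holds the published miR-200c clinical-relevance
contingency tables from a 255-patient TCGA colon adenocarcinoma cohort:
for each clinical feature, patient counts cross-tabulated by high/low
miR-200c expression (columns ordered high, low). Row totals differ across
features because missing clinical values are dropped per feature.

The age table printed in that source is internally inconsistent (its margin
does not equal the sum of its cells), so it is excluded here.
``MIR200C_REPORTED_P`` records the p-values reported alongside the tables,
for comparison against recomputation.
"""

from __future__ import annotations

from .clinical import ContingencyTable

_HIGH_LOW = ["high", "low"]


def _t(rows: list[str], counts: list[list[int]]) -> ContingencyTable:
    return ContingencyTable(rows, list(_HIGH_LOW), counts)


MIR200C_CLINICAL_TABLES: dict[str, ContingencyTable] = {
    "distant_metastasis": _t(["0", "1"], [[107, 97], [22, 19]]),
    "colon_polyps_history": _t(["yes", "no"], [[47, 58], [78, 55]]),
    "lymphatic_invasion": _t(["yes", "no"], [[69, 58], [43, 58]]),
    "tumor_stage": _t(
        ["I", "II", "III", "IV"],
        [[24, 26], [47, 42], [36, 29], [22, 19]],
    ),
    "neoplasm_cancer_status": _t(["with_tumor", "tumor_free"], [[110, 104], [13, 19]]),
    "positive_lymph_nodes_ge2": _t(["ge2", "lt2"], [[37, 46], [83, 77]]),
    "vascular_invasion": _t(["yes", "no"], [[29, 29], [63, 88]]),
    "overall_survival": _t(["le_median", "gt_median"], [[66, 90], [58, 34]]),
}

MIR200C_REPORTED_P: dict[str, float] = {
    "distant_metastasis": 1.0,
    "colon_polyps_history": 0.04,
    "lymphatic_invasion": 0.1,
    "tumor_stage": 0.88,
    "neoplasm_cancer_status": 0.34,
    "positive_lymph_nodes_ge2": 0.34,
    "vascular_invasion": 0.35,
    "overall_survival": 0.0025,
}
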