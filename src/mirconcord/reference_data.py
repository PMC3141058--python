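"""Reference per-miRNA concordance summary rows from the original
ovarian-cancer epithelium (CEPI) vs surface-epithelium (OSE) study.

These are the published per-miRNA/per-method IC / NC / PC percentages and
target totals for the twelve differentially expressed annotated miRNAs —
under miRanda predictions, under the three-algorithm intersection, and for
the experimentally validated miR-7/miR-128 targets — together with the
per-algorithm overall trios.  They serve as fixed inputs for validating the
aggregation rules (unweighted mean of per-miRNA percentages within the up-
and down-regulated groups, then the mean of the two group means; unweighted
means across prediction algorithms and validation methods): recomputing the
summary rows from the per-miRNA rows must land within rounding of the
published aggregate rows.
"""

from __future__ import annotations

import pandas as pd

#: per-miRNA fractions under miRanda predictions (tissue comparison)
TISSUE_MIRANDA_ROWS: list[dict] = [
    {"mirna": "miR-7", "direction": "up", "total": 2363, "pct_IC": 10.62, "pct_NC": 79.94, "pct_PC": 9.44},
    {"mirna": "miR-18a", "direction": "up", "total": 1738, "pct_IC": 11.10, "pct_NC": 79.86, "pct_PC": 9.03},
    {"mirna": "miR-18b", "direction": "up", "total": 1710, "pct_IC": 11.40, "pct_NC": 79.24, "pct_PC": 9.36},
    {"mirna": "miR-126", "direction": "up", "total": 84, "pct_IC": 14.29, "pct_NC": 75.00, "pct_PC": 10.71},
    {"mirna": "miR-128", "direction": "up", "total": 2691, "pct_IC": 11.82, "pct_NC": 79.23, "pct_PC": 8.96},
    {"mirna": "miR-141", "direction": "up", "total": 3074, "pct_IC": 13.53, "pct_NC": 77.91, "pct_PC": 8.56},
    {"mirna": "miR-205", "direction": "up", "total": 2268, "pct_IC": 13.49, "pct_NC": 78.31, "pct_PC": 8.20},
    {"mirna": "miR-429", "direction": "up", "total": 3316, "pct_IC": 13.48, "pct_NC": 78.62, "pct_PC": 7.90},
    {"mirna": "miR-93*", "direction": "up", "total": 2252, "pct_IC": 13.14, "pct_NC": 77.00, "pct_PC": 9.86},
    {"mirna": "miR-383", "direction": "down", "total": 2118, "pct_IC": 9.02, "pct_NC": 78.80, "pct_PC": 12.18},
    {"mirna": "miR-320a", "direction": "down", "total": 3073, "pct_IC": 8.30, "pct_NC": 79.08, "pct_PC": 12.63},
    {"mirna": "miR-193a-5p", "direction": "down", "total": 1216, "pct_IC": 12.01, "pct_NC": 78.45, "pct_PC": 9.54},
]

#: published aggregate rows for the miRanda table
TISSUE_MIRANDA_AGGREGATES = {
    "up": {"IC": 12.54, "NC": 78.34, "PC": 9.11},
    "down": {"IC": 9.77, "NC": 78.78, "PC": 11.45},
    "overall": {"IC": 11.16, "NC": 78.56, "PC": 10.28},
}

#: per-miRNA fractions under the miRanda ∩ TargetScan ∩ PicTar intersection
TISSUE_INTERSECTION_ROWS: list[dict] = [
    {"mirna": "miR-7", "direction": "up", "total": 105, "pct_IC": 10.48, "pct_NC": 84.76, "pct_PC": 4.76},
    {"mirna": "miR-18a", "direction": "up", "total": 59, "pct_IC": 13.56, "pct_NC": 83.05, "pct_PC": 3.39},
    {"mirna": "miR-18b", "direction": "up", "total": 59, "pct_IC": 13.56, "pct_NC": 83.05, "pct_PC": 3.39},
    {"mirna": "miR-126", "direction": "up", "total": 2, "pct_IC": 0.00, "pct_NC": 100.00, "pct_PC": 0.00},
    {"mirna": "miR-128", "direction": "up", "total": 237, "pct_IC": 11.81, "pct_NC": 79.75, "pct_PC": 8.44},
    {"mirna": "miR-141", "direction": "up", "total": 177, "pct_IC": 15.82, "pct_NC": 74.58, "pct_PC": 9.60},
    {"mirna": "miR-205", "direction": "up", "total": 73, "pct_IC": 21.92, "pct_NC": 67.12, "pct_PC": 10.96},
    {"mirna": "miR-383", "direction": "down", "total": 15, "pct_IC": 0.00, "pct_NC": 80.00, "pct_PC": 20.00},
    {"mirna": "miR-320a", "direction": "down", "total": 112, "pct_IC": 3.57, "pct_NC": 84.82, "pct_PC": 11.61},
    {"mirna": "miR-193a-5p", "direction": "down", "total": 2, "pct_IC": 0.00, "pct_NC": 50.00, "pct_PC": 50.00},
]

TISSUE_INTERSECTION_AGGREGATES = {
    "up": {"IC": 12.45, "NC": 81.76, "PC": 5.79},
    "down": {"IC": 1.19, "NC": 71.61, "PC": 27.20},
    "overall": {"IC": 6.82, "NC": 76.68, "PC": 16.50},
}

#: per-algorithm overall trios (inputs to the cross-algorithm average)
ALGORITHM_OVERALLS = {
    "M": {"IC": 11.16, "NC": 78.56, "PC": 10.28},
    "TS": {"IC": 10.37, "NC": 79.34, "PC": 10.29},
    "PT": {"IC": 9.41, "NC": 80.48, "PC": 10.11},
}

ALGORITHM_AVERAGE = {"IC": 10.31, "NC": 79.46, "PC": 10.23}

#: tissue-level fractions of experimentally validated targets, per
#: prediction method, for the two transfected miRNAs
VALIDATED_ROWS: dict[str, list[dict]] = {
    "miR-7": [
        {"method": "M", "total": 180, "pct_IC": 12.22, "pct_NC": 80.56, "pct_PC": 7.22},
        {"method": "TS", "total": 60, "pct_IC": 6.67, "pct_NC": 88.33, "pct_PC": 5.00},
        {"method": "PT", "total": 37, "pct_IC": 0.00, "pct_NC": 91.89, "pct_PC": 8.11},
        {"method": "M_TS", "total": 47, "pct_IC": 6.38, "pct_NC": 87.23, "pct_PC": 6.38},
        {"method": "PT_TS", "total": 27, "pct_IC": 0.00, "pct_NC": 96.30, "pct_PC": 3.70},
        {"method": "PT_M", "total": 33, "pct_IC": 0.00, "pct_NC": 90.91, "pct_PC": 9.09},
        {"method": "M_TS_PT", "total": 23, "pct_IC": 0.00, "pct_NC": 95.65, "pct_PC": 4.35},
    ],
    "miR-128": [
        {"method": "M", "total": 252, "pct_IC": 11.90, "pct_NC": 74.60, "pct_PC": 13.49},
        {"method": "TS", "total": 103, "pct_IC": 10.68, "pct_NC": 75.73, "pct_PC": 13.59},
        {"method": "PT", "total": 63, "pct_IC": 17.46, "pct_NC": 69.84, "pct_PC": 12.70},
        {"method": "M_TS", "total": 87, "pct_IC": 12.64, "pct_NC": 72.41, "pct_PC": 14.94},
        {"method": "PT_TS", "total": 49, "pct_IC": 16.33, "pct_NC": 69.39, "pct_PC": 14.29},
        {"method": "M_PT", "total": 52, "pct_IC": 11.54, "pct_NC": 75.00, "pct_PC": 13.46},
        {"method": "M_PT_TS", "total": 43, "pct_IC": 11.63, "pct_NC": 72.09, "pct_PC": 16.28},
    ],
}

VALIDATED_AGGREGATES = {
    "miR-7": {"IC": 3.61, "NC": 90.12, "PC": 6.26},
    "miR-128": {"IC": 13.17, "NC": 72.73, "PC": 14.11},
    "overall": {"IC": 8.39, "NC": 81.42, "PC": 10.19},
}


def tissue_frame(rows: list[dict]) -> pd.DataFrame:
    """Per-miRNA rows as the DataFrame FractionSummary.from_per_mirna expects."""
    df = pd.DataFrame(rows).set_index("mirna")
    df = df.rename(columns={"direction": "mirna_direction"})
    return df[["total", "pct_IC", "pct_NC", "pct_PC", "mirna_direction"]]
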