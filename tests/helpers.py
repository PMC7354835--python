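"""Shared test helpers: derived-feature shortcuts and the printed-count oracle data.

PRINTED_UNIVARIABLE holds the published univariable 2x2 rows (counts as
(stable-unexposed, progressed-unexposed, stable-exposed, progressed-exposed)
with the published OR, 95% CI and p).  These serve as closed-form oracle
inputs; every entry was recomputed from the counts before being frozen here.
"""

from __future__ import annotations

import pandas as pd

from neuroprog import features
from neuroprog.cohort_io import CohortTable, collapse_outcomes
from neuroprog.models import ContingencyTable


def pattern_exposure(
    cohort: CohortTable,
    count_col: str = "n_both",
    cutoff: int = 2,
    z_threshold: float = 0.0,
) -> pd.Series:
    """End-to-end exposure: z-score, classify lobes, dichotomize the count."""
    panel = features.compute_zscores(cohort)
    profile = features.classify_lobes(panel, z_threshold)
    flags = features.dichotomize_count(profile.counts[count_col], cutoff)
    return pd.Series(flags.values, index=cohort.df.index)


def outcome_of(cohort: CohortTable) -> pd.Series:
    return collapse_outcomes(cohort)


def ct(cells: tuple[int, int, int, int]) -> ContingencyTable:
    return ContingencyTable(*cells)


# (label, cells, OR, (ci_low, ci_high), p or None for "<0.001")
PRINTED_UNIVARIABLE = [
    ("markers_M1_1_vs_0", (16, 4, 14, 9), 2.57, (0.65, 10.21), 0.179),
    ("markers_M1_2_vs_0", (16, 4, 16, 11), 2.75, (0.72, 10.48), 0.138),
    ("markers_M1_3_vs_0", (16, 4, 3, 3), 4.00, (0.58, 27.82), 0.161),
    ("markers_M1_sex", (24, 13, 25, 14), 1.03, (0.40, 2.65), 0.945),
    ("markers_M2_1_vs_0", (42, 8, 35, 23), 3.45, (1.37, 8.67), 0.008),
    ("markers_M2_2_vs_0", (42, 8, 22, 19), 4.53, (1.71, 12.01), 0.002),
    ("sex_full_cohort", (50, 27, 49, 23), 0.87, (0.44, 1.72), 0.687),
    ("pattern_atrophy_only", (58, 32, 41, 18), 0.80, (0.39, 1.61), 0.524),
    ("pattern_hypometab_only", (67, 32, 32, 18), 1.18, (0.58, 2.41), 0.654),
    ("pattern_both", (69, 17, 30, 33), 4.46, (2.16, 9.22), None),
    ("frontal_congruent", (25, 4, 20, 25), 7.81, (2.33, 26.15), 0.001),
    ("frontal_iso_hypometab", (25, 4, 23, 14), 3.80, (1.09, 13.24), 0.036),
    ("frontal_iso_atrophy", (25, 4, 31, 7), 1.41, (0.37, 5.37), 0.613),
    ("temporal_congruent", (28, 6, 28, 30), 5.00, (1.80, 13.88), 0.002),
    ("temporal_iso_hypometab", (28, 6, 21, 8), 1.78, (0.54, 5.90), 0.347),
    ("temporal_iso_atrophy", (28, 6, 22, 6), 1.27, (0.36, 4.50), 0.708),
    ("parietal_congruent", (26, 7, 28, 27), 3.58, (1.33, 9.62), 0.011),
    ("parietal_iso_hypometab", (26, 7, 20, 10), 1.86, (0.60, 5.74), 0.282),
    ("parietal_iso_atrophy", (26, 7, 25, 6), 0.89, (0.26, 3.02), 0.854),
    ("occipital_congruent", (17, 9, 33, 21), 1.20, (0.45, 3.19), 0.712),
    ("occipital_iso_hypometab", (17, 9, 20, 10), 0.94, (0.31, 2.86), 0.920),
    ("occipital_iso_atrophy", (17, 9, 29, 10), 0.65, (0.22, 1.92), 0.437),
]
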