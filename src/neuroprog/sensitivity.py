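"""Sensitivity and subgroup analysis grid for the pattern progression model.

The published robustness programme varies, one axis at a time or jointly:
the z-score dichotomization threshold (0, 0.1, 0.5 in magnitude; negative
for abnormal-low variables, positive for abnormal-high ones), the lobe-count
cut-off (1, 2, 3), the outcome definition (clinician label vs an MMSE
decline of >= 3 points), the adjustment set (age+sex, optionally plus
disease duration and education) and the cohort filter (all patients vs
MCI+dementia only).  :func:`run_sensitivity` evaluates every requested cell,
records the full model table with provenance, and flags whether each cell's
+A/+H point estimate keeps the direction of the base cell — the robustness
criterion of interest.  Cell-level failures (degenerate outcomes, separation)
are captured as structured failures, never raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import features
from .cohort_io import CohortTable, collapse_outcomes
from .models import model_table

__all__ = [
    "GridSpec",
    "GridCell",
    "SensitivityGrid",
    "mmse_decline_outcome",
    "subgroup_filter",
    "pattern_model_table",
    "run_sensitivity",
]

log = logging.getLogger(__name__)

PATTERN_TERMS = {
    "atrophy_only": "n_atrophy_only",
    "hypometab_only": "n_hypometab_only",
    "both": "n_both",
}


@dataclass(frozen=True)
class GridSpec:
    """Axes of the sensitivity grid; the first entry of each axis is the base."""

    z_thresholds: tuple[float, ...] = (0.0, 0.1, 0.5)
    lobe_cutoffs: tuple[int, ...] = (2, 1, 3)
    outcomes: tuple[str, ...] = ("clinician",)        # or "mmse_decline"
    adjustments: tuple[str, ...] = ("age_sex",)       # or "age_sex_duration_education"
    cohort_filters: tuple[str, ...] = ("all",)        # or "mci_dementia"
    mmse_delta: int = 3
    rescore_subgroups: bool = False  # recompute z within subgroup instead of inheriting

    def __post_init__(self) -> None:
        if not (self.z_thresholds and self.lobe_cutoffs and self.outcomes
                and self.adjustments and self.cohort_filters):
            raise ValueError("every grid axis must be non-empty")
        if any(t < 0 for t in self.z_thresholds):
            raise ValueError("z thresholds are magnitudes (>= 0)")

    def cells(self):
        return product(self.z_thresholds, self.lobe_cutoffs, self.outcomes,
                       self.adjustments, self.cohort_filters)


@dataclass
class GridCell:
    key: tuple
    n: int | None = None
    n_excluded: int = 0
    table: pd.DataFrame | None = None
    error: str | None = None
    direction_matches_base: bool | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None

    def pattern_or(self, pattern: str = "both") -> float:
        if self.table is None:
            return float("nan")
        row = self.table[(self.table["variable"] == pattern)
                         & (self.table["level"] == "True")]
        return float(row["or_univariable"].iloc[0]) if len(row) else float("nan")


@dataclass
class SensitivityGrid:
    spec: GridSpec
    cells: dict[tuple, GridCell]

    @property
    def base_key(self) -> tuple:
        return (self.spec.z_thresholds[0], self.spec.lobe_cutoffs[0],
                self.spec.outcomes[0], self.spec.adjustments[0],
                self.spec.cohort_filters[0])

    def summary(self) -> pd.DataFrame:
        rows = []
        for key, cell in self.cells.items():
            rows.append(
                {
                    "z_threshold": key[0], "lobe_cutoff": key[1], "outcome": key[2],
                    "adjustment": key[3], "cohort_filter": key[4],
                    "n": cell.n, "n_excluded": cell.n_excluded,
                    "or_both_univariable": cell.pattern_or("both"),
                    "direction_matches_base": cell.direction_matches_base,
                    "error": cell.error,
                }
            )
        return pd.DataFrame(rows)


def mmse_decline_outcome(cohort: CohortTable, delta: int = 3) -> pd.Series:
    """Alternative outcome: progressed iff baseline minus follow-up MMSE >= delta.

    Subjects missing either MMSE score get a missing outcome (they are
    excluded downstream); a decline of exactly ``delta`` counts as
    progression.
    """
    base = cohort.df["mmse_baseline"].astype(float)
    fup = (cohort.df["mmse_followup"].astype(float)
           if "mmse_followup" in cohort.df.columns
           else pd.Series(np.nan, index=cohort.df.index))
    decline = base - fup
    out = pd.Series(
        np.where(decline >= delta, "progressed", "stable"), index=cohort.df.index
    )
    n_missing = int(decline.isna().sum())
    if n_missing:
        log.info("mmse_decline_outcome: excluding %d subjects without both MMSE scores",
                 n_missing)
    return out.where(decline.notna())


def subgroup_filter(cohort: CohortTable, keep: tuple[str, ...] = ("MCI", "dementia")) -> CohortTable:
    """Restrict the cohort to the given diagnosis groups (default drops SCD)."""
    mask = cohort.df["diagnosis_group"].isin(keep)
    if not mask.any():
        raise ValueError(f"no subjects left after keeping {keep}")
    return cohort.filter(mask, provenance_suffix=f"keep={'+'.join(keep)}")


def pattern_model_table(
    cohort: CohortTable,
    outcome: pd.Series,
    z_threshold: float = 0.0,
    lobe_cutoff: int = 2,
    adjustment: str = "age_sex",
    panel: features.ZScorePanel | None = None,
) -> pd.DataFrame:
    """The pattern progression model at a given threshold/cut-off configuration.

    Rebuilds lobe features at ``-z_threshold`` (abnormal-low direction),
    dichotomizes each pattern count at ``lobe_cutoff`` and fits the three
    pattern exposures mutually adjusted along with the adjustment covariates.
    """
    if panel is None:
        panel = features.compute_zscores(cohort)
    profile = features.classify_lobes(panel, -abs(z_threshold))
    idx = cohort.df.index
    terms: dict[str, pd.Series] = {}
    for name, col in PATTERN_TERMS.items():
        exposure = features.dichotomize_count(profile.counts[col], lobe_cutoff)
        terms[name] = pd.Series(
            pd.Categorical(exposure.map({False: "False", True: "True"}),
                           categories=["False", "True"]),
            index=idx,
        )
    adjust = {
        "age": cohort.df["age"].astype(float),
        "sex": pd.Series(pd.Categorical(cohort.df["sex"], categories=["female", "male"]),
                         index=idx),
    }
    if adjustment == "age_sex_duration_education":
        adjust["disease_duration"] = cohort.df["disease_duration"].astype(float)
        adjust["education"] = cohort.df["education"].astype(float)
    elif adjustment != "age_sex":
        raise ValueError(f"unknown adjustment set {adjustment!r}")
    return model_table(outcome, terms, adjustments=adjust)


def run_sensitivity(cohort: CohortTable, spec: GridSpec = GridSpec()) -> SensitivityGrid:
    """Evaluate the full sensitivity grid; every cell holds a result or a failure.

    By default z-scores are computed once on the full cohort and inherited by
    subgroup cells (the subgroup analyses are the same model on fewer
    patients); ``spec.rescore_subgroups`` recomputes them within the
    subgroup instead.
    """
    full_panel = features.compute_zscores(cohort)
    grid = SensitivityGrid(spec=spec, cells={})
    base_or: float | None = None
    for key in spec.cells():
        z_thr, cutoff, outcome_def, adjustment, cohort_filter = key
        cell = GridCell(key=key, provenance={
            "z_threshold": z_thr, "lobe_cutoff": cutoff, "outcome": outcome_def,
            "adjustment": adjustment, "cohort_filter": cohort_filter,
            "provenance": cohort.provenance,
        })
        try:
            if cohort_filter == "mci_dementia":
                sub = subgroup_filter(cohort)
                if spec.rescore_subgroups:
                    panel = features.compute_zscores(sub)
                else:
                    ids = sub.df["subject_id"].astype(str).values
                    panel = features.ZScorePanel(
                        z=full_panel.z.loc[ids], direction=full_panel.direction,
                        mean=full_panel.mean, sd=full_panel.sd)
            elif cohort_filter == "all":
                sub, panel = cohort, full_panel
            else:
                raise ValueError(f"unknown cohort filter {cohort_filter!r}")

            if outcome_def == "clinician":
                outcome = collapse_outcomes(sub)
            elif outcome_def == "mmse_decline":
                outcome = mmse_decline_outcome(sub, spec.mmse_delta)
            else:
                raise ValueError(f"unknown outcome definition {outcome_def!r}")
            cell.n_excluded = int(outcome.isna().sum())

            table = pattern_model_table(
                sub, outcome, z_threshold=z_thr, lobe_cutoff=cutoff,
                adjustment=adjustment, panel=panel,
            )
            cell.table = table
            cell.n = table.attrs.get("n")
            log.info("cell %s: n=%s excluded=%d", key, cell.n, cell.n_excluded)
        except Exception as exc:  # structured failure, grid keeps going
            cell.error = f"{type(exc).__name__}: {exc}"
            log.info("cell %s failed: %s", key, cell.error)
        grid.cells[key] = cell
        if key == grid.base_key and cell.ok:
            base_or = cell.pattern_or("both")
    if base_or is not None and np.isfinite(base_or):
        for cell in grid.cells.values():
            if cell.ok:
                orr = cell.pattern_or("both")
                if np.isfinite(orr):
                    cell.direction_matches_base = (orr > 1) == (base_or > 1)
    return grid
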