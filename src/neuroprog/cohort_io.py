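"""Cohort data model and delimited-text I/O.

A cohort is a per-subject table of demographics, clinical scores, regional
imaging quantities (8 unilateral lobe volumes in mm^3, 8 unilateral lobe
FDG-PET SUVRs, total ventricular volume, total grey+white-matter SUVR),
optional CSF total tau, and a 12-month clinical disease-course label.
The table is held as a :class:`pandas.DataFrame` with canonical snake_case
column names; :func:`read_cohort` maps arbitrary column names onto those
roles through a user-supplied schema.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "BILATERAL_LOBES",
    "VOLUME_COLUMNS",
    "SUVR_COLUMNS",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "RAW_OUTCOMES",
    "CohortTable",
    "CohortSchemaError",
    "CohortParseError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "collapse_outcome",
    "collapse_outcomes",
    "write_results_table",
]

#: Unilateral lobes, left/right x frontal/temporal/parietal/occipital.
BILATERAL_LOBES = ("frontal", "temporal", "parietal", "occipital")
LOBES = tuple(f"{side}_{lobe}" for lobe in BILATERAL_LOBES for side in ("left", "right"))

VOLUME_COLUMNS = tuple(f"vol_{lobe}" for lobe in LOBES)
SUVR_COLUMNS = tuple(f"suvr_{lobe}" for lobe in LOBES)

REQUIRED_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "diagnosis_group",
    "mmse_baseline",
    "outcome_raw",
    "ventricular_volume",
    "total_suvr",
)
OPTIONAL_COLUMNS = (
    "etiology",
    "mmse_followup",
    "follow_up_days",
    "csf_tau",
    "disease_duration",
    "education",
)

SEXES = ("female", "male")
DIAGNOSIS_GROUPS = ("SCD", "MCI", "dementia")
RAW_OUTCOMES = ("progression", "stable", "fluctuation", "improvement")

#: Collapse of the 4 clinician disease-course labels into a binary outcome:
#: too few fluctuating/improving courses exist for separate analysis, so all
#: non-progressing courses count as stable.
OUTCOME_COLLAPSE = {
    "progression": "progressed",
    "stable": "stable",
    "fluctuation": "stable",
    "improvement": "stable",
}

NUMERIC_COLUMNS = (
    ("age", "mmse_baseline", "mmse_followup", "follow_up_days", "ventricular_volume",
     "total_suvr", "csf_tau", "disease_duration", "education")
    + VOLUME_COLUMNS
    + SUVR_COLUMNS
)


class CohortSchemaError(ValueError):
    """A required role is missing or a lobe panel is incomplete."""


class CohortParseError(ValueError):
    """A cell could not be parsed as the type its column requires."""


class CohortValidationError(ValueError):
    """A parsed table violates a cohort invariant."""


@dataclass
class CohortTable:
    """An ordered collection of subject records plus provenance.

    ``df`` uses canonical column names; rows are subjects.  ``truth`` is
    only populated for synthetic cohorts and carries generator bookkeeping
    (latent severity, true exposure), never used by the analysis itself.
    """

    df: pd.DataFrame
    provenance: str = "unspecified"
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        validate_cohort(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_lobe_volumes(self) -> bool:
        return all(c in self.df.columns for c in VOLUME_COLUMNS)

    @property
    def has_lobe_suvrs(self) -> bool:
        return all(c in self.df.columns for c in SUVR_COLUMNS)

    def filter(self, mask: pd.Series, provenance_suffix: str = "filtered") -> "CohortTable":
        sub = self.df.loc[mask].reset_index(drop=True)
        truth = self.truth.loc[mask.values].reset_index(drop=True) if self.truth is not None else None
        return CohortTable(sub, provenance=f"{self.provenance}|{provenance_suffix}", truth=truth)


def _check_lobe_panel(columns, panel, modality: str) -> None:
    present = [c for c in panel if c in columns]
    if present and len(present) != len(panel):
        missing = sorted(set(panel) - set(present))
        raise CohortSchemaError(
            f"incomplete {modality} lobe panel: missing columns {missing}; "
            "the 8 unilateral lobes must be all present or all absent"
        )


def validate_cohort(df: pd.DataFrame) -> None:
    """Check structural and range invariants; raise on violation.

    MMSE below the study's inclusion floor of 18 only warns, because the
    analysis code must still accept externally assembled cohorts.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns (roles): {missing}")
    _check_lobe_panel(df.columns, VOLUME_COLUMNS, "MRI volume")
    _check_lobe_panel(df.columns, SUVR_COLUMNS, "FDG-PET SUVR")

    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise CohortValidationError(f"duplicate subject_id values: {sorted(dup.unique())}")

    for col, allowed in (("sex", SEXES), ("diagnosis_group", DIAGNOSIS_GROUPS),
                         ("outcome_raw", RAW_OUTCOMES)):
        bad = set(df[col].dropna().unique()) - set(allowed)
        if bad:
            raise CohortValidationError(f"unknown {col} labels {sorted(bad)}; allowed {allowed}")

    for col in ("mmse_baseline", "mmse_followup"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            out = vals.dropna()
            if ((out < 0) | (out > 30)).any():
                raise CohortValidationError(f"{col} outside the 0-30 MMSE range")
    low = pd.to_numeric(df["mmse_baseline"], errors="coerce")
    if (low.dropna() < 18).any():
        warnings.warn(
            "mmse_baseline below 18: outside the study inclusion criterion (MMSE >= 18)",
            UserWarning,
            stacklevel=2,
        )
    if "mmse_followup" in df.columns and df["mmse_followup"].isna().any():
        warnings.warn(
            "missing follow-up MMSE for some subjects; they are excluded from "
            "MMSE-decline-based outcomes",
            UserWarning,
            stacklevel=2,
        )

    positive = list(VOLUME_COLUMNS) + list(SUVR_COLUMNS) + ["ventricular_volume", "total_suvr"]
    for col in positive:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce").dropna()
            if (vals <= 0).any():
                raise CohortValidationError(f"{col} must be strictly positive")


def read_cohort(path: str | Path, schema: dict[str, str] | None = None) -> CohortTable:
    """Read a delimited cohort file into a validated :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV (``,``) or TSV (``\\t``, chosen by ``.tsv``/``.txt`` suffix) file
        with a header row, UTF-8.
    schema
        Optional mapping ``role -> column name in the file`` for any role
        whose column is not already canonically named.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    if schema:
        missing = [col for col in schema.values() if col not in df.columns]
        if missing:
            raise CohortSchemaError(f"schema maps to absent columns: {missing}")
        df = df.rename(columns={v: k for k, v in schema.items()})

    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            raw = df[col]
            parsed = pd.to_numeric(raw, errors="coerce")
            bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
            if bad.any():
                idx = int(np.flatnonzero(bad.values)[0])
                raise CohortParseError(
                    f"non-numeric value {raw.iloc[idx]!r} in column {col!r} at data row {idx}"
                )
            df[col] = parsed
    for col in ("mmse_baseline", "mmse_followup", "follow_up_days", "education"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return CohortTable(df, provenance=str(path))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort as CSV/TSV (suffix-selected); inverse of read_cohort."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    cohort.df.to_csv(path, sep=sep, index=False)


def collapse_outcome(outcome_raw: str) -> str:
    """Collapse a clinician disease-course label to progressed/stable."""
    try:
        return OUTCOME_COLLAPSE[outcome_raw]
    except KeyError:
        raise CohortValidationError(
            f"unknown disease-course label {outcome_raw!r}; expected one of {RAW_OUTCOMES}"
        ) from None


def collapse_outcomes(cohort: CohortTable) -> pd.Series:
    """Binary outcome for every subject (progressed/stable), index-aligned."""
    return cohort.df["outcome_raw"].map(collapse_outcome)


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a model results table (one row per term level) as delimited text."""
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    results.to_csv(path, sep=sep, index=False)


def spec_digest(obj) -> str:
    """Short stable digest of a parameter object, used for provenance notes."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
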