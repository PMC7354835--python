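"""Feature engineering: intracohort z-scores and abnormality patterns.

All imaging and fluid markers are standardized against the study cohort's own
mean and sample standard deviation (no normative population is involved).
Direction conventions: lower-than-expected lobe volumes, lobe SUVRs and total
grey+white-matter SUVR are abnormal (atrophy / hypometabolism), while
higher-than-expected ventricular volume and CSF total tau are abnormal.

From the 8 unilateral lobes (left/right x frontal/temporal/parietal/occipital)
each subject gets per-lobe atrophy (+A) and hypometabolism (+H) flags, counts
of lobes carrying the patterns +A/-H, -A/+H and +A/+H, and per-bilateral-lobe
anatomical levels (no abnormality / isolated atrophy / isolated
hypometabolism / congruent-or-non-isolated abnormality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import BILATERAL_LOBES, LOBES, SUVR_COLUMNS, VOLUME_COLUMNS, CohortTable

__all__ = [
    "ABNORMAL_LOW",
    "ABNORMAL_HIGH",
    "ANATOMICAL_LEVELS",
    "MARKER_SETS",
    "ZScorePanel",
    "LobePatternProfile",
    "MarkerCount",
    "DegenerateVariableError",
    "direction_for",
    "compute_zscores",
    "dichotomize",
    "classify_lobes",
    "dichotomize_count",
    "anatomical_levels",
    "abnormal_marker_count",
]

ABNORMAL_LOW = "abnormal_low"    # abnormal when z < threshold (volumes, SUVRs)
ABNORMAL_HIGH = "abnormal_high"  # abnormal when z > threshold (ventricles, tau)

#: Ordered levels of the per-bilateral-lobe anatomical variable; the first
#: level is the model reference.
ANATOMICAL_LEVELS = (
    "no_abnormality",
    "congruent_or_nonisolated",
    "isolated_hypometabolism",
    "isolated_atrophy",
)

#: Abnormal-marker sets: M1 includes CSF tau (complete-case on tau), M2 does not.
MARKER_SETS = {
    "M1": ("ventricular_volume", "total_suvr", "csf_tau"),
    "M2": ("ventricular_volume", "total_suvr"),
}

_HIGH_DIRECTION = {"ventricular_volume", "csf_tau"}


class DegenerateVariableError(ValueError):
    """A variable cannot be z-scored (fewer than 2 values or zero spread)."""


def direction_for(variable: str) -> str:
    """Direction convention for a canonical variable name."""
    return ABNORMAL_HIGH if variable in _HIGH_DIRECTION else ABNORMAL_LOW


@dataclass
class ZScorePanel:
    """Subject x variable standardized values with direction conventions.

    ``z`` columns each have mean 0 and sample SD 1 over their non-missing
    entries; ``mean``/``sd`` record the standardization constants so the
    transform is invertible.
    """

    z: pd.DataFrame
    direction: dict[str, str]
    mean: pd.Series
    sd: pd.Series

    @property
    def variables(self) -> list[str]:
        return list(self.z.columns)


def compute_zscores(cohort: CohortTable, variables: list[str] | None = None) -> ZScorePanel:
    """Intracohort z-scores: (x - mean) / sample SD, column-wise.

    Each variable is standardized over the subjects non-missing for it, so a
    marker measured in a subset (CSF tau) is standardized against that
    subset's own mean and SD — exactly the subjects who can enter models
    using it.
    """
    if variables is None:
        variables = [
            c
            for c in list(VOLUME_COLUMNS) + list(SUVR_COLUMNS)
            + ["ventricular_volume", "total_suvr", "csf_tau"]
            if c in cohort.df.columns
        ]
    missing = [v for v in variables if v not in cohort.df.columns]
    if missing:
        raise KeyError(f"variables absent from cohort: {missing}")

    data = cohort.df[variables].astype(float)
    means, sds = {}, {}
    for v in variables:
        col = data[v].dropna()
        if len(col) < 2:
            raise DegenerateVariableError(f"{v}: fewer than 2 non-missing values")
        sd = float(col.std(ddof=1))
        if sd == 0.0:
            raise DegenerateVariableError(f"{v}: zero standard deviation")
        means[v], sds[v] = float(col.mean()), sd
    mean = pd.Series(means)
    sd = pd.Series(sds)
    z = (data - mean) / sd
    z.index = cohort.df["subject_id"].astype(str).values
    return ZScorePanel(
        z=z,
        direction={v: direction_for(v) for v in variables},
        mean=mean,
        sd=sd,
    )


def dichotomize(z, threshold: float = 0.0, direction: str = ABNORMAL_LOW):
    """Abnormality flag(s) for z-score(s) under a direction convention.

    ``abnormal_low``: abnormal iff z < threshold (threshold must be <= 0);
    ``abnormal_high``: abnormal iff z > threshold (threshold must be >= 0).
    A z exactly at the threshold is *not* abnormal (strict inequality).
    Accepts scalars, arrays, Series or DataFrames; missing stays missing.
    """
    if direction == ABNORMAL_LOW:
        if threshold > 0:
            raise ValueError("abnormal_low threshold must be <= 0")
        flag = z < threshold
    elif direction == ABNORMAL_HIGH:
        if threshold < 0:
            raise ValueError("abnormal_high threshold must be >= 0")
        flag = z > threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(z, (pd.Series, pd.DataFrame)):
        return flag.where(z.notna())
    return flag


@dataclass
class LobePatternProfile:
    """Per-subject, per-unilateral-lobe abnormality flags and pattern counts.

    ``atrophy``/``hypometab`` are boolean subject x lobe frames;
    ``counts`` holds the number of lobes (0-8) carrying each of the patterns
    ``n_atrophy_only`` (+A/-H), ``n_hypometab_only`` (-A/+H), ``n_both``
    (+A/+H) and ``n_neither`` (-A/-H); the four always sum to 8.
    """

    atrophy: pd.DataFrame
    hypometab: pd.DataFrame
    counts: pd.DataFrame
    z_threshold: float


def classify_lobes(panel: ZScorePanel, z_threshold: float = 0.0) -> LobePatternProfile:
    """Flag pronounced atrophy/hypometabolism per unilateral lobe and count patterns.

    A lobe is +A when its volume z-score is below ``z_threshold`` and +H when
    its SUVR z-score is below ``z_threshold`` (both are abnormal-low).
    """
    need = [c for c in list(VOLUME_COLUMNS) + list(SUVR_COLUMNS) if c not in panel.z.columns]
    if need:
        raise KeyError(f"panel lacks lobe columns: {need}")
    vol = panel.z[list(VOLUME_COLUMNS)].to_numpy()
    suvr = panel.z[list(SUVR_COLUMNS)].to_numpy()
    atrophy = vol < z_threshold
    hypometab = suvr < z_threshold
    counts = pd.DataFrame(
        {
            "n_atrophy_only": (atrophy & ~hypometab).sum(axis=1),
            "n_hypometab_only": (~atrophy & hypometab).sum(axis=1),
            "n_both": (atrophy & hypometab).sum(axis=1),
            "n_neither": (~atrophy & ~hypometab).sum(axis=1),
        },
        index=panel.z.index,
    )
    return LobePatternProfile(
        atrophy=pd.DataFrame(atrophy, index=panel.z.index, columns=list(LOBES)),
        hypometab=pd.DataFrame(hypometab, index=panel.z.index, columns=list(LOBES)),
        counts=counts,
        z_threshold=z_threshold,
    )


def dichotomize_count(count, cutoff: int = 2):
    """Exposure flag for a lobe count: exposed iff count >= cutoff.

    The primary analysis contrasts subjects with >= 2 affected lobes against
    0-1; sensitivity analyses move the cut-off to 1 or 3.
    """
    if cutoff not in (1, 2, 3):
        raise ValueError("lobe-count cutoff must be 1, 2 or 3")
    return count >= cutoff


def anatomical_levels(profile: LobePatternProfile) -> pd.DataFrame:
    """Collapse unilateral flags into a 4-level variable per bilateral lobe.

    With A = atrophy in either hemisphere and H = hypometabolism in either
    hemisphere of the lobe: neither -> ``no_abnormality``; A only ->
    ``isolated_atrophy``; H only -> ``isolated_hypometabolism``; both ->
    ``congruent_or_nonisolated`` (same-hemisphere congruence and
    cross-hemisphere co-occurrence are deliberately not distinguished).
    """
    out = {}
    for lobe in BILATERAL_LOBES:
        a = (
            profile.atrophy[f"left_{lobe}"] | profile.atrophy[f"right_{lobe}"]
        ).to_numpy()
        h = (
            profile.hypometab[f"left_{lobe}"] | profile.hypometab[f"right_{lobe}"]
        ).to_numpy()
        level = np.where(
            a & h,
            "congruent_or_nonisolated",
            np.where(a, "isolated_atrophy",
                     np.where(h, "isolated_hypometabolism", "no_abnormality")),
        )
        out[lobe] = pd.Categorical(level, categories=list(ANATOMICAL_LEVELS))
    return pd.DataFrame(out, index=profile.atrophy.index)


@dataclass
class MarkerCount:
    """Abnormal-marker counts over a marker set, complete-case.

    ``counts`` is indexed by subject_id and only contains subjects with every
    marker in the set measured; ``n_excluded`` records how many subjects were
    dropped for missingness (tau, typically).
    """

    counts: pd.Series
    marker_set: str
    n_excluded: int
    thresholds: tuple[float, float]


def abnormal_marker_count(
    panel: ZScorePanel,
    marker_set: str = "M1",
    thresholds: tuple[float, float] = (0.0, 0.0),
) -> MarkerCount:
    """Count abnormal markers per subject over marker set M1 or M2.

    ``thresholds`` is ``(low_direction, high_direction)``: the abnormal-low
    threshold applies to the total SUVR, the abnormal-high one to ventricular
    volume and CSF tau. Subjects missing any marker in the set are excluded
    (complete-case), which for M1 restricts to the tau-measured subset.
    """
    try:
        markers = MARKER_SETS[marker_set]
    except KeyError:
        raise ValueError(f"unknown marker set {marker_set!r}; use 'M1' or 'M2'") from None
    missing = [m for m in markers if m not in panel.z.columns]
    if missing:
        raise KeyError(f"panel lacks marker columns: {missing}")
    low_thr, high_thr = thresholds
    sub = panel.z[list(markers)]
    complete = sub.notna().all(axis=1)
    if not complete.any():
        raise ValueError(f"no complete cases for marker set {marker_set}")
    sub = sub.loc[complete]
    flags = pd.DataFrame(index=sub.index)
    for m in markers:
        if panel.direction[m] == ABNORMAL_HIGH:
            flags[m] = dichotomize(sub[m], high_thr, ABNORMAL_HIGH)
        else:
            flags[m] = dichotomize(sub[m], low_thr, ABNORMAL_LOW)
    counts = flags.astype(bool).sum(axis=1)
    counts.name = f"n_abnormal_{marker_set}"
    return MarkerCount(
        counts=counts,
        marker_set=marker_set,
        n_excluded=int((~complete).sum()),
        thresholds=(low_thr, high_thr),
    )
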