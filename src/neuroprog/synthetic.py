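"""Synthetic memory-clinic cohorts and deterministic contingency fixtures.

Two generators live here:

* :func:`generate_cohort` draws a cohort from a latent-severity model that
  mirrors the analysis assumptions — one standard-normal severity drives both
  lobewise atrophy (low volume) and hypometabolism (low SUVR) signals, and
  1-year progression follows a logistic model of the dichotomized +A/+H lobe
  count.  Margins are calibrated to a mixed memory-clinic population:
  n = 149, age 70.3 (SD 9.8), near-balanced sex, roughly one third
  progressors, CSF tau measured in about half the cohort.

* :func:`make_contingency_fixture` and friends build small deterministic
  cohorts whose derived exposure x outcome table equals requested 2x2 (or
  per-level) counts — including the counts printed in the source cohort's
  result tables (:data:`PRINTED_TABLES`) — with raw lobe values constructed
  so that intracohort z-scoring reproduces the intended flags.  Every fixture
  is verified against its request after construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features
from .cohort_io import (
    BILATERAL_LOBES,
    LOBES,
    CohortTable,
    spec_digest,
)
from .models import crosstab

__all__ = [
    "SyntheticSpec",
    "FixtureRequest",
    "FixtureConstructionError",
    "generate_cohort",
    "make_contingency_fixture",
    "make_marker_level_fixture",
    "make_anatomical_fixture",
    "named_fixture",
    "PRINTED_TABLES",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generating model (defaults = the emulated cohort).

    ``pattern_effect_log_or`` is the log odds ratio of progression per unit
    of the dichotomized +A/+H exposure (>= ``lobe_cutoff`` of 8 unilateral
    lobes with both volume and SUVR generating signals below zero); the
    default ln(4.46) matches the primary published effect.  The intercept
    -1.4 puts the marginal progression fraction near one third.
    ``risk_from='severity'`` switches to a deliberately mis-specified mode
    where risk follows continuous latent severity instead of the
    dichotomized pattern (for robustness experiments).
    """

    n: int = 149
    progression_log_odds_intercept: float = -1.4
    pattern_effect_log_or: float = float(np.log(4.46))
    age_mean: float = 70.3
    age_sd: float = 9.8
    latent_loading_atrophy: float = 0.6
    latent_loading_hypometab: float = 0.6
    residual_corr: float = 0.5
    tau_available_fraction: float = 76 / 149
    lobe_cutoff: int = 2
    risk_from: str = "pattern"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        for name in ("latent_loading_atrophy", "latent_loading_hypometab",
                     "tau_available_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.residual_corr < 1.0:
            raise ValueError("residual_corr must be in [0, 1)")
        if self.lobe_cutoff not in (1, 2, 3):
            raise ValueError("lobe_cutoff must be 1, 2 or 3")
        if self.risk_from not in ("pattern", "severity"):
            raise ValueError("risk_from must be 'pattern' or 'severity'")


# Affine maps from unit-variance signals to physical scales. Arbitrary but
# fixed; intracohort z-scoring cancels them exactly (z of mean + sd*signal
# equals the standardized signal).
_VOL_MEAN = {"frontal": 180_000.0, "temporal": 120_000.0,
             "parietal": 110_000.0, "occipital": 70_000.0}
_VOL_SD = {"frontal": 18_000.0, "temporal": 13_000.0,
           "parietal": 12_000.0, "occipital": 8_000.0}
_SUVR_MEAN = {"frontal": 1.15, "temporal": 1.05, "parietal": 1.10, "occipital": 1.20}
_SUVR_SD = 0.10


def _equicorrelated(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """n x p unit-variance noise with constant pairwise correlation rho."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, p))
    return np.sqrt(rho) * shared + np.sqrt(1 - rho) * own


def generate_cohort(spec: SyntheticSpec = SyntheticSpec()) -> CohortTable:
    """Draw a synthetic cohort; identical spec (incl. seed) -> identical table.

    The returned table carries a ``truth`` frame with the latent severity,
    the generating +A/+H lobe count, the true exposure flag and the
    progression probability, for generator self-checks only.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    s = rng.standard_normal(n)  # latent severity, higher = worse
    age = spec.age_mean + spec.age_sd * rng.standard_normal(n)
    z_age = (age - spec.age_mean) / spec.age_sd
    sex = np.where(rng.random(n) < 0.5, "female", "male")

    la, lh = spec.latent_loading_atrophy, spec.latent_loading_hypometab
    vol_z = -la * s[:, None] + np.sqrt(1 - la**2) * _equicorrelated(
        rng, n, 8, spec.residual_corr
    )
    suvr_z = -lh * s[:, None] + np.sqrt(1 - lh**2) * _equicorrelated(
        rng, n, 8, spec.residual_corr
    )

    df = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)]})
    df["age"] = np.round(age, 1)
    df["sex"] = sex
    for j, lobe in enumerate(LOBES):
        base = lobe.split("_", 1)[1]
        df[f"vol_{lobe}"] = _VOL_MEAN[base] + _VOL_SD[base] * vol_z[:, j]
    for j, lobe in enumerate(LOBES):
        base = lobe.split("_", 1)[1]
        df[f"suvr_{lobe}"] = np.maximum(
            _SUVR_MEAN[base] + _SUVR_SD * suvr_z[:, j], 0.05
        )

    # ventricular volume grows with age and severity; lognormal keeps it
    # positive and right-skewed like real ventricles
    vent_sig = 0.35 * z_age + 0.45 * s + 0.55 * rng.standard_normal(n)
    df["ventricular_volume"] = 57_000.0 * np.exp(0.55 * vent_sig)
    tot_sig = -0.6 * s + 0.8 * rng.standard_normal(n)
    df["total_suvr"] = np.maximum(1.092 + 0.106 * tot_sig, 0.05)
    tau_sig = 0.5 * s + 0.87 * rng.standard_normal(n)
    tau = 360.0 * np.exp(0.45 * tau_sig)
    have_tau = rng.random(n) < spec.tau_available_fraction  # MCAR
    df["csf_tau"] = np.where(have_tau, np.round(tau, 1), np.nan)

    # generating +A/+H count from the latent z-signals themselves
    both = (vol_z < 0) & (suvr_z < 0)
    count_ah = both.sum(axis=1)
    exposed = count_ah >= spec.lobe_cutoff
    if spec.risk_from == "pattern":
        lin = spec.progression_log_odds_intercept + spec.pattern_effect_log_or * exposed
    else:
        lin = spec.progression_log_odds_intercept + spec.pattern_effect_log_or * s
    p_prog = 1.0 / (1.0 + np.exp(-lin))
    progressed = rng.random(n) < p_prog
    # a small share of non-progressing courses is labelled improvement or
    # fluctuation, as clinicians occasionally do
    u = rng.random(n)
    outcome_raw = np.where(
        progressed, "progression",
        np.where(u < 0.05, "improvement", np.where(u < 0.06, "fluctuation", "stable")),
    )
    df["outcome_raw"] = outcome_raw

    # diagnosis strata follow severity; thresholds give roughly the
    # 35 SCD / 33 MCI / 81 dementia mix of a memory-clinic population
    df["diagnosis_group"] = np.where(
        s < -0.72, "SCD", np.where(s < -0.11, "MCI", "dementia")
    )
    mmse_b = np.clip(np.round(28.0 - 2.2 * np.clip(s, -1, 3)
                              + rng.normal(0, 1.2, n)), 18, 30).astype(int)
    decline = np.where(progressed, rng.poisson(3.0, n), rng.poisson(0.7, n))
    df["mmse_baseline"] = mmse_b
    df["mmse_followup"] = np.clip(mmse_b - decline, 0, 30).astype(int)
    df["follow_up_days"] = np.clip(
        np.round(rng.normal(424, 55, n)), 300, 600
    ).astype(int)
    df["disease_duration"] = np.round(np.clip(rng.gamma(2.0, 1.5, n), 0.1, 20.0), 1)
    df["education"] = np.clip(np.round(rng.normal(12, 3.5, n)), 5, 22).astype(int)

    truth = pd.DataFrame(
        {
            "severity": s,
            "count_ah": count_ah,
            "exposed": exposed,
            "p_progression": p_prog,
        }
    )
    return CohortTable(
        df, provenance=f"synthetic:{spec_digest(spec)}", truth=truth
    )


# ---------------------------------------------------------------------------
# deterministic contingency fixtures


class FixtureConstructionError(ValueError):
    """The requested contingency structure cannot be realized."""


@dataclass(frozen=True)
class FixtureRequest:
    """A 2x2 target: (stable, progressed) x (unexposed, exposed) counts."""

    stable_unexposed: int
    progressed_unexposed: int
    stable_exposed: int
    progressed_exposed: int
    feature: str = "pattern_both"  # +A/+H lobe count >= cutoff

    def __post_init__(self) -> None:
        cells = (self.stable_unexposed, self.progressed_unexposed,
                 self.stable_exposed, self.progressed_exposed)
        if any(c < 0 for c in cells):
            raise ValueError("counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("total must be positive")


# exposure-encoding lobe flag patterns: exposed subjects carry the pattern in
# all 8 lobes, unexposed subjects carry the complementary pattern (so every
# raw column has two clusters and a strictly interior mean)
_PATTERN_FLAGS = {
    "pattern_both": ((True, True), (False, False)),       # +A/+H vs -A/-H
    "pattern_atrophy_only": ((True, False), (False, True)),   # +A/-H vs -A/+H
    "pattern_hypometab_only": ((False, True), (True, False)),  # -A/+H vs +A/-H
}


def _base_frame(n: int, progressed: np.ndarray) -> pd.DataFrame:
    """Deterministic demographics for a fixture cohort of size n."""
    idx = np.arange(n)
    df = pd.DataFrame({"subject_id": [f"F{i:04d}" for i in range(n)]})
    df["age"] = 60.0 + (idx % 21)  # 60..80, deterministic spread
    df["sex"] = np.where(idx % 2 == 0, "female", "male")
    df["diagnosis_group"] = np.array(["dementia", "MCI", "dementia"])[idx % 3]
    df["mmse_baseline"] = np.where(progressed, 24, 28)
    df["mmse_followup"] = np.where(progressed, 20, 27)
    df["outcome_raw"] = np.where(progressed, "progression", "stable")
    df["follow_up_days"] = 420
    return df


def _jitter(n: int, scale: float) -> np.ndarray:
    # deterministic sub-cluster jitter, strictly smaller than half the
    # cluster separation so z-score signs are guaranteed
    return scale * ((np.arange(n) % 7) - 3) / 3.0


def _fill_two_cluster(df: pd.DataFrame, col: str, low_mask: np.ndarray,
                      base: float, rel_sep: float = 0.2, rel_jit: float = 0.01) -> None:
    vals = np.where(low_mask, base * (1 - rel_sep), base * (1 + rel_sep))
    df[col] = vals + _jitter(len(df), rel_jit * base)


def _lobe_base(col: str) -> float:
    kind, lobe = col.split("_", 1)
    base = lobe.split("_", 1)[1]
    return _VOL_MEAN[base] if kind == "vol" else _SUVR_MEAN[base]


def make_contingency_fixture(req: FixtureRequest, lobe_cutoff: int = 2) -> CohortTable:
    """Cohort whose derived lobe-pattern exposure x outcome table equals ``req``.

    Exposed subjects carry the requested pattern in all 8 unilateral lobes
    (count 8 >= any cutoff); unexposed subjects carry the complementary
    pattern (count 0). Both exposure groups must be non-empty so that every
    raw column has an interior intracohort mean. The derived table is
    re-checked after construction.
    """
    try:
        (exp_a, exp_h), (une_a, une_h) = _PATTERN_FLAGS[req.feature]
    except KeyError:
        raise FixtureConstructionError(
            f"unknown fixture feature {req.feature!r}; "
            f"known: {sorted(_PATTERN_FLAGS)}"
        ) from None
    n_unexposed = req.stable_unexposed + req.progressed_unexposed
    n_exposed = req.stable_exposed + req.progressed_exposed
    if n_unexposed == 0 or n_exposed == 0:
        raise FixtureConstructionError(
            "both exposure groups must be non-empty to encode the pattern in "
            "raw lobe values (intracohort z-scores need spread)"
        )
    n = n_unexposed + n_exposed
    exposed = np.zeros(n, dtype=bool)
    exposed[n_unexposed:] = True
    progressed = np.zeros(n, dtype=bool)
    progressed[req.stable_unexposed:n_unexposed] = True
    progressed[n_unexposed + req.stable_exposed:] = True

    df = _base_frame(n, progressed)
    for lobe in LOBES:
        atro_low = np.where(exposed, exp_a, une_a)
        hypo_low = np.where(exposed, exp_h, une_h)
        _fill_two_cluster(df, f"vol_{lobe}", atro_low, _lobe_base(f"vol_{lobe}"))
        _fill_two_cluster(df, f"suvr_{lobe}", hypo_low, _lobe_base(f"suvr_{lobe}"))
    # fluid/global markers co-vary with exposure (abnormal when exposed)
    _fill_two_cluster(df, "ventricular_volume", ~exposed, 57_000.0)
    _fill_two_cluster(df, "total_suvr", exposed, 1.092)
    _fill_two_cluster(df, "csf_tau", ~exposed, 360.0)

    cohort = CohortTable(df, provenance=f"fixture:{req.feature}:{spec_digest(req)}")
    _verify_pattern_fixture(cohort, req, lobe_cutoff)
    return cohort


def _verify_pattern_fixture(cohort: CohortTable, req: FixtureRequest, cutoff: int) -> None:
    from .cohort_io import collapse_outcomes

    count_col = {
        "pattern_both": "n_both",
        "pattern_atrophy_only": "n_atrophy_only",
        "pattern_hypometab_only": "n_hypometab_only",
    }[req.feature]
    panel = features.compute_zscores(cohort)
    profile = features.classify_lobes(panel, 0.0)
    exposure = features.dichotomize_count(profile.counts[count_col], cutoff)
    outcome = collapse_outcomes(cohort)
    got = crosstab(
        pd.Series(exposure.values, index=outcome.index), outcome
    ).as_tuple()
    want = (req.stable_unexposed, req.progressed_unexposed,
            req.stable_exposed, req.progressed_exposed)
    if got != want:
        raise FixtureConstructionError(
            f"fixture self-check failed: derived table {got} != requested {want}"
        )


def make_marker_level_fixture(
    level_counts: dict[int, tuple[int, int]], marker_set: str = "M2"
) -> CohortTable:
    """Cohort whose abnormal-marker count reproduces per-level (stable, progressed) counts.

    A subject at level k has exactly the first k markers of the set abnormal
    (ventricular volume high, then total SUVR low, then CSF tau high).  Every
    marker must be abnormal in some subjects and normal in others, which
    holds whenever level 0 and the top level are non-empty.
    """
    markers = features.MARKER_SETS[marker_set]
    levels = sorted(level_counts)
    if levels != list(range(len(markers) + 1)):
        raise FixtureConstructionError(
            f"{marker_set} needs levels 0..{len(markers)}, got {levels}"
        )
    if sum(sum(v) for v in level_counts.values()) == 0:
        raise FixtureConstructionError("empty request")
    for k in (0, len(markers)):
        if sum(level_counts[k]) == 0:
            raise FixtureConstructionError(
                f"level {k} empty: marker columns would be degenerate"
            )

    level_arr, prog_arr = [], []
    for k in levels:
        ns, np_ = level_counts[k]
        level_arr += [k] * (ns + np_)
        prog_arr += [False] * ns + [True] * np_
    level = np.array(level_arr)
    progressed = np.array(prog_arr)
    n = len(level)

    df = _base_frame(n, progressed)
    abnormal = {m: level > i for i, m in enumerate(markers)}
    _fill_two_cluster(df, "ventricular_volume", ~abnormal["ventricular_volume"], 57_000.0)
    _fill_two_cluster(df, "total_suvr", abnormal["total_suvr"], 1.092)
    if "csf_tau" in markers:
        _fill_two_cluster(df, "csf_tau", ~abnormal["csf_tau"], 360.0)
    # lobe columns: abnormal alongside any abnormal marker, irrelevant to the
    # marker-count feature but kept non-degenerate
    any_ab = level > 0
    for lobe in LOBES:
        _fill_two_cluster(df, f"vol_{lobe}", any_ab, _lobe_base(f"vol_{lobe}"))
        _fill_two_cluster(df, f"suvr_{lobe}", any_ab, _lobe_base(f"suvr_{lobe}"))

    cohort = CohortTable(df, provenance=f"fixture:{marker_set}:{spec_digest(level_counts)}")
    panel = features.compute_zscores(cohort)
    mc = features.abnormal_marker_count(panel, marker_set)
    got = mc.counts.to_numpy()
    if not np.array_equal(got, level):
        raise FixtureConstructionError("marker-level fixture self-check failed")
    return cohort


def make_anatomical_fixture(level_counts: dict[str, tuple[int, int]]) -> CohortTable:
    """Cohort reproducing per-level (stable, progressed) counts of the 4-level anatomical variable.

    The requested level is applied identically to all four bilateral lobes
    (both hemispheres), so each lobe's derived anatomical variable matches
    the request.  Keys must be the four anatomical level names.
    """
    want_levels = set(features.ANATOMICAL_LEVELS)
    if set(level_counts) != want_levels:
        raise FixtureConstructionError(
            f"level_counts keys must be exactly {sorted(want_levels)}"
        )
    atro_low = {"no_abnormality": False, "isolated_atrophy": True,
                "isolated_hypometabolism": False, "congruent_or_nonisolated": True}
    hypo_low = {"no_abnormality": False, "isolated_atrophy": False,
                "isolated_hypometabolism": True, "congruent_or_nonisolated": True}
    for flags in (atro_low, hypo_low):
        n_low = sum(sum(level_counts[lv]) for lv in flags if flags[lv])
        n_high = sum(sum(level_counts[lv]) for lv in flags if not flags[lv])
        if n_low == 0 or n_high == 0:
            raise FixtureConstructionError(
                "each modality needs abnormal and normal subjects to z-score"
            )

    lv_arr, prog_arr = [], []
    for lv in features.ANATOMICAL_LEVELS:
        ns, np_ = level_counts[lv]
        lv_arr += [lv] * (ns + np_)
        prog_arr += [False] * ns + [True] * np_
    lv_arr = np.array(lv_arr)
    progressed = np.array(prog_arr)
    n = len(lv_arr)

    df = _base_frame(n, progressed)
    a_low = np.array([atro_low[lv] for lv in lv_arr])
    h_low = np.array([hypo_low[lv] for lv in lv_arr])
    for lobe in LOBES:
        _fill_two_cluster(df, f"vol_{lobe}", a_low, _lobe_base(f"vol_{lobe}"))
        _fill_two_cluster(df, f"suvr_{lobe}", h_low, _lobe_base(f"suvr_{lobe}"))
    any_ab = a_low | h_low
    _fill_two_cluster(df, "ventricular_volume", ~any_ab, 57_000.0)
    _fill_two_cluster(df, "total_suvr", any_ab, 1.092)

    cohort = CohortTable(df, provenance=f"fixture:anatomical:{spec_digest(level_counts)}")
    panel = features.compute_zscores(cohort)
    profile = features.classify_lobes(panel, 0.0)
    levels = features.anatomical_levels(profile)
    for lobe in BILATERAL_LOBES:
        if not np.array_equal(levels[lobe].astype(str).to_numpy(), lv_arr):
            raise FixtureConstructionError("anatomical fixture self-check failed")
    return cohort


# (stable, progressed) counts of the published result tables, used to build
# named fixtures and as closed-form oracle inputs in the tests
PRINTED_TABLES: dict[str, dict] = {
    "table2_m1": {
        "kind": "marker", "marker_set": "M1",
        "levels": {0: (16, 4), 1: (14, 9), 2: (16, 11), 3: (3, 3)},
    },
    "table2_m2": {
        "kind": "marker", "marker_set": "M2",
        "levels": {0: (42, 8), 1: (35, 23), 2: (22, 19)},
    },
    "table3_atrophy_only": {
        "kind": "pattern", "feature": "pattern_atrophy_only",
        "cells": (58, 32, 41, 18),
    },
    "table3_hypometab_only": {
        "kind": "pattern", "feature": "pattern_hypometab_only",
        "cells": (67, 32, 32, 18),
    },
    "table3_both": {
        "kind": "pattern", "feature": "pattern_both",
        "cells": (69, 17, 30, 33),
    },
    "table4_frontal": {
        "kind": "anatomical",
        "levels": {"no_abnormality": (25, 4), "congruent_or_nonisolated": (20, 25),
                   "isolated_hypometabolism": (23, 14), "isolated_atrophy": (31, 7)},
    },
    "table4_temporal": {
        "kind": "anatomical",
        "levels": {"no_abnormality": (28, 6), "congruent_or_nonisolated": (28, 30),
                   "isolated_hypometabolism": (21, 8), "isolated_atrophy": (22, 6)},
    },
    "table4_parietal": {
        "kind": "anatomical",
        "levels": {"no_abnormality": (26, 7), "congruent_or_nonisolated": (28, 27),
                   "isolated_hypometabolism": (20, 10), "isolated_atrophy": (25, 6)},
    },
    "table4_occipital": {
        "kind": "anatomical",
        "levels": {"no_abnormality": (17, 9), "congruent_or_nonisolated": (33, 21),
                   "isolated_hypometabolism": (20, 10), "isolated_atrophy": (29, 10)},
    },
}


def named_fixture(name: str) -> CohortTable:
    """Build one of the built-in fixtures reproducing a published count table."""
    try:
        entry = PRINTED_TABLES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(PRINTED_TABLES)}") from None
    if entry["kind"] == "pattern":
        a, b, c, d = entry["cells"]
        return make_contingency_fixture(
            FixtureRequest(a, b, c, d, feature=entry["feature"])
        )
    if entry["kind"] == "marker":
        return make_marker_level_fixture(entry["levels"], entry["marker_set"])
    return make_anatomical_fixture(entry["levels"])
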