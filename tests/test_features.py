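"""Feature engineering: z-scores, dichotomization, patterns, marker counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuroprog import features
from neuroprog.cohort_io import LOBES
from neuroprog.features import (
    ABNORMAL_HIGH,
    ABNORMAL_LOW,
    DegenerateVariableError,
    ZScorePanel,
    abnormal_marker_count,
    anatomical_levels,
    classify_lobes,
    compute_zscores,
    dichotomize,
    dichotomize_count,
)
from neuroprog.synthetic import SyntheticSpec, generate_cohort


def _panel_from_z(vol_z, suvr_z, n=None):
    """Build a ZScorePanel directly from given lobe z-values (bypassing scaling)."""
    n = n or len(next(iter(vol_z.values())))
    cols = {}
    for lobe in LOBES:
        cols[f"vol_{lobe}"] = vol_z[lobe]
        cols[f"suvr_{lobe}"] = suvr_z[lobe]
    z = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
    return ZScorePanel(
        z=z,
        direction={c: ABNORMAL_LOW for c in z.columns},
        mean=pd.Series(0.0, index=z.columns),
        sd=pd.Series(1.0, index=z.columns),
    )


class TestComputeZscores:
    def test_three_values(self, synth_cohort):
        """Values (1,2,3) standardize to (-1,0,1): sample SD is exactly 1."""
        df = synth_cohort.df.iloc[:3].copy().reset_index(drop=True)
        df["age"] = [1.0, 2.0, 3.0]
        from neuroprog.cohort_io import CohortTable

        panel = compute_zscores(CohortTable(df), ["age"])
        assert np.allclose(panel.z["age"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_hand_computed_example(self, synth_cohort):
        """(2,4,4,4,5,5,7,9): mean 5, sample SD ~2.138, so z(9) ~ 1.871."""
        from neuroprog.cohort_io import CohortTable

        df = synth_cohort.df.iloc[:8].copy().reset_index(drop=True)
        df["age"] = [2.0, 4.0, 4.0, 4.0, 5.0, 5.0, 7.0, 9.0]
        panel = compute_zscores(CohortTable(df), ["age"])
        assert panel.z["age"].iloc[-1] == pytest.approx(1.8708287, abs=1e-6)
        assert panel.z["age"].iloc[4] == pytest.approx(0.0)  # value at the mean

    def test_columns_standardized(self, synth_cohort):
        panel = compute_zscores(synth_cohort)
        for col in panel.variables:
            z = panel.z[col].dropna()
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_tau_standardized_on_measured_subset(self):
        """Tau z-scores use the tau-complete subset's own mean/SD."""
        cohort = generate_cohort(SyntheticSpec(n=200, seed=2))
        panel = compute_zscores(cohort)
        tau_z = panel.z["csf_tau"].dropna()
        assert len(tau_z) == cohort.df["csf_tau"].notna().sum()
        assert abs(tau_z.mean()) < 1e-9

    def test_degenerate_variable_raises(self, synth_cohort):
        from neuroprog.cohort_io import CohortTable

        df = synth_cohort.df.copy()
        df["age"] = 70.0
        with pytest.raises(DegenerateVariableError, match="age"):
            compute_zscores(CohortTable(df), ["age"])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40))
    def test_restandardization_idempotent(self, values):
        """Z-scoring an already-standardized column leaves it unchanged."""
        x = np.asarray(values)
        if x.std(ddof=1) < 1e-6:
            return
        z = (x - x.mean()) / x.std(ddof=1)
        z2 = (z - z.mean()) / z.std(ddof=1)
        assert np.allclose(z, z2, atol=1e-9)


class TestDichotomize:
    @pytest.mark.parametrize(
        "z,thr,direction,expected",
        [
            (-0.2, 0.0, ABNORMAL_LOW, True),
            (0.2, 0.0, ABNORMAL_LOW, False),
            (0.0, 0.0, ABNORMAL_LOW, False),   # boundary: strict inequality
            (0.0, 0.0, ABNORMAL_HIGH, False),
            (0.2, 0.0, ABNORMAL_HIGH, True),
            (-0.2, -0.5, ABNORMAL_LOW, False),  # sensitivity threshold
            (-0.6, -0.5, ABNORMAL_LOW, True),
            (0.6, 0.5, ABNORMAL_HIGH, True),
            (-0.5, -0.5, ABNORMAL_LOW, False),  # exactly at threshold
        ],
    )
    def test_rules(self, z, thr, direction, expected):
        assert bool(dichotomize(z, thr, direction)) is expected

    def test_direction_threshold_consistency(self):
        with pytest.raises(ValueError):
            dichotomize(0.0, 0.5, ABNORMAL_LOW)
        with pytest.raises(ValueError):
            dichotomize(0.0, -0.5, ABNORMAL_HIGH)

    def test_missing_stays_missing(self):
        s = pd.Series([np.nan, -1.0])
        out = dichotomize(s, 0.0, ABNORMAL_LOW)
        assert pd.isna(out.iloc[0]) and out.iloc[1] == True  # noqa: E712


class TestClassifyLobes:
    def test_all_abnormal(self):
        panel = _panel_from_z({l: [-1.0] for l in LOBES}, {l: [-1.0] for l in LOBES})
        counts = classify_lobes(panel).counts.iloc[0]
        assert (counts["n_atrophy_only"], counts["n_hypometab_only"],
                counts["n_both"]) == (0, 0, 8)

    def test_all_normal(self):
        panel = _panel_from_z({l: [1.0] for l in LOBES}, {l: [1.0] for l in LOBES})
        counts = classify_lobes(panel).counts.iloc[0]
        assert (counts["n_atrophy_only"], counts["n_hypometab_only"],
                counts["n_both"]) == (0, 0, 0)

    def test_mixed_enumeration(self):
        """Left-frontal atrophy-only plus right-temporal hypometabolism-only."""
        vol = {l: [1.0] for l in LOBES}
        suvr = {l: [1.0] for l in LOBES}
        vol["left_frontal"] = [-1.0]
        suvr["right_temporal"] = [-1.0]
        counts = classify_lobes(_panel_from_z(vol, suvr)).counts.iloc[0]
        assert (counts["n_atrophy_only"], counts["n_hypometab_only"],
                counts["n_both"]) == (1, 1, 0)

    def test_counts_sum_to_eight_and_threshold_monotone(self):
        """On 1000 random subjects: the four pattern counts partition the 8
        lobes, and a more negative threshold never increases abnormality."""
        rng = np.random.default_rng(123)
        vol = {l: rng.standard_normal(1000) for l in LOBES}
        suvr = {l: rng.standard_normal(1000) for l in LOBES}
        panel = _panel_from_z(vol, suvr)
        prev_abnormal = None
        for thr in (0.0, -0.1, -0.5, -1.0):
            prof = classify_lobes(panel, thr)
            total = prof.counts[
                ["n_atrophy_only", "n_hypometab_only", "n_both", "n_neither"]
            ].sum(axis=1)
            assert (total == 8).all()
            abnormal = prof.atrophy.to_numpy().sum() + prof.hypometab.to_numpy().sum()
            if prev_abnormal is not None:
                assert abnormal <= prev_abnormal
            prev_abnormal = abnormal

    def test_missing_lobe_column_raises(self, synth_cohort):
        panel = compute_zscores(synth_cohort, ["vol_left_frontal"])
        with pytest.raises(KeyError):
            classify_lobes(panel)


class TestDichotomizeCount:
    @pytest.mark.parametrize(
        "count,cutoff,expected",
        [(2, 2, True), (1, 2, False), (1, 1, True), (3, 3, True), (2, 3, False),
         (0, 1, False), (8, 2, True)],
    )
    def test_rules(self, count, cutoff, expected):
        assert bool(dichotomize_count(count, cutoff)) is expected

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            dichotomize_count(2, 4)


class TestAnatomicalLevels:
    def test_truth_table_all_16_combinations(self):
        """Brute-force truth table over every flag combination of one lobe."""
        rows = []
        for al in (0, 1):
            for ar in (0, 1):
                for hl in (0, 1):
                    for hr in (0, 1):
                        rows.append((al, ar, hl, hr))
        vol = {l: np.ones(16) for l in LOBES}
        suvr = {l: np.ones(16) for l in LOBES}
        vol["left_frontal"] = np.array([-1.0 if r[0] else 1.0 for r in rows])
        vol["right_frontal"] = np.array([-1.0 if r[1] else 1.0 for r in rows])
        suvr["left_frontal"] = np.array([-1.0 if r[2] else 1.0 for r in rows])
        suvr["right_frontal"] = np.array([-1.0 if r[3] else 1.0 for r in rows])
        levels = anatomical_levels(classify_lobes(_panel_from_z(vol, suvr)))
        for (al, ar, hl, hr), got in zip(rows, levels["frontal"].astype(str)):
            a, h = al or ar, hl or hr
            want = (
                "congruent_or_nonisolated" if a and h
                else "isolated_atrophy" if a
                else "isolated_hypometabolism" if h
                else "no_abnormality"
            )
            assert got == want, (al, ar, hl, hr)
        # other lobes are untouched and normal
        assert (levels["temporal"].astype(str) == "no_abnormality").all()

    def test_cross_hemisphere_cooccurrence_is_level_three(self):
        """Left atrophy with right hypometabolism counts as non-isolated
        co-occurrence, not as two isolated findings."""
        vol = {l: [1.0] for l in LOBES}
        suvr = {l: [1.0] for l in LOBES}
        vol["left_parietal"] = [-1.0]
        suvr["right_parietal"] = [-1.0]
        levels = anatomical_levels(classify_lobes(_panel_from_z(vol, suvr)))
        assert str(levels["parietal"].iloc[0]) == "congruent_or_nonisolated"


class TestMarkerCount:
    def _marker_panel(self, vent, tot, tau):
        z = pd.DataFrame(
            {"ventricular_volume": vent, "total_suvr": tot, "csf_tau": tau},
            index=[f"S{i}" for i in range(len(vent))],
        )
        return ZScorePanel(
            z=z,
            direction={"ventricular_volume": ABNORMAL_HIGH,
                       "total_suvr": ABNORMAL_LOW, "csf_tau": ABNORMAL_HIGH},
            mean=pd.Series(0.0, index=z.columns),
            sd=pd.Series(1.0, index=z.columns),
        )

    def test_all_three_abnormal(self):
        panel = self._marker_panel([0.5], [-0.5], [0.5])
        assert abnormal_marker_count(panel, "M1").counts.iloc[0] == 3

    def test_boundary_zero_not_abnormal(self):
        panel = self._marker_panel([0.0], [0.0], [0.0])
        assert abnormal_marker_count(panel, "M1").counts.iloc[0] == 0

    def test_complete_case_sizes(self):
        """M1 restricts to the tau subset; M2 keeps the full cohort."""
        cohort = generate_cohort(SyntheticSpec(n=149, seed=21))
        panel = compute_zscores(cohort)
        n_tau = int(cohort.df["csf_tau"].notna().sum())
        m1 = abnormal_marker_count(panel, "M1")
        m2 = abnormal_marker_count(panel, "M2")
        assert len(m1.counts) == n_tau
        assert m1.n_excluded == 149 - n_tau
        assert len(m2.counts) == 149
        assert m1.counts.max() <= 3 and m2.counts.max() <= 2

    def test_unknown_set(self):
        panel = self._marker_panel([0.0], [0.0], [0.0])
        with pytest.raises(ValueError):
            abnormal_marker_count(panel, "M9")
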