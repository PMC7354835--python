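"""Descriptive cohort statistics: group comparisons, correlations, MMSE regressions.

Baseline group comparisons dispatch the test named per variable, matching
standard cohort-table practice: Pearson chi-squared (without continuity
correction) for balanced categorical variables, Fisher's exact test for
sparse categorical tables (r x c by enumeration, falling back to a seeded
conditional Monte-Carlo permutation test when the table is too large to
enumerate), one-way ANOVA for approximately normal numeric variables and
Kruskal-Wallis for skewed ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "RegressionResult",
    "chi2_test",
    "fisher_exact_rxc",
    "baseline_table",
    "spearman_matrix",
    "mmse_change_regression",
]


@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p: float
    summaries: dict
    warnings: list


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p: float
    n: int


@dataclass
class RegressionResult:
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int
    fitted: np.ndarray
    residuals: np.ndarray


def chi2_test(table: np.ndarray) -> tuple[float, float, list[str]]:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    warn = []
    if (expected < 5).any():
        warn.append(f"{int((expected < 5).sum())} cells with expected count < 5")
    return float(stat), float(p), warn


def _table_log_prob(table: np.ndarray, lgam_margins: float, lgam_n: float) -> float:
    # conditional (hypergeometric) log-probability of a table given margins
    return lgam_margins - lgam_n - gammaln(table + 1).sum()


def fisher_exact_rxc(
    table: np.ndarray,
    max_tables: int = 500_000,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher exact p for an r x c table (conditional on margins).

    Enumerates all tables with the observed margins and sums the conditional
    probabilities of tables no more probable than the observed one (the
    standard two-sided definition).  If the enumeration would exceed
    ``max_tables`` nodes, a seeded permutation Monte-Carlo of the same
    conditional test is used instead.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a non-negative 2-D count array")
    if obs.shape == (2, 2):
        return float(stats.fisher_exact(obs)[1])
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    lgam_margins = gammaln(row + 1).sum() + gammaln(col + 1).sum()
    lgam_n = gammaln(n + 1)
    logp_obs = _table_log_prob(obs, lgam_margins, lgam_n)
    tol = 1e-7

    total = 0.0
    nodes = count()
    r, c = obs.shape

    def fill(i: int, remaining_col: np.ndarray, acc_lgam: float) -> bool:
        """Enumerate row i onward; returns False if the node budget blew."""
        nonlocal total
        if next(nodes) > max_tables:
            return False
        if i == r - 1:
            last = remaining_col
            if (last < 0).any():
                return True
            logp = lgam_margins - lgam_n - acc_lgam - gammaln(last + 1).sum()
            if logp <= logp_obs + tol:
                total += np.exp(logp)
            return True
        # compositions of row[i] into c cells bounded by remaining_col
        def comps(j: int, left: int, current: list[int]) -> bool:
            if j == c - 1:
                if left > remaining_col[j]:
                    return True
                return fill(
                    i + 1,
                    remaining_col - np.array(current + [left]),
                    acc_lgam + gammaln(np.array(current + [left]) + 1).sum(),
                )
            hi = min(left, remaining_col[j])
            for v in range(hi + 1):
                if not comps(j + 1, left - v, current + [v]):
                    return False
            return True

        return comps(0, int(row[i]), [])

    if fill(0, col.copy(), 0.0):
        return float(min(total, 1.0))

    # budget exceeded: conditional Monte-Carlo via label permutation
    rng = np.random.default_rng(seed)
    xs = np.repeat(np.arange(r), row)
    ys = np.repeat(np.arange(c), col)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(ys)
        t = np.zeros((r, c), dtype=int)
        np.add.at(t, (xs, perm), 1)
        if _table_log_prob(t, lgam_margins, lgam_n) <= logp_obs + tol:
            hits += 1
    return float((hits + 1) / (n_mc + 1))


def baseline_table(
    df: pd.DataFrame,
    group: pd.Series,
    variable_specs: list[tuple[str, str]],
) -> list[GroupComparison]:
    """Compare variables between outcome groups; one test per variable spec.

    ``variable_specs`` is a list of ``(column, test)`` with test one of
    ``pearson_chi2``, ``fisher_exact``, ``anova``, ``kruskal_wallis``.
    Categorical tests summarize counts (%) per group; numeric tests report
    mean (SD) for ANOVA and median (range) for Kruskal-Wallis.
    """
    results = []
    groups = [g for g in group.dropna().unique()]
    if not groups:
        raise ValueError("no groups")
    for col, test in variable_specs:
        mask = df[col].notna() & group.notna()
        x = df.loc[mask, col]
        g = group.loc[mask]
        warn: list[str] = []
        if test in ("pearson_chi2", "fisher_exact"):
            tab = pd.crosstab(x, g)
            counts = np.asarray(tab)
            if test == "pearson_chi2":
                stat, p, warn = chi2_test(counts)
            else:
                stat, p = np.nan, fisher_exact_rxc(counts)
            summaries = {
                grp: {lvl: (int(tab.loc[lvl, grp]),
                            100 * tab.loc[lvl, grp] / tab[grp].sum())
                      for lvl in tab.index}
                for grp in tab.columns
            }
        elif test == "anova":
            samples = [x[g == grp].astype(float) for grp in groups]
            stat, p = stats.f_oneway(*samples)
            summaries = {grp: {"mean": float(s.mean()), "sd": float(s.std(ddof=1))}
                         for grp, s in zip(groups, samples)}
        elif test == "kruskal_wallis":
            samples = [x[g == grp].astype(float) for grp in groups]
            stat, p = stats.kruskal(*samples)
            summaries = {
                grp: {"median": float(s.median()),
                      "range": (float(s.min()), float(s.max()))}
                for grp, s in zip(groups, samples)
            }
        else:
            raise ValueError(f"unknown test {test!r} for variable {col!r}")
        results.append(
            GroupComparison(variable=col, test=test, statistic=float(stat),
                            p=float(p), summaries=summaries, warnings=warn)
        )
    return results


def spearman_matrix(
    df: pd.DataFrame, variables: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations with two-sided p-values.

    Ties get average ranks; p comes from the t approximation. Returns a long
    table with one row per unordered pair plus the ``significant`` flag used
    to mask non-significant cells in correlograms. Markers measured in a
    subset (CSF tau) are correlated over their pairwise-complete subjects.
    """
    rows = []
    for i, vx in enumerate(variables):
        for vy in variables[i + 1:]:
            pair = df[[vx, vy]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 paired observations for ({vx}, {vy})")
            for v in (vx, vy):
                if pair[v].nunique() < 2:
                    raise ValueError(f"{v} is constant over the pairwise-complete subset")
            rho, p = stats.spearmanr(pair[vx], pair[vy])
            rows.append(
                {"var_x": vx, "var_y": vy, "rho": float(rho), "p": float(p),
                 "n": len(pair), "significant": bool(p < alpha)}
            )
    return pd.DataFrame(rows)


def mmse_change_regression(
    mmse_baseline: pd.Series,
    mmse_followup: pd.Series,
    z: pd.Series,
    predictor_name: str = "z",
) -> RegressionResult:
    """OLS of MMSE change (follow-up minus baseline) on a biomarker z-score.

    Decline is therefore negative. Subjects missing either MMSE score or the
    biomarker are excluded; fitted values and residuals are returned for
    Q-Q / residual diagnostics.
    """
    data = pd.DataFrame(
        {"y": mmse_followup.astype(float) - mmse_baseline.astype(float), "z": z}
    ).dropna()
    if len(data) < 3:
        raise ValueError("fewer than 3 subjects with both MMSE scores and the biomarker")
    if data["z"].nunique() < 2:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(data["z"], data["y"])
    fitted = res.intercept + res.slope * data["z"].to_numpy()
    return RegressionResult(
        predictor=predictor_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(data),
        fitted=fitted,
        residuals=data["y"].to_numpy() - fitted,
    )
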