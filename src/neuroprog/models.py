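"""Association models: 2x2 odds ratios, logistic regression, CV, collinearity.

Univariable effects of a binary exposure on the binary progression outcome are
estimated from the 2x2 table with the Woolf (log) method: OR = ad'/bc' with
SE(log OR) = sqrt(sum of reciprocal cell counts) and a normal-approximation
CI and two-sided p. Logistic regression (Newton/IRLS maximum likelihood via
statsmodels) provides the multivariable, mutually adjusted estimates; for a
single binary predictor the two routes agree exactly, which the test suite
exploits as a closed-form oracle.

Internal validation is repeated stratified k-fold cross-validation with
balanced accuracy; multicollinearity is diagnosed with the Belsley condition
number of the column-equilibrated design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "LogisticFit",
    "CVResult",
    "ZeroCellError",
    "crosstab",
    "odds_ratio_woolf",
    "build_design",
    "fit_logistic",
    "model_table",
    "repeated_cv",
    "balanced_accuracy",
    "condition_number",
    "format_p",
]

PROGRESSED, STABLE = "progressed", "stable"


class ZeroCellError(ValueError):
    """A 2x2 cell is zero: the Woolf estimate is undefined without correction."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: outcome (stable/progressed) x exposure (un/exposed)."""

    stable_unexposed: int
    progressed_unexposed: int
    stable_exposed: int
    progressed_exposed: int

    def __post_init__(self) -> None:
        cells = self.as_tuple()
        if any(c < 0 for c in cells):
            raise ValueError("negative cell count")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.stable_unexposed,
            self.progressed_unexposed,
            self.stable_exposed,
            self.progressed_exposed,
        )

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    continuity_corrected: bool = False


def crosstab(exposure: pd.Series, outcome: pd.Series) -> ContingencyTable:
    """Cross-tabulate a boolean exposure against the binary outcome.

    ``outcome`` holds the labels 'progressed'/'stable'. Subjects missing
    either variable are dropped.
    """
    df = pd.DataFrame({"e": exposure, "o": outcome}).dropna()
    if df.empty:
        raise ValueError("no subjects with both exposure and outcome defined")
    bad = set(df["o"].unique()) - {PROGRESSED, STABLE}
    if bad:
        raise ValueError(f"outcome labels must be progressed/stable, got {sorted(bad)}")
    e = df["e"].astype(bool)
    o = df["o"] == PROGRESSED
    return ContingencyTable(
        stable_unexposed=int((~e & ~o).sum()),
        progressed_unexposed=int((~e & o).sum()),
        stable_exposed=int((e & ~o).sum()),
        progressed_exposed=int((e & o).sum()),
    )


def odds_ratio_woolf(
    table: ContingencyTable, alpha: float = 0.05, haldane: bool = False
) -> OddsRatioResult:
    """Woolf odds ratio with normal-approximation CI and two-sided p.

    With cells a (stable, unexposed), b (progressed, unexposed), c (stable,
    exposed), d (progressed, exposed): OR = (d*a)/(b*c),
    SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d). ``haldane`` adds 0.5 to every
    cell (Haldane-Anscombe correction) and flags the result; by default a
    zero cell raises :class:`ZeroCellError` instead.
    """
    a, b, c, d = (float(x) for x in table.as_tuple())
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif min(a, b, c, d) == 0:
        raise ZeroCellError(
            "zero cell in 2x2 table; pass haldane=True for the +0.5 correction"
        )
    log_or = np.log(d * a) - np.log(b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zq = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - zq * se)),
        ci_high=float(np.exp(log_or + zq * se)),
        p=float(p),
        method="woolf_2x2",
        continuity_corrected=haldane,
    )


# ---------------------------------------------------------------------------
# logistic regression


def build_design(terms: dict[str, pd.Series]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand named terms into a numeric design matrix (no intercept column).

    Boolean/categorical/object terms are dummy-coded against their first
    level (reference): female for sex, 'unexposed' / count 0 / no_abnormality
    for the study variables. Numeric terms enter as-is. Returns the design
    and a map term -> its design columns.
    """
    cols: dict[str, pd.Series] = {}
    term_columns: dict[str, list[str]] = {}
    for name, series in terms.items():
        s = series
        if isinstance(s, pd.Series) and isinstance(s.dtype, pd.CategoricalDtype):
            levels = [lv for lv in s.cat.categories if lv in set(s.dropna().unique())]
            produced = []
            for lv in levels[1:]:
                col = f"{name}[{lv}]"
                cols[col] = (s == lv).astype(float).where(s.notna())
                produced.append(col)
            term_columns[name] = produced
        elif s.dtype == bool or s.dtype == object:
            if s.dtype == object:
                levels = sorted(s.dropna().unique())
                if len(levels) > 2:
                    raise ValueError(
                        f"term {name!r}: >2 unlabelled levels; pass an ordered Categorical"
                    )
                produced = []
                for lv in levels[1:]:
                    col = f"{name}[{lv}]"
                    cols[col] = (s == lv).astype(float).where(s.notna())
                    produced.append(col)
                term_columns[name] = produced
            else:
                col = f"{name}[yes]"
                cols[col] = s.astype(float)
                term_columns[name] = [col]
        else:
            cols[name] = s.astype(float)
            term_columns[name] = [name]
    X = pd.DataFrame(cols)
    return X, term_columns


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``table`` has one row per non-reference design column: coefficient,
    OR = exp(coef), 95% CI from the inverse observed information, and the
    two-sided Wald p. ``params``/``cov`` include the intercept (term
    'const').
    """

    params: pd.Series
    cov: pd.DataFrame
    table: pd.DataFrame
    n: int
    converged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)
    term_columns: dict[str, list[str]] = field(default_factory=dict)

    def odds_ratio(self, column: str, alpha: float = 0.05) -> OddsRatioResult:
        beta = self.params[column]
        se = float(np.sqrt(self.cov.loc[column, column]))
        zq = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(over="ignore"):  # separated fits can overflow to inf
            return OddsRatioResult(
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - zq * se)),
                ci_high=float(np.exp(beta + zq * se)),
                p=float(2 * stats.norm.sf(abs(beta) / se)),
                method="logistic_wald",
            )


SEPARATION_BETA = 15.0


def fit_logistic(outcome: pd.Series, terms: dict[str, pd.Series], alpha: float = 0.05) -> LogisticFit:
    """Fit progression ~ terms by Newton maximum likelihood with Wald CIs.

    ``outcome`` holds 'progressed'/'stable'; rows missing the outcome or any
    term are dropped (complete-case). Raises on rank-deficient designs,
    attaches a separation warning (|beta| > 15) without failing.
    """
    X, term_columns = build_design(terms)
    y = outcome.map({PROGRESSED: 1.0, STABLE: 0.0})
    data = pd.concat([y.rename("_y"), X], axis=1).dropna()
    n = len(data)
    if n == 0:
        raise ValueError("no complete cases")
    if data["_y"].nunique() < 2:
        raise ValueError("outcome has a single class within the complete-case set")
    Xc = sm.add_constant(data.drop(columns="_y"), has_constant="add")
    for col in X.columns:
        if data[col].nunique() < 2:
            raise ValueError(f"term column {col!r} is constant within the complete-case set")
    if n <= Xc.shape[1]:
        raise ValueError(f"n={n} too small for {Xc.shape[1]} parameters")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {Xc.shape[1]}): collinear terms "
            f"among {list(Xc.columns)}"
        )
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(data["_y"], Xc)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except np.linalg.LinAlgError:
            # singular Hessian under (quasi-)complete separation: fall back
            # to a gradient method so estimates are still returned
            res = model.fit(method="bfgs", maxiter=500, disp=0)
            notes.append("Newton failed (singular Hessian); bfgs fallback used")
    params = res.params
    cov = pd.DataFrame(res.cov_params(), index=params.index, columns=params.index)
    big = params.drop("const")[lambda s: s.abs() > SEPARATION_BETA]
    if len(big):
        notes.append(f"possible separation: |coefficient| > {SEPARATION_BETA} for {list(big.index)}")
    fit = LogisticFit(
        params=params,
        cov=cov,
        table=pd.DataFrame(),
        n=n,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        warnings=notes,
        term_columns=term_columns,
    )
    rows = []
    for col in X.columns:
        orr = fit.odds_ratio(col, alpha=alpha)
        rows.append(
            {
                "column": col,
                "coef": float(params[col]),
                "odds_ratio": orr.odds_ratio,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "p": orr.p,
            }
        )
    fit.table = pd.DataFrame(rows)
    return fit


def format_p(p: float) -> str:
    """Render a p-value in table style: 3 decimals, '<0.001' below that."""
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


def model_table(
    outcome: pd.Series,
    terms: dict[str, pd.Series],
    adjustments: dict[str, pd.Series] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build a results table: per-level counts, univariable and multivariable ORs.

    Each term is fit alone (univariable) and all terms are fit jointly with
    the adjustment covariates (mutually adjusted multivariable model, the
    published convention being adjustment for age and sex). Categorical terms
    get one row per level with the reference level marked '-'; continuous
    terms get a single row. Counts are n (% of outcome column), mirroring the
    published table layout.
    """
    adjustments = adjustments or {}
    all_terms = {**adjustments, **terms}
    # terms constant within their complete-case set (a fixture or a degenerate
    # grid cell can produce them) are reported with counts but not estimated
    estimable: dict[str, pd.Series] = {}
    dropped: list[str] = []
    for name, s in all_terms.items():
        X1, _ = build_design({name: s})
        d1 = pd.concat([outcome.rename("_y"), X1], axis=1).dropna() if X1.shape[1] else pd.DataFrame()
        if X1.shape[1] == 0 or any(d1[c].nunique() < 2 for c in X1.columns):
            dropped.append(name)
        else:
            estimable[name] = s
    if not estimable:
        raise ValueError("no estimable (non-constant) terms")
    multi = fit_logistic(outcome, estimable, alpha=alpha)

    # count denominators within the multivariable complete-case set
    keep = pd.concat(
        [outcome.rename("_y"), build_design(estimable)[0]], axis=1
    ).dropna().index
    oc = outcome.loc[keep]
    n_stable = int((oc == STABLE).sum())
    n_prog = int((oc == PROGRESSED).sum())

    nan_est = {k: np.nan for k in (
        "or_univariable", "ci_low_univariable", "ci_high_univariable",
        "p_univariable", "or_multivariable", "ci_low_multivariable",
        "ci_high_multivariable", "p_multivariable")}
    rows = []
    for name, series in all_terms.items():
        uni = fit_logistic(outcome, {name: series}, alpha=alpha) if name in estimable else None
        s = series.loc[keep]
        if _is_categorical_like(series):
            levels = _levels_of(series)
            for i, lv in enumerate(levels):
                ns = int(((s == lv) & (oc == STABLE)).sum())
                np_ = int(((s == lv) & (oc == PROGRESSED)).sum())
                row = {
                    "variable": name,
                    "level": str(lv),
                    "n_stable": ns,
                    "pct_stable": 100 * ns / n_stable if n_stable else np.nan,
                    "n_progressed": np_,
                    "pct_progressed": 100 * np_ / n_prog if n_prog else np.nan,
                }
                if i == 0 or uni is None:
                    row.update(nan_est)
                else:
                    col = multi.term_columns[name][i - 1]
                    ou = uni.odds_ratio(col, alpha)
                    om = multi.odds_ratio(col, alpha)
                    row.update(
                        or_univariable=ou.odds_ratio, ci_low_univariable=ou.ci_low,
                        ci_high_univariable=ou.ci_high, p_univariable=ou.p,
                        or_multivariable=om.odds_ratio, ci_low_multivariable=om.ci_low,
                        ci_high_multivariable=om.ci_high, p_multivariable=om.p,
                    )
                rows.append(row)
        else:
            row = {
                "variable": name,
                "level": "(per unit)",
                "n_stable": n_stable,
                "pct_stable": 100.0,
                "n_progressed": n_prog,
                "pct_progressed": 100.0,
            }
            if uni is None:
                row.update(nan_est)
            else:
                col = multi.term_columns[name][0]
                ou = uni.odds_ratio(col, alpha)
                om = multi.odds_ratio(col, alpha)
                row.update(
                    or_univariable=ou.odds_ratio, ci_low_univariable=ou.ci_low,
                    ci_high_univariable=ou.ci_high, p_univariable=ou.p,
                    or_multivariable=om.odds_ratio, ci_low_multivariable=om.ci_low,
                    ci_high_multivariable=om.ci_high, p_multivariable=om.p,
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n"] = len(keep)
    out.attrs["dropped_terms"] = dropped
    out.attrs["multivariable_warnings"] = multi.warnings
    return out


def _is_categorical_like(s: pd.Series) -> bool:
    return (
        isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool or s.dtype == object
    )


def _levels_of(s: pd.Series):
    if isinstance(s.dtype, pd.CategoricalDtype):
        return [lv for lv in s.cat.categories if lv in set(s.dropna().unique())]
    if s.dtype == bool:
        return [False, True]
    return sorted(s.dropna().unique())


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    k: int
    repeats: int
    seed: int
    threshold: float
    fold_accuracies: np.ndarray  # shape (repeats, k)
    overall_accuracy: float
    balanced_accuracy: float

    @property
    def repeat_accuracies(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)


def balanced_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 for binary labels (1 = progressed)."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch")
    pos, neg = truth.sum(), (~truth).sum()
    if pos == 0 or neg == 0:
        raise ValueError("both truth classes must be present")
    sens = (predicted & truth).sum() / pos
    spec = (~predicted & ~truth).sum() / neg
    return float((sens + spec) / 2)


def repeated_cv(
    X: pd.DataFrame,
    outcome: pd.Series,
    k: int = 10,
    repeats: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    stratified: bool = True,
) -> CVResult:
    """Repeated (stratified) k-fold cross-validation of a logistic model.

    Per repeat the cohort is partitioned into k folds (stratified on outcome
    by default, matching standard resampling practice); per fold, an
    unpenalized logistic model is fit on the training part and the held-out
    subjects are classified at the probability ``threshold`` (a tie at
    exactly 0.5 classifies as progressed). The overall accuracy is the mean
    of fold accuracies; the balanced accuracy is computed on all held-out
    predictions pooled. Deterministic under a fixed ``seed``.
    """
    data = pd.concat([outcome.rename("_y"), X], axis=1).dropna()
    Xa = data.drop(columns="_y").to_numpy(dtype=float)
    ya = (data["_y"] == PROGRESSED).to_numpy()
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    if stratified and counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    accs = np.empty((repeats, k))
    pooled_pred: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    # C=inf disables regularization (plain maximum likelihood)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    for r in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        splitter = (StratifiedKFold if stratified else KFold)(
            n_splits=k, shuffle=True, random_state=rs
        )
        for f, (tr, te) in enumerate(splitter.split(Xa, ya)):
            clf.fit(Xa[tr], ya[tr])
            prob = clf.predict_proba(Xa[te])[:, list(clf.classes_).index(True)]
            pred = prob >= threshold
            accs[r, f] = float((pred == ya[te]).mean())
            pooled_pred.append(pred)
            pooled_truth.append(ya[te])
    return CVResult(
        k=k,
        repeats=repeats,
        seed=seed,
        threshold=threshold,
        fold_accuracies=accs,
        overall_accuracy=float(accs.mean()),
        balanced_accuracy=balanced_accuracy(
            np.concatenate(pooled_pred), np.concatenate(pooled_truth)
        ),
    )


# ---------------------------------------------------------------------------
# multicollinearity


def condition_number(
    design: pd.DataFrame | np.ndarray,
    convention: str = "belsley",
    include_intercept: bool = True,
) -> float:
    """Eigensystem condition number of a design matrix.

    ``belsley`` (default): columns (including an appended intercept) are
    scaled to unit Euclidean length and the condition number is
    sqrt(lambda_max / lambda_min) of X'X — equivalently the ratio of extreme
    singular values of the equilibrated design. ``correlation`` instead uses
    the eigenvalues of the predictor correlation matrix (no intercept).
    Returns ``inf`` for an exactly singular design.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("design must have at least 2 columns")
    if convention == "belsley":
        if include_intercept:
            X = np.column_stack([X, np.ones(X.shape[0])])
        norms = np.linalg.norm(X, axis=0)
        if (norms == 0).any():
            return float("inf")
        Xs = X / norms
        ev = np.linalg.eigvalsh(Xs.T @ Xs)
    elif convention == "correlation":
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            return float("inf")
        ev = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    ev = np.clip(ev, 0.0, None)
    if ev.min() <= ev.max() * 1e-12:
        return float("inf")
    return float(np.sqrt(ev.max() / ev.min()))
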