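"""Two-group comparison and regression workflow for syntactic measures.

The workflow mirrors standard clinical-linguistics practice: Shapiro–Wilk
normality checks per group, Levene's homogeneity test (mean-centred, the
SPSS convention), an independent-samples t-test (pooled variance when
Levene's p > 0.05, Welch otherwise), Cohen's d with pooled SD, then a
feature-selection chain for regressing text MDD on syntactic indices —
Pearson screening (drop p >= alpha or |r| < r_min), iterative VIF
screening (drop the worst column while any VIF >= threshold), and
SPSS-style stepwise selection (enter at p < 0.05, remove at p > 0.10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("synspeech")

__all__ = [
    "GroupComparison",
    "RegressionModel",
    "ScreeningReport",
    "compare_groups",
    "correlation_screen",
    "vif_screen",
    "stepwise_regression",
]


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    levene_F: float
    levene_p: float
    t_statistic: float
    p_two_tailed: float
    cohens_d: float
    equal_variances_assumed: bool
    n_a: int = 0
    n_b: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "sd_a": self.sd_a, "sd_b": self.sd_b,
            "shapiro_p_a": self.shapiro_p_a, "shapiro_p_b": self.shapiro_p_b,
            "levene_F": self.levene_F, "levene_p": self.levene_p,
            "t": self.t_statistic, "p": self.p_two_tailed,
            "cohens_d": self.cohens_d,
            "equal_variances_assumed": self.equal_variances_assumed,
            "n_a": self.n_a, "n_b": self.n_b,
        }


@dataclass
class RegressionModel:
    selected: list[str]
    coefficients: pd.DataFrame  # columns: B, SE, beta, VIF; index: selected
    r_squared: float
    adjusted_r_squared: float
    intercept: float = 0.0

    def as_dict(self) -> dict:
        return {
            "selected": self.selected,
            "coefficients": self.coefficients.to_dict(orient="index"),
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "adjusted_r_squared": self.adjusted_r_squared,
        }


@dataclass
class ScreeningReport:
    retained: list[str] = field(default_factory=list)
    dropped_correlation: list[tuple[str, float, float]] = field(default_factory=list)
    dropped_vif: list[tuple[str, float]] = field(default_factory=list)


def compare_groups(sample_a, sample_b) -> GroupComparison:
    """Independent two-sample comparison with distributional checks.

    Pooled-variance t when Levene's p > 0.05, Welch otherwise; Cohen's d
    always uses the pooled standard deviation and is reported as a signed
    value (magnitude = |d|).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both samples")
    shapiro_a = stats.shapiro(a).pvalue if np.var(a) > 0 else float("nan")
    shapiro_b = stats.shapiro(b).pvalue if np.var(b) > 0 else float("nan")
    levene = stats.levene(a, b, center="mean")
    equal_var = bool(levene.pvalue > 0.05)
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    na, nb = len(a), len(b)
    pooled_sd = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )
    d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(np.std(a, ddof=1)), sd_b=float(np.std(b, ddof=1)),
        shapiro_p_a=float(shapiro_a), shapiro_p_b=float(shapiro_b),
        levene_F=float(levene.statistic), levene_p=float(levene.pvalue),
        t_statistic=float(t_res.statistic), p_two_tailed=float(t_res.pvalue),
        cohens_d=float(d), equal_variances_assumed=equal_var,
        n_a=na, n_b=nb,
    )


def correlation_screen(
    feature_matrix: pd.DataFrame,
    target,
    alpha: float = 0.05,
    r_min: float = 0.100,
) -> ScreeningReport:
    """Pearson screen: keep columns with |r| >= r_min and p < alpha.

    Constant columns are dropped with a warning (r undefined).  Rows with
    a missing feature or target value are excluded per column (pairwise).
    """
    y = np.asarray(target, dtype=float)
    if len(feature_matrix) != len(y):
        raise ValueError("feature matrix and target are not aligned")
    if len(y) < 4:
        raise ValueError("need at least 4 rows")
    report = ScreeningReport()
    for name in feature_matrix.columns:
        x = feature_matrix[name].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 4 or np.var(x[mask]) == 0:
            logger.warning("correlation screen: dropping constant/empty column %s",
                           name)
            report.dropped_correlation.append((name, float("nan"), float("nan")))
            continue
        r, p = stats.pearsonr(x[mask], y[mask])
        if abs(r) >= r_min and p < alpha:
            report.retained.append(name)
        else:
            report.dropped_correlation.append((name, float(r), float(p)))
    return report


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R²_j) regressing column j on the other columns."""
    n, k = X.shape
    vifs = np.empty(k)
    for j in range(k):
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            vifs[j] = np.inf
            continue
        r2 = 1 - np.sum(resid**2) / sst
        vifs[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_screen(feature_matrix: pd.DataFrame, threshold: float = 5.0) -> ScreeningReport:
    """Iteratively drop the highest-VIF column while any VIF >= threshold.

    Perfect collinearity yields an infinite VIF and is handled by removal,
    never by failure.
    """
    frame = feature_matrix.dropna()
    columns = list(frame.columns)
    report = ScreeningReport()
    while len(columns) >= 2:
        X = frame[columns].to_numpy(dtype=float)
        vifs = _vif_values(X)
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        name = columns.pop(worst)
        report.dropped_vif.append((name, float(vifs[worst])))
        logger.info("VIF screen: dropped %s (VIF=%.3g)", name, vifs[worst])
    report.retained = columns
    return report


def stepwise_regression(
    feature_matrix: pd.DataFrame,
    target,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionModel:
    """Forward selection with backward elimination (SPSS-style stepwise).

    At each step the candidate with the smallest partial-F p-value enters
    if p < ``p_enter``; after each entry, any included predictor whose
    p-value exceeds ``p_remove`` is removed.  The final fit reports
    unstandardised B with SE, standardised beta (z-scored variables),
    per-predictor VIF, R² and adjusted R².  Rows with missing values are
    dropped listwise.
    """
    y_all = np.asarray(target, dtype=float)
    frame = feature_matrix.copy()
    frame["__target__"] = y_all
    frame = frame.dropna()
    if len(frame) < frame.shape[1] + 1:
        raise ValueError("too few complete rows for stepwise regression")
    y = frame.pop("__target__").to_numpy()
    names = list(frame.columns)
    X = frame.to_numpy(dtype=float)
    n = len(y)

    included: list[int] = []

    def fit(cols: list[int]):
        design = sm.add_constant(X[:, cols]) if cols else np.ones((n, 1))
        return sm.OLS(y, design).fit()

    while True:
        changed = False
        # forward step: best remaining candidate by partial-F (== t-test) p
        candidates = [j for j in range(len(names)) if j not in included]
        best_j, best_p = None, 1.0
        for j in candidates:
            if np.var(X[:, j]) == 0:
                continue
            res = fit(included + [j])
            p = res.pvalues[-1]
            if p < best_p:
                best_p, best_j = p, j
        if best_j is not None and best_p < p_enter:
            included.append(best_j)
            changed = True
        # backward step: drop any included predictor with p > p_remove
        while len(included) > 0:
            res = fit(included)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        empty = pd.DataFrame(columns=["B", "SE", "beta", "VIF"])
        return RegressionModel(selected=[], coefficients=empty,
                               r_squared=0.0, adjusted_r_squared=0.0)

    res = fit(included)
    selected = [names[j] for j in included]
    Xs = X[:, included]
    sd_x = Xs.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    betas = res.params[1:] * sd_x / sd_y
    if len(included) >= 2:
        vifs = _vif_values(Xs)
    else:
        vifs = np.array([1.0])
    table = pd.DataFrame(
        {"B": res.params[1:], "SE": res.bse[1:], "beta": betas, "VIF": vifs},
        index=selected,
    )
    return RegressionModel(
        selected=selected,
        coefficients=table,
        r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        intercept=float(res.params[0]),
    )
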