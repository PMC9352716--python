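"""Group comparison, effect sizes, ANCOVA, regression and logistic risk models.

The analysis proceeds in four steps: (1) group differences on the VR
navigation variables and (2) on the community navigation variables, with the
test chosen per variable by a per-group Shapiro-Wilk normality gate (pooled
two-sample t when both groups pass, Wilcoxon rank-sum otherwise) and an
unsigned pooled-SD Cohen's d always attached; (3) for patients only, simple
standardized linear regressions of the composite disorientation score on each
VR variable, reporting beta, R-squared and Cohen's f-squared = R2/(1-R2); and
(4) binomial logistic regression of the high/low disorientation-risk label on
the step-3-significant predictors, reporting the odds ratio per unit of the
predictor with a Wald p-value.

Conventions: the rank-sum statistic W is the Mann-Whitney U of the first
sample (rank sum minus n_x(n_x+1)/2, midranks for ties), with an exact p for
small untied samples and a tie-corrected, continuity-corrected normal
approximation otherwise. No multiple-testing correction is applied at any
step (see docs/methods.md for the caveat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "DegenerateDataError",
    "SeparationError",
    "GroupComparison",
    "RegressionFit",
    "LogisticFit",
    "AncovaFit",
    "cohens_d_pooled",
    "wilcoxon_rank_sum",
    "compare_groups",
    "ancova_adjusted",
    "linear_regression_standardized",
    "logistic_risk",
    "f_squared",
]


class DegenerateDataError(ValueError):
    """Input has no usable variation for the requested statistic."""


class SeparationError(RuntimeError):
    """Logistic regression with perfectly separated classes (small-n hazard)."""


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # "students_t" | "wilcoxon_rank_sum"
    statistic: float
    p_value: float
    cohens_d: float
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float


@dataclass(frozen=True)
class RegressionFit:
    predictor: str
    beta_standardized: float
    p_value: float
    r_squared: float
    f_squared: float
    residuals_normal: bool
    n: int


@dataclass(frozen=True)
class LogisticFit:
    predictor: str
    odds_ratio: float
    p_value: float
    n_high: int
    n_low: int


@dataclass(frozen=True)
class AncovaFit:
    outcome: str
    covariate: str
    F_statistic: float
    df_between: int
    df_within: int
    p_value: float
    transform_applied: str


def cohens_d_pooled(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Unsigned Cohen's d with the pooled standard deviation.

    d = |m1 - m2| / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)),
    computable from summary statistics alone.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateDataError("degenerate groups: both standard deviations are zero")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return abs(mean1 - mean2) / pooled


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (W, p).

    W is the Mann-Whitney U of ``x``: the rank sum of ``x`` in the pooled
    midrank ordering minus n_x(n_x+1)/2, so W ranges over [0, n_x * n_y].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical across both samples")
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _normalish(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0:
        return False  # a constant group is not plausibly normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(sample).pvalue > alpha


def compare_groups(x, y, alpha_normality: float = 0.05,
                   variable: str = "") -> GroupComparison:
    """Normality-gated two-group comparison with pooled-SD effect size.

    Both groups pass Shapiro-Wilk at ``alpha_normality`` -> pooled-variance
    Student's t; otherwise -> Wilcoxon rank-sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least three observations per group")
    if _normalish(x, alpha_normality) and _normalish(y, alpha_normality):
        res = sps.ttest_ind(x, y, equal_var=True)
        test, stat, p = "students_t", float(res.statistic), float(res.pvalue)
    else:
        test = "wilcoxon_rank_sum"
        stat, p = wilcoxon_rank_sum(x, y)
    d = cohens_d_pooled(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )
    return GroupComparison(
        variable=variable, test_used=test, statistic=stat, p_value=p,
        cohens_d=d, n1=int(x.size), n2=int(y.size),
        mean1=float(x.mean()), sd1=float(x.std(ddof=1)),
        mean2=float(y.mean()), sd2=float(y.std(ddof=1)),
    )


def ancova_adjusted(
    outcome_by_group: tuple,
    covariate_by_group: tuple,
    transform: str = "none",
    outcome_name: str = "outcome",
    covariate_name: str = "covariate",
) -> AncovaFit:
    """One-way ANCOVA of the group effect controlling for one covariate.

    ``transform="inverse"`` replaces the outcome by its reciprocal first (the
    usual remedy for positive skew; requires strictly positive outcomes).
    The group F carries (1, n - 3) degrees of freedom: one model df each for
    group and covariate plus the intercept.
    """
    y1, y2 = (np.asarray(a, dtype=float) for a in outcome_by_group)
    c1, c2 = (np.asarray(a, dtype=float) for a in covariate_by_group)
    if y1.size != c1.size or y2.size != c2.size:
        raise ValueError("outcome and covariate lengths differ within a group")
    y = np.concatenate([y1, y2])
    cov = np.concatenate([c1, c2])
    grp = np.concatenate([np.zeros(y1.size), np.ones(y2.size)])
    if transform == "inverse":
        if np.any(y == 0):
            raise ValueError("inverse transform undefined for zero outcomes")
        y = 1.0 / y
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    X = sm.add_constant(np.column_stack([grp, cov]))
    fit = sm.OLS(y, X).fit()
    t_group = fit.tvalues[1]
    df_within = int(fit.df_resid)
    F = float(t_group**2)
    p = float(sps.f.sf(F, 1, df_within))
    return AncovaFit(
        outcome=outcome_name, covariate=covariate_name,
        F_statistic=F, df_between=1, df_within=df_within, p_value=p,
        transform_applied=transform,
    )


def f_squared(r_squared: float) -> float:
    """Cohen's f-squared for a regression: R2 / (1 - R2)."""
    if not 0 <= r_squared < 1:
        raise ValueError("R-squared must lie in [0, 1)")
    return r_squared / (1.0 - r_squared)


def linear_regression_standardized(x, y, predictor: str = "x") -> RegressionFit:
    """OLS of z-scored outcome on z-scored predictor.

    Returns the standardized slope (equal to the Pearson correlation), its
    two-sided p, R-squared, f-squared, and a Shapiro-Wilk residual-normality
    flag at the 0.05 level.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("predictor has zero variance")
    if np.ptp(y) == 0:
        raise DegenerateDataError("outcome has zero variance")
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    fit = sm.OLS(zy, sm.add_constant(zx)).fit()
    r2 = float(fit.rsquared)
    if r2 >= 1.0 - 1e-12:
        raise DegenerateDataError("perfect fit: f-squared undefined at R-squared = 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_normal = bool(sps.shapiro(fit.resid).pvalue > 0.05)
    return RegressionFit(
        predictor=predictor,
        beta_standardized=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        r_squared=r2,
        f_squared=f_squared(r2),
        residuals_normal=res_normal,
        n=int(x.size),
    )


def logistic_risk(x, labels, predictor: str = "x") -> LogisticFit:
    """Binomial logistic regression of a high/low risk label on one predictor.

    ``labels`` may be booleans or the strings "high"/"low". Returns the odds
    ratio exp(slope) per unit of ``x`` with its Wald p-value. Perfect
    separation — a real hazard at this study's n = 15 — raises
    :class:`SeparationError` rather than returning a divergent estimate.
    """
    x = np.asarray(x, dtype=float)
    lab = np.asarray(
        [v if isinstance(v, (bool, np.bool_, int, np.integer)) else v == "high"
         for v in labels],
        dtype=float,
    )
    if x.size != lab.size:
        raise ValueError("predictor and labels must have the same length")
    if x.size < 4:
        raise ValueError("need at least four observations")
    n_high = int(lab.sum())
    n_low = int(lab.size - n_high)
    if n_high == 0 or n_low == 0:
        raise DegenerateDataError("both risk classes must be present")
    if np.ptp(x) == 0:
        # No information in the predictor: odds are class-base-rate only.
        return LogisticFit(predictor, 1.0, 1.0, n_high, n_low)
    if x[lab == 1].min() >= x[lab == 0].max() or x[lab == 1].max() <= x[lab == 0].min():
        raise SeparationError(
            f"{predictor}: classes are completely separated; the MLE diverges"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(lab, sm.add_constant(x)).fit(disp=0)
        except PerfectSeparationError as err:
            raise SeparationError(str(err)) from err
    slope = float(fit.params[1])
    if not np.isfinite(slope) or abs(slope) > 50:
        raise SeparationError(f"{predictor}: quasi-separated fit (|slope| > 50)")
    return LogisticFit(
        predictor=predictor,
        odds_ratio=float(np.exp(slope)),
        p_value=float(fit.pvalues[1]),
        n_high=n_high,
        n_low=n_low,
    )
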