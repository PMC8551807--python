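"""Cohort-level sexual-dimorphism statistics.

Implements the sexual dimorphism index (SDI), the normality-driven
dispatch between pooled t, Welch and Mann-Whitney tests, correlation
screening for multicollinearity, the multivariate assumption battery run
before discriminant analysis (Mardia's skewness/kurtosis, Mahalanobis
outliers, Box's M), and the intraclass correlation coefficient for
repeat-reconstruction consistency.

Cohorts are pandas DataFrames in the cohort CSV schema (see
:mod:`osteoinertia.reference_data`), with a ``sex`` column holding
'male'/'female'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SDIResult",
    "SexComparison",
    "CorrelationReport",
    "AssumptionBattery",
    "SingularCovarianceError",
    "sdi",
    "sdi_result",
    "compare_sexes",
    "correlation_screen",
    "assumption_battery",
    "icc",
]


class SingularCovarianceError(ValueError):
    """Pooled covariance singular; names the collinear variables."""


def sdi(male_mean: float, female_mean: float) -> float:
    """Sexual dimorphism index (Xm - Xf) / (Xm + Xf) * 100, in percent.

    Positive when the male mean is larger. Antisymmetric under swapping
    the sexes and invariant to rescaling both means.
    """
    s = male_mean + female_mean
    if s <= 0:
        raise ValueError("male_mean + female_mean must be positive")
    return (male_mean - female_mean) / s * 100.0


@dataclass
class SDIResult:
    variable: str
    male_mean: float
    female_mean: float
    sdi: float


def sdi_result(cohort: pd.DataFrame, variable: str) -> SDIResult:
    """SDI of one variable computed from a cohort's per-sex means."""
    groups = cohort.groupby("sex")[variable].mean()
    xm, xf = float(groups["male"]), float(groups["female"])
    return SDIResult(variable=variable, male_mean=xm, female_mean=xf,
                     sdi=sdi(xm, xf))


@dataclass
class SexComparison:
    """Between-sex test with the audit trail that drove the dispatch."""

    variable: str
    test_used: str  # 't' | 'welch' | 'mann_whitney'
    statistic: float
    dof: float | None
    p_value: float
    shapiro_p: dict = field(default_factory=dict)
    levene_p: float | None = None


def compare_sexes(
    cohort: pd.DataFrame, variable: str, alpha: float = 0.05
) -> SexComparison:
    """Dispatching between-sex comparison of one variable.

    Shapiro-Wilk per sex, then Levene (mean-centered) across sexes:
    both groups normal and homoscedastic -> pooled t; normal but
    heteroscedastic -> Welch; any non-normal group -> Mann-Whitney U.
    """
    x = cohort.loc[cohort["sex"] == "male", variable].to_numpy(dtype=float)
    y = cohort.loc[cohort["sex"] == "female", variable].to_numpy(dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 records per sex")
    sw = {"male": float(sps.shapiro(x).pvalue), "female": float(sps.shapiro(y).pvalue)}
    lev = float(sps.levene(x, y, center="mean").pvalue)
    normal = sw["male"] >= alpha and sw["female"] >= alpha
    if not normal:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return SexComparison(variable, "mann_whitney", float(res.statistic),
                             None, float(res.pvalue), sw, lev)
    equal_var = lev >= alpha
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    name = "t" if equal_var else "welch"
    return SexComparison(variable, name, float(res.statistic),
                         float(res.df), float(res.pvalue), sw, lev)


@dataclass
class CorrelationReport:
    """Pearson matrix among variables plus covariate Spearman screen."""

    pearson: pd.DataFrame
    multicollinear: list  # (var_a, var_b, r_p) with |r_p| > threshold
    spearman: pd.DataFrame | None
    constant_variables: list
    threshold: float


def correlation_screen(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
    covariates: tuple[str, ...] = ("height_cm", "weight_kg"),
    threshold: float = 0.80,
) -> CorrelationReport:
    """Flag multicollinear variable pairs and screen body-size covariates.

    Pearson correlations among the bone variables (pairs with
    \\|r_p\\| > ``threshold`` are flagged for exclusion from discriminant
    candidates); Spearman correlations between each available covariate
    and each variable. Constant variables are excluded and reported.
    """
    from .reference_data import VARIABLES

    variables = tuple(variables or [v for v in VARIABLES if v in cohort.columns])
    constant = [v for v in variables if cohort[v].nunique() <= 1]
    active = [v for v in variables if v not in constant]
    pearson = cohort[active].corr(method="pearson")
    flagged = []
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            r = float(pearson.loc[a, b])
            if abs(r) > threshold:
                flagged.append((a, b, r))
    spearman = None
    covs = [c for c in covariates if c in cohort.columns]
    if covs:
        rows = {}
        for c in covs:
            rows[c] = {
                v: float(sps.spearmanr(cohort[c], cohort[v]).statistic)
                for v in active
            }
        spearman = pd.DataFrame(rows).T
    return CorrelationReport(
        pearson=pearson, multicollinear=flagged, spearman=spearman,
        constant_variables=constant, threshold=threshold,
    )


def _mardia(X: np.ndarray) -> dict:
    """Mardia's multivariate skewness and kurtosis with p-values.

    Skewness: b1p = mean over pairs of (centered Mahalanobis inner
    product)^3; n*b1p/6 ~ chi2 with p(p+1)(p+2)/6 df. Kurtosis:
    b2p = mean squared Mahalanobis distance; normal under
    N(p(p+2), 8p(p+2)/n).
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n  # ML covariance, the conventional Mardia scaling
    Sinv = np.linalg.pinv(S)
    D = Xc @ Sinv @ Xc.T
    b1 = float((D**3).sum()) / n**2
    b2 = float((np.diag(D) ** 2).mean())
    df_skew = p * (p + 1) * (p + 2) / 6.0
    skew_stat = n * b1 / 6.0
    skew_p = float(sps.chi2.sf(skew_stat, df_skew))
    kurt_z = (b2 - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2 * sps.norm.sf(abs(kurt_z)))
    return dict(skewness=b1, skew_statistic=skew_stat, skew_p=skew_p,
                kurtosis=b2, kurt_z=float(kurt_z), kurt_p=kurt_p)


@dataclass
class AssumptionBattery:
    """Pre-discriminant multivariate assumption report."""

    mardia: dict  # sex -> skewness/kurtosis statistics and p-values
    mahalanobis: pd.DataFrame  # per-record d^2, chi2 p, outlier flag
    outliers: list  # row labels with p < outlier_alpha
    box_m: dict  # statistic, df, p_value, passed
    outlier_alpha: float
    box_m_alpha: float


def _check_singular(X: np.ndarray, variables) -> None:
    corr = np.corrcoef(X, rowvar=False)
    if X.shape[1] > 1:
        pairs = [
            (variables[i], variables[j])
            for i in range(len(variables))
            for j in range(i + 1, len(variables))
            if abs(corr[i, j]) > 0.9999
        ]
        if pairs or np.linalg.matrix_rank(np.cov(X, rowvar=False)) < X.shape[1]:
            raise SingularCovarianceError(
                f"singular pooled covariance; collinear variables: {pairs or variables}"
            )


def assumption_battery(
    cohort: pd.DataFrame,
    variables: tuple[str, ...],
    outlier_alpha: float = 0.001,
    box_m_alpha: float = 0.001,
) -> AssumptionBattery:
    """Mardia normality, Mahalanobis outliers and Box's M, per the
    conventional pre-discriminant checklist (thresholds configurable;
    0.001 for both the outlier rule and Box's M by default)."""
    import pingouin as pg

    variables = tuple(variables)
    p = len(variables)
    mardia = {}
    maha_rows = []
    for sex, grp in cohort.groupby("sex"):
        X = grp[list(variables)].to_numpy(dtype=float)
        if X.shape[0] <= p:
            raise ValueError(
                f"group {sex!r} has n={X.shape[0]} <= p={p} variables"
            )
        _check_singular(X, variables)
        mardia[sex] = _mardia(X)
        Xc = X - X.mean(axis=0)
        S = np.cov(X, rowvar=False)
        d2 = np.einsum("ni,ij,nj->n", Xc, np.linalg.inv(S), Xc)
        pvals = sps.chi2.sf(d2, df=p)
        for label, dd, pv in zip(grp.index, d2, pvals):
            maha_rows.append(
                dict(index=label, sex=sex, d2=float(dd), p_value=float(pv),
                     outlier=bool(pv < outlier_alpha))
            )
    maha = pd.DataFrame(maha_rows).set_index("index")
    outliers = list(maha.index[maha["outlier"]])

    bm = pg.box_m(cohort, dvs=list(variables), group="sex")
    stat = float(bm["Chi2"].iloc[0])
    bm_p = float(bm["pval"].iloc[0])
    box = dict(statistic=stat, df=float(bm["df"].iloc[0]), p_value=bm_p,
               passed=bool(bm_p > box_m_alpha))
    return AssumptionBattery(
        mardia=mardia, mahalanobis=maha, outliers=outliers, box_m=box,
        outlier_alpha=outlier_alpha, box_m_alpha=box_m_alpha,
    )


def icc(
    measurements_a,
    measurements_b,
    form: str = "ICC(A,1)",
) -> float:
    """Agreement between two repeat measurement sessions of the same bones.

    Default form is the single-measurement, absolute-agreement, two-way
    ICC (McGraw-Wong ICC(A,1); the repeat reconstructions are the two
    "raters"). Any form pingouin reports — ICC(1,1), ICC(A,1), ICC(C,1)
    and their k-average versions — can be requested.
    """
    import warnings

    a = np.asarray(measurements_a, dtype=float)
    b = np.asarray(measurements_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length paired vectors with n >= 3")
    if np.var(np.concatenate([a, b])) == 0 or np.var((a + b) / 2) == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    if np.array_equal(a, b):
        return 1.0  # exact agreement; avoids a 0/0 mean-square ratio
    import pingouin as pg

    long = pd.DataFrame({
        "target": np.r_[np.arange(len(a)), np.arange(len(b))],
        "rater": ["A"] * len(a) + ["B"] * len(b),
        "score": np.r_[a, b],
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        )
    value = float(table.set_index("Type").loc[form, "ICC"])
    if not np.isfinite(value):
        raise ValueError("ICC undefined for these data")
    return value
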