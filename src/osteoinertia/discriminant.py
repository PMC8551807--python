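"""Two-group canonical discriminant analysis for sex estimation.

The canonical direction is ``a ∝ Sw^-1 (mean_male - mean_female)`` with
``Sw`` the pooled within-group covariance (n - g divisor), scaled so the
pooled within-group score variance equals 1 and shifted so the overall
sample mean scores 0::

    Y = a_1 x_1 + ... + a_p x_p + C

Group centroids are the scores at the group means; with equal priors the
sectioning point is their midpoint, and a case is assigned to the male
side of it (footnote convention: when the male centroid is positive,
Y above the sectioning point reads male, and conversely).

Stepwise variable selection minimizes the overall Wilks' lambda subject
to partial-F gates. With g groups and p variables already entered, the
partial F for entering v is::

    F = ((Lambda_p / Lambda_{p+1}) - 1) * (n - g - p) / (g - 1)

(for removal, the same expression viewed from the smaller model). The
default gates are F-to-enter 3.84 and F-to-remove 2.71. Wilks' lambda is
det(W)/det(T) of the within/total SSCP matrices; its chi-square uses
Bartlett's correction -(n - 1 - (p + g)/2) ln(Lambda).

The module also ships the ten published metatarsal discriminant
functions (left/right, metatarsals 1-5) transcribed verbatim, so new
cases can be scored without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import reference_data as ref

__all__ = [
    "DiscriminantFunction",
    "StepwiseConfig",
    "SelectionStep",
    "SelectionTrace",
    "ClassificationBlock",
    "ClassificationReport",
    "SexDiscriminantClassifier",
    "fit_discriminant",
    "stepwise_select",
    "score",
    "classify",
    "sectioning_point",
    "loo_accuracy",
    "published_functions",
    "wilks_lambda",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class DiscriminantFunction:
    """A linear sex-discriminant function Y = sum(a_i x_i) + C."""

    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    constant: float
    centroid_male: float
    centroid_female: float
    sectioning_point: float
    std_coefficients: tuple[float, ...] | None = None
    structure_matrix: tuple[float, ...] | None = None
    wilks_lambda: float | None = None
    chi_square: float | None = None
    label: str = ""

    def score(self, record):
        """Discriminant score(s) Y for a mapping, Series or DataFrame."""
        if isinstance(record, pd.DataFrame):
            missing = [v for v in self.variables if v not in record.columns]
            if missing:
                raise KeyError(f"record missing variables: {missing}")
            X = record[list(self.variables)].to_numpy(dtype=float)
            return X @ np.asarray(self.coefficients) + self.constant
        missing = [v for v in self.variables if v not in record]
        if missing:
            raise KeyError(f"record missing variables: {missing}")
        return float(
            sum(a * float(record[v]) for a, v in zip(self.coefficients, self.variables))
            + self.constant
        )

    def classify(self, record):
        """'male' / 'female' by the sectioning-point rule; ties are
        'indeterminate'."""
        y = self.score(record)
        if np.ndim(y) > 0:
            return np.array([self._label_one(v) for v in np.asarray(y)])
        return self._label_one(y)

    def _label_one(self, y: float) -> str:
        if y == self.sectioning_point:
            return "indeterminate"
        male_above = self.centroid_male > self.centroid_female
        return "male" if (y > self.sectioning_point) == male_above else "female"


@dataclass(frozen=True)
class StepwiseConfig:
    """Partial-F gates for stepwise selection."""

    f_enter: float = 3.84
    f_remove: float = 2.71
    max_steps: int = 100

    def __post_init__(self):
        if not (self.f_enter > self.f_remove > 0):
            raise ValueError("require f_enter > f_remove > 0")


@dataclass(frozen=True)
class SelectionStep:
    action: str  # 'enter' | 'remove'
    variable: str
    wilks_lambda: float
    partial_f: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    selected: tuple[str, ...] = ()

    @property
    def empty(self) -> bool:
        return len(self.selected) == 0


@dataclass
class ClassificationBlock:
    male_correct: int
    male_total: int
    female_correct: int
    female_total: int

    @property
    def male_pct(self) -> float:
        return 100.0 * self.male_correct / self.male_total

    @property
    def female_pct(self) -> float:
        return 100.0 * self.female_correct / self.female_total

    @property
    def total_pct(self) -> float:
        return (self.male_pct + self.female_pct) / 2.0


@dataclass
class ClassificationReport:
    """Original-sample and leave-one-out classification accuracy."""

    original: ClassificationBlock
    cross_validated: ClassificationBlock
    variables: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# core algebra


def _groups(cohort: pd.DataFrame, variables: Sequence[str], sex_col: str = "sex"):
    Xm = cohort.loc[cohort[sex_col] == "male", list(variables)].to_numpy(dtype=float)
    Xf = cohort.loc[cohort[sex_col] == "female", list(variables)].to_numpy(dtype=float)
    if len(Xm) == 0 or len(Xf) == 0:
        raise ValueError("both sexes must be present")
    return Xm, Xf


def _sscp(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc


def wilks_lambda(cohort: pd.DataFrame, variables: Sequence[str]) -> float:
    """Overall Wilks' lambda det(W)/det(T) for the two sex groups."""
    variables = list(variables)
    if not variables:
        return 1.0
    Xm, Xf = _groups(cohort, variables)
    W = _sscp(Xm) + _sscp(Xf)
    T = _sscp(np.vstack([Xm, Xf]))
    detT = np.linalg.det(T)
    if detT <= 0:
        raise np.linalg.LinAlgError("singular total SSCP")
    return float(np.linalg.det(W) / detT)


def _partial_f(lam_small: float, lam_big: float, n: int, p_small: int, g: int = 2) -> float:
    # F for adding one variable to a model of p_small variables:
    # numerator df = g - 1, denominator df = n - g - p_small
    dof = n - g - p_small
    if dof <= 0 or lam_big <= 0:
        return np.nan
    return (lam_small / lam_big - 1.0) * dof / (g - 1)


def stepwise_select(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    config: StepwiseConfig = StepwiseConfig(),
) -> SelectionTrace:
    """Stepwise Wilks'-lambda variable selection with partial-F gates.

    At each step the candidate minimizing the overall lambda is entered
    if its partial F-to-enter passes ``f_enter``; after every entry, any
    included variable whose F-to-remove falls below ``f_remove`` is
    removed (smallest first). Terminates when no change (or on a cycle).
    An empty trace (nothing passes entry) is a valid result.
    """
    candidates = list(candidates)
    n = len(cohort)
    included: list[str] = []
    lam_cur = 1.0
    trace = SelectionTrace()
    seen: set[tuple[str, ...]] = set()
    for _ in range(config.max_steps):
        changed = False
        # entry
        best = None
        for v in candidates:
            if v in included:
                continue
            try:
                lam = wilks_lambda(cohort, included + [v])
            except np.linalg.LinAlgError:
                continue
            F = _partial_f(lam_cur, lam, n, len(included))
            if np.isnan(F) or F < config.f_enter:
                continue
            if best is None or lam < best[1]:
                best = (v, lam, F)
        if best is not None:
            v, lam, F = best
            included.append(v)
            lam_cur = lam
            trace.steps.append(SelectionStep("enter", v, lam, F))
            changed = True
        # removal sweep
        while len(included) > 1:
            worst = None
            for v in included:
                rest = [w for w in included if w != v]
                lam_rest = wilks_lambda(cohort, rest)
                F = _partial_f(lam_rest, lam_cur, n, len(rest))
                if worst is None or F < worst[2]:
                    worst = (v, lam_rest, F)
            if worst is None or worst[2] >= config.f_remove:
                break
            v, lam_rest, F = worst
            included.remove(v)
            lam_cur = lam_rest
            trace.steps.append(SelectionStep("remove", v, lam_rest, F))
            changed = True
        key = tuple(sorted(included))
        if not changed or key in seen:
            break
        seen.add(key)
    trace.selected = tuple(included)
    return trace


def _name_collinear(X: np.ndarray, variables: Sequence[str]) -> list:
    corr = np.corrcoef(X, rowvar=False)
    return [
        (variables[i], variables[j])
        for i in range(len(variables))
        for j in range(i + 1, len(variables))
        if abs(corr[i, j]) > 0.9999
    ]


def fit_discriminant(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    sex_col: str = "sex",
    label: str = "",
) -> DiscriminantFunction:
    """Fit the two-group canonical discriminant function.

    Coefficients are scaled to unit pooled within-group score variance;
    the constant centers the overall sample mean score at 0. Standardized
    coefficients, the structure matrix (pooled within-group correlations
    between each variable and the score), group centroids, the equal-prior
    sectioning point, Wilks' lambda and its Bartlett chi-square are all
    attached. The canonical sign is fixed so the variable with the largest
    absolute standardized coefficient carries a positive one.
    """
    variables = tuple(variables)
    if not variables:
        raise ValueError("need at least one variable")
    Xm, Xf = _groups(cohort, variables, sex_col)
    n_m, n_f = len(Xm), len(Xf)
    n, g, p = n_m + n_f, 2, len(variables)
    if n - g - p + 1 <= 0:
        raise ValueError("too few records for the number of variables")
    W = _sscp(Xm) + _sscp(Xf)
    Sw = W / (n - g)
    mean_m, mean_f = Xm.mean(axis=0), Xf.mean(axis=0)
    try:
        w = np.linalg.solve(Sw, mean_m - mean_f)
        norm2 = float(w @ Sw @ w)
        if norm2 <= 0 or not np.isfinite(norm2):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        pairs = _name_collinear(np.vstack([Xm, Xf]), variables)
        raise SingularCovarianceError(
            f"singular pooled within-group covariance; collinear: {pairs or variables}"
        ) from None
    a = w / np.sqrt(norm2)
    sd_within = np.sqrt(np.diag(Sw))
    std = a * sd_within
    pivot = int(np.argmax(np.abs(std)))
    if std[pivot] < 0:
        a, std = -a, -std
    grand = (n_m * mean_m + n_f * mean_f) / n
    C = -float(a @ grand)
    cm = float(a @ mean_m + C)
    cf = float(a @ mean_f + C)
    structure = (Sw @ a) / sd_within
    lam = wilks_lambda(cohort, variables)
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam)
    return DiscriminantFunction(
        variables=variables,
        coefficients=tuple(float(v) for v in a),
        constant=C,
        centroid_male=cm,
        centroid_female=cf,
        sectioning_point=sectioning_point(cm, cf),
        std_coefficients=tuple(float(v) for v in std),
        structure_matrix=tuple(float(v) for v in structure),
        wilks_lambda=lam,
        chi_square=float(chi2),
        label=label,
    )


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-group covariance is singular."""


def sectioning_point(
    centroid_male: float, centroid_female: float, priors: str = "equal"
) -> float:
    """Classification threshold between the group centroids.

    Equal priors (the only supported setting) put it at the midpoint.
    """
    if priors != "equal":
        raise NotImplementedError("only equal priors are supported")
    if centroid_male == centroid_female:
        raise ValueError("equal centroids: no sectioning point")
    return (centroid_male + centroid_female) / 2.0


def score(model: DiscriminantFunction, record):
    """Discriminant score Y of a record under a function."""
    return model.score(record)


def classify(model: DiscriminantFunction, record):
    """Sex label for a record; exact ties give 'indeterminate'."""
    return model.classify(record)


def loo_accuracy(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    reselect: bool = False,
    config: StepwiseConfig = StepwiseConfig(),
) -> ClassificationReport:
    """Original-sample and leave-one-out classification accuracy.

    Each held-out case is classified by a function refit on the remaining
    cases. By default the variable set stays fixed (coefficients only are
    refit), mirroring the usual cross-validation semantics of stepwise
    discriminant software; ``reselect=True`` reruns selection per fold.
    """
    variables = tuple(variables)
    counts = {"male": [0, 0], "female": [0, 0]}
    full = fit_discriminant(cohort, variables)
    pred = full.classify(cohort)
    for truth, lab in zip(cohort["sex"], pred):
        counts[truth][1] += 1
        counts[truth][0] += int(lab == truth)
    original = ClassificationBlock(
        counts["male"][0], counts["male"][1],
        counts["female"][0], counts["female"][1],
    )
    counts = {"male": [0, 0], "female": [0, 0]}
    for idx in cohort.index:
        rest = cohort.drop(index=idx)
        vars_i = variables
        if reselect:
            vars_i = stepwise_select(rest, variables, config).selected
            if not vars_i:
                vars_i = variables
        model_i = fit_discriminant(rest, vars_i)
        lab = model_i.classify(cohort.loc[idx])
        truth = cohort.loc[idx, "sex"]
        counts[truth][1] += 1
        counts[truth][0] += int(lab == truth)
    cross = ClassificationBlock(
        counts["male"][0], counts["male"][1],
        counts["female"][0], counts["female"][1],
    )
    return ClassificationReport(original=original, cross_validated=cross,
                                variables=variables)


def published_functions() -> dict[tuple[str, int], DiscriminantFunction]:
    """The ten published metatarsal discriminant functions.

    Keyed (side, metatarsal); all coefficients, constants, centroids and
    sectioning points are the printed values.
    """
    registry = {}
    for key, spec in ref.PUBLISHED_FUNCTIONS.items():
        side, mt = key
        registry[key] = DiscriminantFunction(
            variables=tuple(spec["variables"]),
            coefficients=tuple(spec["coefficients"]),
            constant=spec["constant"],
            centroid_male=spec["centroid_male"],
            centroid_female=spec["centroid_female"],
            sectioning_point=spec["sectioning_point"],
            std_coefficients=tuple(spec["std_coefficients"]),
            structure_matrix=tuple(spec["structure_matrix"]),
            wilks_lambda=spec["wilks_lambda"],
            chi_square=spec["chi_square"],
            label=f"{side} metatarsal {mt}",
        )
    return registry


# ---------------------------------------------------------------------------
# scikit-learn estimator


class SexDiscriminantClassifier(BaseEstimator, ClassifierMixin):
    """Two-group canonical discriminant classifier (scikit-learn API).

    Parameters
    ----------
    variables : sequence of str, optional
        Columns to use when X is a DataFrame (default: all candidates).
    stepwise : bool
        Run Wilks'-lambda stepwise selection before fitting.
    f_enter, f_remove : float
        Partial-F gates for the stepwise search.

    Attributes
    ----------
    function_ : DiscriminantFunction
        The fitted function (coefficients, centroids, sectioning point).
    variables_ : tuple of str
        Variables in the fitted function.
    coef_, intercept_ : ndarray, float
        Unstandardized coefficients and constant.
    selection_trace_ : SelectionTrace or None
    classes_ : ndarray
        Always ``['female', 'male']``.
    """

    def __init__(self, variables=None, stepwise=False,
                 f_enter=3.84, f_remove=2.71):
        self.variables = variables
        self.stepwise = stepwise
        self.f_enter = f_enter
        self.f_remove = f_remove

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        cols = list(self.variables) if self.variables else [
            f"x{i}" for i in range(X.shape[1])
        ]
        return pd.DataFrame(X, columns=cols)

    def fit(self, X, y):
        df = self._as_frame(X).copy()
        y = np.asarray(y)
        labels = set(np.unique(y))
        if labels != {"male", "female"}:
            if len(labels) != 2:
                raise ValueError("need exactly two classes")
            # map arbitrary binary labels onto the male/female convention
            lab_sorted = sorted(labels)
            y = np.where(y == lab_sorted[0], "female", "male")
        df["sex"] = y
        candidates = tuple(self.variables) if self.variables else tuple(
            c for c in df.columns if c != "sex"
        )
        self.selection_trace_ = None
        variables = candidates
        if self.stepwise:
            cfg = StepwiseConfig(f_enter=self.f_enter, f_remove=self.f_remove)
            self.selection_trace_ = stepwise_select(df, candidates, cfg)
            if self.selection_trace_.empty:
                raise ValueError(
                    "no variable passed the F-to-enter gate; empty model"
                )
            variables = self.selection_trace_.selected
        fn = fit_discriminant(df, variables)
        self.function_ = fn
        self.variables_ = fn.variables
        self.coef_ = np.asarray(fn.coefficients)
        self.intercept_ = fn.constant
        self.centroids_ = {"male": fn.centroid_male, "female": fn.centroid_female}
        self.sectioning_point_ = fn.sectioning_point
        self.wilks_lambda_ = fn.wilks_lambda
        self.classes_ = np.array(["female", "male"])
        return self

    def decision_function(self, X):
        df = self._as_frame(X)
        return self.function_.score(df)

    def predict(self, X):
        df = self._as_frame(X)
        labels = self.function_.classify(df)
        # sklearn predict must be deterministic two-class: break exact
        # ties (measure zero) toward female
        return np.where(np.asarray(labels) == "male", "male", "female")
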