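"""Statistical stages: age classes, jackknifed DFA, correlations, GLMs.

Four analyses operate on the per-crab cohort table (metadata plus the six
appearance metrics):

* **Age-class assignment** by carapace width (CW): either sex-specific
  maturity estimates (females mature by 28 mm CW, males above 21 mm) or a
  single 25 mm threshold (adult iff CW ≥ 25 mm).  The two criteria are
  compared by which one the appearance metrics discriminate better.
* **Jackknifed DFA** — linear discriminant analysis with leave-one-out
  cross-validation: each crab is classified by a discriminant function
  fitted on all the others, yielding a confusion matrix and proportions
  correct that are conservative relative to resubstitution.
* **Spearman rank correlations** of each metric against continuous
  carapace width, with the t approximation t = r_s·sqrt((n−2)/(1−r_s²)).
* **General linear models** (fixed effects site, shore zone, life stage
  with their pairwise interactions) after Box-Cox transformation of the
  response; non-significant interactions are removed stepwise (largest p
  first) and the model refitted.  Unbalanced designs are tested with
  marginal (Type II) sums of squares.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AGE_CRITERIA",
    "ClassificationResult",
    "CorrelationResult",
    "GlmResult",
    "assign_age",
    "lda_loocv",
    "compare_age_criteria",
    "spearman_vs_size",
    "boxcox",
    "glm_stepwise",
]

#: Named age-class criteria mapping (sex, carapace width in mm) -> label.
AGE_CRITERIA = ("maturity", "width25")


@dataclass
class ClassificationResult:
    """Confusion matrix (rows predicted, columns true) and accuracies."""

    confusion: pd.DataFrame
    per_group_correct: pd.Series
    overall_correct: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation reported with its t statistic and df."""

    rho: float
    t: float
    df: int
    p: float
    n: int


@dataclass
class GlmResult:
    """Final ANOVA table with the stepwise interaction-removal trace."""

    anova: pd.DataFrame
    removal_trace: list[tuple[str, float]]  # (term, p at removal)
    retained_terms: list[str]
    boxcox_power: float | None
    alpha: float
    model: object = field(repr=False, default=None)


def assign_age(
    cohort: pd.DataFrame,
    criterion: str = "width25",
    width_col: str = "carapace_width_mm",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Label every crab with a life stage.

    ``"width25"``: adult iff CW ≥ 25 mm, juvenile below (sex ignored).
    ``"maturity"``: mature females at CW ≥ 28 mm, mature males above
    21 mm; labels are ``mature``/``immature``.  Rows with missing width
    are dropped with a warning.
    """
    out = cohort.copy()
    missing = out[width_col].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} rows dropped: missing carapace width",
            stacklevel=2,
        )
        out = out[~missing]
    width = out[width_col].to_numpy(dtype=float)
    if np.any(width <= 0):
        raise ValueError("carapace widths must be positive")
    if criterion == "width25":
        out["stage"] = np.where(width >= 25.0, "adult", "juvenile")
    elif criterion == "maturity":
        sex = out[sex_col].astype(str).str.lower().str[0].to_numpy()
        if not np.isin(sex, ["f", "m"]).all():
            raise ValueError("maturity criterion needs sex coded f/m for every crab")
        mature = np.where(sex == "f", width >= 28.0, width > 21.0)
        out["stage"] = np.where(mature, "mature", "immature")
    else:
        raise ValueError(f"unknown age criterion {criterion!r}; use one of {AGE_CRITERIA}")
    return out


def lda_loocv(
    cohort: pd.DataFrame,
    feature_cols: tuple[str, ...],
    label_col: str,
) -> ClassificationResult:
    """Leave-one-out cross-validated linear discriminant classification.

    Each observation is classified by a discriminant function fitted on
    all remaining observations (shared within-group covariance, priors
    proportional to training group sizes).  Posterior ties break toward
    the first-listed group.  Rejects collinear feature sets, which make
    the within-group covariance singular.
    """
    x = cohort[list(feature_cols)].to_numpy(dtype=float)
    y = cohort[label_col].to_numpy()
    labels = [lbl for lbl in pd.unique(y)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to discriminate")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise ValueError(
            "collinear features: within-group covariance is singular; "
            "drop or combine correlated metrics"
        )
    counts = pd.Series(y).value_counts()
    if (counts <= len(feature_cols)).any():
        warnings.warn(
            "some groups have no more observations than features; "
            "LOOCV discriminants may be unstable",
            stacklevel=2,
        )
    n = len(y)
    pred = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(x[train], y[train])
        pred[i] = clf.predict(x[i][None, :])[0]
    order = sorted(labels, key=str)
    confusion = pd.crosstab(
        pd.Series(pred, name="predicted"), pd.Series(y, name="true")
    ).reindex(index=order, columns=order, fill_value=0)
    per_group = pd.Series(
        {g: confusion.loc[g, g] / confusion[g].sum() for g in order},
        name="proportion_correct",
    )
    overall = float((pred == y).mean())
    return ClassificationResult(
        confusion=confusion, per_group_correct=per_group, overall_correct=overall, n=n
    )


def compare_age_criteria(
    cohort: pd.DataFrame,
    feature_cols: tuple[str, ...],
    criteria: tuple[str, ...] = AGE_CRITERIA,
) -> tuple[str, dict[str, ClassificationResult]]:
    """Pick the age criterion whose classes the metrics separate best.

    Runs the jackknifed DFA under each candidate criterion and selects
    the one with the highest overall proportion correct.
    """
    results: dict[str, ClassificationResult] = {}
    for crit in criteria:
        labelled = assign_age(cohort, criterion=crit)
        results[crit] = lda_loocv(labelled, feature_cols, "stage")
    best = max(results, key=lambda c: results[c].overall_correct)
    return best, results


def spearman_vs_size(
    cohort: pd.DataFrame,
    metric: str,
    size_col: str = "carapace_width_mm",
    method: str = "t",
) -> CorrelationResult:
    """Spearman rank correlation of one metric against carapace width.

    rho uses midranks for ties; p comes from the t approximation
    (df = n − 2) by default, or full permutation enumeration for n ≤ 8
    with ``method="exact"``.
    """
    sub = cohort[[metric, size_col]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xm = sub[metric].to_numpy(dtype=float)
    xs = sub[size_col].to_numpy(dtype=float)
    if np.std(xm) == 0 or np.std(xs) == 0:
        raise ValueError(f"correlation undefined: {metric!r} or size is constant")
    rho = float(scipy.stats.spearmanr(xm, xs).statistic)
    df = n - 2
    if abs(rho) >= 1.0:
        t = np.inf * np.sign(rho)
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = 2.0 * scipy.stats.t.sf(abs(t), df)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only enumerable for n <= 8")
        rs = scipy.stats.rankdata(xs)
        count = 0
        total = 0
        for perm in itertools.permutations(scipy.stats.rankdata(xm)):
            r = np.corrcoef(perm, rs)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    elif method != "t":
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho=rho, t=float(t), df=df, p=float(p), n=n)


def boxcox(
    values: np.ndarray, power: float | None = None
) -> tuple[np.ndarray, float]:
    """Box-Cox transform: (v^λ − 1)/λ, or ln v at λ = 0.

    With ``power=None`` the exponent is estimated by maximum likelihood.
    Strictly positive input required.  Returns (transformed, λ).
    """
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("Box-Cox requires strictly positive finite values")
    if power is None:
        transformed, lam = scipy.stats.boxcox(v)
        return transformed, float(lam)
    if power == 0:
        return np.log(v), 0.0
    return (v**power - 1.0) / power, float(power)


def _term_name(factors: tuple[str, ...]) -> str:
    return ":".join(f"C({f})" for f in factors)


def glm_stepwise(
    cohort: pd.DataFrame,
    response: str,
    factors: tuple[str, ...] = ("site", "zone", "stage"),
    interactions: tuple[tuple[str, str], ...] | None = None,
    alpha: float = 0.05,
    boxcox_power: float | None = None,
) -> GlmResult:
    """Fixed-effects GLM with stepwise removal of non-significant interactions.

    Fits an OLS model of the (optionally Box-Cox transformed) response on
    the main-effect factors plus candidate two-way interactions, tests
    terms with Type II F statistics, and repeatedly removes the
    interaction with the largest p ≥ ``alpha``, refitting after each
    removal.  Main effects are never removed.
    """
    if interactions is None:
        interactions = tuple(itertools.combinations(factors, 2))
    data = cohort.copy()
    lam: float | None = None
    if boxcox_power is not None:
        data["_response_"], lam = boxcox(data[response].to_numpy(), boxcox_power)
    else:
        data["_response_"] = data[response].astype(float)
    main_terms = [f"C({f})" for f in factors]
    inter_terms = [_term_name(pair) for pair in interactions]
    trace: list[tuple[str, float]] = []
    current = list(inter_terms)
    while True:
        formula = "_response_ ~ " + " + ".join(main_terms + current)
        model = smf.ols(formula, data=data).fit()
        if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            raise ValueError("rank-deficient design: empty factor-level combinations")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_lm(model, typ=2)
        if not current:
            break
        pvals = table.loc[current, "PR(>F)"]
        worst = pvals.idxmax()
        if pvals[worst] >= alpha:
            trace.append((worst, float(pvals[worst])))
            current.remove(worst)
        else:
            break
    df_resid = float(table.loc["Residual", "df"])
    table = table.drop(index="Residual").assign(df_resid=df_resid)
    return GlmResult(
        anova=table,
        removal_trace=trace,
        retained_terms=main_terms + current,
        boxcox_power=lam,
        alpha=alpha,
        model=model,
    )
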