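"""Clinical statistics for the plaque-index / kidney-function analysis.

Covers the renal-function formulas (CKD-EPI eGFR, percentage eGFR change),
the CKD and plaque-index categorisations, the nonparametric two-group tests
used for cohort tables (Mann-Whitney U, Fisher's exact), 2x2 odds ratios,
logistic regression with Wald odds-ratio CIs (statsmodels backed), and the
empirical ROC curve. The covariate-adjusted binormal ROC regression lives in
:mod:`plaqueindex.rocreg`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ClinicalError",
    "ApiCategory",
    "TestResult",
    "LogisticFit",
    "ckd_epi_egfr",
    "delta_pct_egfr",
    "classify_ckd",
    "categorize_api",
    "mann_whitney",
    "fisher_exact",
    "odds_ratio_2x2",
    "fit_logistic",
    "empirical_roc",
]


class ClinicalError(ValueError):
    pass


class ApiCategory(enum.Enum):
    """Plaque-index categories used as reference coding in the outcome models."""

    ZERO = "0"
    POSITIVE_LT10 = "<10"
    GE10 = ">=10"


# ---------------------------------------------------------------------------
# renal function formulas


def ckd_epi_egfr(creatinine_mg_dl: float, age_years: float, sex: str, black: bool = False) -> float:
    """Estimated GFR (mL/min/1.73 m^2) by the 2009 CKD-EPI creatinine equation.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] * 1.159 [black, only if requested]

    with k = 0.7 / a = -0.329 for females and k = 0.9 / a = -0.411 for
    males. The race coefficient is off by default (race-free variant).
    """
    if creatinine_mg_dl <= 0:
        raise ClinicalError(f"creatinine must be > 0 mg/dL, got {creatinine_mg_dl}")
    if age_years <= 0:
        raise ClinicalError(f"age must be > 0 years, got {age_years}")
    s = str(sex).lower()
    if s in ("f", "female", "w"):
        kappa, alpha, sex_mult = 0.7, -0.329, 1.018
    elif s in ("m", "male"):
        kappa, alpha, sex_mult = 0.9, -0.411, 1.0
    else:
        raise ClinicalError(f"sex must be male/female, got {sex!r}")
    ratio = creatinine_mg_dl / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993 ** age_years
    egfr *= sex_mult
    if black:
        egfr *= 1.159
    return egfr


def delta_pct_egfr(pre: float, last: float) -> float:
    """Percentage eGFR change from baseline: 100 * (last - pre) / pre."""
    if pre <= 0:
        raise ClinicalError(f"baseline eGFR must be > 0, got {pre}")
    return (last - pre) / pre * 100.0


def classify_ckd(egfr: float, threshold: float = 60.0) -> bool:
    """True iff eGFR is below the CKD threshold (default 60, KDIGO stage >= 3)."""
    if egfr <= 0:
        raise ClinicalError(f"eGFR must be > 0, got {egfr}")
    return egfr < threshold


def categorize_api(api: float) -> ApiCategory:
    """0 -> ZERO; (0, 10) -> POSITIVE_LT10; >= 10 -> GE10."""
    if not np.isfinite(api) or api < 0:
        raise ClinicalError(f"API must be finite and >= 0, got {api}")
    if api == 0:
        return ApiCategory.ZERO
    return ApiCategory.POSITIVE_LT10 if api < 10.0 else ApiCategory.GE10


# ---------------------------------------------------------------------------
# two-group tests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ClinicalError(f"p-value outside [0,1]: {self.p_value}")


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution (no ties, combined n <= 12), otherwise the
    tie-corrected normal approximation with continuity correction. The
    reported statistic is U for the first sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ClinicalError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= 12 and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann-whitney-exact" if exact else "mann-whitney-normal",
        n=(x.size, y.size),
    )


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ClinicalError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ClinicalError("table cells must be non-negative integers")
    t = t.astype(int)
    if np.any(t < 0):
        raise ClinicalError("table cells must be non-negative")
    return t


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    p = sum of hypergeometric probabilities of all margin-fixed tables no
    more probable than the observed one.
    """
    t = _check_2x2(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ClinicalError("both margins must be positive")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), method="fisher-exact",
                      n=tuple(int(v) for v in t.sum(axis=1)))


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # 0.5 added to every cell (a zero cell was present)


def odds_ratio_2x2(table, alpha: float = 0.05) -> OddsRatio:
    """Cross-product odds ratio with the Woolf logit confidence interval.

    Zero cells trigger the standard 0.5 continuity correction on all cells.
    """
    t = _check_2x2(table).astype(float)
    corrected = bool(np.any(t == 0))
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return OddsRatio(
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - z * se)),
        ci_high=float(np.exp(np.log(orr) + z * se)),
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """Wald-style logistic regression summary (one row per covariate)."""

    table: pd.DataFrame  # index: term; columns: coef, or_, ci_low, ci_high, p
    pseudo_r2: float
    converged: bool
    n: int
    flags: list[str] = field(default_factory=list)

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "or_"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def summary(self) -> str:
        lines = [f"Logistic regression (n={self.n}, McFadden R2={self.pseudo_r2:.3f}, "
                 f"converged={self.converged})"]
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(str(self.table))
        return "\n".join(lines)


def expand_api_categories(df: pd.DataFrame, api_col: str = "api") -> pd.DataFrame:
    """Add 0/1 indicator columns ``api_lt10`` and ``api_ge10`` (ZERO = reference)."""
    api = df[api_col].to_numpy(float)
    if np.any(api < 0) or not np.all(np.isfinite(api)):
        raise ClinicalError("API values must be finite and >= 0")
    out = df.copy()
    out["api_lt10"] = ((api > 0) & (api < 10)).astype(int)
    out["api_ge10"] = (api >= 10).astype(int)
    return out


def fit_logistic(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    api_col: str = "api",
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald ORs and 95% CIs.

    A covariate named like the plaque-index column is auto-expanded into the
    ZERO / <10 / >=10 indicator coding. Constant covariates are dropped with
    a flag; separation and non-convergence are flagged, never silently
    returned.
    """
    y = cohort[outcome].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ClinicalError(f"outcome {outcome!r} must be binary with both classes present, "
                            f"found values {classes}")
    y = (y == classes.max()).astype(float)

    work = cohort
    cols: list[str] = []
    for c in covariates:
        if c == api_col:
            work = expand_api_categories(work, api_col)
            cols += ["api_lt10", "api_ge10"]
        else:
            cols.append(c)

    flags: list[str] = []
    X = work[cols].astype(float)
    keep = [c for c in cols if X[c].nunique() > 1]
    for c in cols:
        if c not in keep:
            flags.append(f"dropped constant covariate {c!r}")
    X = sm.add_constant(X[keep], has_constant="add")
    if len(work) <= X.shape[1]:
        raise ClinicalError("need more observations than parameters")

    converged = True
    res = None
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # perfect separation / singular Hessian
        flags.append(f"maximum likelihood failed ({exc.__class__.__name__}: {exc}); "
                     "likely separation — returning a diagnostic-only fit")
        converged = False
    if res is None:
        nan = np.full(X.shape[1], np.nan)
        table = pd.DataFrame(
            {"coef": nan, "or_": nan, "ci_low": nan, "ci_high": nan, "p": nan},
            index=X.columns,
        )
        return LogisticFit(table=table, pseudo_r2=float("nan"), converged=False,
                           n=len(work), flags=flags)
    params = res.params
    try:
        ci = res.conf_int(alpha=0.05)
        pvals = res.pvalues
    except Exception:
        ci = pd.DataFrame(np.full((len(params), 2), np.nan), index=params.index)
        pvals = pd.Series(np.full(len(params), np.nan), index=params.index)
        converged = False
    if np.any(np.abs(params.values) > 15):
        flags.append("possible separation: |coefficient| > 15 on the log-odds scale")
        converged = converged and False

    table = pd.DataFrame({
        "coef": params,
        "or_": np.exp(params),
        "ci_low": np.exp(ci[0]),
        "ci_high": np.exp(ci[1]),
        "p": pvals,
    })
    try:
        pseudo = float(res.prsquared)
    except Exception:
        llnull = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
        pseudo = float(1 - res.llf / llnull)
    return LogisticFit(table=table, pseudo_r2=pseudo, converged=converged,
                       n=len(work), flags=flags)


# ---------------------------------------------------------------------------
# empirical ROC


@dataclass(frozen=True)
class RocPoints:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def empirical_roc(scores, labels) -> RocPoints:
    """Empirical ROC points and trapezoidal AUC (higher score = disease-like).

    The AUC equals the Mann-Whitney U statistic of the case scores scaled by
    n1*n0 (ties counted half).
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size != 2:
        raise ClinicalError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocPoints(fpr=fpr, tpr=tpr, auc=auc)
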