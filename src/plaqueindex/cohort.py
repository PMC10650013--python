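"""Synthetic surgical cohorts with plaque-index-dependent CKD risk.

Emulates a partial-nephrectomy cohort in which chronic kidney disease (CKD)
at last follow-up depends log-linearly on the categorised abdominal aortic
plaque index (API), alongside comorbidity burden and baseline renal
function. One latent comorbidity factor ``u ~ N(0,1)`` per patient couples
age, Charlson index, hypertension/diabetes/coronary disease, baseline eGFR
and the plaque index, so the generated arms show the familiar pattern of an
older, more comorbid, more calcified CKD arm.

The outcome is drawn from a logistic model

    logit P(CKD) = b0 + b_cci * CCI + b_egfr * eGFR_pre
                   + b_lt10 * 1[0 < API < 10] + b_ge10 * 1[API >= 10]

whose default coefficients anchor to odds ratios of 1.27 (CCI, per point),
0.98 (baseline eGFR, per unit), 2.96 (API < 10 vs 0) and 25.2 (API >= 10 vs
0), with the intercept calibrated so the marginal CKD prevalence is ~0.268
(49/183). Follow-up eGFR applies one per-patient percentage change drawn
around an API-category mean, and the last-FU value is kept on the
label-consistent side of the CKD threshold so the generated labels agree
with ``classify_ckd`` applied to the trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .clinical import ClinicalError, fisher_exact, mann_whitney

__all__ = ["CohortSpec", "generate_cohort", "summarize_cohort", "write_cohort", "read_cohort"]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Outcome coefficients are on the log-odds scale. ``api_zero_weight`` is
    the marginal probability of a zero plaque index (no measurable plaque);
    positive values are log-normal. ``delta_mean_by_category`` gives the mean
    percentage eGFR change for API category ZERO / <10 / >=10.
    """

    n: int = 183
    seed: int = 0

    # covariate marginals
    age_mean: float = 65.0
    age_sd: float = 9.0
    cci_log_rate: float = 1.25  # Poisson log-rate at u = 0
    htn_intercept: float = -1.80
    htn_slope_u: float = 0.9
    htn_slope_api: float = 0.55
    dm_intercept: float = -4.15
    dm_slope_u: float = 0.8
    dm_slope_api: float = 0.55
    cad_prevalence_logit: float = -2.4
    pulm_prevalence_logit: float = -1.9
    male_fraction: float = 0.63
    pre_egfr_mean: float = 82.0
    pre_egfr_sd: float = 13.0

    # plaque-index mixture: point mass at zero + log-normal tail
    api_zero_weight: float = 0.35
    api_log_mu: float = 0.2
    api_log_sd: float = 1.3
    api_u_loading: float = 0.35  # latent-factor loading of log API (and zero odds)

    # outcome model (log-odds)
    outcome_intercept: float = -1.217  # calibrated: marginal prevalence ~= 49/183
    beta_cci: float = float(np.log(1.27))
    beta_egfr: float = float(np.log(0.98))
    beta_api_lt10: float = float(np.log(2.96))
    beta_api_ge10: float = float(np.log(25.2))

    # eGFR trajectory
    delta_mean_by_category: tuple[float, float, float] = (-2.5, -6.0, -18.0)
    delta_sd: float = 8.0
    ckd_threshold: float = 60.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ClinicalError("cohort size must be >= 1")
        bad = []
        if not 0.0 <= self.api_zero_weight <= 1.0:
            bad.append("api_zero_weight not in [0,1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            bad.append("male_fraction not in [0,1]")
        for name in ("age_sd", "pre_egfr_sd", "api_log_sd", "delta_sd"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        if self.ckd_threshold <= 0:
            bad.append("ckd_threshold must be > 0")
        if bad:
            raise ClinicalError("invalid cohort spec: " + "; ".join(bad))

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["delta_mean_by_category"] = list(self.delta_mean_by_category)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        d = yaml.safe_load(text)
        if "delta_mean_by_category" in d:
            d["delta_mean_by_category"] = tuple(d["delta_mean_by_category"])
        return cls(**d)


_HISTOLOGIES = ("cRCC", "pRCC", "chRCC", "oncocytoma", "other")
_HISTOLOGY_P = (0.50, 0.17, 0.06, 0.12, 0.15)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    u = rng.standard_normal(n)

    age = np.clip(spec.age_mean + 6.0 * u + rng.normal(0, 7.0, n), 40, 89)
    sex_male = rng.random(n) < spec.male_fraction
    bmi = np.clip(rng.normal(26.5, 3.5, n), 17, 45)
    cci = rng.poisson(np.exp(spec.cci_log_rate + 0.35 * u))
    asa_latent = 0.7 * u + rng.normal(0, 0.7, n)
    asa = 1 + (asa_latent > -1.2).astype(int) + (asa_latent > 1.0) + (asa_latent > 2.2)
    pre_egfr = np.clip(
        spec.pre_egfr_mean - 8.0 * u + rng.normal(0, spec.pre_egfr_sd * 0.85, n), 15, 130
    )

    # plaque index: zero-inflated log-normal, coupled to the latent factor
    p_zero = _expit(
        np.log(spec.api_zero_weight / (1 - spec.api_zero_weight)) - spec.api_u_loading * u
    ) if 0 < spec.api_zero_weight < 1 else np.full(n, spec.api_zero_weight)
    is_zero = rng.random(n) < p_zero
    api = np.where(
        is_zero,
        0.0,
        np.exp(rng.normal(spec.api_log_mu + spec.api_u_loading * u, spec.api_log_sd)),
    )
    api = np.minimum(api, 60.0)

    log1p_api = np.log1p(api)
    hypertension = rng.random(n) < _expit(
        spec.htn_intercept + spec.htn_slope_u * u + spec.htn_slope_api * log1p_api + 0.45 * cci
    )
    diabetes = rng.random(n) < _expit(
        spec.dm_intercept + spec.dm_slope_u * u + spec.dm_slope_api * log1p_api + 0.45 * cci
    )
    coronary = rng.random(n) < _expit(spec.cad_prevalence_logit + 0.6 * u + 0.3 * log1p_api)
    pulmonary = rng.random(n) < _expit(spec.pulm_prevalence_logit + 0.2 * u)

    # surgical / tumor covariates (noise covariates for the report layout)
    renal_score = 4 + rng.binomial(8, 0.38, n)
    ischemia_min = np.clip(np.round(np.exp(rng.normal(np.log(15.0), 0.4, n))), 5, 60)
    clavien = rng.choice(5, size=n, p=(0.55, 0.25, 0.12, 0.06, 0.02))
    ebl_ml = np.round(np.exp(rng.normal(np.log(120.0), 0.9, n)))
    tumor_side_left = rng.random(n) < 0.5
    tumor_dim_cm = np.round(np.exp(rng.normal(np.log(3.0), 0.45, n)), 1)
    histology = rng.choice(_HISTOLOGIES, size=n, p=_HISTOLOGY_P)

    # outcome
    api_lt10 = (api > 0) & (api < 10)
    api_ge10 = api >= 10
    eta = (
        spec.outcome_intercept
        + spec.beta_cci * cci
        + spec.beta_egfr * pre_egfr
        + spec.beta_api_lt10 * api_lt10
        + spec.beta_api_ge10 * api_ge10
    )
    ckd = rng.random(n) < _expit(eta)

    # eGFR trajectory: one per-patient percentage change around the API-category mean
    means = np.select(
        [api == 0, api_lt10, api_ge10],
        list(spec.delta_mean_by_category),
    )
    delta = means + rng.normal(0, spec.delta_sd, n)
    t_noise = rng.normal(0, 3.0, (4, n))
    egfr_t = {
        name: np.clip(pre_egfr * (1 + (delta + t_noise[i]) / 100.0), 5, None)
        for i, name in enumerate(("egfr_discharge", "egfr_6m", "egfr_12m", "egfr_24m"))
    }

    last_raw = pre_egfr * (1 + delta / 100.0)
    thr = spec.ckd_threshold
    below = thr * (1 - 0.03 - 0.35 * np.abs(rng.standard_normal(n)))
    above = thr * (1 + 0.03 + 0.25 * np.abs(rng.standard_normal(n)))
    egfr_last = np.where(
        ckd,
        np.where(last_raw < thr * 0.97, last_raw, below),
        np.where(last_raw >= thr * 1.03, last_raw, above),
    )
    egfr_last = np.clip(egfr_last, 5, None)
    # store delta consistent with the *stored* (rounded) eGFR columns
    pre_r = np.round(pre_egfr, 1)
    last_r = np.round(egfr_last, 1)
    delta_last = (last_r - pre_r) / pre_r * 100.0

    return pd.DataFrame({
        "id": np.arange(n),
        "age": np.round(age, 1),
        "sex_male": sex_male.astype(int),
        "bmi": np.round(bmi, 1),
        "cci": cci,
        "asa": asa,
        "hypertension": hypertension.astype(int),
        "diabetes": diabetes.astype(int),
        "coronary_disease": coronary.astype(int),
        "pulmonary_disease": pulmonary.astype(int),
        "pre_egfr": pre_r,
        "api": np.round(api, 3),
        "renal_score": renal_score,
        "ischemia_min": ischemia_min.astype(int),
        "clavien": clavien,
        "ebl_ml": ebl_ml,
        "tumor_side_left": tumor_side_left.astype(int),
        "tumor_dim_cm": tumor_dim_cm,
        "histology": histology,
        "egfr_discharge": np.round(egfr_t["egfr_discharge"], 1),
        "egfr_6m": np.round(egfr_t["egfr_6m"], 1),
        "egfr_12m": np.round(egfr_t["egfr_12m"], 1),
        "egfr_24m": np.round(egfr_t["egfr_24m"], 1),
        "egfr_last": last_r,
        "delta_pct_egfr_last": np.round(delta_last, 2),
        "ckd_label": ckd.astype(int),
    })


_DEFAULT_CONTINUOUS = [
    "age", "bmi", "cci", "asa", "pre_egfr", "api", "renal_score", "ischemia_min",
    "ebl_ml", "tumor_dim_cm", "egfr_discharge", "egfr_6m", "egfr_12m", "egfr_24m",
    "egfr_last", "delta_pct_egfr_last",
]
_DEFAULT_BINARY = [
    "sex_male", "hypertension", "diabetes", "coronary_disease", "pulmonary_disease",
    "tumor_side_left",
]


def summarize_cohort(
    cohort: pd.DataFrame,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    arm_col: str = "ckd_label",
) -> pd.DataFrame:
    """Per-arm median (IQR) / count (%) summary with two-group p-values.

    Continuous variables get median (IQR) and a Mann-Whitney p; binary
    variables get count (%) and a Fisher's-exact p. Requires both arms to be
    present.
    """
    if cohort.empty:
        raise ClinicalError("cohort is empty")
    arms = sorted(cohort[arm_col].unique())
    if len(arms) != 2:
        raise ClinicalError(f"need exactly two arms in {arm_col!r}, found {arms}")
    continuous = [c for c in (continuous if continuous is not None else _DEFAULT_CONTINUOUS)
                  if c in cohort.columns]
    binary = [c for c in (binary if binary is not None else _DEFAULT_BINARY)
              if c in cohort.columns]
    g0 = cohort[cohort[arm_col] == arms[0]]
    g1 = cohort[cohort[arm_col] == arms[1]]

    rows = []
    for c in continuous:
        x0, x1 = g0[c].to_numpy(float), g1[c].to_numpy(float)
        med0, q0a, q0b = np.median(x0), *np.percentile(x0, [25, 75])
        med1, q1a, q1b = np.median(x1), *np.percentile(x1, [25, 75])
        p = mann_whitney(x0, x1).p_value
        rows.append({
            "variable": c, "type": "continuous",
            f"arm_{arms[0]}": f"{med0:.2f} ({q0a:.2f}-{q0b:.2f})",
            f"arm_{arms[1]}": f"{med1:.2f} ({q1a:.2f}-{q1b:.2f})",
            f"median_{arms[0]}": med0, f"median_{arms[1]}": med1,
            "p_value": p,
        })
    for c in binary:
        k0, n0 = int(g0[c].sum()), len(g0)
        k1, n1 = int(g1[c].sum()), len(g1)
        table = [[k1, n1 - k1], [k0, n0 - k0]]
        try:
            p = fisher_exact(table).p_value
        except ClinicalError:
            p = np.nan
        rows.append({
            "variable": c, "type": "binary",
            f"arm_{arms[0]}": f"{k0} ({100 * k0 / n0:.1f}%)",
            f"arm_{arms[1]}": f"{k1} ({100 * k1 / n1:.1f}%)",
            f"median_{arms[0]}": k0 / n0, f"median_{arms[1]}": k1 / n1,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"api", "pre_egfr", "egfr_last", "ckd_label"}
    missing = required - set(df.columns)
    if missing:
        raise ClinicalError(f"cohort CSV missing required columns: {sorted(missing)}")
    return df
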