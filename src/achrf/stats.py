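"""Agreement and grade-association statistics for HRF count tables.

Two families of analyses are covered:

* method agreement — intraclass correlation from a two-way mixed-effects
  model (measurement method fixed, optionally SUN grade fixed, subject
  random intercept) plus the Pearson coefficient on the pairs; and
* grade association — mixed-effects linear regressions of the automated
  count (raw and log-transformed) on the clinical SUN grade with age, sex
  and laterality as fixed covariates and a per-patient random intercept,
  plus a grade-0-vs-control comparison and per-grade descriptive tables.

For the always-balanced paired agreement design the variance components
have a closed form: the method effect and residual variance come from the
within-subject differences, the subject variance from the residual of the
subject means about the fixed covariates.  SUN grades (0, 0.5+, 1+ ... 4+)
enter regressions as consecutive integer steps 0..5, so a "1-step
increase" is one position on the ordinal ladder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import EstimationError, InputError, ParameterError

__all__ = [
    "SUN_GRADES",
    "grade_to_step",
    "EyeRecord",
    "AgreementResult",
    "GradeModelResult",
    "pearson",
    "icc_agreement",
    "grade_model",
    "compare_groups",
    "summarize_by_grade",
    "records_to_frame",
]

SUN_GRADES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)


def grade_to_step(grade: float) -> int:
    """Recode a SUN grade to its position on the ordinal ladder (0..5)."""
    try:
        return SUN_GRADES.index(float(grade))
    except ValueError:
        raise ParameterError(f"{grade!r} is not a SUN grade {SUN_GRADES}") from None


@dataclass
class EyeRecord:
    """One eye's metadata and counts for the statistical analyses."""

    patient_id: str
    eye: str                     # OD | OS
    group: str                   # uveitis | control
    sun_grade: float             # one of SUN_GRADES
    auto_count: int
    manual_count: int | None = None
    age_years: float = 0.0
    sex: str = "F"               # F | M

    def __post_init__(self):
        if self.eye not in ("OD", "OS"):
            raise ParameterError("eye must be OD or OS")
        if self.group not in ("uveitis", "control"):
            raise ParameterError("group must be uveitis or control")
        if self.sex not in ("F", "M"):
            raise ParameterError("sex must be F or M")
        grade_to_step(self.sun_grade)  # validates
        if self.auto_count < 0:
            raise ParameterError("auto_count must be non-negative")


@dataclass
class AgreementResult:
    icc: float
    pearson_r: float
    n_pairs: int
    method: str


@dataclass
class GradeModelResult:
    slope_per_grade: float
    log_slope: float
    pct_change_per_grade: float
    p_values: dict[str, float]
    variance_components: tuple[float, float]  # (between_patient, residual)


def records_to_frame(records: list[EyeRecord]) -> pd.DataFrame:
    """Records as a model-ready DataFrame with recoded covariates."""
    if not records:
        raise InputError("no records")
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "eye_os": [1.0 if r.eye == "OS" else 0.0 for r in records],
        "group_uveitis": [1.0 if r.group == "uveitis" else 0.0 for r in records],
        "sun_grade": [r.sun_grade for r in records],
        "grade_step": [float(grade_to_step(r.sun_grade)) for r in records],
        "auto_count": [float(r.auto_count) for r in records],
        "log_count": [math.log(r.auto_count + 1.0) for r in records],
        "manual_count": [np.nan if r.manual_count is None else float(r.manual_count)
                         for r in records],
        "age_years": [r.age_years for r in records],
        "sex_m": [1.0 if r.sex == "M" else 0.0 for r in records],
    })


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ParameterError("need at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc ** 2).sum()))
    sy = float(np.sqrt((yc ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise EstimationError("correlation undefined for a zero-variance vector")
    return float((xc * yc).sum() / (sx * sy))


def icc_agreement(x, y, covariate_grade=None) -> AgreementResult:
    """Intraclass correlation between two paired measurement methods.

    Fits (in closed form — the paired design is always balanced) the
    two-way mixed model ``value = mu + method + [grade] + subject + error``
    with the method (and optional SUN grade) fixed and a per-subject random
    intercept, and returns

        ICC = sigma^2_subject / (sigma^2_subject + sigma^2_error)

    together with the Pearson coefficient on the pairs.  With the balanced
    design the within-subject differences carry ``method`` and the residual
    variance, while the subject means carry the grade effect and the
    subject variance, so REML reduces to two independent least-squares
    problems.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 subjects")
    d = y - x
    s = (x + y) / 2.0
    sigma_e2 = float(np.var(d, ddof=1)) / 2.0
    if covariate_grade is None:
        design = np.ones((n, 1))
        method = "two-way mixed, method fixed, subject random (closed form)"
    else:
        steps = np.asarray([grade_to_step(g) for g in np.asarray(covariate_grade)],
                           dtype=float)
        if steps.shape != x.shape:
            raise ParameterError("grade covariate must match x and y in length")
        design = np.column_stack([np.ones(n), steps])
        method = "two-way mixed, method+grade fixed, subject random (closed form)"
    coef, _, rank, _ = np.linalg.lstsq(design, s, rcond=None)
    resid = s - design @ coef
    df = n - rank
    if df <= 0:
        raise EstimationError("not enough subjects for the fixed effects")
    ms_s = float((resid ** 2).sum()) / df
    sigma_b2 = max(0.0, ms_s - sigma_e2 / 2.0)
    total = sigma_b2 + sigma_e2
    icc = 1.0 if total == 0.0 else sigma_b2 / total
    try:
        r = pearson(x, y)
    except EstimationError:
        r = float("nan")
    return AgreementResult(icc=float(icc), pearson_r=r, n_pairs=n, method=method)


def _fit_mixed(df: pd.DataFrame, response: str, fixed: list[str]):
    """MixedLM with per-patient random intercept; OLS fallback for
    degenerate designs (one observation per patient or a perfect fit)."""
    formula = f"{response} ~ " + " + ".join(fixed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["patient_id"])
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
            if np.all(np.isfinite(np.asarray(fit.params, dtype=float))):
                # cov_re is already on the response scale
                group_var = float(fit.cov_re.iloc[0, 0])
                return fit.params, fit.pvalues, (group_var, float(fit.scale))
        except (np.linalg.LinAlgError, ValueError):
            pass
        ols = smf.ols(formula, df).fit()
        return ols.params, ols.pvalues, (0.0, float(ols.mse_resid))


_COVARIATES = ["age_years", "sex_m", "eye_os"]


def grade_model(records: list[EyeRecord], response: str = "raw") -> GradeModelResult:
    """Mixed-effects regression of automated counts on the SUN grade step.

    Fits both the raw-count and the log-transformed (``ln(count + 1)``)
    models with age, sex and laterality as fixed covariates and a
    per-patient random intercept.  ``response`` selects which model's
    p-values and variance components are reported;
    ``pct_change_per_grade = 100 (e^{log slope} - 1)`` always comes from
    the log model and ``slope_per_grade`` from the raw model.
    """
    if response not in ("raw", "log1p"):
        raise ParameterError("response must be 'raw' or 'log1p'")
    df = records_to_frame(records)
    if df["grade_step"].nunique() < 2:
        raise EstimationError("singular design: need at least 2 distinct grades")
    if df["patient_id"].nunique() < 3:
        raise EstimationError("need at least 3 patients")
    fixed = ["grade_step"] + [c for c in _COVARIATES if df[c].nunique() > 1]
    raw_params, raw_p, raw_vc = _fit_mixed(df, "auto_count", fixed)
    log_params, log_p, log_vc = _fit_mixed(df, "log_count", fixed)
    log_slope = float(log_params["grade_step"])
    chosen_p, chosen_vc = (raw_p, raw_vc) if response == "raw" else (log_p, log_vc)
    return GradeModelResult(
        slope_per_grade=float(raw_params["grade_step"]),
        log_slope=log_slope,
        pct_change_per_grade=100.0 * (math.exp(log_slope) - 1.0),
        p_values={k: float(v) for k, v in chosen_p.items()},
        variance_components=chosen_vc,
    )


def compare_groups(records: list[EyeRecord]) -> tuple[float, float]:
    """Clinically quiet uveitic eyes (grade 0) versus healthy controls.

    Fits ``count ~ group + age + sex + laterality`` with a per-patient
    random intercept and returns the group (uveitis) effect and its
    p-value.  Uveitis records must all carry SUN grade 0.
    """
    if not records:
        raise InputError("no records")
    df = records_to_frame(records)
    if (df["group_uveitis"] == 1).sum() == 0 or (df["group_uveitis"] == 0).sum() == 0:
        raise InputError("both uveitis and control groups must be present")
    if not np.all(df.loc[df["group_uveitis"] == 1, "sun_grade"] == 0):
        raise ParameterError("uveitis records must be restricted to SUN grade 0")
    fixed = ["group_uveitis"] + [c for c in _COVARIATES if df[c].nunique() > 1]
    params, pvals, _ = _fit_mixed(df, "auto_count", fixed)
    return float(params["group_uveitis"]), float(pvals["group_uveitis"])


def summarize_by_grade(records: list[EyeRecord]) -> pd.DataFrame:
    """Per-grade descriptive table: n, median, IQR (Q1, Q3) and range.

    Quantiles use linear interpolation (type 7), the common default.
    """
    df = records_to_frame(records)
    rows = []
    for grade, sub in df.groupby("sun_grade"):
        counts = sub["auto_count"].to_numpy()
        rows.append({
            "sun_grade": grade,
            "n": int(counts.size),
            "median": float(np.median(counts)),
            "q1": float(np.quantile(counts, 0.25)),
            "q3": float(np.quantile(counts, 0.75)),
            "min": float(counts.min()),
            "max": float(counts.max()),
        })
    return pd.DataFrame(rows).sort_values("sun_grade").reset_index(drop=True)
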