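"""Log10-linear regression of sNfL on age and sex, and the exponentiated
upper-limit (97.5th percentile) cut-off formula.

Serum NfL is approximately log-normal at a given age, so an OLS fit of
log10(sNfL) on age and a female indicator,

    log10(sNfL) = b0 + b_age * age + b_female * female + e,   e ~ N(0, s^2)

yields a closed-form predicted upper percentile: adding ``z * s`` (z = 1.96
for the 97.5th) to the linear predictor and exponentiating gives

    sNfL_97.5(age, sex) = 10**(b0 + z*s) * (10**b_age)**age * (10**b_female)**female

i.e. a multiplicative scale constant, a per-year age factor, and a female
factor. A published healthy-adult fit of this form is frozen in
:data:`ADULT_REFERENCE_FIT` so the formula machinery is usable without
any raw cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort

__all__ = [
    "LogLinearFit",
    "UpperLimitFormula",
    "fit_loglinear",
    "exponentiate_upper_limit",
    "predict_upper_limit",
    "ADULT_REFERENCE_FIT",
]


@dataclass(frozen=True)
class LogLinearFit:
    """OLS fit of log10(sNfL) on age and a female indicator (female = 1).

    ``residual_se`` is the residual standard deviation with n - 3 degrees
    of freedom; p-values are from the t distribution.
    """

    intercept: float  # log10(pg/ml)
    beta_age: float  # log10 units per year
    beta_female: float  # log10 units
    residual_se: float  # log10 units
    n: int
    p_age: float = float("nan")
    p_female: float = float("nan")

    def __post_init__(self) -> None:
        if not self.residual_se >= 0:
            raise ValueError("residual_se must be >= 0")
        if self.n <= 3:
            raise ValueError("need n > 3 for a three-parameter fit")

    def linear_predictor(self, age, female):
        return self.intercept + self.beta_age * np.asarray(age) + self.beta_female * np.asarray(female)


@dataclass(frozen=True)
class UpperLimitFormula:
    """Multiplicative form of the predicted upper percentile.

    ``predict = scale * age_factor**age * female_factor**[female]``.
    """

    scale: float  # pg/ml at age 0, male
    age_factor: float  # per-year multiplicative factor
    female_factor: float  # multiplicative factor for females
    z_mult: float  # standard-normal quantile baked into scale

    def __post_init__(self) -> None:
        if min(self.scale, self.age_factor, self.female_factor) <= 0:
            raise ValueError("all factors must be > 0")


#: Frozen coefficients of a published log10-linear model of serum NfL on
#: age and sex in 223 healthy adults (ages 18-70): intercept 0.326,
#: age slope 0.012/yr, female coefficient -0.059, residual SE 0.166.
ADULT_REFERENCE_FIT = LogLinearFit(
    intercept=0.326,
    beta_age=0.012,
    beta_female=-0.059,
    residual_se=0.166,
    n=223,
    p_age=0.001,
    p_female=0.008,
)


def fit_loglinear(cohort: Cohort) -> LogLinearFit:
    """OLS of log10(sNfL) on age and a female indicator.

    Raises if the design is rank-deficient (single sex or a single distinct
    age) or if any concentration is non-positive.
    """
    df = cohort.data
    if (df["snfl_pg_ml"] <= 0).any():
        raise ValueError("log10 transform requires strictly positive sNfL")
    female = (df["sex"] == "F").astype(float).to_numpy()
    age = df["age_years"].to_numpy(dtype=float)
    if np.unique(female).size < 2:
        raise ValueError("rank-deficient design: female indicator is constant (single-sex cohort)")
    if np.unique(age).size < 2:
        raise ValueError("rank-deficient design: need at least two distinct ages")
    X = sm.add_constant(np.column_stack([age, female]))
    res = sm.OLS(np.log10(df["snfl_pg_ml"].to_numpy()), X).fit()
    return LogLinearFit(
        intercept=float(res.params[0]),
        beta_age=float(res.params[1]),
        beta_female=float(res.params[2]),
        residual_se=float(np.sqrt(res.mse_resid)),
        n=int(res.nobs),
        p_age=float(res.pvalues[1]),
        p_female=float(res.pvalues[2]),
    )


def exponentiate_upper_limit(fit: LogLinearFit, z_mult: float = 1.96) -> UpperLimitFormula:
    """Closed-form upper-percentile formula from a log10-linear fit.

    ``scale = 10**(intercept + z_mult * residual_se)``;
    ``age_factor = 10**beta_age``; ``female_factor = 10**beta_female``.
    ``z_mult = 1.96`` gives the two-sided-95% upper bound (97.5th
    percentile); ``z_mult = 0`` gives the median line.
    """
    return UpperLimitFormula(
        scale=10.0 ** (fit.intercept + z_mult * fit.residual_se),
        age_factor=10.0**fit.beta_age,
        female_factor=10.0**fit.beta_female,
        z_mult=z_mult,
    )


def predict_upper_limit(formula: UpperLimitFormula, age, sex: str):
    """Predicted upper limit in pg/ml at (age, sex); vectorized over age."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    female = 1.0 if sex == "F" else 0.0
    out = formula.scale * formula.age_factor**age * formula.female_factor**female
    return out if out.ndim else float(out)
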