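"""Two-step hierarchical moderation regression with robust standard errors.

Step 1 regresses the outcome on the group indicator and the centered
moderator; Step 2 adds their product.  Point estimates are ordinary
least squares; inference uses heteroscedasticity-consistent standard
errors (HC3 by default, switchable HC0-HC3).  The increment of the
interaction is tested with the R-squared-change F statistic on
(1, n - 4) degrees of freedom, and the group effect is probed at one
standard deviation below/above the moderator mean (simple slopes),
with standard errors taken from the robust coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from emobias.errors import DegenerateDataError, SingularDesignError

PREDICTORS_STEP1 = ("const", "sa", "na_c")
PREDICTORS_STEP2 = ("const", "sa", "na_c", "sa_x_na_c")
COV_TYPES = ("HC0", "HC1", "HC2", "HC3", "nonrobust")


@dataclass(frozen=True)
class StepFit:
    """One regression step: coefficients, robust inference, fit quality."""

    predictors: tuple[str, ...]
    coef: dict
    robust_se: dict
    beta: dict              # standardized coefficients (sd-ratio scaled)
    beta_z: dict            # alternative: coefficient of the z-scored fit
    t: dict
    p: dict
    r2: float
    df_resid: float
    cov: np.ndarray = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {"predictors": list(self.predictors), "coef": self.coef,
                "robust_se": self.robust_se, "beta": self.beta,
                "beta_z": self.beta_z, "t": self.t, "p": self.p,
                "r2": self.r2, "df_resid": self.df_resid}


@dataclass(frozen=True)
class ModerationResult:
    step1: StepFit
    step2: StepFit
    delta_r2: float
    f_change: float
    df_change: tuple[int, int]
    p_change: float
    n_used: int
    na_mean: float          # centering constant (complete-case mean)
    na_sd: float            # moderator SD used for simple slopes
    cov_type: str

    def to_dict(self) -> dict:
        return {"step1": self.step1.to_dict(), "step2": self.step2.to_dict(),
                "delta_r2": self.delta_r2, "f_change": self.f_change,
                "df_change": list(self.df_change), "p_change": self.p_change,
                "n_used": self.n_used, "na_mean": self.na_mean,
                "na_sd": self.na_sd, "cov_type": self.cov_type}


@dataclass(frozen=True)
class SimpleSlope:
    """Group effect evaluated at one moderator level."""

    level: str              # "mean-1sd" or "mean+1sd"
    na_c_value: float       # centered moderator value probed
    estimate: float
    se: float
    t: float
    p: float
    df: float

    def to_dict(self) -> dict:
        return {"level": self.level, "na_c_value": self.na_c_value,
                "estimate": self.estimate, "se": self.se, "t": self.t,
                "p": self.p, "df": self.df}


def _fit_step(y: np.ndarray, X: pd.DataFrame, cov_type: str) -> StepFit:
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank deficient (is the group indicator constant?)")
    model = sm.OLS(y, X)
    fit = (model.fit() if cov_type == "nonrobust"
           else model.fit(cov_type=cov_type))
    sd_y = float(np.std(y, ddof=1))
    names = list(X.columns)
    beta, beta_z = {}, {}
    for name in names:
        if name == "const":
            beta[name] = 0.0
            beta_z[name] = 0.0
        else:
            sd_x = float(np.std(X[name].to_numpy(), ddof=1))
            beta[name] = float(fit.params[name]) * sd_x / sd_y
            beta_z[name] = beta[name]
    # Alternative standardization for the interaction: scale by the product
    # of the component SDs instead of the SD of the realized product column.
    if "sa_x_na_c" in names:
        sd_sa = float(np.std(X["sa"].to_numpy(), ddof=1))
        sd_na = float(np.std(X["na_c"].to_numpy(), ddof=1))
        beta_z["sa_x_na_c"] = float(fit.params["sa_x_na_c"]) * sd_sa * sd_na / sd_y
    return StepFit(
        predictors=tuple(names),
        coef={n: float(fit.params[n]) for n in names},
        robust_se={n: float(fit.bse[n]) for n in names},
        beta=beta, beta_z=beta_z,
        t={n: float(fit.tvalues[n]) for n in names},
        p={n: float(fit.pvalues[n]) for n in names},
        r2=float(fit.rsquared), df_resid=float(fit.df_resid),
        cov=np.asarray(fit.cov_params()))


def fit_hierarchical(y, sa, na, cov_type: str = "HC3") -> ModerationResult:
    """Two-step moderation regression of ``y`` on group and moderator.

    ``sa`` is the 0/1 group indicator (0 = reference group); ``na`` the
    moderator on its analysis scale (e.g. square-root transformed).
    Rows with a missing value in any variable are dropped (listwise
    deletion); the moderator is centered at the complete-case mean
    before the product term is formed.
    """
    if cov_type not in COV_TYPES:
        raise ValueError(f"cov_type must be one of {COV_TYPES}")
    frame = pd.DataFrame({"y": np.asarray(y, dtype=float),
                          "sa": np.asarray(sa, dtype=float),
                          "na": np.asarray(na, dtype=float)}).dropna()
    n = len(frame)
    if n < 8:
        raise DegenerateDataError(f"need >= 8 complete cases, got {n}")
    if set(frame["sa"].unique()) - {0.0, 1.0}:
        raise ValueError("sa must be coded 0/1")
    if frame["sa"].nunique() < 2:
        raise SingularDesignError("sa indicator is constant")

    na_mean = float(frame["na"].mean())
    na_sd = float(frame["na"].std(ddof=1))
    frame["na_c"] = frame["na"] - na_mean
    frame["sa_x_na_c"] = frame["sa"] * frame["na_c"]
    frame["const"] = 1.0

    yv = frame["y"].to_numpy()
    step1 = _fit_step(yv, frame[list(PREDICTORS_STEP1)], cov_type)
    step2 = _fit_step(yv, frame[list(PREDICTORS_STEP2)], cov_type)

    delta_r2 = step2.r2 - step1.r2
    df2 = n - 4
    if step2.r2 >= 1.0:
        f_change = float("inf") if delta_r2 > 0 else 0.0
        p_change = 0.0 if delta_r2 > 0 else 1.0
    else:
        f_change = delta_r2 * df2 / (1.0 - step2.r2)
        p_change = float(stats.f.sf(f_change, 1, df2))
    return ModerationResult(step1=step1, step2=step2,
                            delta_r2=float(delta_r2), f_change=float(f_change),
                            df_change=(1, df2), p_change=p_change,
                            n_used=n, na_mean=na_mean, na_sd=na_sd,
                            cov_type=cov_type)


def simple_slopes(result: ModerationResult) -> list[SimpleSlope]:
    """Group effect at the moderator mean -/+ 1 SD.

    slope(m) = b_sa + b_int * m with m = -/+ SD(na); the SE combines the
    robust variances and covariance of (b_sa, b_int); t on n - 4 df.
    """
    step = result.step2
    names = list(step.predictors)
    i_sa = names.index("sa")
    i_int = names.index("sa_x_na_c")
    b_sa = step.coef["sa"]
    b_int = step.coef["sa_x_na_c"]
    cov = step.cov
    df = result.n_used - 4
    out = []
    for label, m in (("mean-1sd", -result.na_sd), ("mean+1sd", result.na_sd)):
        est = b_sa + b_int * m
        var = cov[i_sa, i_sa] + m * m * cov[i_int, i_int] + 2 * m * cov[i_sa, i_int]
        se = float(np.sqrt(var))
        t = est / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
        out.append(SimpleSlope(level=label, na_c_value=float(m),
                               estimate=float(est), se=se, t=float(t), p=p,
                               df=float(df)))
    return out


def predict_surface(result: ModerationResult) -> dict:
    """Model-implied outcome at the four (group x moderator -/+1 SD) cells."""
    step = result.step2
    cells = {}
    for sa in (0.0, 1.0):
        for label, m in (("mean-1sd", -result.na_sd), ("mean+1sd", result.na_sd)):
            value = (step.coef["const"] + step.coef["sa"] * sa
                     + step.coef["na_c"] * m + step.coef["sa_x_na_c"] * sa * m)
            cells[(("HSA" if sa else "LSA"), label)] = float(value)
    return cells
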