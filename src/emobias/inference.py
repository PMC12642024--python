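"""Univariate group statistics: distribution screens, transforms,
variance tests, two-sample t-tests and effect sizes."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from emobias.errors import DegenerateDataError


@dataclass(frozen=True)
class SummaryStats:
    """n / mean / sd (n-1 denominator) summary of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateDataError(f"need n >= 2, got {self.n}")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise DegenerateDataError(f"invalid sd: {self.sd}")

    @classmethod
    def from_values(cls, values) -> "SummaryStats":
        x = np.asarray(values, dtype=float)
        return cls(n=int(x.size), mean=float(x.mean()),
                   sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class SkewKurtosis:
    skew: float
    kurtosis: float     # excess kurtosis
    passed: bool


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str                    # "student" or "welch"
    cohens_d: float                 # pooled-SD standardized difference
    levene_w: float | None = None   # present when the variance gate ran
    levene_p: float | None = None

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "variant": self.variant, "cohens_d": self.cohens_d,
                "levene_w": self.levene_w, "levene_p": self.levene_p}


def skew_kurtosis_check(values, skew_limit: float = 1.0,
                        kurtosis_limit: float = 2.0) -> SkewKurtosis:
    """Sample-size-adjusted skewness and excess kurtosis with a pass flag.

    Uses the bias-corrected estimators (the values SPSS prints); passes
    iff |skew| <= skew_limit and |kurtosis| <= kurtosis_limit.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("need at least 3 values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant vector has no shape statistics")
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    passed = abs(skew) <= skew_limit and abs(kurt) <= kurtosis_limit
    return SkewKurtosis(skew=skew, kurtosis=kurt, passed=passed)


def sqrt_transform(values) -> np.ndarray:
    """Element-wise square root (used to de-skew non-negative scores)."""
    x = np.asarray(values, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValueError("square-root transform requires non-negative input")
    return np.sqrt(x)


def levene_test(a, b) -> tuple[float, float]:
    """Levene's equality-of-variances test, mean-centered deviations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs n >= 2")
    dev = np.concatenate([np.abs(a - a.mean()), np.abs(b - b.mean())])
    if np.ptp(dev) == 0:
        raise DegenerateDataError(
            "absolute deviations are constant; Levene W undefined")
    w, p = stats.levene(a, b, center="mean")
    return float(w), float(p)


def cohens_d_from_summary(g1: SummaryStats, g2: SummaryStats) -> float:
    """Pooled-SD Cohen's d, (mean1 - mean2) / s_pooled, (n-1) weights."""
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    if sp2 == 0:
        if g1.mean == g2.mean:
            return 0.0
        raise DegenerateDataError("zero pooled variance with unequal means")
    return (g1.mean - g2.mean) / math.sqrt(sp2)


def t_from_summary(g1: SummaryStats, g2: SummaryStats,
                   variant: str = "student") -> TTestResult:
    """Two-sample t-test from group summaries.

    ``student`` pools variances with (n1-1, n2-1) weights on
    n1 + n2 - 2 df; ``welch`` uses separate variances with Satterthwaite
    df.  Cohen's d is always the pooled-SD standardized difference, with
    the same sign convention as t (group 1 minus group 2).
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    diff = g1.mean - g2.mean
    v1, v2 = g1.sd**2, g2.sd**2
    if v1 == 0 and v2 == 0:
        raise DegenerateDataError("both groups have zero variance")
    if variant == "student":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se = math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    else:
        se = math.sqrt(v1 / g1.n + v2 / g2.n)
        df = (v1 / g1.n + v2 / g2.n) ** 2 / (
            (v1 / g1.n) ** 2 / (g1.n - 1) + (v2 / g2.n) ** 2 / (g2.n - 1))
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, variant=variant,
                       cohens_d=cohens_d_from_summary(g1, g2))


def compare_groups(a, b, alpha: float = 0.05) -> TTestResult:
    """Two-sample comparison with a Levene variance gate.

    Runs Levene's test first; if its p < alpha the Welch variant is
    used ("equal variance not assumed"), otherwise Student's.  The
    chosen path and the gate statistics are recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w, lp = levene_test(a, b)
    variant = "welch" if lp < alpha else "student"
    base = t_from_summary(SummaryStats.from_values(a),
                          SummaryStats.from_values(b), variant=variant)
    return TTestResult(t=base.t, df=base.df, p=base.p, variant=variant,
                       cohens_d=base.cohens_d, levene_w=w, levene_p=lp)
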