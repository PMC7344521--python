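"""Method-agreement and validity statistics, implemented from first principles.

Covers the statistical toolkit of a concurrent/discriminant/construct
validity study: ICC(2,1) (two-way random effects, absolute agreement, single
measurement) with its F-based 95% confidence interval, Bland-Altman bias and
limits of agreement, RMSE over paired measurements, the standard error of
measurement SEM = sd_pooled*sqrt(1-ICC), the minimal detectable change
MDC = 1.96*SEM*sqrt(2), Pearson correlation, unpaired t-tests (pooled and
Welch, from raw data or printed summary statistics), simple linear
regression with adjusted R², Fisher-z power/sample-size for detecting a
correlation, and qualitative strength labels.

Only the distribution functions (t, F, normal) come from scipy; every
statistic itself is computed explicitly so each formula is auditable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy import stats as _dist

from .errors import (
    InfeasibleQueryError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "GroupSummary",
    "TTestResult",
    "RegressionFit",
    "AgreementReport",
    "icc_2_1",
    "bland_altman",
    "rmse_pairs",
    "sem_from_icc",
    "mdc_from_sem",
    "pearson_r",
    "pearson_test",
    "ttest_unpaired",
    "linreg_adjusted_r2",
    "n_for_pearson",
    "classify_strength",
    "agreement_report",
    "format_p",
]


def _paired_arrays(m1, m2, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise InvalidInputError("paired measurements must be equal-length 1-D arrays")
    if a.size < min_n:
        raise InvalidInputError(f"at least {min_n} pairs required, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("paired measurements contain missing/non-finite values")
    return a, b


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: n, mean, sample SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError("group summary requires n >= 2")
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise InvalidInputError("group requires at least 2 values")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("group values contain non-finite entries")
        return cls(int(v.size), float(v.mean()), float(v.std(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    """Unpaired two-sample t-test outcome."""

    t: float
    df: float
    p: float
    variant: str


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares y ~ x with adjusted determination coefficient."""

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    n: int


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement panel for one measure across subjects."""

    measure: str
    units: str
    n: int
    icc: float
    icc_ci_95: tuple[float, float]
    r: float
    rmse: float
    bias: float
    loa_lower: float
    loa_upper: float
    sem: float
    mdc: float


# --------------------------------------------------------------------------- #
# intraclass correlation
# --------------------------------------------------------------------------- #

def _mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = methods)."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_err)


def icc_2_1(m1, m2, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Returns the point estimate and its F-based ``1 - alpha`` confidence
    interval (the standard interval for this ICC form).  The estimate is

        (MS_rows - MS_err) / (MS_rows + (k-1) MS_err + k (MS_cols - MS_err)/n)

    with k = 2 methods and n subjects.
    """
    a, b = _paired_arrays(m1, m2, min_n=3)
    y = np.column_stack([a, b])
    n, k = y.shape
    if np.allclose(y, y.flat[0]):
        raise UndefinedStatisticError("ICC undefined: all values identical")
    ms_rows, ms_cols, ms_err = _mean_squares(y)
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    icc = (ms_rows - ms_err) / denom

    if ms_err == 0.0 and ms_cols <= ms_err:
        return float(icc), (1.0, 1.0)  # perfect agreement

    # F-based CI for the absolute-agreement single-measure form
    r = min(icc, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_coef = (k * r) / (n * (1.0 - r))
        b_coef = 1.0 + (k * r * (n - 1)) / (n * (1.0 - r))
        num = (a_coef * ms_cols + b_coef * ms_err) ** 2
        den = (a_coef * ms_cols) ** 2 / (k - 1) + (b_coef * ms_err) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else float("nan")
    if not np.isfinite(v) or v <= 0:
        v = (n - 1) * (k - 1)
    f_l = _dist.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = _dist.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    d = k * ms_cols + (k * n - k - n) * ms_err
    if np.isfinite(f_l):
        lower = n * (ms_rows - f_l * ms_err) / (f_l * d + n * ms_rows)
    else:  # F -> infinity limit (tiny denominator df at extreme estimates)
        lower = -n * ms_err / d if d > 0 else -1.0
    if np.isfinite(f_u):
        upper = n * (f_u * ms_rows - ms_err) / (d + n * f_u * ms_rows)
    else:
        upper = 1.0
    return float(icc), (float(max(lower, -1.0)), float(min(upper, 1.0)))


# --------------------------------------------------------------------------- #
# agreement on paired values
# --------------------------------------------------------------------------- #

def bland_altman(m1, m2) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    Differences are method1 - method2; bias is their mean and the limits are
    bias ± 1.96 times their sample standard deviation (n-1 denominator).
    """
    a, b = _paired_arrays(m1, m2, min_n=2)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def rmse_pairs(m1, m2) -> float:
    """Root-mean-square difference across paired subject measurements."""
    a, b = _paired_arrays(m1, m2, min_n=1)
    d = a - b
    return float(np.sqrt(np.mean(d * d)))


def sem_from_icc(sd_pooled: float, icc: float) -> float:
    """Standard error of measurement, sd_pooled * sqrt(1 - ICC)."""
    if not 0.0 <= icc <= 1.0:
        raise InvalidParameterError("icc must lie in [0, 1]")
    if sd_pooled < 0:
        raise InvalidParameterError("sd_pooled must be >= 0")
    return float(sd_pooled * math.sqrt(1.0 - icc))


def mdc_from_sem(sem: float) -> float:
    """Minimal (smallest) detectable change, 1.96 * SEM * sqrt(2)."""
    if sem < 0:
        raise InvalidParameterError("sem must be >= 0")
    return float(1.96 * sem * math.sqrt(2.0))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    a, b = _paired_arrays(x, y, min_n=3)
    ax = a - a.mean()
    by = b - b.mean()
    sx = math.sqrt(float(np.sum(ax * ax)))
    sy = math.sqrt(float(np.sum(by * by)))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    r = float(np.sum(ax * by) / (sx * sy))
    return max(-1.0, min(1.0, r))


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value.

    The p-value comes from the exact t transform t = r sqrt((n-2)/(1-r²))
    on n-2 degrees of freedom.
    """
    a, b = _paired_arrays(x, y, min_n=3)
    r = pearson_r(a, b)
    n = a.size
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(_dist.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


# --------------------------------------------------------------------------- #
# group comparison
# --------------------------------------------------------------------------- #

def _as_summary(g) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return GroupSummary.from_values(g)


def ttest_unpaired(a, b, variant: str = "pooled") -> TTestResult:
    """Unpaired two-sample t-test from raw values or group summaries.

    ``variant="pooled"`` is the classical equal-variance Student test;
    ``variant="welch"`` uses the Satterthwaite degrees of freedom.  Results
    from raw data and from that data's (n, mean, sd) summaries are identical
    by construction.
    """
    ga, gb = _as_summary(a), _as_summary(b)
    va, vb = ga.sd**2, gb.sd**2
    diff = ga.mean - gb.mean
    if variant == "pooled":
        df = ga.n + gb.n - 2
        sp2 = ((ga.n - 1) * va + (gb.n - 1) * vb) / df
        if sp2 == 0.0:
            if diff == 0.0:
                return TTestResult(0.0, float(df), 1.0, variant)
            raise UndefinedStatisticError(
                "zero pooled variance with unequal means (infinite t)"
            )
        t = diff / math.sqrt(sp2 * (1.0 / ga.n + 1.0 / gb.n))
    elif variant == "welch":
        se2 = va / ga.n + vb / gb.n
        if se2 == 0.0:
            if diff == 0.0:
                return TTestResult(0.0, float(ga.n + gb.n - 2), 1.0, variant)
            raise UndefinedStatisticError(
                "zero variance in both groups with unequal means (infinite t)"
            )
        t = diff / math.sqrt(se2)
        df = se2**2 / (
            (va / ga.n) ** 2 / (ga.n - 1) + (vb / gb.n) ** 2 / (gb.n - 1)
        )
    else:
        raise InvalidParameterError(f"unknown t-test variant {variant!r}")
    p = 2.0 * float(_dist.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0), variant)


def linreg_adjusted_r2(x, y) -> RegressionFit:
    """Ordinary least squares of y on x with the adjusted R².

    adj R² = 1 - (1 - R²)(n - 1)/(n - 2) for the single-predictor model.
    """
    a, b = _paired_arrays(x, y, min_n=3)
    n = a.size
    ax = a - a.mean()
    sxx = float(np.sum(ax * ax))
    if sxx == 0.0:
        raise UndefinedStatisticError("singular design: x is constant")
    slope = float(np.sum(ax * (b - b.mean())) / sxx)
    intercept = float(b.mean() - slope * a.mean())
    resid = b - (intercept + slope * a)
    sst = float(np.sum((b - b.mean()) ** 2))
    if sst == 0.0:
        r2 = 1.0
    else:
        r2 = 1.0 - float(np.sum(resid * resid)) / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(slope, intercept, r2, adj, n)


# --------------------------------------------------------------------------- #
# power / classification
# --------------------------------------------------------------------------- #

def n_for_pearson(
    target_r: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 100_000,
) -> int:
    """Smallest n detecting a correlation ``target_r`` (two-sided test).

    Solves the Fisher-z power equation with the small-sample bias correction

        sqrt(n - 3) * (atanh(|r|) + |r| / (2 (n - 1))) >= z_{1-alpha/2} + z_{power}

    by scanning n upwards from the minimum supported size (4).
    """
    if not 0.0 < abs(target_r) < 1.0:
        raise InvalidParameterError("target_r must satisfy 0 < |r| < 1")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if not 0.0 < power < 1.0:
        raise InvalidParameterError("power must lie in (0, 1)")
    r = abs(target_r)
    z_required = float(_dist.norm.ppf(1.0 - alpha / 2.0) + _dist.norm.ppf(power))
    for n in range(4, n_max + 1):
        lhs = math.sqrt(n - 3) * (math.atanh(r) + r / (2.0 * (n - 1)))
        if lhs >= z_required:
            return n
    raise InfeasibleQueryError(
        f"no n <= {n_max} reaches power {power} for r = {target_r} at alpha = {alpha}"
    )


def classify_strength(value: float, kind: str) -> str:
    """Qualitative agreement/correlation label.

    ICC: < 0.6 poor, 0.6-0.8 good (closed at both ends), > 0.8 excellent.
    r (absolute value used): < 0.3 negligible, 0.3-0.7 weak to moderate
    (closed at both ends), > 0.7 good.
    """
    if kind not in ("icc", "r"):
        raise InvalidParameterError("kind must be 'icc' or 'r'")
    if not -1.0 <= value <= 1.0:
        raise InvalidInputError("value must lie in [-1, 1]")
    if kind == "icc":
        if value < 0.6:
            return "poor"
        return "good" if value <= 0.8 else "excellent"
    a = abs(value)
    if a < 0.3:
        return "negligible"
    return "weak to moderate" if a <= 0.7 else "good"


def format_p(p: float) -> str:
    """Render a p-value to 3 decimals with a '<0.001' floor."""
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"


# --------------------------------------------------------------------------- #
# one-call agreement panel
# --------------------------------------------------------------------------- #

def agreement_report(
    m1,
    m2,
    measure: str = "",
    units: str = "",
    sd_pooled: float | None = None,
) -> AgreementReport:
    """Compute the full agreement panel for one measure.

    ``sd_pooled`` is the between-subject SD entering the SEM; by default the
    two methods' cohort SDs are pooled as sqrt((sd1² + sd2²)/2).  A sample
    ICC slightly below 0 is floored at 0 for the SEM (its defined domain).
    """
    a, b = _paired_arrays(m1, m2, min_n=3)
    icc, ci = icc_2_1(a, b)
    r = pearson_r(a, b)
    rmse = rmse_pairs(a, b)
    bias, lo, hi = bland_altman(a, b)
    if sd_pooled is None:
        sd_pooled = math.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
    sem = sem_from_icc(sd_pooled, min(max(icc, 0.0), 1.0))
    mdc = mdc_from_sem(sem)
    return AgreementReport(
        measure, units, int(a.size), icc, ci, r, rmse, bias, lo, hi, sem, mdc
    )
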