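"""Reliability, agreement and power statistics for jump-metric studies.

* Test–retest reliability: two-way random-effects, absolute-agreement
  intraclass correlation (single-measure ICC(2,1) by default, average-measure
  ICC(2,k) optionally), with the F-based 95% CI and the
  poor/moderate/good/excellent bands applied to the CI lower bound;
  SEM = SD * sqrt(1 - ICC) and SEM% = 100 * SEM / mean.
* Validity: Pearson correlations with Bonferroni adjustment and the
  trivial … extremely-high magnitude bands.
* Agreement between estimated and measured 1RM: paired t, Cohen's d for
  paired data (mean difference / sd of differences) and Bland–Altman bias
  with 1.96-sd limits of agreement.
* A-priori sample size for the multiple-regression R^2-deviation-from-zero
  F test via the noncentral-F distribution with noncentrality f^2 * n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))
D_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "moderate"), (np.inf, "large"))
R_BANDS = (
    (0.1, "trivial"), (0.3, "small"), (0.5, "moderate"),
    (0.7, "high"), (0.9, "very high"), (np.inf, "extremely high"),
)


def _band(value: float, bands) -> str:
    for upper, label in bands:
        if value < upper:
            return label
    return bands[-1][1]  # pragma: no cover


# --------------------------------------------------------------------------
# reliability
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float   # between-participant mean square
    ms_cols: float   # between-trial mean square
    ms_error: float  # residual mean square
    n: int           # participants
    k: int           # trials


def icc_absolute_agreement(
    trials, *, form: str = "single", alpha: float = 0.05
) -> ICCResult:
    """Two-way random-effects absolute-agreement ICC of a complete matrix.

    ``trials`` is participants x repeated trials.  ``form='single'`` gives
    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E)/n);
    ``form='average'`` the Spearman–Brown-stepped ICC(2,k).  The CI follows
    the standard F-approximation with Satterthwaite degrees of freedom.
    """
    x = np.asarray(trials, dtype=float)
    if x.ndim != 2:
        raise ValueError("trials must be a 2-d participants x trials matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 participants and 2 trials")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported; complete the matrix first")
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("undefined ICC: total variance is zero")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("undefined ICC: degenerate variance decomposition")
    icc1 = (msr - mse) / denom

    # F-based CI for ICC(2,1) (Satterthwaite df), per the standard treatment
    a = k * icc1 / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    b = 1.0 + k * icc1 * (n - 1.0) / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_up = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_lo = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_up * mse) / (
            f_up * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_lo * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_lo * msr
        )
    else:  # perfect agreement: CI collapses
        lo = hi = icc1
    lo, hi = min(lo, icc1), max(hi, icc1)

    if form == "average":
        step = lambda r: r * k / (1.0 + (k - 1.0) * r)
        icc1, lo, hi = step(icc1), step(lo), step(hi)
    return ICCResult(
        icc=float(icc1), ci_low=float(lo), ci_high=float(hi),
        ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse), n=n, k=k,
    )


def sem_from_icc(sd: float, icc: float, mean: float | None = None):
    """SEM = SD * sqrt(1 - ICC); SEM% = 100 * SEM / mean when a mean is given."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if icc > 1:
        raise ValueError("icc cannot exceed 1")
    sem = sd * float(np.sqrt(1.0 - icc))
    if mean is None:
        return sem
    if mean <= 0:
        raise ValueError("mean must be positive for SEM%")
    return sem, 100.0 * sem / mean


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    sem: float
    sem_percent: float
    interpretation: str
    mean: float
    sd: float
    form: str


def reliability_report(trials, *, form: str = "single", alpha: float = 0.05) -> ReliabilityReport:
    """ICC + SEM summary of a participants x trials matrix.

    The SD feeding the SEM is the between-participant SD of per-participant
    trial means; the mean is the grand mean.  The qualitative band is read
    off the CI lower bound.
    """
    x = np.asarray(trials, dtype=float)
    res = icc_absolute_agreement(x, form=form, alpha=alpha)
    sd = float(x.mean(axis=1).std(ddof=1))
    mean = float(x.mean())
    sem, sem_pct = sem_from_icc(sd, res.icc, mean)
    return ReliabilityReport(
        icc=res.icc, icc_ci_low=res.ci_low, icc_ci_high=res.ci_high,
        sem=sem, sem_percent=sem_pct,
        interpretation=_band(res.ci_low, ICC_BANDS),
        mean=mean, sd=sd, form=form,
    )


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def correlations_bonferroni(metrics, y, *, m_tests: int = 10):
    """Pearson r of each metric column against ``y`` with Bonferroni adjustment.

    ``m_tests`` is the family size for the correction (default 10: five
    metrics in each of two jump types).  Returns a DataFrame indexed by
    metric with r, p_raw, p_adjusted and the magnitude band.
    """
    import pandas as pd

    df = pd.DataFrame(metrics)
    y = np.asarray(y, dtype=float)
    if len(df) != y.size:
        raise ValueError("metrics and y lengths differ")
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    rows = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"constant column: {col!r}")
        r, p = sps.pearsonr(x, y)
        rows[col] = {
            "r": float(r),
            "p_raw": float(p),
            "p_adjusted": min(1.0, m_tests * float(p)),
            "magnitude": _band(abs(float(r)), R_BANDS),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# --------------------------------------------------------------------------
# agreement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementReport:
    bias: float        # mean(e - m), kg
    loa_low: float     # bias - 1.96 sd(diff)
    loa_high: float    # bias + 1.96 sd(diff)
    sd_diff: float
    t_statistic: float
    t_p_value: float
    cohens_d: float
    d_interpretation: str
    n: int


LOA_MULTIPLIER = 1.96  # 95% limits of agreement


def paired_comparison(estimated, measured) -> AgreementReport:
    """Paired t, Cohen's d and Bland–Altman agreement of e vs m.

    Cohen's d for paired data is mean(diff)/sd(diff).  With zero-variance
    differences the t test degenerates: zero bias is reported as p = 1
    (perfect agreement by convention), nonzero bias as p = 0 (the difference
    is exact).
    """
    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if e.shape != m.shape or e.ndim != 1:
        raise ValueError("estimated and measured must be 1-d of equal length")
    n = e.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = e - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        t_stat = 0.0 if bias == 0 else np.inf * np.sign(bias)
        p = 1.0 if bias == 0 else 0.0
        cohen = 0.0 if bias == 0 else np.inf * np.sign(bias)
    else:
        t_stat, p = sps.ttest_rel(e, m)
        cohen = bias / sd
    return AgreementReport(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd,
        t_statistic=float(t_stat),
        t_p_value=float(p),
        cohens_d=float(cohen),
        d_interpretation=_band(abs(float(cohen)), D_BANDS),
        n=n,
    )


# --------------------------------------------------------------------------
# power analysis
# --------------------------------------------------------------------------

def f2_from_r2(r2: float) -> float:
    """Cohen's f^2 = R^2 / (1 - R^2)."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    return r2 / (1.0 - r2)


def regression_power(n: int, f2: float, n_predictors: int, alpha: float = 0.05) -> float:
    """Power of the fixed-model R^2 = 0 F test at sample size ``n``.

    Noncentral F with df1 = k, df2 = n - k - 1 and noncentrality f^2 * n.
    """
    if f2 <= 0:
        raise ValueError("f2 must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_predictors < 1:
        raise ValueError("need at least one predictor")
    df2 = n - n_predictors - 1
    if df2 < 1:
        return 0.0
    fcrit = sps.f.ppf(1.0 - alpha, n_predictors, df2)
    return float(1.0 - sps.ncf.cdf(fcrit, n_predictors, df2, f2 * n))


def power_min_n(
    f2: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_predictors: int = 2,
    max_n: int = 10**6,
) -> int:
    """Smallest n whose regression F-test power reaches ``target_power``."""
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    n = n_predictors + 2
    while n <= max_n:
        if regression_power(n, f2, n_predictors, alpha) >= target_power:
            return n
        n += 1
    raise ValueError(f"no n <= {max_n} reaches power {target_power}")


def normality_check(sample):
    """Shapiro–Wilk statistic and p for 3 <= n <= 5000 (thin pre-check)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)
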