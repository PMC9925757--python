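"""Method-comparison statistics: ICC, Deming regression, Bland–Altman, paired t.

These are the tools used to compare two annotation methods (e.g. visual
classification against guideline-based classification) when neither can be
taken as error-free:

* **ICC** — intraclass correlation from a two-way mixed-effects model
  (subjects random, raters/measures fixed), consistency definitions
  ICC(3,1) for a single measure and ICC(3,k) for the average of k measures;
* **Deming regression** — errors-in-variables straight-line fit with error
  variance ratio λ (default 1, i.e. orthogonal regression), confidence
  intervals by the jackknife;
* **Bland–Altman** — mean paired difference with 1.96 SD limits of
  agreement;
* **paired t-test** — classical two-sided test on the paired differences.

When applied to nominal class codes (Early=1, Variable=2, Late=3) these
mechanics reproduce a common, if statistically debatable, practice in the
method-comparison literature; the coding must be made explicit by the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ICCResult",
    "DemingResult",
    "BlandAltmanResult",
    "PairedTResult",
    "icc_two_way_mixed",
    "deming",
    "bland_altman",
    "paired_t",
    "CLASS_CODES",
]

#: default nominal coding used when comparing categorical annotations
CLASS_CODES = {"Early": 1, "Variable": 2, "Late": 3}


@dataclass(frozen=True)
class ICCResult:
    """Two-way mixed-model intraclass correlations (consistency)."""

    single: float            #: ICC(3,1)
    average: float           #: ICC(3,k)
    single_ci: tuple[float, float]
    average_ci: tuple[float, float]
    ms_rows: float           #: between-subject mean square
    ms_error: float          #: residual mean square
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class DemingResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    lam: float


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    #: per-pair (mean, difference) coordinates for plotting
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    p_value: float
    mean_diff: float
    #: True when the differences have zero variance (test degenerate)
    zero_variance: bool = False


def icc_two_way_mixed(
    table: np.ndarray, confidence: float = 0.95
) -> ICCResult:
    """ICC from an n-subjects × k-raters table, two-way mixed model.

    Consistency definitions (Shrout–Fleiss 3,1 and 3,k):

        single  = (MS_R − MS_E) / (MS_R + (k−1)·MS_E)
        average = (MS_R − MS_E) / MS_R

    with MS_R the between-subject and MS_E the residual mean square of the
    two-way ANOVA decomposition.  Confidence bounds follow the classical
    F-distribution construction.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings table must be n subjects × k ≥ 2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings table must have no missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_error = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_error = ss_error / df_error
    if ms_rows <= 0 or (ms_rows < 1e-12 and ms_error < 1e-12):
        raise ValueError("zero between-subject variance: ICC undefined")
    single = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
    average = (ms_rows - ms_error) / ms_rows

    alpha = 1.0 - confidence
    if ms_error <= 0:
        single_ci = (single, single)
        average_ci = (average, average)
    else:
        f_obs = ms_rows / ms_error
        f_upper = stats.f.ppf(1 - alpha / 2, df_rows, df_error)
        f_lower = stats.f.ppf(1 - alpha / 2, df_error, df_rows)
        fl = f_obs / f_upper
        fu = f_obs * f_lower
        single_ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        average_ci = (1 - 1 / fl, 1 - 1 / fu)
    return ICCResult(
        single=float(single),
        average=float(average),
        single_ci=(float(single_ci[0]), float(single_ci[1])),
        average_ci=(float(average_ci[0]), float(average_ci[1])),
        ms_rows=float(ms_rows),
        ms_error=float(ms_error),
        n_subjects=n,
        n_raters=k,
    )


def _deming_slope(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float]:
    """Closed-form errors-in-variables slope and intercept."""
    xm, ym = x.mean(), y.mean()
    sxx = np.mean((x - xm) ** 2)
    syy = np.mean((y - ym) ** 2)
    sxy = np.mean((x - xm) * (y - ym))
    if abs(sxy) < 1e-300:
        # variance-only branch: no covariance to orient the line
        slope = np.sqrt(syy / (lam * sxx)) if sxx > 0 else 0.0
    else:
        d = syy - lam * sxx
        slope = (d + np.sqrt(d * d + 4 * lam * sxy * sxy)) / (2 * sxy)
    return float(slope), float(ym - slope * xm)


def deming(
    x, y, lam: float = 1.0, confidence: float = 0.95
) -> DemingResult:
    """Deming regression of y on x with error-variance ratio λ.

    λ = var(error in y) / var(error in x); λ = 1 is orthogonal regression.
    95% confidence intervals are jackknife (leave-one-out) estimates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples, n ≥ 3")
    if np.var(x) == 0:
        raise ValueError("x must have positive variance")
    slope, intercept = _deming_slope(x, y, lam)

    n = len(x)
    slopes = np.empty(n)
    intercepts = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        slopes[i], intercepts[i] = _deming_slope(x[mask], y[mask], lam)
        mask[i] = True
    # jackknife pseudo-value variance
    def _jack_ci(theta: float, loo: np.ndarray) -> tuple[float, float]:
        pseudo = n * theta - (n - 1) * loo
        se = np.sqrt(np.var(pseudo, ddof=1) / n)
        tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
        return (theta - tcrit * se, theta + tcrit * se)

    return DemingResult(
        slope=slope,
        intercept=intercept,
        slope_ci=_jack_ci(slope, slopes),
        intercept_ci=_jack_ci(intercept, intercepts),
        lam=lam,
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement: mean difference ± 1.96 · SD (sample, n−1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired samples, n ≥ 2")
    diffs = x - y
    means = (x + y) / 2.0
    d_bar = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=d_bar,
        loa_lower=d_bar - 1.96 * sd,
        loa_upper=d_bar + 1.96 * sd,
        sd_diff=sd,
        means=means,
        diffs=diffs,
    )


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test on the differences x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired samples, n ≥ 2")
    diffs = x - y
    if np.var(diffs, ddof=1) == 0:
        # degenerate: identical shifts everywhere
        if abs(diffs.mean()) > 0:
            return PairedTResult(np.inf, 0.0, float(diffs.mean()), zero_variance=True)
        return PairedTResult(0.0, 1.0, 0.0, zero_variance=True)
    t_stat, p = stats.ttest_rel(x, y)
    return PairedTResult(float(t_stat), float(p), float(diffs.mean()))
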