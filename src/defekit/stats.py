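"""Statistical workflow for defecation biomarkers.

The analysis recipe applied to every continuous biomarker:

1. fence outliers with the interquartile range (keep values inside
   ``[Q1 - k*IQR, Q3 + k*IQR]``, ``k = 1.5``);
2. test each group for normality (Shapiro-Wilk at the comparison alpha);
3. compare the two groups with Welch's t-test when both groups look
   Gaussian, otherwise with the Mann-Whitney U test; all tests two-sided
   at alpha = 0.05, no multiple-testing correction by default (an
   optional Bonferroni / Benjamini-Hochberg flag is provided).

Stool-dropping durations are modelled as log-normal; the fit is the
closed-form maximum-likelihood estimate on logs: ``mu_hat = mean(ln x)``,
``sigma_hat = sd(ln x)`` with denominator ``n``.  The Bristol-scale
contrasts compare adjacent form groups and the pooled constipation-side
{1,2,3} versus diarrhea-side {5,6,7} groups (form 4 excluded from the
pooled contrast).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateFitError, InsufficientSampleError

__all__ = [
    "ComparisonResult",
    "LogNormalFit",
    "RegressionFit",
    "BsfsContrast",
    "BSFS_CONTRAST_GROUPS",
    "iqr_filter",
    "choose_test",
    "compare_groups",
    "fit_lognormal",
    "lognormal_pdf",
    "lognormal_from_moments",
    "bsfs_contrasts",
    "linear_fit",
    "adjust_pvalues",
]

WELCH_T = "welch_t"
MANN_WHITNEY_U = "mann_whitney_u"

#: The five Bristol-scale contrasts, in reporting order.
BSFS_CONTRAST_GROUPS: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = (
    ((1, 2), (3,)),
    ((3,), (4,)),
    ((4,), (5,)),
    ((5,), (6, 7)),
    ((1, 2, 3), (5, 6, 7)),
)


@dataclass(frozen=True)
class ComparisonResult:
    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    test_used: str
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "groups": list(self.group_labels),
            "n": list(self.n),
            "means": list(self.means),
            "sds": list(self.sds),
            "test": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class LogNormalFit:
    """Closed-form ML log-normal fit plus the raw arithmetic moments."""

    mu_hat: float
    sigma_hat: float
    arith_mean: float
    arith_sd: float
    n: int

    @property
    def median(self) -> float:
        return math.exp(self.mu_hat)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class BsfsContrast:
    """One Bristol-group comparison; ``result is None`` when not computable."""

    label: str
    groups: tuple[tuple[int, ...], tuple[int, ...]]
    result: ComparisonResult | None
    note: str = ""

    @property
    def computable(self) -> bool:
        return self.result is not None


# -- outlier fencing -------------------------------------------------------


def iqr_filter(
    values,
    multiplier: float = 1.5,
    quartile_method: str = "linear",
):
    """Single-pass IQR fence: keep values within ``[Q1 - m*IQR, Q3 + m*IQR]``.

    Quartiles by linear interpolation between order statistics by default
    (``quartile_method`` is forwarded to :func:`numpy.percentile`).  Order
    is preserved; an empty input yields an empty output.
    """
    if multiplier < 0:
        raise ValueError("IQR multiplier must be >= 0")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr
    q1, q3 = np.percentile(arr, [25, 75], method=quartile_method)
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return arr[(arr >= lo) & (arr <= hi)]


# -- two-group testing -----------------------------------------------------


def choose_test(a, b, alpha: float = 0.05) -> str:
    """Normality gate: Welch's t-test iff Shapiro-Wilk accepts both groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientSampleError(
            f"normality gate needs n >= 3 per group, got {len(a)} and {len(b)}"
        )
    pa = sps.shapiro(a).pvalue
    pb = sps.shapiro(b).pvalue
    return WELCH_T if (pa >= alpha and pb >= alpha) else MANN_WHITNEY_U


def compare_groups(
    a,
    b,
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided, normality-gated two-group comparison."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    test = choose_test(a, b, alpha)
    if test == WELCH_T:
        res = sps.ttest_ind(a, b, equal_var=False)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        group_labels=tuple(labels),
        n=(len(a), len(b)),
        means=(float(np.mean(a)), float(np.mean(b))),
        sds=(float(np.std(a, ddof=1)), float(np.std(b, ddof=1))),
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
    )


# -- log-normal model ------------------------------------------------------


def fit_lognormal(values) -> LogNormalFit:
    """ML log-normal fit: mean and SD (denominator n) of the log values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientSampleError("log-normal fit needs n >= 2")
    if np.any(arr <= 0):
        raise ValueError("log-normal fit requires strictly positive values")
    logs = np.log(arr)
    return LogNormalFit(
        mu_hat=float(np.mean(logs)),
        sigma_hat=float(np.std(logs, ddof=0)),
        arith_mean=float(np.mean(arr)),
        arith_sd=float(np.std(arr, ddof=1)),
        n=int(arr.size),
    )


def lognormal_pdf(x, mu_hat: float, sigma_hat: float):
    """Log-normal density; zero on the non-positive half line."""
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    out = np.zeros_like(xv)
    pos = xv > 0
    xp = xv[pos]
    out[pos] = (
        1.0
        / (xp * sigma_hat * math.sqrt(2.0 * math.pi))
        * np.exp(-((np.log(xp) - mu_hat) ** 2) / (2.0 * sigma_hat**2))
    )
    return float(out[0]) if scalar else out


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments inversion: arithmetic (mean, sd) -> (mu, sigma).

    ``sigma^2 = ln(1 + (sd/mean)^2)``, ``mu = ln(mean) - sigma^2 / 2``.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


# -- Bristol-scale contrasts ----------------------------------------------


def bsfs_contrasts(
    table: pd.DataFrame,
    response: str,
    alpha: float = 0.05,
    remove_outliers: bool = True,
    multiplier: float = 1.5,
    bsfs_column: str = "BSFS",
) -> list[BsfsContrast]:
    """The five Bristol-group comparisons of a response biomarker.

    Outlier fencing (when enabled) is applied to the response column once,
    across the whole table, before grouping — per-analysis-variable
    fencing, independent of any other biomarker.  Contrasts whose groups
    have fewer than three observations are flagged not-computable and the
    remaining contrasts are still returned.
    """
    if response not in table.columns or bsfs_column not in table.columns:
        raise KeyError(f"table needs columns {response!r} and {bsfs_column!r}")
    df = table[[bsfs_column, response]].dropna()
    if remove_outliers and len(df) > 0:
        kept = iqr_filter(df[response].to_numpy(), multiplier)
        lo, hi = (kept.min(), kept.max()) if kept.size else (np.inf, -np.inf)
        df = df[(df[response] >= lo) & (df[response] <= hi)]

    out: list[BsfsContrast] = []
    for ga, gb in BSFS_CONTRAST_GROUPS:
        label = f"BSFS{'/'.join(map(str, ga))} vs BSFS{'/'.join(map(str, gb))}"
        va = df.loc[df[bsfs_column].isin(ga), response].to_numpy()
        vb = df.loc[df[bsfs_column].isin(gb), response].to_numpy()
        if len(va) < 3 or len(vb) < 3:
            out.append(
                BsfsContrast(
                    label,
                    (ga, gb),
                    None,
                    note=f"not computable: n = {len(va)}/{len(vb)} (< 3)",
                )
            )
            continue
        res = compare_groups(
            va, vb, labels=(f"BSFS{ga}", f"BSFS{gb}"), alpha=alpha
        )
        out.append(BsfsContrast(label, (ga, gb), res))
    return out


# -- regression ------------------------------------------------------------


def linear_fit(x, y) -> RegressionFit:
    """Ordinary least squares of y on x; R^2 = squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientSampleError("linear fit needs n >= 3")
    if np.allclose(x, x[0]):
        raise DegenerateFitError("regressor is constant")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


# -- optional multiplicity adjustment --------------------------------------


def adjust_pvalues(p_values, method: str = "none"):
    """Optional multiplicity adjustment (off in the default workflow).

    ``method``: ``none``, ``bonferroni`` or ``bh`` (Benjamini-Hochberg).
    """
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return p.copy()
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")
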