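"""Repeatability and method-agreement statistics for paired scar-mass
measurement series: Bland–Altman bias and limits of agreement, Pearson r,
Lin's concordance correlation coefficient (CCC), two-way random-effects
intraclass correlation (ICC, absolute agreement, single or average
measure), within-subject coefficient of variation, paired t-tests, and
Bonett's ICC sample-size formula.

Differences are always oriented first argument minus second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .core import ValidationError

__all__ = [
    "AgreementReport",
    "bland_altman",
    "pearson_r",
    "ccc",
    "icc",
    "cv_pct",
    "paired_t",
    "bonett_n",
    "agreement_report",
]


@dataclass
class AgreementReport:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: Optional[float]
    ccc: Optional[float]
    icc_single: Optional[float]
    icc_average: Optional[float]
    cv_pct: Optional[float]
    t_stat: Optional[float]
    p_value: Optional[float]
    orientation: str = "first minus second"


def _series(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"series length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValidationError("need at least 2 paired measurements")
    return x, y


def bland_altman(x, y) -> Tuple[float, float, Tuple[float, float]]:
    """Mean difference, sample SD of differences, and 95% limits of
    agreement (bias ± 1.96 SD)."""
    x, y = _series(x, y)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, (bias - 1.96 * sd, bias + 1.96 * sd)


def pearson_r(x, y) -> float:
    x, y = _series(x, y)
    return float(stats.pearsonr(x, y)[0])


def ccc(x, y) -> Optional[float]:
    """Lin's concordance: 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²), population
    (1/n) moments.  Undefined (None) when both series are constant with
    equal means."""
    x, y = _series(x, y)
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    denom = sx2 + sy2 + (float(x.mean()) - float(y.mean())) ** 2
    if denom == 0:
        return None
    return 2.0 * sxy / denom


def icc(x, y, form: str = "two_way_random_absolute_single") -> Optional[float]:
    """Two-way random-effects absolute-agreement ICC from the mean squares
    of the subjects × raters table (raters are the two series).

    ``form`` selects the single-measure (ICC(2,1)) or average-measure
    (ICC(2,k)) estimate.  Degenerate mean squares give None.
    """
    x, y = _series(x, y)
    n = x.size
    if n < 3:
        raise ValidationError("icc requires at least 3 subjects")
    table = np.stack([x, y], axis=1)  # n × k
    k = 2
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "two_way_random_absolute_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "two_way_random_absolute_average":
        denom = msr + (msc - mse) / n
    else:
        raise ValidationError(f"unknown ICC form {form!r}")
    if denom == 0 or not np.isfinite(denom):
        return None
    return float((msr - mse) / denom)


def cv_pct(x, y) -> Optional[float]:
    """Within-subject coefficient of variation (root-mean-square method):
    100 · sqrt( mean_i (d_i²/2) ) / grand mean.  Defined for n >= 1."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"series length mismatch: {x.size} vs {y.size}")
    if x.size < 1:
        raise ValidationError("need at least 1 paired measurement")
    grand = float(np.mean(np.concatenate([x, y])))
    if grand <= 0:
        return None
    d = x - y
    return 100.0 * math.sqrt(float(np.mean(d**2 / 2.0))) / grand


def paired_t(x, y) -> Tuple[Optional[float], Optional[float]]:
    """Two-tailed paired t-test: t = bias / (sd_diff/√n), p from t(n−1)."""
    x, y = _series(x, y)
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0:
        return None, None  # all differences identical; test undefined
    n = d.size
    t = float(d.mean()) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


def bonett_n(rho: float, width: float, k: int = 2, alpha: float = 0.05) -> int:
    """Bonett (2002) sample size for an ICC confidence interval:

        n = ⌈ 8 z²_{α/2} (1−ρ)² (1+(k−1)ρ)² / (k (k−1) w²) + 1 ⌉

    with a floor of 2 subjects.
    """
    if not 0.0 < rho < 1.0:
        raise ValidationError("rho must lie in (0, 1)")
    if width <= 0:
        raise ValidationError("width must be positive")
    if k < 2:
        raise ValidationError("k (raters) must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n = 8.0 * z**2 * (1.0 - rho) ** 2 * (1.0 + (k - 1) * rho) ** 2 / (
        k * (k - 1) * width**2
    ) + 1.0
    return max(2, math.ceil(n))


def agreement_report(x, y) -> AgreementReport:
    """All pairwise agreement statistics for two measurement series."""
    x, y = _series(x, y)
    bias, sd, (lo, hi) = bland_altman(x, y)
    t, p = paired_t(x, y)
    return AgreementReport(
        n=x.size,
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        pearson_r=pearson_r(x, y) if x.std() > 0 and y.std() > 0 else None,
        ccc=ccc(x, y),
        icc_single=icc(x, y, "two_way_random_absolute_single") if x.size >= 3 else None,
        icc_average=icc(x, y, "two_way_random_absolute_average") if x.size >= 3 else None,
        cv_pct=cv_pct(x, y),
        t_stat=t,
        p_value=p,
    )
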