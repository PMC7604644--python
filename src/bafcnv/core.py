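"""Shared mathematical core for BAF-shift CNV detection.

Everything downstream (threshold simulation, window scanning, merging) is
built on four primitives defined here:

* the folded-VAF <-> cell-fraction transforms for heterozygous SNPs hit by a
  single-copy deletion or duplication on one haplotype,
* exact (Clopper-Pearson) binomial confidence intervals on VAFs and their
  push-forward to cell-fraction intervals,
* a log-normal model of per-site sequencing depth, and
* a coverage-weighted two-sample t-test (reliability-weight convention).

All VAF arithmetic is done on the folded (minor-allele) scale, ``min(v, 1-v)``,
because a heterozygous site cannot distinguish which haplotype carries the
alternate allele: a VAF of 67% and a VAF of 33% carry identical evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DELETION = "deletion"
DUPLICATION = "duplication"
CNV_TYPES = (DELETION, DUPLICATION)

#: z-quantile used for normal-approximation 99% intervals (coverage indicator)
_Z99 = float(stats.norm.ppf(0.995))


def _check_cnv_type(cnv_type: str) -> None:
    if cnv_type not in CNV_TYPES:
        raise ValueError(f"unknown cnv_type {cnv_type!r}; expected one of {CNV_TYPES}")


def fold_vaf(vaf):
    """Fold a variant allele frequency onto the minor-allele scale.

    Returns ``min(vaf, 1 - vaf)``, mapping [0, 1] onto [0, 0.5]. Accepts
    scalars or arrays; idempotent.
    """
    v = np.asarray(vaf, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("VAF must lie in [0, 1]")
    out = np.minimum(v, 1.0 - v)
    return out if out.ndim else float(out)


def expected_vaf(cnv_type: str, cf):
    """Expected folded VAF of a heterozygous SNP inside a CNV.

    For an event present in a fraction ``cf`` of cells and affecting one
    haplotype, the minor-allele expectation is

    * deletion:    (1 - cf) / (2 - cf)   -- 0.5 at cf=0, 0 at cf=1
    * duplication: 1 / (2 + cf)          -- 0.5 at cf=0, 1/3 at cf=1

    i.e. the affected allele's share of the (cf-weighted) total copy number.
    Strictly decreasing in ``cf`` for both types.
    """
    _check_cnv_type(cnv_type)
    c = np.asarray(cf, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("cell fraction must lie in [0, 1]")
    if cnv_type == DELETION:
        out = (1.0 - c) / (2.0 - c)
    else:
        out = 1.0 / (2.0 + c)
    return out if out.ndim else float(out)


def cf_from_vaf(cnv_type: str, vaf):
    """Invert :func:`expected_vaf`: cell fraction explaining an observed VAF.

    The input is folded first. Deletion: ``(1 - 2v) / (1 - v)``; duplication:
    ``(1 - 2v) / v``. Results are clamped to [0, 1]: values above 1 would
    correspond to copy numbers outside [1, 3], which are not modelled. A
    folded VAF of exactly 0 under the duplication model (where the formula
    diverges) clamps to 1.
    """
    _check_cnv_type(cnv_type)
    v = np.asarray(fold_vaf(vaf), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if cnv_type == DELETION:
            out = (1.0 - 2.0 * v) / (1.0 - v)
        else:
            out = (1.0 - 2.0 * v) / v
    out = np.where(np.isfinite(out), out, 1.0)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def binomial_ci(alt_count, depth, level: float = 0.99):
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion.

    Vectorised over ``alt_count``/``depth``. Returns ``(low, high)`` on the
    VAF scale with guaranteed coverage >= ``level``; the exact construction is
    what makes the "covers 0.5 in 99 of 100 cases" gating criterion honest at
    low depth.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    k = np.asarray(alt_count, dtype=float)
    n = np.asarray(depth, dtype=float)
    if np.any(n < 1):
        raise ValueError("depth must be >= 1")
    if np.any((k < 0) | (k > n)):
        raise ValueError("alt_count must satisfy 0 <= alt_count <= depth")
    a = 1.0 - level
    with np.errstate(invalid="ignore"):
        low = np.where(k > 0, stats.beta.ppf(a / 2.0, k, n - k + 1.0), 0.0)
        high = np.where(k < n, stats.beta.isf(a / 2.0, k + 1.0, n - k), 1.0)
    if low.ndim:
        return low, high
    return float(low), float(high)


@dataclass(frozen=True)
class CfEstimate:
    """Cell-fraction estimate with a confidence interval.

    Invariant: ``0 <= ci_low <= cf <= ci_high <= 1``.
    """

    cf: float
    ci_low: float
    ci_high: float
    cnv_type: str


def cf_interval(alt_count: int, depth: int, cnv_type: str, level: float = 0.99) -> CfEstimate:
    """Push a binomial VAF interval through the CF transform.

    The CF-vs-unfolded-VAF map ``g(v) = cf_from_vaf(type, fold(v))`` is
    V-shaped: decreasing on [0, 0.5], increasing on [0.5, 1]. For a VAF
    interval on one side of 0.5 the CF endpoints are therefore the swapped,
    transformed VAF endpoints; an interval straddling 0.5 reaches g(0.5) = 0.
    """
    low, high = binomial_ci(alt_count, depth, level)
    g_lo = cf_from_vaf(cnv_type, low)
    g_hi = cf_from_vaf(cnv_type, high)
    ci_high = max(g_lo, g_hi)
    ci_low = 0.0 if low < 0.5 < high else min(g_lo, g_hi)
    cf = cf_from_vaf(cnv_type, alt_count / depth)
    cf = min(max(cf, ci_low), ci_high)
    return CfEstimate(cf=cf, ci_low=ci_low, ci_high=ci_high, cnv_type=cnv_type)


@dataclass(frozen=True)
class CoverageModel:
    """Log-normal model of per-site sequencing depth.

    ``meanlog``/``sdlog`` parameterise the distribution of log(depth);
    sampled depths are rounded to integers and floored at ``min_depth``.
    """

    meanlog: float
    sdlog: float
    min_depth: int = 1

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        d = rng.lognormal(self.meanlog, self.sdlog, size=size)
        return np.maximum(np.rint(d).astype(np.int64), self.min_depth)


def fit_coverage_model(depths, min_depth: int = 1) -> CoverageModel:
    """Maximum-likelihood log-normal fit to observed positive depths.

    Zero depths are excluded (log undefined); at least 30 positive depths are
    required — below that the user should supply meanlog/sdlog directly.
    """
    d = np.asarray(depths, dtype=float)
    d = d[d > 0]
    if d.size < 30:
        raise ValueError(
            f"need >= 30 positive depths to fit a coverage model (got {d.size}); "
            "supply CoverageModel(meanlog, sdlog) explicitly instead"
        )
    logs = np.log(d)
    return CoverageModel(meanlog=float(logs.mean()), sdlog=float(logs.std()), min_depth=min_depth)


@dataclass(frozen=True)
class WeightedSample:
    """Values with positive reliability weights (here: CFs weighted by depth)."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("all weights must be > 0")


def _weighted_moments(x: np.ndarray, w: np.ndarray, axis: int = -1):
    """Weighted mean, unbiased weighted variance, effective sample size.

    Reliability-weight convention: m = Σwx/Σw; s² = Σw(x−m)²/(Σw − Σw²/Σw);
    n_eff = (Σw)²/Σw². With equal weights these are the ordinary mean,
    ddof=1 variance, and n.
    """
    sw = w.sum(axis=axis)
    sw2 = (w * w).sum(axis=axis)
    m = (w * x).sum(axis=axis) / sw
    dev = x - np.expand_dims(m, axis)
    denom = sw - sw2 / sw
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (w * dev * dev).sum(axis=axis) / denom
    n_eff = sw * sw / sw2
    return m, var, n_eff


def weighted_welch(a_vals, a_w, b_vals, b_w, alternative: str = "greater", axis: int = -1):
    """Vectorised coverage-weighted Welch t-test (one-tailed).

    Operates along ``axis`` so a batch of simulated windows can be tested in
    one call. Returns ``(t, p)`` arrays; entries where either side's
    effective sample size falls below 2 (test inapplicable) are NaN. When
    both sides have zero variance, p is 0.5 for equal means and 0/1 by the
    sign of the difference otherwise.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a_vals = np.asarray(a_vals, dtype=float)
    a_w = np.asarray(a_w, dtype=float)
    b_vals = np.asarray(b_vals, dtype=float)
    b_w = np.asarray(b_w, dtype=float)

    ma, va, na = _weighted_moments(a_vals, a_w, axis)
    mb, vb, nb = _weighted_moments(b_vals, b_w, axis)
    se2 = va / na + vb / nb
    diff = ma - mb

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 * se2 / (
            (va / na) ** 2 / (na - 1.0) + (vb / nb) ** 2 / (nb - 1.0)
        )
        p = stats.t.sf(t, df) if alternative == "greater" else stats.t.cdf(t, df)

    # degenerate windows: zero pooled variance -> decide by sign of the
    # mean difference; insufficient effective sample size -> NaN
    zero_se = se2 == 0
    if np.any(zero_se):
        sign = np.sign(diff)
        p_deg = np.where(sign == 0, 0.5, np.where(sign > 0, 0.0, 1.0))
        if alternative == "less":
            p_deg = np.where(sign == 0, 0.5, 1.0 - p_deg)
        t = np.where(zero_se, np.where(sign == 0, 0.0, np.copysign(np.inf, sign)), t)
        p = np.where(zero_se, p_deg, p)
    bad = (na < 2) | (nb < 2)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    if np.ndim(t):
        return t, p
    return float(t), float(p)


def weighted_t_test(a: WeightedSample, b: WeightedSample, alternative: str = "greater"):
    """One-tailed weighted two-sample t-test on two :class:`WeightedSample`.

    With all weights equal the result is identical to Welch's t-test.
    Returns ``(statistic, p_value)``; NaN when the effective sample size of
    either sample is below 2 (callers skip such windows).
    """
    if a.values.size < 2 or b.values.size < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = weighted_welch(a.values, a.weights, b.values, b.weights, alternative)
    if np.isnan(p):
        warnings.warn("weighted t-test inapplicable (effective sample size < 2)", stacklevel=2)
    return t, p


def normal_mean_interval(x: np.ndarray, level: float = 0.99):
    """Normal-approximation CI for a mean (used by the coverage indicator)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 observations")
    m = float(x.mean())
    se = float(x.std(ddof=1)) / np.sqrt(n)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return m, m - z * se, m + z * se
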