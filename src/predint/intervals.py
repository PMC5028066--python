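"""Confidence and prediction intervals for means, correlations, and d-values.

A prediction interval (PI) answers: given an original study's summary
statistics and a planned replication sample size, what range of replication
statistics is consistent with sampling error alone?  It differs from a
confidence interval (CI), which targets the population parameter: a 95% CI
around an original estimate captures far fewer than 95% of replication
estimates, especially when the original sample dwarfs the replication.

Three study designs are supported:

* **means** — one-sample (M, SD, N); the PI is a t interval on the
  difference between the original and an imagined identical replication,
  with the variance ``SD^2/N1 + SD^2/N2`` and ``df = N1 - 1`` (only the
  original SD is available, so the pooled-df shortcut does not apply).
* **correlations** — (r, N); component CIs come from the Fisher r-to-z
  transform and are combined with Zou's modified asymptotic method, which
  respects the asymmetry of the sampling distribution of non-zero r.
* **standardized mean differences (Cohen's d)** — (d, n1, n2); component
  CIs invert the noncentral-t distribution, and the same Zou combination
  applies on the d scale.

All interval constructors return a full-precision :class:`Interval`;
rounding happens only at the reporting layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import optimize, stats

__all__ = [
    "Interval",
    "MeanStudy",
    "CorrelationStudy",
    "DStudy",
    "ReplicationPlan",
    "mean_ci",
    "mean_pi",
    "fisher_ci",
    "zou_combine",
    "correlation_pi",
    "correlation_pi_simple",
    "correlation_pi_rtoz",
    "d_to_t",
    "d_ci_noncentral",
    "noncentral_t_ncp",
    "d_pi",
    "d_unbiased",
]

#: Root-finder bracket padding and tolerance for the noncentrality parameter.
_NCP_TOL = 1e-8


def _check_level(level: float) -> None:
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level!r}")


def _t_crit(df: float, level: float) -> float:
    return float(stats.t.ppf((1.0 + level) / 2.0, df))


def _z_crit(level: float) -> float:
    return float(stats.norm.ppf((1.0 + level) / 2.0))


@dataclass(frozen=True)
class Interval:
    """A two-sided interval ``[lower, upper]`` at confidence/prediction
    level ``level`` (e.g. 0.95)."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper):
            raise ValueError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        _check_level(self.level)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        """Closed-interval membership (boundaries count as inside)."""
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class MeanStudy:
    """Summary statistics of a one-sample study of a mean."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd!r}")
        if self.n < 2:
            raise ValueError(f"n must be at least 2, got {self.n!r}")


@dataclass(frozen=True)
class CorrelationStudy:
    """A Pearson correlation and its sample size.

    Requires ``|r| < 1`` and ``n >= 4`` so the Fisher standard error
    ``1/sqrt(n - 3)`` is finite.
    """

    r: float
    n: int

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError(f"|r| must be < 1, got {self.r!r}")
        if self.n < 4:
            raise ValueError(f"n must be at least 4, got {self.n!r}")


@dataclass(frozen=True)
class DStudy:
    """A two-group standardized mean difference (pooled-SD Cohen's d)."""

    d: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(
                f"cell sizes must be at least 2, got {self.n1!r}, {self.n2!r}"
            )
        if self.n1 + self.n2 < 5:
            raise ValueError(
                "n1 + n2 must be at least 5 for stable noncentral-t inversion"
            )

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


@dataclass(frozen=True)
class ReplicationPlan:
    """Planned replication sample size(s).

    For means and correlations set ``n_rep``; for two-group d-values set
    ``n1_rep`` and ``n2_rep``.
    """

    n_rep: int | None = None
    n1_rep: int | None = None
    n2_rep: int | None = None

    def single_n(self, minimum: int) -> int:
        if self.n_rep is None:
            raise ValueError("this design requires a single replication n_rep")
        if self.n_rep < minimum:
            raise ValueError(
                f"replication n must be at least {minimum}, got {self.n_rep!r}"
            )
        return self.n_rep

    def cell_ns(self) -> tuple[int, int]:
        if self.n1_rep is None or self.n2_rep is None:
            raise ValueError("two-group designs require n1_rep and n2_rep")
        if self.n1_rep < 2 or self.n2_rep < 2:
            raise ValueError("replication cell sizes must be at least 2")
        if self.n1_rep + self.n2_rep < 5:
            raise ValueError("replication cells must satisfy n1 + n2 >= 5")
        return self.n1_rep, self.n2_rep


# ---------------------------------------------------------------------------
# Means
# ---------------------------------------------------------------------------

def mean_ci(study: MeanStudy, level: float = 0.95) -> Interval:
    """One-sample t confidence interval ``M +/- t_{n-1} * SD/sqrt(n)``."""
    _check_level(level)
    half = _t_crit(study.n - 1, level) * study.sd / math.sqrt(study.n)
    return Interval(study.mean - half, study.mean + half, level)


def mean_pi(study: MeanStudy, plan: ReplicationPlan, level: float = 0.95) -> Interval:
    """Prediction interval for a replication mean.

    ``M1 +/- t_{N1-1} * sqrt(SD1^2/N1 + SD1^2/N2)`` — the t interval for the
    difference between the original mean and the mean of a planned
    replication of size N2, using the original SD for both studies.  The
    degrees of freedom are ``N1 - 1`` (not ``N1 + N2 - 2``) because only the
    original sample contributes variance information.
    """
    _check_level(level)
    n2 = plan.single_n(minimum=1)
    se = study.sd * math.sqrt(1.0 / study.n + 1.0 / n2)
    half = _t_crit(study.n - 1, level) * se
    return Interval(study.mean - half, study.mean + half, level)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def fisher_ci(study: CorrelationStudy, level: float = 0.95) -> Interval:
    """Fisher r-to-z confidence interval for a correlation.

    Bounds are ``tanh(atanh(r) +/- z * 1/sqrt(n-3))`` and always lie
    strictly inside (-1, 1); for r != 0 the interval is asymmetric about r.
    """
    _check_level(level)
    z = math.atanh(study.r)
    half = _z_crit(level) / math.sqrt(study.n - 3)
    return Interval(math.tanh(z - half), math.tanh(z + half), level)


def zou_combine(point: float, ci_orig: Interval, ci_rep: Interval) -> Interval:
    """Combine two confidence intervals around the same estimate into a
    prediction interval via Zou's modified asymptotic method.

    With original CI ``(l1, u1)`` and replication CI ``(l2, u2)``, both
    built around ``point``::

        LL = point - sqrt((point - l1)^2 + (u2 - point)^2)
        UL = point + sqrt((point - l2)^2 + (u1 - point)^2)

    The quadrature of the one-sided arms preserves any asymmetry of the
    component intervals.  Both inputs must contain ``point``; violating
    that indicates a caller bug, not a data pathology.
    """
    if not ci_orig.contains(point):
        raise ValueError(
            f"point {point} lies outside the original-study interval "
            f"[{ci_orig.lower}, {ci_orig.upper}]"
        )
    if not ci_rep.contains(point):
        raise ValueError(
            f"point {point} lies outside the replication interval "
            f"[{ci_rep.lower}, {ci_rep.upper}]"
        )
    if ci_orig.level != ci_rep.level:
        raise ValueError("component intervals must share a confidence level")
    lower = point - math.hypot(point - ci_orig.lower, ci_rep.upper - point)
    upper = point + math.hypot(point - ci_rep.lower, ci_orig.upper - point)
    return Interval(lower, upper, ci_orig.level)


def correlation_pi(
    study: CorrelationStudy, plan: ReplicationPlan, level: float = 0.95
) -> Interval:
    """Prediction interval for a replication correlation (Zou combination).

    Builds a Fisher CI around the original r at the original n and a second
    Fisher CI around the same r at the replication n (the original r is the
    best available estimate of the replication r), then combines them with
    :func:`zou_combine`.  Bounds are reported as computed — they are not
    clamped to (-1, 1); a warning is emitted in the rare configurations
    where a bound escapes the parameter range.
    """
    n_rep = plan.single_n(minimum=4)
    ci_orig = fisher_ci(study, level)
    ci_rep = fisher_ci(CorrelationStudy(study.r, n_rep), level)
    interval = zou_combine(study.r, ci_orig, ci_rep)
    if interval.lower < -1 or interval.upper > 1:
        warnings.warn(
            "correlation prediction interval extends beyond (-1, 1); "
            "bounds are reported unclamped",
            stacklevel=2,
        )
    return interval


def correlation_pi_simple(
    study: CorrelationStudy, plan: ReplicationPlan, level: float = 0.95
) -> Interval:
    """Simple-asymptotic prediction interval for a correlation.

    ``r +/- z * sqrt((1-r^2)^2/(N1-1) + (1-r^2)^2/(N2-1))`` — a symmetric
    normal-theory interval that ignores the skew of the sampling
    distribution of r.  Provided for comparison; increasingly inaccurate as
    |r| grows, where :func:`correlation_pi` should be preferred.
    """
    _check_level(level)
    n_rep = plan.single_n(minimum=4)
    v = (1.0 - study.r**2) ** 2
    se = math.sqrt(v / (study.n - 1) + v / (n_rep - 1))
    half = _z_crit(level) * se
    return Interval(study.r - half, study.r + half, level)


def correlation_pi_rtoz(
    study: CorrelationStudy, plan: ReplicationPlan, level: float = 0.95
) -> Interval:
    """Prediction interval computed on the Fisher z scale.

    Applies the simple asymptotic method to ``atanh(r)`` with variance
    ``1/(N1-3) + 1/(N2-3)`` and maps the bounds back through ``tanh``, so
    the result is asymmetric on the r scale and confined to (-1, 1).
    """
    _check_level(level)
    n_rep = plan.single_n(minimum=4)
    z = math.atanh(study.r)
    half = _z_crit(level) * math.sqrt(
        1.0 / (study.n - 3) + 1.0 / (n_rep - 3)
    )
    return Interval(math.tanh(z - half), math.tanh(z + half), level)


# ---------------------------------------------------------------------------
# Standardized mean differences
# ---------------------------------------------------------------------------

def d_to_t(d: float, n1: int, n2: int) -> float:
    """Convert a pooled-SD d to the observed two-sample t statistic,
    ``t = d / sqrt(1/n1 + 1/n2)``."""
    return d / math.sqrt(1.0 / n1 + 1.0 / n2)


def noncentral_t_ncp(t_obs: float, df: float, prob: float) -> float:
    """Noncentrality parameter at which ``t_obs`` sits at quantile ``prob``.

    Solves ``nct.cdf(t_obs; df, ncp) == prob`` for ncp with bracketed
    root-finding.  The CDF is strictly decreasing in ncp, so the root is
    unique; the bracket ``t_obs -/+ (10*max(1, |t_obs|) + 10)`` comfortably
    covers any level a caller can request.

    Raises
    ------
    RuntimeError
        If the bracket does not straddle the root or the root finder fails
        to converge at absolute tolerance 1e-8.
    """
    pad = 10.0 * max(1.0, abs(t_obs)) + 10.0
    lo, hi = t_obs - pad, t_obs + pad

    def f(ncp: float) -> float:
        c = stats.nct.cdf(t_obs, df, ncp)
        if math.isnan(c):
            # scipy underflows deep in the tails; the CDF is ~0 when the
            # noncentrality sits far above t_obs and ~1 far below it
            c = 0.0 if ncp > t_obs else 1.0
        return c - prob

    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo > 0 > f_hi):
        raise RuntimeError(
            f"noncentrality bracket [{lo}, {hi}] does not straddle the "
            f"target quantile {prob} for t={t_obs}, df={df}"
        )
    try:
        return float(optimize.brentq(f, lo, hi, xtol=_NCP_TOL))
    except Exception as exc:  # pragma: no cover - scipy failure diagnostics
        raise RuntimeError(
            f"noncentral-t inversion failed for t={t_obs}, df={df}, "
            f"prob={prob}: {exc}"
        ) from exc


def d_ci_noncentral(study: DStudy, level: float = 0.95) -> Interval:
    """Noncentral-t confidence interval for a standardized mean difference.

    The observed d is converted to a t statistic, the noncentrality
    parameters whose distributions place that t at the upper and lower tail
    quantiles are found numerically, and the bounds are mapped back to the
    d scale.  Asymmetric about d whenever d != 0.
    """
    _check_level(level)
    scale = math.sqrt(1.0 / study.n1 + 1.0 / study.n2)
    t_obs = study.d / scale
    alpha = 1.0 - level
    ncp_upper = noncentral_t_ncp(t_obs, study.df, alpha / 2.0)
    ncp_lower = noncentral_t_ncp(t_obs, study.df, 1.0 - alpha / 2.0)
    return Interval(ncp_lower * scale, ncp_upper * scale, level)


def d_pi(study: DStudy, plan: ReplicationPlan, level: float = 0.95) -> Interval:
    """Prediction interval for a replication d-value.

    Noncentral-t CIs are built around the original d at the original cell
    sizes and at the planned replication cell sizes (the original d stands
    in for the unknown replication d), then combined with
    :func:`zou_combine` on the d scale.
    """
    n1_rep, n2_rep = plan.cell_ns()
    ci_orig = d_ci_noncentral(study, level)
    ci_rep = d_ci_noncentral(DStudy(study.d, n1_rep, n2_rep), level)
    return zou_combine(study.d, ci_orig, ci_rep)


def d_unbiased(d: float, df: int) -> float:
    """Hedges small-sample correction, ``d * (1 - 3 / (4*df - 1))``.

    Removes (approximately) the positive bias of the pooled-SD d; the
    adjustment shrinks toward the identity as df grows.  ``df`` is the
    pooled degrees of freedom ``n1 + n2 - 2``.
    """
    if df < 1:
        raise ValueError(f"df must be at least 1, got {df!r}")
    return d * (1.0 - 3.0 / (4.0 * df - 1.0))
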