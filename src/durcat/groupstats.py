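"""Between-group inference: pooled t tests, Cohen's d, JZS Bayes factors,
normality diagnostics, and power.

Frequentist comparisons use the pooled-variance (Student) two-sample t test.
Each comparison is accompanied by a base-10 log Bayes factor (LBF) under the
default JZS prior — a Cauchy prior with scale r on the standardized effect
size, equivalently a zero-mean normal prior with variance g where g follows
an inverse-chi-square(1) mixing density scaled by r^2.  The default scale is
r = sqrt(2)/2.  Conventionally |LBF| > 0.5, 1, 2 mark substantial, strong
and definitive evidence (positive: for a group difference; negative: for
the null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "DEFAULT_PRIOR_SCALE",
    "GroupSummary",
    "GroupComparison",
    "pooled_t_test",
    "cohens_d",
    "jzs_log10_bf",
    "evidence_category",
    "compare_groups",
    "shapiro_wilk",
    "required_sample_size",
]

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group on one measure: n, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2 per group, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_samples(cls, x) -> "GroupSummary":
        x = np.asarray(x, float)
        x = x[~np.isnan(x)]
        return cls(n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: t, df, two-tailed p, Cohen's d, log10 BF."""

    t: float
    df: int
    p: float
    cohen_d: float
    lbf: float
    alpha: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    @property
    def evidence(self) -> str:
        return evidence_category(self.lbf)


def _as_summary(g) -> GroupSummary:
    return g if isinstance(g, GroupSummary) else GroupSummary.from_samples(g)


def _pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    df = g1.n + g2.n - 2
    return math.sqrt(((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df)


def pooled_t_test(g1, g2) -> tuple[float, int, float]:
    """Pooled-variance Student t test from samples or group summaries.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2 and a two-tailed p from
    the central t distribution.
    """
    g1, g2 = _as_summary(g1), _as_summary(g2)
    df = g1.n + g2.n - 2
    sp = _pooled_sd(g1, g2)
    se = sp * math.sqrt(1.0 / g1.n + 1.0 / g2.n)
    if se == 0:
        t = 0.0 if g1.mean == g2.mean else math.inf
    else:
        t = (g1.mean - g2.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), int(df), p


def cohens_d(g1, g2) -> float:
    """Pooled-SD standardized mean difference (m1 - m2) / s_pooled."""
    g1, g2 = _as_summary(g1), _as_summary(g2)
    sp = _pooled_sd(g1, g2)
    if sp == 0:
        raise ValueError("zero pooled SD: d undefined")
    return float((g1.mean - g2.mean) / sp)


def jzs_log10_bf(t: float, n1: int, n2: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """log10 JZS Bayes factor (BF10) for a two-sample design.

    Marginalizes the alternative over the JZS prior by one-dimensional
    quadrature on the mixing variance g (substituting g = e^u so the
    integrand is evaluated in log space and stays finite for |t| well
    beyond 12), with effective sample size N = n1*n2/(n1+n2) and
    df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if r <= 0:
        raise ValueError("prior scale r must be > 0")
    t = float(t)
    nu = n1 + n2 - 2
    N = n1 * n2 / (n1 + n2)
    t2 = t * t

    def log_integrand(u: float) -> float:
        g = math.exp(u)
        # inverse-gamma(1/2, r^2/2) density on g, times the marginal t kernel
        log_prior = 0.5 * math.log(r * r / (2.0 * math.pi)) - 1.5 * u - r * r / (2.0 * g)
        log_kernel = -0.5 * math.log1p(N * g) - (nu + 1) / 2.0 * math.log1p(
            t2 / ((1.0 + N * g) * nu)
        )
        return log_prior + log_kernel + u  # + u: Jacobian of g = e^u

    # peak-shifted quadrature keeps exp() in range for extreme t
    us = np.linspace(-40.0, 40.0, 81)
    shift = max(log_integrand(u) for u in us)
    num, err = integrate.quad(
        lambda u: math.exp(log_integrand(u) - shift), -40.0, 40.0, limit=400
    )
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * num:
        raise RuntimeError(
            f"JZS integration did not converge (integral={num}, abserr={err})"
        )
    log_num = math.log(num) + shift
    log_den = -(nu + 1) / 2.0 * math.log1p(t2 / nu)
    return float((log_num - log_den) / math.log(10.0))


_EVIDENCE_BINS = (
    (2.0, "definitive H1"),
    (1.0, "strong H1"),
    (0.5, "substantial H1"),
)


def evidence_category(lbf: float) -> str:
    """Map a log10 Bayes factor to the conventional evidence label.

    Thresholds at |LBF| = 0.5, 1, 2; a value exactly on a boundary is
    assigned to the weaker category (e.g. 0.5 -> "anecdotal").
    """
    if not np.isfinite(lbf):
        raise ValueError("lbf must be finite")
    a = abs(lbf)
    side = "H1" if lbf > 0 else "H0"
    if a > 2.0:
        return f"definitive {side}"
    if a > 1.0:
        return f"strong {side}"
    if a > 0.5:
        return f"substantial {side}"
    return "anecdotal"


def compare_groups(
    g1,
    g2,
    alpha: float = 0.05,
    r: float = DEFAULT_PRIOR_SCALE,
) -> GroupComparison:
    """Full two-group comparison: pooled t, Cohen's d, and log10 JZS BF."""
    s1, s2 = _as_summary(g1), _as_summary(g2)
    t, df, p = pooled_t_test(s1, s2)
    d = cohens_d(s1, s2)
    lbf = jzs_log10_bf(t, s1.n, s2.n, r=r)
    return GroupComparison(t=t, df=df, p=p, cohen_d=d, lbf=lbf, alpha=alpha, n1=s1.n, n2=s2.n)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test (Royston's approximation), 3 <= n <= 5000.

    Reported as a diagnostic alongside parametric tests, not used as a gate.
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: W undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.85) -> int:
    """Smallest per-group n giving the two-sample pooled t test the requested
    power against effect size d, via the noncentral t distribution
    (noncentrality d * sqrt(n/2), df = 2n - 2)."""
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not (0 < power < 1):
        raise ValueError("power must be in (0, 1)")
    for n in range(2, 1_000_001):
        df = 2 * n - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        nc = d * math.sqrt(n / 2.0)
        achieved = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return n
    raise ValueError("requested power unreachable below n = 1e6 per group")
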