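"""Cumulative-Gaussian psychometric fitting and threshold estimation.

The proportion of "long" responses is modelled as a function of log10
duration with a two-parameter cumulative Gaussian,

    p(d) = Phi((log10 d - mu) / sigma),

fitted by binomial maximum likelihood (asymptotes fixed at 0 and 1).  The
derived quantities are the field's standard summaries:

* PSE  = 10**mu — the duration judged "long" half the time (accuracy);
* JND  = z75 * sigma — the log10-axis span between the 50% and 75% points;
* Weber fraction Wf = 10**JND - 1 — unitless sensory precision (precision).

Binomial ML is used because each point of the curve is a small binomial
count (4 trials per duration in the standard design), for which a Gaussian
least-squares error model would be misspecified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

from .observer import Z75

__all__ = [
    "ProportionTable",
    "PsychometricFit",
    "BootstrapCI",
    "aggregate_proportions",
    "fit_cumulative_gaussian",
    "fit_participant",
    "fit_aggregate",
    "bootstrap_fit_ci",
]

SIGMA_BOUNDS = (1e-3, 2.0)


@dataclass(frozen=True)
class ProportionTable:
    """Per-duration counts of "long" responses out of trials presented."""

    durations: np.ndarray  # seconds, unique, increasing
    n: np.ndarray  # trials per duration
    k: np.ndarray  # "long" responses per duration

    def __post_init__(self) -> None:
        d, n, k = (np.asarray(a) for a in (self.durations, self.n, self.k))
        if len(d) == 0:
            raise ValueError("empty proportion table")
        if np.any(np.diff(d) <= 0):
            raise ValueError("durations must be unique and increasing")
        if np.any(d <= 0):
            raise ValueError("durations must be positive")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= k <= n in every row")

    @property
    def n_trials(self) -> int:
        return int(np.sum(self.n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"duration_s": self.durations, "n": self.n, "k_long": self.k}
        )


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted curve parameters and derived thresholds.

    ``mu``/``sigma`` are in log10-duration units.  Derived fields satisfy
    pse = 10**mu, jnd = z75*sigma, weber = 10**jnd - 1 exactly.  For a
    non-convergent fit (degenerate data or optimizer failure) ``converged``
    is False and all parameter fields are NaN.
    """

    mu: float
    sigma: float
    pse: float
    jnd: float
    weber: float
    loglik: float
    n_trials: int
    converged: bool

    @classmethod
    def failed(cls, n_trials: int) -> "PsychometricFit":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, n_trials, False)

    @classmethod
    def from_params(
        cls, mu: float, sigma: float, loglik: float, n_trials: int, converged: bool = True
    ) -> "PsychometricFit":
        jnd = Z75 * sigma
        return cls(
            mu=float(mu),
            sigma=float(sigma),
            pse=float(10.0**mu),
            jnd=float(jnd),
            weber=float(10.0**jnd - 1.0),
            loglik=float(loglik),
            n_trials=int(n_trials),
            converged=bool(converged),
        )


def aggregate_proportions(trials: pd.DataFrame) -> ProportionTable:
    """Tally "long" responses per distinct duration of a trial table."""
    if len(trials) == 0:
        raise ValueError("no trials to aggregate")
    bad = ~trials["response"].isin(["short", "long"])
    if bad.any():
        raise ValueError(
            f"unknown response token(s) at rows {list(trials.index[bad][:5])}"
        )
    g = (
        trials.assign(is_long=(trials["response"] == "long").astype(int))
        .groupby("duration_s", sort=True)["is_long"]
        .agg(["count", "sum"])
    )
    return ProportionTable(
        durations=g.index.to_numpy(float),
        n=g["count"].to_numpy(int),
        k=g["sum"].to_numpy(int),
    )


def binomial_loglik(mu: float, sigma: float, tab: ProportionTable) -> float:
    """Binomial log-likelihood (up to the fixed combinatorial constant)."""
    z = (np.log10(tab.durations) - mu) / sigma
    return float(np.sum(tab.k * log_ndtr(z) + (tab.n - tab.k) * log_ndtr(-z)))


def _neg_loglik(params: np.ndarray, logd: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    mu, sigma = params
    z = (logd - mu) / sigma
    return -float(np.sum(k * log_ndtr(z) + (n - k) * log_ndtr(-z)))


def fit_cumulative_gaussian(
    tab: ProportionTable,
    mu_bounds: tuple[float, float] | None = None,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
) -> PsychometricFit:
    """Maximum-likelihood fit of the cumulative Gaussian to a count table.

    Degenerate tables (all responses "short" or all "long") carry no
    information about the curve's location and are returned as flagged,
    non-convergent fits; downstream stages must exclude and log them.

    Initialization: ``mu0`` at the log10 geometric mean of the tested
    durations, ``sigma0`` at a quarter of the tested log10 span; L-BFGS-B
    with a 1e-8 objective tolerance, with a coarse grid restart if the
    first solve fails or pins sigma at a bound.
    """
    if len(tab.durations) < 3:
        raise ValueError("need at least 3 distinct durations to fit")
    ktot = int(np.sum(tab.k))
    if ktot == 0 or ktot == tab.n_trials:
        return PsychometricFit.failed(tab.n_trials)

    logd = np.log10(tab.durations)
    if mu_bounds is None:
        mu_bounds = (logd[0] - 0.5, logd[-1] + 0.5)
    mu0 = 0.5 * (logd[0] + logd[-1])
    sigma0 = (logd[-1] - logd[0]) / 4.0
    n = np.asarray(tab.n, float)
    k = np.asarray(tab.k, float)

    def solve(x0):
        return minimize(
            _neg_loglik,
            x0,
            args=(logd, n, k),
            method="L-BFGS-B",
            bounds=[mu_bounds, sigma_bounds],
            options={"ftol": 1e-8, "gtol": 1e-10, "maxiter": 500},
        )

    res = solve(np.array([mu0, np.clip(sigma0, *sigma_bounds)]))
    # multistart safeguard: the likelihood can be multimodal enough for a
    # single gradient descent to stall in a shallow local optimum, so always
    # polish a second start from the best point of a coarse grid and keep
    # whichever solution is better
    mus = np.linspace(*mu_bounds, 25)
    sigmas = np.geomspace(sigma_bounds[0], sigma_bounds[1], 25)
    M, S = np.meshgrid(mus, sigmas, indexing="ij")
    z = (logd[None, None, :] - M[..., None]) / S[..., None]
    ll = np.sum(k * log_ndtr(z) + (n - k) * log_ndtr(-z), axis=-1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    res2 = solve(np.array([mus[i], sigmas[j]]))
    if res2.fun < res.fun or (not res.success and res2.success):
        res = res2
    sigma_at_bound = (
        res.x[1] <= sigma_bounds[0] * (1 + 1e-9) or res.x[1] >= sigma_bounds[1] * (1 - 1e-9)
    )
    converged = bool(res.success) and not sigma_at_bound
    if not converged:
        return PsychometricFit.failed(tab.n_trials)
    mu, sigma = res.x
    return PsychometricFit.from_params(mu, sigma, -res.fun, tab.n_trials, True)


def fit_participant(trials: pd.DataFrame) -> PsychometricFit:
    """Fit one participant's trials in one timing range."""
    for col in ("participant_id", "range"):
        if col in trials.columns and trials[col].nunique() > 1:
            raise ValueError(f"trials span multiple values of {col!r}; fit them separately")
    return fit_cumulative_gaussian(aggregate_proportions(trials))


def fit_aggregate(trials: pd.DataFrame) -> PsychometricFit:
    """Fit the pooled trials of many participants (one curve per group/range)."""
    if "range" in trials.columns and trials["range"].nunique() > 1:
        raise ValueError("aggregate fits must not pool across timing ranges")
    return fit_cumulative_gaussian(aggregate_proportions(trials))


@dataclass(frozen=True)
class BootstrapCI:
    """Nonparametric percentile intervals for PSE and Weber fraction."""

    pse_lo: float
    pse_hi: float
    weber_lo: float
    weber_hi: float
    n_boot: int
    n_failed: int
    reliable: bool


def bootstrap_fit_ci(
    trials: pd.DataFrame, n_boot: int, seed: int, level: float = 0.95
) -> BootstrapCI:
    """Resample trials with replacement, refit, take percentile bounds.

    Replicates whose refit does not converge are dropped and counted; if
    more than 20% fail the interval is flagged unreliable.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    base = fit_participant(trials)
    if not base.converged:
        raise ValueError("base fit did not converge; no bootstrap interval")
    rng = np.random.default_rng(seed)
    m = len(trials)
    pses, webers = [], []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        rep = fit_cumulative_gaussian(
            aggregate_proportions(trials.iloc[idx].reset_index(drop=True))
        )
        if rep.converged:
            pses.append(rep.pse)
            webers.append(rep.weber)
        else:
            failed += 1
    if not pses:
        return BootstrapCI(*(float("nan"),) * 4, n_boot, failed, False)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    pse_lo, pse_hi = np.percentile(pses, [lo, hi])
    w_lo, w_hi = np.percentile(webers, [lo, hi])
    return BootstrapCI(
        float(pse_lo),
        float(pse_hi),
        float(w_lo),
        float(w_hi),
        n_boot,
        failed,
        failed <= 0.2 * n_boot,
    )
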