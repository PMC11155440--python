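"""Generative observer model and synthetic-cohort simulation.

An observer categorizes a sound of duration ``d`` as "long" with probability

    p(d) = lapse/2 + (1 - lapse) * Phi((log10 d - log10 pse) / sigma)

where ``pse`` is the point of subjective equality (the subjective category
boundary, in seconds), ``sigma`` is the spread of the internal duration
representation on the log10 axis, and ``lapse`` is a stimulus-independent
error rate (default 0, matching the two-parameter fitting model).  ``sigma``
is parameterized through the Weber fraction Wf = 10**JND - 1 with
JND = z75 * sigma, the span between the 50% and 75% points of the curve on
the log10 axis.

The cohort simulator draws per-participant parameters from group-level
distributions (a dyscalculic-like group with high Weber fractions and a
control-like group with low ones), runs a full method-of-constant-stimuli
session per timing range, and emits tidy trial and metadata tables — the
contract consumed by every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import RangeSpec, SUBSECOND, SECOND, build_duration_set, build_trial_schedule

__all__ = [
    "Z75",
    "WEBER_FLOOR",
    "ObserverParams",
    "RangeMoments",
    "GroupSpec",
    "CohortSpec",
    "STUDY_COHORT",
    "sigma_from_weber",
    "weber_from_sigma",
    "p_long",
    "simulate_session",
    "simulate_cohort",
]

#: 75th percentile of the standard normal; converts sigma (log10 units) to JND.
Z75 = float(norm.ppf(0.75))

#: Lower truncation bound for Weber-fraction draws (avoids degenerate step observers).
WEBER_FLOOR = 0.01


def sigma_from_weber(weber: float) -> float:
    """Spread of the log10-duration representation implied by a Weber fraction.

    Inverts Wf = 10**(z75 * sigma) - 1.  Exact inverse of
    :func:`weber_from_sigma`.
    """
    weber = float(weber)
    if weber <= 0:
        raise ValueError(f"weber must be > 0, got {weber}")
    return float(np.log10(1.0 + weber) / Z75)


def weber_from_sigma(sigma: float) -> float:
    """Weber fraction 10**(z75*sigma) - 1 implied by a log10-axis spread."""
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return float(10.0 ** (Z75 * sigma) - 1.0)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant."""

    id: str
    group: str
    pse: float
    weber: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.pse <= 0:
            raise ValueError(f"pse must be > 0, got {self.pse}")
        if self.weber <= 0:
            raise ValueError(f"weber must be > 0, got {self.weber}")
        if not (0 <= self.lapse < 0.5):
            raise ValueError(f"lapse must be in [0, 0.5), got {self.lapse}")

    @property
    def sigma(self) -> float:
        return sigma_from_weber(self.weber)


def p_long(duration, obs: ObserverParams):
    """Probability of a "long" response at one or more durations (seconds)."""
    d = np.asarray(duration, dtype=float)
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    z = (np.log10(d) - np.log10(obs.pse)) / obs.sigma
    p = obs.lapse / 2.0 + (1.0 - obs.lapse) * norm.cdf(z)
    return p if p.ndim else float(p)


def simulate_session(obs: ObserverParams, schedule, seed: int) -> pd.DataFrame:
    """Bernoulli-sample one session of the schedule; deterministic per seed.

    Returns a tidy frame with one row per trial: participant_id, group,
    range, trial_index, duration_s, response.
    """
    rng = np.random.default_rng(seed)
    d = schedule.durations
    p = p_long(d, obs)
    long_resp = rng.random(len(d)) < p
    return pd.DataFrame(
        {
            "participant_id": obs.id,
            "group": obs.group,
            "range": schedule.stimulus_set.range_spec.name,
            "trial_index": np.arange(len(d)),
            "duration_s": d,
            "response": np.where(long_resp, "long", "short"),
        }
    )


@dataclass(frozen=True)
class RangeMoments:
    """Target distribution of one group's parameters in one timing range.

    ``weber_mean``/``weber_sd`` describe a normal truncated below at
    :data:`WEBER_FLOOR`; ``pse_mean``/``pse_sd`` set the median and
    coefficient of variation of a log-normal PSE distribution.
    """

    weber_mean: float
    weber_sd: float
    pse_mean: float
    pse_sd: float

    def __post_init__(self) -> None:
        if self.weber_mean <= 0 or self.pse_mean <= 0:
            raise ValueError("means must be > 0")
        if self.weber_sd < 0 or self.pse_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    moments: Mapping[str, RangeMoments]  # keyed by range name

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class CohortSpec:
    """Two (or more) groups of simulated observers plus the master seed."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    lapse: float = 0.0

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


def _study_cohort(n_control: int = 22, n_dd: int = 15, seed: int = 0) -> CohortSpec:
    # Group moments match the study's per-range Weber-fraction and PSE
    # summaries (mean (SD)); groups differ only in Weber fraction.
    control = GroupSpec(
        "control",
        n_control,
        {
            "subsecond": RangeMoments(0.13, 0.05, 0.56, 0.10),
            "second": RangeMoments(0.14, 0.07, 1.5, 0.3),
        },
    )
    dd = GroupSpec(
        "DD",
        n_dd,
        {
            "subsecond": RangeMoments(0.24, 0.15, 0.56, 0.10),
            "second": RangeMoments(0.22, 0.10, 1.6, 0.3),
        },
    )
    return CohortSpec(groups=(dd, control), seed=seed)


#: Default cohort: 15 DD-like vs 22 control-like observers with the study's
#: group-level Weber-fraction and PSE moments in both timing ranges.
STUDY_COHORT = _study_cohort()


def study_cohort(n_control: int = 22, n_dd: int = 15, seed: int = 0) -> CohortSpec:
    """The default study-matched cohort spec with configurable sizes and seed."""
    return _study_cohort(n_control=n_control, n_dd=n_dd, seed=seed)


def _draw_weber(m: RangeMoments, rng: np.random.Generator) -> float:
    """Normal draw truncated below at WEBER_FLOOR, by rejection."""
    if m.weber_sd == 0:
        if m.weber_mean < WEBER_FLOOR:
            raise ValueError("degenerate spec: weber mean below truncation floor")
        return m.weber_mean
    trunc_mass = norm.cdf((WEBER_FLOOR - m.weber_mean) / m.weber_sd)
    if trunc_mass > 0.5:
        raise ValueError(
            f"degenerate spec: truncation at {WEBER_FLOOR} removes "
            f"{trunc_mass:.0%} of the Weber distribution"
        )
    while True:
        w = rng.normal(m.weber_mean, m.weber_sd)
        if w >= WEBER_FLOOR:
            return float(w)


def _draw_pse(m: RangeMoments, rng: np.random.Generator) -> float:
    """Log-normal PSE: median pse_mean, coefficient of variation pse_sd/pse_mean."""
    if m.pse_sd == 0:
        return m.pse_mean
    cv = m.pse_sd / m.pse_mean
    s = np.sqrt(np.log1p(cv**2))
    return float(m.pse_mean * np.exp(rng.normal(0.0, s)))


# Descriptive targets for the synthetic metadata table, per group:
# (age mean, age sd, age range), P(female), math-z (mean, sd),
# non-verbal-z (mean, sd), reading-z (mean, sd), fraction with reading scores.
_METADATA_MOMENTS = {
    "control": dict(
        age=(11.0, 2.2, (8, 16)),
        p_female=12 / 22,
        math=(0.0, 0.8),
        nonverbal=(0.6, 0.55),
        reading=(0.2, 0.8),
        reading_frac=9 / 22,
    ),
    "DD": dict(
        age=(10.0, 2.0, (8, 15)),
        p_female=8 / 15,
        math=(-2.3, 0.7),
        nonverbal=(0.7, 0.6),
        reading=(-3.3, 2.4),
        reading_frac=11 / 15,
    ),
}


def _draw_metadata(pid: str, group: str, rng: np.random.Generator) -> dict:
    m = _METADATA_MOMENTS.get(group, _METADATA_MOMENTS["control"])
    lo, hi = m["age"][2]
    age = float(np.clip(rng.normal(m["age"][0], m["age"][1]), lo, hi))
    has_reading = rng.random() < m["reading_frac"]
    row = {
        "participant_id": pid,
        "group": group,
        "age_years": round(age, 1),
        "gender": "F" if rng.random() < m["p_female"] else "M",
        "nonverbal_z": round(float(rng.normal(*m["nonverbal"])), 3),
        "math_z": round(float(rng.normal(*m["math"])), 3),
        "reading_word_z": np.nan,
        "reading_nonword_z": np.nan,
    }
    if has_reading:
        mu, sd = m["reading"]
        row["reading_word_z"] = round(float(rng.normal(mu, sd)), 3)
        row["reading_nonword_z"] = round(float(rng.normal(mu, sd)), 3)
    return row


def simulate_cohort(
    spec: CohortSpec,
    ranges: Iterable[RangeSpec] = (SUBSECOND, SECOND),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every participant of a cohort through every timing range.

    Returns ``(trials, metadata)``: the tidy trial table (one row per
    categorization trial) and the participant metadata table.  Fully
    reproducible from ``(spec, ranges)`` — all randomness descends from
    ``spec.seed`` via a spawned seed sequence.
    """
    ranges = list(ranges)
    stim_sets = {r.name: build_duration_set(r) for r in ranges}
    param_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))

    trial_frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    counter = 0
    for g in spec.groups:
        for i in range(g.n):
            pid = f"{g.name}{i + 1:03d}"
            meta_rows.append(_draw_metadata(pid, g.name, param_rng))
            for r in ranges:
                if r.name not in g.moments:
                    continue
                m = g.moments[r.name]
                obs = ObserverParams(
                    id=pid,
                    group=g.name,
                    pse=_draw_pse(m, param_rng),
                    weber=_draw_weber(m, param_rng),
                    lapse=spec.lapse,
                )
                counter += 1
                sched_seed = int(
                    np.random.SeedSequence((spec.seed, counter, 1)).generate_state(1)[0]
                    % (2**31)
                )
                resp_seed = int(
                    np.random.SeedSequence((spec.seed, counter, 2)).generate_state(1)[0]
                    % (2**31)
                )
                schedule = build_trial_schedule(stim_sets[r.name], sched_seed)
                trial_frames.append(simulate_session(obs, schedule, resp_seed))
    trials = pd.concat(trial_frames, ignore_index=True)
    metadata = pd.DataFrame(meta_rows)
    return trials, metadata
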