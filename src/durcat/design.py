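"""Stimulus-set construction for the auditory duration-categorization task.

The task is a method of constant stimuli: a timing range is sampled into
``n_steps`` durations spaced uniformly on a log axis (spanning one octave on
either side of the range's geometric mean, i.e. a total factor of 4), each
presented ``reps`` times in random order.  Before testing, the observer hears
four anchor sounds — the two extremes of the range, twice each — that define
what "short" and "long" mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RangeSpec",
    "StimulusSet",
    "TrialSchedule",
    "SUBSECOND",
    "SECOND",
    "BUILTIN_RANGES",
    "build_duration_set",
    "build_trial_schedule",
]


@dataclass(frozen=True)
class RangeSpec:
    """One timing range of the categorization task.

    Parameters
    ----------
    name : str
        Range label, e.g. ``"subsecond"`` or ``"second"``.
    d_min, d_max : float
        Shortest and longest durations, in seconds.
    n_steps : int
        Number of distinct test durations (log-uniformly spaced).
    reps : int
        Repetitions of each duration within a session.
    """

    name: str
    d_min: float
    d_max: float
    n_steps: int = 11
    reps: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError(
                f"need 0 < d_min < d_max, got d_min={self.d_min}, d_max={self.d_max}"
            )
        if self.n_steps < 3:
            raise ValueError(f"n_steps must be >= 3, got {self.n_steps}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")

    @property
    def geometric_mean(self) -> float:
        """Nominal reference duration of the range, sqrt(d_min * d_max)."""
        return float(np.sqrt(self.d_min * self.d_max))

    @property
    def n_trials(self) -> int:
        return self.n_steps * self.reps


#: Sub-second range: 0.25–1 s, reference 0.5 s, 11 durations x 4 reps = 44 trials.
SUBSECOND = RangeSpec("subsecond", 0.25, 1.0, 11, 4)
#: Supra-second range: 0.75–3 s, reference 1.5 s, 11 durations x 4 reps = 44 trials.
SECOND = RangeSpec("second", 0.75, 3.0, 11, 4)

BUILTIN_RANGES: dict[str, RangeSpec] = {r.name: r for r in (SUBSECOND, SECOND)}


@dataclass(frozen=True)
class StimulusSet:
    """The ordered durations of one range plus its four anchor sounds."""

    range_spec: RangeSpec
    durations: np.ndarray
    anchors: tuple[tuple[float, str], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": np.arange(len(self.durations)), "duration_s": self.durations}
        )


@dataclass(frozen=True)
class TrialSchedule:
    """A seeded random ordering of the reps-fold multiset of durations."""

    stimulus_set: StimulusSet
    durations: np.ndarray  # one entry per trial, in presentation order
    seed: int

    def __len__(self) -> int:
        return len(self.durations)

    @property
    def trials(self) -> list[tuple[int, float]]:
        return list(enumerate(self.durations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial_index": np.arange(len(self)), "duration_s": self.durations}
        )


def build_duration_set(spec: RangeSpec) -> StimulusSet:
    """Build the log-uniformly spaced duration set of a range.

    The i-th duration is ``d_min * (d_max/d_min)**(i/(n_steps-1))``, so the
    set is strictly increasing, has equal consecutive ratios, and its
    geometric mean equals that of the range.  Anchors are two presentations
    of ``d_min`` (labelled "short") followed by two of ``d_max`` ("long").
    """
    n = spec.n_steps
    exponents = np.arange(n) / (n - 1)
    durations = spec.d_min * (spec.d_max / spec.d_min) ** exponents
    # guard endpoint roundoff so first/last are exactly the bounds
    durations[0] = spec.d_min
    durations[-1] = spec.d_max
    durations.setflags(write=False)
    anchors = (
        (spec.d_min, "short"),
        (spec.d_min, "short"),
        (spec.d_max, "long"),
        (spec.d_max, "long"),
    )
    return StimulusSet(range_spec=spec, durations=durations, anchors=anchors)


def build_trial_schedule(stim: StimulusSet, seed: int) -> TrialSchedule:
    """Randomly order ``reps`` copies of each duration; deterministic per seed."""
    reps = stim.range_spec.reps
    multiset = np.repeat(stim.durations, reps)
    rng = np.random.default_rng(seed)
    order = rng.permutation(multiset)
    order.setflags(write=False)
    return TrialSchedule(stimulus_set=stim, durations=order, seed=seed)
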