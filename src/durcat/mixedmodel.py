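"""Repeated-measures group analysis: random-intercept model via the classical
split-plot decomposition.

The study design is between-group (DD-like vs control-like) x within-subject
(two timing ranges), with one measurement per participant per range.  A
random-intercept linear mixed model on such data decomposes exactly into two
independent ordinary regressions:

* a *between* part on each participant's mean across ranges, which carries
  the group effect and any participant-level covariates;
* a *within* part on each participant's between-range difference, which
  carries the range main effect (the intercept, with groups effect-coded so
  it is the unweighted mean across groups) and the group x range interaction.

On balanced complete data the resulting F tests equal the classical
split-plot ANOVA.  Denominator degrees of freedom follow the split-plot
convention: between terms use N_participants - p_between; within terms use
N_complete - 2.  Participants measured in only one range contribute to the
between part (their available measurement is their mean) but are excluded
from the within part.  Covariates enter as participant-level main effects
only, so they cancel from within-participant differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FTest", "MixedModelResult", "mixed_model_anova"]


@dataclass(frozen=True)
class FTest:
    f: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class MixedModelResult:
    """Per-term F tests plus variance components of the random-intercept fit."""

    terms: Mapping[str, FTest]
    var_participant: float
    var_residual: float
    n_participants: int
    n_complete: int
    incomplete_ids: tuple[str, ...]


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _drop_term_f(X: np.ndarray, y: np.ndarray, col: int, df_den: int) -> FTest:
    """Type-III F for one column: SSE increase when the column is dropped."""
    _, sse_full = _ols(X, y)
    Xr = np.delete(X, col, axis=1)
    _, sse_red = _ols(Xr, y)
    ms_err = sse_full / df_den
    f = max(sse_red - sse_full, 0.0) / ms_err if ms_err > 0 else np.inf
    p = float(stats.f.sf(f, 1, df_den))
    return FTest(f=float(f), df_num=1, df_den=df_den, p=p)


def mixed_model_anova(
    measures: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    value_col: str = "value",
) -> MixedModelResult:
    """Fit value ~ group + range + group:range (+ covariates) with a
    participant random intercept.

    Parameters
    ----------
    measures : DataFrame
        Long table with columns ``participant_id``, ``group``, ``range`` and
        ``value_col`` — one row per participant per range.
    metadata : DataFrame, optional
        Participant-level table (indexed or keyed by ``participant_id``)
        providing covariate columns.  ``gender`` is encoded as a two-level
        indicator; other covariates are used as numeric.
    covariates : sequence of str
        Metadata columns to partial out of the group comparison.
    """
    req = {"participant_id", "group", "range", value_col}
    missing = req - set(measures.columns)
    if missing:
        raise ValueError(f"measures table lacks columns {sorted(missing)}")
    if measures[value_col].isna().all():
        raise ValueError("all measurements missing")

    wide = measures.pivot_table(
        index="participant_id", columns="range", values=value_col, aggfunc="first"
    )
    range_levels = sorted(measures["range"].unique())
    if len(range_levels) != 2:
        raise ValueError(f"expected exactly 2 range levels, got {range_levels}")

    groups = measures.drop_duplicates("participant_id").set_index("participant_id")["group"]
    glabels = sorted(groups.unique())
    if len(glabels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {glabels}")

    if covariates:
        if metadata is None:
            raise ValueError("covariates requested but no metadata table given")
        meta = metadata.set_index("participant_id") if "participant_id" in metadata.columns else metadata

    # ---- between part: participant means over available ranges ----
    ybar = wide.mean(axis=1, skipna=True)
    pids = ybar.index.to_numpy()
    g_eff = np.where(groups.loc[pids].to_numpy() == glabels[0], 0.5, -0.5)
    cols = [np.ones(len(pids)), g_eff]
    names = ["group"]
    for c in covariates:
        v = meta.loc[pids, c]
        if v.dtype == object or str(v.dtype).startswith("category"):
            levels = sorted(v.dropna().unique())
            if len(levels) != 2:
                raise ValueError(f"covariate {c!r} must be two-level, got {levels}")
            x = np.where(v.to_numpy() == levels[0], 0.5, -0.5).astype(float)
        else:
            x = v.to_numpy(float)
        if np.isnan(x).any():
            bad = pids[np.isnan(x)]
            raise ValueError(f"covariate {c!r} missing for participants {list(bad[:5])}")
        cols.append(x)
        names.append(c)
    Xb = np.column_stack(cols)
    n_part, p_between = len(pids), Xb.shape[1]
    df_between = n_part - p_between
    if df_between < 1:
        raise ValueError("not enough participants for the between-subject design")
    yb = ybar.to_numpy(float)
    terms: dict[str, FTest] = {}
    for name, col in zip(names, range(1, p_between)):
        terms[name] = _drop_term_f(Xb, yb, col, df_between)
    _, sse_between = _ols(Xb, yb)
    ms_between = sse_between / df_between

    # ---- within part: range differences of complete participants ----
    complete = wide.dropna()
    incomplete = tuple(sorted(set(pids) - set(complete.index)))
    n_c = len(complete)
    if n_c < 3:
        raise ValueError("fewer than 3 participants with both ranges")
    diff = (complete[range_levels[1]] - complete[range_levels[0]]).to_numpy(float)
    gc = np.where(groups.loc[complete.index].to_numpy() == glabels[0], 0.5, -0.5)
    Xw = np.column_stack([np.ones(n_c), gc])
    df_within = n_c - 2
    terms["range"] = _drop_term_f(Xw, diff, 0, df_within)
    terms["group:range"] = _drop_term_f(Xw, diff, 1, df_within)
    _, sse_within = _ols(Xw, diff)
    ms_within = sse_within / df_within

    # variance components: var(diff) = 2 s2_e; var(mean) = s2_u + s2_e/2
    var_resid = ms_within / 2.0
    var_participant = max(ms_between - var_resid / 2.0, 0.0)

    return MixedModelResult(
        terms=terms,
        var_participant=float(var_participant),
        var_residual=float(var_resid),
        n_participants=n_part,
        n_complete=n_c,
        incomplete_ids=incomplete,
    )
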