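"""End-to-end study orchestration: simulate (or ingest) -> fit -> infer -> report.

A *study* is: trial-level categorization data for two groups in up to two
timing ranges, plus participant metadata.  The pipeline fits every
participant x range psychometric curve, excludes (loudly) non-convergent
fits, summarizes Weber fractions and PSEs per group, runs the group
comparisons (pooled t, Cohen's d, JZS log10 BF; Bonferroni-corrected alpha
across ranges), normality diagnostics, and the random-intercept mixed model
(plus a covariate-adjusted variant), and assembles everything into a
:class:`StudyReport` that can be written as delimited-text tables plus a
human-readable summary and a run manifest.

All numeric table output is written at full precision; rounding is applied
only in the rendered ``summary.txt``.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import BUILTIN_RANGES, SECOND, SUBSECOND, RangeSpec
from .groupstats import (
    DEFAULT_PRIOR_SCALE,
    GroupSummary,
    compare_groups,
    shapiro_wilk,
)
from .mixedmodel import MixedModelResult, mixed_model_anova
from .observer import CohortSpec, GroupSpec, RangeMoments, simulate_cohort, study_cohort
from .psychfit import aggregate_proportions, fit_cumulative_gaussian

__all__ = [
    "RunConfig",
    "StudyReport",
    "load_config",
    "run_simulation_study",
    "run_ingest_study",
    "analyze_study",
    "fit_all_participants",
]

TRIAL_COLUMNS = ["participant_id", "group", "range", "trial_index", "duration_s", "response"]
METADATA_REQUIRED = ["participant_id", "group"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs: design, cohort (or input files), seeds, knobs."""

    ranges: tuple[RangeSpec, ...] = (SUBSECOND, SECOND)
    cohort: CohortSpec | None = None
    seed: int = 0
    bf_prior_scale: float = DEFAULT_PRIOR_SCALE
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age_years", "nonverbal_z", "gender")
    outdir: str | None = None

    @property
    def alpha_per_range(self) -> float:
        """Bonferroni-corrected threshold across the tested timing ranges."""
        return self.alpha / max(len(self.ranges), 1)

    def with_seed(self, seed: int) -> "RunConfig":
        cohort = (
            dataclasses.replace(self.cohort, seed=seed) if self.cohort is not None else None
        )
        return dataclasses.replace(self, seed=seed, cohort=cohort)


def default_config(seed: int = 0, n_control: int = 22, n_dd: int = 15) -> RunConfig:
    """Study-matched default: 22 control-like vs 15 DD-like observers,
    both timing ranges, default JZS prior scale, alpha 0.05 (0.025/range)."""
    return RunConfig(cohort=study_cohort(n_control=n_control, n_dd=n_dd, seed=seed), seed=seed)


def _range_from_dict(d: Mapping) -> RangeSpec:
    return RangeSpec(
        name=d["name"],
        d_min=float(d["d_min"]),
        d_max=float(d["d_max"]),
        n_steps=int(d.get("n_steps", 11)),
        reps=int(d.get("reps", 4)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Read a plain-text (YAML) run configuration.

    ``ranges`` entries may be built-in names ("subsecond", "second") or
    mappings with keys name/d_min/d_max/n_steps/reps.  A ``cohort`` block
    defines groups with per-range moments; omit it for ingest-only runs.
    """
    raw = yaml.safe_load(Path(path).read_text())
    ranges = tuple(
        BUILTIN_RANGES[r] if isinstance(r, str) else _range_from_dict(r)
        for r in raw.get("ranges", ["subsecond", "second"])
    )
    cohort = None
    if "cohort" in raw:
        c = raw["cohort"]
        groups = tuple(
            GroupSpec(
                name=g["name"],
                n=int(g["n"]),
                moments={
                    rname: RangeMoments(**{k: float(v) for k, v in m.items()})
                    for rname, m in g["moments"].items()
                },
            )
            for g in c["groups"]
        )
        cohort = CohortSpec(
            groups=groups,
            seed=int(c.get("seed", raw.get("seed", 0))),
            lapse=float(c.get("lapse", 0.0)),
        )
    return RunConfig(
        ranges=ranges,
        cohort=cohort,
        seed=int(raw.get("seed", 0)),
        bf_prior_scale=float(raw.get("bf_prior_scale", DEFAULT_PRIOR_SCALE)),
        alpha=float(raw.get("alpha", 0.05)),
        covariates=tuple(raw.get("covariates", ("age_years", "nonverbal_z", "gender"))),
        outdir=raw.get("outdir"),
    )


@dataclass
class StudyReport:
    """All outputs of one study run, with provenance."""

    fits: pd.DataFrame
    aggregate_fits: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    demographics: pd.DataFrame
    shapiro: pd.DataFrame
    mixed_models: dict[str, MixedModelResult]
    exclusions: pd.DataFrame
    notes: list[str]
    config: RunConfig
    timings: dict[str, float] = field(default_factory=dict)

    def mixed_table(self) -> pd.DataFrame:
        rows = []
        for model, res in self.mixed_models.items():
            for term, ft in res.terms.items():
                rows.append(
                    {
                        "model": model,
                        "term": term,
                        "F": ft.f,
                        "df_num": ft.df_num,
                        "df_den": ft.df_den,
                        "p": ft.p,
                        "var_participant": res.var_participant,
                        "var_residual": res.var_residual,
                        "n_participants": res.n_participants,
                    }
                )
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = [
            f"durcat {__version__} study report (seed={self.config.seed})",
            "",
            "Group-level thresholds (Weber fraction) and accuracy (PSE):",
        ]
        for _, r in self.summaries.iterrows():
            lines.append(
                f"  {r['measure']:>6} | {r['range']:>9} | {r['group']:>8}: "
                f"{r['mean']:.2f} ({r['sd']:.2f})  n={int(r['n'])}"
            )
        lines.append("")
        lines.append(
            f"Group comparisons (pooled t, alpha={self.config.alpha_per_range:.3f} "
            "Bonferroni-corrected across ranges):"
        )
        for _, r in self.comparisons.iterrows():
            lines.append(
                f"  {r['measure']:>6} | {r['range']:>9}: t({int(r['df'])}) = {r['t']:.2f}, "
                f"p = {r['p']:.3g}, d = {r['cohen_d']:.2f}, LBF = {r['lbf']:.2f} "
                f"[{r['evidence']}]"
            )
        if len(self.demographics):
            lines.append("")
            lines.append("Demographic / neuropsychological comparisons:")
            for _, r in self.demographics.iterrows():
                lines.append(
                    f"  {r['measure']:>12}: t({int(r['df'])}) = {r['t']:.2f}, "
                    f"p = {r['p']:.3g}, LBF = {r['lbf']:.2f}"
                )
        if self.mixed_models:
            lines.append("")
            lines.append("Mixed models (random participant intercept):")
            for model, res in self.mixed_models.items():
                terms = ", ".join(
                    f"{t}: F({ft.df_num},{ft.df_den}) = {ft.f:.2f}, p = {ft.p:.3g}"
                    for t, ft in res.terms.items()
                )
                lines.append(f"  {model}: {terms}")
        lines.append("")
        lines.append(f"Exclusions: {len(self.exclusions)}")
        for _, r in self.exclusions.iterrows():
            lines.append(f"  {r['participant_id']} ({r['range']}): {r['reason']}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        tables = {
            "fits.csv": self.fits,
            "aggregate_fits.csv": self.aggregate_fits,
            "summaries.csv": self.summaries,
            "comparisons.csv": self.comparisons,
            "demographics.csv": self.demographics,
            "shapiro.csv": self.shapiro,
            "mixed_models.csv": self.mixed_table(),
            "exclusions.csv": self.exclusions,
        }
        for name, df in tables.items():
            df.to_csv(out / name, index=False)
        (out / "summary.txt").write_text(self.summary_text())
        manifest = {
            "package_version": __version__,
            "seed": self.config.seed,
            "alpha": self.config.alpha,
            "bf_prior_scale": self.config.bf_prior_scale,
            "covariates": list(self.config.covariates),
            "ranges": [dataclasses.asdict(r) for r in self.config.ranges],
            "notes": self.notes,
            "timings_s": {**self.timings, "write": time.perf_counter() - t0},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return out


def validate_trials(trials: pd.DataFrame) -> None:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    bad = ~trials["response"].isin(["short", "long"])
    if bad.any():
        rows = list(trials.index[bad][:10])
        raise ValueError(f"unknown response token(s) in trial rows {rows}")
    if (trials["duration_s"] <= 0).any():
        rows = list(trials.index[trials["duration_s"] <= 0][:10])
        raise ValueError(f"non-positive durations in trial rows {rows}")


def fit_all_participants(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every participant x range; return (fits table, exclusion log)."""
    rows, excl = [], []
    for (pid, grp, rng_name), sub in trials.groupby(
        ["participant_id", "group", "range"], sort=True
    ):
        fit = fit_cumulative_gaussian(aggregate_proportions(sub))
        rows.append(
            {
                "participant_id": pid,
                "group": grp,
                "range": rng_name,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "pse_s": fit.pse,
                "jnd_log10": fit.jnd,
                "weber": fit.weber,
                "loglik": fit.loglik,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
        )
        if not fit.converged:
            excl.append(
                {
                    "participant_id": pid,
                    "group": grp,
                    "range": rng_name,
                    "reason": "psychometric fit did not converge (degenerate or unstable data)",
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(excl, columns=["participant_id", "group", "range", "reason"])


def _fit_aggregates(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (grp, rng_name), sub in trials.groupby(["group", "range"], sort=True):
        fit = fit_cumulative_gaussian(aggregate_proportions(sub))
        rows.append(
            {
                "group": grp,
                "range": rng_name,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "pse_s": fit.pse,
                "weber": fit.weber,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def _reading_index(metadata: pd.DataFrame) -> pd.Series | None:
    cols = {"reading_word_z", "reading_nonword_z"}
    if not cols <= set(metadata.columns):
        return None
    both = metadata[list(cols)].notna().all(axis=1)
    idx = metadata.loc[both, ["reading_word_z", "reading_nonword_z"]].mean(axis=1)
    return pd.Series(idx.to_numpy(), index=metadata.loc[both, "participant_id"])


def analyze_study(
    trials: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RunConfig,
) -> StudyReport:
    """The full inference stage shared by simulation and ingest entry points."""
    timings: dict[str, float] = {}
    notes: list[str] = []
    t0 = time.perf_counter()
    validate_trials(trials)

    fits, exclusions = fit_all_participants(trials)
    timings["fit"] = time.perf_counter() - t0
    good = fits[fits["converged"]]
    agg = _fit_aggregates(trials)

    glabels = sorted(trials["group"].unique())
    if len(glabels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {glabels}")
    # DD-like group listed first in comparisons when present (difference = impaired - control)
    if "DD" in glabels:
        glabels = ["DD"] + [g for g in glabels if g != "DD"]

    t1 = time.perf_counter()
    summaries, comparisons, shapiro_rows = [], [], []
    for measure, col in (("weber", "weber"), ("pse", "pse_s")):
        for rng_name in sorted(good["range"].unique()):
            sub = good[good["range"] == rng_name]
            by_group = {g: sub.loc[sub["group"] == g, col].to_numpy() for g in glabels}
            for g in glabels:
                x = by_group[g]
                if len(x) < 2:
                    notes.append(
                        f"{measure}/{rng_name}/{g}: fewer than 2 convergent fits; "
                        "group summary omitted"
                    )
                    continue
                summaries.append(
                    {
                        "measure": measure,
                        "range": rng_name,
                        "group": g,
                        "n": len(x),
                        "mean": float(np.mean(x)),
                        "sd": float(np.std(x, ddof=1)),
                    }
                )
                if len(x) >= 3 and np.ptp(x) > 0:
                    w, p = shapiro_wilk(x)
                    shapiro_rows.append(
                        {"measure": measure, "range": rng_name, "group": g, "W": w, "p": p}
                    )
            if all(len(by_group[g]) >= 2 for g in glabels):
                cmp_ = compare_groups(
                    by_group[glabels[0]],
                    by_group[glabels[1]],
                    alpha=config.alpha_per_range,
                    r=config.bf_prior_scale,
                )
                comparisons.append(
                    {
                        "measure": measure,
                        "range": rng_name,
                        "group_1": glabels[0],
                        "group_2": glabels[1],
                        "t": cmp_.t,
                        "df": cmp_.df,
                        "p": cmp_.p,
                        "cohen_d": cmp_.cohen_d,
                        "lbf": cmp_.lbf,
                        "alpha": cmp_.alpha,
                        "significant": cmp_.significant,
                        "evidence": cmp_.evidence,
                    }
                )

    # demographic / neuropsychological t tests
    demo_rows = []
    meta = metadata.copy()
    reading = _reading_index(meta)
    if reading is None:
        notes.append("metadata lacks reading columns; reading comparison omitted")
    demo_measures: list[tuple[str, pd.Series]] = []
    for col in ("age_years", "nonverbal_z", "math_z"):
        if col in meta.columns and meta[col].notna().sum() >= 4:
            demo_measures.append((col, pd.Series(meta[col].to_numpy(), index=meta["participant_id"])))
        else:
            notes.append(f"metadata lacks usable column {col!r}; comparison omitted")
    if reading is not None and len(reading) >= 4:
        demo_measures.append(("reading_index", reading))
    elif reading is not None:
        notes.append("fewer than 4 participants with both reading scores; reading comparison omitted")
    group_of = pd.Series(meta["group"].to_numpy(), index=meta["participant_id"])
    for name, series in demo_measures:
        vals = series.dropna()
        gs = {g: vals[group_of.loc[vals.index] == g].to_numpy() for g in glabels}
        if any(len(gs[g]) < 2 for g in glabels):
            notes.append(f"{name}: fewer than 2 values in a group; comparison omitted")
            continue
        cmp_ = compare_groups(gs[glabels[0]], gs[glabels[1]], alpha=config.alpha, r=config.bf_prior_scale)
        demo_rows.append(
            {
                "measure": name,
                "group_1": glabels[0],
                "group_2": glabels[1],
                "n_1": len(gs[glabels[0]]),
                "n_2": len(gs[glabels[1]]),
                "t": cmp_.t,
                "df": cmp_.df,
                "p": cmp_.p,
                "cohen_d": cmp_.cohen_d,
                "lbf": cmp_.lbf,
            }
        )

    # mixed models (need both ranges)
    mixed: dict[str, MixedModelResult] = {}
    if good["range"].nunique() == 2:
        for measure, col in (("weber", "weber"), ("pse", "pse_s")):
            tbl = good.rename(columns={col: "value"})[
                ["participant_id", "group", "range", "value"]
            ]
            try:
                mixed[measure] = mixed_model_anova(tbl, metadata=meta)
            except ValueError as e:
                notes.append(f"mixed model for {measure} skipped: {e}")
        if config.covariates:
            usable = [
                c for c in config.covariates if c in meta.columns and meta[c].notna().all()
            ]
            dropped = set(config.covariates) - set(usable)
            if dropped:
                notes.append(
                    f"covariates {sorted(dropped)} unavailable or incomplete; "
                    "dropped from adjusted model"
                )
            if usable and "weber" in mixed:
                tbl = good.rename(columns={"weber": "value"})[
                    ["participant_id", "group", "range", "value"]
                ]
                try:
                    mixed["weber_adjusted"] = mixed_model_anova(
                        tbl, metadata=meta, covariates=usable
                    )
                except ValueError as e:
                    notes.append(f"covariate-adjusted mixed model skipped: {e}")
    else:
        notes.append("fewer than 2 timing ranges with convergent fits; mixed models skipped")
    timings["inference"] = time.perf_counter() - t1

    return StudyReport(
        fits=fits,
        aggregate_fits=agg,
        summaries=pd.DataFrame(
            summaries, columns=["measure", "range", "group", "n", "mean", "sd"]
        ),
        comparisons=pd.DataFrame(
            comparisons,
            columns=[
                "measure", "range", "group_1", "group_2", "t", "df", "p",
                "cohen_d", "lbf", "alpha", "significant", "evidence",
            ],
        ),
        demographics=pd.DataFrame(
            demo_rows,
            columns=["measure", "group_1", "group_2", "n_1", "n_2", "t", "df", "p", "cohen_d", "lbf"],
        ),
        shapiro=pd.DataFrame(shapiro_rows, columns=["measure", "range", "group", "W", "p"]),
        mixed_models=mixed,
        exclusions=exclusions,
        notes=notes,
        config=config,
        timings=timings,
    )


def run_simulation_study(config: RunConfig) -> tuple[StudyReport, pd.DataFrame, pd.DataFrame]:
    """Simulate the configured cohort and run the full analysis.

    Returns ``(report, trials, metadata)`` so the simulated tables can be
    written alongside the report (and later re-ingested).
    """
    if config.cohort is None:
        raise ValueError("run_simulation_study needs a cohort spec in the config")
    t0 = time.perf_counter()
    trials, metadata = simulate_cohort(config.cohort, config.ranges)
    report = analyze_study(trials, metadata, config)
    report.timings["simulate"] = time.perf_counter() - t0
    if config.outdir:
        out = report.write(config.outdir)
        trials.to_csv(out / "trials.csv", index=False)
        metadata.to_csv(out / "metadata.csv", index=False)
    return report, trials, metadata


def run_ingest_study(
    trials_path: str | Path,
    metadata_path: str | Path,
    config: RunConfig | None = None,
    column_map: Mapping[str, str] | None = None,
) -> StudyReport:
    """Analyze an existing trial/metadata table pair (e.g. a deposited dataset).

    ``column_map`` maps file column names to the schema names
    (participant_id, group, range, trial_index, duration_s, response, ...);
    files already in the schema need no map.  A file produced by
    :func:`run_simulation_study` reproduces that study's report exactly.
    """
    config = config or RunConfig()
    # round_trip parsing: re-ingesting a written table must reproduce the
    # exact float64 values, so the downstream report is bit-identical
    trials = pd.read_csv(trials_path, float_precision="round_trip")
    metadata = pd.read_csv(metadata_path, float_precision="round_trip")
    if column_map:
        trials = trials.rename(columns=dict(column_map))
        metadata = metadata.rename(columns=dict(column_map))
    validate_trials(trials)
    missing = set(METADATA_REQUIRED) - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns {sorted(missing)}")
    report = analyze_study(trials, metadata, config)
    if config.outdir:
        report.write(config.outdir)
    return report
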