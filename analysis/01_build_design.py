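#!/usr/bin/env python
"""Reconstruct the two timing-range stimulus sets and a trial schedule.

Builds the sub-second (0.25–1 s) and supra-second (0.75–3 s) duration sets —
11 log-spaced steps spanning one octave either side of the range's geometric
mean — plus a seeded 44-trial schedule per range, and writes them under
results/design/.
"""

from pathlib import Path

from durcat import BUILTIN_RANGES, build_duration_set, build_trial_schedule

OUT = Path(__file__).resolve().parent.parent / "results" / "design"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, spec in BUILTIN_RANGES.items():
        stim = build_duration_set(spec)
        sched = build_trial_schedule(stim, seed=SEED)
        stim.to_frame().to_csv(OUT / f"stimuli_{name}.csv", index=False)
        sched.to_frame().to_csv(OUT / f"schedule_{name}.csv", index=False)
        print(f"{name}: reference {spec.geometric_mean:.2f} s, "
              f"{spec.n_steps} durations x {spec.reps} reps = {len(sched)} trials")
        print("  durations (s):", ", ".join(f"{d:.2f}" for d in stim.durations))
        print("  anchors:", ", ".join(f"{d:.2f}={lab}" for d, lab in stim.anchors))
    print(f"\nwrote design tables to {OUT}")


if __name__ == "__main__":
    main()
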