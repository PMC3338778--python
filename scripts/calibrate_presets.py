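"""Check (and help tune) the per-genotype motility presets.

For each preset this simulates many 5-cell cohorts (25 samples, 5-min
interval), summarizes each cohort with the same statistics the analysis
pipeline reports, and compares the median cohort mean against the published
calibration anchors: total distance, velocity, and time moving/paused, each
with a tolerance of +/- 2 printed SEM.

Run:  python scripts/calibrate_presets.py [--n-cohorts 500] [--seed 0]
"""

from __future__ import annotations

import argparse

import numpy as np

from motanlage import synthetic_data as sd
from motanlage import track_metrics as tm

# (mean, sem) anchors per genotype: distance um, velocity um/min,
# time moving min, time paused min.
TARGETS = {
    "WT": {"T_um": (53, 4), "velocity_um_min": (0.5, 0.1),
           "time_moving_min": (92, 16.4), "time_paused_min": (32, 16.8)},
    "HET": {"T_um": (74, 10), "velocity_um_min": (0.6, 0.1),
            "time_moving_min": (101, 7.4), "time_paused_min": (24, 7.4)},
    "MUT": {"T_um": (23, 1), "velocity_um_min": (0.2, 0.02),
            "time_moving_min": (59, 14), "time_paused_min": (66, 14)},
}


def cohort_medians(group: str, n_cohorts: int, seed: int) -> dict[str, float]:
    params = sd.preset_params(group)
    per_metric: dict[str, list[float]] = {m: [] for m in TARGETS[group]}
    for i in range(n_cohorts):
        ts = sd.simulate_tracks(params, 5, 25, 5.0, seed=seed + i)
        summary = tm.summarize_group(list(ts.tracks), group)
        for metric in per_metric:
            per_metric[metric].append(summary.metrics[metric].mean)
    return {m: float(np.median(v)) for m, v in per_metric.items()}


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-cohorts", type=int, default=500)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    failures = 0
    for group, targets in TARGETS.items():
        medians = cohort_medians(group, args.n_cohorts, args.seed)
        print(f"== {group} ==")
        for metric, (mean, sem) in targets.items():
            got = medians[metric]
            ok = abs(got - mean) <= 2 * sem
            failures += not ok
            print(
                f"  {metric:18s} median={got:8.3f} target={mean}+/-{2 * sem}"
                f"  {'ok' if ok else 'MISS'}"
            )
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
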