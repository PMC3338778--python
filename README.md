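# motanlage

Quantitative analysis toolkit for time-lapse motility, focal-adhesion and
expression read-outs of cultured myogenic cells, bundled with a synthetic-data
generator so the whole pipeline is testable without any raw microscopy or
microarray data.

## What it does

| Module | Purpose |
| --- | --- |
| `motanlage.synthetic_data` | Run/pause persistent-random-walk track simulator with calibrated WT/HET/MUT presets; adhesion scenes + image rendering; expression replicates; DNA-content histograms |
| `motanlage.track_metrics` | Per-track path length T, net displacement D, D/T directionality, moving/paused time budget, velocity, direction changes; group mean ± SEM |
| `motanlage.msd_analysis` | Displacement and path-squared mean-square curves, linear-fit x-intercept randomness diagnostic, persistent-random-walk (S, P) fit |
| `motanlage.group_stats` | Mean ± SEM, pooled/Welch/paired t-tests (raw data or summaries), Monte-Carlo Dunnett many-to-one comparisons |
| `motanlage.adhesion_quant` | Puncta detection (threshold + 8-connected components), leading/trailing partition along a polarity axis, maturity classes, group summaries |
| `motanlage.expression_fold` | Signed fold-change tables (negative-reciprocal convention), replicate-consistency filtering, per-category ranking; packaged reference table of 38 candidate genes |
| `motanlage.cell_population` | Percent-positive counts and G1/S/G2 phase fractions from DNA-content histograms |

## CLI

All functionality is exposed through the `motanlage` command:

```sh
# simulate a 5-cell WT cohort and summarize it
motanlage simulate tracks --preset WT --n-cells 5 --seed 1 --out tracks.csv
motanlage track-stats --in tracks.csv --pause-threshold 1.0 --out stats.csv

# MSD curve, randomness diagnostic and persistent-walk fit
motanlage msd --in tracks.csv --lags 20:120:20 --msd-mode displacement --fit prw

# many-to-one comparisons against a control group (long CSV: group,value)
motanlage compare --in values.csv --control WT --method dunnett --seed 7

# adhesion scenes and their quantification
motanlage simulate adhesions --n-cells 18 --seed 3 --out puncta.csv --sidecar scenes.csv
motanlage adhesions --in puncta.csv --sidecar scenes.csv

# fold-change table (packaged reference means, or your own replicate TSV)
motanlage foldchange --out folds.tsv
motanlage foldchange --in expr.tsv --round 1 --out folds.tsv

# population statistics
motanlage percent-positive --pos 877808 --total 5237143
motanlage simulate histogram --g1 0.69 --s 0.18 --g2 0.13 --out hist.csv
motanlage cellcycle --in hist.csv
```

File formats are plain text: tracks as CSV (`track_id,frame,t_min,x_um,y_um`),
puncta as CSV with a geometry sidecar, expression as long-format TSV
(`gene,genotype,replicate,value`), histograms as CSV
(`bin_left,bin_right,count`).

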