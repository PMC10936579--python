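# binlat

Binaural-perception assessment pipeline: lateralization scoring on a 9-key
intracranial position scale, order-statistic normative classification
against a control cohort, longitudinal change tracking across measurement
phases, and an adaptive tone-in-noise staircase simulator with binaural
masking level difference (BMLD) extraction. A synthetic-cohort generator
emulates control-like and clinically observed pathological listener
behaviors (lateral shifts, side-oriented responding, high variability,
left-right confusions) so that every stage is testable end to end without
any real participant data.

## Components

| module                | what it does |
|-----------------------|--------------|
| `binlat.schema`       | domain types: stimuli, trials, sessions, audiograms |
| `binlat.io`           | CSV/JSON formats for all pipeline artifacts |
| `binlat.metrics`      | the 31-variable quantitative lateralization description |
| `binlat.normative`    | per-metric normal ranges (2nd..(n-1)th sorted control value), divergence counting, normality rule (≤ 5 of 31) |
| `binlat.longitudinal` | phase-to-phase change in control-SD units (sign: + = toward control mean), trajectories, cluster heat-map table |
| `binlat.thresholds`   | one-up/three-down staircase simulation (79.4 %-correct convergence), threshold + BMLD extraction, PTA3 audiometric summaries |
| `binlat.cohort`       | seeded synthetic cohorts: listener models, observers, tracks, audiograms |
| `binlat.cli`          | `binlat` command tying the stages together |

## CLI

```bash
binlat --seed 7 simulate --controls 12 --patients 6 --out-dir run/
binlat metrics     --trials run/trials.csv --out run/metrics.csv
binlat normative   --metrics run/metrics.csv --out run/normative.json
binlat diverge     --metrics run/metrics.csv --normative run/normative.json \
                   --out run/divergence.csv
binlat longitudinal --metrics run/metrics.csv --normative run/normative.json \
                   --out-changes run/changes.csv --out-summary run/summary.json
binlat bmld        --tracks run/tracks.csv --out run/bmld.csv
binlat report      --dir run/ --out run/report.md --figures
```

All randomness flows from `--seed`; identical seed and configuration give
byte-identical outputs. A YAML file passed via `--config` overrides the
cohort-generation defaults (`binlat.cohort.DEFAULT_CONFIG`).

## File formats

UTF-8 comma-delimited tables with one header row; undefined values are the
literal token `NA`. Key files: `trials.csv` (participant_id, group, phase,
cue_type, cue_value, presentation_index, response_key), `metrics.csv`
(ids + 31 metric columns in fixed order), `normative.json` (per metric:
lo/hi/mean/sd/iqr/n_controls), `tracks.csv` (per-trial staircase log),
`audiometry.csv`, `divergence.csv`, `changes.csv`, `summary.json`.

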