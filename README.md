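# napamyloid

Synthetic compound nerve action potential (NAP) experiments and their
dose–response analysis, end to end:

- **simulate** — a seeded generator of whole-nerve recordings: axon classes
  with lognormal conduction velocities and recruitment thresholds, biphasic
  unit kernels, refractory availability at short inter-stimulus intervals,
  slow Wallerian amplitude decline across 30-minute segments, and a
  non-monotonic concentration-dependent depression that ramps in after the
  drug is added. The default design is 112 nerves in 9 concentration
  groups, 36 segments, and two interleaved 7-stimulus sets (an increasing
  current ramp at 4 ms intervals, and a 15 mA series with intervals
  shortening from 166 ms to 1 ms) sampled at 99 kHz.
- **features** — automated marking of 12 parameters per NAP (peak/trough
  amplitudes, velocity, duration, half-level rise/decline/recovery
  latencies, fixed-offset slope amplitudes, stimulus–response ratio), with
  linear-interpolated fractional crossings and baseline normalization to
  segment 3.
- **registration** — per-nerve four-parameter waveform normalization
  `out(i) = a·w(b·i + c) − d` fitted by Nelder–Mead against an exemplar
  nerve's first-segment waveform under a weight vector that ignores the
  stimulus artifact and tapers over the tail; the fit is frozen and applied
  to every segment.
- **param_stats** — endpoint one-way ANOVA (Bonferroni 0.05/12 per test),
  confirmatory Kruskal–Wallis (0.1/12), quadratic regression on the ordinal
  concentration, a balanced split-plot repeated-measures ANOVA
  (concentration between subjects; segment and stimulus within),
  Benjamini–Hochberg step-up FDR over Spearman screens, and 12×7
  significance-count tables with a chi-square independence test (df = 66).
- **waveform_stats** — pointwise Spearman correlation of the registered
  voltage with concentration at every time point, raw-p and FDR masks, the
  |R|-profile vs template-voltage correlation, and a chi-square test of
  whether significant points cluster at particular latencies.
- **pipeline/CLI** — one config, one seed, a JSON + Markdown report and
  figures.

## CLI

```sh
napamyloid run --config cfg.yaml --seed 17 --out results/
```

runs every stage and writes `report.json`, `report.md`, tidy CSVs
(`features.csv`, `registration_params.csv`, `anova.csv`, `regression.csv`,
`rm_anova.csv`, `count_table_*.csv`, `correlation_map.csv`) and figures.
Stages are also available individually:

```sh
napamyloid simulate --config cfg.yaml --seed 17 --out data/
napamyloid features --data data/waveforms.csv --out features.csv
napamyloid register --data data/waveforms.csv --out registered/
napamyloid stats    --features features.csv --out stats/
napamyloid wavecorr --registered registered/registered.csv --out wavestats/
```

A config file has four required sections (`design`, `protocol`,
`population`, `drug`) and optional `marking`, `stats`, `registration`
sections; omitted keys take the defaults shown in
`napamyloid/simulate.py`. Example:

```yaml
design:
  n_segments: 36
protocol: {}
population:
  noise_sd: 0.02
drug:
  effect_by_conc: {0: 0.0, 1: 0.08, 2: 0.12, 3: 0.2, 4: 0.3,
                   5: 0.22, 6: 0.1, 7: 0.02, 8: 0.0}
```

## Reproducibility

All randomness flows from a single root seed; per-nerve streams are derived
by hashing `(seed, nerve_id)`, so a nerve's data is identical whether it is
simulated alone or as part of the full design. Identical seeds and configs
produce byte-identical report JSON.
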