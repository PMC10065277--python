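# proxhrv

Analysis toolkit for stop-distance (proxemics) experiments with concurrent
heart-rate-variability recording. It covers the full measurement chain:

- **synthetic** — session/cohort generators for the eight-episode paradigm
  (approach–hold–return between 500 cm and a per-condition stop distance),
  with chest-strap RR streams calibrated to a target RMSSD, injected RR
  artifacts, bounded proximity sensor noise, and planted ground truth for
  recovery testing.
- **stream_io** — readers/writers for the two wearable stream formats and
  per-beat timestamp reconstruction from bare RR exports.
- **preprocess** — per-second median resampling of the proximity channel, RR
  artifact replacement (≥ 1200 ms or |Z| > 2 → raw-series median), listwise
  missing-HRV exclusion, and trigger alignment to local distance minima.
- **hrv** — RMSSD and mean heart rate over 60 s baseline/task windows and
  10 s pre-trigger (ultra-short-term) windows; half-open `(start, end]`
  window semantics.
- **paradigm** — episode-minimum detection, per-condition preferred
  distances, active/passive pooling, and per-person HRV standardisation
  (ratio to own baseline).
- **stats** — mixed-design ANOVA/ANCOVA (two-level factors, split-plot
  strata, partial η²), Bonferroni post hocs, Mann-Whitney U with
  rank-biserial r and Fisher-z CIs, chi-square, Spearman + Benjamini-
  Hochberg FDR, case-resampling bootstrap regression, and simulation-based
  power.
- **pipeline / cli** — one-command orchestration producing a reproducible
  report bundle (tidy CSVs + JSON + run log), bit-identical under a fixed
  seed.

## File formats

**RR export** — plain text, one interbeat interval (ms) per line; the
recording start time is encoded in the filename as
`YYYY-MM-DD_HH-MM-SS.txt`:

```
2019-11-03_10-15-00.txt
-----------------------
812
805
819.5
```

**Proximity trace** — CSV with header `t_ms,distance_cm` (milliseconds
since trace start, centimetres). Negative distances are clamped to zero
with a logged warning.

**Trigger overrides** — CSV `trigger_index,t_s` applied after automatic
local-minimum alignment.

## CLI

```bash
# write a synthetic fixture cohort (plain-text files)
proxhrv simulate --out cohort/ --n-asd 22 --n-cp 21 --seed 1

# run the full pipeline on it (or use --mode simulate to skip fixtures)
proxhrv run --mode ingest --input-dir cohort/ --out bundle/ --seed 1

# render a readable summary from the bundle
proxhrv report bundle/ --plot
```

`run` also accepts `--config pipeline.yaml`; CLI flags override file keys.
Exit codes: 0 success, 1 user error, 2 internal error.

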