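# coforage

At-sea association analysis for simultaneously GPS/TDR-tracked central-place
foragers (e.g. breeding seabirds). The package turns raw GPS fix tables and
time-depth records into:

- speed-filtered fixes and complete **foraging trips** (colony departure to
  return), linearly interpolated onto a regular time grid;
- **dives** (zero-offset-corrected, 1 m minimum depth) grouped into **bouts**
  via a bout-ending criterion fitted by maximum likelihood to a two-process
  exponential mixture of surface intervals;
- dyadic **association episodes** (pairs within a configurable radius for at
  least a minimum-duration unit, with gap merging and automated exclusion of
  "rafting" near the colony);
- **synchronous dives** (dive initiations within a 4-s window during a shared
  episode, greedy one-to-one matching);
- a per-track **association classification** (groups 1, 2, 3a, 3b, 3c) with
  time budgets, per-pair and per-deployment-day summary tables;
- group-level statistics: a Mantel permutation test of nest proximity vs.
  association time and a Mann–Whitney U sex comparison.

A seeded synthetic-deployment generator (`coforage.simulate`) produces
GPS/TDR/deployment tables with full ground truth (trips, dives, bouts,
episode intervals, sync dives, classifications), so the entire pipeline is
testable without any field data. Small published reference tables are bundled
(`coforage.reference.fixture_tables`) for validation.

## Command-line usage

```sh
# generate a synthetic deployment (raw CSVs + truth/ subdirectory)
coforage simulate --seed 1 --out data/sim

# full pipeline: ingest -> trips -> dives/bouts -> episodes -> sync ->
# classification -> summaries -> stats (+ manifest.json for reproducibility)
coforage run --gps data/sim/gps.csv --tdr data/sim/tdr.csv \
             --deployments data/sim/deployments.csv \
             --colony data/sim/colony.yaml --out results/run

# or with a single YAML config
coforage run --config pipeline.yaml

# individual stages on prior-stage CSVs
coforage filter-trips --gps data/sim/gps.csv --colony data/sim/colony.yaml --out s1
coforage dives --tdr data/sim/tdr.csv --interpolated s1/interpolated.csv \
               --trips s1/trips.csv --out s2
coforage associate --interpolated s1/interpolated.csv --colony data/sim/colony.yaml --out s3
coforage classify --trips s1/trips.csv --episodes s3/episodes.csv \
                  --dives s2/dives.csv --deployments data/sim/deployments.csv --out s4
coforage stats --pair-summary s4/pair_summary.csv --classification s4/classification.csv \
               --deployments data/sim/deployments.csv --out stats.json
```

Exit codes: 0 success, 2 configuration error, 3 data error. Without TDR input
the pipeline runs in a GPS-only degraded mode (classification restricted to
groups 1/2/3a and flagged).

Input schemas: GPS CSV `id,timestamp,lat,lon`; TDR CSV `id,timestamp,depth_m`;
deployments CSV `id,sex,nest_id,nest_lat,nest_lon,date`; colony YAML/JSON
`{lat, lon, rafting_radius_m}`. Timestamps are parsed to UTC (naive values are
assumed UTC with a warning).

## Key defaults

| Setting | Default | Notes |
| --- | --- | --- |
| speed filter | > 2.0 m/s removed | forward-pass, strict inequality |
| colony radius (trip segmentation) | 150 m | |
| interpolation grid | 60 s | |
| dive threshold | 1 m | after zero-offset correction (300-s rolling 2% quantile) |
| bout criterion variable | raw post-dive interval | `postdive_diff` / `duration_diff` available |
| association radius | 500 m | derivable from mean bout horizontal distance |
| minimum episode duration | 744 s (12.4 min) | derivable from mean bout duration |
| synchrony window | 4 s (inclusive) | |
| rafting buffer | 1000 m from colony | episode portions with both members inside are trimmed |
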