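# whalenav

Agent-based simulation of collective baleen-whale navigation in noisy ocean
soundscapes. Virtual whales migrate toward a target via a velocity-jump
random walk, pooling their inherent (von Mises-distributed) knowledge of the
target direction with the headings of conspecifics whose calls remain
detectable above the ambient noise. Rising noise masks communication,
triggers avoidance behaviour (negative phonotaxis), and can erode inherent
navigation information; shallow water triggers deep-water-seeking land
avoidance. Ensembles of runs are summarized by four metrics: a median
trajectory built by intersection switching, a binned occupancy spread
region, arrivals over time, and the mean distance of the population to the
target.

No real ocean data is bundled: a synthetic-environment module generates
idealized bathymetry (open sea, islands, straits, basins, coastal ramps),
currents, a wind noise floor, mobile vessel lanes, and fixed construction
sources with daily duty cycles. Gridded layers can also be read/written as
CF-style NetCDF (or a CSV fallback) for use with real data.

## Layout

- `whalenav.environment` — gridded lon/lat/time fields, bilinear/linear
  interpolation, bearings, displacement, land mask, gradient directions.
- `whalenav.acoustics` — log-range transmission loss, SNR + received-level
  detection, detection range, dB power summation, noise-map rendering.
- `whalenav.navigation` — von Mises sampling, heading fusion, noise/land
  avoidance sigmoids, behavioural weight resolution.
- `whalenav.simulator` — the time-stepping engine, scenario configuration,
  ensembles, CSV trajectory IO.
- `whalenav.metrics` — median trajectory, spread region, arrivals,
  mean distance, daily detected-whale counts.
- `whalenav.scenarios` — synthetic seas, environment recipes, and the
  preset library (`pristine`, `current_synthetic`, `avoidance_sweep`,
  `info_loss`, `traffic_increase`, `slowdown`, `construction`).

Conventions: headings are radians counter-clockwise from east; positions
are degrees (lon, lat); distances km; depths metres (positive = water);
noise levels dB re 1 µPa at 1 m; time is hours since simulation start.

## CLI

```sh
# generate the synthetic layers of a preset as NetCDF
whalenav generate-env --preset pristine --duration 24 --out env/

# run a reduced ensemble and compute metrics
whalenav run --preset pristine --repeats 2 --seed 7 \
    --n-whales 10 --duration 72 --dt 0.25 --out out/
whalenav metrics --run out/
whalenav report --metrics out/metrics.json
```

`run` writes `trajectories.csv` (repeat, id, t_hours, lon, lat,
heading_rad, n_detected, arrived), `config.yaml` (round-trippable scenario
config) and `runlog.json` (seed, config hash, environment checksum).
Presets default to paper-scale parameters (100 whales, 744 h, 10 repeats);
use the flags above for desk-scale runs. Sweep presets
(`avoidance_sweep`, `info_loss`, `construction`) expose variants through
`--variant`.

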