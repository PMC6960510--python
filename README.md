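# furrowscan

Dual 2D-lidar field phenotyping: simulate boom-mounted lidar scans of
replicated row-crop trials, extract per-plot canopy height and canopy
cover, validate cover against overhead fisheye imagery, and summarize the
traits genetically.

## The problem

Measuring plant height and canopy width across thousands of small plots,
repeatedly through a season, is the throughput bottleneck of field
genetics: manual measurement does not scale, and survey-grade 3D lidar
produces point clouds too heavy for same-day analysis. A practical
alternative mounts two low-cost industrial 2D scanning lasers on a ground
vehicle, each nadir-down over the furrow between a plot's two crop rows,
and reduces every sweep to two numbers on the fly.

The package implements that reduction end to end for a maize diversity
trial: 1728 plots of 3.66 m × 1.52 m, two rows each, scanned in 36
transects at 0.48 m·s⁻¹ with 5 Hz sweep output (a sweep every ≈0.1 m).
Each sensor reports 251 distances per sweep — a 90° field of view at 0.36°
angular resolution, both endpoints counted — serialized as a fixed-width
1278-byte ASCII message.

## The method

Every return is projected to its vertical drop, *z = d·cos θ*. Heights are
measured against a soil reference:

- **ZREF** — at initialization, parked over a clear alley, each sensor
  averages the vertical distances of the 29 beams in the center 10°
  window; ZREF is the mean of the two sensors.
- **SREF** — per sweep, the mean of center-window beams within ±50 mm of
  ZREF (the soil visible through the furrow); if fewer than 5 qualify the
  sweep falls back to ZREF.
- A beam is a **plant hit** when `SREF − z > 50 mm`. Per sweep,
  **CH** = max plant-hit height (m) and **CC** = plant-hit fraction of
  in-plot beams. Plot values are means over the ~28 sweeps crossing each
  plot, reduced to a single 1728-line summary CSV.

Cover is independently validated from overhead fisheye images (equi-solid
projection *r = 2f·sin(θ/2)*): each plot image is cropped, converted to the
green–red normalized difference *(G−R)/(G+R)*, split at the local minimum
of its bimodal histogram, and the green-pixel fraction regressed against
lidar CC. Genetic summaries use row-adjusted genotype means (breeding
values), broad-sense heritability *H² = σ²g/(σ²g+σ²e)* from
expected-mean-squares ANOVA, and Pearson genetic correlations with
permutation p-values.

A first-class synthetic-data module simulates the whole system — ray-cast
canopies with tunable height, cover and porosity over rough soil, GNSS
NMEA sentences, UTM-anchored plot polygons, logger `.DAT` files — so every
stage is testable against known ground truth without hardware.

## Worked example

```sh
furrowscan all --seed 1 --out session/
```

simulates a full scan of the default 1728-plot field (about 30 s), then
processes and summarizes it. Typical log output:

```
[furrowscan] sensor 00: read 39528 records (0 skipped)
[furrowscan] sensor 00: 32942 in-plot, 6586 removed (alleys/buffers)
[furrowscan] sensor 01: read 39528 records (0 skipped)
[furrowscan] sensor 01: 32939 in-plot, 6589 removed (alleys/buffers)
[furrowscan] merged summary: 1728 plot lines
```

Each sensor logs 39,528 records (79,056 total — one line per sweep and
sensor); records over alleys and buffers are removed, and the merged
summary has exactly one line per plot:

```
plot_id genotype  treatment       n_records  ch_mean_m  ch_sd_m  cc_mean_pct  cc_sd_pct
0       G071      well-irrigated  38         1.491026   0.001546 86.057479    1.985352
1       G229      well-irrigated  38         0.729269   0.000945 44.210526    3.839212
2       G130      well-irrigated  38         0.897799   0.000741 55.945862    2.879100
```

`ch_mean_m` is the plot's mean canopy height in metres, `cc_mean_pct` its
mean canopy cover in percent, each with the per-plot standard deviation
over sweeps. The genetics report (`session/genetics.csv`) then gives, per
treatment, the variance components, heritability and the CH–CC genetic
correlation, e.g. H² ≈ 72–75% for canopy height under the default
simulation settings.

## Layout

| module | contents |
| --- | --- |
| `sweep_geometry` | angular bookkeeping, polar↔Cartesian conversion |
| `protocol` | 1278-byte message codec, NMEA parsing, UTM, `.DAT` I/O |
| `field_simulator` | field scenes, ray-casting, session simulation |
| `trait_extraction` | ZREF/SREF calibration, plant/soil classification, CH/CC |
| `plot_pipeline` | plot assignment, summaries, sensor merge, field capacity |
| `cover_validation` | fisheye model, vegetation index, thresholding, regression |
| `genetics` | breeding values, heritability, genetic correlation |
| `cli` | `furrowscan` command-line entry points |

See `docs/methods.md` for the models, parameter choices and limitations.
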