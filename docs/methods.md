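# Methods

## Sensor and sweep model

Each lidar unit is modeled as a nadir-down 2D scanning laser with fixed
0.36° angular resolution, operated at a 90° field of view centered on
nadir (251 optical angles, both endpoints counted; the full device sweep
is 270°/751 angles). Index 0 is the +45° starting angle and the angle
decreases by one resolution step per index, which places nadir exactly at
index 125 and makes the 10° initialization window a symmetric run of 29
indices. Distances are integer millimetres; values are bounded at 9999 mm
by the serialized field width, and 9999 doubles as the no-surface
sentinel. A return at angle θ and distance d maps to lateral offset
`x = d·sin θ` and vertical drop `z = d·cos θ` in the sensor's sweep plane.

The wire format is a fixed-width ASCII message: a 23-byte header
(`$` + 2-char unit address + 8-digit controller milliseconds + 4-digit
ZREF + 4-digit SREF, comma-delimited) followed by five bytes per optical
angle (4 zero-padded digits + separator), i.e. 1278 bytes for 251 points
and 3778 for 751. The header field order inside the 23 bytes is this
package's convention; the two byte totals constrain only the widths.
Error-check values live in the logger wrapper record, not the payload, to
preserve those totals. Serialization and parsing are exact inverses and
are property-tested as such.

## Positioning

Logger records carry GNGGA/GNRMC sentences' parsed latitude/longitude
(checksum-validated; failures are counted and skipped) converted to UTM
zone 12N. The transverse Mercator conversion is implemented in-package
with the Karney–Krüger flattening series through n⁶ (sub-millimetre
accuracy inside a zone) and is cross-checked in the tests against an
independently coded Snyder-series formulation to ≤ 1 cm. Synthesized NMEA
sentences carry 7-decimal minutes, matching the sub-centimetre precision
of an RTK receiver, so positions survive the NMEA round trip at the
accuracy plot assignment needs. Coordinates outside the zone-12 longitude
band are still projected (zone forced) with a warning.

## Soil reference and trait extraction

ZREF is measured once per session with the platform parked over a clear
alley: per sensor, the mean vertical distance of the 29 center-window
beams; the session value averages the two sensors. Any max-range return
inside the window aborts initialization. SREF is recomputed per sweep as
the mean vertical distance of center-window beams within ±50 mm of ZREF,
falling back to ZREF when fewer than 5 qualify (canopy closed over the
furrow). The 50 mm soil gate and the 50 mm plant threshold `h_min` are
several times the observed soil-reference uncertainty of such systems
(single-digit millimetres in our simulations); both are configurable.

Classification is per beam: plant iff `SREF − z > h_min` (strict, so a
return exactly at the threshold is soil); max-range beams are excluded
from both classes. Per sweep, CH is the maximum plant-hit height above
SREF among beams within the plot's lateral half-width (0.76 m each side of
the furrow), consistent with height-to-the-uppermost-leaf field protocols;
CC is the plant fraction of in-window beams. CH and CC answer different
questions (tallest organ vs. horizontal occupancy), which is why CC is a
beam-hit fraction rather than a projected-width measure.

## Plot pipeline

Plots are 3.66 m × 1.52 m rectangles in a 72-column × 24-range UTM-anchored
grid with 0.76 m alleys between ranges. Assignment is half-open on
boundaries shared by two plots (the plot with the larger origin wins) and
closed on the field's outer edges, so every point belongs to at most one
plot; a brute-force polygon-containment oracle checks the fast grid path,
including exact boundary points (a 1 µm tolerance absorbs float noise).
Per-plot statistics are means and sample (n−1) standard deviations of the
per-sweep values; the summary always has one line per layout plot, with
empty plots carried as missing. The two per-sensor summaries merge by
record-count-weighted means (for mean and sd columns alike) with counts
adding — for the disjoint plot sets the dual-boom geometry produces this
is a plain union, and duplicate inputs pass through unchanged.

Field capacity is the usual machinery arithmetic: theoretical capacity =
speed × swath × 60 (m²·min⁻¹), efficiency = 100 × actual / theoretical.

## Synthetic field scenes

The generator's defaults are the study conditions of the modeled trial:
1728 plots in six 12-column blocks — three replicate blocks per irrigation
treatment — each containing 248 accessions once plus four check varieties
ten times, randomized within block. Genotype effects on canopy height are
drawn once from Normal(0, σ²g) with σg = 0.25 m and shared across
treatments; plot values add treatment means (1.1 m well-irrigated, 0.8 m
drought-stressed — a late-season operating point, when trait differences
are largest) and Normal(0, σ²e) plot noise with σe = 0.13 m, floored at
0.08 m. These give a plot-basis heritability near 78%. Target cover is
logit-linear in height, spanning roughly 0.05–0.85 over the realized
height range.

Each crop row is an axis-aligned canopy box: lateral half-width set from
the plot's target cover (`rw = cover·0.76/(2(1−porosity))`, capped at
0.37 m so a canopy closes over its own furrow but never spans the
inter-plot furrow), top at the plot's height, Bernoulli porosity 0.25 per
beam–box encounter. A ray entering a box returns the entry distance with
probability 1−porosity, otherwise continues — possibly through further
boxes, including the neighboring columns' (which matters only as beam
blocking) — to a soil plane with Normal(0, 5 mm) roughness. This is the
simplest geometry that yields tunable cover together with partial soil
visibility through canopy gaps.

The per-plot *effective cover* truth is computed analytically by
traversing each optical angle's boxes in entry order, accumulating
survival probability, and crediting in-window mass above `h_min` to plant
and the rest to soil — i.e., the exact expectation of the extractor's CC
under the scan geometry and classification rule, rather than the nominal
cover parameter.

Sessions run one transect per adjacent column pair (36 passes), sensors
1.52 m apart and each over its column's furrow, sweeps every
speed/output-rate = 0.096 m, recording gated to the field boundary. The
default mount height is 2.23 m, the raised late-season setting matching
the default trait distribution; 1.65 m suits early-season scenes. Every
random stream derives from one master seed via named spawns keyed by
(sensor, transect), so outputs are byte-identical per seed regardless of
execution order.

What the simulator deliberately omits: leaf-level organ geometry, wind
and plant motion, sensor intensity/multi-return behavior, GNSS multipath
and latency, and real soil spectral variation. Passing recovery tests
therefore demonstrate that the algorithms are correct and unbiased under
the stated canopy model, not that field data will match at the same
tolerances.

## Fisheye cover validation

The camera model is an ideal equi-solid fisheye (`r = 2f·sin(θ/2)`,
default f = 8 mm) leveled at 2.8 m over the plot center. Plot cropping
maps the ground rectangle's corners through the lens model and takes the
axis-aligned pixel bounding box — deliberately only an approximation of
the curvilinear true extent. The vegetation index is `(G − R)/(G + R)` on
raw 8-bit digital numbers (no radiometric calibration is modeled), which
separates green canopy from strongly red soils. Its histogram (256 bins
over [−1, 1], 5-bin moving-average smoothing) is split at the minimum bin
strictly between the two highest modes; modes must have prominence ≥ 15%
of the highest smoothed count, so sampling wiggle on a unimodal histogram
is not mistaken for bimodality — unimodal images fall back to a fixed
cutoff (default 0.0). Valley ties resolve to the lowest bin value.

The synthetic renderer paints random canopy discs on red soil under the
same lens model until the painted fraction reaches the target; the
achieved painted fraction is the recorded truth, so the estimator is
judged against exactly what was drawn. Validation regressions are
ordinary least squares of lidar on reference with r² = squared Pearson;
RMSE is computed on paired differences, not regression residuals, because
association and absolute agreement are different claims.

## Genetic summaries

Treatments are always analyzed separately. Breeding values are genotype
means of trait values adjusted for fixed design-row effects estimated
jointly with genotype by least squares, with reference-level (drop-first)
row coding: a disturbance confined to a non-reference row is absorbed
entirely by that row's effect and leaves breeding values untouched, and
any residual gauge shift is a common constant that cancels in
heritabilities and correlations. Variance components come from
method-of-moments expected-mean-squares ANOVA on the row-adjusted values —
the closed-form `σ̂²g = (MSg − MSe)/r` when balanced, Henderson-style
effective replicate number `r₀ = (N − Σn²ᵢ/N)/(g − 1)` otherwise — with a
negative genotype component clamped to zero. This estimator was chosen
over an iterative mixed-model fit because it reproduces the defined
quantity exactly and is checkable against hand arithmetic. Heritability
is `H² = 100·σ²g/(σ²g + σ²e)`; the denominator excludes any block/row
component by construction, since row effects are removed before the
ANOVA. The genetic correlation is the Pearson coefficient between two
traits' breeding values, reported with a two-sided permutation p-value
(10,000 label shuffles by default, seeded).

## Problem sizes and numerical choices

The default full-field session is 36 transects × 1098 sweeps × 2 sensors
(79,056 records, ≈ 55 MB per `.DAT` file) and runs in well under a minute;
recovery studies use a 72-plot height-gradient scene and 75 rendered
plot images, sizes at which the binomial and regression tolerances in the
tests are already decisive. Angle-count arithmetic guards against binary
representation of decimal degrees (270/0.36 evaluates below 750 in
doubles) with a 1e−9 slack before flooring; the same guard applies to
sweep counts per transect. Distances above the 4-digit field width raise
rather than widen, keeping the message size contract exact.

## Known limitations

- Plants taller than the mount height are physically unmeasurable; scenes
  must pair trait distributions with a sufficient mount height, as the
  real system did by raising the boom late in the season.
- CH is a per-sweep maximum and therefore inherits any positive outlier a
  misclassified beam would produce; the 50 mm threshold makes this rare
  under the modeled noise but real tassels, weeds or insects are not
  modeled.
- The equi-solid lens is ideal: no distortion residuals, vignetting or
  perspective layover; cropped tall-plant layover present in real imagery
  is out of scope.
- The EMS heritability assumes independent plot residuals; spatial
  autocorrelation beyond the row effect would inflate it.
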