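"""Synthetic dual-lidar scan sessions of a parametric maize field.

The simulator is first-class, tested code: it renders the ground truth that
every downstream stage is validated against.  A :class:`FieldScene` holds a
UTM-anchored grid of two-row plots with genotype-structured plant heights
and covers; :func:`simulate_session` drives a virtual boom carrying two
sensors (1.52 m apart, each centered over a plot furrow) along the field's
transects at 0.48 m·s⁻¹, emitting 5 Hz sweep messages with synthesized
GNGGA/GNRMC position strings, and writes one logger .DAT file per sensor
plus a per-plot truth table.

Canopy model: each crop row is an axis-aligned box (lateral half-width set
by the plot's target cover, top at the plot's canopy height) that a beam
entering it returns from with probability ``1 − porosity``; surviving beams
continue to the roughness-perturbed soil plane.  This is the simplest
geometry that produces tunable cover together with partial soil visibility
through canopy gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocol
from .errors import LayoutError, ParameterError
from .plot_pipeline import FieldLayout
from .sweep_geometry import SensorGeometry
from .trait_extraction import CalibrationState, ExtractionParams, \
    extract_block, initialize_zref

# Default UTM 12N anchor: roughly the modeled field site in central Arizona.
DEFAULT_ORIGIN = (409200.0, 3658200.0)

TREATMENTS = ("well-irrigated", "drought-stressed")


@dataclass(frozen=True)
class PlantModel:
    """Ground-truth canopy description of one plot."""

    canopy_height_m: float
    cover_fraction: float
    porosity: float
    row_offset_m: float = 0.38     # lateral position of each row from plot center
    row_halfwidth_m: float = 0.19  # half-width of each row's canopy box

    def __post_init__(self):
        if self.canopy_height_m < 0:
            raise ParameterError("canopy height must be non-negative")
        if not 0 <= self.cover_fraction <= 1:
            raise ParameterError("cover fraction must lie in [0, 1]")
        if not 0 <= self.porosity <= 1:
            raise ParameterError("porosity must lie in [0, 1]")


@dataclass(frozen=True)
class PlatformTrack:
    """Motion and mounting of the dual-sensor boom."""

    speed: float = 0.48            # m/s forward
    output_rate_hz: float = 5.0
    sensor_offset_m: float = 0.76  # each unit this far from platform center
    mount_height_m: float = 2.23   # tall-canopy operating point; early-season
    #                                sessions run at ~1.65 m

    def __post_init__(self):
        if self.speed <= 0 or self.output_rate_hz <= 0:
            raise ParameterError("speed and output rate must be positive")

    @property
    def sweep_spacing_m(self) -> float:
        return self.speed / self.output_rate_hz


@dataclass
class FieldScene:
    """Synthetic field: layout, per-plot plants, soil roughness."""

    layout: FieldLayout
    plants: pd.DataFrame  # indexed by plot_id
    soil_roughness_mm: float = 5.0

    def plant(self, plot_id: int) -> PlantModel:
        r = self.plants.loc[plot_id]
        return PlantModel(
            canopy_height_m=float(r.canopy_height_m),
            cover_fraction=float(r.cover_fraction),
            porosity=float(r.porosity),
            row_offset_m=float(r.row_offset_m),
            row_halfwidth_m=float(r.row_halfwidth_m),
        )


def _cover_to_halfwidth(cover: np.ndarray, porosity: np.ndarray,
                        halfwidth_m: float = 0.76) -> np.ndarray:
    """Row-box half-width producing a given beam-hit cover near nadir.

    Two rows of width ``2·rw`` inside a ``2·halfwidth`` window, each hit
    with probability ``1 − porosity``, give cover ≈ 2·rw·(1−p)/halfwidth.
    Capped at 0.37 m: row canopies can close over their own furrow but
    never quite span the inter-plot furrow, so a plot's canopy stays inside
    its own lateral window.
    """
    rw = cover * halfwidth_m / (2.0 * np.maximum(1.0 - porosity, 1e-9))
    return np.minimum(rw, 0.37)


def generate_field(
    seed: int,
    n_accessions: int = 248,
    n_checks: int = 4,
    check_reps: int = 10,
    blocks: int = 6,
    n_cols: int = 72,
    n_ranges: int = 24,
    plot_width: float = 1.52,
    plot_length: float = 3.66,
    alley: float = 0.76,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    mu_ch_m: tuple[float, float] = (1.1, 0.8),
    sigma_g_m: float = 0.25,
    sigma_e_m: float = 0.13,
    porosity: float = 0.25,
    cover_logit: tuple[float, float] = (-3.214, 2.695),
    soil_roughness_mm: float = 5.0,
) -> FieldScene:
    """Build a genotype-structured field scene with a known truth table.

    The default design mirrors a replicated diversity-panel trial: each of
    six blocks (three replicate blocks per irrigation treatment, laid out
    as 12-column bands) contains every accession once plus four check
    varieties planted ``check_reps`` times, filling 72 × 24 = 1728 plots.

    Genotype effects on canopy height are drawn once from
    ``Normal(0, σ_g²)`` and shared across treatments; plot values add
    treatment means and ``Normal(0, σ_e²)`` plot noise.  Target cover is
    logit-linear in height.
    """
    if n_cols % blocks:
        raise LayoutError(f"{n_cols} columns do not divide into {blocks} blocks")
    plots_per_block = (n_cols // blocks) * n_ranges
    if n_accessions + n_checks * check_reps != plots_per_block:
        raise LayoutError(
            f"{n_accessions} accessions + {n_checks}×{check_reps} checks "
            f"!= {plots_per_block} plots per block"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    genotypes = [f"G{i + 1:03d}" for i in range(n_accessions)] + \
                [f"CHK{i + 1}" for i in range(n_checks)]
    g_eff = dict(zip(genotypes, rng.normal(0.0, sigma_g_m, len(genotypes))))

    layout = FieldLayout(
        origin_easting=origin[0], origin_northing=origin[1],
        n_cols=n_cols, n_ranges=n_ranges, plot_width=plot_width,
        plot_length=plot_length, alley=alley,
    )
    plots = layout.plots
    cols_per_block = n_cols // blocks
    block_of_col = plots["col"] // cols_per_block
    plots["block"] = block_of_col
    plots["treatment"] = np.where(
        block_of_col < blocks // 2, TREATMENTS[0], TREATMENTS[1]
    )

    # randomized genotype assignment within each block
    entries = genotypes[:n_accessions] + \
        [g for g in genotypes[n_accessions:] for _ in range(check_reps)]
    assignment = np.empty(len(plots), dtype=object)
    for b in range(blocks):
        mask = (plots["block"] == b).to_numpy()
        perm = rng.permutation(entries)
        assignment[mask] = perm
    plots["genotype"] = assignment

    mu = np.where(plots["treatment"] == TREATMENTS[0], mu_ch_m[0], mu_ch_m[1])
    g = np.array([g_eff[x] for x in plots["genotype"]])
    ch = np.clip(mu + g + rng.normal(0.0, sigma_e_m, len(plots)), 0.08, None)
    a, b_slope = cover_logit
    cover = 1.0 / (1.0 + np.exp(-(a + b_slope * ch)))

    por = np.full(len(plots), porosity)
    plants = pd.DataFrame({
        "plot_id": plots["plot_id"],
        "canopy_height_m": ch,
        "cover_fraction": cover,
        "porosity": por,
        "row_offset_m": plot_width / 4.0,
        "row_halfwidth_m": _cover_to_halfwidth(cover, por, plot_width / 2.0),
    }).set_index("plot_id")

    return FieldScene(layout=layout, plants=plants,
                      soil_roughness_mm=soil_roughness_mm)


# ---------------------------------------------------------------------------
# Ray casting


def _box_entry(sin_a: np.ndarray, cos_a: np.ndarray, mount_mm: float,
               x1: np.ndarray, x2: np.ndarray, top: np.ndarray,
               active: np.ndarray):
    """Entry distance of each ray into a lateral slab × [0, top] box.

    ``sin_a``/``cos_a`` are per-angle ``(m,)``; ``x1``/``x2``/``top`` and
    ``active`` are per-sweep ``(n, 1)`` (mm).  Returns ``(t_entry, hit)``
    of shape ``(n, m)``.
    """
    sx = np.where(np.abs(sin_a) < 1e-12, 1e-12, sin_a)
    ta = x1 / sx
    tb = x2 / sx
    lo_x = np.minimum(ta, tb)
    hi_x = np.maximum(ta, tb)
    lo_z = (mount_mm - top) / cos_a
    hi_z = mount_mm / cos_a
    t_entry = np.maximum(lo_x, lo_z)
    hit = (t_entry <= np.minimum(hi_x, hi_z)) & (t_entry >= 0) & active & (top > 0)
    return t_entry, hit


def _sweep_boxes(scene: FieldScene, col: int, ys: np.ndarray, x_sensor: float):
    """Canopy boxes visible to a sensor over column ``col`` at northings ``ys``.

    Yields ``(x1_mm, x2_mm, top_mm, porosity, active)`` arrays of shape
    ``(n, 1)`` — two row boxes for the sensor's own column and each
    existing neighbor column (neighbors matter only as beam blockers).
    """
    lay = scene.layout
    rng_idx = np.floor((ys - lay.origin_northing) / lay.range_pitch).astype(int)
    off = ys - lay.origin_northing - rng_idx * lay.range_pitch
    in_plot = (rng_idx >= 0) & (rng_idx < lay.n_ranges) & (off <= lay.plot_length)
    rng_safe = np.clip(rng_idx, 0, lay.n_ranges - 1)

    for c in (col - 1, col, col + 1):
        if not 0 <= c < lay.n_cols:
            continue
        pids = c * lay.n_ranges + rng_safe
        sub = scene.plants.loc[pids]
        top = (sub["canopy_height_m"].to_numpy() * 1000.0)[:, None]
        por = sub["porosity"].to_numpy()[:, None]
        rw = (sub["row_halfwidth_m"].to_numpy() * 1000.0)[:, None]
        roff = (sub["row_offset_m"].to_numpy() * 1000.0)[:, None]
        center = (lay.column_center_easting(c) - x_sensor) * 1000.0
        act = in_plot[:, None]
        for sign in (-1.0, 1.0):
            xc = center + sign * roff
            yield xc - rw, xc + rw, top, por, act


def raycast_block(scene: FieldScene, x_sensor: float, ys: np.ndarray,
                  mount_mm: float, geom: SensorGeometry,
                  rng: np.random.Generator) -> np.ndarray:
    """Cast all rays of a stack of sweeps; returns integer mm distances.

    ``x_sensor`` is the sensor easting (m); ``ys`` the sweep northings (m).
    Each ray that enters a canopy box returns the box entry distance with
    probability ``1 − porosity`` (independently per box), otherwise it
    continues to the roughness-perturbed soil plane.  Distances are clamped
    to the 4-digit field bound (9999 mm) as the no-surface sentinel.
    """
    ys = np.asarray(ys, dtype=float)
    angles = np.radians(geom.angles())
    sin_a, cos_a = np.sin(angles), np.cos(angles)
    n, m = ys.size, geom.n_angles

    soil = rng.normal(0.0, scene.soil_roughness_mm, (n, m))
    d_best = (mount_mm - soil) / cos_a  # soil by default

    col = int(np.floor((x_sensor - scene.layout.origin_easting)
                       / scene.layout.plot_width))
    for x1, x2, top, por, act in _sweep_boxes(scene, col, ys, x_sensor):
        t, hit = _box_entry(sin_a, cos_a, mount_mm, x1, x2, top, act)
        returned = hit & (rng.random((n, m)) < (1.0 - por))
        d_best = np.where(returned & (t < d_best), t, d_best)

    return np.clip(np.rint(d_best), 0, 9999).astype(np.int32)


def raycast_sweep(scene: FieldScene, sensor_easting: float,
                  sensor_northing: float, mount_mm: float,
                  geom: SensorGeometry, rng: np.random.Generator) -> np.ndarray:
    """Single-sweep convenience wrapper around :func:`raycast_block`."""
    lay = scene.layout
    if not (lay.origin_easting - lay.plot_width <= sensor_easting
            <= lay.origin_easting + lay.field_width + lay.plot_width):
        raise ParameterError("sensor pose outside the field bounding box")
    return raycast_block(scene, sensor_easting,
                         np.array([sensor_northing]), mount_mm, geom, rng)[0]


def expected_plot_cover(scene: FieldScene, plot_id: int,
                        geom: SensorGeometry, mount_mm: float,
                        lateral_halfwidth_mm: float = 760.0,
                        h_min_mm: float = 50.0) -> float:
    """Effective beam-hit cover of a plot under the scan geometry.

    Deterministic expectation of the extractor's CC for a sensor centered
    over the plot furrow: per optical angle, canopy boxes are traversed in
    entry order accumulating Bernoulli survival; plant probability mass
    inside the lateral window goes to the numerator, surviving soil mass to
    the denominator.  Canopy returns at or below the plant threshold
    ``h_min_mm`` count as soil, exactly as the classifier treats them.
    Soil roughness is ignored (it does not move beams across the plant
    threshold at the modeled scales).
    """
    lay = scene.layout
    col, rng_i = divmod(int(plot_id), lay.n_ranges)
    x_sensor = lay.column_center_easting(col)
    y = lay.origin_northing + rng_i * lay.range_pitch + lay.plot_length / 2.0
    ys = np.array([y])

    angles = np.radians(geom.angles())
    sin_a, cos_a = np.sin(angles), np.cos(angles)
    m = geom.n_angles

    boxes = list(_sweep_boxes(scene, col, ys, x_sensor))
    t_mat = np.full((len(boxes), m), np.inf)
    p_mat = np.ones((len(boxes), m))
    for i, (x1, x2, top, por, act) in enumerate(boxes):
        t, hit = _box_entry(sin_a, cos_a, mount_mm, x1, x2, top, act)
        t_mat[i] = np.where(hit[0], t[0], np.inf)
        p_mat[i] = np.where(hit[0], por[0], 1.0)

    order = np.argsort(t_mat, axis=0)
    surv = np.ones(m)
    plant_w = np.zeros(m)
    soil_w = np.zeros(m)
    for rank in range(len(boxes)):
        idx = order[rank]
        t = t_mat[idx, np.arange(m)]
        por = p_mat[idx, np.arange(m)]
        enters = np.isfinite(t)
        t_safe = np.where(enters, t, 0.0)
        x_entry = t_safe * sin_a
        h_entry = mount_mm - t_safe * cos_a
        in_win = enters & (np.abs(x_entry) <= lateral_halfwidth_mm)
        returned = surv * (1.0 - por)
        plant_w += np.where(in_win & (h_entry > h_min_mm), returned, 0.0)
        soil_w += np.where(in_win & (h_entry <= h_min_mm), returned, 0.0)
        surv = np.where(enters, surv * por, surv)
    x_ground = mount_mm * sin_a / cos_a
    soil_w += np.where(np.abs(x_ground) <= lateral_halfwidth_mm, surv, 0.0)

    denom = plant_w.sum() + soil_w.sum()
    return float(plant_w.sum() / denom) if denom > 0 else float("nan")


def truth_table(scene: FieldScene, geom: SensorGeometry, mount_mm: float,
                lateral_halfwidth_mm: float = 760.0) -> pd.DataFrame:
    """Per-plot ground truth: true CH (m) and effective CC (%)."""
    rows = []
    for pid in scene.layout.plots["plot_id"]:
        cc = expected_plot_cover(scene, pid, geom, mount_mm,
                                 lateral_halfwidth_mm)
        rows.append((pid, cc))
    t = pd.DataFrame(rows, columns=["plot_id", "true_cc"])
    out = scene.layout.plots[["plot_id", "genotype", "treatment", "block",
                              "col"]].rename(columns={"col": "row"}).copy()
    out["true_ch_m"] = scene.plants["canopy_height_m"].to_numpy()
    out["true_cc_pct"] = t["true_cc"].to_numpy() * 100.0
    return out


# ---------------------------------------------------------------------------
# Session simulation


@dataclass(frozen=True)
class SessionResult:
    """File outputs and calibration of one simulated scan session."""

    dat00: Path
    dat01: Path
    truth_csv: Path
    layout_csv: Path
    calibration: CalibrationState
    n_records_per_sensor: int


def transect_record_count(scanned_length_m: float, spacing_m: float) -> int:
    """Sweeps recorded along one transect: ``floor(L / spacing) + 1``."""
    return int(math.floor(scanned_length_m / spacing_m * (1 + 1e-12) + 1e-9)) + 1


def simulate_session(scene: FieldScene, track: PlatformTrack, seed: int,
                     out_dir, geom: SensorGeometry | None = None,
                     date_utc: str = "2018-09-25",
                     start_utc: str = "17:00:00") -> SessionResult:
    """Simulate a full two-sensor scan of the field and write its files.

    One transect per pair of adjacent plot columns: the platform travels
    north with sensor 00 over the even column of the pair and sensor 01
    over the odd column, emitting interlaced messages every
    ``speed / output_rate`` metres.  Recording is gated to the field
    boundary (no records during turns).  Initialization parks the sensors
    over the first alley to measure ZREF exactly as the controller does.

    Writes ``lidar00.dat``, ``lidar01.dat``, ``truth.csv`` and
    ``layout.csv`` under ``out_dir``.
    """
    if geom is None:
        geom = SensorGeometry(output_rate_hz=track.output_rate_hz)
    lay = scene.layout
    if lay.n_cols % 2:
        raise LayoutError("dual-sensor transects need an even column count")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mount_mm = track.mount_height_m * 1000.0
    n_transects = lay.n_cols // 2

    seq = np.random.SeedSequence(seed)
    init_ss, *transect_ss = seq.spawn(1 + 2 * n_transects)

    # --- initialization over the first alley (clear soil between ranges)
    init_rng = np.random.default_rng(init_ss)
    y_alley = lay.origin_northing + lay.plot_length + lay.alley / 2.0
    x00 = lay.column_center_easting(0)
    x01 = lay.column_center_easting(1)
    sweep00 = raycast_block(scene, x00, np.array([y_alley]), mount_mm, geom,
                            init_rng)[0]
    sweep01 = raycast_block(scene, x01, np.array([y_alley]), mount_mm, geom,
                            init_rng)[0]
    calib = initialize_zref(sweep00, sweep01, geom)
    zref_int = int(round(calib.zref_mm))

    spacing = track.sweep_spacing_m
    cnt = transect_record_count(lay.field_length, spacing)
    ys = lay.origin_northing + np.arange(cnt) * spacing
    # gate to the experiment boundary (pause outside)
    ys = ys[(ys >= lay.origin_northing)
            & (ys <= lay.origin_northing + lay.field_length)]

    params = ExtractionParams(lateral_halfwidth_mm=lay.plot_width * 500.0)
    per_sensor: dict[str, dict[str, list]] = {
        "00": {"dist": [], "e": [], "n": []},
        "01": {"dist": [], "e": [], "n": []},
    }
    for t in range(n_transects):
        for k, (addr, col) in enumerate((("00", 2 * t), ("01", 2 * t + 1))):
            rng = np.random.default_rng(transect_ss[2 * t + k])
            x_s = lay.column_center_easting(col)
            block = raycast_block(scene, x_s, ys, mount_mm, geom, rng)
            per_sensor[addr]["dist"].append(block)
            per_sensor[addr]["e"].append(np.full(ys.size, x_s))
            per_sensor[addr]["n"].append(ys.copy())

    h0, m0, s0 = (int(v) for v in start_utc.split(":"))
    t0 = h0 * 3600 + m0 * 60 + s0
    nmea_date = date_utc[8:10] + date_utc[5:7] + date_utc[2:4]

    paths = {"00": out_dir / "lidar00.dat", "01": out_dir / "lidar01.dat"}
    n_records = 0
    for addr in ("00", "01"):
        dist = np.vstack(per_sensor[addr]["dist"])
        east = np.concatenate(per_sensor[addr]["e"])
        north = np.concatenate(per_sensor[addr]["n"])
        n_records = dist.shape[0]

        srefs = extract_block(dist, calib, geom, params)["sref_mm"].to_numpy()
        lat, lon = protocol.from_utm(east, north)

        records = []
        for i in range(n_records):
            sec = t0 + i * (1.0 / track.output_rate_hz)
            hh, rem = divmod(int(sec), 3600)
            mm_, ss = divmod(rem, 60)
            frac = sec - int(sec)
            utc = f"{hh:02d}{mm_:02d}{ss:02d}.{int(round(frac * 100)):02d}"
            gga = protocol.make_gngga(lat[i], lon[i], utc)
            rmc = protocol.make_gnrmc(lat[i], lon[i], utc, date=nmea_date)
            plat, plon, quality, _ = protocol.parse_nmea_position(gga, rmc)
            pe, pn = protocol.to_utm(plat, plon)
            msg = protocol.ControllerMessage(
                address=addr,
                timestamp_ms=(int(round(sec * 1000)) + (110 if addr == "01" else 0))
                % 10**8,
                zref_mm=zref_int,
                sref_mm=int(round(srefs[i])),
                distances=dist[i],
            )
            raw = protocol.serialize_message(msg).decode("ascii").rstrip("\n")
            ts = f"{date_utc} {hh:02d}:{mm_:02d}:{ss:02d}.{int(round(frac * 10)):01d}"
            records.append(protocol.LoggerRecord(
                logger_timestamp=ts, record_number=i, latitude=plat,
                longitude=plon, gnss_quality=quality, easting=pe,
                northing=pn, message=raw,
            ))
        protocol.write_dat(records, paths[addr], table=f"lidar{addr}")

    truth = truth_table(scene, geom, mount_mm, params.lateral_halfwidth_mm)
    truth_csv = out_dir / "truth.csv"
    truth.to_csv(truth_csv, index=False)
    layout_csv = out_dir / "layout.csv"
    lay.to_text(layout_csv)

    return SessionResult(
        dat00=paths["00"], dat01=paths["01"], truth_csv=truth_csv,
        layout_csv=layout_csv, calibration=calib,
        n_records_per_sensor=n_records,
    )


# ---------------------------------------------------------------------------
# Trait-table generator for quantitative-genetic recovery studies


def simulate_trait_table(n_genotypes: int = 252, reps: int = 3,
                         h2_pct: float = 78.0, mu: float = 1.1,
                         var_g: float = 0.0625, seed: int = 0,
                         treatment: str = TREATMENTS[0]) -> pd.DataFrame:
    """Balanced genotype × replicate trait table with known heritability.

    Residual variance is set from the target broad-sense heritability:
    ``σ_e² = σ_g² (100 − H²) / H²``.  Each replicate is one design row, so
    the table is a randomized-complete-block analogue.
    """
    if not 0 < h2_pct <= 100:
        raise ParameterError("heritability must lie in (0, 100]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    var_e = var_g * (100.0 - h2_pct) / h2_pct
    g = rng.normal(0.0, math.sqrt(var_g), n_genotypes)
    rows = []
    for r in range(reps):
        noise = rng.normal(0.0, math.sqrt(var_e), n_genotypes)
        for i in range(n_genotypes):
            rows.append((f"G{i + 1:03d}", r, treatment, mu + g[i] + noise[i]))
    return pd.DataFrame(rows, columns=["genotype", "row", "treatment", "trait"])
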