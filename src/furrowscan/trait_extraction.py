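"""Soil-reference calibration and per-sweep canopy height / cover extraction.

The sensors are mounted nadir-down and centered over the furrow between a
plot's two crop rows, so the center of every sweep sees soil whenever the
canopy has not closed over the furrow.  Height is therefore measured
against a *soil reference*:

* **ZREF** — the session reference, measured once at initialization with
  the platform parked over a clear alley: the mean vertical distance of the
  29 beams in the center 10° window, averaged over both sensors.
* **SREF** — the dynamic per-sweep reference: the mean vertical distance of
  center-window beams that still look like soil (within a tolerance of
  ZREF); when the canopy closes over the furrow the sweep falls back to
  ZREF.

Each return is projected to its vertical drop ``z = d·cos(θ)``.  A return
is a *plant hit* when it sits more than ``h_min`` above SREF; per sweep,
canopy height CH is the tallest plant hit (in metres above SREF) and canopy
cover CC is the fraction of in-plot beams that are plant hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InitializationError, ParameterError
from .sweep_geometry import SensorGeometry, center_window_indices

PLANT, SOIL, EXCLUDED = 1, 0, -1


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable thresholds of the extraction algorithms (all in mm / degrees).

    ``h_min_mm`` — minimum height above SREF for a plant classification
    (strict inequality; default 50 mm, several times the observed
    soil-reference uncertainty band).
    ``soil_tol_mm`` — half-width of the soil gate around ZREF used when
    picking SREF points.
    ``min_soil_points`` — fewer qualifying center-window points than this
    triggers the ZREF fallback.
    ``window_deg`` — angular width of the nadir-centered soil window.
    ``lateral_halfwidth_mm`` — half-width of the in-plot lateral window
    (plot half-width, 760 mm for 1.52 m plots).
    ``max_range_mm`` — sentinel value for beams with no surface return.
    """

    h_min_mm: float = 50.0
    soil_tol_mm: float = 50.0
    min_soil_points: int = 5
    window_deg: float = 10.0
    lateral_halfwidth_mm: float = 760.0
    max_range_mm: int = 9999


@dataclass(frozen=True)
class CalibrationState:
    """Session soil reference, overall and per sensor (mm)."""

    zref_mm: float
    per_sensor_zref_mm: tuple[float, float]


@dataclass(frozen=True)
class SweepTraits:
    """Per-sweep extracted products."""

    sref_mm: float
    ch_m: float
    cc_frac: float
    n_plant_hits: int
    n_soil_hits: int


def _window_vertical(sweep: np.ndarray, geom: SensorGeometry,
                     window_deg: float) -> tuple[np.ndarray, np.ndarray]:
    sweep = np.asarray(sweep, dtype=float)
    if sweep.shape != (geom.n_angles,):
        raise ParameterError(
            f"sweep must have {geom.n_angles} distances, got {sweep.shape}"
        )
    idx = center_window_indices(window_deg, geom)
    angles = np.radians(geom.angles()[idx])
    return sweep[idx], sweep[idx] * np.cos(angles)


def initialize_zref(sweep00: np.ndarray, sweep01: np.ndarray,
                    geom: SensorGeometry,
                    params: ExtractionParams = ExtractionParams()) -> CalibrationState:
    """Session initialization over clear soil.

    Each sensor's reference is the mean vertical distance of the 29
    center-window beams (for the 10° default window); ZREF is the average
    of the two sensors.  Any max-range return inside the window indicates
    the sensor is not looking at soil and aborts initialization.
    """
    per_sensor = []
    for sweep in (sweep00, sweep01):
        d, z = _window_vertical(sweep, geom, params.window_deg)
        if np.any(d >= params.max_range_mm):
            raise InitializationError(
                "max-range return inside the initialization window; "
                "sensors must be parked over clear soil"
            )
        per_sensor.append(float(np.mean(z)))
    return CalibrationState(
        zref_mm=float(np.mean(per_sensor)),
        per_sensor_zref_mm=(per_sensor[0], per_sensor[1]),
    )


def compute_sref(sweep: np.ndarray, calib: CalibrationState,
                 geom: SensorGeometry,
                 params: ExtractionParams = ExtractionParams()) -> float:
    """Dynamic soil reference for one sweep.

    Mean vertical distance of center-window beams within ``soil_tol_mm`` of
    ZREF; falls back to ZREF when fewer than ``min_soil_points`` qualify
    (canopy closed over the furrow).
    """
    d, z = _window_vertical(sweep, geom, params.window_deg)
    ok = (np.abs(z - calib.zref_mm) <= params.soil_tol_mm) & (d < params.max_range_mm)
    if ok.sum() < params.min_soil_points:
        return calib.zref_mm
    return float(np.mean(z[ok]))


def classify_hits(sweep: np.ndarray, sref_mm: float, geom: SensorGeometry,
                  params: ExtractionParams = ExtractionParams()) -> np.ndarray:
    """Per-beam plant/soil labels for one sweep.

    A beam is a plant hit iff its height above SREF strictly exceeds
    ``h_min_mm``; otherwise soil.  Max-range beams represent no surface and
    are excluded from both classes.
    """
    sweep = np.asarray(sweep, dtype=float)
    z = sweep * np.cos(np.radians(geom.angles()))
    labels = np.where(sref_mm - z > params.h_min_mm, PLANT, SOIL)
    labels[sweep >= params.max_range_mm] = EXCLUDED
    return labels


def sweep_traits(sweep: np.ndarray, calib: CalibrationState,
                 geom: SensorGeometry,
                 params: ExtractionParams = ExtractionParams()) -> SweepTraits:
    """Extract SREF, CH and CC from a single sweep."""
    df = extract_block(np.asarray(sweep, dtype=float)[None, :], calib, geom, params)
    row = df.iloc[0]
    return SweepTraits(
        sref_mm=float(row.sref_mm), ch_m=float(row.ch_m),
        cc_frac=float(row.cc_frac),
        n_plant_hits=int(row.n_plant), n_soil_hits=int(row.n_soil),
    )


def extract_block(distances: np.ndarray, calib: CalibrationState,
                  geom: SensorGeometry,
                  params: ExtractionParams = ExtractionParams()) -> pd.DataFrame:
    """Vectorized extraction over a stack of sweeps.

    ``distances`` is ``(n_sweeps, n_angles)`` in integer or float mm.
    Returns a DataFrame with one row per sweep: ``sref_mm``, ``ch_m``,
    ``cc_frac`` (NaN when no in-window beam is valid), ``n_plant``,
    ``n_soil``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[1] != geom.n_angles:
        raise ParameterError(
            f"distances must be (n, {geom.n_angles}), got {d.shape}"
        )
    angles = np.radians(geom.angles())
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    z = d * cos_a            # vertical drop, mm
    x = d * sin_a            # lateral offset, mm
    valid = d < params.max_range_mm

    # SREF per sweep from the nadir soil window
    widx = center_window_indices(params.window_deg, geom)
    zw, vw = z[:, widx], valid[:, widx]
    soil_pt = vw & (np.abs(zw - calib.zref_mm) <= params.soil_tol_mm)
    n_ok = soil_pt.sum(axis=1)
    sums = np.where(soil_pt, zw, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sref = np.where(n_ok >= params.min_soil_points,
                        sums / np.maximum(n_ok, 1), calib.zref_mm)

    height = sref[:, None] - z   # mm above soil reference
    plant = valid & (height > params.h_min_mm)
    in_window = valid & (np.abs(x) <= params.lateral_halfwidth_mm)
    plant_w = plant & in_window
    soil_w = in_window & ~plant

    n_plant = plant_w.sum(axis=1)
    n_soil = soil_w.sum(axis=1)
    ch = np.where(plant_w, height, 0.0).max(axis=1) / 1000.0
    denom = n_plant + n_soil
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, n_plant / np.maximum(denom, 1), np.nan)

    return pd.DataFrame({
        "sref_mm": sref, "ch_m": ch, "cc_frac": cc,
        "n_plant": n_plant, "n_soil": n_soil,
    })
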