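"""Plot identification, alley removal, by-plot summaries and sensor merge.

The experimental layout is a UTM-anchored grid of two-row plots (default
1728 plots of 3.66 m × 1.52 m arranged as 72 columns × 24 ranges, with
unplanted alleys between ranges).  Extracted per-sweep records are tagged
with the plot polygon containing their GNSS position; records falling in
alleys, buffers or outside the field are removed.  Each plot is then
summarized as the mean and sample standard deviation of its per-sweep
canopy height and cover, and the two per-sensor summary tables are merged
into a single file with exactly one line per plot.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .errors import IntegrityError, LayoutError, ParameterError

SUMMARY_COLUMNS = [
    "plot_id", "genotype", "treatment", "block", "row", "n_records",
    "ch_mean_m", "ch_sd_m", "cc_mean_pct", "cc_sd_pct",
]


@dataclass
class FieldLayout:
    """Regular grid of plot polygons anchored in UTM zone 12N metres.

    Plot ids run range-major within column: ``plot_id = col * n_ranges +
    rng``.  Columns are contiguous east–west strips of ``plot_width``;
    ranges are separated by unplanted alleys of ``alley`` metres along the
    travel (northing) direction.
    """

    origin_easting: float
    origin_northing: float
    n_cols: int = 72
    n_ranges: int = 24
    plot_width: float = 1.52
    plot_length: float = 3.66
    alley: float = 0.76
    plots: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_cols <= 0 or self.n_ranges <= 0:
            raise LayoutError("layout must have positive plot counts")
        if self.plot_width <= 0 or self.plot_length <= 0 or self.alley <= 0:
            raise LayoutError("plot dimensions and alley width must be positive")
        if self.plots is None:
            ids = np.arange(self.n_cols * self.n_ranges)
            self.plots = pd.DataFrame({
                "plot_id": ids,
                "col": ids // self.n_ranges,
                "rng": ids % self.n_ranges,
                "genotype": "", "treatment": "", "block": -1,
            })
        if len(self.plots) != self.n_cols * self.n_ranges:
            raise LayoutError(
                f"plot table has {len(self.plots)} rows for a "
                f"{self.n_cols}×{self.n_ranges} grid"
            )

    # geometry -------------------------------------------------------------

    @property
    def range_pitch(self) -> float:
        return self.plot_length + self.alley

    @property
    def field_length(self) -> float:
        """North–south extent from the first plot edge to the last (m)."""
        return self.n_ranges * self.plot_length + (self.n_ranges - 1) * self.alley

    @property
    def field_width(self) -> float:
        return self.n_cols * self.plot_width

    def plot_origin(self, plot_id: int) -> tuple[float, float]:
        col, rng = divmod(int(plot_id), self.n_ranges)
        return (self.origin_easting + col * self.plot_width,
                self.origin_northing + rng * self.range_pitch)

    def polygon(self, plot_id: int):
        x0, y0 = self.plot_origin(plot_id)
        return box(x0, y0, x0 + self.plot_width, y0 + self.plot_length)

    def polygons(self) -> list:
        return [self.polygon(p) for p in self.plots["plot_id"]]

    def plot_center(self, plot_id: int) -> tuple[float, float]:
        x0, y0 = self.plot_origin(plot_id)
        return x0 + self.plot_width / 2, y0 + self.plot_length / 2

    def column_center_easting(self, col: int) -> float:
        return self.origin_easting + (col + 0.5) * self.plot_width

    # assignment -----------------------------------------------------------

    def assign(self, easting, northing) -> np.ndarray:
        """Vectorized plot assignment; −1 for alleys/buffers/outside.

        Edges shared by two plots are half-open: the point belongs to the
        plot with the larger origin.  Points on the field's outer boundary
        belong to the adjacent edge plot (they are inside exactly one
        closed polygon).
        """
        e = np.atleast_1d(np.asarray(easting, dtype=float))
        n = np.atleast_1d(np.asarray(northing, dtype=float))
        xr = e - self.origin_easting
        yr = n - self.origin_northing
        tol = 1e-6  # metres; absorbs float noise on exact boundaries

        col = np.floor(xr / self.plot_width + tol).astype(int)
        # outer east edge: closed (inside exactly one polygon)
        col[np.abs(xr - self.n_cols * self.plot_width) <= tol] = self.n_cols - 1
        ok_col = (col >= 0) & (col < self.n_cols)

        rng = np.floor(yr / self.range_pitch + tol).astype(int)
        off = yr - rng * self.range_pitch
        # north edge of each plot faces an alley, so it is closed
        in_range = off <= self.plot_length + tol
        ok_rng = (rng >= 0) & (rng < self.n_ranges) & in_range

        out = np.where(ok_col & ok_rng, col * self.n_ranges + rng, -1)
        return out

    # serialization --------------------------------------------------------

    def to_text(self, path) -> None:
        """Write the layout as commented-header CSV (UTM 12N metres)."""
        header = (
            f"# furrowscan layout v1\n"
            f"# origin_easting={self.origin_easting!r} "
            f"origin_northing={self.origin_northing!r}\n"
            f"# n_cols={self.n_cols} n_ranges={self.n_ranges} "
            f"plot_width={self.plot_width!r} plot_length={self.plot_length!r} "
            f"alley={self.alley!r}\n"
        )
        buf = io.StringIO()
        self.plots.to_csv(buf, index=False)
        Path(path).write_text(header + buf.getvalue())

    @classmethod
    def from_text(cls, path) -> "FieldLayout":
        text = Path(path).read_text().splitlines()
        if not text or "furrowscan layout" not in text[0]:
            raise LayoutError(f"{path} is not a layout file")
        meta: dict[str, float] = {}
        body_start = 0
        for i, line in enumerate(text):
            if not line.startswith("#"):
                body_start = i
                break
            for tok in line.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = float(v)
        plots = pd.read_csv(
            io.StringIO("\n".join(text[body_start:])),
            dtype={"genotype": str, "treatment": str},
            keep_default_na=False,
        )
        return cls(
            origin_easting=meta["origin_easting"],
            origin_northing=meta["origin_northing"],
            n_cols=int(meta["n_cols"]), n_ranges=int(meta["n_ranges"]),
            plot_width=meta["plot_width"], plot_length=meta["plot_length"],
            alley=meta["alley"], plots=plots,
        )


def assign_plot(easting: float, northing: float, layout: FieldLayout):
    """Plot id containing a point, or ``None`` for alleys/buffers/outside."""
    out = int(layout.assign(easting, northing)[0])
    return None if out < 0 else out


def assign_plot_bruteforce(easting: float, northing: float,
                           layout: FieldLayout):
    """Reference assignment by shapely containment over all plot polygons.

    A point inside exactly one closed polygon belongs to it; a point on a
    boundary shared by several polygons belongs to the one with the larger
    (northing, easting) origin.  Quadratic; intended for cross-checking.
    """
    p = Point(easting, northing)
    hits = [pid for pid in layout.plots["plot_id"]
            if layout.polygon(pid).intersects(p)]
    if not hits:
        return None
    hits.sort(key=lambda pid: layout.plot_origin(pid)[::-1])
    return int(hits[-1])


# ---------------------------------------------------------------------------
# Summaries


def summarize_plots(records: pd.DataFrame, layout: FieldLayout) -> pd.DataFrame:
    """Per-plot mean and sample sd (ddof=1) of CH and CC.

    ``records`` must carry ``plot_id`` (−1 rows are ignored), ``ch_m`` and
    ``cc_frac``.  The output has exactly one row per layout plot, in plot-id
    order; plots with no records carry NaN statistics and ``n_records`` 0.
    CC statistics are reported in percent.
    """
    tagged = records[records["plot_id"] >= 0]
    g = tagged.groupby("plot_id")
    stats = pd.DataFrame({
        "n_records": g.size(),
        "ch_mean_m": g["ch_m"].mean(),
        "ch_sd_m": g["ch_m"].std(ddof=1),
        "cc_mean_pct": g["cc_frac"].mean() * 100.0,
        "cc_sd_pct": g["cc_frac"].std(ddof=1) * 100.0,
    })
    out = layout.plots[["plot_id", "genotype", "treatment", "block", "col"]] \
        .rename(columns={"col": "row"}).copy()
    out = out.merge(stats, how="left", left_on="plot_id", right_index=True)
    out["n_records"] = out["n_records"].fillna(0).astype(int)
    return out.sort_values("plot_id").reset_index(drop=True)[SUMMARY_COLUMNS]


def merge_sensor_summaries(summary00: pd.DataFrame,
                           summary01: pd.DataFrame) -> pd.DataFrame:
    """Union of two per-sensor summary tables, keyed by plot.

    Where both sensors observed a plot, statistics are combined as
    record-count-weighted means and the record counts add.  Conflicting
    genotype labels for one plot raise :class:`IntegrityError`.
    """
    a = summary00.set_index("plot_id")
    b = summary01.set_index("plot_id")
    if not a.index.equals(b.index):
        raise IntegrityError("sensor summaries cover different plot sets")
    for col in ("genotype", "treatment", "block", "row"):
        both = (a["n_records"] > 0) & (b["n_records"] > 0)
        if not (a.loc[both, col] == b.loc[both, col]).all():
            raise IntegrityError(f"conflicting {col} labels between sensors")

    na = a["n_records"].to_numpy(dtype=float)
    nb = b["n_records"].to_numpy(dtype=float)
    out = a.copy()
    # carry labels from whichever sensor saw the plot
    for col in ("genotype", "treatment", "block", "row"):
        out[col] = np.where(na > 0, a[col], b[col])
    for col in ("ch_mean_m", "ch_sd_m", "cc_mean_pct", "cc_sd_pct"):
        va, vb = a[col].to_numpy(dtype=float), b[col].to_numpy(dtype=float)
        wa = np.where(np.isnan(va), 0.0, na)
        wb = np.where(np.isnan(vb), 0.0, nb)
        tot = wa + wb
        with np.errstate(invalid="ignore", divide="ignore"):
            out[col] = np.where(
                tot > 0,
                (np.nan_to_num(va) * wa + np.nan_to_num(vb) * wb)
                / np.maximum(tot, 1.0),
                np.nan,
            )
    out["n_records"] = (na + nb).astype(int)
    return out.reset_index()[SUMMARY_COLUMNS]


# ---------------------------------------------------------------------------
# Field capacity


def process_session(dat00, dat01, layout: FieldLayout,
                    geom=None, params=None, log=None):
    """Run the full post-processing pipeline on a two-sensor session.

    Stages: read .DAT → reformat (parse messages, UTM positions) → extract
    per-sweep SREF/CH/CC → tag records with plot ids (alley and buffer
    records removed) → per-plot summaries per sensor → merge.

    Returns ``(summary, counts)`` where ``summary`` has one row per layout
    plot and ``counts`` is a per-stage record ledger satisfying
    ``records_read == assigned + removed`` per sensor.
    """
    from . import protocol
    from .sweep_geometry import SensorGeometry
    from .trait_extraction import CalibrationState, ExtractionParams, extract_block

    if geom is None:
        geom = SensorGeometry()
    if params is None:
        params = ExtractionParams()
    log = log or (lambda msg: None)

    counts: dict[str, int] = {}
    summaries = []
    for label, path in (("00", dat00), ("01", dat01)):
        records, skipped = protocol.read_dat(path)
        counts[f"records_read_{label}"] = len(records)
        counts[f"records_skipped_{label}"] = skipped
        log(f"sensor {label}: read {len(records)} records ({skipped} skipped)")

        table = protocol.reformat(records, geom)
        zrefs = table["zref_mm"].unique()
        if len(zrefs) > 1:
            raise IntegrityError(
                f"sensor {label}: ZREF changes mid-session: {sorted(zrefs)}"
            )
        calib = CalibrationState(float(zrefs[0]), (float(zrefs[0]),) * 2)

        dist_cols = [c for c in table.columns if c.startswith("d")
                     and c[1:].isdigit()]
        traits = extract_block(
            table[dist_cols].to_numpy(), calib, geom, params
        )
        traits["easting"] = table["easting"].to_numpy()
        traits["northing"] = table["northing"].to_numpy()
        traits["timestamp"] = table["timestamp"].to_numpy()

        traits["plot_id"] = layout.assign(
            traits["easting"].to_numpy(), traits["northing"].to_numpy()
        )
        assigned = int((traits["plot_id"] >= 0).sum())
        counts[f"records_assigned_{label}"] = assigned
        counts[f"records_removed_{label}"] = len(traits) - assigned
        log(f"sensor {label}: {assigned} in-plot, "
            f"{len(traits) - assigned} removed (alleys/buffers)")

        summaries.append(summarize_plots(traits, layout))

    merged = merge_sensor_summaries(summaries[0], summaries[1])
    counts["summary_rows"] = len(merged)
    log(f"merged summary: {len(merged)} plot lines")
    return merged, counts


def field_capacity(speed: float, swath: float) -> float:
    """Theoretical field capacity in m²·min⁻¹ from speed (m/s) and swath (m)."""
    if speed <= 0 or swath <= 0:
        raise ParameterError("speed and swath must be positive")
    return speed * swath * 60.0


def field_efficiency(actual: float, theoretical: float) -> float:
    """Field efficiency in percent: 100 · actual / theoretical capacity."""
    if theoretical <= 0:
        raise ParameterError("theoretical capacity must be positive")
    if actual < 0:
        raise ParameterError("actual capacity must be non-negative")
    return 100.0 * actual / theoretical
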