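"""Image-based fractional-cover estimation used to validate lidar cover.

An overhead fisheye camera (equi-solid projection, ``r = 2f·sin(θ/2)``) is
leveled and centered mid-plot about 2.8 m above ground.  Each image is
cropped to a rectangular approximation of the plot's extent, converted to
a green–red normalized difference index ``(G − R)/(G + R)``, and classified
by the local minimum between the two modes of the index histogram (green
canopy vs. strongly red soil).  The green fraction is the ratio of pixels
above the threshold to all valid pixels.  A synthetic plot-image renderer
with known painted cover makes the whole path testable without photographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NoThresholdError, ParameterError


@dataclass(frozen=True)
class FisheyeModel:
    """Ideal equi-solid fisheye camera looking straight down.

    ``f`` is the lens focal length and ``pixels_per_unit_r`` the sensor
    scale, in consistent length units (mm here); ``camera_height_m`` is the
    nadir height above ground.
    """

    f: float = 8.0
    camera_height_m: float = 2.8
    image_center: tuple[float, float] = (200.0, 200.0)
    pixels_per_unit_r: float = 31.0

    def __post_init__(self):
        if self.f <= 0 or self.camera_height_m <= 0 or self.pixels_per_unit_r <= 0:
            raise ParameterError("fisheye parameters must be positive")


def equisolid_radius(theta: float, f: float):
    """Equi-solid image radius ``r = 2·f·sin(θ/2)`` for view angle θ (deg)."""
    if np.any(np.asarray(f) <= 0):
        raise ParameterError("focal length must be positive")
    th = np.asarray(theta, dtype=float)
    if np.any((th < 0) | (th > 180)):
        raise ParameterError("view angle must lie in [0, 180] degrees")
    r = 2.0 * f * np.sin(np.radians(th) / 2.0)
    return float(r) if np.ndim(theta) == 0 else r


def ground_to_pixel(model: FisheyeModel, gx, gy):
    """Map ground offsets from nadir (m) to pixel coordinates (col, row)."""
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    rho = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(rho, model.camera_height_m))
    r_pix = equisolid_radius(theta, model.f) * model.pixels_per_unit_r
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(rho > 0, gx / np.maximum(rho, 1e-300), 0.0)
        uy = np.where(rho > 0, gy / np.maximum(rho, 1e-300), 0.0)
    return model.image_center[0] + r_pix * ux, model.image_center[1] + r_pix * uy


def pixel_to_ground(model: FisheyeModel, px, py):
    """Inverse of :func:`ground_to_pixel`; NaN outside the hemisphere."""
    dx = (np.asarray(px, dtype=float) - model.image_center[0]) \
        / model.pixels_per_unit_r
    dy = (np.asarray(py, dtype=float) - model.image_center[1]) \
        / model.pixels_per_unit_r
    r = np.hypot(dx, dy)
    s = r / (2.0 * model.f)
    with np.errstate(invalid="ignore"):
        theta = 2.0 * np.arcsin(np.minimum(s, 1.0))
        rho = model.camera_height_m * np.tan(theta)
    rho = np.where((s <= math.sin(math.radians(45.0))) & (theta < math.pi / 2),
                   rho, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        gx = np.where(r > 0, rho * dx / np.maximum(r, 1e-300), 0.0)
        gy = np.where(r > 0, rho * dy / np.maximum(r, 1e-300), 0.0)
    return gx, gy


def crop_to_plot(image: np.ndarray, model: FisheyeModel,
                 extent: tuple[float, float, float, float]) -> np.ndarray:
    """Axis-aligned crop of the pixel bounding box of a ground rectangle.

    ``extent`` is ``(xmin, xmax, ymin, ymax)`` in metres relative to nadir.
    The rectangular crop is deliberately only an approximation of the true
    curvilinear plot extent.  Extents reaching beyond the image are clipped
    with a warning.
    """
    xmin, xmax, ymin, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ParameterError("plot extent must have positive area")
    corners_x = np.array([xmin, xmin, xmax, xmax])
    corners_y = np.array([ymin, ymax, ymin, ymax])
    px, py = ground_to_pixel(model, corners_x, corners_y)
    c0, c1 = int(np.floor(px.min())), int(np.ceil(px.max()))
    r0, r1 = int(np.floor(py.min())), int(np.ceil(py.max()))
    h, w = image.shape[:2]
    if c0 < 0 or r0 < 0 or c1 > w or r1 > h:
        import warnings

        warnings.warn("plot extent reaches beyond the image; crop clipped",
                      stacklevel=2)
    c0, c1 = max(c0, 0), min(c1, w)
    r0, r1 = max(r0, 0), min(r1, h)
    return image[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# Index + thresholding


def gndvi(red: np.ndarray, green: np.ndarray) -> np.ndarray:
    """Per-pixel green–red normalized difference ``(G − R)/(G + R)``.

    Pixels with ``G + R == 0`` are undefined (NaN).  Bands are interpreted
    as non-negative digital numbers.
    """
    r = np.asarray(red, dtype=float)
    g = np.asarray(green, dtype=float)
    if r.shape != g.shape:
        raise ParameterError(f"band shapes differ: {r.shape} vs {g.shape}")
    if np.any(r < 0) or np.any(g < 0):
        raise ParameterError("band values must be non-negative")
    total = g + r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (g - r) / np.where(total > 0, total, 1.0),
                       np.nan)
    return out


def index_histogram(index_image: np.ndarray, bins: int = 256,
                    value_range: tuple[float, float] = (-1.0, 1.0)):
    """Histogram of an index image over its defined pixels."""
    vals = np.asarray(index_image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    counts, edges = np.histogram(vals, bins=bins, range=value_range)
    return counts, edges


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(counts, dtype=float), kernel, mode="same")


def bimodal_threshold(counts: np.ndarray, edges: np.ndarray,
                      smooth_window: int = 5,
                      prominence_frac: float = 0.15) -> float:
    """Valley threshold of a bimodal histogram.

    Counts are smoothed with a moving average; modes are local maxima with
    prominence of at least ``prominence_frac`` of the highest smoothed
    count (so sampling wiggle on a single mode does not masquerade as
    bimodality).  The bin-center of the minimum smoothed count strictly
    between the two highest modes is returned; valley ties resolve to the
    lowest bin value.  Raises :class:`NoThresholdError` when fewer than two
    modes survive (callers fall back to a fixed cutoff).
    """
    from scipy.signal import find_peaks

    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 3:
        raise ParameterError("histogram must be a 1-D array of >= 3 bins")
    sm = _smooth(counts, smooth_window)
    # pad so maxima at the histogram ends are detectable
    padded = np.concatenate([[-1.0], sm, [-1.0]])
    peaks, props = find_peaks(padded, prominence=prominence_frac * sm.max())
    peaks = peaks - 1
    if len(peaks) < 2:
        raise NoThresholdError("histogram is unimodal after smoothing")
    top_two = sorted(sorted(peaks, key=lambda i: sm[i], reverse=True)[:2])
    lo, hi = int(top_two[0]), int(top_two[1])
    if hi - lo < 2:
        raise NoThresholdError("modes are adjacent; no interior valley")
    interior = sm[lo + 1 : hi]
    valley = lo + 1 + int(np.argmin(interior))  # argmin → lowest bin on ties
    centers = 0.5 * (np.asarray(edges)[:-1] + np.asarray(edges)[1:])
    return float(centers[valley])


def fractional_cover(index_image: np.ndarray, threshold: float) -> float:
    """Fraction of defined pixels strictly above the threshold."""
    vals = np.asarray(index_image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ParameterError("index image has no defined pixels")
    return float(np.mean(vals > threshold))


@dataclass(frozen=True)
class CoverEstimate:
    """Green-fraction estimate with the threshold and histogram behind it."""

    green_fraction: float
    threshold: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    threshold_is_fallback: bool = False


def estimate_cover(rgb_image: np.ndarray, bins: int = 256,
                   smooth_window: int = 5,
                   fallback_threshold: float = 0.0) -> CoverEstimate:
    """Full image → cover path: index, histogram, valley threshold, fraction."""
    img = np.asarray(rgb_image, dtype=float)
    idx = gndvi(img[..., 0], img[..., 1])
    counts, edges = index_histogram(idx, bins=bins)
    fallback = False
    try:
        thr = bimodal_threshold(counts, edges, smooth_window)
    except NoThresholdError:
        thr = fallback_threshold
        fallback = True
    return CoverEstimate(
        green_fraction=fractional_cover(idx, thr), threshold=thr,
        histogram_counts=counts, histogram_edges=edges,
        threshold_is_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# Synthetic plot-image renderer


def render_plot_image(true_cover: float, model: FisheyeModel, seed: int,
                      image_size: tuple[int, int] = (400, 400),
                      plot_extent: tuple[float, float, float, float] =
                      (-1.83, 1.83, -0.76, 0.76),
                      plant_rg: tuple[float, float] = (60.0, 160.0),
                      soil_rg: tuple[float, float] = (170.0, 90.0),
                      color_sd: float = 10.0,
                      blob_radius_m: float = 0.09,
                      max_blobs: int = 20000):
    """Render a green-canopy-on-red-soil fisheye plot image with known truth.

    Canopy discs are added at random inside the plot extent until the
    painted-pixel fraction within the extent reaches ``true_cover``; the
    achieved painted fraction is the returned truth.  Returns
    ``(rgb uint8 image, plant mask, painted_cover)``.
    """
    if not 0 <= true_cover <= 1:
        raise ParameterError("true cover must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    h, w = image_size
    py, px = np.mgrid[0:h, 0:w]
    gx, gy = pixel_to_ground(model, px, py)
    xmin, xmax, ymin, ymax = plot_extent
    in_plot = (gx >= xmin) & (gx <= xmax) & (gy >= ymin) & (gy <= ymax)
    in_plot &= np.isfinite(gx) & np.isfinite(gy)
    n_plot = int(in_plot.sum())
    if n_plot == 0:
        raise ParameterError("plot extent does not intersect the image")

    mask = np.zeros((h, w), dtype=bool)
    painted = 0
    for _ in range(max_blobs):
        if painted / n_plot >= true_cover:
            break
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        rad = blob_radius_m * rng.uniform(0.6, 1.4)
        # paint only inside the disc's pixel bounding box
        bx, by = ground_to_pixel(model, np.array([cx - rad, cx + rad, cx, cx]),
                                 np.array([cy, cy, cy - rad, cy + rad]))
        c0 = max(int(np.floor(bx.min())) - 1, 0)
        c1 = min(int(np.ceil(bx.max())) + 2, w)
        r0 = max(int(np.floor(by.min())) - 1, 0)
        r1 = min(int(np.ceil(by.max())) + 2, h)
        sub = ((gx[r0:r1, c0:c1] - cx) ** 2 + (gy[r0:r1, c0:c1] - cy) ** 2
               <= rad**2) & in_plot[r0:r1, c0:c1]
        new = sub & ~mask[r0:r1, c0:c1]
        painted += int(new.sum())
        mask[r0:r1, c0:c1] |= sub

    img = np.empty((h, w, 3))
    img[..., 0] = np.where(mask, plant_rg[0], soil_rg[0])
    img[..., 1] = np.where(mask, plant_rg[1], soil_rg[1])
    img[..., 2] = 60.0
    img += rng.normal(0.0, color_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, mask, painted / n_plot


def load_rgb(path) -> np.ndarray:
    """Read an RGB image file (PNG/TIFF) as a uint8 array."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ParameterError(f"{path} is not an RGB image")
    return img[..., :3]


def save_rgb(image: np.ndarray, path) -> None:
    """Write an RGB uint8 array to an image file."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Regression validation


@dataclass(frozen=True)
class ValidationResult:
    """OLS comparison of lidar values against an independent reference."""

    slope: float
    intercept: float
    r2: float
    rmse: float
    n: int

    def report(self) -> str:
        return (
            f"n         {self.n}\n"
            f"slope     {self.slope:.4f}\n"
            f"intercept {self.intercept:.4f}\n"
            f"r2        {self.r2:.4f}\n"
            f"rmse      {self.rmse:.4f}\n"
        )


def validate(lidar_values, reference_values) -> ValidationResult:
    """Simple linear regression of lidar values on a reference method.

    The RMSE is computed on the paired differences (lidar − reference),
    not on regression residuals, so slope/r² and RMSE answer different
    questions: association versus absolute agreement.
    """
    y = np.asarray(lidar_values, dtype=float)
    x = np.asarray(reference_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ParameterError("inputs must be equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ParameterError("need at least 3 paired finite values")
    if np.ptp(x) == 0:
        raise ParameterError("reference values have zero variance")
    fit = stats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return ValidationResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue**2), rmse=rmse, n=int(x.size),
    )
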