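"""AFM height-map processing for supported-lipid-bilayer (SLB) thickness.

Pipeline (mirrors the standard SLB step-height workflow):

1. :func:`flatten` — iterative line-wise first-order background removal.
   Per fast-scan line: fit a straight line to all pixels; refit after
   rejecting pixels more than 1 nm *above* the fit (bilayer patches
   protrude upward); refit once more after rejecting pixels more than
   0.5 nm above the second fit; subtract the final fit.  The substrate
   mode of the result is then centred at zero.
2. :func:`smooth` — 10 x 10 pixel moving average (shrunken windows at the
   edges).
3. :func:`patch_thickness` — histogram of a patch-containing crop with
   0.05 nm bins; the two most prominent peaks separated by at least 1 nm
   are the substrate (lower) and the patch (upper); their distance is the
   bilayer thickness.  Peak positions are refined by parabolic
   interpolation around the histogram mode.

Bin width and the peak-separation floor are configuration keys — they are
chosen so that the few-angstrom experimental spread stays resolvable while
noise peaks are suppressed, and are not claimed to match any particular
lab's in-house scripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .constants import NM

#: One-sided rejection thresholds of the iterative line fit (m).
REJECT_FIRST = 1e-9
REJECT_SECOND = 0.5e-9
#: Moving-average window (pixels).
SMOOTH_WINDOW = 10
#: Histogram bin width and minimal peak separation (m).
BIN_WIDTH = 0.05e-9
MIN_PEAK_SEPARATION = 1e-9
#: A third peak with prominence within this fraction of the second peak's
#: makes the histogram ambiguous.
AMBIGUITY_FRACTION = 0.2


class ThicknessError(ValueError):
    """Raised when no bilayer patch (or an ambiguous one) is found."""


@dataclass(frozen=True)
class HeightMap:
    """Pixel grid of AFM heights (m) with the lateral pixel size (m)."""

    heights: np.ndarray
    pixel_size: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "heights", h)
        if h.ndim != 2 or min(h.shape) < 16:
            raise ValueError("height map must be 2-D and at least 16x16")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")


@dataclass(frozen=True)
class ThicknessResult:
    """Histogram-derived bilayer thickness for one crop."""

    substrate_peak: float  # m
    patch_peak: float      # m
    thickness: float       # m
    bin_centers: np.ndarray
    counts: np.ndarray
    n_pixels_patch: int

    def __post_init__(self):
        if self.thickness < 0:
            raise ValueError("thickness must be non-negative")
        if abs(self.thickness - (self.patch_peak - self.substrate_peak)) > 1e-15:
            raise ValueError("thickness must equal patch_peak - substrate_peak")


# ---------------------------------------------------------------------------
# Flatten
# ---------------------------------------------------------------------------

def _line_fit(x, y):
    """Least-squares line through (x, y); returns fitted values on x."""
    coeff = np.polyfit(x, y, 1)
    return np.polyval(coeff, x)


def _height_histogram(values, bin_width):
    """Histogram with bin centres aligned to the minimum height value.

    Aligning the grid so that ``min(values)`` sits at a bin centre keeps
    exact two-level maps (substrate at h0, patch at h0 + k*bin_width) from
    straddling bin edges.  One guaranteed-empty bin pads each side so that
    boundary spikes remain detectable local maxima.
    """
    lo, hi = values.min(), values.max()
    n_bins = int(np.ceil((hi - lo) / bin_width)) + 4
    edges = lo - 1.5 * bin_width + np.arange(n_bins + 1) * bin_width
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def _histogram_mode(values, bin_width=BIN_WIDTH):
    """Histogram mode with parabolic refinement (m)."""
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width:
        return float(values.mean())
    centers, counts = _height_histogram(values, bin_width)
    i = int(np.argmax(counts))
    return float(_parabolic_peak(centers, counts, i))


def _parabolic_peak(centers, counts, i):
    if i <= 0 or i >= counts.size - 1:
        return centers[i]
    y0, y1, y2 = counts[i - 1], counts[i], counts[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return centers[i]
    delta = 0.5 * (y0 - y2) / denom
    return centers[i] + delta * (centers[1] - centers[0])


def flatten(
    height_map: HeightMap,
    reject_first: float = REJECT_FIRST,
    reject_second: float = REJECT_SECOND,
    min_pixels: int = 4,
) -> HeightMap:
    """Iterative line-wise first-order background subtraction.

    Rejection is one-sided (pixels *above* the fit): SLB patches protrude
    upward, substrate pixels do not.  A line whose rejection leaves fewer
    than ``min_pixels`` pixels falls back to the previous pass's fit with
    a warning.  The substrate mode of the output is centred at zero.
    """
    h = height_map.heights.copy()
    cols = np.arange(h.shape[1], dtype=float)
    starved = 0
    for r in range(h.shape[0]):
        line = h[r]
        fit = _line_fit(cols, line)
        for thresh in (reject_first, reject_second):
            keep = line - fit <= thresh
            if keep.sum() < min_pixels:
                starved += 1
                break
            fit = np.polyval(np.polyfit(cols[keep], line[keep], 1), cols)
        h[r] = line - fit
    if starved:
        warnings.warn(
            f"{starved} line(s) starved the rejection fit; previous-pass fit used",
            stacklevel=2,
        )
    h -= _histogram_mode(h.ravel())
    return HeightMap(heights=h, pixel_size=height_map.pixel_size,
                     metadata={**height_map.metadata, "flattened": True})


def smooth(height_map: HeightMap, window: int = SMOOTH_WINDOW) -> HeightMap:
    """Uniform ``window`` x ``window`` moving average.

    Edge pixels average over the shrunken window that fits inside the map
    (implemented as a ratio of zero-padded box filters).
    """
    h = height_map.heights
    if min(h.shape) < window:
        raise ValueError(f"map smaller than the {window}x{window} smoothing window")
    num = ndimage.uniform_filter(h, size=window, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(h), size=window, mode="constant", cval=0.0)
    return HeightMap(heights=num / den, pixel_size=height_map.pixel_size,
                     metadata={**height_map.metadata, "smoothed": window})


# ---------------------------------------------------------------------------
# Thickness
# ---------------------------------------------------------------------------

def patch_thickness(
    height_map: HeightMap,
    crop: tuple[int, int, int, int] | None = None,
    bin_width: float = BIN_WIDTH,
    min_separation: float = MIN_PEAK_SEPARATION,
    gaussian_peaks: bool = False,
) -> ThicknessResult:
    """Bilayer thickness from the height histogram of a crop.

    ``crop`` is (row0, row1, col0, col1), half-open, defaulting to the full
    map.  The two most prominent histogram maxima separated by at least
    ``min_separation`` are assigned substrate (lower) and patch (upper);
    thickness is their distance.  Peak positions are refined by parabolic
    interpolation, or by a local Gaussian fit when ``gaussian_peaks`` is
    set.

    Raises
    ------
    ThicknessError
        "< 2 peaks found" when the crop lacks either level; "ambiguous
        peaks" when a third peak rivals the second in prominence.
    """
    h = height_map.heights
    if crop is not None:
        r0, r1, c0, c1 = crop
        if not (0 <= r0 < r1 <= h.shape[0] and 0 <= c0 < c1 <= h.shape[1]):
            raise ValueError("crop outside the map")
        h = h[r0:r1, c0:c1]
    values = h.ravel()
    lo, hi = values.min(), values.max()
    if hi - lo < min_separation:
        raise ThicknessError("< 2 peaks found: height range below the separation floor")
    centers, counts = _height_histogram(values, bin_width)

    peaks, props = signal.find_peaks(counts, prominence=1.0)
    if peaks.size < 2:
        raise ThicknessError("< 2 peaks found")
    order = np.argsort(props["prominences"])[::-1]
    first = peaks[order[0]]
    second = None
    second_prom = None
    for idx in order[1:]:
        if abs(centers[peaks[idx]] - centers[first]) >= min_separation:
            second = peaks[idx]
            second_prom = props["prominences"][idx]
            break
    if second is None:
        raise ThicknessError("< 2 peaks found: no second peak beyond the separation floor")
    # ambiguity: a third distinct peak with prominence within 20% of the second
    for idx in order[1:]:
        pk = peaks[idx]
        if pk in (first, second):
            continue
        if (
            abs(centers[pk] - centers[first]) >= min_separation
            and abs(centers[pk] - centers[second]) >= min_separation
            and props["prominences"][idx] >= (1.0 - AMBIGUITY_FRACTION) * second_prom
        ):
            raise ThicknessError("ambiguous peaks: third peak rivals the second")

    def refine(i):
        if gaussian_peaks:
            return _gaussian_peak(centers, counts, i)
        return _parabolic_peak(centers, counts, i)

    pos = sorted([refine(first), refine(second)])
    substrate, patch = pos
    thickness = patch - substrate
    n_patch = int(np.sum(np.abs(values - patch) < thickness / 2.0))
    return ThicknessResult(
        substrate_peak=float(substrate),
        patch_peak=float(patch),
        thickness=float(thickness),
        bin_centers=centers,
        counts=counts,
        n_pixels_patch=n_patch,
    )


def _gaussian_peak(centers, counts, i, half_width=6):
    """Local Gaussian fit around histogram index i (optional refinement)."""
    from scipy.optimize import curve_fit

    lo = max(i - half_width, 0)
    hi = min(i + half_width + 1, counts.size)
    x, y = centers[lo:hi], counts[lo:hi].astype(float)

    def gauss(xx, a, mu, sd):
        return a * np.exp(-((xx - mu) ** 2) / (2 * sd**2))

    try:
        popt, _ = curve_fit(
            gauss, x, y, p0=(counts[i], centers[i], 2 * (centers[1] - centers[0]))
        )
        return float(popt[1])
    except RuntimeError:
        return _parabolic_peak(centers, counts, i)


def run_pipeline(height_map: HeightMap, crop=None, **kwargs) -> ThicknessResult:
    """Convenience: flatten -> smooth -> patch_thickness."""
    return patch_thickness(smooth(flatten(height_map)), crop=crop, **kwargs)


# ---------------------------------------------------------------------------
# CSV I/O (Gwyddion-style plain matrix export)
# ---------------------------------------------------------------------------

def read_heightmap_csv(path, units: str = "nm", pixel_size: float = 1.0) -> HeightMap:
    """Read a plain numeric-matrix CSV height map.

    Comma or semicolon delimiters are sniffed; lines starting with '#' are
    skipped.  ``units`` is 'nm' (default, Gwyddion CSV export) or 'm'.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data lines")
    delim = ";" if lines[0].count(";") >= lines[0].count(",") and ";" in lines[0] else ","
    try:
        rows = [np.array([float(v) for v in ln.strip().split(delim)]) for ln in lines]
    except ValueError as exc:
        raise ValueError(f"{path}: malformed matrix CSV ({exc})") from exc
    if len({r.size for r in rows}) != 1:
        raise ValueError(f"{path}: ragged rows in matrix CSV")
    h = np.stack(rows)
    scale = {"nm": NM, "m": 1.0}[units]
    return HeightMap(heights=h * scale, pixel_size=pixel_size, metadata={"source": str(path)})


def write_heightmap_csv(path, height_map: HeightMap, units: str = "nm") -> None:
    """Write a height map as a plain matrix CSV (heights in ``units``)."""
    scale = {"nm": NM, "m": 1.0}[units]
    np.savetxt(path, height_map.heights / scale, delimiter=",", fmt="%.6g",
               header=f"heights in {units}", comments="# ")
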