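"""Synthetic vesicle images and subpixel contour detection.

Under phase contrast a giant unilamellar vesicle (GUV) appears as a dark
ring on a light background.  This module renders such ring images from a
known contour (the forward model) and detects a closed contour from an
image at subpixel precision (the inverse step feeding the fluctuation and
electrodeformation analyses).

Conventions
-----------
* Row-major pixel grid, origin at the top-left pixel centre.
* Polar angles are measured counterclockwise from the +x (column) axis.
* Contour radii are stored in metres; ``pixel_size`` converts to pixels.
* The contour edge is defined as the *radial minimum* of the smoothed
  intensity profile (dark ring), not the maximum gradient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class ContourError(ValueError):
    """Raised when contour detection fails (no edge, open or ambiguous)."""


@dataclass(frozen=True)
class VesicleContour:
    """Equatorial vesicle contour r(phi) for one video frame.

    Attributes
    ----------
    angles : ndarray
        Uniform angular grid in [0, 2pi), radians, strictly increasing.
    radii : ndarray
        Radius at each angle, metres, all positive.
    center : tuple of float
        (row, col) of the contour centre in pixel coordinates.
    frame_time : float
        Acquisition time of the frame in seconds.
    """

    angles: np.ndarray
    radii: np.ndarray
    center: tuple[float, float] = (0.0, 0.0)
    frame_time: float = 0.0

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "radii", radii)
        if angles.ndim != 1 or angles.shape != radii.shape:
            raise ValueError("angles and radii must be 1-D arrays of equal length")
        if np.any(radii <= 0):
            raise ValueError("radii must be positive")
        d = np.diff(angles)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-8, atol=1e-12):
            raise ValueError("angles must be strictly increasing and uniform")

    @property
    def n_points(self) -> int:
        return self.angles.size

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())

    @property
    def aspect_ratio(self) -> float:
        """a/b of the best-fit ellipse through the contour (2nd Fourier mode)."""
        a, b, _ = fit_ellipse(self)
        return a / b


@dataclass(frozen=True)
class VesicleImage:
    """Grayscale image of a single vesicle.

    ``pixels`` holds intensities in arbitrary units, ``pixel_size`` is the
    physical pixel pitch in metres, ``center_hint`` an optional (row, col)
    prior for the vesicle centre.
    """

    pixels: np.ndarray
    pixel_size: float
    center_hint: tuple[float, float] | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or min(px.shape) < 64:
            raise ValueError("image must be 2-D and at least 64x64 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def uniform_angles(n_points: int) -> np.ndarray:
    """Uniform angular grid in [0, 2pi) with ``n_points`` samples."""
    return np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)


def fit_ellipse(contour: VesicleContour) -> tuple[float, float, float]:
    """Semi-axes (a, b) and orientation of the elliptical component.

    Uses the q=0 and q=2 Fourier components of r(phi): for a mildly
    eccentric ellipse r(phi) ~ r0 + r2*cos(2(phi - phi0)), giving
    a = r0 + |r2|, b = r0 - |r2|.  Returns (a, b, phi0) with a >= b.
    """
    r = contour.radii
    n = r.size
    c = np.fft.rfft(r) / n
    r0 = c[0].real
    r2 = 2.0 * np.abs(c[2])
    phi0 = -np.angle(c[2]) / 2.0
    return r0 + r2, r0 - r2, phi0


# ---------------------------------------------------------------------------
# Forward model: render a ring image from a contour
# ---------------------------------------------------------------------------

def render_image(
    contour: VesicleContour,
    shape: tuple[int, int],
    pixel_size: float,
    ring_width: float,
    contrast: float = 0.5,
    noise_sd: float = 0.0,
    background: float = 1.0,
    seed: int | None = None,
) -> VesicleImage:
    """Render a dark-ring vesicle image from a contour.

    The intensity along each ray from the contour centre is
    ``background - contrast * exp(-(rho - r(theta))^2 / (2 w^2))`` with
    ``w = ring_width``; the minimum therefore sits exactly on the contour.
    Gaussian noise of ``noise_sd`` is added per pixel.

    Parameters are in metres (``pixel_size``, ``ring_width``); the contour
    centre is placed at the image centre unless the contour carries one.
    """
    rows, cols = shape
    cr, cc = contour.center
    if (cr, cc) == (0.0, 0.0):
        cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    r_px = contour.radii / pixel_size
    max_r = r_px.max() + 3.0 * ring_width / pixel_size
    if cr - max_r < 0 or cc - max_r < 0 or cr + max_r > rows - 1 or cc + max_r > cols - 1:
        raise ValueError("contour (plus ring width margin) exceeds frame bounds")

    yy, xx = np.mgrid[0:rows, 0:cols]
    dx = xx - cc
    dy = -(yy - cr)  # +y up so angles run counterclockwise from +x
    rho = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    # periodic linear interpolation of r(theta)
    n = contour.n_points
    pos = theta / (2.0 * np.pi) * n
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    frac = pos - np.floor(pos)
    r_theta = (1.0 - frac) * r_px[i0] + frac * r_px[i1]

    w = ring_width / pixel_size
    img = background - contrast * np.exp(-((rho - r_theta) ** 2) / (2.0 * w * w))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return VesicleImage(pixels=img, pixel_size=pixel_size, center_hint=(cr, cc))


# ---------------------------------------------------------------------------
# Inverse: subpixel contour detection
# ---------------------------------------------------------------------------

def _radial_profiles(pixels, center, angles, radii_px):
    """Sample intensity along rays; returns (n_angles, n_radii) array."""
    cr, cc = center
    cols = cc + radii_px[None, :] * np.cos(angles)[:, None]
    rows = cr - radii_px[None, :] * np.sin(angles)[:, None]
    return ndimage.map_coordinates(
        pixels, np.stack([rows.ravel(), cols.ravel()]), order=1, mode="nearest"
    ).reshape(len(angles), len(radii_px))


def _parabolic_refine(y, i):
    """Subpixel extremum position from 3-point parabola around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def detect_contour(
    image: VesicleImage,
    n_points: int = 256,
    contrast_threshold: float = 0.1,
    max_iter: int = 25,
    frame_time: float = 0.0,
) -> VesicleContour:
    """Detect a closed dark-ring contour at subpixel precision.

    For each of ``n_points`` rays from the estimated centre the smoothed
    radial intensity profile's minimum is localised by parabolic
    interpolation; the centre is refined iteratively from the contour
    centroid until it shifts by less than 0.1 pixel.

    Raises
    ------
    ContourError
        "no edge found" if no ray has contrast above
        ``contrast_threshold`` (relative to the image intensity range);
        "open contour" if more than 5% of rays fail;
        "ambiguous contour" if a majority of rays see a second ring of
        comparable depth and no ``center_hint`` disambiguates it.
    """
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    span = hi - lo
    if span <= 0:
        raise ContourError("no edge found: flat image")
    # work on a normalized copy: detection is intensity-scale invariant
    norm = (px - lo) / span

    if image.center_hint is not None:
        center = image.center_hint
        hinted = True
    else:
        inv = 1.0 - norm
        total = inv.sum()
        yy, xx = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
        center = (float((inv * yy).sum() / total), float((inv * xx).sum() / total))
        hinted = False

    angles = uniform_angles(n_points)
    max_r = min(center[0], center[1], px.shape[0] - 1 - center[0], px.shape[1] - 1 - center[1])
    radii_px = np.arange(1.0, max(max_r, 8.0))
    r_expect = None

    for _ in range(max_iter):
        prof = _radial_profiles(norm, center, angles, radii_px)
        prof = ndimage.gaussian_filter1d(prof, sigma=1.0, axis=1)
        r_det = np.full(n_points, np.nan)
        second_ring = 0
        for k in range(n_points):
            p = prof[k]
            # local minima with sufficient depth
            interior = np.arange(1, len(p) - 1)
            is_min = (p[interior] < p[interior - 1]) & (p[interior] <= p[interior + 1])
            cand = interior[is_min]
            depth = p.max() - p[cand] if cand.size else np.array([])
            good = cand[depth >= contrast_threshold] if cand.size else cand
            if good.size == 0:
                continue
            deepest = good[np.argmin(p[good])]
            if good.size > 1:
                others = good[good != deepest]
                if np.any(p.max() - p[others] >= 0.5 * (p.max() - p[deepest])):
                    second_ring += 1
                    if hinted or r_expect is not None:
                        ref = r_expect if r_expect is not None else radii_px[deepest]
                        deepest = good[np.argmin(np.abs(radii_px[good] - ref))]
            r_det[k] = np.interp(_parabolic_refine(p, deepest), np.arange(len(p)), radii_px)

        n_fail = int(np.isnan(r_det).sum())
        if n_fail == n_points:
            raise ContourError("no edge found")
        if second_ring > n_points // 2 and not hinted:
            raise ContourError("ambiguous contour: multiple rings detected")
        if n_fail > 0.05 * n_points:
            raise ContourError(f"open contour: {n_fail}/{n_points} rays failed")
        # fill isolated failures by periodic interpolation
        if n_fail:
            ok = ~np.isnan(r_det)
            r_det = np.interp(
                angles, angles[ok], r_det[ok], period=2.0 * np.pi
            )
        r_expect = float(np.median(r_det))
        # refine centre from first Fourier moment of the contour
        dx = float(np.mean(r_det * np.cos(angles))) * 2.0
        dy = float(np.mean(r_det * np.sin(angles))) * 2.0
        new_center = (center[0] - dy, center[1] + dx)
        shift = np.hypot(new_center[0] - center[0], new_center[1] - center[1])
        center = new_center
        if shift < 0.1:
            break

    return VesicleContour(
        angles=angles,
        radii=r_det * image.pixel_size,
        center=center,
        frame_time=frame_time,
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_tiff(path, pixel_size: float, center_hint=None) -> VesicleImage:
    """Read a grayscale 8/16-bit TIFF as a VesicleImage."""
    import tifffile

    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 3:  # first page of a stack
        data = data[0]
    return VesicleImage(pixels=data, pixel_size=pixel_size, center_hint=center_hint)


def write_tiff(path, image: VesicleImage, dtype="uint16") -> None:
    """Write a VesicleImage to TIFF, linearly rescaled to the dtype range."""
    import tifffile

    px = image.pixels
    lo, hi = px.min(), px.max()
    span = hi - lo if hi > lo else 1.0
    scaled = (px - lo) / span
    if dtype == "uint8":
        out = (scaled * 255).astype(np.uint8)
    else:
        out = (scaled * 65535).astype(np.uint16)
    tifffile.imwrite(path, out)


def contours_to_frame(contours) -> "pandas.DataFrame":  # noqa: F821
    """Stack contours into a tidy frame: frame, angle_rad, radius_um."""
    import pandas as pd

    recs = []
    for i, c in enumerate(contours):
        recs.append(
            pd.DataFrame(
                {
                    "frame": i,
                    "angle_rad": c.angles,
                    "radius_um": c.radii / 1e-6,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def frame_to_contours(df) -> list[VesicleContour]:
    """Inverse of :func:`contours_to_frame`."""
    out = []
    for _, grp in df.groupby("frame", sort=True):
        out.append(
            VesicleContour(
                angles=grp["angle_rad"].to_numpy(),
                radii=grp["radius_um"].to_numpy() * 1e-6,
            )
        )
    return out
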