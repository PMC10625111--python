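"""Seeded synthetic-data generators with known ground truth.

Every generator reproduces exactly the statistical structure its matching
estimator assumes, so each analysis stage can be validated by parameter
recovery:

* :func:`gen_flicker_contours` draws per-frame equatorial Fourier mode
  amplitudes as independent zero-mean complex Gaussians whose variances
  equal the quasi-spherical Helfrich spectrum of
  :func:`photomem.flicker.mode_variance` (mode amplitudes are i.i.d. per
  frame — no temporal correlation; the estimator only uses per-mode
  variances, so switching dynamics are deliberately out of scope here).
* :func:`gen_trace` produces aspect-ratio relaxation traces with
  epoch-wise exponential kinetics.
* :func:`gen_sweep` produces frequency sweeps whose aspect ratio crosses 1
  exactly at the critical frequency of
  :func:`photomem.capacitance.critical_frequency_model`.
* :func:`gen_heightmap` produces tilted, noisy two-level AFM height maps.

All generators take an explicit integer seed (no hidden global state) and
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import capacitance as cap
from . import flicker
from .afm_thickness import HeightMap
from .constants import DEFAULT_TEMPERATURE, kbt
from .electrodeform import ILLUMINATION_LABELS, AspectRatioTrace
from .imaging_contour import VesicleContour, uniform_angles

#: Shape of the synthetic sweep's aspect-ratio curve: total prolate-oblate
#: amplitude and transition width in decades of frequency.  Typical
#: experimental sweeps span aspect ratios ~1.1 down to ~0.9 over roughly a
#: decade around the crossing.
SWEEP_DEPTH = 0.12
SWEEP_WIDTH_DECADES = 0.6

#: Default sweep frequency grid: log-spaced 500 Hz - 1 MHz.
def default_sweep_frequencies(n: int = 41) -> np.ndarray:
    return np.logspace(np.log10(500.0), 6.0, n)


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlickerTruth:
    """Ground truth for a synthetic flicker stack.

    Defaults are the fluctuation-spectroscopy study conditions: 3000
    frames of a 15 um vesicle at 296 K sampled at 256 contour points, a
    reduced tension of order a few (sigma ~ 1e-9 N/m), and ~10 nm radial
    detection noise.
    """

    kappa: float = 20.0 * kbt()        # J (20 k_BT)
    sigma: float = 1.8e-9              # N/m
    radius: float = 15e-6              # m
    temperature: float = DEFAULT_TEMPERATURE
    n_frames: int = 3000
    n_points: int = 256
    pixel_noise: float = 10e-9         # m, radial noise SD
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.n_points < 64 or (self.n_points & (self.n_points - 1)) != 0:
            raise ValueError("n_points must be a power of two >= 64 (resampling requirement)")

    @property
    def sigma_bar(self) -> float:
        return self.sigma * self.radius**2 / self.kappa


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth for a synthetic aspect-ratio kinetic trace.

    The default schedule is dark baseline, a 5 s UV epoch (aspect rises by
    ``amplitude`` with time constant ``tau``) and a blue epoch (decays
    back), sampled at 100 frames/s with 1% aspect-ratio noise.
    """

    tau: float = 0.525                 # s
    baseline: float = 1.1              # aspect ratio in the trans state
    amplitude: float = 0.1             # UV-induced aspect-ratio jump
    frame_rate: float = 100.0          # 1/s
    duration: float = 12.0             # s
    noise_sd: float = 0.01
    epoch_schedule: tuple = ((0.0, "dark"), (2.0, "UV"), (7.0, "blue"))
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0 or self.frame_rate <= 0:
            raise ValueError("tau and frame_rate must be positive")
        starts = [t for t, _ in self.epoch_schedule]
        if sorted(starts) != list(starts) or len(set(starts)) != len(starts):
            raise ValueError("overlapping or unordered epochs")
        for _, label in self.epoch_schedule:
            if label not in ILLUMINATION_LABELS:
                raise ValueError(f"unknown illumination label {label!r}")


@dataclass(frozen=True)
class SweepTruth:
    """Ground truth for a synthetic capacitance frequency sweep.

    Defaults follow the capacitance protocol: POPC-like C_m
    (0.43 uF/cm^2 = 4.3e-3 F/m^2), inner conductivity 42.70 uS/cm and
    conductivity ratio 0.52, 2% per-point aspect-ratio noise.
    """

    cm: float = 4.3e-3                 # F/m^2
    lambda_in: float = 42.70e-4        # S/m
    lambda_out: float = 42.70e-4 / 0.52
    radius: float = 6e-6               # m
    frequencies: np.ndarray = field(default_factory=default_sweep_frequencies)
    ar_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if self.lambda_in <= 0 or self.lambda_out <= 0:
            raise ValueError("conductivities must be positive")
        if self.lambda_in / self.lambda_out >= 1:
            raise ValueError("conductivity ratio must be < 1 "
                             "(no prolate-oblate transition otherwise)")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def ratio(self) -> float:
        return self.lambda_in / self.lambda_out

    @property
    def critical_frequency(self) -> float:
        return cap.critical_frequency_model(self.radius, self.cm, self.lambda_in, self.ratio)


def make_ellipse_mask(shape: tuple[int, int], coverage: float = 0.4,
                      axis_ratio: float = 1.3) -> np.ndarray:
    """Centred elliptical patch mask covering ``coverage`` of the pixels."""
    if not 0 < coverage < 0.8:
        raise ValueError("coverage must be in (0, 0.8)")
    rows, cols = shape
    area = coverage * rows * cols
    b = np.sqrt(area / (np.pi * axis_ratio))   # semi-axis along rows
    a = axis_ratio * b                          # semi-axis along cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    return ((rr - (rows - 1) / 2) / b) ** 2 + ((cc - (cols - 1) / 2) / a) ** 2 <= 1.0


@dataclass(frozen=True)
class MapTruth:
    """Ground truth for a synthetic AFM height map.

    Defaults emulate a 256x256 scan with a bilayer patch covering 40% of
    the frame, a 6.2 nm step, ~2 nm tilt across the rows (plus a milder
    column tilt), and 0.1 nm surface roughness.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 5e-6 / 256     # m
    patch_mask: np.ndarray | None = None
    step_height: float = 6.2e-9        # m
    tilt_per_row: float = 2e-9 / 256   # m/pixel along rows
    tilt_per_col: float = 1e-9 / 256   # m/pixel along cols
    roughness_sd: float = 0.1e-9       # m
    seed: int = 0

    def __post_init__(self):
        if self.step_height < 0:
            raise ValueError("step height must be non-negative")
        mask = self.patch_mask
        if mask is None:
            mask = make_ellipse_mask(self.shape)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError("patch_mask shape mismatch")
        if mask.mean() >= 0.8:
            raise ValueError("patch must cover < 80% of pixels "
                             "(substrate must remain identifiable)")
        object.__setattr__(self, "patch_mask", mask)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_flicker_contours(truth: FlickerTruth) -> list[VesicleContour]:
    """Synthetic equatorial contour stack with a Helfrich mode spectrum.

    Per frame, each Fourier mode q in [2, n_points/4] receives an
    independent complex Gaussian amplitude with variance
    V(q; kappa, sigma_bar) from :func:`photomem.flicker.mode_variance`
    (converged Legendre truncation, matching the estimator's convention);
    radial pixel noise is added after synthesis.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_points
    q_max = n // 4
    q = np.arange(2, q_max + 1)
    v = flicker.mode_variance(q, truth.kappa, truth.sigma_bar,
                              truth.temperature, l_max=flicker.L_MAX_FACTOR * q_max)
    angles = uniform_angles(n)
    sd = np.sqrt(np.asarray(v) / 2.0)
    nf = truth.n_frames
    amp = rng.normal(0.0, sd, size=(nf, q.size)) + 1j * rng.normal(0.0, sd, size=(nf, q.size))
    spec = np.zeros((nf, n // 2 + 1), dtype=complex)
    spec[:, 2 : q_max + 1] = amp
    u = np.fft.irfft(spec * n, n=n, axis=1)
    r = truth.radius * (1.0 + u)
    if truth.pixel_noise > 0:
        r = r + rng.normal(0.0, truth.pixel_noise, size=r.shape)
    return [
        VesicleContour(angles=angles, radii=r[i], frame_time=float(i))
        for i in range(nf)
    ]


def gen_trace(truth: TraceTruth) -> AspectRatioTrace:
    """Synthetic aspect-ratio kinetic trace with epoch-wise exponentials.

    Dark epochs hold the trans baseline; a UV epoch relaxes from the
    baseline up to baseline + amplitude with time constant tau; a blue
    epoch relaxes back down.  Gaussian noise of ``noise_sd`` is added per
    frame.
    """
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.duration * truth.frame_rate))
    t = np.arange(n) / truth.frame_rate
    labels = np.empty(n, dtype=object)
    mean = np.empty(n)
    schedule = list(truth.epoch_schedule)
    bounds = [s for s, _ in schedule] + [np.inf]
    level = truth.baseline  # value at the start of the current epoch
    for k, (t0, label) in enumerate(schedule):
        sel = (t >= t0) & (t < bounds[k + 1])
        target = truth.baseline + truth.amplitude if label == "UV" else truth.baseline
        if label == "dark":
            target = level  # darkness holds the current state
        mean[sel] = target - (target - level) * np.exp(-(t[sel] - t0) / truth.tau)
        labels[sel] = label
        if np.any(sel):
            level = mean[sel][-1]
    aspect = mean + (rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else 0.0)
    return AspectRatioTrace(
        times=t,
        aspect=np.clip(aspect, 1e-6, None),
        illumination=labels.astype(str),
        field_on=np.ones(n, dtype=bool),
    )


def sweep_aspect_model(frequencies, f_c, depth=SWEEP_DEPTH, width=SWEEP_WIDTH_DECADES):
    """Smooth monotone-decreasing aspect-ratio curve crossing 1 at f_c."""
    logf = np.log10(np.asarray(frequencies, dtype=float))
    return 1.0 + depth * np.tanh((np.log10(f_c) - logf) / width)


def gen_sweep(truth: SweepTruth) -> cap.FrequencySweep:
    """Synthetic frequency sweep crossing a/b = 1 at the model f_c.

    The noiseless curve is a tanh in log-frequency through the critical
    frequency of :func:`photomem.capacitance.critical_frequency_model`;
    Gaussian noise of ``ar_noise_sd`` is added per point.
    """
    rng = np.random.default_rng(truth.seed)
    aspect = sweep_aspect_model(truth.frequencies, truth.critical_frequency)
    if truth.ar_noise_sd > 0:
        aspect = aspect + rng.normal(0.0, truth.ar_noise_sd, size=aspect.shape)
    return cap.FrequencySweep(
        frequencies=truth.frequencies,
        aspect=aspect,
        radius=truth.radius,
        lambda_in=truth.lambda_in,
        lambda_out=truth.lambda_out,
    )


def gen_heightmap(truth: MapTruth) -> HeightMap:
    """Synthetic AFM height map: plane tilt + patch step + roughness.

    height(r, c) = r*tilt_per_row + c*tilt_per_col + step_height*mask(r, c)
    + Gaussian roughness; substrate pixels have mask 0.
    """
    rng = np.random.default_rng(truth.seed)
    rows, cols = truth.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    h = rr * truth.tilt_per_row + cc * truth.tilt_per_col
    h = h + truth.step_height * truth.patch_mask
    if truth.roughness_sd > 0:
        h = h + rng.normal(0.0, truth.roughness_sd, size=h.shape)
    return HeightMap(heights=h, pixel_size=truth.pixel_size,
                     metadata={"synthetic": True, "seed": truth.seed})
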