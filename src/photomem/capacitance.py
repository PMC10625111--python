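"""Specific membrane capacitance and dielectric constant from vesicle
electrodeformation frequency sweeps.

For an inner/outer conductivity ratio Lambda = lambda_in/lambda_out < 1 a
vesicle in an AC field is prolate at low frequency, spherical at a critical
frequency f_c, and oblate above it.  The crossing frequency depends on the
specific membrane capacitance C_m:

    f_c = lambda_in / (2 pi R C_m) * [ (1 - Lambda)(3 + Lambda) ]^(-1/2)

so a linear fit of f_c versus 1/R over several vesicles yields C_m.  The
measured C_m is the series combination of the bare bilayer capacitance C_B
and the diffuse double layers on both sides,

    1/C_m = 1/C_B + 1/C_D,in + 1/C_D,out,     C_D = eps_rW eps0 / lambda_D,

with lambda_D the Debye screening length of each solution; the membrane
dielectric constant then follows from C_B = eps_rB eps0 / d with the
bilayer thickness d measured independently (AFM).

The exponent of the radical term is kept as a single named constant
(``RADICAL_EXPONENT``); the adopted form reproduces the downstream numbers
of the electrodeformation protocol this module implements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    DEFAULT_TEMPERATURE,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
    WATER_RELATIVE_PERMITTIVITY,
)

#: Exponent applied to (1 - Lambda)(3 + Lambda) in the critical-frequency
#: model.  Recorded in output metadata; do not change silently.
RADICAL_EXPONENT = -0.5


class SweepError(ValueError):
    """Raised when a frequency sweep has no usable prolate-oblate crossing."""


@dataclass(frozen=True)
class FrequencySweep:
    """Aspect ratio a/b versus AC field frequency for one vesicle."""

    frequencies: np.ndarray  # Hz, strictly increasing
    aspect: np.ndarray       # dimensionless a/b
    radius: float            # m
    lambda_in: float         # S/m
    lambda_out: float        # S/m

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        ar = np.asarray(self.aspect, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "aspect", ar)
        if f.shape != ar.shape or f.ndim != 1:
            raise ValueError("frequencies and aspect must be 1-D and aligned")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.lambda_in <= 0 or self.lambda_out <= 0:
            raise ValueError("conductivities must be positive")

    @property
    def conductivity_ratio(self) -> float:
        return self.lambda_in / self.lambda_out


@dataclass(frozen=True)
class CapacitanceSet:
    """Complete capacitance chain for one membrane composition.

    The series identity 1/cm = 1/cb + 1/cd_in + 1/cd_out holds to 1e-12
    (relative) by construction; see :func:`capacitance_set`.
    """

    cm: float         # specific membrane capacitance, F/m^2
    cb: float         # bare bilayer capacitance, F/m^2
    cd_in: float      # inner double-layer capacitance, F/m^2
    cd_out: float     # outer double-layer capacitance, F/m^2
    eps_membrane: float  # relative dielectric constant of the bilayer
    thickness: float  # m
    debye_in: float   # m
    debye_out: float  # m
    eps_water: float = WATER_RELATIVE_PERMITTIVITY
    eps0: float = VACUUM_PERMITTIVITY

    def __post_init__(self):
        for name in ("cm", "cb", "cd_in", "cd_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lhs = 1.0 / self.cm
        rhs = 1.0 / self.cb + 1.0 / self.cd_in + 1.0 / self.cd_out
        if abs(lhs - rhs) > 1e-12 * lhs:
            raise ValueError("series-capacitance identity violated")


# ---------------------------------------------------------------------------
# Critical frequency
# ---------------------------------------------------------------------------

def critical_frequency_model(
    radius: float, cm: float, lambda_in: float, ratio: float
) -> float:
    """Prolate-oblate transition frequency f_c in Hz.

    f_c = lambda_in/(2 pi R C_m) * [(1-Lambda)(3+Lambda)]^RADICAL_EXPONENT,
    strictly decreasing in R and in C_m; requires 0 < Lambda < 1.
    """
    if radius <= 0 or cm <= 0 or lambda_in <= 0:
        raise ValueError("radius, cm and lambda_in must be positive")
    if not 0 < ratio < 1:
        raise SweepError("conductivity ratio must satisfy 0 < Lambda < 1 "
                         "(no prolate-oblate transition otherwise)")
    radical = ((1.0 - ratio) * (3.0 + ratio)) ** RADICAL_EXPONENT
    return lambda_in / (2.0 * np.pi * radius * cm) * radical


def detect_critical_frequency(sweep: FrequencySweep) -> float:
    """Crossing frequency where the aspect ratio passes through 1.

    A 3-point median prefilter suppresses outliers; the crossing is then
    located by linear interpolation of aspect versus log10(frequency).  If
    several crossings survive the filter the lowest-frequency one is
    returned with a warning.
    """
    f = sweep.frequencies
    ar = sweep.aspect
    if f.size < 3:
        raise SweepError("sweep too short to locate a crossing")
    sm = medfilt(ar, kernel_size=3)
    # median filter leaves endpoints; keep raw values there
    sm[0], sm[-1] = ar[0], ar[-1]
    d = sm - 1.0
    sign_change = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    if sign_change.size == 0:
        raise SweepError("no transition in sweep (aspect ratio never crosses 1)")
    if sign_change.size > 1:
        warnings.warn(
            "noisy sweep: multiple aspect-ratio crossings; using the lowest frequency",
            stacklevel=2,
        )
    i = int(sign_change[0])
    x0, x1 = np.log10(f[i]), np.log10(f[i + 1])
    y0, y1 = d[i], d[i + 1]
    logfc = x0 + (0.0 - y0) * (x1 - x0) / (y1 - y0)
    return float(10.0**logfc)


def fit_specific_capacitance(
    points, lambda_in: float, ratio: float
) -> tuple[float, float]:
    """Specific membrane capacitance from (R, f_c) pairs of several vesicles.

    Ordinary least squares of f_c against 1/R (slope s, free intercept);
    C_m = lambda_in / (2 pi s) * [(1-Lambda)(3+Lambda)]^RADICAL_EXPONENT.
    Returns (cm, cm_se) with the SE propagated from the slope SE.
    """
    pts = [(float(r), float(fc)) for r, fc in points]
    if len(pts) < 3:
        raise ValueError("insufficient vesicles: need >= 3 (R, f_c) points")
    if not 0 < ratio < 1:
        raise SweepError("conductivity ratio must satisfy 0 < Lambda < 1")
    x = np.array([1.0 / r for r, _ in pts])
    y = np.array([fc for _, fc in pts])
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate radii: no spread in 1/R")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    if slope <= 0:
        raise ValueError("negative slope: f_c must increase with 1/R")
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    slope_se = np.sqrt(np.sum(resid**2) / dof / sxx)
    radical = ((1.0 - ratio) * (3.0 + ratio)) ** RADICAL_EXPONENT
    cm = lambda_in / (2.0 * np.pi * slope) * radical
    cm_se = cm * slope_se / slope
    return float(cm), float(cm_se)


# ---------------------------------------------------------------------------
# Double layers and dielectric constant
# ---------------------------------------------------------------------------

def debye_length(
    c_salt: float,
    temperature: float = DEFAULT_TEMPERATURE,
    eps_water: float = WATER_RELATIVE_PERMITTIVITY,
) -> float:
    """Debye screening length of a 1:1 electrolyte.

    lambda_D = sqrt(eps_rW eps0 k_B T / (2 N_A e^2 c)) with ``c_salt`` in
    mol/m^3 (1 mol/m^3 = 1 mM).  Monotone decreasing in c_salt.
    """
    if c_salt <= 0:
        raise ValueError("salt concentration must be positive")
    num = eps_water * VACUUM_PERMITTIVITY * BOLTZMANN * temperature
    den = 2.0 * AVOGADRO * ELEMENTARY_CHARGE**2 * c_salt
    return float(np.sqrt(num / den))


def double_layer_capacitance(
    debye: float, eps_water: float = WATER_RELATIVE_PERMITTIVITY
) -> float:
    """Diffuse double-layer capacitance C_D = eps_rW eps0 / lambda_D (F/m^2)."""
    if debye <= 0:
        raise ValueError("Debye length must be positive")
    return eps_water * VACUUM_PERMITTIVITY / debye


def bare_bilayer_capacitance(cm: float, cd_in: float, cd_out: float) -> float:
    """Bare bilayer capacitance from the series-capacitor correction.

    C_B = 1 / (1/C_m - 1/C_D,in - 1/C_D,out); requires the double layers
    not to dominate (1/C_m > 1/C_D,in + 1/C_D,out).
    """
    if min(cm, cd_in, cd_out) <= 0:
        raise ValueError("capacitances must be positive")
    inv = 1.0 / cm - 1.0 / cd_in - 1.0 / cd_out
    if inv <= 0:
        raise ValueError("double layers dominate; C_B undefined")
    return 1.0 / inv


def dielectric_constant(cb: float, thickness: float) -> float:
    """Relative dielectric constant eps_rB = C_B d / eps0."""
    if cb <= 0 or thickness <= 0:
        raise ValueError("cb and thickness must be positive")
    return cb * thickness / VACUUM_PERMITTIVITY


def capacitance_set(
    cm: float,
    thickness: float,
    debye_in: float,
    debye_out: float,
    eps_water: float = WATER_RELATIVE_PERMITTIVITY,
) -> CapacitanceSet:
    """Full capacitance chain: measured C_m -> C_B -> eps_rB.

    All inputs SI (F/m^2 and m).  The returned set satisfies the series
    identity by construction.
    """
    cd_in = double_layer_capacitance(debye_in, eps_water)
    cd_out = double_layer_capacitance(debye_out, eps_water)
    cb = bare_bilayer_capacitance(cm, cd_in, cd_out)
    eps = dielectric_constant(cb, thickness)
    return CapacitanceSet(
        cm=cm,
        cb=cb,
        cd_in=cd_in,
        cd_out=cd_out,
        eps_membrane=eps,
        thickness=thickness,
        debye_in=debye_in,
        debye_out=debye_out,
        eps_water=eps_water,
    )
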