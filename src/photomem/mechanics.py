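"""Membrane elasticity bookkeeping: stretching modulus, interleaflet
coupling, volume-conservation thickness relation, and area-change
arithmetic for LUV (DLS) and Langmuir-monolayer data.

The stretching (area-compressibility) modulus K_A is the slope of the
mechanical tension versus relative area strain,

    Sigma(A) = K_A (A - A0)/A0,

fitted here in the equivalent linear-in-A form (slope K_A/A0, intercept
-K_A) to avoid a nonlinear optimization.  The interleaflet coupling
constant follows the polymer-brush relation kappa/K = beta d^2, reported
as 1/beta = K d^2 / kappa: 12 for bound leaflets, 24 for the polymer-brush
prediction, 48 for freely sliding leaflets.

Sign conventions: every percent change carries its sign (shrinkage is
negative, never silently absolute-valued).  Monolayer expansion is
reported as 100 (A_cis - A_trans)/A_trans so that the cis (UV) state's
larger molecular area gives a positive expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TensionAreaPoint:
    """One (area per lipid, mechanical tension) observation (SI units)."""

    area_per_lipid: float  # m^2
    tension: float         # N/m

    def __post_init__(self):
        if self.area_per_lipid <= 0:
            raise ValueError("area per lipid must be positive")


@dataclass(frozen=True)
class ElasticitySet:
    """Consistent elasticity record: kappa, K, d and 1/beta.

    The invariant inv_beta = K d^2 / kappa holds to 1e-12 (relative).
    """

    kappa: float           # J
    stretch_modulus: float  # N/m
    thickness: float       # m
    inv_beta: float        # dimensionless
    area_per_lipid_0: float | None = None  # m^2, zero-tension area

    def __post_init__(self):
        for name in ("kappa", "stretch_modulus", "thickness", "inv_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        expected = self.stretch_modulus * self.thickness**2 / self.kappa
        if abs(self.inv_beta - expected) > 1e-12 * expected:
            raise ValueError("inv_beta inconsistent with K d^2 / kappa")

    @classmethod
    def from_moduli(cls, kappa, stretch_modulus, thickness, area_per_lipid_0=None):
        return cls(
            kappa=kappa,
            stretch_modulus=stretch_modulus,
            thickness=thickness,
            inv_beta=coupling_constant(kappa, stretch_modulus, thickness),
            area_per_lipid_0=area_per_lipid_0,
        )


@dataclass(frozen=True)
class SizeChangeRecord:
    """Before/after size (radius or area per lipid) with percent change."""

    before: float
    after: float
    percent_change: float

    def __post_init__(self):
        if self.before <= 0:
            raise ValueError("'before' must be positive")


# ---------------------------------------------------------------------------
# Stretching modulus
# ---------------------------------------------------------------------------

def fit_stretching_modulus(points) -> tuple[float, float, float]:
    """Two-parameter fit of Sigma = K_A (A - A0)/A0.

    Linear in A: Sigma = (K_A/A0) A - K_A, so ordinary least squares gives
    K_A = -intercept and A0 = -intercept/slope.  Returns
    (K_A, K_A_se, A0) in SI units (N/m, N/m, m^2).  A negative fitted K_A
    is flagged with a warning; degenerate area spacing or zero tension
    variation raise.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need >= 3 tension-area points")
    a = np.array([p.area_per_lipid for p in pts])
    s = np.array([p.tension for p in pts])
    if np.ptp(s) == 0:
        raise ValueError("no tension variation")
    am = a.mean()
    saa = np.sum((a - am) ** 2)
    if saa <= 0 or np.ptp(a) < 1e-12 * am:
        raise ValueError("degenerate area spacing")
    slope = np.sum((a - am) * (s - s.mean())) / saa
    intercept = s.mean() - slope * am
    k_a = -intercept
    if k_a <= 0:
        warnings.warn("negative fitted stretching modulus", stacklevel=2)
    a0 = -intercept / slope if slope != 0 else np.nan
    resid = s - (intercept + slope * a)
    dof = max(len(pts) - 2, 1)
    s2 = np.sum(resid**2) / dof
    intercept_se = np.sqrt(s2 * (1.0 / len(pts) + am**2 / saa))
    return float(k_a), float(intercept_se), float(a0)


# ---------------------------------------------------------------------------
# Coupling and thickness
# ---------------------------------------------------------------------------

def coupling_constant(kappa: float, stretch_modulus: float, thickness: float) -> float:
    """Interleaflet coupling 1/beta = K d^2 / kappa (dimensionless)."""
    if kappa <= 0 or stretch_modulus <= 0 or thickness <= 0:
        raise ValueError("kappa, K and d must be positive")
    return stretch_modulus * thickness**2 / kappa


def thickness_from_area_conservation(
    area_increase_fraction: float, thickness_0: float
) -> tuple[float, float]:
    """Thickness change of a volume-preserving elastic sheet.

    An area change dA/A at constant volume (volume = area x thickness)
    gives dd/d0 = (dA/A)/(1 + dA/A) and d_new = d0/(1 + dA/A).  Returns
    (relative thickness decrease, new thickness).
    """
    if area_increase_fraction <= -1:
        raise ValueError("area change fraction must exceed -1")
    if thickness_0 <= 0:
        raise ValueError("thickness must be positive")
    x = area_increase_fraction
    return x / (1.0 + x), thickness_0 / (1.0 + x)


# ---------------------------------------------------------------------------
# Area-change arithmetic
# ---------------------------------------------------------------------------

def sphere_area_change(r_before: float, r_after: float) -> float:
    """Percent area change of a sphere from its radius (DLS on LUVs)."""
    if r_before <= 0 or r_after <= 0:
        raise ValueError("radii must be positive")
    return 100.0 * (r_after**2 - r_before**2) / r_before**2


def monolayer_expansion(area_trans: float, area_cis: float) -> float:
    """Percent monolayer area expansion at fixed surface pressure.

    100 (A_cis - A_trans)/A_trans: the UV (cis) state occupies more area
    per lipid, so expansion is positive.  Reverse switching gives the
    (negative) contraction.
    """
    if area_trans <= 0 or area_cis <= 0:
        raise ValueError("areas must be positive")
    return 100.0 * (area_cis - area_trans) / area_trans
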