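"""Flicker (fluctuation) spectroscopy: bending rigidity and tension from
thermal shape undulations of quasi-spherical vesicles.

Model
-----
The shape of a quasi-spherical vesicle of mean radius R is expanded in
spherical harmonics, u(theta, phi) = sum_{l,m} u_lm Y_lm.  For the Helfrich
bending energy with bending rigidity kappa and (reduced) tension
sigma_bar = sigma R^2 / kappa, equipartition gives

    <|u_lm|^2> = k_B T / { kappa (l-1)(l+2) [ l(l+1) + sigma_bar ] }

Microscopy observes the equatorial cross-section r(phi).  Its Fourier
coefficients u_q = (1/2pi) int u(pi/2, phi) e^{-i q phi} dphi pick up all
l >= q through the equatorial value of the spherical harmonic, so the
observable per-mode variance is

    V(q) = (k_B T / kappa) * sum_{l=max(q,2)}^{l_max}
           N_lq / [ (l-1)(l+2) (l(l+1) + sigma_bar) ]

with the equatorial projection weight

    N_lq = |Y_lq(pi/2, 0)|^2
         = (2l+1)/(4 pi) * (l-q)!/(l+q)! * [P_l^q(0)]^2,

where P_l^q is the associated Legendre function (N_lq = 0 for odd l+q).
The transform normalization is one-sided complex coefficients obtained as
``fft(u)/n``; a single frame with u(phi) = eps*cos(3 phi) therefore has
msa(3) = eps^2/4.

The Legendre sum is truncated at l_max = 8*q_max by default (truncation
error < 0.1%, checked by doubling).  The fit is a weighted least-squares
of the measured mean-square amplitudes against V(q; kappa, sigma_bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .constants import BOLTZMANN, DEFAULT_TEMPERATURE
from .imaging_contour import VesicleContour

#: QC acceptance windows (tension in N/m, radius in m)
QC_SIGMA_MIN = 1e-9
QC_SIGMA_MAX = 1e-7
QC_RADIUS_MIN = 10e-6
QC_RADIUS_MAX = 25e-6

#: Default crossover-mode choice: low modes 3-5 are tension dominated, so
#: fits start at q_min = 3 to retain sensitivity to sigma while the bending
#: branch constrains kappa.
DEFAULT_Q_MIN = 3

#: Spherical-harmonic truncation of the Legendre sum, as a multiple of the
#: largest mode used.  The tail of the sum decays only as 1/l^2 relative
#: to its head, so l_max = 8 q_max is needed for < 0.1% truncation error
#: (checked by doubling); smaller factors bias kappa visibly.
L_MAX_FACTOR = 8


# ---------------------------------------------------------------------------
# Spectrum model
# ---------------------------------------------------------------------------

def _log_legendre_equator_sq(l: np.ndarray, q: int) -> np.ndarray:
    """log [P_l^q(0)]^2 via the closed form, stable for large l, q.

    P_l^m(0) = 2^m cos(pi(l+m)/2) Gamma((l+m+1)/2) / (sqrt(pi) Gamma((l-m)/2 + 1))
    """
    return 2.0 * (
        q * np.log(2.0)
        - 0.5 * np.log(np.pi)
        + gammaln((l + q + 1) / 2.0)
        - gammaln((l - q) / 2.0 + 1.0)
    )


def legendre_equator_sq(l: np.ndarray, q: int) -> np.ndarray:
    """[P_l^q(0)]^2; zero for odd l + q."""
    l = np.asarray(l)
    parity = (l + q) % 2 == 0
    return np.where(parity, np.exp(_log_legendre_equator_sq(l, q)), 0.0)


def equatorial_weight(l: np.ndarray, q: int) -> np.ndarray:
    """N_lq = |Y_lq(pi/2,0)|^2, the equatorial projection weight.

    Assembled fully in log space: the factorial ratio and [P_l^q(0)]^2
    individually overflow for l of a few hundred while their product stays
    of order 1/l.
    """
    l = np.asarray(l, dtype=float)
    parity = (l + q) % 2 == 0
    log_n = (
        np.log((2.0 * l + 1.0) / (4.0 * np.pi))
        + gammaln(l - q + 1.0)
        - gammaln(l + q + 1.0)
        + _log_legendre_equator_sq(l, q)
    )
    return np.where(parity, np.exp(log_n), 0.0)


def mode_variance(
    q: np.ndarray | int,
    kappa: float,
    sigma_bar: float,
    temperature: float = DEFAULT_TEMPERATURE,
    l_max: int | None = None,
) -> np.ndarray:
    """Model variance V(q) of the equatorial Fourier mode q.

    Parameters
    ----------
    q : int or array of int
        Equatorial mode number(s), q >= 2.
    kappa : float
        Bending rigidity in joules.
    sigma_bar : float
        Reduced tension sigma R^2 / kappa (dimensionless).
    l_max : int, optional
        Spherical-harmonic truncation; defaults to L_MAX_FACTOR * max(q).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    qs = np.atleast_1d(np.asarray(q, dtype=int))
    if np.any(qs < 2):
        raise ValueError("modes q must be >= 2")
    if l_max is None:
        l_max = L_MAX_FACTOR * int(qs.max())
    kt = BOLTZMANN * temperature
    out = np.empty(qs.shape, dtype=float)
    for i, qq in enumerate(qs):
        l = np.arange(max(qq, 2), l_max + 1, dtype=float)
        denom = (l - 1.0) * (l + 2.0) * (l * (l + 1.0) + sigma_bar)
        out[i] = (kt / kappa) * np.sum(equatorial_weight(l, int(qq)) / denom)
    return out if np.ndim(q) else float(out[0])


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeSpectrum:
    """Time-averaged equatorial fluctuation spectrum.

    ``msa`` holds the across-frame mean of |u_q|^2 (dimensionless, radii
    normalized by the per-frame mean radius), ``msa_se`` its standard error.
    """

    modes: np.ndarray
    msa: np.ndarray
    msa_se: np.ndarray
    n_frames: int
    mean_radius: float

    def __post_init__(self):
        if np.any(np.asarray(self.msa) < 0):
            raise ValueError("mean-square amplitudes must be non-negative")
        if np.any(np.diff(self.modes) <= 0):
            raise ValueError("modes must be strictly increasing")


@dataclass(frozen=True)
class FlickerFit:
    """Fitted Helfrich parameters for one vesicle."""

    kappa: float            # J
    sigma: float            # N/m
    sigma_bar: float        # dimensionless sigma R^2 / kappa
    temperature: float      # K
    q_min: int
    q_max: int
    kappa_se: float
    sigma_se: float
    l_max: int
    sigma_at_bound: bool = False

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.q_min < 2 or self.q_max <= self.q_min:
            raise ValueError("need q_min >= 2 and q_max > q_min")
        if self.l_max < self.q_max:
            raise ValueError("l_max must be >= q_max")

    @property
    def kappa_kbt(self) -> float:
        return self.kappa / (BOLTZMANN * self.temperature)


@dataclass(frozen=True)
class VesicleQC:
    """Per-vesicle quality-control record."""

    mean_radius: float
    sigma: float
    defect_flag: bool = False


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_spectrum(contours) -> ModeSpectrum:
    """Fluctuation spectrum from a stack of equatorial contours.

    Per frame the relative radial displacement
    u(phi) = (r(phi) - R_frame)/R_frame is Fourier transformed
    (coefficients fft/n, one-sided); msa(q) is the across-frame mean of
    |u_q|^2 for 2 <= q <= n_points/4 with its standard error.
    """
    contours = list(contours)
    if len(contours) < 100:
        raise ValueError(f"too few frames: {len(contours)} < 100")
    n_points = contours[0].n_points
    if any(c.n_points != n_points for c in contours):
        raise ValueError("inconsistent contour lengths")
    radii = np.stack([c.radii for c in contours])  # (frames, points)
    r_frame = radii.mean(axis=1, keepdims=True)
    u = radii / r_frame - 1.0
    coeff = np.fft.rfft(u, axis=1) / n_points
    power = np.abs(coeff) ** 2  # (frames, n_points//2 + 1)
    modes = np.arange(2, n_points // 4 + 1)
    p = power[:, modes]
    msa = p.mean(axis=0)
    msa_se = p.std(axis=0, ddof=1) / np.sqrt(len(contours))
    return ModeSpectrum(
        modes=modes,
        msa=msa,
        msa_se=msa_se,
        n_frames=len(contours),
        mean_radius=float(r_frame.mean()),
    )


def fit_helfrich(
    spectrum: ModeSpectrum,
    temperature: float = DEFAULT_TEMPERATURE,
    q_min: int = DEFAULT_Q_MIN,
    q_max: int | None = None,
    l_max: int | None = None,
) -> FlickerFit:
    """Weighted least-squares fit of the quasi-spherical Helfrich spectrum.

    Fits (kappa, sigma_bar) to msa(q) over q in [q_min, q_max] with weights
    1/SE^2; the tension follows as sigma = sigma_bar * kappa / R^2.
    Standard errors come from the scaled fit covariance.  A reduced tension
    pinned at the optimizer bound is reported via ``sigma_at_bound``
    (treated as a QC failure downstream).
    """
    if q_max is None:
        # default fit range ends at n_points/8 <=> half the reported modes
        q_max = int(spectrum.modes.max()) // 2
    if q_max > spectrum.modes.max():
        raise ValueError("q_max exceeds available modes")
    if l_max is None:
        l_max = L_MAX_FACTOR * q_max
    sel = (spectrum.modes >= q_min) & (spectrum.modes <= q_max)
    q = spectrum.modes[sel].astype(int)
    y = spectrum.msa[sel]
    se = spectrum.msa_se[sel]
    se = np.where(se > 0, se, np.max(se) if np.max(se) > 0 else 1.0)
    kt = BOLTZMANN * temperature

    # parameters: log amplitude A = log(kT/kappa), log sigma_bar
    l_arrays = [np.arange(max(int(qq), 2), l_max + 1, dtype=float) for qq in q]
    weights_lq = [equatorial_weight(l, int(qq)) for l, qq in zip(l_arrays, q)]

    def model(params):
        log_a, log_sbar = params
        sbar = np.exp(log_sbar)
        out = np.empty(q.size)
        for i, l in enumerate(l_arrays):
            denom = (l - 1.0) * (l + 2.0) * (l * (l + 1.0) + sbar)
            out[i] = np.exp(log_a) * np.sum(weights_lq[i] / denom)
        return out

    def residuals(params):
        return (model(params) - y) / se

    # initialize the amplitude from the highest (bending-dominated) mode
    x0 = np.array([np.log(max(y[-1] / model((0.0, 0.0))[-1], 1e-12)), np.log(5.0)])
    lb = np.array([-60.0, np.log(1e-4)])
    ub = np.array([10.0, np.log(1e8)])
    res = optimize.least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise RuntimeError(f"Helfrich fit did not converge: {res.message}")
    log_a, log_sbar = res.x
    at_bound = bool(
        np.isclose(log_sbar, lb[1], atol=1e-6) or np.isclose(log_sbar, ub[1], atol=1e-6)
    )
    kappa = kt / np.exp(log_a)
    sigma_bar = np.exp(log_sbar)
    sigma = sigma_bar * kappa / spectrum.mean_radius**2

    # covariance of (log_a, log_sbar) from the scaled Jacobian
    dof = max(q.size - 2, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        var_log_a = cov[0, 0]
        var_log_s = cov[1, 1]
        cov_as = cov[0, 1]
    except np.linalg.LinAlgError:
        var_log_a = var_log_s = cov_as = np.nan
    kappa_se = kappa * np.sqrt(var_log_a) if np.isfinite(var_log_a) else np.nan
    # sigma = kT * sbar / (A_exp ... ) -> d log sigma = d log sbar - d log a... :
    # sigma = sigma_bar * kappa / R^2, log sigma = log_sbar - log_a + const
    var_log_sigma = var_log_s + var_log_a - 2.0 * cov_as
    sigma_se = sigma * np.sqrt(var_log_sigma) if np.isfinite(var_log_sigma) else np.nan

    return FlickerFit(
        kappa=float(kappa),
        sigma=float(sigma),
        sigma_bar=float(sigma_bar),
        temperature=temperature,
        q_min=int(q_min),
        q_max=int(q_max),
        kappa_se=float(kappa_se),
        sigma_se=float(sigma_se),
        l_max=int(l_max),
        sigma_at_bound=at_bound,
    )


def qc_filter(fit: FlickerFit, qc: VesicleQC) -> tuple[bool, str]:
    """Accept/reject a vesicle per the study's quality-control rules.

    Accept iff 10 um <= R <= 25 um, 1e-9 <= sigma <= 1e-7 N/m, the vesicle
    is defect-free, and the tension fit did not pin at a bound.  Returns
    (accepted, reason); reason names the violated rule.
    """
    if qc.defect_flag:
        return False, "reject(defect)"
    if not (QC_RADIUS_MIN <= qc.mean_radius <= QC_RADIUS_MAX):
        return False, "reject(radius)"
    if not (QC_SIGMA_MIN <= qc.sigma <= QC_SIGMA_MAX):
        return False, "reject(tension)"
    if fit.sigma_at_bound:
        return False, "reject(tension-fit-at-bound)"
    return True, "accept"
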