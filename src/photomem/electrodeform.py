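"""Vesicle electrodeformation analysis.

A GUV in a moderate AC field deforms into a prolate ellipsoid with
semi-axes ``a`` (along the field) and ``b`` (perpendicular).  The total
membrane area follows from the prolate spheroid formula

    A = 2 pi b [ b + a * arcsin(eps)/eps ],   eps^2 = 1 - (b/a)^2,

continuous at eps -> 0 (sphere: A = 4 pi R^2).  Photoisomerization of the
azo-PC lipid changes the available membrane area; the relative change
100 (A_light - A_initial)/A_initial quantifies it, and exponential fits to
the aspect-ratio response under UV/blue illumination give the switching
time constants.  A one-way ANOVA compares area changes across groups of
vesicles (reversibility test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

#: Below this eccentricity the arcsin(eps)/eps factor is evaluated by its
#: Taylor series 1 + eps^2/6 + 3 eps^4/40 to avoid 0/0.
_EPS_SERIES_CUTOFF = 1e-4

ILLUMINATION_LABELS = ("dark", "UV", "blue")


class OblateShapeError(ValueError):
    """Prolate-only area formula applied to an oblate shape."""


@dataclass(frozen=True)
class EllipsoidShape:
    """Prolate spheroid semi-axes: ``a`` along the field, ``b`` across (m)."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def eccentricity(self) -> float:
        # tolerate rounding at the sphere limit (b/a within 1e-12 of 1)
        if self.b > self.a * (1.0 + 1e-12):
            raise OblateShapeError("eccentricity defined only for a >= b")
        return float(np.sqrt(max(1.0 - (self.b / self.a) ** 2, 0.0)))

    @property
    def aspect_ratio(self) -> float:
        return self.a / self.b


@dataclass(frozen=True)
class AspectRatioTrace:
    """Aspect-ratio time series with per-frame illumination labels."""

    times: np.ndarray
    aspect: np.ndarray
    illumination: np.ndarray  # strings from ILLUMINATION_LABELS
    field_on: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        ar = np.asarray(self.aspect, dtype=float)
        il = np.asarray(self.illumination)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "aspect", ar)
        object.__setattr__(self, "illumination", il)
        if t.shape != ar.shape or t.shape != il.shape:
            raise ValueError("times, aspect and illumination must align")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(ar <= 0):
            raise ValueError("aspect ratios must be positive")
        bad = set(np.unique(il)) - set(ILLUMINATION_LABELS)
        if bad:
            raise ValueError(f"unknown illumination labels: {sorted(bad)}")
        if self.field_on is not None:
            fo = np.asarray(self.field_on, dtype=bool)
            object.__setattr__(self, "field_on", fo)
            if fo.shape != t.shape:
                raise ValueError("field_on must align with times")


@dataclass(frozen=True)
class AreaChangeResult:
    """Photo-induced relative area change."""

    area_initial: float  # m^2
    area_light: float    # m^2
    delta_percent: float

    def __post_init__(self):
        if self.area_initial <= 0 or self.area_light <= 0:
            raise ValueError("areas must be positive")


@dataclass(frozen=True)
class KineticsFit:
    """Exponential relaxation fit of one illumination epoch."""

    tau: float        # s
    amplitude: float  # signed; negative for a decaying (blue) response
    baseline: float
    rmse: float
    window: tuple[float, float]
    flat: bool = False  # amplitude indistinguishable from zero

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")


# ---------------------------------------------------------------------------
# Area
# ---------------------------------------------------------------------------

def _arcsin_over_eps(eps: float) -> float:
    if eps < _EPS_SERIES_CUTOFF:
        e2 = eps * eps
        return 1.0 + e2 / 6.0 + 3.0 * e2 * e2 / 40.0
    return float(np.arcsin(eps) / eps)


def ellipsoid_area(shape: EllipsoidShape, allow_oblate: bool = False) -> float:
    """Surface area of the deformed vesicle in m^2.

    Prolate (a >= b): A = 2 pi b (b + a arcsin(eps)/eps).  Oblate input
    raises unless ``allow_oblate`` is set, in which case the standard
    oblate-spheroid formula is used (needed only for sweep data; the area
    measurement protocol guarantees prolates).
    """
    a, b = shape.a, shape.b
    if b > a * (1.0 + 1e-12):
        if not allow_oblate:
            raise OblateShapeError("oblate shape: prolate area formula inapplicable")
        # oblate spheroid: equatorial semi-axis b > polar semi-axis a
        e = np.sqrt(1.0 - (a / b) ** 2)
        if e < _EPS_SERIES_CUTOFF:
            return 4.0 * np.pi * ((a + b) / 2.0) ** 2
        return float(2.0 * np.pi * b * b + np.pi * a * a / e * np.log((1 + e) / (1 - e)))
    eps = shape.eccentricity
    return float(2.0 * np.pi * b * (b + a * _arcsin_over_eps(eps)))


def relative_area_change(area_initial: float, area_light: float) -> float:
    """Percent area change 100 (A_l - A_i)/A_i; shrinkage is negative."""
    if area_initial <= 0:
        raise ValueError("initial area must be positive")
    return 100.0 * (area_light - area_initial) / area_initial


def area_change_result(shape_initial: EllipsoidShape, shape_light: EllipsoidShape) -> AreaChangeResult:
    """Area change between two prolate shapes (convenience wrapper)."""
    a_i = ellipsoid_area(shape_initial)
    a_l = ellipsoid_area(shape_light)
    return AreaChangeResult(a_i, a_l, relative_area_change(a_i, a_l))


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def segment_epochs(trace: AspectRatioTrace) -> list[tuple[str, float, float]]:
    """Maximal runs of constant illumination label, in time order.

    Returns (label, start_time, end_time) per epoch; the end time is the
    last frame time of the run.
    """
    il = trace.illumination
    if il.size == 0:
        return []
    out = []
    start = 0
    for i in range(1, il.size):
        if il[i] != il[start]:
            out.append((str(il[start]), float(trace.times[start]), float(trace.times[i - 1])))
            start = i
    out.append((str(il[start]), float(trace.times[start]), float(trace.times[-1])))
    return out


def fit_relaxation(
    trace: AspectRatioTrace,
    epoch: str,
    occurrence: int = 0,
    flat_snr: float = 2.0,
) -> KineticsFit:
    """Exponential fit of one illumination epoch.

    Fits aspect(t) = baseline - amplitude * exp(-(t - t0)/tau) over the
    ``occurrence``-th epoch with the given label; t0 is fixed to the epoch
    start (the illumination switches stepwise, so floating t0 would only
    correlate with tau).  An amplitude below ``flat_snr`` residual SDs is
    flagged as flat (tau not meaningful).
    """
    epochs = [e for e in segment_epochs(trace) if e[0] == epoch]
    if occurrence >= len(epochs):
        raise ValueError(f"epoch {epoch!r} (occurrence {occurrence}) not present")
    _, t_start, t_end = epochs[occurrence]
    sel = (trace.times >= t_start) & (trace.times <= t_end)
    t = trace.times[sel]
    y = trace.aspect[sel]
    if t.size < 20:
        raise ValueError(f"epoch has {t.size} frames; need >= 20")
    t0 = t[0]

    def model(tt, baseline, amplitude, tau):
        return baseline - amplitude * np.exp(-(tt - t0) / tau)

    span = t[-1] - t0
    p0 = (y[-1], y[-1] - y[0], max(span / 5.0, 1e-6))
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"relaxation fit did not converge: {exc}") from exc
    baseline, amplitude, tau = popt
    resid = y - model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    amp_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    flat = abs(amplitude) < flat_snr * amp_se or abs(amplitude) < 1e-12
    return KineticsFit(
        tau=float(tau),
        amplitude=float(amplitude),
        baseline=float(baseline),
        rmse=rmse,
        window=(float(t0), float(t[-1])),
        flat=bool(flat),
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA (F, p) across groups of area changes.

    Degenerate input with zero between-group variability returns
    (0.0, 1.0); zero within-group variance with distinct means returns
    (inf, 0.0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_between <= 1e-30 * max(ss_within, 1.0):
        return 0.0, 1.0
    if ss_within <= 1e-30 * ss_between:
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
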