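"""Parameter-recovery protocols validating each estimator end to end.

Each function generates synthetic data at a known ground truth with the
matching generator, runs the full analysis chain, and returns the median
recovered value over ``n_seeds`` independent replicates.  These protocols
are what the package's acceptance checks run; they are also convenient for
benchmarking estimator robustness at other operating points.

Problem sizes follow the study conditions: 3000 contour frames per
vesicle for flicker spectroscopy, 10 vesicles with radii 3-10 um per
capacitance fit, 256x256 height maps, 100 frames/s kinetic traces, and
5 tension-area points spanning area strains of 1-8%.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import afm_thickness as afm
from . import capacitance as cap
from . import electrodeform as ed
from . import flicker as fl
from . import mechanics as mech
from . import synthetic_data as sd
from .constants import DEFAULT_TEMPERATURE, kbt


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent 31-bit seeds from a master seed."""
    return np.random.default_rng(seed).integers(0, 2**31, size=n)


def recover_specific_capacitance(
    cm: float,
    n_seeds: int = 200,
    seed: int = 0,
    n_vesicles: int = 10,
    radius_range: tuple[float, float] = (3e-6, 10e-6),
    lambda_in: float = 42.70e-4,
    ratio: float = 0.52,
    ar_noise_sd: float = 0.02,
) -> float:
    """Median recovered C_m (F/m^2) from noisy synthetic frequency sweeps."""
    radii = np.linspace(*radius_range, n_vesicles)
    estimates = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        points = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # noisy sweeps may multi-cross
            for radius in radii:
                truth = sd.SweepTruth(
                    cm=cm, lambda_in=lambda_in, lambda_out=lambda_in / ratio,
                    radius=radius, ar_noise_sd=ar_noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                fc = cap.detect_critical_frequency(sd.gen_sweep(truth))
                points.append((radius, fc))
        estimates.append(cap.fit_specific_capacitance(points, lambda_in, ratio)[0])
    return float(np.median(estimates))


def recover_bending_rigidity(
    kappa_kbt: float,
    n_seeds: int = 100,
    seed: int = 0,
    sigma_bar: float = 5.0,
    radius: float = 15e-6,
    n_frames: int = 3000,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Median recovered bending rigidity (kBT) from synthetic contour stacks."""
    kappa = kappa_kbt * kbt(temperature)
    estimates = []
    for s in _child_seeds(seed, n_seeds):
        truth = sd.FlickerTruth(
            kappa=kappa, sigma=sigma_bar * kappa / radius**2, radius=radius,
            temperature=temperature, n_frames=n_frames, seed=int(s),
        )
        spectrum = fl.compute_spectrum(sd.gen_flicker_contours(truth))
        fit = fl.fit_helfrich(spectrum, temperature=temperature)
        estimates.append(fit.kappa_kbt)
    return float(np.median(estimates))


def recover_bilayer_thickness(
    step_height: float = 6.2e-9,
    n_seeds: int = 100,
    seed: int = 0,
    roughness_sd: float = 0.1e-9,
) -> float:
    """Median recovered step height (m) via the full AFM pipeline."""
    estimates = []
    for s in _child_seeds(seed, n_seeds):
        truth = sd.MapTruth(step_height=step_height, roughness_sd=roughness_sd,
                            seed=int(s))
        estimates.append(afm.run_pipeline(sd.gen_heightmap(truth)).thickness)
    return float(np.median(estimates))


def recover_time_constant(
    tau: float,
    epoch: str = "UV",
    n_seeds: int = 200,
    seed: int = 0,
    noise_sd: float = 0.01,
) -> float:
    """Median recovered relaxation time constant (s) from kinetic traces."""
    estimates = []
    for s in _child_seeds(seed, n_seeds):
        truth = sd.TraceTruth(tau=tau, noise_sd=noise_sd, seed=int(s))
        estimates.append(ed.fit_relaxation(sd.gen_trace(truth), epoch).tau)
    return float(np.median(estimates))


def recover_stretching_modulus(
    k_a: float = 221.8e-3,
    a0: float = 0.62e-18,
    n_seeds: int = 200,
    seed: int = 0,
    tension_noise: float = 0.03,
    strains: tuple[float, float] = (0.01, 0.08),
    n_points: int = 5,
) -> float:
    """Median recovered stretching modulus (N/m) from noisy tension-area fits."""
    strain_grid = np.linspace(*strains, n_points)
    estimates = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        points = [
            mech.TensionAreaPoint(
                area_per_lipid=a0 * (1 + x),
                tension=k_a * x * (1 + rng.normal(0.0, tension_noise)),
            )
            for x in strain_grid
        ]
        estimates.append(mech.fit_stretching_modulus(points)[0])
    return float(np.median(estimates))
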