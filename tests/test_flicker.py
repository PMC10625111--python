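"""Flicker spectroscopy: spectrum computation, Helfrich fit, QC."""

import numpy as np
import pytest
from scipy.special import lpmv

from photomem import synthetic_data as sd
from photomem.constants import kbt
from photomem.flicker import (
    VesicleQC,
    compute_spectrum,
    equatorial_weight,
    fit_helfrich,
    legendre_equator_sq,
    mode_variance,
    qc_filter,
)
from photomem.imaging_contour import VesicleContour, uniform_angles


def make_frames(radii_fn, n_frames, n_points=64):
    ang = uniform_angles(n_points)
    return [
        VesicleContour(angles=ang, radii=radii_fn(ang), frame_time=float(i))
        for i in range(n_frames)
    ]


class TestSpectrumModel:
    @pytest.mark.parametrize("l", range(2, 13))
    def test_legendre_zero_argument_against_scipy(self, l):
        for q in range(2, l + 1):
            ref = lpmv(q, l, 0.0) ** 2
            got = float(legendre_equator_sq(np.array([l]), q)[0])
            assert got == pytest.approx(ref, rel=1e-10, abs=1e-300)

    def test_odd_parity_weights_vanish(self):
        l = np.arange(3, 20, 2)
        assert np.all(equatorial_weight(l, 2)[l % 2 == 1] == 0)

    def test_tension_free_high_q_scaling(self):
        # sigma_bar -> 0, large q: V(q) ~ q^-3
        q = np.arange(10, 31)
        v = mode_variance(q, 1e-19, 1e-4, l_max=200)
        slope = np.polyfit(np.log(q), np.log(v), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.1)

    def test_truncation_converged(self):
        # doubling the default l_max = 8 q_max changes V(q) by < 0.1%
        q = np.arange(3, 33)
        v1 = mode_variance(q, 20 * kbt(), 5.0, l_max=8 * 32)
        v2 = mode_variance(q, 20 * kbt(), 5.0, l_max=16 * 32)
        assert np.all(np.abs(v2 / v1 - 1) < 0.001)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mode_variance(5, -1e-19, 5.0)
        with pytest.raises(ValueError):
            mode_variance(1, 1e-19, 5.0)


class TestComputeSpectrum:
    def test_perfect_circles_zero_spectrum(self):
        frames = make_frames(lambda ang: np.full_like(ang, 10e-6), 120)
        spec = compute_spectrum(frames)
        assert np.all(spec.msa == 0)
        assert spec.mean_radius == pytest.approx(10e-6)

    def test_pure_cosine_mode_normalization(self):
        # u(phi) = eps cos(3 phi) -> msa(3) = eps^2/4, all other modes 0
        eps = 0.01
        frames = make_frames(lambda ang: 10e-6 * (1 + eps * np.cos(3 * ang)), 100)
        spec = compute_spectrum(frames)
        i3 = list(spec.modes).index(3)
        assert spec.msa[i3] == pytest.approx(eps**2 / 4, rel=1e-10)
        others = np.delete(spec.msa, i3)
        assert np.all(others < 1e-12 * spec.msa[i3] + 1e-30)

    def test_fft_equals_direct_summation_dft(self):
        # oracle equality on 16-point toy contours
        rng = np.random.default_rng(42)
        ang = uniform_angles(16)
        frames = [
            VesicleContour(angles=ang, radii=10e-6 * (1 + 0.01 * rng.normal(size=16)))
            for _ in range(100)
        ]
        spec = compute_spectrum(frames)
        direct = []
        for q in spec.modes:
            acc = []
            for c in frames:
                u = c.radii / c.radii.mean() - 1.0
                coeff = np.sum(u * np.exp(-1j * q * ang)) / 16
                acc.append(np.abs(coeff) ** 2)
            direct.append(np.mean(acc))
        assert np.allclose(spec.msa, direct, rtol=1e-12, atol=1e-30)

    def test_generator_closure_within_3se(self):
        kappa = 20 * kbt()
        truth = sd.FlickerTruth(
            kappa=kappa, sigma=5 * kappa / (15e-6) ** 2, radius=15e-6,
            pixel_noise=0.0, seed=1,
        )
        spec = compute_spectrum(sd.gen_flicker_contours(truth))
        from photomem.flicker import L_MAX_FACTOR

        v = mode_variance(
            spec.modes, kappa, 5.0, l_max=L_MAX_FACTOR * int(spec.modes.max())
        )
        z = np.abs(spec.msa - v) / spec.msa_se
        assert np.all(z < 3.0)

    def test_too_few_frames(self):
        frames = make_frames(lambda ang: np.full_like(ang, 10e-6), 50)
        with pytest.raises(ValueError, match="too few"):
            compute_spectrum(frames)

    def test_inconsistent_lengths(self):
        frames = make_frames(lambda ang: np.full_like(ang, 10e-6), 100, 64)
        frames += make_frames(lambda ang: np.full_like(ang, 10e-6), 10, 128)
        with pytest.raises(ValueError, match="inconsistent"):
            compute_spectrum(frames)


class TestFitHelfrich:
    def test_self_consistent_recovery(self):
        kappa = 20 * kbt()
        est = []
        for seed in range(5):
            truth = sd.FlickerTruth(
                kappa=kappa, sigma=10 * kappa / (15e-6) ** 2, radius=15e-6,
                pixel_noise=0.0, seed=seed,
            )
            fit = fit_helfrich(compute_spectrum(sd.gen_flicker_contours(truth)))
            est.append(fit.kappa)
        assert abs(np.median(est) / kappa - 1) < 0.10

    def test_sigma_bar_recovery(self):
        kappa = 20 * kbt()
        truth = sd.FlickerTruth(
            kappa=kappa, sigma=10 * kappa / (15e-6) ** 2, radius=15e-6,
            pixel_noise=0.0, seed=0,
        )
        fit = fit_helfrich(compute_spectrum(sd.gen_flicker_contours(truth)))
        assert abs(fit.sigma_bar / 10.0 - 1) < 0.25
        # sigma follows from sigma_bar, kappa, R
        assert fit.sigma == pytest.approx(
            fit.sigma_bar * fit.kappa / truth.radius**2, rel=1e-12
        )

    def test_temperature_scaling_identity(self):
        # kappa enters only through kT/kappa: doubling T doubles fitted kappa
        kappa = 20 * kbt()
        truth = sd.FlickerTruth(
            kappa=kappa, sigma=5 * kappa / (15e-6) ** 2, radius=15e-6,
            pixel_noise=0.0, seed=2,
        )
        spec = compute_spectrum(sd.gen_flicker_contours(truth))
        f1 = fit_helfrich(spec, temperature=296.0)
        f2 = fit_helfrich(spec, temperature=592.0)
        assert f2.kappa == pytest.approx(2 * f1.kappa, rel=1e-6)
        assert f2.sigma_bar == pytest.approx(f1.sigma_bar, rel=1e-6)

    def test_qmax_beyond_spectrum(self):
        frames = make_frames(lambda ang: np.full_like(ang, 10e-6), 100)
        spec = compute_spectrum(frames)
        with pytest.raises(ValueError, match="q_max"):
            fit_helfrich(spec, q_max=1000)


class TestQCFilter:
    def make_fit(self, sigma, radius=15e-6, at_bound=False):
        from photomem.flicker import FlickerFit

        kappa = 20 * kbt()
        return (
            FlickerFit(
                kappa=kappa, sigma=sigma, sigma_bar=sigma * radius**2 / kappa,
                temperature=296.0, q_min=3, q_max=16, kappa_se=0.0, sigma_se=0.0,
                l_max=32, sigma_at_bound=at_bound,
            ),
            VesicleQC(mean_radius=radius, sigma=sigma),
        )

    def test_accept_in_range(self):
        fit, qc = self.make_fit(1e-8)
        assert qc_filter(fit, qc) == (True, "accept")

    def test_reject_radius(self):
        fit, qc = self.make_fit(1e-8, radius=30e-6)
        ok, reason = qc_filter(fit, qc)
        assert not ok and "radius" in reason

    def test_reject_tension(self):
        fit, qc = self.make_fit(1e-6)
        ok, reason = qc_filter(fit, qc)
        assert not ok and "tension" in reason

    def test_reject_defect(self):
        fit, qc = self.make_fit(1e-8)
        qc = VesicleQC(mean_radius=qc.mean_radius, sigma=qc.sigma, defect_flag=True)
        ok, reason = qc_filter(fit, qc)
        assert not ok and "defect" in reason

    def test_reject_pinned_tension_fit(self):
        fit, qc = self.make_fit(1e-8, at_bound=True)
        ok, reason = qc_filter(fit, qc)
        assert not ok and "bound" in reason
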