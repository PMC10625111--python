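"""Electrodeformation: prolate area formula, kinetics fits, ANOVA."""

import numpy as np
import pytest
from scipy.integrate import quad

from photomem import synthetic_data as sd
from photomem.electrodeform import (
    AspectRatioTrace,
    EllipsoidShape,
    OblateShapeError,
    anova_oneway,
    ellipsoid_area,
    fit_relaxation,
    relative_area_change,
    segment_epochs,
)


def prolate_area_quadrature(a, b):
    """Surface of revolution of the ellipse x=b sin t, z=a cos t about z."""

    def integrand(t):
        return (
            2.0
            * np.pi
            * b
            * np.sin(t)
            * np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        )

    val, _ = quad(integrand, 0.0, np.pi, epsabs=1e-22, epsrel=1e-13)
    return val


class TestEllipsoidArea:
    def test_sphere_limit(self):
        r = 7e-6
        assert ellipsoid_area(EllipsoidShape(r, r)) == pytest.approx(4 * np.pi * r**2)

    def test_worked_example(self):
        # a=10 um, b=5 um: eps = sqrt(3)/2, arcsin(eps) = pi/3, A ~ 537.0 um^2
        area = ellipsoid_area(EllipsoidShape(10e-6, 5e-6))
        assert area / 1e-12 == pytest.approx(537.0, abs=0.05)
        assert area == pytest.approx(prolate_area_quadrature(10e-6, 5e-6), rel=1e-9)

    @pytest.mark.parametrize("aspect", [1.001, 1.01, 1.1, 1.5, 2.0, 4.0, 10.0])
    def test_quadrature_oracle(self, aspect):
        b = 5e-6
        a = aspect * b
        assert ellipsoid_area(EllipsoidShape(a, b)) == pytest.approx(
            prolate_area_quadrature(a, b), rel=1e-9
        )

    def test_near_sphere_series_consistency(self):
        # a=10, b=9.99 um: to first order in the asphericity the area equals
        # that of a sphere of radius (a + 2b)/3
        a, b = 10e-6, 9.99e-6
        area = ellipsoid_area(EllipsoidShape(a, b))
        sphere = 4 * np.pi * ((a + 2 * b) / 3) ** 2
        assert abs(area - sphere) / sphere < 1e-4

    def test_continuity_at_series_cutoff(self):
        b = 10e-6
        eps = 1e-4  # cutoff eccentricity
        for scale in (0.999, 1.001):
            e = eps * scale
            a = b / np.sqrt(1 - e**2)
            assert ellipsoid_area(EllipsoidShape(a, b)) == pytest.approx(
                prolate_area_quadrature(a, b), rel=1e-12
            )

    def test_monotone_in_a(self):
        b = 5e-6
        areas = [
            ellipsoid_area(EllipsoidShape(a * 1e-6, b))
            for a in np.linspace(5.0001, 50, 40)
        ]
        assert np.all(np.diff(areas) > 0)

    def test_oblate_rejected_unless_allowed(self):
        with pytest.raises(OblateShapeError, match="oblate"):
            ellipsoid_area(EllipsoidShape(5e-6, 10e-6))
        # oblate formula against quadrature of the oblate surface
        a, b = 5e-6, 10e-6

        def integrand(t):
            return 2 * np.pi * b * np.sin(t) * np.sqrt(
                (b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2
            )

        ref, _ = quad(integrand, 0, np.pi, epsrel=1e-13)
        assert ellipsoid_area(EllipsoidShape(a, b), allow_oblate=True) == pytest.approx(
            ref, rel=1e-9
        )

    def test_invalid_axes(self):
        with pytest.raises(ValueError):
            EllipsoidShape(0.0, 1e-6)


class TestRelativeAreaChange:
    def test_no_change(self):
        assert relative_area_change(1e-10, 1e-10) == 0.0

    def test_twenty_percent(self):
        assert relative_area_change(100e-12, 120e-12) == pytest.approx(20.0)

    def test_shrinkage_negative(self):
        assert relative_area_change(100e-12, 90e-12) == pytest.approx(-10.0)

    def test_nonpositive_initial_area(self):
        with pytest.raises(ValueError):
            relative_area_change(0.0, 1e-12)

    def test_end_to_end_programmed_jump(self):
        """A programmed 15% area jump survives the shape->area->percent chain.

        Aspect ratios are mapped to prolate shapes at fixed volume; the UV
        plateau aspect is chosen (by root finding) so the true area gain is
        15%, then the pipeline must report it.
        """
        from scipy.optimize import brentq

        vol = 4 / 3 * np.pi * (10e-6) ** 3

        def shape(aspect):
            b = (3 * vol / (4 * np.pi * aspect)) ** (1 / 3)
            return EllipsoidShape(aspect * b, b)

        a_dark = 1.05
        area_dark = ellipsoid_area(shape(a_dark))
        target = 1.15 * area_dark
        a_uv = brentq(lambda x: ellipsoid_area(shape(x)) - target, 1.06, 5.0)
        measured = relative_area_change(area_dark, ellipsoid_area(shape(a_uv)))
        assert measured == pytest.approx(15.0, rel=1e-9)


class TestKinetics:
    def test_noiseless_exact(self):
        truth = sd.TraceTruth(tau=0.525, noise_sd=0.0)
        fit = fit_relaxation(sd.gen_trace(truth), "UV")
        assert fit.tau == pytest.approx(0.525, rel=1e-6)
        assert not fit.flat

    def test_blue_epoch_negative_amplitude(self):
        truth = sd.TraceTruth(tau=0.335, noise_sd=0.0)
        fit = fit_relaxation(sd.gen_trace(truth), "blue")
        assert fit.tau == pytest.approx(0.335, rel=1e-6)
        assert fit.amplitude < 0  # decay back toward the trans baseline

    def test_flat_trace_flagged(self):
        truth = sd.TraceTruth(amplitude=0.0, noise_sd=0.001, seed=7)
        fit = fit_relaxation(sd.gen_trace(truth), "UV")
        assert fit.flat

    def test_missing_epoch(self):
        truth = sd.TraceTruth(epoch_schedule=((0.0, "dark"), (2.0, "UV")))
        with pytest.raises(ValueError, match="not present"):
            fit_relaxation(sd.gen_trace(truth), "blue")

    def test_too_few_frames(self):
        truth = sd.TraceTruth(frame_rate=2.0, duration=9.0)  # UV epoch has 10 frames
        with pytest.raises(ValueError, match="frames"):
            fit_relaxation(sd.gen_trace(truth), "UV")


class TestSegmentEpochs:
    def test_constant_label(self):
        tr = AspectRatioTrace(
            times=np.arange(5.0), aspect=np.ones(5), illumination=np.array(["dark"] * 5)
        )
        assert segment_epochs(tr) == [("dark", 0.0, 4.0)]

    def test_schedule_closure(self):
        truth = sd.TraceTruth()
        epochs = segment_epochs(sd.gen_trace(truth))
        assert [e[0] for e in epochs] == ["dark", "UV", "blue"]
        assert epochs[1][1] == pytest.approx(2.0)
        assert epochs[2][1] == pytest.approx(7.0)

    def test_empty_trace(self):
        tr = AspectRatioTrace(
            times=np.array([]), aspect=np.array([]), illumination=np.array([])
        )
        assert segment_epochs(tr) == []


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == 0.0 and p == 1.0

    def test_separated_groups(self):
        f, p = anova_oneway([[1.0, 2.0, 3.0], [11.0, 12.0, 13.0]])
        assert f > 50 and p < 1e-3

    def test_hand_computed_oracle(self):
        # three groups, SS computed from the definition
        groups = [[6.0, 8.0, 4.0, 5.0], [8.0, 12.0, 9.0, 11.0], [13.0, 9.0, 11.0, 8.0]]
        flat = np.concatenate(groups)
        grand = flat.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(np.sum((np.array(g) - np.mean(g)) ** 2) for g in groups)
        f_hand = (ssb / 2) / (ssw / 9)
        f, p = anova_oneway(groups)
        assert f == pytest.approx(f_hand, rel=1e-12)
        assert 0 < p < 1

    def test_zero_within_variance_distinct_means(self):
        f, p = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(f) and p == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0]])
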