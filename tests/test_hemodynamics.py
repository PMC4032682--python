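"""Dimensionless-number computations and the 6-feature pattern assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avscreen.exceptions import (
    DegenerateLoopError,
    DomainError,
    IncompleteSubjectError,
)
from avscreen.hemodynamics import (
    AcousticConfig,
    CrossSection,
    DOSClass,
    FeaturePattern,
    FluidProperties,
    Site,
    build_feature_vector,
    classify_dos,
    critical_peak_reynolds,
    degree_of_stenosis,
    doppler_velocity,
    hydraulic_diameter,
    pressure_drop,
    resistive_index,
    reynolds,
    site_profile,
    strouhal,
    supra_ratios,
    supracritical_reynolds,
    womersley,
)

from conftest import make_measurement

WATER_LIKE = FluidProperties(density=1055.0, dynamic_viscosity_mu=0.0035)


class TestDopplerVelocity:
    def test_zero_shift_zero_velocity(self):
        assert doppler_velocity(0.0, AcousticConfig()) == 0.0

    def test_hand_evaluated_shift(self):
        cfg = AcousticConfig(sound_speed_c=1540.0, center_frequency_f0=7.5e6,
                             doppler_angle_theta=60.0)
        assert doppler_velocity(4870.0, cfg) == pytest.approx(0.99997, abs=1e-4)

    @given(st.floats(1.0, 2e4), st.floats(0.0, 80.0))
    def test_linearity_in_shift(self, f_d, theta):
        cfg = AcousticConfig(doppler_angle_theta=theta)
        assert doppler_velocity(2 * f_d, cfg) == pytest.approx(
            2 * doppler_velocity(f_d, cfg)
        )

    def test_angle_at_or_beyond_90_rejected(self):
        with pytest.raises(DomainError):
            AcousticConfig(doppler_angle_theta=90.0)


class TestResistiveIndex:
    @pytest.mark.parametrize(
        "vp, vm, expected",
        [
            (103.20, 37.00, 0.6415),  # Class I site A velocity means
            (25.61, 7.86, 0.6931),    # Class III site L velocity means
        ],
    )
    def test_printed_velocity_means(self, vp, vm, expected):
        assert resistive_index(vp, vm) == pytest.approx(expected, abs=1e-4)

    def test_equal_velocities_give_zero(self):
        assert resistive_index(50.0, 50.0) == 0.0

    def test_unit_free(self):
        assert resistive_index(103.20, 37.00) == pytest.approx(
            resistive_index(1.0320, 0.3700)
        )

    @given(
        st.floats(1e-3, 1e3),
        # V_m/V_p bounded away from 0 so the quotient stays below 1 in floats
        st.floats(1e-9, 1.0, exclude_max=True),
    )
    def test_bounded_in_unit_interval(self, vp, frac):
        vm = frac * vp
        res = resistive_index(vp, vm)
        assert 0.0 <= res < 1.0

    def test_swapped_inputs_rejected(self):
        with pytest.raises(DomainError):
            resistive_index(37.0, 103.2)
        with pytest.raises(DomainError):
            resistive_index(0.0, 0.0)


class TestPressureDrop:
    def test_zero(self):
        assert pressure_drop(0.0) == 0.0

    @pytest.mark.parametrize(
        "vp_m_s, dp", [(1.0320, 4.26), (0.7221, 2.09)]
    )
    def test_published_site_means(self, vp_m_s, dp):
        assert pressure_drop(vp_m_s) == pytest.approx(dp, abs=0.01)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            pressure_drop(-0.1)


class TestDimensionlessNumbers:
    def test_reynolds_hand_value(self):
        assert reynolds(1.0, 0.005, WATER_LIKE) == pytest.approx(1507.1, abs=0.1)

    def test_reynolds_linear_in_diameter(self):
        assert reynolds(1.0, 0.0025, WATER_LIKE) == pytest.approx(
            0.5 * reynolds(1.0, 0.005, WATER_LIKE)
        )

    def test_womersley_hand_value(self):
        assert womersley(0.005, 1.0, WATER_LIKE) == pytest.approx(3.44, abs=0.01)

    def test_womersley_unit_radius_inversion(self):
        # choosing D_H/2 = sqrt(nu / (2 pi f)) makes alpha exactly 1
        nu = WATER_LIKE.kinematic_viscosity
        f = 1.3
        d_h = 2.0 * math.sqrt(nu / (2 * math.pi * f))
        assert womersley(d_h, f, WATER_LIKE) == pytest.approx(1.0)

    @given(st.floats(1e-4, 0.05), st.floats(0.5, 3.0))
    def test_womersley_linear_in_diameter(self, d, f):
        a1 = womersley(d, f, WATER_LIKE)
        a2 = womersley(2 * d, f, WATER_LIKE)
        assert a2 == pytest.approx(2 * a1)

    def test_strouhal_identity_and_hand_value(self):
        assert strouhal(1.0, 1.0, 1.0) == 1.0
        assert strouhal(1.25, 0.005, 1.0) == pytest.approx(0.00625)

    def test_strouhal_doubles_when_velocity_halves(self):
        assert strouhal(1.0, 0.005, 0.5) == pytest.approx(
            2 * strouhal(1.0, 0.005, 1.0)
        )

    def test_nonpositive_inputs_rejected(self):
        for fn in (lambda: reynolds(0, 0.005, WATER_LIKE),
                   lambda: womersley(0.005, 0, WATER_LIKE),
                   lambda: strouhal(1.0, 0.005, 0)):
            with pytest.raises(DomainError):
                fn()


class TestCriticalPeakReynolds:
    def test_power_law_coefficient(self):
        assert critical_peak_reynolds(1.0, 1.0) == 169.0

    def test_hand_evaluated_point(self):
        assert critical_peak_reynolds(2.0, 0.5) == pytest.approx(362.3, abs=0.1)

    @given(st.floats(0.1, 10.0), st.floats(1e-3, 1.0), st.floats(1.01, 3.0))
    def test_monotone_decreasing_in_strouhal(self, alpha, st_num, factor):
        assert critical_peak_reynolds(alpha, st_num * factor) < critical_peak_reynolds(
            alpha, st_num
        )


class TestSupracriticalReynolds:
    def test_transition_point_and_absolute_value(self):
        assert supracritical_reynolds(169.0, 169.0) == 0.0
        assert supracritical_reynolds(1507.1, 169.0) == pytest.approx(1338.1)
        assert supracritical_reynolds(100.0, 169.0) == pytest.approx(69.0)


class TestHydraulicDiameter:
    def test_circle_and_square(self):
        circle = CrossSection(area_A=math.pi, perimeter_segments=[2 * math.pi])
        assert hydraulic_diameter(circle) == pytest.approx(2.0)
        square = CrossSection(area_A=1.0, perimeter_segments=[1.0] * 4)
        assert hydraulic_diameter(square) == pytest.approx(1.0)

    def test_inscribed_polygon_converges_to_circle_diameter(self):
        # regular n-gon inscribed in a unit-diameter circle: D_H = cos(pi/n)
        errors = []
        for n in (8, 16, 64):
            theta = math.pi / n
            area = 0.5 * n * 0.25 * math.sin(2 * theta)
            side = math.sin(theta)  # 2 * r * sin(theta), r = 1/2
            cs = CrossSection(area_A=area, perimeter_segments=[side] * n)
            d_h = hydraulic_diameter(cs)
            assert d_h == pytest.approx(math.cos(theta))
            errors.append(abs(d_h - 1.0))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1.5e-3

    def test_invalid_cross_sections_rejected(self):
        with pytest.raises(DomainError):
            CrossSection(area_A=1.0, perimeter_segments=[])
        with pytest.raises(DomainError):
            CrossSection(area_A=1.0, perimeter_segments=[1.0, -1.0])


class TestDegreeOfStenosis:
    def test_endpoints(self):
        assert degree_of_stenosis(5.0, 5.0) == 0.0
        assert degree_of_stenosis(0.0, 5.0) == 1.0

    def test_class_iii_threshold_diameter(self):
        assert degree_of_stenosis(5.0 / math.sqrt(2), 5.0) == pytest.approx(0.5)

    @given(st.floats(0.0, 1.0), st.floats(0.5, 50.0))
    def test_inverse_map_is_identity(self, dos, D):
        d = D * math.sqrt(1.0 - dos)
        assert degree_of_stenosis(d, D) == pytest.approx(dos, abs=1e-12)

    def test_lesion_wider_than_vessel_rejected(self):
        with pytest.raises(DomainError):
            degree_of_stenosis(6.0, 5.0)

    def test_class_bands(self):
        assert classify_dos(0.10) is DOSClass.I
        assert classify_dos(0.40) is DOSClass.II
        assert classify_dos(0.80) is DOSClass.III


class TestSupraRatios:
    def test_per_unit_normalisation(self):
        assert supra_ratios(7.0, 7.0, 7.0) == (1.0, 1.0, 1.0)
        r = supra_ratios(1338.1, 669.05, 1003.6)
        assert r[0] == pytest.approx(2.0)
        assert r[1] == 1.0
        assert r[2] == pytest.approx(1.5, abs=1e-4)

    @given(
        st.floats(0.0, 1e4),
        st.floats(1.0, 1e4),
        st.floats(0.0, 1e4),
        st.floats(1e-3, 1e3),
    )
    def test_loop_ratio_one_and_scale_invariance(self, a, l, v, scale):
        base = supra_ratios(a, l, v)
        scaled = supra_ratios(scale * a, scale * l, scale * v)
        assert base[1] == 1.0 and scaled[1] == 1.0
        assert scaled[0] == pytest.approx(base[0], rel=1e-9)
        assert scaled[2] == pytest.approx(base[2], rel=1e-9)

    def test_degenerate_loop_denominator(self):
        with pytest.raises(DegenerateLoopError):
            supra_ratios(100.0, 0.0, 100.0)


class TestFeatureVector:
    def test_identical_sites_collapse_to_unit_ratios(self, fluid):
        ms = [make_measurement(site=s) for s in Site]
        pat = build_feature_vector(ms, fluid)
        res = resistive_index(103.2, 37.0)
        assert np.allclose(pat.phi[:3], 1.0)
        assert np.allclose(pat.phi[3:], res)

    def test_published_class_i_site_means(self, fluid):
        ms = {
            Site.A: make_measurement(Site.A, V_p=103.20, V_m=37.00),
            Site.L: make_measurement(Site.L, V_p=64.60, V_m=28.83),
            Site.V: make_measurement(Site.V, V_p=82.56, V_m=35.43),
        }
        pat = build_feature_vector(ms, fluid)
        assert pat.phi[3:] == pytest.approx([0.6415, 0.5537, 0.5708], abs=1e-4)
        assert pat.phi[1] == 1.0

    def test_missing_site_rejected(self, fluid):
        with pytest.raises(IncompleteSubjectError):
            build_feature_vector([make_measurement(Site.A), make_measurement(Site.L)], fluid)

    def test_mixed_subjects_rejected(self, fluid):
        ms = [
            make_measurement(Site.A, subject_id="S1"),
            make_measurement(Site.L, subject_id="S2"),
            make_measurement(Site.V, subject_id="S1"),
        ]
        with pytest.raises(DomainError):
            build_feature_vector(ms, fluid)

    def test_site_profile_invariants(self, fluid):
        prof = site_profile(make_measurement(), fluid)
        assert prof.Re > 0 and prof.alpha > 0 and prof.St > 0
        assert prof.Re_peak > 0 and prof.Re_supra >= 0
        assert 0 <= prof.Res < 1 and prof.delta_P >= 0

    def test_pattern_validation(self):
        with pytest.raises(DomainError):
            FeaturePattern(phi=np.ones(5))
        with pytest.raises(DomainError):
            FeaturePattern(phi=np.array([1.0, 1.0, np.nan, 0.5, 0.5, 0.5]))
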