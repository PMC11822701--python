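import numpy as np
import pytest

from uvfield.errors import AxisProximityError, NearFieldError, ValidationError
from uvfield.sources import (DirectionalSource, LineSource, PointSource,
                             RelativeIntensityProfile, effective_segment,
                             hemisphere_profile_integral, i_max_from_power,
                             keitz_irradiance, keitz_power, line_field,
                             point_field, radiate_directional, radiate_line,
                             radiate_point)

from oracles import line_source_quadrature, random_line_config


# ---------------------------------------------------------------------------
# Directional
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("normal, expected_fr, expected_irr", [
    ((0, 0, 1), 10.0, 10.0),                      # normal incidence
    ((0, 0, -1), 0.0, 0.0),                       # back-facing: shadowed
    ((np.sin(np.pi / 3), 0, np.cos(np.pi / 3)), 10.0, 5.0),   # 60 deg incidence
])
def test_directional_cosine_law(normal, expected_fr, expected_irr):
    src = DirectionalSource(10.0, (0, 0, -1))
    fr, irr = radiate_directional(src, (0, 0, 0), np.asarray(normal, float))
    assert fr == pytest.approx(expected_fr, abs=1e-12)
    assert irr == pytest.approx(expected_irr, rel=1e-12, abs=1e-12)


def test_directional_grazing_counts_as_lit():
    """H(0) = 1: an element edge-on to the beam has full fluence rate."""
    src = DirectionalSource(10.0, (0, 0, -1))
    fr, irr = radiate_directional(src, (0, 0, 0), (1.0, 0.0, 0.0))
    assert fr == 10.0 and irr == 0.0


def test_directional_rejects_non_unit_normal():
    src = DirectionalSource(1.0, (0, 0, -1))
    with pytest.raises(ValidationError):
        radiate_directional(src, (0, 0, 0), (0, 0, 2))


# ---------------------------------------------------------------------------
# Relative intensity profiles
# ---------------------------------------------------------------------------

class TestProfile:
    def test_knot_values_exact_in_both_modes(self):
        for mode in ("linear", "closest"):
            prof = RelativeIntensityProfile([0, 30, 60, 90], [1.0, 0.9, 0.5, 0.1], mode)
            for a, v in zip([0, 30, 60, 90], [1.0, 0.9, 0.5, 0.1]):
                assert prof(a) == pytest.approx(v)

    def test_cosine_table_interpolates(self):
        prof = RelativeIntensityProfile.cosine(n_knots=91)
        assert prof(60.0) == pytest.approx(0.5, abs=1e-4)

    def test_beyond_last_knot_is_zero(self):
        prof = RelativeIntensityProfile([0, 45], [1.0, 0.5])
        assert prof(55.0) == 0.0

    def test_closest_mode_snaps(self):
        prof = RelativeIntensityProfile([0, 10, 20], [1.0, 0.6, 0.2], mode="closest")
        assert prof(4.9) == 1.0
        assert prof(5.1) == 0.6

    def test_negative_angle_rejected(self):
        prof = RelativeIntensityProfile.cosine()
        with pytest.raises(ValidationError):
            prof(-1.0)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValidationError):
            RelativeIntensityProfile([10, 20], [1.0, 0.5])       # no 0 knot
        with pytest.raises(ValidationError):
            RelativeIntensityProfile([0, 20], [0.5, 0.4])        # peak != 1


# ---------------------------------------------------------------------------
# Point source
# ---------------------------------------------------------------------------

class TestPointSource:
    def make(self, i_max=0.036):
        return PointSource.from_center_axis(
            i_max, RelativeIntensityProfile.cosine(), [0, 0, 0], [0, 0, 1])

    def test_on_axis_inverse_square(self):
        src = self.make(0.036)
        fr, irr = radiate_point(src, [0, 0, 0.1], [0, 0, -1])
        assert fr == pytest.approx(3.6, rel=1e-6)
        assert irr == pytest.approx(fr, rel=1e-12)

    def test_back_facing_is_dark(self):
        src = self.make()
        fr, irr = radiate_point(src, [0, 0, 0.1], [0, 0, 1])
        assert fr == 0.0 and irr == 0.0

    def test_oblique_hand_geometry(self):
        """60 deg off-axis at 0.2 m, normal aimed back at the source."""
        src = self.make(1.0)
        s = np.array([np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3)])
        point = 0.2 * s
        fr, irr = radiate_point(src, point, -s)
        expected = 1.0 * 0.5 / 0.04          # I_max f(60deg)=cos60 / d^2
        assert fr == pytest.approx(expected, rel=1e-4)
        assert irr == pytest.approx(fr, rel=1e-12)

    def test_inverse_square_doubling(self):
        src = self.make()
        fr1, _ = radiate_point(src, [0, 0, 0.05], [0, 0, -1])
        fr2, _ = radiate_point(src, [0, 0, 0.10], [0, 0, -1])
        assert fr2 == pytest.approx(fr1 / 4.0, rel=1e-12)

    def test_near_field_guard(self):
        src = self.make()
        with pytest.raises(NearFieldError):
            radiate_point(src, [0, 0, 1e-9], [0, 0, -1])

    def test_energy_conservation_on_enclosing_sphere(self):
        """Integrated irradiance over an enclosing sphere recovers the power.

        Detector elements on the sphere face the source, so irradiance equals
        fluence rate and the surface integral is int I_max f(theta) dOmega.
        """
        from scipy.special import roots_legendre
        i_max = 0.035
        src = self.make(i_max)
        radius = 0.7
        mu, w_mu = roots_legendre(200)          # nodes in cos(theta)
        phi = np.linspace(0.0, 2 * np.pi, 401)[:-1]
        w_phi = 2 * np.pi / 400
        total = 0.0
        for m, wm in zip(mu, w_mu):
            st = np.sqrt(1 - m**2)
            pts = radius * np.column_stack([st * np.cos(phi), st * np.sin(phi),
                                            np.full_like(phi, m)])
            normals = -pts / radius
            _, irr = point_field(src, pts, normals)
            total += wm * w_phi * np.sum(irr) * radius**2
        expected = i_max * hemisphere_profile_integral(src.profile)
        assert total == pytest.approx(expected, rel=1e-4)

    def test_i_max_from_power_cosine_closed_form(self):
        prof = RelativeIntensityProfile.cosine(n_knots=721)
        assert i_max_from_power(np.pi, prof) == pytest.approx(1.0, rel=1e-5)


# ---------------------------------------------------------------------------
# Line source
# ---------------------------------------------------------------------------

def lamp(power=1.0, length=0.129, center=(0, 0, 0.1), axis=(0, 1, 0)):
    return LineSource.from_center_axis(power, length, center, axis)


class TestEffectiveSegment:
    def test_full_span_below_lamp(self):
        seg = effective_segment(lamp(), [0, 0, 0], [0, 0, 1])
        assert seg.l_minus == pytest.approx(-0.0645)
        assert seg.l_plus == pytest.approx(0.0645)

    def test_plane_through_center_half_span(self):
        """Element plane contains the lamp center, normal along +axis."""
        seg = effective_segment(lamp(), [0.2, 0, 0.1], [0, 1, 0])
        assert seg.l_minus == pytest.approx(0.0, abs=1e-15)
        assert seg.l_plus == pytest.approx(0.0645)

    def test_lamp_fully_behind_plane(self):
        seg = effective_segment(lamp(), [0, 0, 0], [0, 0, -1])
        assert seg.empty
        fr, irr = radiate_line(lamp(), [0, 0, 0], [0, 0, -1])
        assert fr == 0.0 and irr == 0.0

    def test_on_axis_guard(self):
        with pytest.raises(AxisProximityError):
            effective_segment(lamp(), [0, 0.01, 0.1], [0, 0, 1])


class TestLineSource:
    def test_keitz_identity_at_symmetric_detector(self):
        src = lamp(power=2.0, center=(0, 0, 0))
        for d in (0.09, 0.25, 0.8):
            _, irr = radiate_line(src, [d, 0, 0], [-1, 0, 0])
            assert irr == pytest.approx(keitz_irradiance(2.0, d, 0.129), rel=1e-12)

    def test_far_field_inverse_square_limit(self):
        """At D = 100 L the Keitz form approaches P/(pi^2 D^2) within 0.01%."""
        L = 0.129
        d = 100 * L
        irr = keitz_irradiance(1.0, d, L)
        assert irr == pytest.approx(1.0 / (np.pi**2 * d**2), rel=1e-4)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(25):
            power, length, center, axis, point, normal = random_line_config(rng)
            src = LineSource.from_center_axis(power, length, center, axis)
            fr, irr = radiate_line(src, point, normal)
            fr_o, irr_o = line_source_quadrature(power, length, center, axis,
                                                 point, normal)
            assert fr == pytest.approx(fr_o, rel=1e-6, abs=1e-12)
            assert irr == pytest.approx(irr_o, rel=1e-6, abs=1e-12)

    def test_fluence_rate_bounds_irradiance(self, rng):
        for _ in range(50):
            power, length, center, axis, point, normal = random_line_config(rng)
            src = LineSource.from_center_axis(power, length, center, axis)
            fr, irr = radiate_line(src, point, normal)
            assert fr >= 0.0 and irr >= 0.0
            assert irr <= fr * (1 + 1e-12)

    def test_mirror_symmetry(self, rng):
        """Reflecting the whole configuration through a coordinate plane
        leaves fluence rate and irradiance unchanged."""
        for plane in range(3):
            mirror = np.ones(3)
            mirror[plane] = -1.0
            for _ in range(10):
                power, length, center, axis, point, normal = random_line_config(rng)
                src = LineSource.from_center_axis(power, length, center, axis)
                src_m = LineSource.from_center_axis(power, length,
                                                    center * mirror, axis * mirror)
                got = radiate_line(src, point, normal)
                got_m = radiate_line(src_m, point * mirror, normal * mirror)
                assert got[0] == pytest.approx(got_m[0], rel=1e-12, abs=1e-15)
                assert got[1] == pytest.approx(got_m[1], rel=1e-12, abs=1e-15)

    def test_point_source_mirror_symmetry(self, rng):
        mirror = np.array([1.0, -1.0, 1.0])
        prof = RelativeIntensityProfile.cosine()
        for _ in range(10):
            center = rng.normal(size=3)
            axis = rng.normal(size=3); axis /= np.linalg.norm(axis)
            point = center + rng.normal(size=3)
            normal = rng.normal(size=3); normal /= np.linalg.norm(normal)
            a = PointSource.from_center_axis(1.0, prof, center, axis)
            b = PointSource.from_center_axis(1.0, prof, center * mirror, axis * mirror)
            got = radiate_point(a, point, normal)
            got_m = radiate_point(b, point * mirror, normal * mirror)
            assert got[0] == pytest.approx(got_m[0], rel=1e-12, abs=1e-15)
            assert got[1] == pytest.approx(got_m[1], rel=1e-12, abs=1e-15)


class TestKeitzPower:
    def test_round_trip_through_line_model(self):
        src = lamp(power=1.0, center=(0, 0, 0), axis=(0, 1, 0))
        _, irr = radiate_line(src, [0.5, 0, 0], [-1, 0, 0])
        assert keitz_power(irr, 0.5, 0.129) == pytest.approx(1.0, rel=1e-10)

    def test_far_field_asymptotics(self):
        d, L = 50.0, 0.129
        e = keitz_irradiance(1.0, d, L)
        assert keitz_power(e, d, L) == pytest.approx(e * np.pi**2 * d**2, rel=1e-4)

    def test_constant_recovery_across_distance_sweep(self):
        """One fixed power generates exact readings at many distances; the
        inversion recovers the same power at every one of them."""
        L, P = 0.129, 1.6
        for d in np.linspace(0.09, 1.2, 12):
            e = keitz_irradiance(P, d, L)
            assert keitz_power(e, d, L) == pytest.approx(P, rel=1e-12)

    def test_rejects_non_positive_inputs(self):
        for bad in ((0.0, 1, 1), (1, 0.0, 1), (1, 1, 0.0)):
            with pytest.raises(ValidationError):
                keitz_power(*bad)
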