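"""Stomach lumen geometry and contraction-wave kinematics."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from gastrosim.geometry import (
    Centreline,
    CircleLumen,
    StomachGeometryParams,
    TubeLumen,
    WaveParameters,
    build_lumen,
)


class TestLumenConstruction:
    def test_boundary_is_closed_and_simple(self, stomach):
        poly = stomach.boundary_polyline(0.0)
        assert np.allclose(poly[0], poly[-1])
        assert Polygon(poly).is_valid

    def test_pyloric_sieve_width(self, static_stomach):
        # rest half-gap 1 mm -> 2 mm channel: only sub-2 mm particles pass
        assert static_stomach.radius(0.0, 0.0) == pytest.approx(1.0)

    def test_antrum_is_lowest_region(self, static_stomach):
        cl = static_stomach.centreline
        lowest = cl.points[np.argmin(cl.points[:, 1])]
        s_low = float(cl.s[np.argmin(cl.points[:, 1])])
        assert 0.0 < s_low < 55.0          # the low point lies in the antral band
        pyl = cl.points[np.argmin(np.abs(cl.s))]
        assert pyl[1] > lowest[1]          # pylorus above the settled contents

    def test_non_positive_radius_rejected(self):
        params = StomachGeometryParams(radius_knots=((-25.0, 2.5), (0.0, -1.0), (103.0, 3.0)))
        with pytest.raises(ValueError, match="radius"):
            build_lumen(params)

    def test_zero_amplitude_is_identity(self):
        lum = build_lumen(waves=WaveParameters(amplitude=0.0))
        s = np.linspace(-10, 100, 41)
        for t in (0.0, 7.3, 55.0):
            assert np.allclose(lum.radius(s, t), lum.radius(s, 0.0))
            assert np.allclose(lum.radius_rate(s, t), 0.0)


class TestWaves:
    def test_periodicity_in_time(self, stomach):
        s = np.linspace(0, 90, 91)
        for t in (0.0, 3.7, 12.2):
            np.testing.assert_allclose(
                stomach.radius(s, t), stomach.radius(s, t + 20.0), rtol=0, atol=1e-12
            )

    def test_crest_travels_at_wave_speed(self, stomach):
        s = np.linspace(15.0, 50.0, 3501)
        waves = stomach.waves
        # pick a time when a crest is inside the window
        t0 = (55.0 - 32.0) / waves.speed
        dt = 1.0
        c0 = s[np.argmin(stomach.radius(s, t0))]
        c1 = s[np.argmin(stomach.radius(s, t0 + dt))]
        assert c0 - c1 == pytest.approx(waves.speed * dt, rel=0.2)

    def test_full_occlusion_clamps_to_floor(self):
        lum = build_lumen(waves=WaveParameters(amplitude=1.0))
        waves = lum.waves
        # the amplitude ramp reaches ~1 only near the pylorus (terminal antral
        # contraction); even there the lumen cannot close below the floor gap
        t = (55.0 - 4.0) / waves.speed      # crest at s = 4
        s = np.linspace(2.0, 10.0, 1000)
        assert lum.radius(s, t).min() == pytest.approx(lum.r_floor)
        assert np.all(lum.radius(s, t) >= lum.r_floor)

    def test_hypomotility_shallower_occlusion_everywhere(self):
        deep = []
        for chi in (0.5, 1.0):
            lum = build_lumen(waves=WaveParameters(chi=chi))
            s = np.linspace(2.0, 53.0, 200)
            occ = np.zeros_like(s)
            for t in np.linspace(0.0, 20.0, 81):
                occ = np.maximum(occ, lum.waves.occlusion(s, t))
            deep.append(occ * lum.rest_radius(s))
        active = deep[1] > 1e-6
        assert active.any()
        assert np.all(deep[0][active] < deep[1][active])

    def test_at_most_two_concurrent_waves(self, stomach):
        for t in np.linspace(0, 40, 161):
            assert 1 <= len(stomach.waves.crest_positions(t)) <= 2


class TestSignedDistance:
    def test_interior_and_exterior_signs(self, stomach):
        pts = np.array([[15.0, 45.0], [40.0, 8.0], [70.0, 60.0], [0.0, 0.0]])
        phi = stomach.signed_distance(pts, 0.0)
        assert phi[0] < 0 and phi[1] < 0      # fundus centre, antrum centre
        assert phi[2] > 0 and phi[3] > 0      # outside the lumen

    def test_static_geometry_has_zero_wall_velocity(self, static_stomach):
        pts = np.array([[15.0, 45.0], [40.0, 8.0], [60.0, 12.0]])
        uw = static_stomach.wall_velocity(pts, 3.0)
        assert np.allclose(uw, 0.0)

    def test_circle_lumen_matches_analytic(self):
        lum = CircleLumen(centre=(5.0, 5.0), radius=8.0)
        th = np.linspace(0, 2 * np.pi, 50)
        for rr in (2.0, 7.5, 9.0):
            pts = np.column_stack([5 + rr * np.cos(th), 5 + rr * np.sin(th)])
            np.testing.assert_allclose(lum.signed_distance(pts, 0.0), rr - 8.0, atol=1e-12)

    def test_tube_sdf_matches_analytic_on_straight_channel(self):
        xs = np.linspace(0.0, 60.0, 200)
        pts_c = np.column_stack([xs, np.full_like(xs, 10.0)])
        cl = Centreline(points=pts_c, s=xs.copy(),
                        tangent=np.tile([1.0, 0.0], (len(xs), 1)),
                        normal=np.tile([0.0, 1.0], (len(xs), 1)))
        lum = TubeLumen(cl, np.array([0.0, 60.0]), np.array([5.0, 5.0]), None, r_floor=0.1)
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(5, 55, 100), rng.uniform(2, 18, 100)])
        phi = lum.signed_distance(pts, 0.0)
        exact = np.abs(pts[:, 1] - 10.0) - 5.0
        np.testing.assert_allclose(phi, exact, atol=0.05)   # < 1% of the radius


class TestArcCoordinate:
    def test_pyloric_plane_is_origin(self, static_stomach):
        cl = static_stomach.centreline
        pyl = cl.points[np.argmin(np.abs(cl.s))]
        s = static_stomach.arc_coordinate(pyl[None, :])
        assert abs(s[0]) < 0.5

    def test_known_centreline_separation(self, static_stomach):
        cl = static_stomach.centreline
        i, j = 40, 90
        s = static_stomach.arc_coordinate(np.vstack([cl.points[i], cl.points[j]]))
        assert abs(s[1] - s[0]) == pytest.approx(abs(cl.s[j] - cl.s[i]), abs=0.3)

    def test_monotone_along_centreline(self, static_stomach):
        cl = static_stomach.centreline
        s = static_stomach.arc_coordinate(cl.points[10:-10:5])
        assert np.all(np.diff(s) > 0)


class TestVolumeConsistency:
    def test_area_rate_matches_wall_flux(self, stomach):
        # d/dt (lumen area) computed geometrically == boundary velocity flux
        for t0 in (2.0, 9.5, 17.0):
            dt = 1e-4
            dadt = (stomach.lumen_area(t0 + dt) - stomach.lumen_area(t0 - dt)) / (2 * dt)
            flux = stomach.wall_flux(t0)
            assert dadt == pytest.approx(flux, rel=0.01, abs=1e-6)

    def test_contact_normal_includes_flank_tilt(self, stomach):
        # place a probe on the distal flank of an active constriction: the
        # inward normal acquires a component along the wave's direction of travel
        waves = stomach.waves
        t = (55.0 - 30.0) / waves.speed     # crest at s = 30
        cl = stomach.centreline
        s_probe = 20.0                       # distal (pyloric) flank of the crest
        i = np.argmin(np.abs(cl.s - s_probe))
        pt = cl.points[i] + 0.8 * stomach.radius(s_probe, t) * cl.normal[i]
        phi, n_in, _ = stomach.wall_contact_query(pt[None, :], t)
        # tangential projection: pushing toward decreasing s (the pylorus)
        assert float(n_in[0] @ cl.tangent[i]) < -0.05
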