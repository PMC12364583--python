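"""Hertzian spring-damper contacts: activation, symmetry, energy budget."""

import math

import numpy as np
import pytest

from gastrosim.contact import (
    ContactParameters,
    detect_contacts,
    contact_force,
    default_stiffness,
    substep_contacts,
)
from gastrosim.geometry import Centreline, TubeLumen
from gastrosim.particles import RigidParticle


def make_particle(i, x, v=(0.0, 0.0), r=2.0):
    return RigidParticle(id=i, r=r, x=np.array(x, float), v=np.array(v, float))


def floor_lumen(y_floor=0.0, half_width=50.0):
    """Straight horizontal tube whose lower wall acts as a floor at y_floor."""
    xs = np.linspace(-50.0, 150.0, 200)
    pts = np.column_stack([xs, np.full_like(xs, y_floor + half_width)])
    cl = Centreline(points=pts, s=xs.copy(),
                    tangent=np.tile([1.0, 0.0], (len(xs), 1)),
                    normal=np.tile([0.0, 1.0], (len(xs), 1)))
    return TubeLumen(cl, np.array([-50.0, 150.0]), np.array([half_width, half_width]),
                     None, r_floor=0.1)


class TestDetection:
    def test_gap_above_activation_yields_no_event(self):
        params = ContactParameters(g_act=0.1)
        parts = [make_particle(0, (0.0, 0.0)), make_particle(1, (4.3, 0.0))]  # gap 0.3
        assert detect_contacts(parts, None, 0.0, params) == []

    def test_initial_release_arrangement_is_contact_free(self):
        # eight particles with 0.2 mm surface gaps; springs must stay inactive
        from gastrosim.runner import initial_particle_positions
        from gastrosim.geometry import build_lumen

        lum = build_lumen()
        pos = initial_particle_positions(lum, 8, 4.0, 0.2)
        parts = [make_particle(i, p) for i, p in enumerate(pos)]
        params = ContactParameters(g_act=0.1)
        events = [e for e in detect_contacts(parts, None, 0.0, params) if e.body_b >= 0]
        assert events == []

    def test_wall_event_gap_from_plane_geometry(self):
        lum = floor_lumen()
        params = ContactParameters(g_act=0.1)
        p = make_particle(0, (50.0, 2.05))          # centre at r + 0.05 from the floor
        events = detect_contacts([p], lum, 0.0, params)
        assert len(events) == 1
        ev = events[0]
        assert ev.body_b == -1
        assert ev.gap == pytest.approx(0.05, abs=0.01)
        assert ev.normal[1] == pytest.approx(1.0, abs=1e-6)   # pushes up into the lumen


class TestForceLaw:
    def test_zero_force_at_activation_boundary(self):
        params = ContactParameters(g_act=0.1)
        parts = [make_particle(0, (0.0, 0.0)), make_particle(1, (4.1, 0.0))]
        events = detect_contacts(parts, None, 0.0, params)
        # gap == g_act exactly: not active (delta == 0 -> zero force)
        if events:
            contact_force(events[0], parts, params)
            np.testing.assert_allclose(events[0].f, 0.0, atol=1e-9)

    def test_head_on_collision_conserves_momentum(self):
        params = ContactParameters(k_n=1e4, gamma_n=2.0, g_act=0.1)
        parts = [make_particle(0, (0.0, 0.0), (30.0, 0.0)),
                 make_particle(1, (4.15, 0.0), (-30.0, 0.0))]
        p_before = sum(p.mass * p.v[0] for p in parts)
        for _ in range(200):
            substep_contacts(parts, None, 0.0, 1e-4, params,
                             accel=np.zeros((2, 2)))
        p_after = sum(p.mass * p.v[0] for p in parts)
        assert p_after == pytest.approx(p_before, abs=1e-12)
        assert parts[0].v[0] < 0 < parts[1].v[0]     # they bounced

    def test_elastic_wall_bounce_conserves_energy(self):
        # gamma_n = 0: kinetic energy before == after within 2%
        lum = floor_lumen()
        p = make_particle(0, (50.0, 2.5), (0.0, -40.0))
        params = ContactParameters(k_n=default_stiffness(p.mass), gamma_n=0.0, g_act=0.1)
        ke0 = 0.5 * p.mass * p.v[1] ** 2
        for _ in range(400):
            substep_contacts([p], lum, 0.0, 1e-4, params, accel=np.zeros((1, 2)))
            if p.v[1] > 0 and p.x[1] > 2.5:
                break
        ke1 = 0.5 * p.mass * p.v[1] ** 2
        assert ke1 == pytest.approx(ke0, rel=0.02)

    def test_damped_collision_dissipates_energy(self):
        lum = floor_lumen()
        p = make_particle(0, (50.0, 2.5), (0.0, -40.0))
        params = ContactParameters(k_n=default_stiffness(p.mass), gamma_n=3.0, g_act=0.1)
        ke0 = 0.5 * p.mass * p.v[1] ** 2
        for _ in range(400):
            substep_contacts([p], lum, 0.0, 1e-4, params, accel=np.zeros((1, 2)))
            if p.v[1] > 0 and p.x[1] > 2.5:
                break
        ke1 = 0.5 * p.mass * p.v[1] ** 2
        assert ke1 < ke0

    def test_restitution_decreases_with_damping(self):
        lum = floor_lumen()
        es = []
        for gamma in (0.0, 2.0, 5.0, 10.0):
            p = make_particle(0, (50.0, 2.5), (0.0, -40.0))
            params = ContactParameters(k_n=default_stiffness(p.mass), gamma_n=gamma,
                                       g_act=0.1)
            for _ in range(400):
                substep_contacts([p], lumen=lum, t=0.0, dt_fluid=1e-4, params=params,
                                 accel=np.zeros((1, 2)))
                if p.v[1] > 0 and p.x[1] > 2.5:
                    break
            es.append(p.v[1] / 40.0)
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_repulsion_only_no_adhesion(self):
        # separating bodies inside the activation zone: the dashpot pull is
        # clipped at zero
        params = ContactParameters(k_n=10.0, gamma_n=100.0, g_act=0.1)
        parts = [make_particle(0, (0.0, 0.0), (-50.0, 0.0)),
                 make_particle(1, (4.05, 0.0), (50.0, 0.0))]
        events = detect_contacts(parts, None, 0.0, params)
        contact_force(events[0], parts, params)
        assert float(events[0].f @ events[0].normal) >= 0.0


class TestSubstepping:
    def test_no_contacts_reduces_to_frozen_acceleration(self):
        p = make_particle(0, (0.0, 50.0))
        accel = np.array([[0.0, -9810.0]])
        substep_contacts([p], None, 0.0, 2e-3, ContactParameters(), accel=accel)
        assert p.v[1] == pytest.approx(-9810.0 * 2e-3, rel=1e-9)

    def test_stack_settles_to_static_equilibrium(self):
        # two discs on a floor under gravity: spring force balances net weight
        lum = floor_lumen()
        g = 9810.0
        p0 = make_particle(0, (50.0, 2.0))
        p1 = make_particle(1, (50.0, 6.05))
        params = ContactParameters(k_n=default_stiffness(p0.mass), gamma_n=8.0, g_act=0.1)
        accel = np.array([[0.0, -g], [0.0, -g]])
        for _ in range(4000):
            substep_contacts([p0, p1], lum, 0.0, 5e-4, params, accel=accel)
        assert abs(p0.v[1]) < 0.5 and abs(p1.v[1]) < 0.5
        # bottom contact supports both weights
        delta = params.g_act - (p0.x[1] - p0.r)
        f_spring = params.k_n * max(delta, 0.0) ** 1.5
        assert f_spring == pytest.approx((p0.mass + p1.mass) * g, rel=0.1)

    def test_substep_count_guard(self):
        p = make_particle(0, (0.0, 0.0))
        params = ContactParameters(k_n=1e12, gamma_n=0.0)
        with pytest.raises(RuntimeError, match="sub-step"):
            substep_contacts([p], None, 0.0, 1.0, params, accel=np.zeros((1, 2)),
                             max_substeps=100)
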