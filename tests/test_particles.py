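"""Rigid-body loads and integration: buoyancy, traction probes, settling."""

import math

import numpy as np
import pytest

from gastrosim.fluid import BoundarySpec, CartesianGrid, FluidProperties, FluidSolver
from gastrosim.particles import (
    RigidParticle,
    hydrodynamic_loads,
    hydrodynamic_loads_many,
    integrate_body,
)

RHO_F = 1.0e-3
G = 9810.0


def make_solver(n=64, h=0.5, mu=1e-3):
    grid = CartesianGrid(n, n, h, (0.0, 0.0))
    return FluidSolver(grid, FluidProperties(rho=RHO_F, mu=mu), BoundarySpec())


class TestHydrodynamicLoads:
    def test_uniform_pressure_gives_no_force(self):
        sol = make_solver()
        st = sol.initial_state()
        st.p[:] = 37.0
        p = RigidParticle(id=0, r=2.0, x=np.array([16.0, 16.0]))
        ld = hydrodynamic_loads(sol, st, p)
        np.testing.assert_allclose(ld.f_pressure, 0.0, atol=1e-10)
        assert ld.p_mean == pytest.approx(37.0)
        assert ld.tau_mean == 0.0

    def test_hydrostatic_field_recovers_archimedes(self):
        # p = rho g . x  ->  F_pressure = -rho A g (upward) within 2%
        sol = make_solver()
        g = sol.grid
        y = (np.arange(g.ny) + 0.5) * g.h
        st = sol.initial_state()
        st.p[:, :] = RHO_F * G * (g.ny * g.h - y)[None, :]
        p = RigidParticle(id=0, r=2.0, x=np.array([16.0, 16.0]))
        ld = hydrodynamic_loads(sol, st, p)
        expected = RHO_F * p.area * G
        assert ld.f_pressure[1] == pytest.approx(expected, rel=0.02)
        assert abs(ld.f_pressure[0]) < 0.02 * expected

    def test_linear_shear_traction_scale_and_moment_symmetry(self):
        # imposed u = gdot*y: tangential traction ~ mu gdot, and the moment of
        # a symmetric stress field vanishes by symmetry
        gdot = 10.0
        mu = 5e-3
        sol = make_solver(mu=mu)
        g = sol.grid
        st = sol.initial_state()
        yu = g.u_points()[:, 1].reshape(g.nx + 1, g.ny)
        st.u = gdot * yu
        p = RigidParticle(id=0, r=2.0, x=np.array([16.0, 16.0]))
        ld = hydrodynamic_loads(sol, st, p)
        assert 0.3 * mu * gdot < ld.tau_mean < 3.0 * mu * gdot
        assert abs(ld.moment) < 0.05 * ld.tau_mean * 2 * math.pi * p.r**2

    def test_decomposition_is_exact(self):
        sol = make_solver()
        st = sol.initial_state()
        rng = np.random.default_rng(5)
        st.p = rng.normal(size=st.p.shape)
        st.u = rng.normal(size=st.u.shape)
        st.v = rng.normal(size=st.v.shape)
        p = RigidParticle(id=0, r=2.0, x=np.array([16.0, 16.0]))
        ld = hydrodynamic_loads(sol, st, p)
        np.testing.assert_array_equal(ld.f_total, ld.f_pressure + ld.f_shear)

    def test_batched_loads_match_single(self):
        sol = make_solver()
        st = sol.initial_state()
        rng = np.random.default_rng(9)
        st.p = rng.normal(size=st.p.shape)
        st.u = rng.normal(size=st.u.shape)
        st.v = rng.normal(size=st.v.shape)
        parts = [RigidParticle(id=i, r=2.0, x=np.array([10.0 + 6 * i, 16.0]))
                 for i in range(3)]
        many = hydrodynamic_loads_many(sol, st, parts)
        for p, ld in zip(parts, many):
            ref = hydrodynamic_loads(sol, st, p)
            np.testing.assert_allclose(ld.f_total, ref.f_total, rtol=1e-12)
            assert ld.tau_mean == pytest.approx(ref.tau_mean)


class TestBodyDynamics:
    def test_ballistic_free_flight(self):
        p = RigidParticle(id=0, r=2.0, x=np.array([0.0, 100.0]))
        dt = 1e-3
        w = p.mass * np.array([0.0, -G])
        for _ in range(1000):
            integrate_body(p, w, 0.0, dt)
        assert p.v[1] == pytest.approx(-G * 1.0, rel=1e-9)
        # symplectic Euler lands within one step-size of the continuous fall
        assert p.x[1] == pytest.approx(100.0 - 0.5 * G, rel=5e-3)

    def test_net_vertical_force_at_rest(self):
        # (rho_s - rho) A g downward, within 3%
        p = RigidParticle(id=0, r=2.0, rho_s=1.1e-3)
        w = p.net_weight(RHO_F, (0.0, -G))
        expected = -(1.1e-3 - 1.0e-3) * p.area * G
        assert w[1] == pytest.approx(expected, rel=0.03)
        assert w[0] == 0.0

    def test_virtual_mass_changes_transient_not_weight(self):
        p1 = RigidParticle(id=0, r=2.0)
        p2 = RigidParticle(id=1, r=2.0)
        f = np.array([1.0, 0.0])
        integrate_body(p1, f, 0.0, 1e-3, m_virtual=0.0)
        integrate_body(p2, f, 0.0, 1e-3, m_virtual=0.5 * RHO_F * p2.area)
        assert abs(p2.v[0]) < abs(p1.v[0])

    def test_nan_force_aborts_with_particle_id(self):
        p = RigidParticle(id=4, r=2.0)
        with pytest.raises(FloatingPointError, match="particle 4"):
            integrate_body(p, np.array([np.nan, 0.0]), 0.0, 1e-3)


class TestSettling:
    def test_terminal_velocity_matches_drag_oracle(self, falling_particle):
        m = falling_particle.metrics
        assert not m["invalid"]
        assert m["rel_err"] <= 0.10

    def test_free_particle_settles_within_one_second(self, falling_particle):
        # rho_s > rho: strictly negative mean vertical velocity develops
        assert falling_particle.metrics["v_sim"] > 0.0   # v_sim is the settling speed

    def test_trajectory_self_convergence_in_dt(self):
        # halving dt shrinks the displacement difference of a short coupled fall
        from gastrosim.contact import ContactParameters
        from gastrosim.coupling import CoupledSimulation

        def final_y(dt):
            grid = CartesianGrid(64, 80, 0.5, (0.0, 0.0))
            sol = FluidSolver(grid, FluidProperties(rho=RHO_F, mu=5e-3), BoundarySpec())
            p = RigidParticle(id=0, r=2.0, rho_s=1.1e-3, x=np.array([16.0, 32.0]))
            sim = CoupledSimulation(sol, None, [p], ContactParameters())
            while sim.state.t < 0.2 - 1e-12:
                sim.step(dt=dt)
            return p.x[1]

        y1, y2, y4 = final_y(2e-3), final_y(1e-3), final_y(5e-4)
        assert abs(y2 - y4) < abs(y1 - y2)


class TestMomentumExchange:
    def test_impulsively_started_particle_momentum_bookkeeping(self):
        # closed box, no gravity: the fluid's momentum changes only by the
        # immersed-boundary forcing injection plus the wall pressure impulse,
        # within 5% of the particle momentum scale (momentum-exchange sanity)
        from gastrosim.contact import ContactParameters
        from gastrosim.coupling import CoupledSimulation

        grid = CartesianGrid(72, 72, 0.5, (0.0, 0.0))
        sol = FluidSolver(grid, FluidProperties(rho=RHO_F, mu=1e-3), BoundarySpec())
        p = RigidParticle(id=0, r=2.0, rho_s=1.1e-3, x=np.array([18.0, 18.0]),
                          v=np.array([30.0, 0.0]))
        sim = CoupledSimulation(sol, None, [p], ContactParameters(), gravity=(0.0, 0.0))
        h = grid.h

        def fluid_px():
            return RHO_F * np.sum(sim.state.u[1:-1, :]) * h * h

        p0 = fluid_px()
        impulse = 0.0
        for _ in range(40):
            rec = sim.step(dt=5e-4)
            pr = sim.state.p
            impulse += rec.dt * (np.sum(pr[0, :]) - np.sum(pr[-1, :])) * h
            impulse += sim.state.forcing_impulse[0]
        dp = fluid_px() - p0
        scale = abs(p.mass * 30.0)
        assert abs(dp - impulse) < 0.05 * scale
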