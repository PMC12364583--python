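"""Fractional-step solver: predictor, immersed-boundary forcing, projection."""

import math

import numpy as np
import pytest

from gastrosim.fluid import (
    BoundarySpec,
    CartesianGrid,
    CFLError,
    FluidProperties,
    FluidSolver,
)


def make_solver(n=32, h=0.5, mu=1e-3, g=(0.0, 0.0), bc=None, **kw):
    grid = CartesianGrid(n, n, h, (0.0, 0.0))
    return FluidSolver(grid, FluidProperties(rho=1e-3, mu=mu, g=g), bc or BoundarySpec(), **kw)


class TestPredictor:
    def test_uniform_flow_is_invariant(self):
        # advection and diffusion vanish for a uniform field (periodic box)
        sol = make_solver(bc=BoundarySpec(periodic_x=True, periodic_y=True))
        st = sol.initial_state()
        st.u[:] = 3.0
        st.v[:] = -1.5
        ustar, vstar, _, _ = sol.predict_velocity(st, 1e-4)
        np.testing.assert_allclose(ustar, 3.0, atol=1e-13)
        np.testing.assert_allclose(vstar, -1.5, atol=1e-13)

    def test_quiescent_gravity_gives_dt_g(self):
        g = (2.0, -9810.0)
        sol = make_solver(g=g)
        st = sol.initial_state()
        dt = 5e-4
        ustar, vstar, _, _ = sol.predict_velocity(st, dt)
        np.testing.assert_allclose(ustar, dt * g[0], atol=1e-15)
        np.testing.assert_allclose(vstar, dt * g[1], atol=1e-12)

    def test_cfl_violation_reports_cell(self):
        sol = make_solver()
        st = sol.initial_state()
        st.u[5, 7] = 1e4
        with pytest.raises(CFLError, match=r"\(5, 7\)"):
            sol.predict_velocity(st, 1e-3)

    def test_diffusion_limit_enforced(self):
        sol = make_solver(mu=0.1)
        st = sol.initial_state()
        with pytest.raises(CFLError, match="diffusion"):
            sol.predict_velocity(st, 1.0)


class TestProjection:
    def test_divergence_free_input_unchanged(self):
        # discrete solenoidal field from a random stream function
        sol = make_solver()
        g = sol.grid
        rng = np.random.default_rng(3)
        psi = rng.normal(size=(g.nx + 1, g.ny + 1))
        psi[0, :] = psi[-1, :] = psi[:, 0] = psi[:, -1] = 0.0   # wall streamline
        u = np.zeros((g.nx + 1, g.ny))
        v = np.zeros((g.nx, g.ny + 1))
        u[:, :] = (psi[:, 1:] - psi[:, :-1]) / g.h
        v[:, :] = -(psi[1:, :] - psi[:-1, :]) / g.h
        sol.apply_velocity_bc(u, v)
        p, u2, v2 = sol.pressure_projection(u.copy(), v.copy(), 1e-3)
        np.testing.assert_allclose(u2, u, atol=1e-9)
        np.testing.assert_allclose(p - p.mean(), 0.0, atol=1e-9)

    def test_gradient_field_projects_to_zero(self):
        # u* = grad(phi) with wall-compatible phi is annihilated exactly
        sol = make_solver()
        g = sol.grid
        L = g.nx * g.h
        x = (np.arange(g.nx) + 0.5) * g.h
        y = (np.arange(g.ny) + 0.5) * g.h
        phi = np.cos(np.pi * x[:, None] / L) * np.cos(np.pi * y[None, :] / L)
        u = np.zeros((g.nx + 1, g.ny))
        v = np.zeros((g.nx, g.ny + 1))
        u[1:-1, :] = (phi[1:, :] - phi[:-1, :]) / g.h
        v[:, 1:-1] = (phi[:, 1:] - phi[:, :-1]) / g.h
        _, u2, v2 = sol.pressure_projection(u, v, 1e-3)
        assert np.abs(u2).max() < 1e-10
        assert np.abs(v2).max() < 1e-10

    def test_post_projection_divergence_below_tolerance(self):
        sol = make_solver()
        st = sol.initial_state()
        rng = np.random.default_rng(11)
        st.u += 10.0 * rng.normal(size=st.u.shape)
        st.v += 10.0 * rng.normal(size=st.v.shape)
        sol.apply_velocity_bc(st.u, st.v)
        st = sol.step(st, dt=1e-5)
        assert np.abs(sol.divergence(st.u, st.v)).max() < sol.div_tol


class TestHydrostatics:
    def test_quiescent_fluid_with_gravity_stays_at_rest(self):
        sol = make_solver(g=(0.0, -9810.0))
        st = sol.initial_state()
        for _ in range(20):
            st = sol.step(st, dt=1e-3)
        assert st.max_speed() < 1e-10
        # pressure gradient balances rho g
        g = sol.grid
        dpdy = (st.p[:, 1:] - st.p[:, :-1]) / g.h
        np.testing.assert_allclose(dpdy, sol.props.rho * -9810.0, rtol=1e-8)


class TestImmersedBoundary:
    def test_static_wall_keeps_quiescent_fluid_at_rest(self):
        sol = make_solver()
        st = sol.initial_state()

        def forcing(t):
            au = np.zeros(st.u.shape)
            av = np.zeros(st.v.shape)
            au[:10, :] = 1.0
            av[:10, :] = 1.0
            return au, av, np.zeros(st.u.shape), np.zeros(st.v.shape)

        st = sol.step(st, dt=1e-3, forcing=forcing)
        assert st.max_speed() == 0.0

    def test_cell_inside_translating_particle_takes_particle_velocity(self):
        sol = make_solver()
        st = sol.initial_state()
        vp = (7.0, 0.0)

        def forcing(t):
            au = np.zeros(st.u.shape)
            av = np.zeros(st.v.shape)
            au[14:18, 14:18] = 1.0
            return au, av, np.full(st.u.shape, vp[0]), np.zeros(st.v.shape)

        ustar = np.zeros(st.u.shape)
        ustar2, _ = sol.apply_immersed_boundaries(
            ustar, np.zeros(st.v.shape), *forcing(0.0)[:2], np.full(st.u.shape, vp[0]),
            np.zeros(st.v.shape),
        )
        np.testing.assert_allclose(ustar2[15, 15], vp[0])

    def test_rotating_disc_drives_rigid_rotation(self):
        # steady state inside a spinning disc: azimuthal speed = omega r
        from gastrosim.particles import RigidParticle

        sol = make_solver(n=48, mu=5e-3)
        g = sol.grid
        centre = np.array([12.0, 12.0])
        omega = 3.0
        disc = RigidParticle(id=0, r=5.0, x=centre)
        up = g.u_points()
        vp_pts = g.v_points()
        phi_u = disc.signed_distance(up).reshape(g.nx + 1, g.ny)
        phi_v = disc.signed_distance(vp_pts).reshape(g.nx, g.ny + 1)
        au = np.clip(0.5 + phi_u / g.h, 0, 1)
        av = np.clip(0.5 + phi_v / g.h, 0, 1)
        tu = (-omega * (up[:, 1] - centre[1])).reshape(g.nx + 1, g.ny)
        tv = (omega * (vp_pts[:, 0] - centre[0])).reshape(g.nx, g.ny + 1)

        st = sol.initial_state()
        for _ in range(300):
            st = sol.step(st, dt=5e-4, forcing=lambda t: (au, av, tu, tv))
        probe = centre + np.array([2.5, 0.0])      # r/2, well inside the disc
        vel = sol.sample_velocity(st.u, st.v, probe[None, :])[0]
        assert vel[1] == pytest.approx(omega * 2.5, rel=0.05)
        assert abs(vel[0]) < 0.05 * omega * 2.5


class TestAnalyticFlows:
    def test_taylor_green_decay_and_divergence(self, analytic_suite):
        res = analytic_suite["taylor_green_decay"]
        assert res.metrics["rel_err"] < 0.02
        assert res.metrics["max_div"] < 1e-8

    def test_taylor_green_spatial_order(self, analytic_suite):
        assert analytic_suite["taylor_green_order"].metrics["order"] >= 1.8

    def test_poiseuille_profile(self, analytic_suite):
        assert analytic_suite["poiseuille"].metrics["max_rel_err"] < 0.02

    def test_peristaltic_channel_pumps_in_wave_direction(self, analytic_suite):
        assert analytic_suite["peristaltic_channel"].metrics["in_wave_direction"]

    def test_closed_lumen_mass_balance(self, analytic_suite):
        m = analytic_suite["closed_lumen_mass_balance"].metrics
        assert m["max_div"] < 1e-6
        assert m["wall_flux_ratio"] < 0.01
        assert m["u_max"] > 1.0       # the wall actually drives a flow
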