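"""Rigid food particles: 2D discs with three degrees of freedom.

Each particle obeys

    m  dv/dt = F_f + F_c + W,      I dw/dt = M_f + M_c,

where F_f and M_f are the hydrodynamic force and moment obtained by
integrating pressure and viscous traction over the disc surface, F_c and M_c
come from the contact model, and W = (m - rho_f A) g is the net weight
(weight minus buoyancy; the fluid is solved in dynamic pressure, so the
hydrostatic part of the load is applied analytically).

All particle quantities are per unit depth (mass g/mm, force uN/mm); a
nominal depth converts them to 3D-equivalent values at output time.  Disc
inertia is I = m r^2 / 2.  A virtual-mass term C_vm rho_f A can be added to
the translational inertia to stabilise the loose fluid-structure coupling at
density ratio ~1.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gastrosim.fluid import FluidSolver, FlowState, bilinear_sample

__all__ = ["RigidParticle", "ParticleLoads", "hydrodynamic_loads", "integrate_body"]


try:  # fast path for the per-step probe sampling in coupled runs
    from numba import njit as _njit

    @_njit(fastmath=True)
    def _probe_fields(p, uc, vc, h, x0, y0, pts):  # pragma: no cover
        """Sample p and the velocity-gradient tensor at probe points.

        ``uc``/``vc`` are cell-centred velocities; gradients are central
        differences evaluated on the fly (indices clamped at the edges).
        """
        n = pts.shape[0]
        nx, ny = p.shape
        out = np.empty((5, n))
        inv2h = 0.5 / h
        for k in range(n):
            fx = (pts[k, 0] - x0) / h
            fy = (pts[k, 1] - y0) / h
            i = int(fx)
            j = int(fy)
            if i < 1:
                i = 1
            if i > nx - 3:
                i = nx - 3
            if j < 1:
                j = 1
            if j > ny - 3:
                j = ny - 3
            wx = fx - i
            wy = fy - j
            w00 = (1 - wx) * (1 - wy)
            w10 = wx * (1 - wy)
            w01 = (1 - wx) * wy
            w11 = wx * wy
            out[0, k] = (p[i, j] * w00 + p[i + 1, j] * w10
                         + p[i, j + 1] * w01 + p[i + 1, j + 1] * w11)
            for q in range(4):
                if q == 0:
                    f = uc
                    dx = True
                elif q == 1:
                    f = uc
                    dx = False
                elif q == 2:
                    f = vc
                    dx = True
                else:
                    f = vc
                    dx = False
                if dx:
                    g00 = (f[i + 1, j] - f[i - 1, j]) * inv2h
                    g10 = (f[i + 2, j] - f[i, j]) * inv2h
                    g01 = (f[i + 1, j + 1] - f[i - 1, j + 1]) * inv2h
                    g11 = (f[i + 2, j + 1] - f[i, j + 1]) * inv2h
                else:
                    g00 = (f[i, j + 1] - f[i, j - 1]) * inv2h
                    g10 = (f[i + 1, j + 1] - f[i + 1, j - 1]) * inv2h
                    g01 = (f[i, j + 2] - f[i, j]) * inv2h
                    g11 = (f[i + 1, j + 2] - f[i + 1, j]) * inv2h
                out[1 + q, k] = g00 * w00 + g10 * w10 + g01 * w01 + g11 * w11
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class RigidParticle:
    """One food particle (disc).  Lengths mm, velocities mm/s, mass g/mm."""

    id: int
    r: float = 2.0
    rho_s: float = 1.1e-3          # g/mm^3 (1.1 g/cm^3)
    x: np.ndarray = field(default_factory=lambda: np.zeros(2))
    v: np.ndarray = field(default_factory=lambda: np.zeros(2))
    omega: float = 0.0
    theta: float = 0.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("particle radius must be positive")
        self.x = np.asarray(self.x, dtype=float).copy()
        self.v = np.asarray(self.v, dtype=float).copy()

    @property
    def area(self) -> float:
        """Disc measure (mm^2); times depth gives the 3D volume."""
        return math.pi * self.r**2

    @property
    def mass(self) -> float:
        return self.rho_s * self.area

    @property
    def inertia(self) -> float:
        return 0.5 * self.mass * self.r**2

    def net_weight(self, rho_fluid: float, g: tuple[float, float]) -> np.ndarray:
        """(m - rho_f A) g : gravity net of buoyancy, per unit depth."""
        return (self.mass - rho_fluid * self.area) * np.asarray(g, dtype=float)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Positive inside the disc (solid), negative in the fluid."""
        rel = np.atleast_2d(pts) - self.x
        return self.r - np.sqrt(rel[:, 0] ** 2 + rel[:, 1] ** 2)

    def solid_velocity(self, pts: np.ndarray) -> np.ndarray:
        """Rigid-body velocity v + w x r at the given points."""
        rel = np.atleast_2d(pts) - self.x
        return self.v + self.omega * np.column_stack([-rel[:, 1], rel[:, 0]])

    def copy(self) -> "RigidParticle":
        return RigidParticle(
            id=self.id, r=self.r, rho_s=self.rho_s,
            x=self.x.copy(), v=self.v.copy(), omega=self.omega, theta=self.theta,
        )


@dataclass(frozen=True)
class ParticleLoads:
    """Hydrodynamic loads on one particle (per unit depth)."""

    f_pressure: np.ndarray   # -closed-surface integral of p n  (uN/mm)
    f_shear: np.ndarray      # integral of viscous traction     (uN/mm)
    moment: float            # about the centre (uN mm / mm)
    p_mean: float            # surface-mean pressure (Pa, gauge = outlet)
    tau_mean: float          # surface-mean |tangential traction| (Pa)

    @property
    def f_total(self) -> np.ndarray:
        """Total hydrodynamic force; pressure + shear parts sum exactly."""
        return self.f_pressure + self.f_shear


def hydrodynamic_loads(
    solver: FluidSolver,
    state: FlowState,
    particle: RigidParticle,
    n_probes: int | None = None,
    grad_offset: float | None = None,
    grads: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> ParticleLoads:
    """Integrate pressure and viscous traction over the disc surface.

    Pressure and the cell-centred velocity gradients are interpolated
    bilinearly at M equispaced probes on two rings just outside the smeared
    interface (offsets ``grad_offset`` and 2x, default h) and linearly
    extrapolated to the surface, where the raw fields are contaminated by the
    interior forcing.  The viscous traction is mu (grad u + grad u^T) . n.
    """
    h = solver.grid.h
    mu = solver.props.mu
    if n_probes is None:
        n_probes = max(32, int(math.ceil(2 * math.pi * particle.r / h)))
    if grad_offset is None:
        grad_offset = h
    theta = (np.arange(n_probes) + 0.5) * (2 * math.pi / n_probes)
    nhat = np.column_stack([np.cos(theta), np.sin(theta)])
    pts1 = particle.x + (particle.r + grad_offset) * nhat
    pts2 = particle.x + (particle.r + 2 * grad_offset) * nhat

    if grads is None:
        grads = solver.velocity_gradients(state.u, state.v)
    dudx, dudy, dvdx, dvdy = grads
    x0, y0 = solver.grid.origin
    cx, cy = x0 + h / 2, y0 + h / 2

    def extrap(field, fx0, fy0):
        a = bilinear_sample(field, fx0, fy0, h, pts1)
        b = bilinear_sample(field, fx0, fy0, h, pts2)
        return 2.0 * a - b

    p_k = extrap(state.p, cx, cy)
    gxx = extrap(dudx, cx, cy)
    gxy = extrap(dudy, cx, cy)
    gyx = extrap(dvdx, cx, cy)
    gyy = extrap(dvdy, cx, cy)

    # viscous traction components: sigma_v . n with sigma_v = mu(grad u + grad u^T)
    tx = mu * (2 * gxx * nhat[:, 0] + (gxy + gyx) * nhat[:, 1])
    ty = mu * ((gxy + gyx) * nhat[:, 0] + 2 * gyy * nhat[:, 1])

    dl = particle.r * (2 * math.pi / n_probes)
    f_pressure = -np.array([np.sum(p_k * nhat[:, 0]), np.sum(p_k * nhat[:, 1])]) * dl
    f_shear = np.array([np.sum(tx), np.sum(ty)]) * dl
    # moment about the centre: r n x t (pressure contributes nothing on a disc)
    mz = particle.r * np.sum(nhat[:, 0] * ty - nhat[:, 1] * tx) * dl

    tn = tx * nhat[:, 0] + ty * nhat[:, 1]
    ttx = tx - tn * nhat[:, 0]
    tty = ty - tn * nhat[:, 1]
    tau_mean = float(np.mean(np.hypot(ttx, tty)))
    return ParticleLoads(
        f_pressure=f_pressure,
        f_shear=f_shear,
        moment=float(mz),
        p_mean=float(np.mean(p_k)),
        tau_mean=tau_mean,
    )


def hydrodynamic_loads_many(
    solver: FluidSolver,
    state: FlowState,
    particles: list[RigidParticle],
    grads=None,
) -> list[ParticleLoads]:
    """Loads for all particles with one interpolation sweep (same physics as
    :func:`hydrodynamic_loads`, batched for the coupled stepper)."""
    if not particles:
        return []
    h = solver.grid.h
    mu = solver.props.mu
    x0, y0 = solver.grid.origin
    cx, cy = x0 + h / 2, y0 + h / 2

    counts, nhats, pts1, pts2 = [], [], [], []
    for p in particles:
        m = max(32, int(math.ceil(2 * math.pi * p.r / h)))
        th = (np.arange(m) + 0.5) * (2 * math.pi / m)
        nh = np.column_stack([np.cos(th), np.sin(th)])
        counts.append(m)
        nhats.append(nh)
        pts1.append(p.x + (p.r + h) * nh)
        pts2.append(p.x + (p.r + 2 * h) * nh)
    nhat = np.vstack(nhats)
    a1 = np.vstack(pts1)
    a2 = np.vstack(pts2)

    if _HAVE_NUMBA and grads is None:
        uc, vc = solver.centre_velocity(state.u, state.v)
        f1 = _probe_fields(state.p, uc, vc, h, cx, cy, a1)
        f2 = _probe_fields(state.p, uc, vc, h, cx, cy, a2)
        p_k, gxx, gxy, gyx, gyy = 2.0 * f1 - f2
    else:
        if grads is None:
            grads = solver.velocity_gradients(state.u, state.v)
        dudx, dudy, dvdx, dvdy = grads

        def extrap(field):
            return 2.0 * bilinear_sample(field, cx, cy, h, a1) - bilinear_sample(
                field, cx, cy, h, a2
            )

        p_k = extrap(state.p)
        gxx = extrap(dudx)
        gxy = extrap(dudy)
        gyx = extrap(dvdx)
        gyy = extrap(dvdy)
    tx = mu * (2 * gxx * nhat[:, 0] + (gxy + gyx) * nhat[:, 1])
    ty = mu * ((gxy + gyx) * nhat[:, 0] + 2 * gyy * nhat[:, 1])
    tn = tx * nhat[:, 0] + ty * nhat[:, 1]
    ttx = tx - tn * nhat[:, 0]
    tty = ty - tn * nhat[:, 1]

    out = []
    k0 = 0
    for p, m in zip(particles, counts):
        sl = slice(k0, k0 + m)
        k0 += m
        nh = nhat[sl]
        dl = p.r * (2 * math.pi / m)
        f_pressure = -np.array([np.sum(p_k[sl] * nh[:, 0]), np.sum(p_k[sl] * nh[:, 1])]) * dl
        f_shear = np.array([np.sum(tx[sl]), np.sum(ty[sl])]) * dl
        mz = p.r * np.sum(nh[:, 0] * ty[sl] - nh[:, 1] * tx[sl]) * dl
        out.append(
            ParticleLoads(
                f_pressure=f_pressure,
                f_shear=f_shear,
                moment=float(mz),
                p_mean=float(np.mean(p_k[sl])),
                tau_mean=float(np.mean(np.hypot(ttx[sl], tty[sl]))),
            )
        )
    return out


def integrate_body(
    particle: RigidParticle,
    f_ext: np.ndarray,
    m_ext: float,
    dt: float,
    m_virtual: float = 0.0,
) -> None:
    """Semi-implicit (symplectic Euler) update of one rigid body in place.

    ``f_ext``/``m_ext`` are the total external force and moment (hydrodynamic
    + contact + net weight).  ``m_virtual`` is the added translational inertia
    C_vm rho_f A used to stabilise loose coupling; it does not alter steady
    states, only transients.
    """
    f_ext = np.asarray(f_ext, dtype=float)
    if not np.all(np.isfinite(f_ext)) or not math.isfinite(m_ext):
        raise FloatingPointError(f"non-finite force on particle {particle.id}")
    particle.v = particle.v + dt * f_ext / (particle.mass + m_virtual)
    particle.omega = particle.omega + dt * m_ext / particle.inertia
    particle.x = particle.x + dt * particle.v
    particle.theta = particle.theta + dt * particle.omega
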