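"""Particle-particle and particle-wall contacts: Hertzian spring + dashpot.

Contacts activate when the surface gap drops below the activation gap
``g_act``; the normal force magnitude is

    F_n = k_n delta^(3/2) + gamma_n * (normal approach speed),  clipped >= 0,

with penetration delta = g_act - gap.  Forces are repulsive only (no
adhesion) and equal-and-opposite.  With the default frictionless contacts the
contact moment M_c is identically zero for discs; an optional Coulomb-style
tangential force (mu_t > 0) provides a moment when enabled.

Because the contact springs are much stiffer than the fluid time scale,
contacts (plus the frozen hydrodynamic load and net weight) are integrated
with internal sub-steps dt_c = min(dt_fluid, 0.1 sqrt(m/k_eff)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "ContactParameters",
    "ContactEvent",
    "detect_contacts",
    "contact_force",
    "substep_contacts",
    "default_stiffness",
]


def default_stiffness(mass: float, v_impact: float = 50.0, max_overlap: float = 0.1) -> float:
    """Hertz stiffness so a head-on impact at ``v_impact`` peaks at ``max_overlap``.

    From the energy balance (1/2) m_red v^2 = (2/5) k delta_max^(5/2) with
    m_red = mass/2 for equal bodies.  Units: force per overlap^(3/2).
    """
    m_red = 0.5 * mass
    return 0.5 * m_red * v_impact**2 / (0.4 * max_overlap**2.5)


@dataclass(frozen=True)
class ContactParameters:
    """Contact-law constants.  g_act must stay below the 0.2 mm initial
    inter-particle surface gap so the springs are inactive at release."""

    k_n: float = 1.0e4        # uN/mm / mm^(3/2) per depth
    gamma_n: float = 5.0      # uN/mm / (mm/s) per depth
    g_act: float = 0.1        # mm
    mu_t: float = 0.0         # Coulomb friction coefficient (0 = frictionless)
    k_n_wall: float | None = None
    gamma_n_wall: float | None = None

    def __post_init__(self):
        if self.k_n <= 0 or self.gamma_n < 0:
            raise ValueError("k_n must be positive and gamma_n non-negative")
        if not (0.0 < self.g_act < 0.2):
            raise ValueError("activation gap must lie in (0, 0.2) mm")

    @property
    def wall_k(self) -> float:
        return self.k_n if self.k_n_wall is None else self.k_n_wall

    @property
    def wall_gamma(self) -> float:
        return self.gamma_n if self.gamma_n_wall is None else self.gamma_n_wall


@dataclass
class ContactEvent:
    """One active proximity event (geometry only until forces are computed)."""

    body_a: int                  # particle index
    body_b: int                  # particle index, or -1 for the wall
    gap: float                   # surface gap (mm); < g_act when active
    normal: np.ndarray           # unit vector pointing from b toward a
    point: np.ndarray            # contact point (mm)
    f: np.ndarray = field(default_factory=lambda: np.zeros(2))   # force on a
    m_a: float = 0.0
    m_b: float = 0.0


def detect_contacts(particles, lumen, t: float, params: ContactParameters):
    """Geometric proximity detection (no forces).

    Particle pairs are active iff the centre distance is below
    r_i + r_j + g_act; a particle-wall event is active iff the wall signed
    distance at the centre exceeds -(r + g_act).  With N = 8 bodies an
    all-pairs sweep is already O(N) events.
    """
    events: list[ContactEvent] = []
    n = len(particles)
    if n > 1:
        xs = np.array([p.x for p in particles])
        rs = np.array([p.r for p in particles])
        for i, j in combinations(range(n), 2):
            d = xs[i] - xs[j]
            dist = float(np.hypot(d[0], d[1]))
            gap = dist - (rs[i] + rs[j])
            if gap < params.g_act:
                nrm = d / dist if dist > 1e-12 else np.array([1.0, 0.0])
                point = xs[j] + (rs[j] + 0.5 * gap) * nrm
                events.append(ContactEvent(i, j, gap, nrm, point))
    if lumen is not None:
        xs = np.array([p.x for p in particles])
        phi, n_in, uw = lumen.wall_contact_query(xs, t)
        for i, p in enumerate(particles):
            gap = float(-phi[i]) - p.r     # phi < 0 inside the lumen
            if gap < params.g_act:
                nrm = np.asarray(n_in[i], dtype=float)
                point = p.x - p.r * nrm
                ev = ContactEvent(i, -1, gap, nrm, point)
                ev.wall_velocity = np.asarray(uw[i], dtype=float)
                events.append(ev)
    return events


def contact_force(event: ContactEvent, particles, params: ContactParameters) -> None:
    """Fill in the spring-dashpot force (stored on the event, acting on body a).

    delta = g_act - gap; F = [k delta^(3/2) + gamma * approach speed]+ along
    the contact normal.  Reaction on body b is exactly -F.
    """
    delta = params.g_act - event.gap
    if delta <= 0.0:
        event.f = np.zeros(2)
        event.m_a = event.m_b = 0.0
        return
    a = particles[event.body_a]
    if event.body_b >= 0:
        b = particles[event.body_b]
        k, gam = params.k_n, params.gamma_n
        v_rel = a.v - b.v
        r_max = min(a.r, b.r)
    else:
        k, gam = params.wall_k, params.wall_gamma
        v_rel = a.v - getattr(event, "wall_velocity", np.zeros(2))
        r_max = a.r
    if delta > 0.25 * r_max:
        import warnings

        warnings.warn(
            "overstiff contact penetration (> 0.25 r); increase k_n or reduce dt",
            RuntimeWarning,
            stacklevel=2,
        )
    approach = -float(v_rel @ event.normal)   # > 0 when closing
    fn = k * delta**1.5 + gam * approach
    fn = max(fn, 0.0)
    f = fn * event.normal
    if params.mu_t > 0.0:
        v_tan = v_rel - (v_rel @ event.normal) * event.normal
        vt = float(np.hypot(v_tan[0], v_tan[1]))
        if vt > 1e-9:
            f = f - params.mu_t * fn * v_tan / vt
    event.f = f
    # moment about each centre from the tangential component at the contact point
    ra = event.point - a.x
    event.m_a = float(ra[0] * f[1] - ra[1] * f[0])
    if event.body_b >= 0:
        b = particles[event.body_b]
        rb = event.point - b.x
        event.m_b = float(rb[0] * (-f[1]) - rb[1] * (-f[0]))
    else:
        event.m_b = 0.0


def substep_contacts(
    particles,
    lumen,
    t: float,
    dt_fluid: float,
    params: ContactParameters,
    accel: np.ndarray,
    alpha_rot: np.ndarray | None = None,
    m_virtual: np.ndarray | None = None,
    max_substeps: int = 10_000,
):
    """Advance particles over one fluid step with contact sub-stepping.

    ``accel`` is the frozen per-particle translational acceleration from
    hydrodynamic loads plus net weight, shape (n, 2); ``alpha_rot`` the frozen
    angular acceleration.  Wall kinematics are evaluated at the (frozen) time
    ``t``.  Returns the list of contact events with peak-force magnitudes
    accumulated over the sub-steps.
    """
    n = len(particles)
    accel = np.asarray(accel, dtype=float)
    if alpha_rot is None:
        alpha_rot = np.zeros(n)
    if m_virtual is None:
        m_virtual = np.zeros(n)
    m_eff = np.array([p.mass for p in particles]) + m_virtual

    k_ref = max(params.k_n, params.wall_k)
    # linearised stiffness at a representative overlap of half the activation gap
    k_lin = k_ref * math.sqrt(max(params.g_act, 1e-6))
    dt_c = min(dt_fluid, 0.1 * math.sqrt(float(m_eff.min()) / k_lin))
    n_sub = max(1, int(math.ceil(dt_fluid / dt_c)))
    if n_sub > max_substeps:
        raise RuntimeError(
            f"contact sub-step count {n_sub} exceeds {max_substeps}: "
            "stiffness/time-step mismatch"
        )
    dt_c = dt_fluid / n_sub

    # wall proximity is linearised over the fluid step: the wall signed
    # distance is queried once, and the gap of particle i evolves as
    # gap0 + (x - x0) . n_in  (particles move < 0.1 mm per fluid step).
    wall_info = None
    if lumen is not None and n:
        xs0 = np.array([p.x for p in particles])
        phi0, n_in, uw = lumen.wall_contact_query(xs0, t)
        wall_info = (xs0, -np.asarray(phi0) - np.array([p.r for p in particles]),
                     np.asarray(n_in), np.asarray(uw))

    inertias = np.array([p.inertia for p in particles])
    peak: dict[tuple[int, int], ContactEvent] = {}
    for _ in range(n_sub):
        events = []
        if n > 1:
            xs = np.array([p.x for p in particles])
            rs = np.array([p.r for p in particles])
            for i, j in combinations(range(n), 2):
                dx = xs[i, 0] - xs[j, 0]
                dy = xs[i, 1] - xs[j, 1]
                dist = math.hypot(dx, dy)
                gap = dist - (rs[i] + rs[j])
                if gap < params.g_act:
                    nrm = np.array([dx, dy]) / dist if dist > 1e-12 else np.array([1.0, 0.0])
                    point = xs[j] + (rs[j] + 0.5 * gap) * nrm
                    events.append(ContactEvent(i, j, gap, nrm, point))
        if wall_info is not None:
            xs0, gap0, n_in, uw = wall_info
            for i, p in enumerate(particles):
                gap = float(gap0[i] + (p.x - xs0[i]) @ n_in[i])
                if gap < params.g_act:
                    ev = ContactEvent(i, -1, gap, n_in[i], p.x - p.r * n_in[i])
                    ev.wall_velocity = uw[i]
                    events.append(ev)
        forces = accel * m_eff[:, None]
        moments = alpha_rot * inertias
        for ev in events:
            contact_force(ev, particles, params)
            forces[ev.body_a] += ev.f
            moments[ev.body_a] += ev.m_a
            if ev.body_b >= 0:
                forces[ev.body_b] -= ev.f
                moments[ev.body_b] += ev.m_b
            key = (ev.body_a, ev.body_b)
            best = peak.get(key)
            if best is None or np.hypot(*ev.f) > np.hypot(*best.f):
                peak[key] = ev
        for i, p in enumerate(particles):
            p.v = p.v + dt_c * forces[i] / m_eff[i]
            p.omega = p.omega + dt_c * moments[i] / p.inertia
            p.x = p.x + dt_c * p.v
            p.theta = p.theta + dt_c * p.omega
    return list(peak.values())
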