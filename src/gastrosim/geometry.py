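"""Parametric 2D stomach lumen and antral contraction-wave kinematics.

The stomach is modelled as a planar tube around a J-shaped centreline: a wide
fundus chamber at the top, a body descending along the greater curvature, an
antrum forming the lowest region, and a pylorus opening into a short straight
duodenal segment.  The arc coordinate ``s`` is measured along the centreline
from the pyloric plane (s = 0), increasing proximally toward the fundus apex;
the duodenum has s < 0.

Antral contraction waves are Gaussian occlusions of the rest radius profile
R0(s) travelling toward the pylorus with speed ``c``, launched every period
``Tp`` and deepening linearly (the amplitude ramp) as they approach the
pylorus, which reproduces the terminal antral contraction.  Antral
hypomotility is a multiplicative scale factor ``chi`` < 1 on the occlusion
amplitude.

Gravity points along -y; the pylorus sits above the lowest antral point so
that settled heavy contents must be carried up to the gastric outlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.spatial import cKDTree

__all__ = [
    "Centreline",
    "WaveParameters",
    "TubeLumen",
    "CircleLumen",
    "EllipseLumen",
    "PointMap",
    "build_lumen",
    "default_stomach_params",
    "StomachGeometryParams",
]


# ---------------------------------------------------------------------------
# centreline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Centreline:
    """Ordered centreline samples with arc coordinate measured from the pylorus.

    Attributes
    ----------
    points : (n, 2) float array, mm.  Ordered from the duodenal end (most
        negative s) to the proximal (fundus apex) end.
    s : (n,) float array, mm.  Cumulative arc length, 0 at the pyloric plane,
        strictly increasing along the samples, negative in the duodenum.
    tangent, normal : (n, 2) unit vectors per sample.  ``normal`` is the
        tangent rotated +90 degrees.
    """

    points: np.ndarray
    s: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        if not np.all(np.diff(self.s) > 0):
            raise ValueError("arc coordinate must be strictly increasing")
        norms = np.linalg.norm(self.tangent, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors")

    @property
    def s_min(self) -> float:
        return float(self.s[0])

    @property
    def s_max(self) -> float:
        return float(self.s[-1])

    @classmethod
    def from_control_points(
        cls,
        control: np.ndarray,
        pylorus_index: int,
        spacing: float = 0.5,
    ) -> "Centreline":
        """Fit a cubic spline through control points and resample uniformly.

        ``pylorus_index`` selects the control point defining s = 0.
        """
        control = np.asarray(control, dtype=float)
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(control, axis=0), axis=1))]
        )
        spline = CubicSpline(chord, control, axis=0)
        # dense evaluation to get accurate arc length, then uniform resample
        tt = np.linspace(chord[0], chord[-1], max(2000, 20 * len(control)))
        xy = spline(tt)
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        n = int(arc[-1] / spacing) + 1
        s_uniform = np.linspace(0.0, arc[-1], n)
        pts = np.column_stack(
            [np.interp(s_uniform, arc, xy[:, 0]), np.interp(s_uniform, arc, xy[:, 1])]
        )
        # arc coordinate of the pylorus control point on the dense arc
        i_py = np.argmin(np.abs(tt - chord[pylorus_index]))
        s_pyl = arc[i_py]
        s_rel = s_uniform - s_pyl
        tang = np.gradient(pts, s_uniform, axis=0)
        tang /= np.linalg.norm(tang, axis=1)[:, None]
        norm = np.column_stack([-tang[:, 1], tang[:, 0]])
        return cls(points=pts, s=s_rel, tangent=tang, normal=norm)


# ---------------------------------------------------------------------------
# contraction waves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveParameters:
    """Travelling antral contraction wave train.

    period : s.  A new wave is launched every ``period``.
    speed : mm/s.  Crest speed toward the pylorus.
    width : mm.  Gaussian half-width (standard deviation) of the occlusion.
    amplitude : peak relative occlusion A in [0, 1].
    s_start : mm.  Arc coordinate where waves originate (zero depth there).
    s_full : mm.  The linear amplitude ramp saturates here: waves run at full
        depth from the terminal-antrum entry down to the pylorus, which is
        what traps settled solids ahead of the terminal antral contraction.
    chi : motility scale in (0, 1]; 1 = healthy, < 1 = hypomotile.
    """

    period: float = 20.0
    speed: float = 2.75
    width: float = 10.0
    amplitude: float = 0.8
    s_start: float = 55.0
    s_full: float = 20.0
    chi: float = 1.0
    # smooth gate width at the pyloric plane (mm): occlusion fades to zero in
    # the duodenum over this distance, which co-modulates the pyloric gap with
    # the arriving wave (closure at terminal antral contraction).
    pyloric_gate: float = 3.0

    def __post_init__(self):
        if self.period <= 0 or self.speed <= 0 or self.width <= 0:
            raise ValueError("period, speed and width must be positive")
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in [0, 1]")
        if not (0.0 < self.chi <= 1.0):
            raise ValueError("chi must lie in (0, 1]")

    def crest_positions(self, t: float) -> np.ndarray:
        """Arc coordinates of all active wave crests at time t.

        Waves exist for every integer launch index (the train extends into the
        past), so the kinematics are exactly periodic in ``t`` with period
        ``period`` from t = 0.  A wave is active while its crest lies in
        (-4 width, s_start].
        """
        tail = 4.0 * self.width
        k_hi = math.floor(t / self.period)
        k_lo = math.ceil((t - (self.s_start + tail) / self.speed) / self.period)
        ks = np.arange(k_lo, k_hi + 1)
        crests = self.s_start - self.speed * (t - ks * self.period)
        return crests[(crests > -tail) & (crests <= self.s_start)]

    def occlusion(self, s: np.ndarray, t: float) -> np.ndarray:
        """Relative occlusion field chi*A*ramp(s)*gate(s)*sum_k G(s - s_k)."""
        s = np.asarray(s, dtype=float)
        occ = np.zeros_like(s)
        ramp = np.clip((self.s_start - s) / (self.s_start - self.s_full), 0.0, 1.0)
        gate = np.clip(s / self.pyloric_gate, 0.0, 1.0)
        shape = self.chi * self.amplitude * ramp * gate
        for sk in self.crest_positions(t):
            occ += shape * np.exp(-((s - sk) ** 2) / (2.0 * self.width**2))
        return np.minimum(occ, 1.0)

    def occlusion_rate(self, s: np.ndarray, t: float) -> np.ndarray:
        """Time derivative of :meth:`occlusion` (analytic)."""
        s = np.asarray(s, dtype=float)
        docc = np.zeros_like(s)
        ramp = np.clip((self.s_start - s) / (self.s_start - self.s_full), 0.0, 1.0)
        gate = np.clip(s / self.pyloric_gate, 0.0, 1.0)
        shape = self.chi * self.amplitude * ramp * gate
        for sk in self.crest_positions(t):
            xi = s - sk
            g = np.exp(-(xi**2) / (2.0 * self.width**2))
            # d(xi)/dt = +speed  (crest moves toward smaller s)
            docc += shape * g * (-xi / self.width**2) * self.speed
        return docc


# ---------------------------------------------------------------------------
# point maps: cached tube coordinates for a fixed set of sample points
# ---------------------------------------------------------------------------

@dataclass
class PointMap:
    """Static tube coordinates of a fixed point set w.r.t. a centreline."""

    s: np.ndarray          # arc coordinate of nearest centreline point
    d: np.ndarray          # signed transverse offset (along +normal)
    normal: np.ndarray     # (n, 2) centreline normal at the nearest point
    tangent: np.ndarray    # (n, 2) centreline tangent at the nearest point
    axial_excess: np.ndarray  # distance beyond the centreline ends (>= 0)
    idx: np.ndarray        # index into the radius-profile grid
    w: np.ndarray          # linear interpolation weight for idx -> idx+1


# ---------------------------------------------------------------------------
# lumen geometries
# ---------------------------------------------------------------------------

class TubeLumen:
    """A 2D lumen defined by a centreline, a rest radius profile and a wave train.

    The instantaneous half-width is

        R(s, t) = max(R0(s) * (1 - occlusion(s, t)), r_floor)

    and the approximate signed distance of a point with tube coordinates
    (s, d) is  phi = |d| - R(s, t)  (negative inside the lumen).  The wall
    velocity is radial: u_wall = sign(d) * normal(s) * dR/dt.
    """

    def __init__(
        self,
        centreline: Centreline,
        s_knots: np.ndarray,
        r_knots: np.ndarray,
        waves: WaveParameters | None,
        r_floor: float = 0.5,
        regions: dict[str, tuple[float, float]] | None = None,
        open_ends: tuple[bool, bool] = (True, False),
    ):
        if np.any(np.asarray(r_knots) <= 0):
            raise ValueError("rest radius profile must be positive")
        self.centreline = centreline
        self.waves = waves
        self.r_floor = float(r_floor)
        self.regions = regions or {}
        # (distal open, proximal open): duodenal outlet, fundic inlet
        self.open_ends = open_ends
        self._r0 = PchipInterpolator(np.asarray(s_knots, float), np.asarray(r_knots, float))
        self._s_knots = np.asarray(s_knots, float)
        self._r_knots = np.asarray(r_knots, float)
        # dense 1D profile grid used for fast per-point radius lookup
        self._sg = np.arange(centreline.s_min, centreline.s_max + 0.25, 0.25)
        self._r0g = self.rest_radius(self._sg)
        self._tree = cKDTree(centreline.points)
        self._profile_cache: tuple[float, np.ndarray, np.ndarray] | None = None

    # -- radius profile ----------------------------------------------------

    def rest_radius(self, s):
        s = np.clip(np.asarray(s, dtype=float), self.centreline.s_min, self.centreline.s_max)
        return np.asarray(self._r0(s))

    def radius(self, s, t: float):
        """Instantaneous half-width R(s, t) (mm)."""
        s = np.asarray(s, dtype=float)
        r0 = self.rest_radius(s)
        if self.waves is None:
            return np.maximum(r0, self.r_floor) if np.ndim(r0) else max(float(r0), self.r_floor)
        occ = self.waves.occlusion(np.clip(s, self.centreline.s_min, self.centreline.s_max), t)
        return np.maximum(r0 * (1.0 - occ), self.r_floor)

    def radius_rate(self, s, t: float):
        """dR/dt (mm/s); zero where the floor clamp is active."""
        s = np.asarray(s, dtype=float)
        r0 = self.rest_radius(s)
        if self.waves is None:
            return np.zeros_like(r0)
        sc = np.clip(s, self.centreline.s_min, self.centreline.s_max)
        occ = self.waves.occlusion(sc, t)
        rate = -r0 * self.waves.occlusion_rate(sc, t)
        clamped = r0 * (1.0 - occ) <= self.r_floor
        return np.where(clamped, 0.0, rate)

    # -- tube coordinates --------------------------------------------------

    def map_points(self, points: np.ndarray) -> PointMap:
        """Compute static tube coordinates (s, d) for a fixed point set."""
        points = np.asarray(points, dtype=float)
        cl = self.centreline
        _, inear = self._tree.query(points)
        # refine by projecting onto the local tangent at the nearest sample
        p0 = cl.points[inear]
        tang = cl.tangent[inear]
        norm = cl.normal[inear]
        rel = points - p0
        ds = np.einsum("ij,ij->i", rel, tang)
        # clamp the along-tangent refinement to the local sample spacing
        spacing = np.median(np.diff(cl.s))
        ds = np.clip(ds, -spacing, spacing)
        s = cl.s[inear] + ds
        d = np.einsum("ij,ij->i", rel, norm)
        ax = np.zeros(len(points))
        low = s < cl.s_min
        high = s > cl.s_max
        ax[low] = cl.s_min - s[low]
        ax[high] = s[high] - cl.s_max
        s = np.clip(s, cl.s_min, cl.s_max)
        idx_f = (s - self._sg[0]) / (self._sg[1] - self._sg[0])
        idx = np.clip(idx_f.astype(int), 0, len(self._sg) - 2)
        w = np.clip(idx_f - idx, 0.0, 1.0)
        return PointMap(s=s, d=d, normal=norm, tangent=tang, axial_excess=ax, idx=idx, w=w)

    def _profile(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Instantaneous (R, dR/dt) on the dense s-grid, memoized per time."""
        cache = self._profile_cache
        if cache is not None and cache[0] == t:
            return cache[1], cache[2]
        if self.waves is None:
            rg = np.maximum(self._r0g, self.r_floor)
            rate_g = np.zeros_like(rg)
        else:
            occ = self.waves.occlusion(self._sg, t)
            unclamped = self._r0g * (1.0 - occ)
            rg = np.maximum(unclamped, self.r_floor)
            rate_g = -self._r0g * self.waves.occlusion_rate(self._sg, t)
            rate_g[unclamped <= self.r_floor] = 0.0
        self._profile_cache = (t, rg, rate_g)
        return rg, rate_g

    def _profile_at(self, pm: PointMap, t: float) -> tuple[np.ndarray, np.ndarray]:
        rg, rate_g = self._profile(t)
        wm = 1.0 - pm.w
        R = rg[pm.idx] * wm + rg[pm.idx + 1] * pm.w
        Rdot = rate_g[pm.idx] * wm + rate_g[pm.idx + 1] * pm.w
        return R, Rdot

    def fields(self, pm: PointMap, t: float):
        """(phi, uwall_x, uwall_y) at the mapped points; phi < 0 in the lumen."""
        R, Rdot = self._profile_at(pm, t)
        phi = np.abs(pm.d) - R
        # open tube ends continue through the domain boundary; closed ends cap
        open_dist, open_prox = self.open_ends
        ax = pm.axial_excess
        end_is_closed = np.where(pm.s <= self.centreline.s_min + 1e-9, not open_dist, not open_prox)
        phi = np.where((ax > 0) & end_is_closed, np.maximum(phi, ax), phi)
        sgn = np.sign(pm.d)
        uwx = sgn * pm.normal[:, 0] * Rdot
        uwy = sgn * pm.normal[:, 1] * Rdot
        # the wall only moves where the point is near the moving boundary;
        # using the radial rate everywhere is fine for forcing (only cells with
        # phi in the smearing band matter).
        return phi, uwx, uwy

    def signed_distance(self, points: np.ndarray, t: float) -> np.ndarray:
        pm = self.map_points(points)
        return self.fields(pm, t)[0]

    def wall_velocity(self, points: np.ndarray, t: float) -> np.ndarray:
        pm = self.map_points(points)
        _, uwx, uwy = self.fields(pm, t)
        return np.column_stack([uwx, uwy])

    def arc_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Arc coordinate (distance to the pylorus along the centreline, mm)."""
        return self.map_points(np.atleast_2d(points)).s

    def wall_contact_query(self, points: np.ndarray, t: float):
        """(phi, inward_normal, u_wall) at arbitrary points, for contact.

        The wall surface is |d| = R(s, t); its gradient includes the flank
        slope dR/ds, so a travelling constriction pushes bodies along the
        tube as well as transversely (the trituration 'shovel').
        """
        pm = self.map_points(np.atleast_2d(points))
        phi, uwx, uwy = self.fields(pm, t)
        rg, _ = self._profile(t)
        drds_g = np.gradient(rg, self._sg)
        wm = 1.0 - pm.w
        drds = drds_g[pm.idx] * wm + drds_g[pm.idx + 1] * pm.w
        sgn = np.where(pm.d >= 0, 1.0, -1.0)
        # grad phi = sign(d) n_hat - dR/ds t_hat; outward from the lumen
        gx = sgn * pm.normal[:, 0] - drds * pm.tangent[:, 0]
        gy = sgn * pm.normal[:, 1] - drds * pm.tangent[:, 1]
        norm = np.sqrt(gx**2 + gy**2)
        n_in = -np.column_stack([gx / norm, gy / norm])
        return phi / norm, n_in, np.column_stack([uwx, uwy])

    # -- integral diagnostics ---------------------------------------------

    def lumen_area(self, t: float, ds: float = 0.1) -> float:
        """Approximate lumen area by integrating the width profile (mm^2)."""
        s = np.arange(self.centreline.s_min, self.centreline.s_max, ds)
        return float(np.sum(2.0 * self.radius(s, t)) * ds)

    def wall_flux(self, t: float, ds: float = 0.1) -> float:
        """Integral of wall velocity . outward normal over the boundary (mm^2/s).

        Equals +d(area)/dt for the radial wall motion of a tube.
        """
        s = np.arange(self.centreline.s_min, self.centreline.s_max, ds)
        return float(np.sum(2.0 * self.radius_rate(s, t)) * ds)

    def boundary_polyline(self, t: float, ds: float = 0.5) -> np.ndarray:
        """Closed boundary polyline (upper side then lower side reversed)."""
        cl = self.centreline
        s = np.arange(cl.s_min, cl.s_max + ds, ds)
        pts = np.column_stack(
            [np.interp(s, cl.s, cl.points[:, 0]), np.interp(s, cl.s, cl.points[:, 1])]
        )
        nx = np.interp(s, cl.s, cl.normal[:, 0])
        ny = np.interp(s, cl.s, cl.normal[:, 1])
        nn = np.column_stack([nx, ny])
        nn /= np.linalg.norm(nn, axis=1)[:, None]
        R = self.radius(s, t)[:, None]
        upper = pts + R * nn
        lower = pts - R * nn
        return np.vstack([upper, lower[::-1], upper[:1]])


class CircleLumen:
    """Analytic circular lumen (exact signed distance), for verification."""

    def __init__(self, centre=(0.0, 0.0), radius=10.0, radius_rate=0.0):
        self.centre = np.asarray(centre, dtype=float)
        self.R = float(radius)
        self.Rdot = float(radius_rate)

    def map_points(self, points):
        return np.asarray(points, dtype=float)

    def fields(self, points, t: float):
        rel = points - self.centre
        r = np.linalg.norm(rel, axis=1)
        phi = r - (self.R + self.Rdot * t)
        with np.errstate(invalid="ignore", divide="ignore"):
            nhat = np.where(r[:, None] > 1e-12, rel / np.maximum(r, 1e-12)[:, None], 0.0)
        uw = self.Rdot * nhat
        return phi, uw[:, 0], uw[:, 1]

    def signed_distance(self, points, t: float):
        return self.fields(np.asarray(points, float), t)[0]

    def wall_contact_query(self, points, t: float):
        points = np.atleast_2d(points)
        phi, uwx, uwy = self.fields(points, t)
        rel = points - self.centre
        r = np.maximum(np.linalg.norm(rel, axis=1), 1e-12)
        n_in = -rel / r[:, None]
        return phi, n_in, np.column_stack([uwx, uwy])


class EllipseLumen:
    """Area-preserving pulsating ellipse: a(t) b(t) = a0 b0 for all t.

    Used for closed-lumen mass-conservation checks: the prescribed wall motion
    displaces no net volume, so a closed incompressible simulation is
    well-posed and the net wall flux vanishes.
    """

    def __init__(self, centre=(0.0, 0.0), a0=10.0, b0=6.0, eps=0.1, omega=1.0):
        self.centre = np.asarray(centre, dtype=float)
        self.a0, self.b0, self.eps, self.omega = float(a0), float(b0), float(eps), float(omega)

    def axes(self, t: float) -> tuple[float, float]:
        a = self.a0 * (1.0 + self.eps * math.sin(self.omega * t))
        return a, self.a0 * self.b0 / a

    def axes_rate(self, t: float) -> tuple[float, float]:
        a, b = self.axes(t)
        adot = self.a0 * self.eps * self.omega * math.cos(self.omega * t)
        return adot, -b * adot / a

    def map_points(self, points):
        return np.asarray(points, dtype=float)

    def fields(self, points, t: float):
        a, b = self.axes(t)
        adot, bdot = self.axes_rate(t)
        rel = points - self.centre
        rho = np.sqrt((rel[:, 0] / a) ** 2 + (rel[:, 1] / b) ** 2)
        phi = (rho - 1.0) * min(a, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = 1.0 / np.maximum(rho, 1e-12)
        uwx = adot * rel[:, 0] / a * inv
        uwy = bdot * rel[:, 1] / b * inv
        return phi, uwx, uwy

    def signed_distance(self, points, t: float):
        return self.fields(np.asarray(points, float), t)[0]

    def wall_contact_query(self, points, t: float):
        points = np.atleast_2d(points)
        phi, uwx, uwy = self.fields(points, t)
        a, b = self.axes(t)
        rel = points - self.centre
        grad = np.column_stack([rel[:, 0] / a**2, rel[:, 1] / b**2])
        gn = np.maximum(np.linalg.norm(grad, axis=1), 1e-12)
        n_in = -grad / gn[:, None]
        return phi, n_in, np.column_stack([uwx, uwy])


# ---------------------------------------------------------------------------
# default stomach geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StomachGeometryParams:
    """Parameters of the default J-shaped stomach lumen (all mm)."""

    control_points: tuple = (
        (86.0, 18.0),   # duodenal end (reaches the domain boundary)
        (66.0, 14.0),   # pylorus (s = 0)
        (52.0, 4.0),    # sinus: the lowest, most dependent point, just
        (38.0, 6.0),    # proximal of the pylorus, where solids settle
        (26.0, 12.0),
        (16.0, 24.0),
        (12.0, 38.0),
        (15.0, 52.0),
        (23.0, 60.0),   # fundus apex
    )
    pylorus_index: int = 1
    # rest radius profile knots (s mm -> half-width mm)
    radius_knots: tuple = (
        (-25.0, 2.5), (-6.0, 2.5), (0.0, 1.0), (6.0, 3.5), (12.0, 5.5),
        (20.0, 7.5), (35.0, 9.0), (55.0, 11.0), (70.0, 13.0), (85.0, 15.0),
        (95.0, 13.0), (101.0, 6.0), (104.0, 3.0),
    )
    r_floor: float = 0.5
    pyloric_half_gap: float = 1.0
    # region bands by arc coordinate (mm): [lo, hi); the terminal antrum is
    # the distal ~2 cm adjoining the pylorus where the TAC collapses the lumen
    terminal_antrum: tuple = (0.0, 20.0)
    antrum: tuple = (0.0, 55.0)
    body: tuple = (55.0, 80.0)
    fundus: tuple = (80.0, 1e9)


def default_stomach_params() -> StomachGeometryParams:
    return StomachGeometryParams()


def build_lumen(
    params: StomachGeometryParams | None = None,
    waves: WaveParameters | None = None,
    validate: bool = True,
) -> TubeLumen:
    """Build the parametric stomach lumen.

    Raises ``ValueError`` for non-positive radii or a self-intersecting
    boundary.  With ``waves=None`` the lumen is static at its rest shape.
    """
    params = params or default_stomach_params()
    knots = np.asarray(params.radius_knots, dtype=float)
    if np.any(knots[:, 1] <= 0):
        raise ValueError("non-positive rest radius in profile knots")
    cl = Centreline.from_control_points(
        np.asarray(params.control_points, dtype=float), params.pylorus_index
    )
    sk, rk = knots[:, 0], knots[:, 1].copy()
    # pin the pyloric half-gap knot
    i0 = np.argmin(np.abs(sk))
    rk[i0] = params.pyloric_half_gap
    regions = {
        "terminal_antrum": params.terminal_antrum,
        "antrum": params.antrum,
        "body": params.body,
        "fundus": params.fundus,
    }
    lumen = TubeLumen(cl, sk, rk, waves, r_floor=params.r_floor, regions=regions)
    if validate:
        _validate_boundary(lumen)
    return lumen


def _validate_boundary(lumen: TubeLumen) -> None:
    from shapely.geometry import Polygon

    poly = Polygon(lumen.boundary_polyline(0.0))
    if not poly.is_valid:
        raise ValueError("lumen boundary is self-intersecting: " + str(poly))
    if poly.area <= 0:
        raise ValueError("lumen boundary encloses no area")
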