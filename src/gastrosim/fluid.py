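"""Incompressible Navier-Stokes on a fixed Cartesian staggered (MAC) grid.

Fractional-step (projection) scheme: an explicit predictor with
Adams-Bashforth-2 time stepping, QUICK (quadratic upwind-biased) advective
fluxes and second-order central diffusion; direct volume-fraction immersed
boundary forcing toward local solid velocities; and a pressure Poisson solve
by direct sparse factorization (the matrix is constant, so the factorization
is reused every step).

Internal units are mm, g, s.  In this system 1 Pa s = 1 g/(mm s) and
1 g/(mm s^2) = 1 Pa, so viscosities entered in Pa s and pressures read in Pa
need no conversion; forces are per unit depth (g mm/s^2 per mm = uN/mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "CartesianGrid",
    "FluidProperties",
    "FlowState",
    "BoundarySpec",
    "FluidSolver",
    "bilinear_sample",
]

_PAD = 2  # ghost layers needed by QUICK


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CartesianGrid:
    """Uniform staggered grid: p at cell centres, u at x-faces, v at y-faces."""

    nx: int
    ny: int
    h: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def extent(self) -> tuple[float, float]:
        return self.nx * self.h, self.ny * self.h

    # staggered sample locations ------------------------------------------
    def cell_centres(self) -> np.ndarray:
        x0, y0 = self.origin
        x = x0 + (np.arange(self.nx) + 0.5) * self.h
        y = y0 + (np.arange(self.ny) + 0.5) * self.h
        X, Y = np.meshgrid(x, y, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def u_points(self) -> np.ndarray:
        x0, y0 = self.origin
        x = x0 + np.arange(self.nx + 1) * self.h
        y = y0 + (np.arange(self.ny) + 0.5) * self.h
        X, Y = np.meshgrid(x, y, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def v_points(self) -> np.ndarray:
        x0, y0 = self.origin
        x = x0 + (np.arange(self.nx) + 0.5) * self.h
        y = y0 + np.arange(self.ny + 1) * self.h
        X, Y = np.meshgrid(x, y, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass(frozen=True)
class FluidProperties:
    """rho in g/mm^3, mu in g/(mm s) (numerically equal to Pa s), g in mm/s^2."""

    rho: float = 1.0e-3
    mu: float = 1.0e-3
    g: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass
class FlowState:
    """Velocity/pressure fields at time t plus AB2 history."""

    u: np.ndarray            # (nx+1, ny)
    v: np.ndarray            # (nx, ny+1)
    p: np.ndarray            # (nx, ny)
    t: float = 0.0
    nu_prev: np.ndarray | None = None   # previous u-RHS (AB2)
    nv_prev: np.ndarray | None = None
    dt_prev: float | None = None
    alpha_u: np.ndarray | None = None   # last solid fractions (diagnostics)
    alpha_v: np.ndarray | None = None
    #: momentum the immersed-boundary forcing injected this step (g mm/s per depth)
    forcing_impulse: tuple[float, float] = (0.0, 0.0)

    def copy(self) -> "FlowState":
        return FlowState(
            u=self.u.copy(), v=self.v.copy(), p=self.p.copy(), t=self.t,
            nu_prev=None if self.nu_prev is None else self.nu_prev.copy(),
            nv_prev=None if self.nv_prev is None else self.nv_prev.copy(),
            dt_prev=self.dt_prev,
            alpha_u=None if self.alpha_u is None else self.alpha_u.copy(),
            alpha_v=None if self.alpha_v is None else self.alpha_v.copy(),
        )

    def max_speed(self) -> float:
        return max(float(np.abs(self.u).max()), float(np.abs(self.v).max()))


@dataclass(frozen=True)
class BoundarySpec:
    """Domain-box boundary conditions.

    Periodic flags override the per-side settings on that axis.  Non-periodic
    sides are 'wall' (no-slip) or 'open' (zero-gradient velocity; pressure is
    referenced through interior Dirichlet cells).
    """

    periodic_x: bool = False
    periodic_y: bool = False
    left: str = "wall"
    right: str = "wall"
    bottom: str = "wall"
    top: str = "wall"

    def __post_init__(self):
        for side in (self.left, self.right, self.bottom, self.top):
            if side not in ("wall", "open"):
                raise ValueError(f"unknown boundary type {side!r}")


class CFLError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# ghost padding
# ---------------------------------------------------------------------------

def _pad_axis(arr, axis, lo, hi, kind):
    """Pad one axis with _PAD ghost layers.

    kind: 'normal' for the component normal to this axis boundary (values
    live on the boundary face; odd reflection about the face), 'tangent' for
    the tangential component (values at half-cells; odd reflection about the
    wall plane), or 'periodic'.
    """
    p = _PAD
    n = arr.shape[axis]
    out_shape = list(arr.shape)
    out_shape[axis] = n + 2 * p
    out = np.empty(out_shape, dtype=arr.dtype)
    sl = [slice(None)] * arr.ndim

    def put(idx, val):
        sl2 = list(sl)
        sl2[axis] = idx
        out[tuple(sl2)] = val

    def get(idx):
        sl2 = list(sl)
        sl2[axis] = idx
        return arr[tuple(sl2)]

    put(slice(p, p + n), arr)
    if kind == "periodic":
        for k in range(1, p + 1):
            put(p - k, get((n - k) % n))
            put(p + n - 1 + k, get((k - 1) % n))
        return out

    # low side
    for k in range(1, p + 1):
        if lo == "wall":
            if kind == "normal":
                put(p - k, -get(k))
            else:
                put(p - k, -get(k - 1))
        else:  # open: zero gradient
            put(p - k, get(0))
    # high side
    for k in range(1, p + 1):
        if hi == "wall":
            if kind == "normal":
                put(p + n - 1 + k, -get(n - 1 - k))
            else:
                put(p + n - 1 + k, -get(n - k))
        else:
            put(p + n - 1 + k, get(n - 1))
    return out


def _pad_u(u, bc: BoundarySpec):
    if bc.periodic_x:
        # u has nx+1 faces with u[0] == u[nx]; wrap with period nx
        p = _PAD
        nxp1 = u.shape[0]
        nx = nxp1 - 1
        out = np.empty((nxp1 + 2 * p, u.shape[1]))
        out[p : p + nxp1] = u
        for k in range(1, p + 1):
            out[p - k] = u[nx - k]
            out[p + nxp1 - 1 + k] = u[k]
        ux = out
    else:
        ux = _pad_axis(u, 0, bc.left, bc.right, "normal")
    if bc.periodic_y:
        uy = np.concatenate([ux[:, -_PAD:], ux, ux[:, :_PAD]], axis=1)
    else:
        uy = _pad_axis(ux, 1, bc.bottom, bc.top, "tangent")
    return uy


def _pad_v(v, bc: BoundarySpec):
    if bc.periodic_y:
        p = _PAD
        nyp1 = v.shape[1]
        ny = nyp1 - 1
        out = np.empty((v.shape[0], nyp1 + 2 * p))
        out[:, p : p + nyp1] = v
        for k in range(1, p + 1):
            out[:, p - k] = v[:, ny - k]
            out[:, p + nyp1 - 1 + k] = v[:, k]
        vy = out
    else:
        vy = _pad_axis(v, 1, bc.bottom, bc.top, "normal")
    if bc.periodic_x:
        vx = np.concatenate([vy[-_PAD:], vy, vy[:_PAD]], axis=0)
    else:
        vx = _pad_axis(vy, 0, bc.left, bc.right, "tangent")
    return vx


def _quick(LL, L, R, RR, vel):
    """QUICK face value between nodes L and R given the face velocity sign."""
    pos = 0.75 * L + 0.375 * R - 0.125 * LL
    neg = 0.75 * R + 0.375 * L - 0.125 * RR
    return np.where(vel >= 0.0, pos, neg)


try:  # optional numba acceleration of the predictor kernel
    from numba import njit as _njit

    @_njit(fastmath=True)
    def _rhs_kernel(U, V, h, nu, gx, gy, nxu, nyu, nxv, nyv):  # pragma: no cover
        P = 2
        n_u = np.empty((nxu, nyu))
        n_v = np.empty((nxv, nyv))
        inv_h = 1.0 / h
        inv_h2 = inv_h * inv_h
        for i in range(nxu):
            ip = P + i
            for j in range(nyu):
                jp = P + j
                ue = 0.5 * (U[ip, jp] + U[ip + 1, jp])
                uw = 0.5 * (U[ip - 1, jp] + U[ip, jp])
                if ue >= 0.0:
                    ueh = 0.75 * U[ip, jp] + 0.375 * U[ip + 1, jp] - 0.125 * U[ip - 1, jp]
                else:
                    ueh = 0.75 * U[ip + 1, jp] + 0.375 * U[ip, jp] - 0.125 * U[ip + 2, jp]
                if uw >= 0.0:
                    uwh = 0.75 * U[ip - 1, jp] + 0.375 * U[ip, jp] - 0.125 * U[ip - 2, jp]
                else:
                    uwh = 0.75 * U[ip, jp] + 0.375 * U[ip - 1, jp] - 0.125 * U[ip + 1, jp]
                vn = 0.5 * (V[ip - 1, jp + 1] + V[ip, jp + 1])
                vs = 0.5 * (V[ip - 1, jp] + V[ip, jp])
                if vn >= 0.0:
                    unh = 0.75 * U[ip, jp] + 0.375 * U[ip, jp + 1] - 0.125 * U[ip, jp - 1]
                else:
                    unh = 0.75 * U[ip, jp + 1] + 0.375 * U[ip, jp] - 0.125 * U[ip, jp + 2]
                if vs >= 0.0:
                    ush = 0.75 * U[ip, jp - 1] + 0.375 * U[ip, jp] - 0.125 * U[ip, jp - 2]
                else:
                    ush = 0.75 * U[ip, jp] + 0.375 * U[ip, jp - 1] - 0.125 * U[ip, jp + 1]
                conv = (ue * ueh - uw * uwh) * inv_h + (vn * unh - vs * ush) * inv_h
                lap = (
                    U[ip + 1, jp] + U[ip - 1, jp] + U[ip, jp + 1] + U[ip, jp - 1]
                    - 4.0 * U[ip, jp]
                ) * inv_h2
                n_u[i, j] = -conv + nu * lap + gx
        for i in range(nxv):
            ip = P + i
            for j in range(nyv):
                jp = P + j
                vn2 = 0.5 * (V[ip, jp] + V[ip, jp + 1])
                vs2 = 0.5 * (V[ip, jp - 1] + V[ip, jp])
                if vn2 >= 0.0:
                    vnh = 0.75 * V[ip, jp] + 0.375 * V[ip, jp + 1] - 0.125 * V[ip, jp - 1]
                else:
                    vnh = 0.75 * V[ip, jp + 1] + 0.375 * V[ip, jp] - 0.125 * V[ip, jp + 2]
                if vs2 >= 0.0:
                    vsh = 0.75 * V[ip, jp - 1] + 0.375 * V[ip, jp] - 0.125 * V[ip, jp - 2]
                else:
                    vsh = 0.75 * V[ip, jp] + 0.375 * V[ip, jp - 1] - 0.125 * V[ip, jp + 1]
                ue2 = 0.5 * (U[ip + 1, jp - 1] + U[ip + 1, jp])
                uw2 = 0.5 * (U[ip, jp - 1] + U[ip, jp])
                if ue2 >= 0.0:
                    veh = 0.75 * V[ip, jp] + 0.375 * V[ip + 1, jp] - 0.125 * V[ip - 1, jp]
                else:
                    veh = 0.75 * V[ip + 1, jp] + 0.375 * V[ip, jp] - 0.125 * V[ip + 2, jp]
                if uw2 >= 0.0:
                    vwh = 0.75 * V[ip - 1, jp] + 0.375 * V[ip, jp] - 0.125 * V[ip - 2, jp]
                else:
                    vwh = 0.75 * V[ip, jp] + 0.375 * V[ip - 1, jp] - 0.125 * V[ip + 1, jp]
                conv = (ue2 * veh - uw2 * vwh) * inv_h + (vn2 * vnh - vs2 * vsh) * inv_h
                lap = (
                    V[ip + 1, jp] + V[ip - 1, jp] + V[ip, jp + 1] + V[ip, jp - 1]
                    - 4.0 * V[ip, jp]
                ) * inv_h2
                n_v[i, j] = -conv + nu * lap + gy
        return n_u, n_v

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# interpolation helpers
# ---------------------------------------------------------------------------

def bilinear_sample(f: np.ndarray, x0: float, y0: float, h: float, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a field whose node (0,0) sits at (x0, y0)."""
    pts = np.atleast_2d(pts)
    fx = (pts[:, 0] - x0) / h
    fy = (pts[:, 1] - y0) / h
    i = np.clip(fx.astype(int), 0, f.shape[0] - 2)
    j = np.clip(fy.astype(int), 0, f.shape[1] - 2)
    wx = np.clip(fx - i, 0.0, 1.0)
    wy = np.clip(fy - j, 0.0, 1.0)
    return (
        f[i, j] * (1 - wx) * (1 - wy)
        + f[i + 1, j] * wx * (1 - wy)
        + f[i, j + 1] * (1 - wx) * wy
        + f[i + 1, j + 1] * wx * wy
    )


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class FluidSolver:
    """Fractional-step incompressible solver with immersed-boundary forcing.

    Parameters
    ----------
    grid, props : discretisation and fluid properties.
    bc : domain-box boundary conditions.
    dirichlet_cells, dirichlet_values : flat indices (into the (nx, ny)
        row-major pressure array) of cells with fixed pressure, e.g. the
        duodenal outlet (p = 0, the gauge of all reported pressures) and the
        fundic tone inlet.
    cfl : convective CFL number used by :meth:`stable_dt`.
    dt_cap : upper bound on the time step (s).
    """

    #: post-projection divergence bound for the direct solve (1/s)
    div_tol = 1.0e-8

    def __init__(
        self,
        grid: CartesianGrid,
        props: FluidProperties,
        bc: BoundarySpec = BoundarySpec(),
        dirichlet_cells: np.ndarray | None = None,
        dirichlet_values: np.ndarray | None = None,
        cfl: float = 0.4,
        dt_cap: float = 2.0e-3,
    ):
        self.grid = grid
        self.props = props
        self.bc = bc
        self.cfl = float(cfl)
        self.dt_cap = float(dt_cap)
        self.dirichlet_cells = (
            np.asarray(dirichlet_cells, dtype=int) if dirichlet_cells is not None else np.empty(0, int)
        )
        self.dirichlet_values = (
            np.asarray(dirichlet_values, dtype=float)
            if dirichlet_values is not None
            else np.zeros(len(self.dirichlet_cells))
        )
        self._pinned = len(self.dirichlet_cells) == 0
        self._lu = splu(self._build_poisson().tocsc())
        # full pressure vector with the Dirichlet values pre-filled
        self._p_template = np.zeros(grid.nx * grid.ny)
        if len(self.dirichlet_cells):
            self._p_template[self.dirichlet_cells] = self.dirichlet_values

    # -- setup -------------------------------------------------------------

    def initial_state(self) -> FlowState:
        g = self.grid
        return FlowState(
            u=np.zeros((g.nx + 1, g.ny)), v=np.zeros((g.nx, g.ny + 1)), p=np.zeros((g.nx, g.ny))
        )

    def _build_poisson(self) -> sp.coo_matrix:
        nx, ny = self.grid.nx, self.grid.ny
        n = nx * ny
        inv_h2 = 1.0 / self.grid.h**2
        idx = np.arange(n).reshape(nx, ny)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)

        def add(i_from, i_to):
            rows.append(i_from.ravel())
            cols.append(i_to.ravel())
            vals.append(np.full(i_from.size, inv_h2))

        # x neighbours
        add(idx[1:, :], idx[:-1, :])
        add(idx[:-1, :], idx[1:, :])
        if self.bc.periodic_x:
            add(idx[0:1, :], idx[-1:, :])
            add(idx[-1:, :], idx[0:1, :])
        # y neighbours
        add(idx[:, 1:], idx[:, :-1])
        add(idx[:, :-1], idx[:, 1:])
        if self.bc.periodic_y:
            add(idx[:, 0:1], idx[:, -1:])
            add(idx[:, -1:], idx[:, 0:1])

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        np.add.at(diag, rows, -inv_h2)

        dir_mask = np.zeros(n, dtype=bool)
        if len(self.dirichlet_cells):
            dir_mask[self.dirichlet_cells] = True
        if self._pinned:
            dir_mask[0] = True
        self._dir_mask = dir_mask

        # reduce to the non-Dirichlet cells; Dirichlet neighbours move to a
        # constant right-hand-side contribution (values are fixed per run)
        active = ~dir_mask
        self._active_idx = np.where(active)[0]
        renum = -np.ones(n, dtype=np.int64)
        renum[self._active_idx] = np.arange(len(self._active_idx))
        row_act = active[rows]
        r2, c2, v2 = rows[row_act], cols[row_act], vals[row_act]
        col_act = active[c2]
        a_rows = renum[r2[col_act]]
        a_cols = renum[c2[col_act]]
        a_vals = v2[col_act]
        n_act = len(self._active_idx)
        a_rows = np.concatenate([a_rows, np.arange(n_act)])
        a_cols = np.concatenate([a_cols, np.arange(n_act)])
        a_vals = np.concatenate([a_vals, diag[self._active_idx]])
        # constant RHS shift from Dirichlet neighbours
        shift = np.zeros(n_act)
        dir_links = ~col_act
        if dir_links.any() and len(self.dirichlet_cells):
            p_dir = np.zeros(n)
            p_dir[self.dirichlet_cells] = self.dirichlet_values
            np.add.at(shift, renum[r2[dir_links]], v2[dir_links] * p_dir[c2[dir_links]])
        self._dir_rhs_shift = shift
        return sp.coo_matrix((a_vals, (a_rows, a_cols)), shape=(n_act, n_act))

    # -- time step control --------------------------------------------------

    def stable_dt(self, state: FlowState) -> float:
        h = self.grid.h
        umax = state.max_speed()
        dt_conv = self.cfl * h / umax if umax > 0 else np.inf
        dt_diff = 0.9 * h**2 * self.props.rho / (4.0 * self.props.mu)
        return float(min(dt_conv, dt_diff, self.dt_cap))

    def _check_cfl(self, state: FlowState, dt: float) -> None:
        h = self.grid.h
        cu = np.abs(state.u) * dt / h
        cv = np.abs(state.v) * dt / h
        worst = max(cu.max(initial=0.0), cv.max(initial=0.0))
        if worst > 0.5 + 1e-12:
            if cu.max(initial=0.0) >= cv.max(initial=0.0):
                cell = np.unravel_index(int(np.argmax(cu)), cu.shape)
            else:
                cell = np.unravel_index(int(np.argmax(cv)), cv.shape)
            cell = tuple(int(c) for c in cell)
            raise CFLError(f"convective CFL {worst:.3f} > 0.5 at cell {cell}")
        dt_diff = self.grid.h**2 * self.props.rho / (4.0 * self.props.mu)
        if dt > dt_diff * (1 + 1e-12):
            raise CFLError(f"dt={dt:.3e}s exceeds explicit diffusion limit {dt_diff:.3e}s")

    # -- spatial operators ---------------------------------------------------

    def rhs(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Convective + diffusive + gravity RHS for both momentum components."""
        if _HAVE_NUMBA:
            U = _pad_u(u, self.bc)
            V = _pad_v(v, self.bc)
            gx, gy = self.props.g
            return _rhs_kernel(
                U, V, self.grid.h, self.props.nu, float(gx), float(gy),
                u.shape[0], u.shape[1], v.shape[0], v.shape[1],
            )
        return self._rhs_numpy(u, v)

    def _rhs_numpy(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pure-numpy reference implementation of :meth:`rhs`."""
        h = self.grid.h
        nu = self.props.nu
        gx, gy = self.props.g
        P = _PAD
        U = _pad_u(u, self.bc)
        V = _pad_v(v, self.bc)
        nxu, nyu = u.shape
        nxv, nyv = v.shape

        # ---- u momentum ----
        Uc = U[:, P : P + nyu]           # padded in x only
        # east/west faces (cell centres): advecting velocity
        ue = 0.5 * (Uc[P : P + nxu] + Uc[P + 1 : P + 1 + nxu])
        uw = 0.5 * (Uc[P - 1 : P - 1 + nxu] + Uc[P : P + nxu])
        ue_hat = _quick(Uc[P - 1 : P - 1 + nxu], Uc[P : P + nxu],
                        Uc[P + 1 : P + 1 + nxu], Uc[P + 2 : P + 2 + nxu], ue)
        uw_hat = _quick(Uc[P - 2 : P - 2 + nxu], Uc[P - 1 : P - 1 + nxu],
                        Uc[P : P + nxu], Uc[P + 1 : P + 1 + nxu], uw)
        # north/south faces (corners): advecting v averaged to u's x-position
        Vyy = V[:, :]                    # fully padded v
        # v faces straddling u[i]: padded v indices (P+i-1, P+i) in x,
        # y faces j+1 (north) and j (south) -> padded (P+j+1), (P+j)
        vn = 0.5 * (Vyy[P - 1 : P - 1 + nxu, P + 1 : P + 1 + nyu]
                    + Vyy[P : P + nxu, P + 1 : P + 1 + nyu])
        vs = 0.5 * (Vyy[P - 1 : P - 1 + nxu, P : P + nyu]
                    + Vyy[P : P + nxu, P : P + nyu])
        Ux = U[P : P + nxu, :]           # padded in y only (x already sliced)
        un_hat = _quick(Ux[:, P - 1 : P - 1 + nyu], Ux[:, P : P + nyu],
                        Ux[:, P + 1 : P + 1 + nyu], Ux[:, P + 2 : P + 2 + nyu], vn)
        us_hat = _quick(Ux[:, P - 2 : P - 2 + nyu], Ux[:, P - 1 : P - 1 + nyu],
                        Ux[:, P : P + nyu], Ux[:, P + 1 : P + 1 + nyu], vs)
        conv_u = (ue * ue_hat - uw * uw_hat) / h + (vn * un_hat - vs * us_hat) / h
        Upp = U[P - 1 : P + nxu + 1, P - 1 : P + nyu + 1]
        lap_u = (
            Upp[2:, 1:-1] + Upp[:-2, 1:-1] + Upp[1:-1, 2:] + Upp[1:-1, :-2]
            - 4.0 * Upp[1:-1, 1:-1]
        ) / h**2
        n_u = -conv_u + nu * lap_u + gx

        # ---- v momentum ----
        Vc = V[P : P + nxv, :]
        vn2 = 0.5 * (Vc[:, P : P + nyv] + Vc[:, P + 1 : P + 1 + nyv])
        vs2 = 0.5 * (Vc[:, P - 1 : P - 1 + nyv] + Vc[:, P : P + nyv])
        vn_hat = _quick(Vc[:, P - 1 : P - 1 + nyv], Vc[:, P : P + nyv],
                        Vc[:, P + 1 : P + 1 + nyv], Vc[:, P + 2 : P + 2 + nyv], vn2)
        vs_hat = _quick(Vc[:, P - 2 : P - 2 + nyv], Vc[:, P - 1 : P - 1 + nyv],
                        Vc[:, P : P + nyv], Vc[:, P + 1 : P + 1 + nyv], vs2)
        ue2 = 0.5 * (U[P + 1 : P + 1 + nxv, P - 1 : P - 1 + nyv]
                     + U[P + 1 : P + 1 + nxv, P : P + nyv])
        uw2 = 0.5 * (U[P : P + nxv, P - 1 : P - 1 + nyv]
                     + U[P : P + nxv, P : P + nyv])
        Vx = V[:, P : P + nyv]
        ve_hat = _quick(Vx[P - 1 : P - 1 + nxv], Vx[P : P + nxv],
                        Vx[P + 1 : P + 1 + nxv], Vx[P + 2 : P + 2 + nxv], ue2)
        vw_hat = _quick(Vx[P - 2 : P - 2 + nxv], Vx[P - 1 : P - 1 + nxv],
                        Vx[P : P + nxv], Vx[P + 1 : P + 1 + nxv], uw2)
        conv_v = (ue2 * ve_hat - uw2 * vw_hat) / h + (vn2 * vn_hat - vs2 * vs_hat) / h
        Vpp = V[P - 1 : P + nxv + 1, P - 1 : P + nyv + 1]
        lap_v = (
            Vpp[2:, 1:-1] + Vpp[:-2, 1:-1] + Vpp[1:-1, 2:] + Vpp[1:-1, :-2]
            - 4.0 * Vpp[1:-1, 1:-1]
        ) / h**2
        n_v = -conv_v + nu * lap_v + gy
        return n_u, n_v

    # -- BC enforcement ------------------------------------------------------

    def apply_velocity_bc(self, u: np.ndarray, v: np.ndarray) -> None:
        bc = self.bc
        if bc.periodic_x:
            u[-1, :] = u[0, :]
        else:
            if bc.left == "wall":
                u[0, :] = 0.0
            else:
                u[0, :] = u[1, :]
            if bc.right == "wall":
                u[-1, :] = 0.0
            else:
                u[-1, :] = u[-2, :]
        if bc.periodic_y:
            v[:, -1] = v[:, 0]
        else:
            if bc.bottom == "wall":
                v[:, 0] = 0.0
            else:
                v[:, 0] = v[:, 1]
            if bc.top == "wall":
                v[:, -1] = 0.0
            else:
                v[:, -1] = v[:, -2]

    # -- fractional step pieces ----------------------------------------------

    def predict_velocity(
        self, state: FlowState, dt: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Explicit AB2 predictor.  Returns (u*, v*, n_u, n_v)."""
        self._check_cfl(state, dt)
        n_u, n_v = self.rhs(state.u, state.v)
        if state.nu_prev is None or state.dt_prev is None:
            ustar = state.u + dt * n_u
            vstar = state.v + dt * n_v
        else:
            beta = dt / (2.0 * state.dt_prev)
            ustar = state.u + dt * ((1.0 + beta) * n_u - beta * state.nu_prev)
            vstar = state.v + dt * ((1.0 + beta) * n_v - beta * state.nv_prev)
        return ustar, vstar, n_u, n_v

    @staticmethod
    def apply_immersed_boundaries(ustar, vstar, alpha_u, alpha_v, u_solid, v_solid):
        """Blend face velocities toward local solid velocities with weight alpha."""
        ustar = ustar + alpha_u * (u_solid - ustar)
        vstar = vstar + alpha_v * (v_solid - vstar)
        return ustar, vstar

    def divergence(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        h = self.grid.h
        return (u[1:, :] - u[:-1, :]) / h + (v[:, 1:] - v[:, :-1]) / h

    def pressure_projection(
        self, ustar: np.ndarray, vstar: np.ndarray, dt: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Solve the pressure Poisson equation and project to divergence-free."""
        g = self.grid
        h = g.h
        rho = self.props.rho
        div = self.divergence(ustar, vstar)
        rhs = (rho / dt) * div.ravel()
        if self._pinned:
            rhs = rhs - rhs.mean()  # compatibility for the pure-Neumann problem
        rhs_act = rhs[self._active_idx] - self._dir_rhs_shift
        p_full = self._p_template.copy()
        p_full[self._active_idx] = self._lu.solve(rhs_act)
        p = p_full.reshape(g.nx, g.ny)
        u = ustar.copy()
        v = vstar.copy()
        c = dt / rho / h
        u[1:-1, :] -= c * (p[1:, :] - p[:-1, :])
        v[:, 1:-1] -= c * (p[:, 1:] - p[:, :-1])
        if self.bc.periodic_x:
            u[0, :] -= c * (p[0, :] - p[-1, :])
            u[-1, :] = u[0, :]
        if self.bc.periodic_y:
            v[:, 0] -= c * (p[:, 0] - p[:, -1])
            v[:, -1] = v[:, 0]
        self.apply_velocity_bc(u, v)
        return p, u, v

    # -- full step -----------------------------------------------------------

    def step(self, state: FlowState, dt: float | None = None, forcing=None) -> FlowState:
        """One fractional step: predict -> force -> project.

        ``forcing`` is None or a callable ``t_new -> (alpha_u, alpha_v,
        u_solid, v_solid)`` giving solid fractions and target velocities on
        the u- and v-face grids.
        """
        if dt is None:
            dt = self.stable_dt(state)
        ustar, vstar, n_u, n_v = self.predict_velocity(state, dt)
        self.apply_velocity_bc(ustar, vstar)
        t_new = state.t + dt
        alpha_u = alpha_v = None
        imp = (0.0, 0.0)
        if forcing is not None:
            alpha_u, alpha_v, us, vs = forcing(t_new)
            u_before, v_before = ustar, vstar
            ustar, vstar = self.apply_immersed_boundaries(ustar, vstar, alpha_u, alpha_v, us, vs)
            self.apply_velocity_bc(ustar, vstar)
            cell = self.props.rho * self.grid.h**2
            imp = (
                float(np.sum(ustar[1:-1, :] - u_before[1:-1, :]) * cell),
                float(np.sum(vstar[:, 1:-1] - v_before[:, 1:-1]) * cell),
            )
        p, u, v = self.pressure_projection(ustar, vstar, dt)
        return FlowState(
            u=u, v=v, p=p, t=t_new, nu_prev=n_u, nv_prev=n_v, dt_prev=dt,
            alpha_u=alpha_u, alpha_v=alpha_v, forcing_impulse=imp,
        )

    # -- sampling helpers ----------------------------------------------------

    def sample_pressure(self, p: np.ndarray, pts: np.ndarray) -> np.ndarray:
        x0, y0 = self.grid.origin
        h = self.grid.h
        return bilinear_sample(p, x0 + h / 2, y0 + h / 2, h, pts)

    def sample_velocity(self, u: np.ndarray, v: np.ndarray, pts: np.ndarray) -> np.ndarray:
        x0, y0 = self.grid.origin
        h = self.grid.h
        uu = bilinear_sample(u, x0, y0 + h / 2, h, pts)
        vv = bilinear_sample(v, x0 + h / 2, y0, h, pts)
        return np.column_stack([uu, vv])

    def centre_velocity(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centred velocity components (for gradients and output)."""
        uc = 0.5 * (u[1:, :] + u[:-1, :])
        vc = 0.5 * (v[:, 1:] + v[:, :-1])
        return uc, vc

    def velocity_gradients(self, u: np.ndarray, v: np.ndarray):
        """Cell-centred velocity gradient tensor components."""
        h = self.grid.h
        uc, vc = self.centre_velocity(u, v)
        dudx = np.gradient(uc, h, axis=0)
        dudy = np.gradient(uc, h, axis=1)
        dvdx = np.gradient(vc, h, axis=0)
        dvdy = np.gradient(vc, h, axis=1)
        return dudx, dudy, dvdx, dvdy
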