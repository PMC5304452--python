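"""Incompressible glottal flow on a staggered Cartesian grid.

Unsteady viscous incompressible Navier-Stokes, solved with a fractional
step (projection) method: explicit advection (central differences with an
optional first-order upwind blend for robustness in the glottal jet) and
explicit diffusion build a provisional velocity; a pressure Poisson solve
with a direct sparse factorization projects it onto the discretely
divergence-free space.  Velocities live on cell faces (MAC arrangement),
pressure at cell centers.

The moving vocal folds are immersed through a sharp-interface ghost-cell
method: velocity nodes just inside the solid mirror the fluid field about
the boundary so the interpolated wall velocity equals the local tissue
velocity; pressure sees the wall as a zero-normal-gradient boundary.

Driving: Dirichlet gauge pressures at the inlet (+dP) and outlet (0) with
zero-gradient velocity, matching a prescribed transglottal pressure drop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import GridSpec
from .immersed import FLUID, GHOST, SOLID, GhostMirror, classify

__all__ = [
    "FluidProperties",
    "FlowState",
    "FlowSolver",
    "classify_cells",
    "material_derivative_P",
]


@dataclass
class FluidProperties:
    """Air constants: density (kg/m^3), kinematic viscosity (m^2/s) and the
    driving transglottal pressure drop (Pa)."""

    rho0: float = 1.1455
    nu0: float = 6.6e-5
    dp_drive: float = 800.0

    def __post_init__(self) -> None:
        if min(self.rho0, self.nu0) <= 0:
            raise ValueError("density and viscosity must be strictly positive")


@dataclass
class FlowState:
    u: np.ndarray          # (nx+1, ny) x-face velocities
    v: np.ndarray          # (nx, ny+1) y-face velocities
    p: np.ndarray          # (nx, ny) cell-center gauge pressure
    t: float = 0.0
    tags: np.ndarray | None = None  # cell-center FLUID/GHOST/SOLID
    div_residual: float = 0.0

    def copy(self) -> "FlowState":
        return FlowState(
            self.u.copy(), self.v.copy(), self.p.copy(), self.t,
            None if self.tags is None else self.tags.copy(), self.div_residual,
        )


def classify_cells(grid: GridSpec, levelset) -> np.ndarray:
    """FLUID/GHOST/SOLID tags at cell centers from a level set."""
    mesh = grid.center_mesh()
    pts = np.column_stack([m.ravel() for m in mesh])
    phi = np.asarray(levelset.sample(pts)).reshape(grid.shape)
    return classify(phi)


def material_derivative_P(
    state_prev: FlowState, state_new: FlowState, dt: float, grid: GridSpec
) -> np.ndarray:
    """DP/Dt = (P_new - P_prev)/dt + U_new . grad(P_new) at cell centers.

    This is the acoustic source term handed to the LPCE solver.  Central
    differences, one-sided next to non-fluid cells; zero on ghost/solid.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state_new.p
    dpdt = (p - state_prev.p) / dt
    uc, vc = face_to_center(state_new.u, state_new.v)
    gx = _center_gradient(p, grid.centers(0), axis=0, tags=state_new.tags)
    gy = _center_gradient(p, grid.centers(1), axis=1, tags=state_new.tags)
    out = dpdt + uc * gx + vc * gy
    if state_new.tags is not None:
        out[state_new.tags != FLUID] = 0.0
    return out


def face_to_center(u: np.ndarray, v: np.ndarray):
    """Average MAC face velocities to cell centers."""
    uc = 0.5 * (u[:-1, :] + u[1:, :])
    vc = 0.5 * (v[:, :-1] + v[:, 1:])
    return uc, vc


def _center_gradient(f, coords, axis, tags=None):
    """Second-order gradient at centers; one-sided where a neighbor is not
    fluid so wall pressure never leaks into the fluid stencil."""
    g = np.zeros_like(f)
    f_ = np.moveaxis(f, axis, 0)
    g_ = np.moveaxis(g, axis, 0)
    c = coords
    g_[1:-1] = (f_[2:] - f_[:-2]) / (c[2:] - c[:-2])[:, None]
    g_[0] = (f_[1] - f_[0]) / (c[1] - c[0])
    g_[-1] = (f_[-1] - f_[-2]) / (c[-1] - c[-2])
    if tags is not None:
        okm = np.moveaxis(tags == FLUID, axis, 0)
        fwd = np.zeros_like(g_)
        bwd = np.zeros_like(g_)
        fwd[:-1] = (f_[1:] - f_[:-1]) / np.diff(c)[:, None]
        bwd[1:] = fwd[:-1]
        use_fwd = np.zeros_like(okm)
        use_bwd = np.zeros_like(okm)
        use_fwd[1:-1] = ~okm[:-2] & okm[2:]
        use_bwd[1:-1] = ~okm[2:] & okm[:-2]
        g_[use_fwd] = fwd[use_fwd]
        g_[use_bwd] = bwd[use_bwd]
        dead = np.zeros_like(okm)
        dead[1:-1] = ~okm[:-2] & ~okm[2:]
        g_[dead] = 0.0
    return g


class FieldSampler:
    """Bilinear sampling of a cell-centered field restricted to fluid cells.

    Stencil weights at non-fluid cells are zeroed and renormalized; points
    whose whole stencil is non-fluid fall back to the nearest fluid cell.
    """

    def __init__(self, grid: GridSpec, fluid_mask: np.ndarray):
        from scipy import ndimage

        self.coords = [grid.centers(i) for i in range(grid.dim)]
        self.shape = fluid_mask.shape
        self.fluid_flat = fluid_mask.ravel()
        _, nearest = ndimage.distance_transform_edt(~fluid_mask, return_indices=True)
        self.nearest_flat = np.ravel_multi_index(
            tuple(nearest[ax] for ax in range(len(self.shape))), self.shape
        ).ravel()

    def sample(self, field: np.ndarray, points: np.ndarray) -> np.ndarray:
        from .immersed import _multilinear_stencil

        points = np.atleast_2d(points)
        idx, w = _multilinear_stencil(self.coords, points)
        flat = np.ravel_multi_index(
            tuple(
                np.clip(idx[..., ax], 0, self.shape[ax] - 1)
                for ax in range(len(self.shape))
            ),
            self.shape,
        )
        w = np.where(self.fluid_flat[flat], w, 0.0)
        tot = w.sum(axis=1)
        bad = tot <= 1e-12
        if np.any(bad):
            # nearest-fluid fallback for markers hugging the wall
            cell = np.ravel_multi_index(
                tuple(
                    np.clip(
                        np.searchsorted(self.coords[ax], points[bad, ax]) - 1,
                        0,
                        self.shape[ax] - 1,
                    )
                    for ax in range(len(self.shape))
                ),
                self.shape,
            )
            flat[bad, 0] = self.nearest_flat[cell]
            w[bad] = 0.0
            w[bad, 0] = 1.0
            tot = w.sum(axis=1)
        return (field.ravel()[flat] * w).sum(axis=1) / tot


class FlowSolver:
    """Fractional-step MAC solver on one 2D grid.

    ``edge_bc`` maps ``(axis, side)`` to ``("pressure", value)``,
    ``("wall",)`` or ``("velocity", fn)`` where ``fn(x, y, t)`` returns the
    (u, v) pair on that edge.  Default: pressure inlet at y-min (gauge
    ``props.dp_drive``), pressure outlet 0 at y-max, walls on the sides.
    ``upwind`` in [0, 1] blends a first-order upwind derivative into the
    central advection scheme (0 = pure second order).
    """

    def __init__(
        self,
        grid: GridSpec,
        props: FluidProperties,
        levelset=None,
        edge_bc: dict | None = None,
        upwind: float = 0.15,
        forcing=None,
    ):
        if grid.dim != 2:
            raise NotImplementedError("the incompressible solver is 2D")
        self.grid = grid
        self.props = props
        self.upwind = float(upwind)
        self.forcing = forcing
        self.xf, self.yf = grid.axes
        self.xc, self.yc = grid.centers(0), grid.centers(1)
        self.dx, self.dy = grid.widths(0), grid.widths(1)

        def _pad(c):
            return np.concatenate(([2 * c[0] - c[1]], c, [2 * c[-1] - c[-2]]))

        self._xfp, self._ycp = _pad(self.xf), _pad(self.yc)
        self._xcp, self._yfp = _pad(self.xc), _pad(self.yf)
        self.edge_bc = {
            (1, 0): ("pressure", props.dp_drive),
            (1, 1): ("pressure", 0.0),
            (0, 0): ("wall",),
            (0, 1): ("wall",),
        }
        if edge_bc:
            self.edge_bc.update(edge_bc)
        self._lu = None
        self._lu_key = None
        self.set_levelset(levelset)

    # ------------------------------------------------------------------ geometry
    def set_levelset(self, levelset, boundary_velocity=None) -> None:
        """Install (or move) the immersed boundary.

        ``boundary_velocity(points) -> (K, 2)`` gives the local tissue
        velocity; defaults to zero (rigid walls).
        """
        self.levelset = levelset
        self.boundary_velocity = boundary_velocity
        nx, ny = self.grid.shape
        if levelset is None:
            self.tags = np.full((nx, ny), FLUID, dtype=np.int8)
            self.mirror_u = self.mirror_v = None
            self.sampler = FieldSampler(self.grid, np.ones((nx, ny), bool))
            self.fluid_u = np.ones((nx + 1, ny), bool)
            self.fluid_v = np.ones((nx, ny + 1), bool)
            return
        self.tags = classify_cells(self.grid, levelset)
        self.mirror_u = GhostMirror([self.xf, self.yc], levelset)
        self.mirror_v = GhostMirror([self.xc, self.yf], levelset)
        self.fluid_u = self.mirror_u.tags == FLUID
        self.fluid_v = self.mirror_v.tags == FLUID
        self.sampler = FieldSampler(self.grid, self.tags == FLUID)

    def initial_state(self) -> FlowState:
        nx, ny = self.grid.shape
        return FlowState(
            np.zeros((nx + 1, ny)), np.zeros((nx, ny + 1)), np.zeros((nx, ny)),
            0.0, self.tags.copy(),
        )

    # ------------------------------------------------------------------ helpers
    def _boundary_velocity_at(self, mirror: GhostMirror, comp: int) -> np.ndarray:
        if mirror.n_ghost == 0:
            return np.zeros(0)
        if self.boundary_velocity is None:
            return np.zeros(mirror.n_ghost)
        return np.asarray(self.boundary_velocity(mirror.boundary_points))[:, comp]

    def _apply_immersed(self, u: np.ndarray, v: np.ndarray) -> None:
        """Ghost mirror + solid fill for both velocity components.

        These values make interpolated wall velocities correct in the
        momentum stencils; they are NOT physical fluxes (see
        :meth:`_apply_wall_flux`)."""
        for mirror, f, comp in ((self.mirror_u, u, 0), (self.mirror_v, v, 1)):
            if mirror is None:
                continue
            solid = mirror.tags == SOLID
            if np.any(solid):
                f[solid] = 0.0
            if mirror.n_ghost:
                ub = self._boundary_velocity_at(mirror, comp)
                vi = mirror.image_values(f)
                f[mirror.ghost_index] = 2.0 * ub - vi

    def _apply_wall_flux(self, u: np.ndarray, v: np.ndarray) -> None:
        """Impose the physical wall-normal flux on every closed face.

        The continuity (projection) step sees the wall at cell
        granularity: an interior face is open only when both adjacent
        pressure cells are fluid; every other interior face carries
        exactly the local tissue velocity component (zero for static
        walls).  Mirrored ghost values would leak mass through the
        immersed boundary; they are used only in the momentum stencils.
        """
        fluid = self.tags == FLUID
        if np.all(fluid):
            return
        fx_open = fluid[:-1, :] & fluid[1:, :]
        fy_open = fluid[:, :-1] & fluid[:, 1:]
        if self.boundary_velocity is None:
            u[1:-1, :] = np.where(fx_open, u[1:-1, :], 0.0)
            v[:, 1:-1] = np.where(fy_open, v[:, 1:-1], 0.0)
            return
        closed_u = np.argwhere(~fx_open)
        if closed_u.size:
            pts = np.column_stack(
                [self.xf[closed_u[:, 0] + 1], self.yc[closed_u[:, 1]]]
            )
            u[closed_u[:, 0] + 1, closed_u[:, 1]] = np.asarray(
                self.boundary_velocity(pts)
            )[:, 0]
        closed_v = np.argwhere(~fy_open)
        if closed_v.size:
            pts = np.column_stack(
                [self.xc[closed_v[:, 0]], self.yf[closed_v[:, 1] + 1]]
            )
            v[closed_v[:, 0], closed_v[:, 1] + 1] = np.asarray(
                self.boundary_velocity(pts)
            )[:, 1]

    def _apply_edges(self, u: np.ndarray, v: np.ndarray, t: float) -> None:
        """On-face edge values (ghost rows/columns are handled in padding)."""
        for (axis, side), bc in self.edge_bc.items():
            kind = bc[0]
            if axis == 0:
                i = -1 if side else 0
                if kind == "wall":
                    u[i, :] = 0.0
                elif kind == "velocity":
                    u[i, :] = bc[1](self.xf[i], self.yc, t)[0]
                elif kind == "pressure":
                    u[i, :] = u[-2 if side else 1, :]
            else:
                j = -1 if side else 0
                if kind == "wall":
                    v[:, j] = 0.0
                elif kind == "velocity":
                    v[:, j] = bc[1](self.xc, self.yf[j], t)[1]
                elif kind == "pressure":
                    v[:, j] = v[:, -2 if side else 1]

    def _ghost_pad(self, f: np.ndarray, grid_kind: str, t: float) -> np.ndarray:
        """Pad one ghost layer on every side encoding the edge conditions.

        grid_kind: "u" (x-face nodes) or "v" (y-face nodes).  Tangential
        walls reflect (no slip), pressure edges copy (zero gradient),
        velocity edges impose the prescribed value by linear reflection.
        Normal components live on the boundary face itself and are already
        set; their ghosts are linear extrapolations.
        """
        g = np.pad(f, 1, mode="edge")
        tang_coords = (
            (self._xfp[1:-1], self._ycp[1:-1])
            if grid_kind == "u"
            else (self._xcp[1:-1], self._yfp[1:-1])
        )
        for (axis, side), bc in self.edge_bc.items():
            kind = bc[0]
            normal = (grid_kind == "u") == (axis == 0)
            sl_ghost = _edge_slice(g.shape, axis, -1 if side else 0)
            if normal:
                inner0 = _edge_slice(g.shape, axis, -2 if side else 1)
                inner1 = _edge_slice(g.shape, axis, -3 if side else 2)
                g[sl_ghost] = 2.0 * g[inner0] - g[inner1]
                continue
            inner = _edge_slice(g.shape, axis, -2 if side else 1)
            if kind == "wall":
                g[sl_ghost] = -g[inner]
            elif kind == "pressure":
                g[sl_ghost] = g[inner]
            elif kind == "velocity":
                comp = 0 if grid_kind == "u" else 1
                tang = tang_coords[1 - axis]
                if axis == 0:
                    wx = self.xf[-1] if side else self.xf[0]
                    wall_val = np.asarray(bc[1](wx, tang, t)[comp])
                else:
                    wy = self.yf[-1] if side else self.yf[0]
                    wall_val = np.asarray(bc[1](tang, wy, t)[comp])
                ghost = 2.0 * wall_val - g[inner][1:-1]
                g[sl_ghost][1:-1] = ghost
        return g

    # ------------------------------------------------------------------ operators
    def divergence(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return (u[1:, :] - u[:-1, :]) / self.dx[:, None] + (
            v[:, 1:] - v[:, :-1]
        ) / self.dy[None, :]

    def _advect_diffuse(self, u, v, t):
        """Explicit momentum right-hand side (advection + diffusion + forcing)."""
        nu = self.props.nu0
        up = self._ghost_pad(u, "u", t)  # (nx+3, ny+2)
        vp = self._ghost_pad(v, "v", t)  # (nx+2, ny+3)
        xf, yf, xc, yc = self.xf, self.yf, self.xc, self.yc
        th = self.upwind

        # --- u momentum at interior x-faces i=1..nx-1, all j
        uc = up[1:-1, 1:-1]  # u itself
        uW, uE = up[:-2, 1:-1], up[2:, 1:-1]
        uS, uN = up[1:-1, :-2], up[1:-1, 2:]
        xfp, ycp = self._xfp, self._ycp
        dxW = (xfp[1:-1] - xfp[:-2])[:, None]
        dxE = (xfp[2:] - xfp[1:-1])[:, None]
        dyS = (ycp[1:-1] - ycp[:-2])[None, :]
        dyN = (ycp[2:] - ycp[1:-1])[None, :]
        dudx_c = (uE - uW) / (dxW + dxE)
        dudy_c = (uN - uS) / (dyS + dyN)
        dudx_up = np.where(uc >= 0, (uc - uW) / dxW, (uE - uc) / dxE)
        # v interpolated to u-nodes: average of the 4 surrounding v faces
        v4 = 0.25 * (vp[:-1, 1:-2] + vp[1:, 1:-2] + vp[:-1, 2:-1] + vp[1:, 2:-1])
        dudy_up = np.where(v4 >= 0, (uc - uS) / dyS, (uN - uc) / dyN)
        adv_u = uc * ((1 - th) * dudx_c + th * dudx_up) + v4 * (
            (1 - th) * dudy_c + th * dudy_up
        )
        lap_u = ((uE - uc) / dxE - (uc - uW) / dxW) / (0.5 * (dxW + dxE)) + (
            (uN - uc) / dyN - (uc - uS) / dyS
        ) / (0.5 * (dyS + dyN))
        rhs_u = -adv_u + nu * lap_u

        # --- v momentum at interior y-faces, all i
        vc = vp[1:-1, 1:-1]
        vW, vE = vp[:-2, 1:-1], vp[2:, 1:-1]
        vS, vN = vp[1:-1, :-2], vp[1:-1, 2:]
        xcp, yfp = self._xcp, self._yfp
        dxW_v = (xcp[1:-1] - xcp[:-2])[:, None]
        dxE_v = (xcp[2:] - xcp[1:-1])[:, None]
        dyS_v = (yfp[1:-1] - yfp[:-2])[None, :]
        dyN_v = (yfp[2:] - yfp[1:-1])[None, :]
        u4 = 0.25 * (up[1:-2, :-1] + up[1:-2, 1:] + up[2:-1, :-1] + up[2:-1, 1:])
        dvdx_c = (vE - vW) / (dxW_v + dxE_v)
        dvdy_c = (vN - vS) / (dyS_v + dyN_v)
        dvdx_up = np.where(u4 >= 0, (vc - vW) / dxW_v, (vE - vc) / dxE_v)
        dvdy_up = np.where(vc >= 0, (vc - vS) / dyS_v, (vN - vc) / dyN_v)
        adv_v = u4 * ((1 - th) * dvdx_c + th * dvdx_up) + vc * (
            (1 - th) * dvdy_c + th * dvdy_up
        )
        lap_v = ((vE - vc) / dxE_v - (vc - vW) / dxW_v) / (0.5 * (dxW_v + dxE_v)) + (
            (vN - vc) / dyN_v - (vc - vS) / dyS_v
        ) / (0.5 * (dyS_v + dyN_v))
        rhs_v = -adv_v + nu * lap_v

        if self.forcing is not None:
            fu, fv = self.forcing
            Xu, Yu = np.meshgrid(xf, yc, indexing="ij")
            Xv, Yv = np.meshgrid(xc, yf, indexing="ij")
            rhs_u = rhs_u + fu(Xu, Yu, t)
            rhs_v = rhs_v + fv(Xv, Yv, t)
        return rhs_u, rhs_v

    # ------------------------------------------------------------------ Poisson
    def _build_poisson(self):
        nx, ny = self.grid.shape
        fluid = self.tags == FLUID
        idx = -np.ones((nx, ny), dtype=np.int64)
        idx[fluid] = np.arange(np.count_nonzero(fluid))
        n = idx.max() + 1
        rows, cols, vals = [], [], []
        bc_rows, bc_coeff, bc_key = [], [], []
        diag = np.zeros(n)
        has_dirichlet = False

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        xc, yc, dx, dy = self.xc, self.yc, self.dx, self.dy
        for i in range(nx):
            for j in range(ny):
                r = idx[i, j]
                if r < 0:
                    continue
                # four faces: (axis, dir)
                for axis, d in ((0, -1), (0, 1), (1, -1), (1, 1)):
                    ii, jj = i + (d if axis == 0 else 0), j + (d if axis == 1 else 0)
                    area = dy[j] if axis == 0 else dx[i]
                    inside = 0 <= ii < nx and 0 <= jj < ny
                    if inside:
                        if idx[ii, jj] >= 0:
                            dist = abs((xc[ii] - xc[i]) if axis == 0 else (yc[jj] - yc[j]))
                            T = area / dist
                            add(r, idx[ii, jj], T)
                            diag[r] -= T
                        # ghost/solid neighbor: Neumann, skip
                    else:
                        bc = self.edge_bc[(axis, 0 if d < 0 else 1)]
                        if bc[0] == "pressure":
                            if axis == 0:
                                dist = (xc[i] - self.xf[0]) if d < 0 else (self.xf[-1] - xc[i])
                            else:
                                dist = (yc[j] - self.yf[0]) if d < 0 else (self.yf[-1] - yc[j])
                            T = area / dist
                            diag[r] -= T
                            bc_rows.append(r)
                            bc_coeff.append(T)
                            bc_key.append((axis, 0 if d < 0 else 1))
                            has_dirichlet = True
                        # wall/velocity edge: Neumann, skip
        for r, v in enumerate(diag):
            add(r, r, v)
        L = sp.csr_matrix(
            (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(n, n)
        )
        pin = None
        if not has_dirichlet:
            pin = 0
            L = L.tolil()
            L[pin, :] = 0.0
            L[pin, pin] = 1.0
            L = L.tocsr()
        return {
            "idx": idx,
            "n": n,
            "lu": spla.splu(L.tocsc()),
            "bc": (np.asarray(bc_rows, dtype=np.int64), np.asarray(bc_coeff), bc_key),
            "pin": pin,
        }

    def _poisson(self):
        key = self.tags.tobytes()
        if self._lu is None or self._lu_key != key:
            self._lu = self._build_poisson()
            self._lu_key = key
        return self._lu

    # ------------------------------------------------------------------ stepping
    @staticmethod
    def _bc_value(bc, t: float) -> float:
        v = bc[1]
        return float(v(t)) if callable(v) else float(v)

    def stable_dt(self, state: FlowState, cfl: float = 0.4) -> float:
        umax = max(float(np.abs(state.u).max()), 1e-12)
        vmax = max(float(np.abs(state.v).max()), 1e-12)
        adv = cfl / (umax / self.dx.min() + vmax / self.dy.min())
        visc = 0.5 / (self.props.nu0 * (1 / self.dx.min() ** 2 + 1 / self.dy.min() ** 2))
        return min(adv, visc)

    def step(self, state: FlowState, dt: float) -> FlowState:
        """Advance one fractional step of length dt."""
        rho = self.props.rho0
        u = state.u.copy()
        v = state.v.copy()
        t = state.t
        self._apply_edges(u, v, t)
        self._apply_immersed(u, v)
        rhs_u, rhs_v = self._advect_diffuse(u, v, t)
        us = u + dt * rhs_u
        vs = v + dt * rhs_v
        self._apply_edges(us, vs, t + dt)
        self._apply_wall_flux(us, vs)

        ps = self._poisson()
        idx, n = ps["idx"], ps["n"]
        fluid = idx >= 0
        div = self.divergence(us, vs)
        cellvol = self.dx[:, None] * self.dy[None, :]
        rhs = (rho / dt) * (div * cellvol)[fluid]
        bc_rows, bc_coeff, bc_key = ps["bc"]
        if bc_rows.size:
            bc_val = np.array(
                [self._bc_value(self.edge_bc[k], t + dt) for k in bc_key]
            )
            np.subtract.at(rhs, bc_rows, bc_coeff * bc_val)
        if ps["pin"] is not None:
            rhs -= rhs.mean()
            rhs[ps["pin"]] = 0.0
        pvec = ps["lu"].solve(rhs)
        if not np.all(np.isfinite(pvec)):
            raise RuntimeError("pressure Poisson solve failed (non-finite result)")
        p = np.zeros_like(state.p)
        p[fluid] = pvec

        un, vn = us, vs
        # interior x-faces between two fluid cells
        fx = fluid[:-1, :] & fluid[1:, :]
        dxd = (self.xc[1:] - self.xc[:-1])[:, None]
        un[1:-1, :] = np.where(
            fx, un[1:-1, :] - (dt / rho) * (p[1:, :] - p[:-1, :]) / dxd, un[1:-1, :]
        )
        fy = fluid[:, :-1] & fluid[:, 1:]
        dyd = (self.yc[1:] - self.yc[:-1])[None, :]
        vn[:, 1:-1] = np.where(
            fy, vn[:, 1:-1] - (dt / rho) * (p[:, 1:] - p[:, :-1]) / dyd, vn[:, 1:-1]
        )
        # pressure-driven boundary faces (inlet/outlet)
        for (axis, side), bc in self.edge_bc.items():
            if bc[0] != "pressure":
                continue
            p_bc = self._bc_value(bc, t + dt)
            if axis == 1:
                j = -1 if side else 0
                jc = -1 if side else 0
                dist = (self.yf[-1] - self.yc[-1]) if side else (self.yc[0] - self.yf[0])
                sgn = 1.0 if side else -1.0
                grad = sgn * (p_bc - p[:, jc]) / dist
                vn[:, j] = np.where(fluid[:, jc], vn[:, j] - (dt / rho) * grad, vn[:, j])
            else:
                i = -1 if side else 0
                ic = -1 if side else 0
                dist = (self.xf[-1] - self.xc[-1]) if side else (self.xc[0] - self.xf[0])
                sgn = 1.0 if side else -1.0
                grad = sgn * (p_bc - p[ic, :]) / dist
                un[i, :] = np.where(fluid[ic, :], un[i, :] - (dt / rho) * grad, un[i, :])

        if not (np.all(np.isfinite(un)) and np.all(np.isfinite(vn))):
            raise RuntimeError("flow field became non-finite")
        res = self.divergence(un, vn)[fluid]
        scale = max(np.abs(un).max(), np.abs(vn).max(), 1.0) / min(
            self.dx.min(), self.dy.min()
        )
        new = FlowState(un, vn, p, t + dt, self.tags.copy(), float(np.abs(res).max() / scale))
        return new

    # ------------------------------------------------------------------ measures
    def outlet_flowrate(self, state: FlowState, y_plane: float | None = None) -> float:
        """Volume flux (per unit depth, m^2/s) through an axial plane."""
        if y_plane is None:
            y_plane = float(self.yf[-1])
        if not (self.yf[0] - 1e-9 <= y_plane <= self.yf[-1] + 1e-9):
            raise ValueError(f"plane y={y_plane} outside the domain")
        j = int(np.argmin(np.abs(self.yf - y_plane)))
        vrow = state.v[:, j]
        fluid = self.tags == FLUID
        if j == 0:
            ok = fluid[:, 0]
        elif j == self.grid.shape[1]:
            ok = fluid[:, -1]
        else:
            ok = fluid[:, j - 1] & fluid[:, j]
        return float(np.sum(np.where(ok, vrow, 0.0) * self.dx))

    def center_velocity(self, state: FlowState):
        return face_to_center(state.u, state.v)


def _edge_slice(shape, axis, index):
    sl = [slice(None)] * len(shape)
    sl[axis] = index
    return tuple(sl)
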