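"""Linearized perturbed compressible equations (LPCE) acoustic solver.

The acoustic field (density, velocity and pressure perturbations rho',
u', p') rides on the incompressible solution (U, P): it is advected by U,
driven by the material derivative DP/Dt of the incompressible pressure,
and exchanges energy through the gamma*P*div(u') and (u'.grad)P terms,
where P is the absolute base pressure (ambient + incompressible gauge).

Discretization: sixth-order central compact (Pade) finite differences in
space with third/fourth-order one-sided closures at boundary points, a
classical four-stage Runge-Kutta integrator in time, an optional
eighth-order low-pass filter to suppress odd-even modes of the compact
scheme, and ghost-cell mirrors on immersed walls.  Works in 1, 2 or 3
dimensions on (possibly non-uniform) tensor grids via the index-space
metric transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _K
from .grid import GridSpec
from .immersed import FLUID as FLUID_TAG, GHOST as GHOST_TAG, SOLID, GhostMirror

__all__ = [
    "AcousticProperties",
    "AcousticState",
    "compact_derivative",
    "LpceSolver",
    "acoustic_energy",
]


@dataclass
class AcousticProperties:
    """Acoustic medium constants.

    The ambient absolute pressure is tied to the speed of sound through
    c = sqrt(gamma * P_amb / rho0); when not given it is derived from c,
    when given it must be consistent to 0.1%.
    """

    gamma: float = 1.4
    c: float = 352.0
    P_amb: float | None = None

    def ambient_pressure(self, rho0: float) -> float:
        p_amb = self.c**2 * rho0 / self.gamma
        if self.P_amb is not None:
            c_check = np.sqrt(self.gamma * self.P_amb / rho0)
            if abs(c_check - self.c) > 1e-3 * self.c:
                raise ValueError(
                    f"P_amb={self.P_amb} inconsistent with c={self.c} "
                    f"(implies c={c_check:.4g})"
                )
            return self.P_amb
        return p_amb


@dataclass
class AcousticState:
    rho: np.ndarray           # density perturbation (kg/m^3)
    u: list                   # velocity perturbation components (m/s)
    p: np.ndarray             # pressure perturbation (Pa)
    t: float = 0.0

    @classmethod
    def zeros(cls, grid: GridSpec) -> "AcousticState":
        shape = grid.shape
        return cls(
            rho=np.zeros(shape),
            u=[np.zeros(shape) for _ in range(grid.dim)],
            p=np.zeros(shape),
        )

    def copy(self) -> "AcousticState":
        return AcousticState(
            self.rho.copy(), [c.copy() for c in self.u], self.p.copy(), self.t
        )

    def is_finite(self) -> bool:
        return (
            np.all(np.isfinite(self.rho))
            and np.all(np.isfinite(self.p))
            and all(np.all(np.isfinite(c)) for c in self.u)
        )


# ---------------------------------------------------------------------------
# compact scheme
# ---------------------------------------------------------------------------


def _compact_matrix(n: int) -> np.ndarray:
    """Dense index-space derivative operator D = A^-1 B (uniform spacing 1).

    Interior rows: classical sixth-order tridiagonal compact scheme;
    second/penultimate rows: fourth-order Pade; end rows: third-order
    one-sided closure.
    """
    if n < 8:
        raise ValueError("compact derivative needs at least 8 points per axis")
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    alpha, a, b = 1.0 / 3.0, 14.0 / 9.0, 1.0 / 9.0
    for i in range(2, n - 2):
        A[i, i - 1 : i + 2] = [alpha, 1.0, alpha]
        B[i, i + 1] += a / 2.0
        B[i, i - 1] -= a / 2.0
        B[i, i + 2] += b / 4.0
        B[i, i - 2] -= b / 4.0
    # fourth-order Pade at the second and penultimate points
    for i in (1, n - 2):
        A[i, i - 1 : i + 2] = [0.25, 1.0, 0.25]
        B[i, i + 1] = 0.75
        B[i, i - 1] = -0.75
    # third-order one-sided closures at the ends
    A[0, 0], A[0, 1] = 1.0, 2.0
    B[0, 0], B[0, 1], B[0, 2] = -2.5, 2.0, 0.5
    A[-1, -1], A[-1, -2] = 1.0, 2.0
    B[-1, -1], B[-1, -2], B[-1, -3] = 2.5, -2.0, -0.5
    return np.linalg.solve(A, B)


def _runs(fluid: np.ndarray, ghost: np.ndarray):
    """Maximal fluid runs along a line, extended by adjacent ghost nodes.

    A ghost sandwiched between two runs is attached to the left run only,
    so every node's derivative row has a single owner."""
    n = fluid.size
    idx = np.flatnonzero(fluid)
    if idx.size == 0:
        return
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[splits + 1]]
    ends = np.r_[idx[splits], idx[-1]]
    last_end = -1
    for a, b in zip(starts, ends):
        if a - 1 >= 0 and ghost[a - 1] and a - 1 > last_end:
            a = a - 1
        if b + 1 < n and ghost[b + 1]:
            b = b + 1
        last_end = b
        yield int(a), int(b)


def _run_entries(n, idx, rowsA, colsA, valsA, rowsB, colsB, valsB):
    """Append the banded A f' = B f entries of one run (global indices idx).

    Long runs carry the sixth-order compact rows; short slivers degrade to
    explicit second/first-order differences (A = identity there)."""

    def addA(r, c, v):
        rowsA.append(np.atleast_1d(idx[r]))
        colsA.append(np.atleast_1d(idx[c]))
        valsA.append(np.atleast_1d(np.asarray(v, float)))

    def addB(r, c, v):
        rowsB.append(np.atleast_1d(idx[r]))
        colsB.append(np.atleast_1d(idx[c]))
        valsB.append(np.atleast_1d(np.asarray(v, float)))

    if n >= 8:
        i = np.arange(2, n - 2)
        addA(i, i, np.ones(i.size))
        addA(i, i - 1, np.full(i.size, 1.0 / 3.0))
        addA(i, i + 1, np.full(i.size, 1.0 / 3.0))
        addB(i, i + 1, np.full(i.size, 7.0 / 9.0))
        addB(i, i - 1, np.full(i.size, -7.0 / 9.0))
        addB(i, i + 2, np.full(i.size, 1.0 / 36.0))
        addB(i, i - 2, np.full(i.size, -1.0 / 36.0))
        for j in (1, n - 2):
            addA([j, j, j], [j - 1, j, j + 1], [0.25, 1.0, 0.25])
            addB([j, j], [j - 1, j + 1], [-0.75, 0.75])
        addA([0, 0], [0, 1], [1.0, 2.0])
        addB([0, 0, 0], [0, 1, 2], [-2.5, 2.0, 0.5])
        addA([n - 1, n - 1], [n - 1, n - 2], [1.0, 2.0])
        addB([n - 1] * 3, [n - 1, n - 2, n - 3], [2.5, -2.0, -0.5])
        return
    i = np.arange(n)
    addA(i, i, np.ones(n))
    if n == 1:
        return
    if n == 2:
        addB([0, 0, 1, 1], [0, 1, 0, 1], [-1.0, 1.0, -1.0, 1.0])
        return
    j = np.arange(1, n - 1)
    addB(j, j + 1, np.full(j.size, 0.5))
    addB(j, j - 1, np.full(j.size, -0.5))
    addB([0, 0, 0], [0, 1, 2], [-1.5, 2.0, -0.5])
    addB([n - 1] * 3, [n - 1, n - 2, n - 3], [1.5, -2.0, 0.5])


def _filter_matrix(n: int, sigma: float, _cache: dict = {}) -> np.ndarray:
    """Explicit low-pass filter: eighth order in the interior, reduced to
    sixth/fourth/second order approaching the ends (endpoint untouched).

    The reduced-order rows damp the spurious modes of the one-sided
    derivative closures, which would otherwise grow under RK4.
    """
    from math import comb

    F = _cache.get((n, sigma))
    if F is not None:
        return F
    F = np.eye(n)
    for i in range(1, n - 1):
        b = min(i, n - 1 - i, 4)
        c = np.array([(-1) ** (k + b) * comb(2 * b, k) for k in range(2 * b + 1)], float)
        F[i, i - b : i + b + 1] -= sigma * c / 4.0**b
    _cache[(n, sigma)] = F
    return F


class _AxisOps:
    """Cached dense operators for one full (unsegmented) grid axis.

    ``Dp`` folds the non-uniform metric (dx/dxi from the same compact
    scheme) into the derivative so one matrix application yields the
    physical derivative; ``F`` is the low-pass filter."""

    def __init__(self, centers: np.ndarray, sigma: float):
        n = centers.size
        self.D = _compact_matrix(n)
        self.metric = self.D @ centers  # dx/dxi, strictly positive
        self.Dp = self.D / self.metric[:, None]
        self.F = _filter_matrix(n, sigma)


def _apply_along(op: np.ndarray, f: np.ndarray, axis: int) -> np.ndarray:
    """Apply a per-axis dense operator; fast paths for 1D/2D matmuls."""
    if f.ndim == 1:
        return op @ f
    if f.ndim == 2:
        return op @ f if axis == 0 else f @ op.T
    if axis == f.ndim - 1:
        return f @ op.T
    if axis == 0:
        return np.einsum("ij,j...->i...", op, f)
    g = np.tensordot(op, np.moveaxis(f, axis, 0), axes=(1, 0))
    return np.moveaxis(g, 0, axis)


def _apply_along_out(op: np.ndarray, W: np.ndarray, spatial_axis: int, out: np.ndarray):
    """Derivative of a stacked field array W (fields, *shape) along one
    spatial axis, written into ``out``."""
    axis = spatial_axis + 1
    if axis == W.ndim - 1:
        np.matmul(W, op.T, out=out)
    elif axis == 1 and W.ndim == 3:
        np.matmul(op, W, out=out)
    else:
        out[...] = _apply_along(op, W, axis)
    return out


def compact_derivative(
    field: np.ndarray, axis: int, grid: GridSpec, _cache: dict = {}
) -> np.ndarray:
    """Sixth-order compact derivative of a cell-centered field along ``axis``."""
    centers = grid.centers(axis)
    key = (centers.size, float(centers[0]), float(centers[-1]), axis, id(grid))
    ops = _cache.get(key)
    if ops is None:
        ops = _AxisOps(centers, 0.0)
        _cache[key] = ops
    return _apply_along(ops.Dp, field, axis)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


class LpceSolver:
    """Advance the LPCE system on the fluid region of a Cartesian grid.

    ``edge_bc`` maps ``(axis, side)`` (side in {0, 1} for min/max) to one
    of ``"wall"`` (rigid: zero normal perturbation velocity), ``"inlet"``
    (p' = 0, u' = 0), ``"open"`` (complete reflection: p' = 0, zero
    velocity gradient) or ``"none"``.  An optional level set marks
    immersed walls treated by ghost-cell mirrors (hard wall: zero normal
    derivative of rho', p', zero normal u').
    """

    CFL_LIMIT = 1.35

    def __init__(
        self,
        grid: GridSpec,
        props: AcousticProperties,
        rho0: float,
        edge_bc: dict | None = None,
        levelset=None,
        filter_strength: float = 0.2,
    ):
        self.grid = grid
        self.props = props
        self.rho0 = rho0
        self.P_amb = props.ambient_pressure(rho0)
        self.edge_bc = dict(edge_bc or {})
        self.sigma = filter_strength
        self.ops = [
            _AxisOps(grid.centers(ax), filter_strength) for ax in range(grid.dim)
        ]
        self.set_levelset(levelset)
        self.set_mean_flow(None, None, None)

    # -- geometry -----------------------------------------------------------
    def set_levelset(self, levelset) -> None:
        self.levelset = levelset
        if levelset is None:
            self.mirror = None
            self.solid_mask = None
            self._seg = None
            self._old_tags = None
            return
        coords = [self.grid.centers(ax) for ax in range(self.grid.dim)]
        self.mirror = GhostMirror(coords, levelset)
        self.solid_mask = self.mirror.tags == SOLID
        # operators depend only on the cell tags; the ghost mirror above is
        # rebuilt every boundary move, the operators only on re-tagging
        old = getattr(self, "_old_tags", None)
        if old is None or not np.array_equal(old, self.mirror.tags):
            self._build_segmented()
            self._old_tags = self.mirror.tags.copy()
        self._build_flat_indices()

    def _build_segmented(self) -> None:
        """Banded segment-wise operators that never couple across solid.

        For each axis the compact scheme is kept in its natural A f' = B f
        form: A (tridiagonal within each fluid run, identity elsewhere) is
        LU-factorized once per geometry, B and the low-pass filter are
        banded sparse matrices, and one derivative application is a banded
        matvec plus an O(N) backsolve for all grid lines at once.  2D
        only; 1D grids keep the single global dense operator.
        """
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        if self.grid.dim != 2:
            self._seg = None
            return
        tags = self.mirror.tags
        fluid = tags == FLUID_TAG
        ghost = tags == GHOST_TAG
        nx, ny = self.grid.shape
        N = nx * ny
        self._seg = []
        for ax in range(2):
            coords = self.grid.centers(ax)
            rowsA, colsA, valsA = [], [], []
            rowsB, colsB, valsB = [], [], []
            rowsF, colsF, valsF = [], [], []
            n_lines = ny if ax == 0 else nx
            for line in range(n_lines):
                if ax == 0:
                    fl, gh = fluid[:, line], ghost[:, line]
                    flat = np.arange(nx) * ny + line
                else:
                    fl, gh = fluid[line, :], ghost[line, :]
                    flat = line * ny + np.arange(ny)
                for a, b in _runs(fl, gh):
                    n = b - a + 1
                    idx = flat[a : b + 1]
                    _run_entries(n, idx, rowsA, colsA, valsA, rowsB, colsB, valsB)
                    F = _filter_matrix(n, self.sigma) if n >= 3 else np.eye(n)
                    rr, cc = np.nonzero(F)
                    rowsF.append(idx[rr])
                    colsF.append(idx[cc])
                    valsF.append(F[rr, cc])

            def cat(parts):
                return (
                    np.concatenate(parts)
                    if parts
                    else np.empty(0, dtype=float)
                )

            rA, cA, vA = cat(rowsA), cat(colsA), cat(valsA)
            A = sp.csc_matrix((vA, (rA.astype(int), cA.astype(int))), shape=(N, N))
            # identity rows for nodes outside every run
            covered = np.zeros(N, dtype=bool)
            covered[rA.astype(int)] = True
            miss = np.flatnonzero(~covered)
            A = A + sp.csc_matrix(
                (np.ones(miss.size), (miss, miss)), shape=(N, N)
            )
            B = sp.csr_matrix(
                (cat(valsB), (cat(rowsB).astype(int), cat(colsB).astype(int))),
                shape=(N, N),
            )
            rF, cF, vF = cat(rowsF), cat(colsF), cat(valsF)
            covered = np.zeros(N, dtype=bool)
            covered[rF.astype(int)] = True
            miss = np.flatnonzero(~covered)
            F = sp.csr_matrix(
                (np.r_[vF, np.ones(miss.size)],
                 (np.r_[rF.astype(int), miss], np.r_[cF.astype(int), miss])),
                shape=(N, N),
            )
            lu = spla.splu(A)
            cfield = (
                np.broadcast_to(coords[:, None], (nx, ny))
                if ax == 0
                else np.broadcast_to(coords[None, :], (nx, ny))
            ).ravel()
            metric = lu.solve(B @ cfield)
            metric = np.where(np.abs(metric) < 1e-300, 1.0, metric)
            # tridiagonal bands of A in flat ordering for the jitted solver
            step = ny if ax == 0 else 1
            sub = np.zeros(N)
            dia = np.ones(N)
            sup = np.zeros(N)
            rr = rA.astype(int)
            cc = cA.astype(int)
            off = cc - rr
            dia[rr[off == 0]] = vA[off == 0]
            sub[rr[off == -step]] = vA[off == -step]
            sup[rr[off == step]] = vA[off == step]
            Bc = B.tocsr()
            Fc = F.tocsr()
            self._seg.append(
                {
                    "lu": lu,
                    "B": Bc,
                    "F": Fc,
                    "inv_metric": 1.0 / metric,
                    "sub": sub,
                    "dia": dia,
                    "sup": sup,
                }
            )

    def _build_flat_indices(self) -> None:
        shape = self.grid.shape
        self._solid_flat = np.flatnonzero(self.solid_mask.ravel())
        m = self.mirror
        if m.n_ghost:
            self._ghost_flat = np.ravel_multi_index(m.ghost_index, shape)
        else:
            self._ghost_flat = np.empty(0, dtype=np.int64)
        if self.grid.dim != 2:
            return
        nx, ny = shape
        self._edge_flat = {}
        for (axis, side), kind in self.edge_bc.items():
            if axis == 0:
                i = nx - 1 if side else 0
                i2 = nx - 2 if side else 1
                edge = np.arange(ny) + i * ny
                inner = np.arange(ny) + i2 * ny
            else:
                j = ny - 1 if side else 0
                j2 = ny - 2 if side else 1
                edge = np.arange(nx) * ny + j
                inner = np.arange(nx) * ny + j2
            self._edge_flat[(axis, side)] = (edge, inner)
        # kernel-format boundary data
        kinds = {"none": 0, "wall": 1, "inlet": 2, "open": 3}
        ek, ea, eidx, einn = [], [], [], []
        off = [0]
        for (axis, side), kind in sorted(self.edge_bc.items()):
            ek.append(kinds[kind])
            ea.append(axis)
            e, i = self._edge_flat[(axis, side)]
            eidx.append(e)
            einn.append(i)
            off.append(off[-1] + e.size)
        m = self.mirror
        if m.n_ghost:
            stencil = m.stencil_flat.astype(np.int64)
            weights = m.weights
            normals = m.normals
        else:
            stencil = np.empty((0, 2**self.grid.dim), dtype=np.int64)
            weights = np.empty((0, 2**self.grid.dim))
            normals = np.empty((0, self.grid.dim))
        self._kernel_bc = (
            np.asarray(ek, dtype=np.int8),
            np.asarray(ea, dtype=np.int64),
            np.asarray(off, dtype=np.int64),
            np.concatenate(eidx).astype(np.int64) if eidx else np.empty(0, np.int64),
            np.concatenate(einn).astype(np.int64) if einn else np.empty(0, np.int64),
            self._ghost_flat.astype(np.int64),
            stencil,
            weights,
            normals,
            self._solid_flat.astype(np.int64),
        )

    def refresh_levelset(self, levelset) -> "np.ndarray | None":
        """Swap in a moved boundary; returns mask of fresh (newly fluid) cells."""
        old_fluid = None if self.mirror is None else self.mirror.fluid_mask
        self.set_levelset(levelset)
        if old_fluid is None or self.mirror is None:
            return None
        return self.mirror.fluid_mask & ~old_fluid

    def fill_fresh_cells(self, state: AcousticState, fresh: np.ndarray) -> None:
        """Fill cells uncovered by boundary motion from fluid neighbors."""
        if fresh is None or not np.any(fresh):
            return
        fluid_old = self.mirror.fluid_mask & ~fresh
        for f in [state.rho, state.p] + state.u:
            total = np.zeros_like(f)
            count = np.zeros_like(f)
            for ax in range(f.ndim):
                for s in (1, -1):
                    total += np.where(_shifted(fluid_old, ax, s), _shifted(f, ax, s), 0.0)
                    count += _shifted(fluid_old, ax, s).astype(float)
            f[fresh] = np.where(count[fresh] > 0, total[fresh] / np.maximum(count[fresh], 1), 0.0)

    # -- mean flow ----------------------------------------------------------
    def set_mean_flow(self, U: list | None, P_gauge: np.ndarray | None, dPdt) -> None:
        """Freeze the incompressible fields over the coming subcycles.

        Ghost cells of the frozen fields are mirrored so derivative
        stencils next to the immersed wall see physical values rather than
        the zeroed solid interior.
        """
        if self.mirror is not None and self.mirror.n_ghost:
            if U is not None:
                U = [c.copy() for c in U]
                self.mirror.mirror_vector_slip(U)
            if P_gauge is not None:
                P_gauge = P_gauge.copy()
                self.mirror.mirror_scalar(P_gauge)
        self.U = U
        self.P_gauge = P_gauge
        self.source = dPdt
        if P_gauge is not None:
            self.gradP = [self.deriv(P_gauge, ax) for ax in range(self.grid.dim)]
            self.P_abs = self.P_amb + P_gauge
        else:
            self.gradP = None
            self.P_abs = self.P_amb
        # flattened copies for the sparse fast path
        self._Uf = None if U is None else [c.ravel() for c in U]
        self._gradPf = None if self.gradP is None else [g.ravel() for g in self.gradP]
        if np.ndim(self.P_abs):
            self._negGPabs = -self.props.gamma * np.ravel(self.P_abs)
        else:
            self._negGPabs = -self.props.gamma * float(self.P_abs)
        self._srcf = None if dPdt is None else np.ravel(dPdt)
        if self.grid.dim == 2:
            N = int(np.prod(self.grid.shape))
            self._Uf_k = (
                np.zeros((2, N)) if self._Uf is None else np.vstack(self._Uf)
            )
            self._gPf_k = (
                np.zeros((2, N)) if self._gradPf is None else np.vstack(self._gradPf)
            )
            self._negGPabs_k = (
                np.asarray(self._negGPabs)
                if np.ndim(self._negGPabs)
                else np.full(N, self._negGPabs)
            )
            self._srcf_k = np.zeros(N) if self._srcf is None else self._srcf

    # -- numerics -----------------------------------------------------------
    def deriv(self, f: np.ndarray, axis: int) -> np.ndarray:
        if getattr(self, "_seg", None) is None or f.ndim != 2:
            return _apply_along(self.ops[axis].Dp, f, axis)
        seg = self._seg[axis]
        d = seg["lu"].solve(seg["B"] @ f.ravel()) * seg["inv_metric"]
        return d.reshape(f.shape)

    def check_cfl(self, dt: float) -> None:
        umax = 0.0
        if self.U is not None:
            umax = max(float(np.max(np.abs(c))) for c in self.U)
        speed = self.props.c + umax
        inv = 0.0
        worst = []
        for ax in range(self.grid.dim):
            w = self.grid.widths(ax)
            inv += 1.0 / w.min()
            worst.append(int(np.argmin(w)))
        cfl = dt * speed * inv
        self.last_cfl = cfl
        if cfl > self.CFL_LIMIT:
            raise ValueError(
                f"acoustic CFL {cfl:.3f} exceeds {self.CFL_LIMIT} "
                f"(limiting cell index {tuple(worst)}); reduce dt"
            )

    # -- boundary conditions -------------------------------------------------
    def apply_bcs(self, state: AcousticState) -> AcousticState:
        """Impose edge and immersed-wall conditions in place; returns state."""
        for (axis, side), kind in self.edge_bc.items():
            if kind == "none":
                continue
            edge = _plane(state.p.ndim, axis, -1 if side else 0)
            inner = _plane(state.p.ndim, axis, -2 if side else 1)
            if kind == "wall":
                state.u[axis][edge] = 0.0
            elif kind == "inlet":
                state.p[edge] = 0.0
                state.rho[edge] = 0.0
                for c in state.u:
                    c[edge] = 0.0
            elif kind == "open":
                state.p[edge] = 0.0
                for c in state.u:
                    c[edge] = c[inner]
            else:
                raise ValueError(f"unknown acoustic boundary kind {kind!r}")
        if self.mirror is not None and self.mirror.n_ghost:
            self.mirror.mirror_scalar(state.rho)
            self.mirror.mirror_scalar(state.p)
            self.mirror.mirror_vector_slip(state.u)
        if self.solid_mask is not None:
            state.rho[self.solid_mask] = 0.0
            state.p[self.solid_mask] = 0.0
            for c in state.u:
                c[self.solid_mask] = 0.0
        return state

    # -- stacked fast path ---------------------------------------------------
    # Fields are stacked as Q[0] = rho', Q[1:1+dim] = u', Q[dim+1] = p' so a
    # whole RK4 stage needs only one dense operator application per axis.

    def _as_view(self, Q: np.ndarray, t: float) -> AcousticState:
        dim = self.grid.dim
        return AcousticState(Q[0], [Q[1 + i] for i in range(dim)], Q[dim + 1], t)

    def _ensure_buffers(self) -> None:
        dim = self.grid.dim
        shape = self.grid.shape
        nf = dim + 2
        if getattr(self, "_buf_shape", None) == (nf,) + shape:
            return
        self._buf_shape = (nf,) + shape
        # work stack carries s = u'.U as its last row
        self._W = np.zeros((nf + 1,) + shape)
        self._dW = [np.zeros((nf + 1,) + shape) for _ in range(dim)]
        self._K = [np.zeros((nf,) + shape) for _ in range(4)]
        self._Qtmp = np.zeros((nf,) + shape)

    def _rhs_stacked(self, Q: np.ndarray, out: np.ndarray) -> None:
        dim = self.grid.dim
        nf = dim + 2
        rho0 = self.rho0
        W = self._W
        W[:nf] = Q
        if self.U is not None:
            s = W[nf]
            np.multiply(Q[1], self.U[0], out=s)
            for ax in range(1, dim):
                s += Q[1 + ax] * self.U[ax]
        else:
            W[nf] = 0.0
        for ax in range(dim):
            _apply_along_out(self.ops[ax].Dp, W, ax, self._dW[ax])
        dW = self._dW
        divu = dW[0][1]
        for ax in range(1, dim):
            divu = divu + dW[ax][1 + ax]
        np.multiply(divu, -rho0, out=out[0])
        np.multiply(divu, -self.props.gamma * self.P_abs, out=out[nf - 1])
        if self.source is not None:
            out[nf - 1] -= self.source
        for ax in range(dim):
            np.multiply(dW[ax][nf - 1], -1.0 / rho0, out=out[1 + ax])
        if self.U is not None:
            for ax in range(dim):
                out[1 + ax] -= dW[ax][nf]
                out[0] -= self.U[ax] * dW[ax][0]
                out[nf - 1] -= self.U[ax] * dW[ax][nf - 1]
        if self.gradP is not None:
            for ax in range(dim):
                out[nf - 1] -= Q[1 + ax] * self.gradP[ax]
        if self.solid_mask is not None:
            out[:, self.solid_mask] = 0.0

    def _filter_stacked(self, Q: np.ndarray) -> None:
        if self.sigma <= 0:
            return
        buf = self._K[3]  # scratch; refilled before its next RK use
        for ax in range(self.grid.dim):
            _apply_along_out(self.ops[ax].F, Q, ax, buf)
            Q[...] = buf

    # -- flat sparse fast path (2D immersed geometry) -------------------------
    # State columns: X[:, 0] = rho', X[:, 1:1+dim] = u', X[:, dim+1] = p' on
    # the flattened (C-order) cell index; per-axis derivatives and filters
    # are single CSR matmuls over all grid lines at once.

    def _ensure_flat_buffers(self) -> None:
        dim = self.grid.dim
        N = int(np.prod(self.grid.shape))
        nf = dim + 2
        if getattr(self, "_flat_shape", None) == (N, nf):
            return
        self._flat_shape = (N, nf)
        self._Xw = np.zeros((N, nf + 1))
        self._Kf = [np.zeros((N, nf)) for _ in range(4)]
        self._Xtmp = np.zeros((N, nf))

    def _bc_flat(self, X: np.ndarray) -> None:
        dim = self.grid.dim
        ip = dim + 1
        for (axis, side), kind in self.edge_bc.items():
            if kind == "none":
                continue
            edge, inner = self._edge_flat[(axis, side)]
            if kind == "wall":
                X[edge, 1 + axis] = 0.0
            elif kind == "inlet":
                X[edge, :] = 0.0
            elif kind == "open":
                X[edge, ip] = 0.0
                X[edge, 1 : 1 + dim] = X[inner, 1 : 1 + dim]
            else:
                raise ValueError(f"unknown acoustic boundary kind {kind!r}")
        m = self.mirror
        if m.n_ghost:
            g = self._ghost_flat
            st, w = m.stencil_flat, m.weights
            X[g, 0] = (X[st, 0] * w).sum(axis=1)
            X[g, ip] = (X[st, ip] * w).sum(axis=1)
            vi = np.stack([(X[st, 1 + ax] * w).sum(axis=1) for ax in range(dim)], axis=1)
            vn = np.einsum("ij,ij->i", vi, m.normals)
            for ax in range(dim):
                X[g, 1 + ax] = vi[:, ax] - 2.0 * vn * m.normals[:, ax]
        X[self._solid_flat, :] = 0.0

    def _rhs_flat(self, X: np.ndarray, out: np.ndarray) -> None:
        dim = self.grid.dim
        nf = dim + 2
        ip = dim + 1
        W = self._Xw
        W[:, :nf] = X
        if self._Uf is not None:
            np.multiply(X[:, 1], self._Uf[0], out=W[:, nf])
            for ax in range(1, dim):
                W[:, nf] += X[:, 1 + ax] * self._Uf[ax]
        else:
            W[:, nf] = 0.0
        s0, s1 = self._seg
        d0 = s0["lu"].solve(s0["B"] @ W) * s0["inv_metric"][:, None]
        d1 = s1["lu"].solve(s1["B"] @ W) * s1["inv_metric"][:, None]
        divu = d0[:, 1] + d1[:, 2]
        np.multiply(divu, -self.rho0, out=out[:, 0])
        np.multiply(divu, self._negGPabs, out=out[:, ip])
        if self._srcf is not None:
            out[:, ip] -= self._srcf
        np.multiply(d0[:, ip], -1.0 / self.rho0, out=out[:, 1])
        np.multiply(d1[:, ip], -1.0 / self.rho0, out=out[:, 2])
        if self._Uf is not None:
            out[:, 1] -= d0[:, nf]
            out[:, 2] -= d1[:, nf]
            for ax, d in ((0, d0), (1, d1)):
                out[:, 0] -= self._Uf[ax] * d[:, 0]
                out[:, ip] -= self._Uf[ax] * d[:, ip]
        if self._gradPf is not None:
            out[:, ip] -= X[:, 1] * self._gradPf[0]
            out[:, ip] -= X[:, 2] * self._gradPf[1]
        out[self._solid_flat, :] = 0.0

    def _step_many_flat(self, state: AcousticState, dt: float, n: int) -> AcousticState:
        dim = self.grid.dim
        nf = dim + 2
        shape = self.grid.shape
        self._ensure_flat_buffers()
        X = np.empty(self._flat_shape)
        X[:, 0] = state.rho.ravel()
        for i in range(dim):
            X[:, 1 + i] = state.u[i].ravel()
        X[:, nf - 1] = state.p.ravel()
        t = state.t
        if _K.HAVE_NUMBA and dim == 2:
            s0, s1 = self._seg
            nx, ny = shape
            _K.lpce_subcycles(
                X, n, dt, nx, ny, self.rho0,
                s0["B"].indptr, s0["B"].indices, s0["B"].data,
                s0["sub"], s0["dia"], s0["sup"], s0["inv_metric"],
                s1["B"].indptr, s1["B"].indices, s1["B"].data,
                s1["sub"], s1["dia"], s1["sup"], s1["inv_metric"],
                s0["F"].indptr, s0["F"].indices, s0["F"].data,
                s1["F"].indptr, s1["F"].indices, s1["F"].data,
                self.sigma > 0,
                self._Uf_k, self._gPf_k, self._negGPabs_k, self._srcf_k,
                self._Uf is not None, self._gradPf is not None,
                self._srcf is not None,
                *self._kernel_bc,
            )
            t += n * dt
            new = AcousticState(
                X[:, 0].reshape(shape).copy(),
                [X[:, 1 + i].reshape(shape).copy() for i in range(dim)],
                X[:, nf - 1].reshape(shape).copy(),
                t,
            )
            if not new.is_finite():
                raise RuntimeError("acoustic field became non-finite")
            return new
        K1, K2, K3, K4 = self._Kf
        Xt = self._Xtmp
        for _ in range(n):
            self._bc_flat(X)
            self._rhs_flat(X, K1)
            np.multiply(K1, 0.5 * dt, out=Xt)
            Xt += X
            self._bc_flat(Xt)
            self._rhs_flat(Xt, K2)
            np.multiply(K2, 0.5 * dt, out=Xt)
            Xt += X
            self._bc_flat(Xt)
            self._rhs_flat(Xt, K3)
            np.multiply(K3, dt, out=Xt)
            Xt += X
            self._bc_flat(Xt)
            self._rhs_flat(Xt, K4)
            K2 += K3
            K2 *= 2.0
            K2 += K1
            K2 += K4
            K2 *= dt / 6.0
            X += K2
            t += dt
            self._bc_flat(X)
            if self.sigma > 0:
                X = self._seg[1]["F"] @ (self._seg[0]["F"] @ X)
                self._bc_flat(X)
        new = AcousticState(
            X[:, 0].reshape(shape).copy(),
            [X[:, 1 + i].reshape(shape).copy() for i in range(dim)],
            X[:, nf - 1].reshape(shape).copy(),
            t,
        )
        if not new.is_finite():
            raise RuntimeError("acoustic field became non-finite")
        return new

    def step_many(
        self, state: AcousticState, dt: float, n: int, check_cfl: bool = True
    ) -> AcousticState:
        """Advance ``n`` RK4 substeps of length ``dt`` (the subcycling loop)."""
        if check_cfl:
            self.check_cfl(dt)
        if getattr(self, "_seg", None) is not None:
            return self._step_many_flat(state, dt, n)
        dim = self.grid.dim
        nf = dim + 2
        self._ensure_buffers()
        Q = np.empty((nf,) + self.grid.shape)
        Q[0] = state.rho
        for i in range(dim):
            Q[1 + i] = state.u[i]
        Q[nf - 1] = state.p
        t = state.t
        K1, K2, K3, K4 = self._K
        Qtmp = self._Qtmp
        for _ in range(n):
            self.apply_bcs(self._as_view(Q, t))
            self._rhs_stacked(Q, K1)
            np.multiply(K1, 0.5 * dt, out=Qtmp)
            Qtmp += Q
            self.apply_bcs(self._as_view(Qtmp, t + 0.5 * dt))
            self._rhs_stacked(Qtmp, K2)
            np.multiply(K2, 0.5 * dt, out=Qtmp)
            Qtmp += Q
            self.apply_bcs(self._as_view(Qtmp, t + 0.5 * dt))
            self._rhs_stacked(Qtmp, K3)
            np.multiply(K3, dt, out=Qtmp)
            Qtmp += Q
            self.apply_bcs(self._as_view(Qtmp, t + dt))
            self._rhs_stacked(Qtmp, K4)
            K2 += K3
            K2 *= 2.0
            K2 += K1
            K2 += K4
            K2 *= dt / 6.0
            Q += K2
            t += dt
            self.apply_bcs(self._as_view(Q, t))
            self._filter_stacked(Q)
            self.apply_bcs(self._as_view(Q, t))
        new = AcousticState(
            Q[0].copy(), [Q[1 + i].copy() for i in range(dim)], Q[nf - 1].copy(), t
        )
        if not new.is_finite():
            raise RuntimeError("acoustic field became non-finite")
        return new

    def step(self, state: AcousticState, dt: float, check_cfl: bool = True) -> AcousticState:
        """One four-stage Runge-Kutta step of length ``dt``."""
        return self.step_many(state, dt, 1, check_cfl=check_cfl)

    # -- measurements --------------------------------------------------------
    def flowrate(self, state: AcousticState, y_plane: float) -> float:
        """Volumetric perturbation rate through an axial plane (m^3/s; per
        unit depth, i.e. m^2/s, in 2D)."""
        return plane_flowrate(
            self.grid,
            state.u[min(1, self.grid.dim - 1)],
            y_plane,
            None if self.mirror is None else self.mirror.fluid_mask,
        )


def _plane(ndim: int, axis: int, index: int):
    sl = [slice(None)] * ndim
    sl[axis] = index
    return tuple(sl)


def _shifted(f: np.ndarray, ax: int, s: int) -> np.ndarray:
    g = np.roll(f, s, axis=ax)
    sl = [slice(None)] * f.ndim
    sl[ax] = slice(0, s) if s > 0 else slice(s, None)
    g[tuple(sl)] = 0
    return g


def plane_flowrate(grid: GridSpec, v: np.ndarray, y_plane: float, fluid_mask=None) -> float:
    """Integral of an axial cell-centered velocity over the plane y = const.

    In 1D this is just the point value; in 2D/3D the transverse cell
    widths weight the sum, restricted to fluid cells when a mask is given.
    """
    ax = min(1, grid.dim - 1)
    c = grid.centers(ax)
    if not (c[0] - grid.widths(ax).max() <= y_plane <= c[-1] + grid.widths(ax).max()):
        raise ValueError(f"plane y={y_plane} outside the domain")
    j = int(np.argmin(np.abs(c - y_plane)))
    if grid.dim == 1:
        return float(v[j])
    sl = _plane(v.ndim, ax, j)
    vals = v[sl]
    mask = None if fluid_mask is None else fluid_mask[sl]
    w = grid.widths(0)[:, None] if grid.dim == 3 else grid.widths(0)
    if grid.dim == 3:
        w = w * grid.widths(2)[None, :]
    if mask is not None:
        vals = np.where(mask, vals, 0.0)
    return float(np.sum(vals * w))


def acoustic_energy(state: AcousticState, rho0: float, c: float, grid: GridSpec, mask=None) -> float:
    """Total acoustic energy: integral of p'^2/(2 rho0 c^2) + rho0 |u'|^2 / 2."""
    dv = grid.widths(0)
    for ax in range(1, grid.dim):
        dv = np.multiply.outer(dv, grid.widths(ax))
    e = state.p**2 / (2.0 * rho0 * c**2)
    for comp in state.u:
        e = e + 0.5 * rho0 * comp**2
    if mask is not None:
        e = np.where(mask, e, 0.0)
    return float(np.sum(e * dv))
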