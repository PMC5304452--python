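"""Explicit staggered coupling of the flow, acoustics and solid solvers.

Each coupled step executes, in order: (1) one incompressible flow step
with the current fold shape and tissue velocity as wall conditions;
(2) the prescribed number of LPCE subcycles driven by the updated flow
and its pressure material derivative; (3) traction update on the fold
surface from the new incompressible pressure, acoustic perturbation
pressure and (optionally) viscous stress; (4) one solid (Newmark) step
under those tractions; (5) contact enforcement against the collision
planes and lumen update (markers + level set + cell tags).  The loop is
loose (no sub-iterations); stability comes from the small time step and
the large tissue/air density ratio.

A hard-wall contact model bounds fold closure: two non-slip collision
planes sit at +-plane_offset off the medial plane, enforcing a small but
finite minimum glottal gap so the flow passage never fully closes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .acoustics import AcousticProperties, AcousticState, LpceSolver
from .analysis import pod
from .flow import FieldSampler, FlowSolver, FluidProperties, face_to_center, material_derivative_P
from .geometry import (
    DuctSpec,
    FEMesh,
    FoldSpec,
    LevelSet,
    build_duct,
    build_folds,
    composite_levelset,
    fold_surface_markers,
    polygon_signed_distance,
)
from .grid import GridSpec
from .solid import STANDARD_LAYERS, SolidSolver, SolidState

__all__ = [
    "ContactModel",
    "CouplingConfig",
    "GlottalRecord",
    "Simulation",
    "surface_traction",
    "enforce_contact",
]


@dataclass
class ContactModel:
    """Collision planes at +-plane_offset from the medial plane; the
    enforced minimum glottal gap is exactly twice the offset."""

    plane_offset: float = 1.0e-4
    min_gap: float = 2.0e-4

    def __post_init__(self) -> None:
        if self.plane_offset <= 0 or self.min_gap <= 0:
            raise ValueError("contact distances must be positive")
        if abs(self.min_gap - 2.0 * self.plane_offset) > 1e-12:
            raise ValueError("min_gap must equal 2 * plane_offset")


@dataclass
class CouplingConfig:
    """Time marching of the coupled loop.

    ``dt_flow`` is shared by the flow and solid solvers; the acoustic
    solver runs ``n_subcycles`` substeps of dt_flow/n_subcycles per flow
    step.  ``perturb`` optionally seeds a tiny random initial fold
    velocity (amplitude in m/s) to break perfect mirror symmetry.
    """

    dt_flow: float = 1.149e-6
    n_subcycles: int = 20
    n_steps: int = 1000
    record_every: int = 1
    snapshot_every: int = 20
    seed: int = 0
    perturb: float = 0.0

    def __post_init__(self) -> None:
        if self.dt_flow <= 0:
            raise ValueError("dt_flow must be positive")
        if self.n_subcycles < 1:
            raise ValueError("n_subcycles must be >= 1")


class GlottalRecord:
    """Per-step time series of the coupled run.

    opening: minimum fold-to-fold distance at the mid-coronal plane (m);
    q_inc / q_ac / q_total: outlet flow rates (m^3/s, using the configured
    anterior-posterior effective depth in 2D); probe pressures carry the
    incompressible (P), acoustic (p') and total (p = P + p') values.
    """

    def __init__(self, probes=(), effective_depth: float = 1.0):
        self.effective_depth = effective_depth
        self.probes = [tuple(p) for p in probes]
        self.t = []
        self.opening = []
        self.q_inc = []
        self.q_ac = []
        self.q_total = []
        self.probe_P = [[] for _ in self.probes]
        self.probe_p_ac = [[] for _ in self.probes]
        self.snapshot_t = []
        self.snapshots = []

    def append(self, t, opening, q_inc, q_ac, probe_P=(), probe_p_ac=()):
        self.t.append(float(t))
        self.opening.append(float(opening))
        self.q_inc.append(float(q_inc))
        self.q_ac.append(float(q_ac))
        self.q_total.append(float(q_inc + q_ac))
        for k, v in enumerate(probe_P):
            self.probe_P[k].append(float(v))
        for k, v in enumerate(probe_p_ac):
            self.probe_p_ac[k].append(float(v))

    def add_snapshot(self, t, surface_displacement):
        self.snapshot_t.append(float(t))
        self.snapshots.append(np.asarray(surface_displacement, float).ravel().copy())

    # dict-style access used by the analysis module
    def __getitem__(self, key):
        return np.asarray(getattr(self, key), dtype=float)

    def arrays(self) -> dict:
        out = {
            "t": np.asarray(self.t),
            "opening": np.asarray(self.opening),
            "q_inc": np.asarray(self.q_inc),
            "q_ac": np.asarray(self.q_ac),
            "q_total": np.asarray(self.q_total),
        }
        for k in range(len(self.probes)):
            out[f"probe{k}_P"] = np.asarray(self.probe_P[k])
            out[f"probe{k}_p_ac"] = np.asarray(self.probe_p_ac[k])
            out[f"probe{k}_p_total"] = out[f"probe{k}_P"] + out[f"probe{k}_p_ac"]
        return out

    def pod_of_vibration(self, n_modes=4):
        if len(self.snapshots) < 2:
            raise ValueError("not enough vibration snapshots for POD")
        return pod(np.asarray(self.snapshots), n_modes=n_modes)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def surface_traction(
    flow_solver: FlowSolver,
    flow_state,
    ac_state: AcousticState | None,
    markers: dict,
    include_viscous: bool = True,
) -> np.ndarray:
    """Per-marker traction vectors (Pa) on the fold surface.

    traction = -(P + p') n + mu (grad U + grad U^T) . n, with the fluid
    fields sampled a small distance off the surface on the fluid side
    (fluid-only interpolation stencils; nearest fluid cell as fallback).
    """
    pos = markers["position"]
    nrm = markers["normal"]
    grid = flow_solver.grid
    delta = 1.0 * np.array(
        [grid.min_width(0), grid.min_width(1)]
    ).min()
    probe = pos + delta * nrm
    sampler = flow_solver.sampler
    P = sampler.sample(flow_state.p, probe)
    if ac_state is not None:
        p_ac = sampler.sample(ac_state.p, probe)
    else:
        p_ac = np.zeros_like(P)
    traction = -(P + p_ac)[:, None] * nrm
    if include_viscous:
        mu = flow_solver.props.rho0 * flow_solver.props.nu0
        uc, vc = face_to_center(flow_state.u, flow_state.v)
        eps = delta
        grad = np.empty((pos.shape[0], 2, 2))
        for ax in range(2):
            dp = probe.copy()
            dm = probe.copy()
            dp[:, ax] += eps
            dm[:, ax] -= eps
            grad[:, 0, ax] = (sampler.sample(uc, dp) - sampler.sample(uc, dm)) / (2 * eps)
            grad[:, 1, ax] = (sampler.sample(vc, dp) - sampler.sample(vc, dm)) / (2 * eps)
        tau = mu * (grad + np.swapaxes(grad, 1, 2))
        traction = traction + np.einsum("kij,kj->ki", tau, nrm)
    return traction


def enforce_contact(
    state: SolidState, mesh: FEMesh, contact: ContactModel
) -> SolidState:
    """Project surface nodes that crossed their collision plane back onto
    it and bring them to rest (non-slip, non-penetration)."""
    out = state.copy()
    surf_nodes = np.unique(mesh.loaded_faces)
    x0 = mesh.nodes[surf_nodes, 0]
    x = x0 + out.d[surf_nodes, 0]
    side = np.where(x0 >= 0.0, 1.0, -1.0)
    crossed = side * x < contact.plane_offset
    if np.any(crossed):
        nodes = surf_nodes[crossed]
        out.d[nodes, 0] = side[crossed] * contact.plane_offset - x0[crossed]
        out.v[nodes] = 0.0
        out.a[nodes] = 0.0
    return out


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


class _CompositeSDF:
    """Duct SDF everywhere, overridden by the deformed fold polygons inside
    a narrow band around the fold bounding box (keeps per-step level-set
    rebuilds cheap)."""

    def __init__(self, duct_sdf, polygons, margin):
        self.duct_sdf = duct_sdf
        self.polygons = polygons
        lo = np.min([p.min(axis=0) for p in polygons], axis=0) - margin
        hi = np.max([p.max(axis=0) for p in polygons], axis=0) + margin
        self.lo, self.hi = lo, hi

    def __call__(self, points):
        points = np.atleast_2d(points)
        phi = np.asarray(self.duct_sdf(points), dtype=float).copy()
        inside = np.all((points >= self.lo) & (points <= self.hi), axis=1)
        if np.any(inside):
            sub = points[inside]
            d = polygon_signed_distance(sub, self.polygons[0])
            for poly in self.polygons[1:]:
                d = np.minimum(d, polygon_signed_distance(sub, poly))
            phi[inside] = np.minimum(phi[inside], d)
        return phi


@dataclass
class SimulationSetup:
    """Everything needed to run a coupled 2D phonation case."""

    duct: DuctSpec = field(default_factory=DuctSpec)
    fold: FoldSpec = field(default_factory=FoldSpec)
    grid: GridSpec | None = None
    fluid: FluidProperties = field(default_factory=FluidProperties)
    acoustic: AcousticProperties = field(default_factory=AcousticProperties)
    materials: dict = field(default_factory=lambda: dict(STANDARD_LAYERS))
    contact: ContactModel = field(default_factory=ContactModel)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    target_elements: int = 400
    upwind: float = 0.4
    filter_strength: float = 0.2
    include_viscous_traction: bool = True
    probes: tuple = ()
    outlet_plane: float | None = None
    effective_depth: float = 0.016
    rigid_folds: bool = False
    pressure_ramp: float = 1.0e-3  # s; inlet pressure rises linearly to dp_drive
    # develop the flow against rigid folds for this many steps, then start
    # the coupled run from the folds' static equilibrium under that load;
    # removes the slow mean-position settling from the transient
    static_init_steps: int = 0
    # exponential smoothing factor for the surface traction (1 = none).
    # The staggered flow->solid exchange is prone to an added-mass
    # two-step flip-flop when the glottis is narrow; smoothing over a few
    # steps (lag ~ dt/relax << one vibration cycle) suppresses it without
    # touching the physical frequencies.
    traction_relax: float = 0.2


class Simulation:
    """Owns the three solvers, the moving interface and the record."""

    PHASES = ("flow", "acoustics", "traction", "solid", "contact", "deform")

    def __init__(self, setup: SimulationSetup):
        self.setup = setup
        if setup.grid is None:
            raise ValueError("SimulationSetup.grid is required")
        if setup.grid.dim != 2:
            raise NotImplementedError(
                "the coupled solver runs 2D (mid-coronal) cases; the 3D code "
                "paths cover geometry, level sets and the FE solid only"
            )
        self.grid = setup.grid
        self.duct_ls = build_duct(setup.duct, self.grid)
        fold_ls, self.mesh = build_folds(
            setup.fold, self.grid, target_elements=setup.target_elements
        )
        self.solid = SolidSolver(self.mesh, setup.materials)
        self.solid_state = self.solid.initial_state()
        if setup.coupling.perturb > 0:
            rng = np.random.default_rng(setup.coupling.seed)
            noise = rng.standard_normal(self.solid_state.v.shape) * setup.coupling.perturb
            noise[self.mesh.fixed] = 0.0
            self.solid_state.v += noise
        self.levelset = self._make_levelset()
        self.flow = FlowSolver(
            self.grid,
            setup.fluid,
            levelset=self.levelset,
            upwind=setup.upwind,
            edge_bc=None,
        )
        if setup.pressure_ramp > 0:
            dp, ramp = setup.fluid.dp_drive, setup.pressure_ramp
            self.flow.edge_bc[(1, 0)] = (
                "pressure",
                lambda t: dp * min(1.0, t / ramp),
            )
        self.flow.boundary_velocity = self._boundary_velocity
        self.flow_state = self.flow.initial_state()
        self.acoustics = LpceSolver(
            self.grid,
            setup.acoustic,
            setup.fluid.rho0,
            edge_bc={(1, 0): "inlet", (1, 1): "open", (0, 0): "none", (0, 1): "none"},
            levelset=self.levelset,
            filter_strength=setup.filter_strength,
        )
        self.ac_state = AcousticState.zeros(self.grid)
        self.outlet_plane = (
            setup.outlet_plane
            if setup.outlet_plane is not None
            else float(self.grid.axes[1][-1])
        )
        self.record = GlottalRecord(setup.probes, setup.effective_depth)
        self.phase_log: list = []
        self.step_count = 0
        self._traction_smooth = None
        self._marker_tree = None
        self._update_markers()
        if setup.static_init_steps > 0 and not setup.rigid_folds:
            self._static_init(setup.static_init_steps)
        self._record_step()

    # -- interface helpers --------------------------------------------------
    def _deformed_polygons(self):
        pos = self.mesh.nodes + self.solid_state.d
        return [pos[self.mesh.boundary_loops[s]] for s in (1, -1)]

    def _make_levelset(self) -> LevelSet:
        polys = self._deformed_polygons()
        margin = 4 * max(self.grid.min_width(0), self.grid.min_width(1))
        sdf = _CompositeSDF(self.duct_ls.sdf, polys, margin)
        mesh = self.grid.center_mesh()
        pts = np.column_stack([m.ravel() for m in mesh])
        phi = sdf(pts).reshape(self.grid.shape)
        return LevelSet(grid=self.grid, phi=phi, sdf=sdf)

    def _update_markers(self):
        self.markers = fold_surface_markers(
            self.mesh, self.solid_state.d, self.solid_state.v
        )
        self._marker_tree = cKDTree(self.markers["position"])

    def _boundary_velocity(self, points):
        """Tissue velocity at wall points: nearest fold marker, zero on the
        static duct walls (i.e. beyond a few cells from any marker)."""
        dist, idx = self._marker_tree.query(np.atleast_2d(points))
        vel = self.markers["velocity"][idx]
        reach = 4.0 * max(self.grid.min_width(0), self.grid.min_width(1))
        return np.where(dist[:, None] <= reach, vel, 0.0)

    def glottal_opening(self) -> float:
        """Minimum fold-to-fold distance across the medial plane."""
        pos = self.mesh.nodes + self.solid_state.d
        surf = np.unique(self.mesh.loaded_faces)
        x0 = self.mesh.nodes[surf, 0]
        xr = pos[surf[x0 >= 0], 0]
        xl = pos[surf[x0 < 0], 0]
        return float(xr.min() - xl.max())

    def glottal_gap_profile(self):
        """Gap vs axial position along the medial surfaces (right - left)."""
        pos = self.mesh.nodes + self.solid_state.d
        med = np.unique(
            self.mesh.loaded_faces[self.mesh.loaded_tag == "medial"]
        )
        x0 = self.mesh.nodes[med, 0]
        right = pos[med[x0 >= 0]]
        left = pos[med[x0 < 0]]
        right = right[np.argsort(right[:, 1])]
        left = left[np.argsort(left[:, 1])]
        y = right[:, 1]
        xl = np.interp(y, left[:, 1], left[:, 0])
        return y, right[:, 0] - xl

    # -- the Table-1 style loop ---------------------------------------------
    def step(self):
        su = self.setup
        dt = su.coupling.dt_flow
        # 1: incompressible flow with current lumen shape and wall velocity
        prev_flow = self.flow_state
        self.flow_state = self.flow.step(prev_flow, dt)
        self.phase_log.append("flow")
        # 2: acoustic subcycles with the updated flow as frozen background
        source = material_derivative_P(prev_flow, self.flow_state, dt, self.grid)
        uc, vc = face_to_center(self.flow_state.u, self.flow_state.v)
        self.acoustics.set_mean_flow([uc, vc], self.flow_state.p, source)
        dt_ac = dt / su.coupling.n_subcycles
        self.acoustics.check_cfl(dt_ac)
        self.ac_state = self.acoustics.step_many(
            self.ac_state, dt_ac, su.coupling.n_subcycles, check_cfl=False
        )
        self.phase_log.append("acoustics")
        # 3: surface traction from P, U, p', u'
        tr = surface_traction(
            self.flow,
            self.flow_state,
            self.ac_state,
            self.markers,
            include_viscous=su.include_viscous_traction,
        )
        alpha = su.traction_relax
        if alpha < 1.0:
            if self._traction_smooth is None:
                self._traction_smooth = tr
            else:
                self._traction_smooth = alpha * tr + (1.0 - alpha) * self._traction_smooth
            tr = self._traction_smooth
        self.phase_log.append("traction")
        # 4: solid step
        if not su.rigid_folds:
            forces = self.solid.traction_forces(tr, self.solid_state.d)
            self.solid_state = self.solid.step(self.solid_state, forces, dt)
        self.phase_log.append("solid")
        # 5: contact + lumen deformation
        self.solid_state = enforce_contact(self.solid_state, self.mesh, su.contact)
        self.phase_log.append("contact")
        self._update_markers()
        self.levelset = self._make_levelset()
        old_fluid_u = self.flow.fluid_u
        old_fluid_v = self.flow.fluid_v
        self.flow.set_levelset(self.levelset, self._boundary_velocity)
        self._fill_fresh_velocity(old_fluid_u, old_fluid_v)
        fresh = self.acoustics.refresh_levelset(self.levelset)
        self.acoustics.fill_fresh_cells(self.ac_state, fresh)
        self.phase_log.append("deform")
        self.step_count += 1
        if self.step_count % su.coupling.record_every == 0:
            self._record_step()
        if self.step_count % su.coupling.snapshot_every == 0:
            self._snapshot()

    def _static_init(self, n_steps: int) -> None:
        """Start from the folds' static deflection under the developed flow.

        The flow is integrated against the undeformed (rigid) folds until
        the pressure distribution is established, the resulting traction
        is applied in a static solve (with contact projection), and the
        clocks are reset so the coupled run starts at t = 0 from that
        equilibrium with quiescent tissue.
        """
        su = self.setup
        dt = su.coupling.dt_flow
        for _ in range(n_steps):
            prev = self.flow_state
            self.flow_state = self.flow.step(prev, dt)
            source = material_derivative_P(prev, self.flow_state, dt, self.grid)
            uc, vc = face_to_center(self.flow_state.u, self.flow_state.v)
            self.acoustics.set_mean_flow([uc, vc], self.flow_state.p, source)
            self.ac_state = self.acoustics.step_many(
                self.ac_state, dt / su.coupling.n_subcycles,
                su.coupling.n_subcycles, check_cfl=False,
            )
        tr = surface_traction(
            self.flow, self.flow_state, self.ac_state, self.markers,
            include_viscous=su.include_viscous_traction,
        )
        d = self.solid.static_solve(self.solid.traction_forces(tr))
        self.solid_state.d[...] = d
        self.solid_state.v[...] = 0.0
        self.solid_state.a[...] = 0.0
        self.solid_state = enforce_contact(self.solid_state, self.mesh, su.contact)
        self._update_markers()
        self.levelset = self._make_levelset()
        self.flow.set_levelset(self.levelset, self._boundary_velocity)
        self.acoustics.set_levelset(self.levelset)
        # restart the clocks; keep the developed flow and acoustic fields,
        # and pin the inlet at the full driving pressure (ramp is over)
        self.flow.edge_bc[(1, 0)] = ("pressure", su.fluid.dp_drive)
        self.flow_state.t = 0.0
        self.ac_state.t = 0.0
        self.solid_state.t = 0.0
        self._traction_smooth = None

    def refresh_geometry(self):
        """Rebuild the interface and cell tags from the current solid state
        (used after restoring a checkpoint)."""
        self._update_markers()
        self.levelset = self._make_levelset()
        self.flow.set_levelset(self.levelset, self._boundary_velocity)
        self.acoustics.set_levelset(self.levelset)

    def _fill_fresh_velocity(self, old_u, old_v):
        for old, mirror, f, comp in (
            (old_u, self.flow.mirror_u, self.flow_state.u, 0),
            (old_v, self.flow.mirror_v, self.flow_state.v, 1),
        ):
            fresh = mirror.fluid_mask & ~old
            if np.any(fresh):
                pts = np.argwhere(fresh)
                coords = np.column_stack(
                    [mirror.coords[ax][pts[:, ax]] for ax in range(2)]
                )
                f[fresh] = self._boundary_velocity(coords)[:, comp]

    def _record_step(self):
        q_inc = (
            self.flow.outlet_flowrate(self.flow_state, self.outlet_plane)
            * self.setup.effective_depth
        )
        q_ac = (
            self.acoustics.flowrate(self.ac_state, self.outlet_plane)
            * self.setup.effective_depth
        )
        probes = self.setup.probes
        P_vals, pac_vals = [], []
        if probes:
            pts = np.asarray(probes, dtype=float)
            P_vals = self.flow.sampler.sample(self.flow_state.p, pts)
            pac_vals = self.flow.sampler.sample(self.ac_state.p, pts)
        self.record.append(
            self.flow_state.t, self.glottal_opening(), q_inc, q_ac, P_vals, pac_vals
        )

    def _snapshot(self):
        med = np.unique(self.mesh.loaded_faces[self.mesh.loaded_tag == "medial"])
        self.record.add_snapshot(self.flow_state.t, self.solid_state.d[med])

    def run(self, n_steps: int | None = None, progress=None):
        n = n_steps if n_steps is not None else self.setup.coupling.n_steps
        for k in range(n):
            self.step()
            if progress is not None and (k + 1) % progress == 0:
                q = self.record.q_total[-1] if self.record.q_total else 0.0
                cfl = getattr(self.acoustics, "last_cfl", float("nan"))
                print(
                    f"step {self.step_count}  t={self.flow_state.t * 1e3:.3f} ms  "
                    f"gap={self.glottal_opening() * 1e3:.3f} mm  Q={q * 1e6:.1f} mL/s  "
                    f"res={self.flow_state.div_residual:.2e}  ac_cfl={cfl:.2f}",
                    flush=True,
                )
        return self.record
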