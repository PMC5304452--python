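import numpy as np
import pytest

from phonosim.coupling import (
    ContactModel,
    CouplingConfig,
    Simulation,
    SimulationSetup,
    enforce_contact,
    surface_traction,
)
from phonosim.flow import FlowSolver, FluidProperties
from phonosim.geometry import DuctSpec, FoldSpec, build_folds
from phonosim.grid import GridSpec, stretched_axis
from phonosim.solid import STANDARD_LAYERS, MaterialLayer, SolidSolver


from _fixtures import small_setup


@pytest.fixture(scope="module")
def mini_sim():
    sim = Simulation(small_setup())
    sim.run(5)
    return sim


class TestContactModel:
    def test_invariant_min_gap_twice_offset(self):
        with pytest.raises(ValueError):
            ContactModel(plane_offset=1e-4, min_gap=3e-4)

    def test_no_crossing_is_identity(self, channel_grid, fold_spec):
        _, mesh = build_folds(fold_spec, channel_grid, target_elements=150)
        solver = SolidSolver(mesh)
        st = solver.initial_state()
        st.d[...] = 1e-5
        out = enforce_contact(st, mesh, ContactModel())
        assert np.array_equal(out.d, st.d)
        assert np.array_equal(out.v, st.v)

    def test_crossing_node_lands_on_plane_at_rest(self, channel_grid, fold_spec):
        _, mesh = build_folds(fold_spec, channel_grid, target_elements=150)
        solver = SolidSolver(mesh)
        st = solver.initial_state()
        contact = ContactModel()
        # push every right-fold surface node 0.05 mm past its plane
        surf = np.unique(mesh.loaded_faces)
        right = surf[mesh.nodes[surf, 0] >= 0]
        st.d[right, 0] = contact.plane_offset - 5e-5 - mesh.nodes[right, 0]
        st.v[right] = -0.3
        out = enforce_contact(st, mesh, contact)
        x_new = mesh.nodes[right, 0] + out.d[right, 0]
        assert np.allclose(x_new, contact.plane_offset)
        assert np.all(out.v[right] == 0.0)

    def test_sinusoidal_forced_motion_clips_gap_at_minimum(self, channel_grid):
        # prescribed penetrating motion: the enforced minimum glottal gap
        # equals exactly 2 x plane offset = 0.2 mm over the whole cycle
        fold = FoldSpec(half_gap=3.0e-4)
        _, mesh = build_folds(fold, channel_grid, target_elements=150)
        solver = SolidSolver(mesh)
        contact = ContactModel(plane_offset=1.0e-4, min_gap=2.0e-4)
        surf = np.unique(mesh.loaded_faces)
        side = np.where(mesh.nodes[surf, 0] >= 0, 1.0, -1.0)
        min_gap_seen = np.inf
        for t in np.linspace(0, 1, 200):
            st = solver.initial_state()
            # drive both folds through the midline and back
            st.d[surf, 0] = -side * 5.0e-4 * np.sin(2 * np.pi * t)
            st = enforce_contact(st, mesh, contact)
            pos = mesh.nodes[surf, 0] + st.d[surf, 0]
            gap = pos[side > 0].min() - pos[side < 0].max()
            min_gap_seen = min(min_gap_seen, gap)
        assert min_gap_seen == pytest.approx(contact.min_gap, rel=1e-12)


class TestSurfaceTraction:
    def _static_flow(self, p_field):
        grid = GridSpec([np.linspace(-0.0105, 0.0105, 43),
                         np.linspace(-0.0305, 0.18, 73)])
        solver = FlowSolver(grid, FluidProperties(dp_drive=0.0))
        st = solver.initial_state()
        X, Y = grid.center_mesh()
        st.p[...] = p_field(X, Y)
        return grid, solver, st

    def test_uniform_pressure_pushes_along_negative_normal(self, fold_spec):
        grid, solver, st = self._static_flow(lambda X, Y: np.full_like(X, 120.0))
        _, mesh = build_folds(fold_spec, grid, target_elements=200)
        from phonosim.geometry import fold_surface_markers

        markers = fold_surface_markers(mesh)
        tr = surface_traction(solver, st, None, markers, include_viscous=False)
        expected = -120.0 * markers["normal"]
        assert np.allclose(tr, expected, atol=1e-9)

    def test_acoustic_pressure_reaches_the_solid(self, fold_spec):
        grid, solver, st = self._static_flow(lambda X, Y: np.zeros_like(X))
        _, mesh = build_folds(fold_spec, grid, target_elements=200)
        from phonosim.acoustics import AcousticState
        from phonosim.geometry import fold_surface_markers

        ac = AcousticState.zeros(grid)
        ac.p[...] = 35.0
        markers = fold_surface_markers(mesh)
        tr = surface_traction(solver, st, ac, markers, include_viscous=False)
        assert np.allclose(tr, -35.0 * markers["normal"], atol=1e-9)

    def test_linear_pressure_net_force_matches_divergence_theorem(self, fold_spec):
        a = 5000.0  # Pa/m along y
        grid, solver, st = self._static_flow(lambda X, Y: a * Y)
        _, mesh = build_folds(fold_spec, grid, target_elements=800)
        from phonosim.geometry import fold_surface_markers

        markers = fold_surface_markers(mesh)
        tr = surface_traction(solver, st, None, markers, include_viscous=False)
        solver_s = SolidSolver(mesh, STANDARD_LAYERS)
        f = solver_s.traction_forces(tr)
        net = f.sum(axis=0)
        # brute-force quadrature oracle: midpoint rule over the loaded
        # faces with the same fluid-side probe offset convention
        delta = min(solver.grid.min_width(0), solver.grid.min_width(1))
        pos, nrm = markers["position"], markers["normal"]
        meas = solver_s.face_measures()
        p_probe = a * (pos[:, 1] + delta * nrm[:, 1])
        expected = np.sum(-p_probe[:, None] * nrm * meas[:, None], axis=0)
        assert net[0] == pytest.approx(expected[0], abs=0.01 * abs(expected[1]))
        assert net[1] == pytest.approx(expected[1], rel=0.01)


class TestCoupledLoop:
    def test_phase_ordering_follows_the_staggered_scheme(self, mini_sim):
        per_step = len(Simulation.PHASES)
        log = mini_sim.phase_log
        assert len(log) % per_step == 0
        for k in range(0, len(log), per_step):
            assert tuple(log[k : k + per_step]) == Simulation.PHASES

    def test_flow_decomposition_identity(self, mini_sim):
        r = mini_sim.record
        q = np.asarray(r.q_total)
        assert np.allclose(q, np.asarray(r.q_inc) + np.asarray(r.q_ac), atol=1e-18)

    def test_record_schema(self, mini_sim):
        arrays = mini_sim.record.arrays()
        for key in ("t", "opening", "q_inc", "q_ac", "q_total"):
            assert key in arrays
            assert arrays[key].shape == arrays["t"].shape

    def test_symmetric_start_opening_equals_rest_gap(self):
        sim = Simulation(small_setup(rigid_folds=True))
        sim.run(3)
        assert np.allclose(sim.record.opening, 2 * sim.setup.fold.half_gap, atol=1e-12)

    def test_prescribed_fold_motion_opening_matches_closed_form(self):
        sim = Simulation(small_setup(rigid_folds=True))
        surf = np.unique(sim.mesh.loaded_faces)
        side = np.where(sim.mesh.nodes[surf, 0] >= 0, 1.0, -1.0)
        for amp in (1e-4, 2.4e-4):
            sim.solid_state.d[:] = 0.0
            sim.solid_state.d[surf, 0] = side * amp
            expected = 2 * (sim.setup.fold.half_gap + amp)
            assert sim.glottal_opening() == pytest.approx(expected, rel=1e-12)

    def test_rigid_limit_reproduces_flow_only_fields(self):
        # folds 1e6 x stiffer: displacement negligible, flow equals the
        # rigid-geometry run to a tight tolerance
        stiff = {
            n: MaterialLayer(l.rho, l.E_p * 1e6, l.nu_p, l.E_pz * 1e6,
                             l.nu_pz, l.G_pz * 1e6, l.eta)
            for n, l in STANDARD_LAYERS.items()
        }
        sim_stiff = Simulation(small_setup(materials=stiff))
        sim_rigid = Simulation(small_setup(rigid_folds=True))
        n = 60
        sim_stiff.run(n)
        sim_rigid.run(n)
        assert np.abs(sim_stiff.solid_state.d).max() < 1e-8
        # scales set by the driving pressure drop
        p_scale = 800.0
        u_scale = np.sqrt(2 * p_scale / 1.1455)
        dp = np.abs(sim_stiff.flow_state.p - sim_rigid.flow_state.p).max()
        dv = np.abs(sim_stiff.flow_state.v - sim_rigid.flow_state.v).max()
        assert dp < 1e-6 * p_scale
        assert dv < 1e-6 * u_scale
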