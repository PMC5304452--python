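import numpy as np
import pytest

from phonosim.geometry import FEMesh, FoldSpec, build_folds
from phonosim.grid import GridSpec
from phonosim.solid import (
    STANDARD_LAYERS,
    MaterialLayer,
    SolidSolver,
    assemble,
    elasticity_tensor,
    plane_strain_tensor,
)


from _fixtures import block_mesh, isotropic_layer


class TestElasticityTensor:
    def test_isotropic_degenerate_case_is_hooke(self):
        E, nu = 1000.0, 0.3
        C = elasticity_tensor(isotropic_layer(E, nu))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        expected = np.zeros((6, 6))
        expected[:3, :3] = lam
        expected[np.arange(3), np.arange(3)] = lam + 2 * mu
        expected[np.arange(3, 6), np.arange(3, 6)] = mu
        assert np.allclose(C, expected, rtol=1e-10)

    @pytest.mark.parametrize("name", ["cover", "ligament", "body"])
    def test_tissue_layers_symmetric_positive_definite(self, name):
        C = elasticity_tensor(STANDARD_LAYERS[name])
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C)[0] > 0

    def test_longitudinal_uniaxial_strain_decouples_at_zero_poisson(self):
        layer = MaterialLayer(1043.0, 2010.0, 0.9, 40000.0, 0.0, 10000.0, 0.0)
        C = elasticity_tensor(layer)
        strain = np.zeros(6)
        strain[2] = 1.0  # unit strain along the anterior-posterior axis
        stress = C @ strain
        assert stress[2] == pytest.approx(layer.E_pz, rel=1e-9)
        assert abs(stress[0]) < 1e-6 * layer.E_pz
        assert abs(stress[1]) < 1e-6 * layer.E_pz

    def test_invalid_tensor_reports_eigenvalue(self):
        with pytest.raises(ValueError, match="positive"):
            MaterialLayer(1000.0, 1000.0, 0.999, 1000.0, 0.9, 100.0, 0.0)


class TestAssembly:
    def test_rigid_translation_has_zero_elastic_force(self, fold_spec, channel_grid):
        _, mesh = build_folds(fold_spec, channel_grid, target_elements=200)
        M, K, C = assemble(mesh, STANDARD_LAYERS)
        d = np.tile([1.0e-3, -2.0e-3], (mesh.nodes.shape[0], 1)).ravel()
        assert np.abs(K @ d).max() < 1e-9 * np.abs(K.data).max()

    def test_total_mass_is_density_times_volume(self, fold_spec, channel_grid):
        _, mesh = build_folds(fold_spec, channel_grid, target_elements=200)
        M, _, _ = assemble(mesh, STANDARD_LAYERS)
        vol = mesh.element_volumes().sum()
        assert M.sum() == pytest.approx(mesh.dim * 1043.0 * vol, rel=1e-9)

    def test_single_element_constant_strain_patch(self):
        # one CST element: uniform strain must give the hand-computed stress
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        mesh = FEMesh(
            nodes=nodes,
            elements=np.array([[0, 1, 2]]),
            layer=np.zeros(1, np.int8),
            side=np.ones(1, np.int8),
            fixed=np.zeros(3, bool),
            loaded_faces=np.array([[1, 2]]),
            loaded_tag=np.array(["medial"]),
        )
        layer = isotropic_layer(E=1000.0, nu=0.25)
        _, K, _ = assemble(mesh, {"cover": layer})
        # impose u = [a x, 0]: uniform strain exx = a, eyy = gxy = 0
        a = 1e-3
        d = np.zeros((3, 2))
        d[:, 0] = a * nodes[:, 0]
        f = (K @ d.ravel()).reshape(3, 2)
        Cp = plane_strain_tensor(layer)
        sxx, syy = Cp[0, 0] * a, Cp[1, 0] * a
        # hand assembly: f = area * B^T sigma with the CST shape gradients
        # b = [-1, 1, 0], c = [-1, 0, 1] (area 1/2, unit triangle)
        b = np.array([-1.0, 1.0, 0.0])
        c = np.array([-1.0, 0.0, 1.0])
        expected = 0.5 * np.column_stack([b * sxx, c * syy])
        assert np.allclose(f, expected, rtol=1e-9)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_untagged_element_rejected(self, fold_spec, channel_grid):
        _, mesh = build_folds(fold_spec, channel_grid, target_elements=100)
        mesh.layer[0] = 7
        with pytest.raises(ValueError, match="layer"):
            assemble(mesh, STANDARD_LAYERS)


class TestDynamics:
    def test_zero_traction_keeps_rest_state(self, fold_spec, channel_grid):
        _, mesh = build_folds(fold_spec, channel_grid, target_elements=150)
        solver = SolidSolver(mesh)
        st = solver.initial_state()
        st2 = solver.step(st, np.zeros_like(st.d), 1e-5)
        assert np.all(st2.d == 0) and np.all(st2.v == 0)

    def test_cantilever_tip_deflection_matches_beam_theory(self):
        L, h = 0.06, 0.004
        mesh = block_mesh(90, 12, L, h)
        layer = isotropic_layer(E=5000.0, nu=0.0)
        solver = SolidSolver(mesh, {"cover": layer})
        P = 0.01  # N per unit depth, applied at the free end
        tr = np.tile([0.0, P / h], (len(mesh.loaded_faces), 1))
        f = solver.traction_forces(tr)
        d = solver.static_solve(f)
        tip = d[np.argmax(mesh.nodes[:, 0] + 1e3 * (mesh.nodes[:, 1] == h / 2)), 1]
        tip = d[mesh.nodes[:, 0].argmax(), 1]
        I = h**3 / 12.0
        euler = P * L**3 / (3 * layer.E_p * I)
        assert tip == pytest.approx(euler, rel=0.05)

    def test_free_vibration_frequency_matches_eigensolution(self):
        mesh = block_mesh(24, 6, 0.02, 0.005)
        layer = isotropic_layer(E=4000.0, nu=0.3, rho=1043.0)
        solver = SolidSolver(mesh, {"cover": layer})
        freqs, vecs = solver.eigenmodes(2)
        f1 = freqs[0]
        # kick the beam in its first mode and watch it ring
        st = solver.initial_state()
        mode = np.zeros(mesh.nodes.size)
        mode[solver.free] = vecs[:, 0]
        st.d[...] = 1e-5 * mode.reshape(-1, 2) / np.abs(mode).max()
        dt = 1.0 / (f1 * 60)
        n = int(round(4 / (f1 * dt)))
        tip = np.empty(n)
        probe = mesh.nodes[:, 0].argmax()
        for k in range(n):
            st = solver.step(st, np.zeros_like(st.d), dt)
            tip[k] = st.d[probe, 1]
        from phonosim.analysis import dominant_frequency

        f_meas = dominant_frequency(tip, 1.0 / dt)
        assert f_meas == pytest.approx(f1, rel=0.02)

    def test_undamped_newmark_conserves_energy(self):
        mesh = block_mesh(12, 4, 0.02, 0.005)
        solver = SolidSolver(mesh, {"cover": isotropic_layer(eta=0.0)})
        st = solver.initial_state()
        rng = np.random.default_rng(3)
        st.v[...] = rng.standard_normal(st.v.shape) * 1e-3
        st.v[mesh.fixed] = 0.0
        e0 = solver.energy(st)
        for _ in range(1000):
            st = solver.step(st, np.zeros_like(st.d), 2e-5)
        assert solver.energy(st) == pytest.approx(e0, rel=1e-8)

    def test_viscous_damping_dissipates_energy(self):
        mesh = block_mesh(12, 4, 0.02, 0.005)
        solver = SolidSolver(mesh, {"cover": isotropic_layer(eta=0.5)})
        st = solver.initial_state()
        rng = np.random.default_rng(3)
        st.v[...] = rng.standard_normal(st.v.shape) * 1e-3
        st.v[mesh.fixed] = 0.0
        energies = [solver.energy(st)]
        for _ in range(400):
            st = solver.step(st, np.zeros_like(st.d), 2e-5)
            energies.append(solver.energy(st))
        diffs = np.diff(energies)
        assert energies[-1] < 0.9 * energies[0]
        assert np.all(diffs <= 1e-12 * energies[0])

    def test_large_longitudinal_moduli_constrain_motion_in_plane(self, fold_spec):
        # 3D fold pair under a physiological surface load.  The large
        # longitudinal moduli realize the in-plane motion constraint two
        # ways: the response stays in-plane dominated, and the fundamental
        # frequency rises several-fold over an equally soft isotropic fold
        # (clamped-end bending kinematics put a floor ~h/L on the axial
        # fraction itself, independent of the moduli).
        grid = GridSpec([
            np.linspace(-0.0105, 0.0105, 25),
            np.linspace(-0.005, 0.011, 17),
            np.linspace(-0.002, 0.018, 17),
        ])
        _, mesh = build_folds(fold_spec, grid, target_elements=900, nz=6)
        assert mesh.dim == 3
        solver = SolidSolver(mesh, STANDARD_LAYERS)
        tr = np.zeros((len(mesh.loaded_faces), 3))
        side = np.where(mesh.nodes[mesh.loaded_faces[:, 0], 0] >= 0, 1.0, -1.0)
        tr[:, 0] = np.where(mesh.loaded_tag == "medial", 800.0 * side, 0.0)
        tr[:, 1] = np.where(mesh.loaded_tag == "inferior", 800.0, 0.0)
        d = solver.static_solve(solver.traction_forces(tr))
        axial = np.abs(d[:, 2]).max()
        inplane = np.abs(d[:, :2]).max()
        assert axial < 0.20 * inplane

        iso = {
            n: MaterialLayer(l.rho, l.E_p, 0.45, l.E_p, 0.45,
                             l.E_p / (2 * 1.45), l.eta)
            for n, l in STANDARD_LAYERS.items()
        }
        f1_aniso = solver.eigenmodes(1)[0][0]
        f1_iso = SolidSolver(mesh, iso).eigenmodes(1)[0][0]
        assert f1_aniso > 2.5 * f1_iso
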