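"""Finite-element vocal fold dynamics.

The tissue obeys the momentum (Navier) equation with a linear
transversely isotropic elastic stress and Kelvin-Voigt viscosity: each of
the cover / ligament / body layers carries its own transverse modulus
E_p, transverse Poisson ratio nu_p, longitudinal modulus E_pz, coupling
ratio nu_pz, longitudinal shear modulus G_pz and viscosity eta.  The
isotropy plane is the coronal (x-y) plane; the symmetry axis is the
anterior-posterior z axis, where large E_pz emulates the longitudinal
tension that keeps fold motion nearly in-plane.

Space is discretized with linear simplices (CST triangles / tet4), time
with Newmark-beta (average acceleration, gamma = 1/2, beta = 1/4).  In 2D
the cross section is treated as plane strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import FEMesh, LAYER_NAMES

__all__ = [
    "MaterialLayer",
    "SolidState",
    "elasticity_tensor",
    "plane_strain_tensor",
    "SolidSolver",
    "assemble",
]

# Voigt order: xx, yy, zz, yz, xz, xy (engineering shear strains)
_VISC_VOIGT = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])


@dataclass
class MaterialLayer:
    """Transversely isotropic viscoelastic constants of one tissue layer (SI)."""

    rho: float = 1043.0      # kg/m^3
    E_p: float = 2010.0      # Pa, in-plane (coronal) Young's modulus
    nu_p: float = 0.9        # in-plane Poisson ratio
    E_pz: float = 40000.0    # Pa, longitudinal Young's modulus
    nu_pz: float = 0.0       # plane-longitudinal Poisson ratio
    G_pz: float = 10000.0    # Pa, longitudinal shear modulus
    eta: float = 0.5         # Pa s, Kelvin-Voigt viscosity

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("tissue density must be positive")
        if self.eta < 0:
            raise ValueError("viscosity must be non-negative")
        elasticity_tensor(self)  # raises if not positive definite


def elasticity_tensor(layer: MaterialLayer) -> np.ndarray:
    """6x6 stiffness matrix (Voigt) for a transversely isotropic material.

    Isotropy plane x-y, symmetry axis z.  Built by inverting the standard
    5-constant compliance; raises if the result is not symmetric positive
    definite (listing the offending eigenvalue).
    """
    Ep, nup, Ez, nupz, Gz = layer.E_p, layer.nu_p, layer.E_pz, layer.nu_pz, layer.G_pz
    if min(Ep, Ez, Gz) <= 0:
        raise ValueError("elastic moduli must be positive")
    S = np.zeros((6, 6))
    S[0, 0] = S[1, 1] = 1.0 / Ep
    S[0, 1] = S[1, 0] = -nup / Ep
    S[2, 2] = 1.0 / Ez
    S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = -nupz / Ez
    S[3, 3] = S[4, 4] = 1.0 / Gz
    S[5, 5] = 2.0 * (1.0 + nup) / Ep
    C = np.linalg.inv(S)
    C = 0.5 * (C + C.T)
    w = np.linalg.eigvalsh(C)
    if w[0] <= 0:
        raise ValueError(
            f"elasticity tensor not positive definite (eigenvalue {w[0]:.4g})"
        )
    return C


# reference values for the three layers (cover, ligament, body), stored SI
STANDARD_LAYERS = {
    "cover": MaterialLayer(1043.0, 2010.0, 0.9, 40000.0, 0.0, 10000.0, 0.5),
    "ligament": MaterialLayer(1043.0, 3310.0, 0.9, 66000.0, 0.0, 40000.0, 0.75),
    "body": MaterialLayer(1043.0, 3990.0, 0.9, 80000.0, 0.0, 20000.0, 1.25),
}


def plane_strain_tensor(layer: MaterialLayer) -> np.ndarray:
    """3x3 in-plane stiffness (xx, yy, xy) under plane strain in z."""
    C = elasticity_tensor(layer)
    idx = np.array([0, 1, 5])
    return C[np.ix_(idx, idx)]


@dataclass
class SolidState:
    d: np.ndarray  # (N, dim) nodal displacement
    v: np.ndarray  # (N, dim) nodal velocity
    a: np.ndarray  # (N, dim) nodal acceleration
    t: float = 0.0

    def copy(self) -> "SolidState":
        return SolidState(self.d.copy(), self.v.copy(), self.a.copy(), self.t)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _b_matrix(pts: np.ndarray):
    """Strain-displacement matrix and volume of one linear simplex."""
    dim = pts.shape[1]
    if dim == 2:
        x, y = pts[:, 0], pts[:, 1]
        area2 = (x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0])
        bi = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]]) / area2
        ci = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / area2
        B = np.zeros((3, 6))
        B[0, 0::2] = bi
        B[1, 1::2] = ci
        B[2, 0::2] = ci
        B[2, 1::2] = bi
        return B, abs(area2) / 2.0
    # tet4
    M = np.hstack([np.ones((4, 1)), pts])
    vol6 = np.linalg.det(M)
    Minv = np.linalg.inv(M)
    grads = Minv[1:, :]  # (3 derivs, 4 nodes)
    B = np.zeros((6, 12))
    for n in range(4):
        gx, gy, gz = grads[:, n]
        B[0, 3 * n] = gx
        B[1, 3 * n + 1] = gy
        B[2, 3 * n + 2] = gz
        B[3, 3 * n + 1] = gz
        B[3, 3 * n + 2] = gy
        B[4, 3 * n] = gz
        B[4, 3 * n + 2] = gx
        B[5, 3 * n] = gy
        B[5, 3 * n + 1] = gx
    return B, abs(vol6) / 6.0


def assemble(mesh: FEMesh, layers: dict, lumped_mass: bool = False):
    """Mass, stiffness and Kelvin-Voigt damping matrices (CSR, full DOF set).

    ``layers`` maps layer name -> :class:`MaterialLayer`; every element
    must carry a valid layer tag.
    """
    dim = mesh.dim
    n_dof = mesh.nodes.shape[0] * dim
    if np.any(mesh.layer < 0) or np.any(mesh.layer >= len(LAYER_NAMES)):
        raise ValueError("untagged element: every element needs a layer")
    missing = [LAYER_NAMES[i] for i in np.unique(mesh.layer) if LAYER_NAMES[i] not in layers]
    if missing:
        raise ValueError(f"missing material definition for layers: {missing}")

    C_by_layer = {}
    visc_by_layer = {}
    for i, name in enumerate(LAYER_NAMES):
        if name not in layers:
            continue
        lay = layers[name]
        if dim == 2:
            C_by_layer[i] = plane_strain_tensor(lay)
            visc_by_layer[i] = lay.eta * np.diag([1.0, 1.0, 0.5])
        else:
            C_by_layer[i] = elasticity_tensor(lay)
            visc_by_layer[i] = lay.eta * _VISC_VOIGT

    npe = dim + 1
    ndpe = npe * dim
    rows, cols = [], []
    kv, cv, mv = [], [], []
    for e, conn in enumerate(mesh.elements):
        pts = mesh.nodes[conn]
        B, vol = _b_matrix(pts)
        li = int(mesh.layer[e])
        rho = layers[LAYER_NAMES[li]].rho
        Ke = B.T @ C_by_layer[li] @ B * vol
        Ce = B.T @ visc_by_layer[li] @ B * vol
        if lumped_mass:
            Me = np.eye(ndpe) * rho * vol / npe
        else:
            # consistent mass for linear simplices
            Mn = (np.ones((npe, npe)) + np.eye(npe)) * rho * vol / (npe * (npe + 1))
            Me = np.kron(Mn, np.eye(dim))
        dof = (conn[:, None] * dim + np.arange(dim)[None, :]).ravel()
        rr, cc = np.meshgrid(dof, dof, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        kv.append(Ke.ravel())
        cv.append(Ce.ravel())
        mv.append(Me.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    shape = (n_dof, n_dof)
    K = sp.csr_matrix((np.concatenate(kv), (rows, cols)), shape=shape)
    C = sp.csr_matrix((np.concatenate(cv), (rows, cols)), shape=shape)
    M = sp.csr_matrix((np.concatenate(mv), (rows, cols)), shape=shape)
    return M, K, C


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


class SolidSolver:
    """Newmark-beta integrator for the assembled fold system.

    Fixed-boundary DOFs are eliminated; the effective matrix is factorized
    once per (dt) and reused.  Surface tractions arrive per loaded face and
    are converted to consistent nodal forces.
    """

    def __init__(
        self,
        mesh: FEMesh,
        layers: dict | None = None,
        lumped_mass: bool = False,
        gamma: float = 0.5,
        beta: float = 0.25,
    ):
        self.mesh = mesh
        self.layers = dict(layers or STANDARD_LAYERS)
        self.gamma, self.beta = gamma, beta
        self.M, self.K, self.C = assemble(mesh, self.layers, lumped_mass)
        dim = mesh.dim
        free = ~np.repeat(mesh.fixed, dim)
        self.free = free
        self.Mf = self.M[free][:, free].tocsc()
        self.Kf = self.K[free][:, free].tocsc()
        self.Cf = self.C[free][:, free].tocsc()
        self._dt = None
        self._lu = None

    def initial_state(self) -> SolidState:
        n, dim = self.mesh.nodes.shape
        return SolidState(np.zeros((n, dim)), np.zeros((n, dim)), np.zeros((n, dim)))

    # -- loads --------------------------------------------------------------
    def face_measures(self, displacement: np.ndarray | None = None) -> np.ndarray:
        pos = self.mesh.nodes if displacement is None else self.mesh.nodes + displacement
        fpts = pos[self.mesh.loaded_faces]
        if self.mesh.dim == 2:
            return np.linalg.norm(fpts[:, 1] - fpts[:, 0], axis=1)
        return 0.5 * np.linalg.norm(
            np.cross(fpts[:, 1] - fpts[:, 0], fpts[:, 2] - fpts[:, 0]), axis=1
        )

    def traction_forces(
        self, tractions: np.ndarray, displacement: np.ndarray | None = None
    ) -> np.ndarray:
        """Consistent nodal forces from per-face traction vectors (Pa)."""
        n, dim = self.mesh.nodes.shape
        f = np.zeros((n, dim))
        if tractions is None:
            return f
        meas = self.face_measures(displacement)
        npf = self.mesh.loaded_faces.shape[1]
        contrib = tractions * (meas / npf)[:, None]
        for k in range(npf):
            np.add.at(f, self.mesh.loaded_faces[:, k], contrib)
        return f

    # -- stepping -----------------------------------------------------------
    def _factorize(self, dt: float) -> None:
        A = self.Mf + self.gamma * dt * self.Cf + self.beta * dt * dt * self.Kf
        self._lu = spla.splu(A.tocsc())
        self._dt = dt

    def step(self, state: SolidState, forces: np.ndarray, dt: float) -> SolidState:
        """One Newmark step under nodal ``forces`` (full (N, dim) array)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self._lu is None or dt != self._dt:
            self._factorize(dt)
        free = self.free
        d = state.d.ravel()[free]
        v = state.v.ravel()[free]
        a = state.a.ravel()[free]
        f = forces.ravel()[free]
        beta, gamma = self.beta, self.gamma
        d_pred = d + dt * v + dt * dt * (0.5 - beta) * a
        v_pred = v + dt * (1.0 - gamma) * a
        rhs = f - self.Cf @ v_pred - self.Kf @ d_pred
        a_new = self._lu.solve(rhs)
        if not np.all(np.isfinite(a_new)):
            raise RuntimeError("solid solve produced non-finite accelerations")
        d_new = d_pred + beta * dt * dt * a_new
        v_new = v_pred + gamma * dt * a_new
        out = state.copy()
        flat_d = out.d.ravel()
        flat_v = out.v.ravel()
        flat_a = out.a.ravel()
        flat_d[free] = d_new
        flat_v[free] = v_new
        flat_a[free] = a_new
        out.t = state.t + dt
        return out

    def static_solve(self, forces: np.ndarray) -> np.ndarray:
        """Static displacement under nodal forces (fixed DOFs pinned)."""
        free = self.free
        d = np.zeros(self.mesh.nodes.size)
        d[free] = spla.spsolve(self.Kf.tocsc(), forces.ravel()[free])
        return d.reshape(self.mesh.nodes.shape)

    def eigenmodes(self, k: int = 6):
        """Lowest undamped natural frequencies (Hz) and mode shapes."""
        vals, vecs = spla.eigsh(self.Kf, k=k, M=self.Mf, sigma=0.0)
        order = np.argsort(vals)
        freqs = np.sqrt(np.maximum(vals[order], 0.0)) / (2 * np.pi)
        return freqs, vecs[:, order]

    def energy(self, state: SolidState) -> float:
        """Total mechanical (kinetic + strain) energy of the free DOFs."""
        free = self.free
        d = state.d.ravel()[free]
        v = state.v.ravel()[free]
        return float(0.5 * v @ (self.Mf @ v) + 0.5 * d @ (self.Kf @ d))
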