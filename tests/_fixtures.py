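"""Shared mesh/setup builders used by several test modules."""

import numpy as np

from phonosim.coupling import CouplingConfig, SimulationSetup
from phonosim.geometry import DuctSpec, FEMesh, FoldSpec
from phonosim.grid import GridSpec, stretched_axis
from phonosim.solid import MaterialLayer


def isotropic_layer(E=1000.0, nu=0.3, rho=1000.0, eta=0.0):
    return MaterialLayer(rho, E, nu, E, nu, E / (2 * (1 + nu)), eta)


def block_mesh(nx, ny, lx, ly, layer=0):
    """Structured triangle mesh of a rectangle, clamped at x = 0."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            q = [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
            if (i + j) % 2 == 0:
                tris += [[q[0], q[1], q[2]], [q[0], q[2], q[3]]]
            else:
                tris += [[q[0], q[1], q[3]], [q[1], q[2], q[3]]]
    elements = np.asarray(tris)
    fixed = np.zeros(len(nodes), bool)
    fixed[[nid(0, j) for j in range(ny + 1)]] = True
    faces = np.asarray([[nid(nx, j), nid(nx, j + 1)] for j in range(ny)])
    return FEMesh(
        nodes=nodes,
        elements=elements,
        layer=np.full(len(elements), layer, np.int8),
        side=np.ones(len(elements), np.int8),
        fixed=fixed,
        loaded_faces=faces,
        loaded_tag=np.array(["medial"] * len(faces)),
    )


def small_setup(**kw):
    """Coarse but functional coupled setup for fast tests."""
    duct = DuctSpec()
    fold = FoldSpec(mount_x=4.0e-3)
    gx = stretched_axis(-0.0105, 0.0105, 36, focus=0.0, ratio=8)
    gy = stretched_axis(duct.y_min, duct.y_max, 72, focus=0.003, ratio=12, width=0.06)
    defaults = dict(
        duct=duct,
        fold=fold,
        grid=GridSpec([gx, gy]),
        coupling=CouplingConfig(dt_flow=3.0e-6, snapshot_every=5),
        target_elements=250,
    )
    defaults.update(kw)
    return SimulationSetup(**defaults)
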