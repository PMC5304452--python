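"""Parametric synthetic geometry: duct, vocal folds, level sets, FE meshes.

The simulated airway is a straight duct along the y (inferior-superior)
axis: a subglottal section, the glottal region occupied by a mirror
symmetric pair of layered vocal folds, and a supraglottal tract.  Geometry
is represented two ways:

* a :class:`LevelSet` — signed distance sampled at flow-grid cell centers,
  negative inside solid, positive in the air — consumed by the immersed
  boundary flow/acoustics solvers;
* a :class:`FEMesh` — simplicial mesh (triangles in 2D, tetrahedra in 3D)
  of the fold bodies with per-element layer tags (cover / ligament / body)
  and boundary faces tagged fixed vs. loaded — consumed by the solid solver.

Coordinates: x = medial-lateral (medial plane at x = 0), y = inferior-
superior (flow axis, fold inferior plane at y = 0), z = anterior-posterior
(3D only).  All lengths are SI meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec

__all__ = [
    "DuctSpec",
    "FoldSpec",
    "LevelSet",
    "FEMesh",
    "build_duct",
    "build_folds",
    "composite_levelset",
    "polygon_signed_distance",
    "min_fluid_aperture",
    "fluid_connected",
]

LAYER_NAMES = ("cover", "ligament", "body")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class DuctSpec:
    """Straight sub- + supraglottal duct along y.

    ``half_width`` is either a constant half width (2D) / radius (3D) or a
    tuple ``(y_stations, values)`` interpolated linearly in between.  The
    glottal span is the axial extent reserved for the vocal folds between
    the two sections, so the duct runs y in
    ``[-sub_length, glottal_span + supra_length]``.
    """

    sub_length: float = 0.0305
    supra_length: float = 0.174
    half_width: object = 0.009
    glottal_span: float = 0.006
    dimension: int = 2

    def __post_init__(self) -> None:
        if self.sub_length <= 0 or self.supra_length <= 0:
            raise ValueError("duct lengths must be positive")
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        hw = self.profile(self.stations())
        if np.any(hw <= 0):
            bad = self.stations()[np.argmin(hw)]
            raise ValueError(
                f"cross-section must be strictly positive; zero/negative half "
                f"width at station y={bad:.4g} m"
            )

    @property
    def y_min(self) -> float:
        return -self.sub_length

    @property
    def y_max(self) -> float:
        return self.glottal_span + self.supra_length

    def stations(self) -> np.ndarray:
        if isinstance(self.half_width, (tuple, list)):
            return np.asarray(self.half_width[0], dtype=float)
        return np.linspace(self.y_min, self.y_max, 33)

    def profile(self, y) -> np.ndarray:
        """Half width (2D) or radius (3D) at axial positions ``y``."""
        y = np.asarray(y, dtype=float)
        if isinstance(self.half_width, (tuple, list)):
            ys, vals = (np.asarray(v, dtype=float) for v in self.half_width)
            return np.interp(y, ys, vals)
        return np.full(y.shape, float(self.half_width))


@dataclass
class FoldSpec:
    """Mirror-symmetric vocal fold pair with a piecewise-linear medial profile.

    The medial surface half-gap h(y) over the fold thickness T is: a linear
    convergent entry ramp (angle ``entry_angle``) over the inferior
    ``entry_frac`` of T, a straight segment at the rest half-gap
    ``half_gap``, and a divergent exit ramp (angle ``exit_angle``) over the
    superior ``exit_frac`` of T.  Each fold spans ``half_gap + depth`` in x
    from the medial surface to its fixed lateral base.

    ``mount_x`` optionally clamps the inferior/superior surfaces beyond
    that |x| as well (recess mounting, the way physical fold replicas are
    glued into a backing block); in a 2D cross section this stands in for
    the anterior/posterior attachment that carries the axial pressure load
    in 3D.
    """

    depth: float = 8.8e-3
    thickness: float = 6.0e-3
    length: float = 16.0e-3
    half_gap: float = 2.0e-4
    entry_angle: float = np.deg2rad(45.0)
    exit_angle: float = np.deg2rad(45.0)
    entry_frac: float = 0.5
    exit_frac: float = 0.2
    cover: float = 0.5e-3
    ligament: float = 1.1e-3
    min_half_gap: float = 1.0e-4
    mount_x: float | None = None

    def __post_init__(self) -> None:
        if self.cover + self.ligament >= self.depth:
            raise ValueError(
                f"cover + ligament thickness ({self.cover + self.ligament:.4g} m)"
                f" must be smaller than the fold depth ({self.depth:.4g} m)"
            )
        if self.half_gap < self.min_half_gap:
            raise ValueError("rest half-gap must be >= contact minimum half-gap")
        if not 0 < self.entry_frac + self.exit_frac < 1:
            raise ValueError("entry_frac + exit_frac must lie in (0, 1)")
        hmax = float(np.max(self.medial_half_gap(np.array([0.0, self.thickness]))))
        if hmax >= self.base_x:
            raise ValueError(
                "entry/exit ramps reach the lateral base; reduce the angles "
                "or the ramp fractions"
            )
        if self.mount_x is not None and not (
            self.half_gap < self.mount_x < self.base_x
        ):
            raise ValueError("mount_x must lie between the medial surface and the base")

    @property
    def base_x(self) -> float:
        """x position of the (fixed) lateral base plane of the right fold."""
        return self.half_gap + self.depth

    def medial_half_gap(self, y) -> np.ndarray:
        """Rest medial-surface half-gap profile h(y) for y in [0, thickness]."""
        y = np.asarray(y, dtype=float)
        T = self.thickness
        y1 = self.entry_frac * T
        y2 = (1.0 - self.exit_frac) * T
        h = np.full(y.shape, self.half_gap)
        ent = y < y1
        h = np.where(ent, self.half_gap + (y1 - y) * np.tan(self.entry_angle), h)
        ext = y > y2
        h = np.where(ext, self.half_gap + (y - y2) * np.tan(self.exit_angle), h)
        return h

    def right_polygon(self, n_medial: int = 33) -> np.ndarray:
        """Closed CCW polygon of the right fold cross section (2D)."""
        T = self.thickness
        ys = np.concatenate(
            [
                [0.0],
                np.linspace(0.0, self.entry_frac * T, 8)[1:],
                np.linspace(self.entry_frac * T, (1 - self.exit_frac) * T, 4)[1:],
                np.linspace((1 - self.exit_frac) * T, T, 8)[1:],
            ]
        )
        hs = self.medial_half_gap(ys)
        medial = np.column_stack([hs, ys])
        poly = np.vstack(
            [
                [self.base_x, 0.0],
                medial,
                [self.base_x, T],
            ]
        )
        return poly


# ---------------------------------------------------------------------------
# level set container
# ---------------------------------------------------------------------------


@dataclass
class LevelSet:
    """Signed distance on the flow grid; negative inside solid.

    ``sdf`` is an optional analytic callable ``sdf(points) -> distances``
    used for sub-cell sampling (staggered velocity nodes, marker probes);
    when absent, multilinear interpolation of the sampled field is used.
    ``markers`` optionally carries the Lagrangian interface: positions
    (K, dim), unit outward (into-fluid) normals (K, dim), velocities and
    the solid boundary face each marker belongs to.
    """

    grid: GridSpec
    phi: np.ndarray
    sdf: object = None
    markers: dict | None = None
    _interp: object = field(default=None, repr=False)

    def sample(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.sdf is not None:
            return np.asarray(self.sdf(points), dtype=float)
        if self._interp is None:
            from scipy.interpolate import RegularGridInterpolator

            cs = [self.grid.centers(i) for i in range(self.grid.dim)]
            self._interp = RegularGridInterpolator(
                cs, self.phi, bounds_error=False, fill_value=None
            )
        return self._interp(points)

    def normal(self, points: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        """Unit gradient of the signed distance (points into the fluid)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        g = np.empty_like(points)
        for ax in range(points.shape[1]):
            dp = points.copy()
            dm = points.copy()
            dp[:, ax] += eps
            dm[:, ax] -= eps
            g[:, ax] = (self.sample(dp) - self.sample(dm)) / (2 * eps)
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return g / norm


# ---------------------------------------------------------------------------
# FE mesh container
# ---------------------------------------------------------------------------


@dataclass
class FEMesh:
    """Simplicial mesh of the two fold bodies.

    nodes: (N, dim); elements: (M, dim+1) node indices; layer: (M,) index
    into :data:`LAYER_NAMES`; side: (M,) +1 right fold / -1 left fold;
    fixed: (N,) bool mask of zero-displacement nodes; loaded_faces:
    (F, dim) node indices of traction-loaded boundary faces (edges in 2D)
    ordered so the outward normal is obtained by the standard rotation;
    loaded_tag: (F,) strings in {medial, inferior, superior}.
    """

    nodes: np.ndarray
    elements: np.ndarray
    layer: np.ndarray
    side: np.ndarray
    fixed: np.ndarray
    loaded_faces: np.ndarray
    loaded_tag: np.ndarray
    boundary_loops: dict | None = None  # side -> ordered node loop (2D only)

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    def element_volumes(self) -> np.ndarray:
        pts = self.nodes[self.elements]
        if self.dim == 2:
            d1 = pts[:, 1] - pts[:, 0]
            d2 = pts[:, 2] - pts[:, 0]
            return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        d1 = pts[:, 1] - pts[:, 0]
        d2 = pts[:, 2] - pts[:, 0]
        d3 = pts[:, 3] - pts[:, 0]
        return np.abs(np.einsum("ij,ij->i", np.cross(d1, d2), d3)) / 6.0

    def boundary_polylines(self, displacement: np.ndarray | None = None):
        """Deformed loaded-surface segments per side: dict side -> (F_s, dim, dim) pts."""
        pos = self.nodes if displacement is None else self.nodes + displacement
        out = {}
        for s in (1, -1):
            mask = self.face_side == s
            out[s] = pos[self.loaded_faces[mask]]
        return out

    def __post_init__(self) -> None:
        # side of each loaded face from the mean x of its nodes
        fx = self.nodes[self.loaded_faces][:, :, 0].mean(axis=1)
        self.face_side = np.where(fx >= 0, 1, -1)


# ---------------------------------------------------------------------------
# signed distance helpers
# ---------------------------------------------------------------------------


def polygon_signed_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Signed distance from 2D ``points`` to closed polygon ``poly``.

    Positive outside, negative inside (matching the fluid-positive level
    set convention for a solid body).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(poly, dtype=float)
    from . import _kernels as _K

    if _K.HAVE_NUMBA:
        return _K.polygon_sdf(
            np.ascontiguousarray(points), np.ascontiguousarray(poly)
        )
    a = poly
    b = np.roll(poly, -1, axis=0)
    # distance to each segment, vectorized over points x segments
    pa = points[:, None, :] - a[None, :, :]
    ba = (b - a)[None, :, :]
    denom = np.einsum("ijk,ijk->ij", ba, ba)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ijk,ijk->ij", pa, ba) / denom, 0.0, 1.0)
    d = np.linalg.norm(pa - t[:, :, None] * ba, axis=2)
    dist = d.min(axis=1)
    # crossing-number point-in-polygon (ray along +x)
    x, y = points[:, 0], points[:, 1]
    ax, ay = a[:, 0], a[:, 1]
    bx, by = b[:, 0], b[:, 1]
    cond = (ay[None, :] > y[:, None]) != (by[None, :] > y[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        xin = ax[None, :] + (y[:, None] - ay[None, :]) / (by - ay)[None, :] * (
            bx - ax
        )[None, :]
    crossing = cond & (x[:, None] < xin)
    inside = np.sum(crossing, axis=1) % 2 == 1
    return np.where(inside, -dist, dist)


def _extruded_distance(d2: np.ndarray, z: np.ndarray, z0: float, z1: float) -> np.ndarray:
    """Signed distance of a 2D shape extruded over [z0, z1] (solid negative)."""
    dz = np.maximum(z0 - z, z - z1)
    outside = np.hypot(np.maximum(d2, 0.0), np.maximum(dz, 0.0))
    inside = np.minimum(np.maximum(d2, dz), 0.0)
    return outside + inside


# ---------------------------------------------------------------------------
# build operations
# ---------------------------------------------------------------------------


def build_duct(spec: DuctSpec, grid: GridSpec) -> LevelSet:
    """Level set of the duct walls; interior (air) positive.

    The distance is exact for a uniform cross section and a planar-wall
    approximation otherwise.  Raises if the narrowest station is resolved
    by fewer than 4 cells.
    """
    if grid.dim != spec.dimension:
        raise ValueError("grid dimension does not match duct spec")
    ys = spec.stations()
    widths = spec.profile(ys)
    i_min = int(np.argmin(widths))
    h_min = widths[i_min]
    xc = grid.centers(0)
    if np.count_nonzero(np.abs(xc) < h_min) < 4:
        raise ValueError(
            f"grid does not resolve the narrowest duct station "
            f"(y={ys[i_min]:.4g} m, half width {h_min:.4g} m) with >= 4 cells"
        )

    def sdf(points):
        points = np.atleast_2d(points)
        h = spec.profile(points[:, 1])
        if spec.dimension == 2:
            r = np.abs(points[:, 0])
        else:
            r = np.hypot(points[:, 0], points[:, 2])
        return h - r

    mesh = grid.center_mesh()
    pts = np.column_stack([m.ravel() for m in mesh])
    phi = sdf(pts).reshape(grid.shape)
    # sparse wall markers, one pair per axial station (diagnostics only)
    yc = grid.centers(1)
    h = spec.profile(yc)
    if spec.dimension == 2:
        pos = np.concatenate(
            [np.column_stack([h, yc]), np.column_stack([-h, yc])]
        )
        nrm = np.concatenate(
            [np.tile([-1.0, 0.0], (yc.size, 1)), np.tile([1.0, 0.0], (yc.size, 1))]
        )
    else:
        pos = np.column_stack([h, yc, np.zeros_like(yc)])
        nrm = np.tile([-1.0, 0.0, 0.0], (yc.size, 1))
    markers = {"position": pos, "normal": nrm, "velocity": np.zeros_like(pos)}
    return LevelSet(grid=grid, phi=phi, sdf=sdf, markers=markers)


def _fold_mesh_2d(spec: FoldSpec, n_xi: int, n_eta: int):
    """Structured transfinite triangulation of the right fold cross section."""
    eta = np.linspace(0.0, 1.0, n_eta + 1)
    xi = np.linspace(0.0, 1.0, n_xi + 1)
    ys = eta * spec.thickness
    h = spec.medial_half_gap(ys)
    X = h[None, :] + xi[:, None] * (spec.base_x - h[None, :])  # (nxi+1, neta+1)
    Y = np.broadcast_to(ys[None, :], X.shape)
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (n_eta + 1) + j

    tris = []
    for i in range(n_xi):
        for j in range(n_eta):
            q = [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
            if (i + j) % 2 == 0:
                tris.append([q[0], q[1], q[2]])
                tris.append([q[0], q[2], q[3]])
            else:
                tris.append([q[0], q[1], q[3]])
                tris.append([q[1], q[2], q[3]])
    elements = np.asarray(tris, dtype=np.int64)

    fixed = np.zeros(nodes.shape[0], dtype=bool)
    for j in range(n_eta + 1):
        fixed[nid(n_xi, j)] = True
    if spec.mount_x is not None:
        # recess mounting: clamp inferior/superior nodes lateral of mount_x
        for i in range(n_xi + 1):
            for j in (0, n_eta):
                if nodes[nid(i, j), 0] >= spec.mount_x - 1e-12:
                    fixed[nid(i, j)] = True

    faces, tags = [], []
    for j in range(n_eta):  # medial surface, outward normal toward -x side
        faces.append([nid(0, j + 1), nid(0, j)])
        tags.append("medial")
    for i in range(n_xi):  # inferior plane y=0, outward normal -y
        faces.append([nid(i, 0), nid(i + 1, 0)])
        tags.append("inferior")
    for i in range(n_xi):  # superior plane y=T, outward normal +y
        faces.append([nid(i + 1, n_eta), nid(i, n_eta)])
        tags.append("superior")
    # closed boundary loop: inferior (base->medial), medial up, superior
    # (medial->base), lateral down
    loop = (
        [nid(i, 0) for i in range(n_xi, -1, -1)]
        + [nid(0, j) for j in range(1, n_eta + 1)]
        + [nid(i, n_eta) for i in range(1, n_xi + 1)]
        + [nid(n_xi, j) for j in range(n_eta - 1, 0, -1)]
    )
    return nodes, elements, fixed, np.asarray(faces), np.asarray(tags), np.asarray(loop)


def _loaded_surface_segments(spec: FoldSpec) -> np.ndarray:
    """Segments of the right fold loaded surface (medial+inferior+superior)."""
    poly = spec.right_polygon()
    segs = []
    pts = poly  # ordered base-inferior, medial up, base-superior
    for k in range(len(pts) - 1):
        segs.append([pts[k], pts[k + 1]])
    return np.asarray(segs)


def _distance_to_segments(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    a = segs[:, 0]
    b = segs[:, 1]
    pa = points[:, None, :] - a[None, :, :]
    ba = (b - a)[None, :, :]
    denom = np.einsum("ijk,ijk->ij", ba, ba)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ijk,ijk->ij", pa, ba) / denom, 0.0, 1.0)
    return np.linalg.norm(pa - t[:, :, None] * ba, axis=2).min(axis=1)


def _assign_layers(spec: FoldSpec, centroids_2d: np.ndarray) -> np.ndarray:
    segs = _loaded_surface_segments(spec)
    d = _distance_to_segments(centroids_2d, segs)
    layer = np.full(centroids_2d.shape[0], 2, dtype=np.int8)  # body
    layer[d <= spec.cover + spec.ligament] = 1
    layer[d <= spec.cover] = 0
    return layer


def _mirror_mesh(nodes, elements, faces):
    """Mirror a right-fold mesh through the medial plane (x -> -x)."""
    m_nodes = nodes.copy()
    m_nodes[:, 0] *= -1
    # flip element orientation to keep positive volumes
    m_elems = elements[:, [1, 0] + list(range(2, elements.shape[1]))]
    m_faces = faces[:, ::-1]
    return m_nodes, m_elems, m_faces


def build_folds(
    spec: FoldSpec,
    grid: GridSpec,
    target_elements: int = 400,
    nz: int = 8,
) -> tuple:
    """Level set + FE mesh of the mirror-symmetric fold pair.

    ``target_elements`` is the approximate triangle/tet count per fold;
    ``nz`` the number of anterior-posterior layers in 3D.
    """
    dim = grid.dim
    per_fold = target_elements if dim == 2 else max(target_elements // (3 * nz), 8)
    # pick nxi:neta ~ depth:thickness aspect
    aspect = spec.depth / spec.thickness
    n_eta = max(3, int(round(np.sqrt(per_fold / (2.0 * aspect)))))
    n_xi = max(3, int(round(per_fold / (2.0 * n_eta))))
    nodes, elements, fixed, faces, tags, loop = _fold_mesh_2d(spec, n_xi, n_eta)
    centroids = nodes[elements].mean(axis=1)
    layer = _assign_layers(spec, centroids)

    if dim == 3:
        nodes, elements, fixed, faces, tags, layer = _extrude_mesh(
            nodes, elements, fixed, faces, tags, layer, spec.length, nz
        )

    m_nodes, m_elems, m_faces = _mirror_mesh(nodes, elements, faces)
    off = nodes.shape[0]
    all_nodes = np.vstack([nodes, m_nodes])
    all_elems = np.vstack([elements, m_elems + off])
    all_layer = np.concatenate([layer, layer])
    all_side = np.concatenate(
        [np.ones(len(elements), dtype=np.int8), -np.ones(len(elements), dtype=np.int8)]
    )
    all_fixed = np.concatenate([fixed, fixed])
    all_faces = np.vstack([faces, m_faces + off])
    all_tags = np.concatenate([tags, tags])

    mesh = FEMesh(
        nodes=all_nodes,
        elements=all_elems,
        layer=all_layer,
        side=all_side,
        fixed=all_fixed,
        loaded_faces=all_faces,
        loaded_tag=all_tags,
        boundary_loops=None if dim == 3 else {1: loop, -1: loop + off},
    )

    poly_r = spec.right_polygon()

    def sdf(points):
        points = np.atleast_2d(points)
        p2 = np.column_stack([np.abs(points[:, 0]), points[:, 1]])
        d2 = polygon_signed_distance(p2, poly_r)
        if dim == 3:
            return _extruded_distance(d2, points[:, 2], 0.0, spec.length)
        return d2

    meshc = grid.center_mesh()
    pts = np.column_stack([m.ravel() for m in meshc])
    phi = sdf(pts).reshape(grid.shape)
    markers = fold_surface_markers(mesh)
    return LevelSet(grid=grid, phi=phi, sdf=sdf, markers=markers), mesh


def _extrude_mesh(nodes, elements, fixed, faces, tags, layer, length, nz):
    """Extrude a triangle mesh into tetrahedra along z in [0, length]."""
    n2 = nodes.shape[0]
    zs = np.linspace(0.0, length, nz + 1)
    nodes3 = np.vstack([np.column_stack([nodes, np.full(n2, z)]) for z in zs])
    tets, lay3 = [], []
    for k in range(nz):
        lo, hi = k * n2, (k + 1) * n2
        for e, tri in enumerate(elements):
            # Delaunay-consistent wedge split via globally sorted indices
            w = [lo + tri[0], lo + tri[1], lo + tri[2], hi + tri[0], hi + tri[1], hi + tri[2]]
            a, b, c = sorted(range(3), key=lambda i: tri[i])
            i0, i1, i2 = (w[a], w[b], w[c])
            j0, j1, j2 = (w[a + 3], w[b + 3], w[c + 3])
            tets += [[i0, i1, i2, j2], [i0, i1, j2, j1], [i0, j1, j2, j0]]
            lay3 += [layer[e]] * 3
    tets = np.asarray(tets, dtype=np.int64)
    # enforce positive orientation
    p = nodes3[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    neg = vol6 < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    fixed3 = np.tile(fixed, nz + 1)
    fixed3[:n2] = True  # anterior end plane
    fixed3[-n2:] = True  # posterior end plane
    # loaded faces: split each extruded boundary quad into two triangles
    f3, t3 = [], []
    for k in range(nz):
        lo, hi = k * n2, (k + 1) * n2
        for f, tag in zip(faces, tags):
            a, b = int(f[0]), int(f[1])
            f3.append([lo + a, lo + b, hi + b])
            f3.append([lo + a, hi + b, hi + a])
            t3 += [tag, tag]
    return (
        nodes3,
        tets,
        fixed3,
        np.asarray(f3, dtype=np.int64),
        np.asarray(t3),
        np.asarray(lay3, dtype=np.int8),
    )


def fold_surface_markers(mesh: FEMesh, displacement=None, velocity=None) -> dict:
    """Markers at loaded-face centroids with outward (into-fluid) normals."""
    pos_nodes = mesh.nodes if displacement is None else mesh.nodes + displacement
    fpts = pos_nodes[mesh.loaded_faces]
    pos = fpts.mean(axis=1)
    if mesh.dim == 2:
        t = fpts[:, 1] - fpts[:, 0]
        nrm = np.column_stack([t[:, 1], -t[:, 0]])
    else:
        nrm = np.cross(fpts[:, 1] - fpts[:, 0], fpts[:, 2] - fpts[:, 0])
    ln = np.linalg.norm(nrm, axis=1, keepdims=True)
    ln[ln == 0] = 1.0
    nrm = nrm / ln
    vel = np.zeros_like(pos)
    if velocity is not None:
        vel = velocity[mesh.loaded_faces].mean(axis=1)
    return {
        "position": pos,
        "normal": nrm,
        "velocity": vel,
        "face": np.arange(len(mesh.loaded_faces)),
    }


def composite_levelset(duct: LevelSet, folds: LevelSet) -> LevelSet:
    """Union of the solid regions: pointwise minimum of the two level sets."""
    if not duct.grid.same_as(folds.grid):
        raise ValueError("duct and fold level sets live on different grids")
    phi = np.minimum(duct.phi, folds.phi)
    sdf = None
    if duct.sdf is not None and folds.sdf is not None:
        d_sdf, f_sdf = duct.sdf, folds.sdf

        def sdf(points):
            return np.minimum(d_sdf(points), f_sdf(points))

    return LevelSet(grid=duct.grid, phi=phi, sdf=sdf, markers=folds.markers)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def min_fluid_aperture(ls: LevelSet) -> tuple:
    """Narrowest fluid opening across x, scanned per axial station.

    Returns ``(width, y_station)`` where width sums the x-extents of fluid
    cells (phi > 0) in the row of cells at that station.  In 3D the scan is
    taken in the mid anterior-posterior plane.
    """
    phi = ls.phi
    if ls.grid.dim == 3:
        phi = phi[:, :, phi.shape[2] // 2]
    dx = ls.grid.widths(0)
    widths = np.where(phi > 0, dx[:, None], 0.0).sum(axis=0)
    j = int(np.argmin(widths))
    return float(widths[j]), float(ls.grid.centers(1)[j])


def fluid_connected(ls: LevelSet) -> bool:
    """True if the fluid region connects the inlet row to the outlet row."""
    fluid = ls.phi > 0
    labels, _ = ndimage.label(fluid)
    first = np.take(labels, 0, axis=1)
    last = np.take(labels, -1, axis=1)
    inlet = set(np.unique(first[np.take(fluid, 0, axis=1)]))
    outlet = set(np.unique(last[np.take(fluid, -1, axis=1)]))
    return len(inlet & outlet - {0}) > 0
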