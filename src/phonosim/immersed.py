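"""Sharp-interface ghost-cell machinery on tensor-product grids.

Both the incompressible solver (staggered velocity/pressure nodes) and the
acoustic solver (collocated cell centers) enforce wall conditions on the
immersed fold/duct boundary the same way: nodes just inside the solid that
have a fluid neighbor become *ghost* nodes; each ghost node mirrors the
field value at its image point (the reflection through the boundary along
the level-set normal), so that the interpolated value at the boundary
satisfies the wall condition.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

FLUID, GHOST, SOLID = 0, 1, 2

__all__ = ["FLUID", "GHOST", "SOLID", "classify", "GhostMirror"]


def classify(phi: np.ndarray) -> np.ndarray:
    """Tag nodes: FLUID (phi > 0), GHOST (solid with a fluid face neighbor),
    SOLID otherwise."""
    fluid = phi > 0
    tags = np.where(fluid, FLUID, SOLID).astype(np.int8)
    if np.all(fluid):
        return tags
    # any face-neighbor fluid?
    neigh = np.zeros_like(fluid)
    for ax in range(phi.ndim):
        for shift in (1, -1):
            neigh |= np.roll(fluid, shift, axis=ax) & _valid_roll(fluid.shape, ax, shift)
    tags[(~fluid) & neigh] = GHOST
    return tags


def _valid_roll(shape, ax, shift):
    m = np.ones(shape, dtype=bool)
    idx = [slice(None)] * len(shape)
    idx[ax] = 0 if shift == 1 else -1
    m[tuple(idx)] = False
    return m


def _multilinear_stencil(coords, points):
    """Corner indices and weights for multilinear interpolation.

    Returns (idx, w): idx is (n_pts, 2**dim, dim) integer corner indices,
    w is (n_pts, 2**dim) weights.  Points are clamped to the grid hull.
    """
    dim = len(coords)
    n = points.shape[0]
    lo = np.empty((n, dim), dtype=np.int64)
    frac = np.empty((n, dim))
    for ax, c in enumerate(coords):
        x = np.clip(points[:, ax], c[0], c[-1])
        i = np.clip(np.searchsorted(c, x) - 1, 0, len(c) - 2)
        lo[:, ax] = i
        frac[:, ax] = (x - c[i]) / (c[i + 1] - c[i])
    corners = np.array(np.meshgrid(*[[0, 1]] * dim, indexing="ij")).reshape(dim, -1).T
    idx = lo[:, None, :] + corners[None, :, :]
    w = np.ones((n, corners.shape[0]))
    for ax in range(dim):
        f = frac[:, ax]
        w *= np.where(corners[None, :, ax] == 1, f[:, None], 1.0 - f[:, None])
    return idx, w


class GhostMirror:
    """Precomputed ghost-node mirror for one tensor grid of sample nodes.

    ``coords``: list of per-axis 1D node coordinates; ``levelset``: object
    with ``sample(points)`` and ``normal(points)``.  Image-point stencils
    are restricted to fluid nodes (weights renormalized); a ghost node
    whose image stencil holds no fluid at all falls back to the nearest
    fluid node.
    """

    def __init__(self, coords, levelset):
        self.coords = [np.asarray(c, dtype=float) for c in coords]
        self.shape = tuple(len(c) for c in self.coords)
        mesh = np.meshgrid(*self.coords, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        phi = np.asarray(levelset.sample(pts)).reshape(self.shape)
        self.phi = phi
        self.tags = classify(phi)
        self.fluid_mask = self.tags == FLUID
        gidx = np.argwhere(self.tags == GHOST)
        self.ghost_index = tuple(gidx.T)
        if gidx.size == 0:
            self.n_ghost = 0
            return
        self.n_ghost = gidx.shape[0]
        gpts = np.column_stack(
            [self.coords[ax][gidx[:, ax]] for ax in range(len(self.coords))]
        )
        d = np.asarray(levelset.sample(gpts))  # negative inside solid
        nrm = np.asarray(levelset.normal(gpts))
        self.boundary_points = gpts - d[:, None] * nrm
        self.normals = nrm
        image = gpts - 2.0 * d[:, None] * nrm
        idx, w = _multilinear_stencil(self.coords, image)
        flat = np.ravel_multi_index(
            tuple(np.clip(idx[..., ax], 0, self.shape[ax] - 1) for ax in range(len(self.shape))),
            self.shape,
        )
        ok = self.fluid_mask.ravel()[flat]
        w = np.where(ok, w, 0.0)
        tot = w.sum(axis=1)
        degenerate = tot <= 1e-12
        if np.any(degenerate):
            # nearest fluid node fallback
            _, nearest = ndimage.distance_transform_edt(
                ~self.fluid_mask, return_indices=True
            )
            near_flat = np.ravel_multi_index(
                tuple(nearest[ax][self.ghost_index] for ax in range(len(self.shape))),
                self.shape,
            )
            flat[degenerate, 0] = near_flat[degenerate]
            w[degenerate] = 0.0
            w[degenerate, 0] = 1.0
            tot = w.sum(axis=1)
        self.stencil_flat = flat
        self.weights = w / tot[:, None]

    # -- value at image point ----------------------------------------------
    def image_values(self, field: np.ndarray) -> np.ndarray:
        if self.n_ghost == 0:
            return np.empty(0)
        return (field.ravel()[self.stencil_flat] * self.weights).sum(axis=1)

    def mirror_scalar(self, field: np.ndarray, boundary_value=None) -> None:
        """Set ghost nodes in-place.

        ``boundary_value`` None -> zero-normal-gradient mirror (ghost =
        image value); scalar/array -> Dirichlet: ghost = 2 b - image.
        """
        if self.n_ghost == 0:
            return
        vi = self.image_values(field)
        if boundary_value is None:
            field[self.ghost_index] = vi
        else:
            field[self.ghost_index] = 2.0 * np.asarray(boundary_value) - vi

    def mirror_vector_slip(self, comps: list) -> None:
        """Ghost values enforcing zero normal component (tangential mirrored)."""
        if self.n_ghost == 0:
            return
        vi = np.column_stack([self.image_values(f) for f in comps])
        vn = np.einsum("ij,ij->i", vi, self.normals)
        vg = vi - 2.0 * vn[:, None] * self.normals
        for ax, f in enumerate(comps):
            f[self.ghost_index] = vg[:, ax]

    def zero_solid(self, field: np.ndarray) -> None:
        field[self.tags == SOLID] = 0.0
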