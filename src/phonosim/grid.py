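"""Cartesian grid description shared by the flow and acoustics solvers.

The solvers operate on (possibly non-uniform) tensor-product Cartesian
grids.  A :class:`GridSpec` stores the cell *face* coordinates along each
axis; cell centers, spacings and face-midpoint locations are derived.  The
same spec serves the staggered (MAC) incompressible solver and the
collocated acoustic solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "stretched_axis"]


def stretched_axis(
    x0: float,
    x1: float,
    n: int,
    focus: float | None = None,
    ratio: float = 1.0,
    width: float = 0.12,
) -> np.ndarray:
    """Return ``n+1`` monotone node coordinates on ``[x0, x1]``.

    With ``ratio == 1`` the axis is uniform.  Otherwise cells are refined
    around ``focus``: the grid-point density follows a Gaussian bump of
    relative half-width ``width`` centered there, with the coarsest cell
    roughly ``ratio`` times the finest one.
    """
    if n < 1:
        raise ValueError("need at least one cell")
    if ratio <= 1.0 or focus is None:
        return np.linspace(x0, x1, n + 1)
    L = x1 - x0
    w_phys = width * L
    x = np.linspace(x0, x1, n + 1)
    # fixed-point iteration: cell size inversely proportional to a Gaussian
    # density bump centered (in physical space) on the focus
    for _ in range(8):
        xm = 0.5 * (x[:-1] + x[1:])
        density = 1.0 + (ratio - 1.0) * np.exp(-(((xm - focus) / w_phys) ** 2))
        widths = 1.0 / density
        widths *= L / widths.sum()
        x[1:] = x0 + np.cumsum(widths)
        x[0], x[-1] = x0, x1
    return x


@dataclass
class GridSpec:
    """Tensor-product Cartesian grid given by per-axis face coordinates.

    ``axes[i]`` holds the strictly increasing face coordinates along axis
    ``i`` (x = medial-lateral, y = inferior-superior / flow axis, optional
    z = anterior-posterior).  All lengths in meters.
    """

    axes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        if not 1 <= len(self.axes) <= 3:
            raise ValueError("GridSpec supports 1, 2 or 3 axes")
        for i, a in enumerate(self.axes):
            if a.ndim != 1 or a.size < 9:
                raise ValueError(
                    f"axis {i}: need at least 9 face coordinates (8 cells), got {a.size}"
                )
            if not np.all(np.diff(a) > 0):
                raise ValueError(f"axis {i}: coordinates must be strictly increasing")

    # -- derived quantities -------------------------------------------------
    @property
    def dim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple:
        """Number of cells along each axis."""
        return tuple(a.size - 1 for a in self.axes)

    def centers(self, axis: int) -> np.ndarray:
        a = self.axes[axis]
        return 0.5 * (a[:-1] + a[1:])

    def widths(self, axis: int) -> np.ndarray:
        return np.diff(self.axes[axis])

    def min_width(self, axis: int) -> float:
        return float(np.min(self.widths(axis)))

    def center_mesh(self) -> list:
        """Cell-center coordinate arrays broadcast to the full cell shape."""
        cs = [self.centers(i) for i in range(self.dim)]
        return list(np.meshgrid(*cs, indexing="ij"))

    def bounds(self) -> list:
        return [(float(a[0]), float(a[-1])) for a in self.axes]

    def contains(self, point) -> bool:
        point = np.atleast_1d(point)
        return all(
            self.axes[i][0] - 1e-12 <= point[i] <= self.axes[i][-1] + 1e-12
            for i in range(self.dim)
        )

    def same_as(self, other: "GridSpec") -> bool:
        return self.dim == other.dim and all(
            a.size == b.size and np.allclose(a, b)
            for a, b in zip(self.axes, other.axes)
        )
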