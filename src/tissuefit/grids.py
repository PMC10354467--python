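"""Uniform cell-centred grids and density containers.

Two grid modes cover the experiments: a 2D Cartesian grid for arbitrary
tissue geometries (collisions) and a 1D radially symmetric grid for
circular expansions, where the first cell centre sits at r = h/2 (no node
at the origin). All lengths are mm, densities cells mm^-2, times hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Grid", "DensityField", "MultiSpeciesState"]


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centred grid.

    mode : {"cartesian2d", "radial1d"}
    h : cell spacing (mm)
    shape : (ny, nx) for cartesian2d, (nr,) for radial1d
    origin : physical coordinate of the first cell centre; for radial1d this
        is fixed at (h/2,).
    """

    mode: str
    h: float
    shape: tuple
    origin: tuple

    def __post_init__(self):
        if self.mode not in ("cartesian2d", "radial1d"):
            raise ValueError(f"unknown grid mode {self.mode!r}")
        if not self.h > 0:
            raise ValueError("h must be > 0")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        if self.mode == "radial1d":
            if len(self.shape) != 1:
                raise ValueError("radial1d grid needs shape (nr,)")
            if abs(self.origin[0] - self.h / 2) > 1e-12 * self.h:
                raise ValueError("radial1d origin must be h/2")
        else:
            if len(self.shape) != 2:
                raise ValueError("cartesian2d grid needs shape (ny, nx)")

    @classmethod
    def cartesian(cls, xlim, ylim, h: float) -> "Grid":
        """Grid covering [xlim] x [ylim] with spacing h (extents rounded up)."""
        nx = max(1, int(np.ceil((xlim[1] - xlim[0]) / h - 1e-9)))
        ny = max(1, int(np.ceil((ylim[1] - ylim[0]) / h - 1e-9)))
        return cls("cartesian2d", h, (ny, nx), (xlim[0] + h / 2, ylim[0] + h / 2))

    @classmethod
    def radial(cls, rmax: float, h: float) -> "Grid":
        nr = max(1, int(np.ceil(rmax / h - 1e-9)))
        return cls("radial1d", h, (nr,), (h / 2,))

    @property
    def ncells(self) -> int:
        return int(np.prod(self.shape))

    def cell_centers(self):
        """Coordinates of cell centres.

        radial1d -> radii array (nr,); cartesian2d -> (X, Y) meshgrids of
        shape (ny, nx).
        """
        if self.mode == "radial1d":
            return self.origin[0] + self.h * np.arange(self.shape[0])
        ny, nx = self.shape
        x = self.origin[0] + self.h * np.arange(nx)
        y = self.origin[1] + self.h * np.arange(ny)
        return np.meshgrid(x, y)

    def cell_volumes(self):
        """Cell measures: h^2 (cartesian) or 2 pi r h (radial annuli)."""
        if self.mode == "radial1d":
            return 2.0 * np.pi * self.cell_centers() * self.h
        return np.full(self.shape, self.h**2)

    def bounds(self):
        """((xmin, xmax), (ymin, ymax)) of the covered physical region."""
        if self.mode == "radial1d":
            r = self.shape[0] * self.h
            return ((-r, r), (-r, r))
        ny, nx = self.shape
        x0 = self.origin[0] - self.h / 2
        y0 = self.origin[1] - self.h / 2
        return ((x0, x0 + nx * self.h), (y0, y0 + ny * self.h))


@dataclass
class DensityField:
    """Single-species density on a grid at one time."""

    grid: Grid
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("densities must be >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("densities must be finite")

    def mass(self) -> float:
        """Total number of cells, sum(rho * cell volume)."""
        return float(np.sum(self.values * self.grid.cell_volumes()))


@dataclass
class MultiSpeciesState:
    """Densities of n >= 1 species sharing one grid and time.

    ``densities`` is stacked as (n_species, *grid.shape).
    """

    grid: Grid
    densities: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.ndim != len(self.grid.shape) + 1:
            raise ValueError("densities must be stacked (n_species, *grid.shape)")
        if self.densities.shape[1:] != self.grid.shape:
            raise ValueError("densities shape does not match grid")
        if self.densities.shape[0] < 1:
            raise ValueError("need at least one species")
        if np.any(self.densities < 0) or not np.all(np.isfinite(self.densities)):
            raise ValueError("densities must be finite and >= 0")

    @classmethod
    def from_fields(cls, fields: Sequence[DensityField]) -> "MultiSpeciesState":
        if not fields:
            raise ValueError("need at least one field")
        g, t = fields[0].grid, fields[0].time
        for f in fields[1:]:
            if f.grid != g or f.time != t:
                raise ValueError("all fields must share grid and time")
        return cls(g, np.stack([f.values for f in fields]), t)

    @property
    def n_species(self) -> int:
        return self.densities.shape[0]

    @property
    def fields(self) -> list[DensityField]:
        return [
            DensityField(self.grid, self.densities[i], self.time)
            for i in range(self.n_species)
        ]

    def field(self, i: int = 0) -> DensityField:
        return DensityField(self.grid, self.densities[i], self.time)

    def total(self) -> DensityField:
        """Total density rho_1 + ... + rho_n as a field."""
        return DensityField(self.grid, self.densities.sum(axis=0), self.time)

    def masses(self) -> np.ndarray:
        vol = self.grid.cell_volumes()
        return np.array(
            [float(np.sum(self.densities[i] * vol)) for i in range(self.n_species)]
        )

    def copy(self) -> "MultiSpeciesState":
        return MultiSpeciesState(self.grid, self.densities.copy(), self.time)
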