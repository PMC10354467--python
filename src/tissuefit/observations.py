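"""Synthetic voxelized observations of model densities.

The observation model mirrors the experimental protocol: local densities
are recorded at the centres of square voxels (115 x 115 um^2 in the source
experiments) at a handful of times, and are noisy versions of the model
density with additive i.i.d. Gaussian errors,

    rho_D(x_i, t_j) = rho(x_i, t_j) + eps,   eps ~ N(0, sigma^2).

Voxel values are area averages of the model field (density quantification
by nucleus counting is an area measure), computed by subsampled
interpolation. Negative noisy values are retained: the error model is
additive and unbounded, and the Gaussian likelihood used for calibration
assumes exactly this generative process.

Noise is seeded per (time, voxel) lattice index, so any subset of voxels
or times is reproducible independently of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import TissueSpec, build_state
from .grids import DensityField, Grid, MultiSpeciesState
from .params import ModelParams
from .solver import sample_field, solve

__all__ = [
    "ObservationSet",
    "ExpansionExperiment",
    "voxel_lattice",
    "voxel_average",
    "observe",
    "expansion_protocol",
    "disc_state",
]

#: observation times of the expansion protocol (h)
PROTOCOL_TIMES = (16.0, 26.0, 36.0, 46.0)
#: experimental voxel side (um)
PROTOCOL_VOXEL_UM = 115.0
#: initial tissue diameter (mm)
PROTOCOL_DIAMETER_MM = 3.4
#: burn-in before the first usable observation (h), emulating the
#: post-stencil-removal transient that the calibration discards
PROTOCOL_BURN_IN_H = 6.0
#: default seeding density (cells mm^-2); the collision experiments seed at
#: 2600 and no expansion seeding density is reported, so this is an assumption
DEFAULT_SEED_DENSITY = 2600.0

UM_TO_MM = 1e-3


@dataclass
class ObservationSet:
    """Noisy voxel observations.

    positions : (N, 2) voxel-centre coordinates (mm)
    times : (J,) strictly increasing observation times (h)
    values : (J, N) observed densities rho_D (cells mm^-2); may be negative
    voxel : voxel side (um)
    sigma_true : generating noise s.d. (generator only, None for real data)
    seed : generator seed (None for real data)
    """

    positions: np.ndarray
    times: np.ndarray
    values: np.ndarray
    voxel: float
    sigma_true: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.times = np.asarray(self.times, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape != (len(self.times), len(self.positions)):
            raise ValueError("values must have shape (n_times, n_voxels)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return self.values.size


@dataclass
class ExpansionExperiment:
    """A synthetic single-tissue expansion: observations plus the known
    density profile at the burn-in time, which calibration uses as its
    initial condition (mirroring the use of the measured 6 h profile)."""

    observations: ObservationSet
    initial_state: MultiSpeciesState
    params_true: ModelParams


def voxel_lattice(bounds, voxel_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxel centres covering a rectangular region.

    Voxels are anchored at the lower corner: centres at
    ``lo + voxel/2 + k voxel`` for as many whole voxels as fit. Returns
    (positions (N, 2), lattice index (N, 2) of each voxel).
    """
    v = voxel_um * UM_TO_MM
    (xlim, ylim) = bounds
    nx = int((xlim[1] - xlim[0]) / v + 1e-9)
    ny = int((ylim[1] - ylim[0]) / v + 1e-9)
    if nx < 1 or ny < 1:
        raise ValueError("voxel larger than the domain")
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    ix, iy = ix.ravel(), iy.ravel()
    x = xlim[0] + v / 2 + ix * v
    y = ylim[0] + v / 2 + iy * v
    return np.column_stack([x, y]), np.column_stack([ix, iy])


def voxel_average(
    field: DensityField, positions: np.ndarray, voxel_um: float, subsample: int = 4
) -> np.ndarray:
    """Area-averaged field value per voxel via subsample^2 midpoint quadrature."""
    v = voxel_um * UM_TO_MM
    off = ((np.arange(subsample) + 0.5) / subsample - 0.5) * v
    ox, oy = np.meshgrid(off, off)
    pts = positions[:, None, :] + np.column_stack([ox.ravel(), oy.ravel()])[None, :, :]
    vals = sample_field(field, pts.reshape(-1, 2)).reshape(len(positions), -1)
    return vals.mean(axis=1)


def _voxel_noise(sigma: float, seed: int, t_index: int, lattice_idx: np.ndarray) -> np.ndarray:
    out = np.empty(len(lattice_idx))
    for k, (ix, iy) in enumerate(lattice_idx):
        rng = np.random.default_rng((int(seed), int(t_index), int(iy), int(ix)))
        out[k] = rng.standard_normal()
    return sigma * out


def observe(
    trajectory: Sequence[MultiSpeciesState],
    times: Sequence[float],
    voxel_um: float,
    sigma: float,
    seed: int,
    species: int | None = None,
    bounds=None,
    subsample: int = 4,
) -> ObservationSet:
    """Voxelize a trajectory at the requested times and add Gaussian noise.

    ``species=None`` observes the total density. The voxel lattice covers
    ``bounds`` (grid bounding box by default). The trajectory must contain
    every requested time.
    """
    by_time = {round(s.time, 9): s for s in trajectory}
    times = [float(t) for t in times]
    missing = [t for t in times if round(t, 9) not in by_time]
    if missing:
        raise ValueError(f"requested times absent from trajectory: {missing}")
    if voxel_um * UM_TO_MM < trajectory[0].grid.h - 1e-12:
        raise ValueError("voxel must be at least as large as the grid spacing")
    if bounds is None:
        bounds = trajectory[0].grid.bounds()
    positions, lattice_idx = voxel_lattice(bounds, voxel_um)
    values = np.empty((len(times), len(positions)))
    for j, t in enumerate(times):
        state = by_time[round(t, 9)]
        field = state.total() if species is None else state.field(species)
        mean = voxel_average(field, positions, voxel_um, subsample)
        if sigma > 0:
            mean = mean + _voxel_noise(sigma, seed, j, lattice_idx)
        values[j] = mean
    return ObservationSet(
        positions=positions,
        times=np.asarray(times),
        values=values,
        voxel=voxel_um,
        sigma_true=sigma,
        seed=seed,
    )


def disc_state(
    grid: Grid, density: float, radius: float, time: float = 0.0
) -> MultiSpeciesState:
    """Uniform circular tissue centred at the origin.

    On a radial grid the rim cell receives the covered fraction of its
    annulus; on a Cartesian grid rasterization goes through
    :func:`tissuefit.geometry.build_state`.
    """
    if grid.mode == "radial1d":
        r = grid.cell_centers()
        frac = np.clip((radius - (r - grid.h / 2)) / grid.h, 0.0, 1.0)
        return MultiSpeciesState(grid, (density * frac)[None, :], time)
    return build_state(
        [TissueSpec("circle", (0.0, 0.0), radius, density)], grid, time=time
    )


def expansion_protocol(
    params: ModelParams,
    sigma: float,
    seed: int,
    rho0: float = DEFAULT_SEED_DENSITY,
    diameter_mm: float = PROTOCOL_DIAMETER_MM,
    times: Sequence[float] = PROTOCOL_TIMES,
    burn_in: float = PROTOCOL_BURN_IN_H,
    voxel_um: float = PROTOCOL_VOXEL_UM,
    domain_radius_mm: float = 3.5,
    solver_h_mm: float = 0.01,
    n_replicates: int = 1,
) -> ExpansionExperiment:
    """Synthetic single-tissue expansion on the experimental protocol.

    A circular tissue of the given diameter and seeding density is placed on
    a radial grid, integrated through the burn-in, then observed on the
    voxel lattice at the requested times. With ``n_replicates > 1`` the
    returned values average independent noise realizations (replicate k uses
    seed ``(seed, k)``), emulating replicate-averaged density profiles.
    """
    grid = Grid.radial(domain_radius_mm, solver_h_mm)
    state0 = disc_state(grid, rho0, diameter_mm / 2.0)
    burn = solve(state0, params, [burn_in])[0]
    traj = solve(burn, params, list(times))
    reps = []
    for k in range(n_replicates):
        rep_seed = seed if n_replicates == 1 else int(
            np.random.SeedSequence((int(seed), k)).generate_state(1)[0] % (2**31)
        )
        reps.append(
            observe(traj, times, voxel_um, sigma, rep_seed)
        )
    values = np.mean([o.values for o in reps], axis=0)
    obs = ObservationSet(
        positions=reps[0].positions,
        times=reps[0].times,
        values=values,
        voxel=voxel_um,
        sigma_true=sigma,
        seed=seed,
    )
    return ExpansionExperiment(observations=obs, initial_state=burn, params_true=params)
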