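"""Time integration and field diagnostics for the growth models.

The solver is explicit, conservative and positivity-preserving (see
:mod:`tissuefit._kernels`). The admissible time step combines the
parabolic bound ``dt <= CFL h^2 / (2 g D_eff)`` — where ``D_eff`` is the
largest effective diffusivity, ``(m-1) D rho_max^(m-1)`` for the porous
family — with ``dt <= 0.1 / r`` so that the explicit logistic update stays
accurate. The geometry factor ``g`` is the number of active space
dimensions (2 for cartesian2d, and 2 for radial1d, whose innermost cell
has face-to-volume ratio twice the Cartesian one).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import _kernels
from .grids import DensityField, Grid, MultiSpeciesState
from .params import ModelParams

__all__ = [
    "stable_dt",
    "step",
    "solve",
    "sample_field",
    "front_position",
    "radial_profile",
    "wave_speed_estimate",
]

#: safety factor on the explicit parabolic stability bound
CFL = 0.4
#: cap on r * dt for the explicit reaction update
REACTION_DT = 0.1


def _geometry_factor(grid: Grid) -> int:
    if grid.mode == "radial1d":
        return 2
    ny, nx = grid.shape
    return max(1, int(nx > 1) + int(ny > 1))


def stable_dt(state: MultiSpeciesState, params: ModelParams, cfl: float = CFL) -> float:
    """Largest admissible explicit time step for the current state."""
    Dint = params.D_internal
    if params.family == "linear":
        Deff = Dint
    else:
        rho_max = float(state.densities.sum(axis=0).max())
        if params.r > 0:
            # growth can drive densities up to ~K during the run
            rho_max = max(rho_max, params.K)
        Deff = (params.m - 1.0) * Dint * rho_max ** (params.m - 1.0) if rho_max > 0 else 0.0
    g = _geometry_factor(state.grid)
    dt_diff = math.inf if Deff == 0 else cfl * state.grid.h**2 / (2.0 * g * Deff)
    dt_reac = math.inf if params.r == 0 else REACTION_DT / params.r
    return min(dt_diff, dt_reac)


def _advance(state: MultiSpeciesState, params: ModelParams, dt: float, nsteps: int) -> None:
    """Run nsteps of size dt on state.densities in place."""
    linear = params.family == "linear"
    args = (
        state.grid.h,
        dt,
        nsteps,
        params.D_internal,
        params.r,
        params.K,
        params.m,
        linear,
    )
    if state.grid.mode == "radial1d":
        _kernels.run_radial(state.densities, *args)
    else:
        _kernels.run_cartesian(state.densities, *args)


def step(state: MultiSpeciesState, params: ModelParams, dt: float) -> MultiSpeciesState:
    """One explicit conservative update of size dt.

    Raises ValueError when dt exceeds the stability bound, reporting the
    admissible value.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bound = stable_dt(state, params)
    if dt > bound * (1 + 1e-12):
        raise ValueError(
            f"dt={dt:g} exceeds the stability bound; admissible dt <= {bound:g} h"
        )
    out = state.copy()
    _advance(out, params, dt, 1)
    out.time = state.time + dt
    return out


def solve(
    state0: MultiSpeciesState,
    params: ModelParams,
    t_out: Sequence[float],
) -> list[MultiSpeciesState]:
    """Integrate from state0 and sample the trajectory exactly at t_out.

    t_out must be strictly increasing with t_out[0] >= state0.time. The
    internal step is chosen adaptively from the stability bound at the start
    of each output interval; the interval is subdivided evenly so each
    requested time is hit exactly. Deterministic for fixed inputs.
    """
    t_out = [float(t) for t in t_out]
    if any(t2 <= t1 for t1, t2 in zip(t_out, t_out[1:])):
        raise ValueError("t_out must be strictly increasing")
    if t_out and t_out[0] < state0.time - 1e-12:
        raise ValueError("t_out[0] must be >= state0.time")

    current = state0.copy()
    out: list[MultiSpeciesState] = []
    for t_target in t_out:
        span = t_target - current.time
        if span > 1e-12:
            dt_max = stable_dt(current, params)
            nsteps = max(1, int(math.ceil(span / dt_max - 1e-12)))
            _advance(current, params, span / nsteps, nsteps)
            current.time = t_target
            if not np.all(np.isfinite(current.densities)):
                raise RuntimeError(
                    f"non-finite densities encountered at t={t_target:g} h"
                )
        snap = current.copy()
        snap.time = t_target
        out.append(snap)
    return out


def sample_field(field: DensityField, points: np.ndarray) -> np.ndarray:
    """Interpolate a field at physical points.

    For radial1d fields ``points`` may be radii (n,) or coordinates (n, 2);
    interpolation is linear in r, constant inside the first cell centre and
    zero beyond the outer cell centre. For cartesian2d fields ``points`` is
    (n, 2) and interpolation is bilinear, zero outside the domain.
    """
    points = np.asarray(points, dtype=float)
    if field.grid.mode == "radial1d":
        r = points if points.ndim == 1 else np.hypot(points[..., 0], points[..., 1])
        centers = field.grid.cell_centers()
        return np.interp(r, centers, field.values, left=field.values[0], right=0.0)
    from scipy.interpolate import RegularGridInterpolator

    ny, nx = field.grid.shape
    x = field.grid.origin[0] + field.grid.h * np.arange(nx)
    y = field.grid.origin[1] + field.grid.h * np.arange(ny)
    interp = RegularGridInterpolator(
        (y, x), field.values, bounds_error=False, fill_value=0.0
    )
    return interp(np.column_stack([points[..., 1].ravel(), points[..., 0].ravel()])).reshape(
        points.shape[:-1]
    )


def front_position(
    field: DensityField,
    threshold: float,
    center=None,
    direction=(1.0, 0.0),
):
    """Outermost radius where the density profile crosses ``threshold``.

    For radial fields the stored profile is used directly; for Cartesian
    fields the profile is sampled along a ray from ``center`` (domain centre
    by default) in ``direction``. Returns None when the maximum density is
    below the threshold (front undefined).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if field.grid.mode == "radial1d":
        radii = field.grid.cell_centers()
        values = field.values
    else:
        (xlim, ylim) = field.grid.bounds()
        if center is None:
            center = ((xlim[0] + xlim[1]) / 2, (ylim[0] + ylim[1]) / 2)
        d = np.asarray(direction, float)
        d = d / np.hypot(*d)
        # distance to the boundary along the ray
        rmax = np.inf
        for c, dc, (lo, hi) in ((center[0], d[0], xlim), (center[1], d[1], ylim)):
            if dc > 1e-12:
                rmax = min(rmax, (hi - c) / dc)
            elif dc < -1e-12:
                rmax = min(rmax, (lo - c) / dc)
        radii = np.arange(field.grid.h / 2, rmax, field.grid.h)
        pts = center + np.outer(radii, d)
        values = sample_field(field, pts)
    above = values >= threshold
    if not above.any():
        return None
    j = int(np.flatnonzero(above)[-1])
    if j == len(radii) - 1:
        return float(radii[j])
    # linear interpolation between the last above-threshold sample and the next
    v0, v1 = values[j], values[j + 1]
    frac = (v0 - threshold) / (v0 - v1)
    return float(radii[j] + frac * (radii[j + 1] - radii[j]))


def radial_profile(field: DensityField, center=None):
    """Angular average per annulus of width h around ``center``.

    Returns (bin_centres, mean_density). For radial fields this is the
    stored profile itself.
    """
    if field.grid.mode == "radial1d":
        return field.grid.cell_centers(), field.values.copy()
    (xlim, ylim) = field.grid.bounds()
    if center is None:
        center = ((xlim[0] + xlim[1]) / 2, (ylim[0] + ylim[1]) / 2)
    if not (xlim[0] <= center[0] <= xlim[1] and ylim[0] <= center[1] <= ylim[1]):
        raise ValueError("center lies outside the domain")
    X, Y = field.grid.cell_centers()
    dist = np.hypot(X - center[0], Y - center[1]).ravel()
    h = field.grid.h
    idx = np.floor(dist / h).astype(int)
    nbins = idx.max() + 1
    sums = np.bincount(idx, weights=field.values.ravel(), minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    mean = np.divide(sums, counts, out=np.zeros(nbins), where=counts > 0)
    return (np.arange(nbins) + 0.5) * h, mean


def wave_speed_estimate(
    trajectory: Sequence[MultiSpeciesState],
    threshold: float,
    species: int = 0,
    **front_kw,
) -> float:
    """Least-squares slope of front position versus time (mm h^-1)."""
    if len(trajectory) < 3:
        raise ValueError("need at least 3 output times")
    times, fronts = [], []
    for st in trajectory:
        pos = front_position(st.field(species), threshold, **front_kw)
        if pos is None:
            raise ValueError(f"front undefined at t={st.time:g} h")
        times.append(st.time)
        fronts.append(pos)
    return float(np.polyfit(times, fronts, 1)[0])
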