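"""Numba time-stepping kernels for the finite-volume scheme.

One explicit conservative update per step. Porous family: face flux
``F = -M_face (P_R - P_L) / h`` with total pressure ``P = D (sum_j rho_j)^(m-1)``
and mobility ``M_face`` equal to the upwind cell's species density (upwinded
by the sign of the face velocity ``-dP/dx``); mobility is exactly zero in
vacuum, which preserves compact supports. Linear family: Fickian flux
``F = -D (rho_R - rho_L) / h`` per species. No-flux at every boundary.
Logistic reaction ``r rho_i (1 - rho_tot / K)`` is applied with explicit
Euler in the same step. Radial kernels weight face fluxes by the face
radius so that the polar mass ``sum 2 pi r_c rho h`` is conserved exactly.
"""

import numpy as np
from numba import njit

__all__ = ["run_radial", "run_cartesian"]


@njit(cache=True)
def run_radial(rho, h, dt, nsteps, D, r, K, m, linear):
    """Advance a (n_species, nr) radial state by nsteps of size dt, in place."""
    ns, nr = rho.shape
    tot = np.empty(nr)
    P = np.empty(nr)
    F = np.empty((ns, nr + 1))
    new = np.empty_like(rho)
    for _ in range(nsteps):
        for k in range(nr):
            s = 0.0
            for i in range(ns):
                s += rho[i, k]
            tot[k] = s
        if linear:
            for i in range(ns):
                F[i, 0] = 0.0
                F[i, nr] = 0.0
                for k in range(1, nr):
                    F[i, k] = -D * (rho[i, k] - rho[i, k - 1]) / h
        else:
            for k in range(nr):
                P[k] = D * tot[k] ** (m - 1.0)
            for i in range(ns):
                F[i, 0] = 0.0
                F[i, nr] = 0.0
                for k in range(1, nr):
                    v = -(P[k] - P[k - 1]) / h
                    mob = rho[i, k - 1] if v > 0.0 else rho[i, k]
                    F[i, k] = mob * v
        for i in range(ns):
            for k in range(nr):
                rc = (k + 0.5) * h
                div = ((k + 1.0) * F[i, k + 1] - k * F[i, k]) / rc
                growth = r * rho[i, k] * (1.0 - tot[k] / K)
                new[i, k] = rho[i, k] - dt * div + dt * growth
        rho[:, :] = new
    return rho


@njit(cache=True)
def run_cartesian(rho, h, dt, nsteps, D, r, K, m, linear):
    """Advance a (n_species, ny, nx) Cartesian state by nsteps of dt, in place.

    A grid with ny == 1 (or nx == 1) has no interior faces in that
    direction and degenerates to a 1D solver.
    """
    ns, ny, nx = rho.shape
    tot = np.empty((ny, nx))
    P = np.empty((ny, nx))
    new = np.empty_like(rho)
    for _ in range(nsteps):
        for j in range(ny):
            for k in range(nx):
                s = 0.0
                for i in range(ns):
                    s += rho[i, j, k]
                tot[j, k] = s
        if not linear:
            for j in range(ny):
                for k in range(nx):
                    P[j, k] = D * tot[j, k] ** (m - 1.0)
        for i in range(ns):
            for j in range(ny):
                for k in range(nx):
                    new[i, j, k] = rho[i, j, k] + dt * r * rho[i, j, k] * (
                        1.0 - tot[j, k] / K
                    )
            # x-direction faces
            for j in range(ny):
                for k in range(1, nx):
                    if linear:
                        Fx = -D * (rho[i, j, k] - rho[i, j, k - 1]) / h
                    else:
                        v = -(P[j, k] - P[j, k - 1]) / h
                        mob = rho[i, j, k - 1] if v > 0.0 else rho[i, j, k]
                        Fx = mob * v
                    new[i, j, k - 1] -= dt * Fx / h
                    new[i, j, k] += dt * Fx / h
            # y-direction faces
            for j in range(1, ny):
                for k in range(nx):
                    if linear:
                        Fy = -D * (rho[i, j, k] - rho[i, j - 1, k]) / h
                    else:
                        v = -(P[j, k] - P[j - 1, k]) / h
                        mob = rho[i, j - 1, k] if v > 0.0 else rho[i, j, k]
                        Fy = mob * v
                    new[i, j - 1, k] -= dt * Fy / h
                    new[i, j, k] += dt * Fy / h
        rho[:, :, :] = new
    return rho
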