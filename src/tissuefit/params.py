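"""Model parameters, constitutive laws and derived biological quantities.

Two continuum families describe the growth of an epithelial monolayer with
cell density ``rho(x, t)`` (cells mm^-2):

* ``linear`` — the Fisher-KPP equation, Fickian flux ``j = -D grad(rho)``
  with constant diffusivity ``D`` (um^2 h^-1);
* ``porous`` — the Porous-Fisher equation, Darcy flux ``j = -rho grad(P)``
  with power-law population pressure ``P(rho) = D rho^(m-1)``, so the
  diffusivity ``D(rho) = D rho^(m-1)`` vanishes in vacuum and the model
  supports compactly supported solutions with sharp invasion fronts.

Both families share logistic growth ``r rho (1 - rho / K)``.

Internally every computation uses mm, hours and cells mm^-2; user-facing
diffusion constants are given in um^2 h^-1 (linear) or um^2 (cells h)^-1
(porous, i.e. per unit density for m = 2) and converted on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ModelParams",
    "DerivedQuantities",
    "crowding_function",
    "diffusivity",
    "packing_radius",
    "growth_summary",
    "round_to_sig",
]

#: um^2 -> mm^2
UM2_TO_MM2 = 1e-6
#: mm -> um
MM_TO_UM = 1e3

_FAMILIES = ("linear", "porous")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a single growth model.

    Parameters
    ----------
    family : {"linear", "porous"}
        Diffusion law: constant (Fisher-KPP) or density-dependent
        (Porous-Fisher).
    D : float
        Diffusion constant. Units: um^2 h^-1 for ``linear``;
        um^2 h^-1 per (cells mm^-2)^(m-1) for ``porous`` (for the default
        m = 2 this is the conventional um^2 (cells h)^-1).
    r : float
        Proliferation rate (h^-1), r >= 0.
    K : float
        Carrying capacity (cells mm^-2).
    m : float
        Pressure exponent of ``P(rho) ~ rho^(m-1)``; must exceed 1 for the
        porous family. Ignored (treated as the m -> 1 limit) for linear.
    """

    family: str
    D: float
    r: float
    K: float
    m: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        for name in ("D", "r", "K", "m"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.family == "porous" and self.m <= 1:
            raise ValueError(f"porous family requires m > 1, got m={self.m}")

    @property
    def D_internal(self) -> float:
        """Diffusion constant in internal units (mm^2 h^-1 based)."""
        return self.D * UM2_TO_MM2

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d_unit = (
            "um^2 h^-1"
            if self.family == "linear"
            else "um^2 h^-1 per (cells mm^-2)^(m-1)"
        )
        return {
            "family": self.family,
            "D": self.D,
            "D_unit": d_unit,
            "r": self.r,
            "r_unit": "h^-1",
            "K": self.K,
            "K_unit": "cells mm^-2",
            "m": self.m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            family=d["family"],
            D=float(d["D"]),
            r=float(d["r"]),
            K=float(d["K"]),
            m=float(d.get("m", 2.0)),
        )


@dataclass(frozen=True)
class DerivedQuantities:
    """Biological numbers derived from a fitted parameter set.

    ``division_time_printed`` follows the reporting convention of rounding
    the effective rate to one significant figure before taking the
    reciprocal; ``division_time`` is the exact reciprocal. Both are NaN when
    the mean density sits at (or above) carrying capacity.
    """

    cell_radius_um: float
    effective_rate: float  # h^-1
    division_time: float  # h
    division_time_printed: float  # h
    average_diffusivity: float  # um^2 h^-1


def crowding_function(rho, K: float):
    """Logistic crowding factor ``f(rho) = 1 - rho / K``.

    Negative values (rho > K) are meaningful: net growth becomes a sink.
    Accepts scalars or arrays.
    """
    import numpy as np

    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("rho must be finite")
    if not (math.isfinite(K) and K > 0):
        raise ValueError(f"K must be positive and finite, got {K}")
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    out = 1.0 - rho / K
    return out if out.ndim else float(out)


def diffusivity(rho, params: ModelParams):
    """Density-dependent diffusivity ``D(rho)`` in um^2 h^-1.

    ``linear`` returns the constant D; ``porous`` returns
    ``D rho^(m-1)``, which vanishes at rho = 0 (degenerate diffusion).
    """
    import numpy as np

    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or not np.all(np.isfinite(rho)):
        raise ValueError("rho must be finite and >= 0")
    if params.family == "linear":
        out = np.full_like(rho, params.D)
    else:
        out = params.D * rho ** (params.m - 1.0)
    return out if out.ndim else float(out)


def packing_radius(K: float) -> float:
    """Cell radius (um) implied by hexagonal close packing at density K.

    Maximum hexagonal packing of discs of radius ``a`` has number density
    ``K = 1 / (2 sqrt(3) a^2)``, hence ``a = (2 sqrt(3) K)^(-1/2)``. K is in
    cells mm^-2; the returned radius is in um, unrounded.
    """
    if not (math.isfinite(K) and K > 0):
        raise ValueError(f"K must be positive and finite, got {K}")
    a_mm = 1.0 / math.sqrt(2.0 * math.sqrt(3.0) * K)
    return a_mm * MM_TO_UM


def round_to_sig(x: float, sig: int = 1) -> float:
    """Round ``x`` to ``sig`` significant figures (x > 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)


def growth_summary(params: ModelParams, rho_bar: float) -> DerivedQuantities:
    """Derived biology at a representative mean density ``rho_bar``.

    effective_rate = r (1 - rho_bar / K); division_time = 1 / effective_rate
    (undefined, reported as NaN, at rho_bar >= K); average_diffusivity =
    D(rho_bar). ``division_time_printed`` rounds the rate to one significant
    figure first.
    """
    if not (0 <= rho_bar):
        raise ValueError("rho_bar must be >= 0")
    eff = params.r * (1.0 - rho_bar / params.K)
    if rho_bar >= params.K or eff <= 0:
        division = math.nan
        division_printed = math.nan
        eff = params.r * (1.0 - rho_bar / params.K)
    else:
        division = 1.0 / eff
        division_printed = 1.0 / round_to_sig(eff, 1)
    return DerivedQuantities(
        cell_radius_um=packing_radius(params.K),
        effective_rate=eff,
        division_time=division,
        division_time_printed=division_printed,
        average_diffusivity=diffusivity(rho_bar, params),
    )
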