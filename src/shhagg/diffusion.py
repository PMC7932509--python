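"""Hydrodynamic radii and Stokes-Einstein diffusion coefficients.

Aggregates are approximated as spheres of additive volume: a free multimer
of n monomers has radius r1 * n^(1/3); a carrier-bound aggregate adds the
Shh volume to a fixed carrier core (large for a lipoprotein particle,
smaller for an HSPG chain), so its radius is (r0^3 + n * r1^3)^(1/3).  The
diffusion coefficient follows from the Stokes-Einstein relation
D = kB * T / (6 pi eta r).

The geometry defaults are a plain volume-additive reconstruction, not a
canonical parameterisation; every constant is exposed on
:class:`GeometryParams`.  The robust qualitative consequences are that D
decreases with size for every mechanism, and that a lipoprotein's large
fixed core makes its diffusion nearly insensitive to Shh loading, while a
bare multimer's is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

BOLTZMANN_J_PER_K = 1.380649e-23

MECHANISMS = ("multimer", "hspg", "lipoprotein")


@dataclass(frozen=True)
class GeometryParams:
    """Sphere-model geometry and solvent conditions.

    Radii in nm; temperature in K; viscosity in Pa*s (default: water-like
    medium at 25 C).
    """

    monomer_radius_nm: float = 2.4
    lipo_core_radius_nm: float = 12.0
    hspg_core_radius_nm: float = 5.0
    packing_exponent: float = 1.0 / 3.0
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4

    def __post_init__(self) -> None:
        if min(self.monomer_radius_nm, self.lipo_core_radius_nm,
               self.hspg_core_radius_nm) <= 0:
            raise ValueError("radii must be positive")
        if self.temperature_K <= 0 or self.viscosity_Pa_s <= 0:
            raise ValueError("temperature and viscosity must be positive")


@dataclass(frozen=True)
class DiffusionEstimate:
    mechanism: str
    size: int
    radius_nm: float
    D_m2_per_s: float


def hydrodynamic_radius(mechanism: str, size: int, geom: GeometryParams) -> float:
    """Sphere-equivalent radius (nm) of an aggregate of ``size`` Shh."""
    if size < 1:
        raise ValueError("size must be >= 1")
    r1 = geom.monomer_radius_nm
    p = geom.packing_exponent
    if mechanism == "multimer":
        return r1 * size**p
    if mechanism == "lipoprotein":
        core = geom.lipo_core_radius_nm
    elif mechanism == "hspg":
        core = geom.hspg_core_radius_nm
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return (core ** (1.0 / p) + size * r1 ** (1.0 / p)) ** p


def diffusion_coefficient(radius_nm: float, temperature_K: float = 298.15,
                          viscosity_Pa_s: float = 8.9e-4) -> float:
    """Stokes-Einstein diffusion coefficient (m^2/s) for a sphere."""
    if radius_nm <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    r_m = radius_nm * 1e-9
    return BOLTZMANN_J_PER_K * temperature_K / (6.0 * math.pi * viscosity_Pa_s * r_m)


def estimate(mechanism: str, size: int, geom: GeometryParams | None = None) -> DiffusionEstimate:
    geom = geom or GeometryParams()
    r = hydrodynamic_radius(mechanism, size, geom)
    return DiffusionEstimate(mechanism, size, r,
                             diffusion_coefficient(r, geom.temperature_K,
                                                   geom.viscosity_Pa_s))


def diffusion_table(max_size: int, geom: GeometryParams | None = None) -> pd.DataFrame:
    """Per-mechanism, per-size radius and D for sizes 1..max_size."""
    geom = geom or GeometryParams()
    rows = [estimate(m, n, geom).__dict__
            for m in MECHANISMS for n in range(1, max_size + 1)]
    return pd.DataFrame(rows)
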