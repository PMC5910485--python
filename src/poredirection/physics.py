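"""Diffusion arithmetic for small fluorescent dyes.

Einstein-Smoluchowski diffusion-time estimates, Stokes-Einstein diffusion
coefficients from hydrodynamic radius, and dye mobility ratios.

The mean-squared-displacement prefactor (2 for 1-D, 4 for 2-D, 6 for 3-D)
is an explicit required argument of :func:`diffusion_time` and never
defaulted: published order-of-magnitude estimates for intracellular
transport are sometimes quoted with the 3-D form while the printed numbers
are consistent with the 2-D prefactor, so callers must state which
convention they mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "BOLTZMANN_J_PER_K",
    "WATER_VISCOSITY_25C",
    "DiffusionQuery",
    "MoleculeGeometry",
    "diffusion_time",
    "stokes_einstein_D",
    "mobility_ratio",
    "load_dye_table",
    "get_molecule",
    "round_sig",
]

BOLTZMANN_J_PER_K = 1.380649e-23
WATER_VISCOSITY_25C = 8.9e-4  # Pa s
ROOM_TEMPERATURE_K = 298.0

_MSD_FACTORS = (2, 4, 6)


@dataclass(frozen=True)
class DiffusionQuery:
    """A characteristic-diffusion-time question.

    Parameters
    ----------
    distance : float
        Traverse distance in metres.
    D : float
        Diffusion coefficient in m^2 s^-1.
    msd_factor : int
        Mean-squared-displacement prefactor: 2 (1-D), 4 (2-D) or 6 (3-D).
    """

    distance: float
    D: float
    msd_factor: int

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError(f"distance must be positive, got {self.distance}")
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.msd_factor not in _MSD_FACTORS:
            raise ValueError(
                f"msd_factor must be one of {_MSD_FACTORS}, got {self.msd_factor}"
            )


@dataclass(frozen=True)
class MoleculeGeometry:
    """Size and mobility descriptors of one dye molecule."""

    name: str
    cross_section_diameter: float  # nm
    D_calc: float | None = None  # m^2 s^-1, geometry-based
    mw: float | None = None  # Da
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.cross_section_diameter <= 0:
            raise ValueError("cross_section_diameter must be positive")


def diffusion_time(query: DiffusionQuery) -> float:
    """Characteristic time to diffuse ``distance`` given ``D``: d^2/(factor*D)."""
    return query.distance**2 / (query.msd_factor * query.D)


def stokes_einstein_D(
    radius: float,
    temperature: float = ROOM_TEMPERATURE_K,
    viscosity: float = WATER_VISCOSITY_25C,
) -> float:
    """Stokes-Einstein diffusion coefficient D = kT / (6 pi eta r).

    ``radius`` in metres, ``temperature`` in kelvin, ``viscosity`` in Pa s.
    """
    if radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must all be positive")
    return BOLTZMANN_J_PER_K * temperature / (6.0 * math.pi * viscosity * radius)


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def mobility_ratio(a: MoleculeGeometry, b: MoleculeGeometry, sig_figs: int = 2) -> float:
    """Ratio of diffusion speeds D_a / D_b.

    Uses the geometry-based coefficients when both molecules carry one;
    otherwise falls back to the Stokes-Einstein inverse-radius route, where
    the ratio reduces to cross_section_b / cross_section_a.
    """
    if a.D_calc is not None and b.D_calc is not None:
        ratio = a.D_calc / b.D_calc
    elif a.cross_section_diameter and b.cross_section_diameter:
        ratio = b.cross_section_diameter / a.cross_section_diameter
    else:  # pragma: no cover - dataclass invariant forbids this
        raise ValueError("need D_calc on both molecules or cross-sections on both")
    return round_sig(ratio, sig_figs)


def load_dye_table() -> pd.DataFrame:
    """Bundled dye-property table (charge, MW, cross-section, geometry-based D)."""
    with resources.files("poredirection.data").joinpath("dye_properties.csv").open() as fh:
        return pd.read_csv(fh)


def get_molecule(name: str) -> MoleculeGeometry:
    """Look a dye up in the bundled table by (case-insensitive) name."""
    table = load_dye_table()
    hit = table[table["name"].str.lower() == name.lower()]
    if hit.empty:
        raise KeyError(f"unknown dye {name!r}; known: {list(table['name'])}")
    row = hit.iloc[0]
    d_calc = None if pd.isna(row["D_calc_m2_s"]) else float(row["D_calc_m2_s"])
    return MoleculeGeometry(
        name=str(row["name"]),
        cross_section_diameter=float(row["cross_section_nm"]),
        D_calc=d_calc,
        mw=float(row["mw_da"]),
        charge=int(row["charge"]),
    )
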