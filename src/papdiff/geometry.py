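"""Geometry of an idealized perisynaptic astrocyte projection (PAP) and
nanoscale unit conversions.

The PAP is idealized as a cylinder of length ``L`` (the distance between the
membrane apposed to the postsynaptic density, the *alpha* face, and the
intracellular Ca2+ stores, the *beta* face) and diameter ``D``.  At this scale
a micromolar concentration corresponds to single-digit molecule numbers, so
the package needs exact, loss-free conversion between molar concentration and
absolute molecule count.

Canonical units
---------------
Lengths are nanometres, volumes are litres at the conversion interface
(cubic metres are also exposed), concentrations are mol/L, and times are
seconds.  Every public function states its units explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import pandas as pd

from .errors import InvalidParameterError

#: Exact SI value of the Avogadro constant, mol^-1.
AVOGADRO: float = 6.02214076e23

_NM3_TO_M3 = 1e-27
_M3_TO_L = 1e3


@dataclass(frozen=True)
class CylinderGeometry:
    """Cylindrical PAP geometry.

    Parameters
    ----------
    length_nm
        Cylinder length L in nm (distance alpha -> beta).  Default 1000 nm.
    diameter_nm
        Cylinder diameter D in nm.  Default 100 nm.
    """

    length_nm: float = 1000.0
    diameter_nm: float = 100.0

    def __post_init__(self) -> None:
        if not (self.length_nm > 0 and self.diameter_nm > 0):
            raise InvalidParameterError(
                f"cylinder dimensions must be positive, got "
                f"L={self.length_nm} nm, D={self.diameter_nm} nm"
            )

    @property
    def cross_section_nm2(self) -> float:
        """Transversal section area pi*D^2/4 in nm^2."""
        return math.pi * self.diameter_nm**2 / 4.0

    @property
    def volume_m3(self) -> float:
        """Internal volume pi*D^2*L/4 in m^3."""
        return self.cross_section_nm2 * self.length_nm * _NM3_TO_M3

    @property
    def volume_l(self) -> float:
        """Internal volume in litres."""
        return self.volume_m3 * _M3_TO_L


@dataclass(frozen=True)
class PhysicalConstants:
    """Transport and bookkeeping constants for the diffusion analysis.

    Attributes
    ----------
    avogadro
        Avogadro constant, mol^-1.
    dab_um2_s
        Cytosolic diffusion coefficient of IP3, um^2/s.  Default 300; a
        disputed literature alternative is 10.
    degradation_horizon_s
        Earliest reported time for IP3 degradation, s.  The no-removal
        assumption of the model is only valid below this horizon.
    """

    avogadro: float = AVOGADRO
    dab_um2_s: float = 300.0
    degradation_horizon_s: float = 0.8

    def __post_init__(self) -> None:
        if not (
            self.avogadro > 0 and self.dab_um2_s > 0 and self.degradation_horizon_s > 0
        ):
            raise InvalidParameterError("physical constants must be strictly positive")


class Volume(NamedTuple):
    """Cylinder volume in both SI and litre units."""

    m3: float
    litres: float


def cylinder_volume(geom: CylinderGeometry) -> Volume:
    """Internal volume of the PAP cylinder.

    Returns the volume both in m^3 and litres.  For the default geometry
    (D = 100 nm, L = 1000 nm) this is 7.8540e-21 m^3 = 7.8540e-18 L — a
    volume in which 1 uM corresponds to fewer than five molecules.
    """
    return Volume(geom.volume_m3, geom.volume_l)


def concentration_to_molecules(
    conc_molar: float, volume_l: float, avogadro: float = AVOGADRO
) -> float:
    """Expected molecule count for a molar concentration in a given volume.

    The result is real-valued; rounding to whole molecules is deliberately
    left to the caller (see :mod:`papdiff.allocation`).

    Parameters
    ----------
    conc_molar
        Concentration in mol/L, >= 0.
    volume_l
        Volume in litres, > 0.
    """
    if conc_molar < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {conc_molar}")
    if volume_l <= 0:
        raise InvalidParameterError(f"volume must be > 0, got {volume_l} L")
    return conc_molar * volume_l * avogadro


def molecules_to_concentration(
    n: float, volume_l: float, avogadro: float = AVOGADRO
) -> float:
    """Molar concentration of ``n`` molecules in ``volume_l`` litres.

    Exact inverse of :func:`concentration_to_molecules`.  In the default PAP
    volume one molecule corresponds to roughly 0.21 uM.
    """
    if n < 0:
        raise InvalidParameterError(f"molecule count must be >= 0, got {n}")
    if volume_l <= 0:
        raise InvalidParameterError(f"volume must be > 0, got {volume_l} L")
    return n / (volume_l * avogadro)


#: Concentrations (mol/L) of the reference conversion table: 1 M, 1 mM, 1 uM, 1 nM.
TABLE1_CONCENTRATIONS: tuple[float, ...] = (1.0, 1e-3, 1e-6, 1e-9)


def conversion_table(
    concentrations: Sequence[float] = TABLE1_CONCENTRATIONS,
    volume_l: float | None = None,
    geom: CylinderGeometry | None = None,
) -> pd.DataFrame:
    """Concentration/molecule-count table for a fixed volume.

    Parameters
    ----------
    concentrations
        Molar concentrations for the rows; defaults to 1 M, 1 mM, 1 uM, 1 nM.
    volume_l
        Volume in litres; defaults to the volume of ``geom`` (or the default
        cylinder when both are omitted).

    Returns
    -------
    pandas.DataFrame
        Columns ``concentration_molar`` and ``molecules``.
    """
    if volume_l is None:
        volume_l = (geom or CylinderGeometry()).volume_l
    rows = [
        {
            "concentration_molar": c,
            "molecules": concentration_to_molecules(c, volume_l),
        }
        for c in concentrations
    ]
    return pd.DataFrame(rows)
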