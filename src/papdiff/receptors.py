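"""Capacity estimates for IP3 receptors at the Ca2+-store face.

Order-of-magnitude geometry: how many IP3R channels fit on the store
membrane facing the projection (cross-section area / receptor footprint),
how many of those slots are plausibly occupied by IP3R rather than RyR and
other proteins, and how much IP3 would be needed to engage the whole pool
given the four-IP3 stoichiometry of receptor activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidParameterError
from .geometry import CylinderGeometry

#: Membrane footprint of one IP3R channel, nm^2 (from the 3JAV cryo-EM
#: structure's in-plane dimensions).
DEFAULT_IP3R_FOOTPRINT_NM2: float = 380.0

#: IP3 molecules required to activate one IP3R channel.
IP3_PER_RECEPTOR: int = 4


@dataclass(frozen=True)
class ReceptorParams:
    """Geometric parameters of the IP3R capacity estimate.

    Attributes
    ----------
    ip3r_footprint_nm2
        In-membrane area of one IP3R, nm^2.
    cross_section_nm2
        Area of the store membrane facing the projection, taken as the
        cylinder cross-section pi*D^2/4 (7854 nm^2 for D = 100 nm).
    sharing_fraction
        Fraction of that face available to IP3R (the rest holds RyR and
        other proteins).  Default 0.5.
    ip3_per_receptor
        Activation stoichiometry, default 4.
    """

    ip3r_footprint_nm2: float = DEFAULT_IP3R_FOOTPRINT_NM2
    cross_section_nm2: float = field(
        default_factory=lambda: CylinderGeometry().cross_section_nm2
    )
    sharing_fraction: float = 0.5
    ip3_per_receptor: int = IP3_PER_RECEPTOR

    def __post_init__(self) -> None:
        if self.ip3r_footprint_nm2 <= 0 or self.cross_section_nm2 <= 0:
            raise InvalidParameterError("areas must be strictly positive")
        if not (0 < self.sharing_fraction <= 1):
            raise InvalidParameterError(
                f"sharing_fraction must be in (0, 1], got {self.sharing_fraction}"
            )
        if self.ip3_per_receptor < 1:
            raise InvalidParameterError("ip3_per_receptor must be >= 1")


def max_ip3r(params: ReceptorParams = ReceptorParams()) -> int:
    """Maximum IP3R count fitting on the store face: floor(area/footprint).

    20 for the defaults (7854 nm^2 face, 380 nm^2 footprint).
    """
    return int(math.floor(params.cross_section_nm2 / params.ip3r_footprint_nm2))


def effective_ip3r(params: ReceptorParams = ReceptorParams()) -> int:
    """IP3R actually facing the projection after sharing the membrane with
    RyR and other proteins: floor(max * sharing_fraction).  10 by default —
    about the pool size needed for a Ca2+ puff."""
    return int(math.floor(max_ip3r(params) * params.sharing_fraction))


def ip3_to_activate_pool(params: ReceptorParams = ReceptorParams()) -> int:
    """IP3 molecules required to engage the whole effective IP3R pool
    (effective count x 4 IP3 each; 40 by default)."""
    return effective_ip3r(params) * params.ip3_per_receptor


def activation_report(
    table: pd.DataFrame, params: ReceptorParams = ReceptorParams()
) -> pd.DataFrame:
    """Annotate a per-condition summary with receptor-activation thresholds.

    Adds two boolean columns to a :func:`papdiff.allocation.table3` frame:
    ``near_beta_ge_4`` (enough IP3 at the store face to activate a single
    receptor) and ``near_beta_ge_pool`` (enough to engage the whole
    effective pool).
    """
    if "near_beta" not in table.columns:
        raise InvalidParameterError("table must contain a near_beta column")
    out = table.copy()
    out["near_beta_ge_4"] = out["near_beta"] >= params.ip3_per_receptor
    out["near_beta_ge_pool"] = out["near_beta"] >= ip3_to_activate_pool(params)
    return out
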