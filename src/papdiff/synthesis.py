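"""IP3 synthesis by phospholipase C (PLC) at the source face.

PLC cleaves membrane PIP2 into IP3 at the face of the projection apposed to
the synapse.  The model is zero-order: ``n_plc`` enzymes each turning over
``kcat`` substrate molecules per second, until the finite PIP2 cluster budget
(three clusters of ~1000 molecules by default) is exhausted.  Substrate
depletion slow-down, PLC regulation and the alternative substrate PIP3 are
all outside the model; IP3 removal is likewise ignored, which is only valid
below the degradation horizon (~0.8 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

#: Default PIP2 budget: three clusters of ~1000 molecules each.
DEFAULT_PIP2_BUDGET: int = 3000


@dataclass(frozen=True)
class SynthesisScenario:
    """One PLC condition: copy number, specific activity and substrate budget.

    Attributes
    ----------
    n_plc
        Number of PLC molecules at the source face (1, 10 or 100 in the
        reference conditions).
    kcat_per_s
        PLC specific activity in catalytic turnovers per second (1000 or
        5000 in the reference conditions).
    pip2_budget
        Total PIP2 molecules available for cleavage.
    """

    n_plc: int
    kcat_per_s: float
    pip2_budget: int = DEFAULT_PIP2_BUDGET

    def __post_init__(self) -> None:
        if self.n_plc < 1:
            raise InvalidParameterError(f"n_plc must be >= 1, got {self.n_plc}")
        if self.kcat_per_s <= 0:
            raise InvalidParameterError(f"kcat must be > 0, got {self.kcat_per_s}")
        if self.pip2_budget < 0:
            raise InvalidParameterError(
                f"pip2_budget must be >= 0, got {self.pip2_budget}"
            )

    @property
    def rate_per_s(self) -> float:
        """Aggregate IP3 synthesis rate, molecules/s."""
        return self.n_plc * self.kcat_per_s


def total_ip3(
    scn: SynthesisScenario, t_s: float, degradation_horizon_s: float = 0.8
) -> float:
    """Total IP3 synthesized after ``t_s`` seconds (real-valued, capped).

    Returns ``min(n_plc * kcat * t, pip2_budget)``.  No degradation is
    subtracted; a warning is logged when ``t_s`` exceeds the degradation
    horizon, where the no-removal assumption breaks down.
    """
    if t_s < 0:
        raise InvalidParameterError(f"time must be >= 0, got {t_s}")
    if t_s > degradation_horizon_s:
        logger.warning(
            "t = %.3g s exceeds the IP3 degradation horizon (%.3g s); "
            "the no-degradation assumption is invalid at this time",
            t_s,
            degradation_horizon_s,
        )
    return min(scn.rate_per_s * t_s, float(scn.pip2_budget))


def depletion_time(scn: SynthesisScenario) -> float:
    """Time in seconds at which the PIP2 budget is exhausted.

    ``pip2_budget / (n_plc * kcat)`` — e.g. 0.6 s for a single PLC at
    5000/s (below the 0.8 s degradation horizon), 6 ms for 100 PLC.
    """
    return scn.pip2_budget / scn.rate_per_s
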