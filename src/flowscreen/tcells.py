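"""T-cell subset composition by CD45RA x CCR7 quadrant gating.

Within a CD4+ or CD8+ parent population, the four canonical subsets are

    naive            CCR7+ CD45RA+
    TEMRA            CCR7- CD45RA+   (terminally differentiated effector memory)
    effector memory  CCR7- CD45RA-
    central memory   CCR7+ CD45RA-

Positivity is strict (x > threshold); boundary events fall on the negative
side, so the four quadrants partition the parent exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .events import EventTable

__all__ = ["SubsetComposition", "quadrant_subsets", "SUBSETS"]

logger = logging.getLogger(__name__)

SUBSETS = ("naive", "temra", "effector_memory", "central_memory")


@dataclass(frozen=True)
class SubsetComposition:
    """Percent of parent events per subset; NaN throughout when the parent is empty."""

    sample_id: str
    compartment: str  # "CD4" or "CD8"
    n_events: int
    naive: float
    temra: float
    effector_memory: float
    central_memory: float

    @property
    def defined(self) -> bool:
        return self.n_events > 0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in SUBSETS}


def quadrant_subsets(
    events: EventTable,
    x_threshold: float,
    y_threshold: float,
    x_channel: str = "CD45RA",
    y_channel: str = "CCR7",
    compartment: str = "",
) -> SubsetComposition:
    """Assign each event to one CD45RA x CCR7 quadrant and report percentages.

    ``events`` must already be gated to the CD4+ or CD8+ compartment.
    Thresholds are fixed bounds in channel units (or derived upstream from an
    isotype/FMO control via ``positivity_threshold``).
    """
    n = events.n_events
    if n == 0:
        logger.warning("sample %s: empty parent population; composition undefined", events.sample_id)
        nan = float("nan")
        return SubsetComposition(events.sample_id, compartment, 0, nan, nan, nan, nan)
    x = events.values(x_channel) > x_threshold  # CD45RA+
    y = events.values(y_channel) > y_threshold  # CCR7+
    counts = {
        "naive": int(np.sum(x & y)),
        "temra": int(np.sum(x & ~y)),
        "effector_memory": int(np.sum(~x & ~y)),
        "central_memory": int(np.sum(~x & y)),
    }
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    return SubsetComposition(events.sample_id, compartment, n, **pct)
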