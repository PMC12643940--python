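"""Coculture killing, T-cell activation, dose-response and engraftment.

Killing assays coculture T cells with AML cells; the readout is the number of
remaining viable AML cells (CD3-CD33+), converted from gated event counts to
absolute numbers with spiked counting beads:

    cells = cell_events x beads_added / bead_events.

Counts are normalized to a designated control condition (wild-type cells or
isotype-control antibody), giving percent-of-control and percent reduction.
T-cell activation is the percent of gated CD4+/CD8+ T cells positive for the
activation markers CD25 and/or CD69. Engraftment in xenograft tissue is the
percent of leukemia-phenotype events among viable events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, QuantificationError
from .events import EventTable
from .gating import Gate

__all__ = [
    "CocultureSample",
    "EngraftmentResult",
    "absolute_count",
    "activation_fraction",
    "normalize_to_control",
    "dose_response_table",
    "engraftment_fraction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CocultureSample:
    """Gated event counts and metadata for one coculture well."""

    sample_id: str
    condition: str  # antibody / genotype label
    dose: float  # antibody concentration (assay units); 0 for untreated
    aml_events: int  # viable CD3-CD33+ events
    bead_events: int
    beads_added: int
    replicate: int = 1
    is_control: bool = False
    tcell_counts: dict[str, int] = field(default_factory=dict)  # compartment/state -> events

    def __post_init__(self) -> None:
        if min(self.aml_events, self.bead_events) < 0 or self.beads_added <= 0:
            raise ConfigurationError(f"{self.sample_id}: counts must be >= 0 and beads_added > 0")

    @property
    def aml_absolute(self) -> float:
        return absolute_count(self.aml_events, self.bead_events, self.beads_added)


@dataclass(frozen=True)
class EngraftmentResult:
    animal_id: str
    compartment: str  # "bone marrow" or "spleen"
    pct_target: float  # percent target-phenotype cells among viable; NaN if no viable events
    n_viable: int


def absolute_count(cell_events: int, bead_events: int, beads_added: int) -> float:
    """Bead-normalized absolute cell number for one tube."""
    if bead_events <= 0:
        raise QuantificationError("no bead events acquired; absolute count undefined")
    if beads_added <= 0:
        raise ConfigurationError("beads_added must be positive")
    return cell_events * beads_added / bead_events


def activation_fraction(
    tcell_events: EventTable,
    cd25_threshold: float,
    cd69_threshold: float,
    policy: Literal["either", "both"] = "either",
    cd25_channel: str = "CD25",
    cd69_channel: str = "CD69",
) -> float:
    """Percent of gated T cells positive for CD25/CD69 per the policy.

    ``policy="either"`` (default) counts cells above either threshold;
    ``"both"`` requires both. Returns NaN for an empty table.
    """
    if policy not in ("either", "both"):
        raise ConfigurationError(f"unknown activation policy {policy!r}")
    if tcell_events.n_events == 0:
        logger.warning("sample %s: no T-cell events; activation undefined", tcell_events.sample_id)
        return float("nan")
    cd25 = tcell_events.values(cd25_channel) > cd25_threshold
    cd69 = tcell_events.values(cd69_channel) > cd69_threshold
    mask = (cd25 | cd69) if policy == "either" else (cd25 & cd69)
    logger.debug("activation policy %s: %d/%d positive", policy, int(mask.sum()), len(mask))
    return 100.0 * float(np.mean(mask))


def normalize_to_control(
    values: Sequence[float],
    control_values: Sequence[float],
) -> dict:
    """Normalize absolute counts to the mean of the control replicates.

    Returns per-replicate normalized percentages, their mean, and the percent
    reduction of the treated mean relative to control.
    """
    control = np.asarray(control_values, dtype=float)
    treated = np.asarray(values, dtype=float)
    if control.size == 0 or treated.size == 0:
        raise QuantificationError("need >= 1 treated and >= 1 control value")
    control_mean = float(control.mean())
    if control_mean <= 0:
        raise QuantificationError(f"control mean must be positive, got {control_mean}")
    normalized = 100.0 * treated / control_mean
    return {
        "normalized_pct": normalized.tolist(),
        "normalized_mean": float(normalized.mean()),
        "pct_reduction": 100.0 - float(normalized.mean()),
    }


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) >= 2 else float("nan")


def dose_response_table(
    samples: Iterable[CocultureSample],
    activation: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-(condition, dose) mean absolute AML count and mean activation.

    ``activation`` optionally maps sample_id -> percent activated. Rows are
    sorted by condition then ascending dose; s.e.m. columns are NaN for
    singleton replicate groups.
    """
    rows = []
    for s in samples:
        rows.append(
            {
                "condition": s.condition,
                "dose": s.dose,
                "sample_id": s.sample_id,
                "aml_count": s.aml_absolute,
                "activation_pct": float("nan") if activation is None else activation.get(s.sample_id, float("nan")),
            }
        )
    if not rows:
        raise ConfigurationError("no coculture samples supplied")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["condition", "dose"], sort=False)
        .agg(
            n_replicates=("aml_count", "size"),
            aml_count_mean=("aml_count", "mean"),
            aml_count_sem=("aml_count", lambda x: _sem(x.to_numpy())),
            activation_mean=("activation_pct", "mean"),
            activation_sem=("activation_pct", lambda x: _sem(x.dropna().to_numpy())),
        )
        .reset_index()
        .sort_values(["condition", "dose"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def engraftment_fraction(
    events: EventTable,
    phenotype_gates: Sequence[Gate],
    viability_gate: Gate,
    animal_id: str = "",
    compartment: str = "",
) -> EngraftmentResult:
    """Percent of viable events matching the full target phenotype.

    The target phenotype (e.g. hCD45+CD3-CD33+CD34+SLAMF6+) is the
    conjunction of ``phenotype_gates`` applied *within* the viable
    population.
    """
    viable = viability_gate.mask(events)
    n_viable = int(viable.sum())
    if n_viable == 0:
        logger.warning("animal %s %s: no viable events; engraftment undefined", animal_id, compartment)
        return EngraftmentResult(animal_id, compartment, float("nan"), 0)
    target = viable.copy()
    for gate in phenotype_gates:
        target &= gate.mask(events)
    return EngraftmentResult(
        animal_id, compartment, 100.0 * float(target.sum()) / n_viable, n_viable
    )
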