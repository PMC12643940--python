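"""Per-population marker statistics: MFI, positivity threshold, % positive.

Positivity is anchored on an isotype (or FMO) control: the threshold is a high
empirical quantile of the control's intensity distribution on the channel
(default the 99th percentile), and an event is called positive when its
intensity lies strictly above that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError
from .events import EventTable

__all__ = ["StatConfig", "MarkerStats", "positivity_threshold", "population_stats"]

MfiStatistic = Literal["arithmetic-mean", "median", "geometric-mean"]


@dataclass(frozen=True)
class StatConfig:
    """How marker statistics are computed.

    mfi_statistic
        Location statistic reported as "MFI". Defaults to the arithmetic mean
        (MFI = mean fluorescence intensity); median and geometric mean are
        common alternatives in cytometry practice.
    positivity_quantile
        Quantile of the isotype distribution used as the positivity threshold;
        strictly between 0 and 1.
    background_subtraction
        If true, the isotype control's own above-threshold fraction is
        subtracted from %positive (floored at 0).
    """

    mfi_statistic: MfiStatistic = "arithmetic-mean"
    positivity_quantile: float = 0.99
    background_subtraction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.positivity_quantile < 1.0:
            raise ConfigurationError(
                f"positivity_quantile must be in (0,1), got {self.positivity_quantile}"
            )
        if self.mfi_statistic not in ("arithmetic-mean", "median", "geometric-mean"):
            raise ConfigurationError(f"unknown mfi_statistic {self.mfi_statistic!r}")


@dataclass(frozen=True)
class MarkerStats:
    """Summary of one marker within one gated population of one sample.

    ``mfi`` is NaN (flagged undefined) when the population is empty;
    ``pct_positive`` is a percentage in [0, 100].
    """

    sample_id: str
    marker: str
    population: str
    n_events: int
    mfi: float
    pct_positive: float
    threshold_used: float

    @property
    def mfi_defined(self) -> bool:
        return not math.isnan(self.mfi)


def _location(x: np.ndarray, statistic: MfiStatistic) -> float:
    if x.size == 0:
        return float("nan")
    if statistic == "arithmetic-mean":
        return float(np.mean(x))
    if statistic == "median":
        return float(np.median(x))
    if np.any(x <= 0):
        raise ConfigurationError("geometric-mean MFI requires strictly positive intensities")
    return float(sps.gmean(x))


def positivity_threshold(
    isotype_events: EventTable, channel: str, config: StatConfig = StatConfig()
) -> float:
    """Positivity threshold: empirical quantile of the isotype distribution."""
    if isotype_events.n_events == 0:
        raise InsufficientDataError(
            f"empty isotype population; cannot derive threshold on {channel!r}"
        )
    return float(np.quantile(isotype_events.values(channel), config.positivity_quantile))


def fraction_above(events: EventTable, channel: str, threshold: float) -> float:
    """Fraction of events strictly above a threshold (NaN if no events)."""
    if events.n_events == 0:
        return float("nan")
    return float(np.mean(events.values(channel) > threshold))


def population_stats(
    events: EventTable,
    marker: str,
    channel: str,
    threshold: float,
    config: StatConfig = StatConfig(),
    population: str = "root",
    isotype: EventTable | None = None,
) -> MarkerStats:
    """Compute MFI and % positive for one marker within a gated population.

    ``pct_positive`` is 100 x the fraction of events strictly above
    ``threshold``. With ``config.background_subtraction`` on, the same
    fraction computed on the paired ``isotype`` table is subtracted and the
    result floored at 0.
    """
    if not math.isfinite(threshold):
        raise ConfigurationError(f"threshold must be finite, got {threshold}")
    n = events.n_events
    if n == 0:
        return MarkerStats(events.sample_id, marker, population, 0, float("nan"), float("nan"), threshold)
    x = events.values(channel)
    pct = 100.0 * float(np.mean(x > threshold))
    if config.background_subtraction:
        if isotype is None:
            raise ConfigurationError("background_subtraction requires a paired isotype table")
        bg = fraction_above(isotype, channel, threshold)
        if not math.isnan(bg):
            pct = max(0.0, pct - 100.0 * bg)
    return MarkerStats(
        sample_id=events.sample_id,
        marker=marker,
        population=population,
        n_events=n,
        mfi=_location(x, config.mfi_statistic),
        pct_positive=pct,
        threshold_used=float(threshold),
    )
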