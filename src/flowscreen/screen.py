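"""Arrayed antibody-screen candidate prioritization.

The screen compares marker expression between leukemic (AML) and healthy
normal bone marrow (NBM) samples inside a primitive gated compartment.
Markers already high on healthy cells are excluded (aggregated NBM MFI >
10,000 or > 10% positive cells, both strict); the rest are scored on two
metrics,

    fold change = AML_MFI / NBM_MFI        (denominator floored)
    absolute shift = AML_MFI - NBM_MFI,

ranked descending on each metric with fractional (average) ranks for ties,
and ordered by the average of the two ranks. Ties in the final order break by
larger absolute shift, then marker name, so output is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, FlowscreenError
from .stats import MarkerStats

__all__ = ["ScreenConfig", "ScreenScore", "exclude_nbm_high", "score_markers", "rank_candidates", "run_screen"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs and plumbing for the screen.

    nbm_mfi_cutoff / nbm_pct_cutoff
        A marker is excluded when its donor-aggregated NBM MFI exceeds
        ``nbm_mfi_cutoff`` (fluorescence units) OR its NBM %positive exceeds
        ``nbm_pct_cutoff`` (percent). Both comparisons strict.
    nbm_floor
        Pseudo-MFI replacing fold-change denominators below it. ``None``
        (default) means: the smallest positive aggregated NBM MFI observed in
        the screen, or 1.0 if there is none.
    donor_aggregation
        How per-donor MFIs are combined within each arm before scoring.
    """

    nbm_mfi_cutoff: float = 10_000.0
    nbm_pct_cutoff: float = 10.0
    nbm_floor: float | None = None
    donor_aggregation: Literal["mean", "median"] = "mean"

    def __post_init__(self) -> None:
        if self.nbm_mfi_cutoff <= 0 or self.nbm_pct_cutoff <= 0:
            raise ConfigurationError("screen cutoffs must be positive")
        if self.nbm_floor is not None and self.nbm_floor <= 0:
            raise ConfigurationError("nbm_floor must be positive")
        if self.donor_aggregation not in ("mean", "median"):
            raise ConfigurationError(f"unknown donor_aggregation {self.donor_aggregation!r}")


@dataclass(frozen=True)
class ScreenScore:
    """Per-marker screen result. Excluded markers carry no ranks (NaN)."""

    marker: str
    aml_mfi: float
    nbm_mfi: float
    fold_change: float
    abs_shift: float
    rank_fc: float = float("nan")
    rank_shift: float = float("nan")
    avg_rank: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""


def _stats_frame(stats: Iterable[MarkerStats] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        df = stats.copy()
    else:
        df = pd.DataFrame(
            [{"marker": s.marker, "sample_id": s.sample_id, "mfi": s.mfi, "pct_positive": s.pct_positive} for s in stats]
        )
    missing = {"marker", "mfi"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"marker stats missing columns: {sorted(missing)}")
    return df


def _aggregate(df: pd.DataFrame, how: str) -> pd.DataFrame:
    agg = {"mfi": how}
    if "pct_positive" in df.columns:
        agg["pct_positive"] = how
    return df.groupby("marker", sort=False).agg(agg)


def exclude_nbm_high(
    nbm_stats: Iterable[MarkerStats] | pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
    markers: Sequence[str] | None = None,
) -> dict[str, str]:
    """Per-marker exclusion: reason string per marker ("" = retained).

    ``nbm_stats`` may be per-donor; donors are aggregated per the config
    before applying the cutoffs. If ``markers`` is given, every listed marker
    must have an NBM record.
    """
    agg = _aggregate(_stats_frame(nbm_stats), config.donor_aggregation)
    if markers is not None:
        absent = sorted(set(markers) - set(agg.index))
        if absent:
            raise FlowscreenError(f"markers without NBM records: {absent}")
    flags: dict[str, str] = {}
    for marker, row in agg.iterrows():
        reasons = []
        if row["mfi"] > config.nbm_mfi_cutoff:
            reasons.append(f"NBM MFI {row['mfi']:.4g} > {config.nbm_mfi_cutoff:.4g}")
        if "pct_positive" in agg.columns and row["pct_positive"] > config.nbm_pct_cutoff:
            reasons.append(f"NBM %positive {row['pct_positive']:.4g} > {config.nbm_pct_cutoff:.4g}")
        flags[str(marker)] = "; ".join(reasons)
    return flags


def score_markers(
    aml_stats: Iterable[MarkerStats] | pd.DataFrame,
    nbm_stats: Iterable[MarkerStats] | pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> list[ScreenScore]:
    """Aggregate per-donor MFIs per arm and compute both screen metrics.

    Returns one unranked :class:`ScreenScore` per marker, with exclusion
    flags from the NBM cutoffs already attached. Fold-change denominators
    below the floor are replaced by it (logged).
    """
    aml = _aggregate(_stats_frame(aml_stats), config.donor_aggregation)
    nbm = _aggregate(_stats_frame(nbm_stats), config.donor_aggregation)
    only_aml = sorted(set(aml.index) - set(nbm.index))
    if only_aml:
        raise FlowscreenError(f"markers without NBM records: {only_aml}")

    floor = config.nbm_floor
    if floor is None:
        positive = nbm["mfi"][nbm["mfi"] > 0]
        floor = float(positive.min()) if len(positive) else 1.0

    flags = exclude_nbm_high(nbm_stats, config)
    scores = []
    for marker in aml.index:
        aml_mfi = float(aml.loc[marker, "mfi"])
        nbm_mfi = float(nbm.loc[marker, "mfi"])
        denom = nbm_mfi
        if denom < floor:
            logger.warning("marker %s: NBM MFI %.4g below floor %.4g; floored", marker, denom, floor)
            denom = floor
        if aml_mfi <= 0:
            logger.warning("marker %s: non-positive aggregated AML MFI %.4g", marker, aml_mfi)
        reason = flags.get(str(marker), "")
        scores.append(
            ScreenScore(
                marker=str(marker),
                aml_mfi=aml_mfi,
                nbm_mfi=nbm_mfi,
                fold_change=aml_mfi / denom,
                abs_shift=aml_mfi - nbm_mfi,
                excluded=bool(reason),
                exclusion_reason=reason,
            )
        )
    return scores


def rank_candidates(scores: Iterable[ScreenScore]) -> list[ScreenScore]:
    """Rank non-excluded markers by the average of their two metric ranks.

    Each metric is ranked descending with fractional (average) ranks for
    ties. The returned list ascends by average rank; ties break by larger
    absolute shift, then marker name. Excluded markers are omitted.
    """
    kept = [s for s in scores if not s.excluded]
    if not kept:
        logger.warning("no candidates remain after exclusion")
        return []
    fc = np.array([s.fold_change for s in kept])
    shift = np.array([s.abs_shift for s in kept])
    rank_fc = rankdata(-fc, method="average")
    rank_shift = rankdata(-shift, method="average")
    ranked = [
        replace(s, rank_fc=float(rf), rank_shift=float(rs), avg_rank=float((rf + rs) / 2.0))
        for s, rf, rs in zip(kept, rank_fc, rank_shift)
    ]
    ranked.sort(key=lambda s: (s.avg_rank, -s.abs_shift, s.marker))
    return ranked


def run_screen(
    aml_stats: Iterable[MarkerStats] | pd.DataFrame,
    nbm_stats: Iterable[MarkerStats] | pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Full screen: score, exclude, rank; returns a tidy result table.

    Output columns: final_rank (1-based, NaN for excluded), marker, aml_mfi,
    nbm_mfi, fold_change, abs_shift (the display value), rank_fc, rank_shift,
    avg_rank, excluded, exclusion_reason. Ranked candidates first, then
    excluded markers alphabetically.
    """
    scores = score_markers(aml_stats, nbm_stats, config)
    ranked = rank_candidates(scores)
    rows = [
        {"final_rank": i + 1, **vars(s)} for i, s in enumerate(ranked)
    ] + [
        {"final_rank": float("nan"), **vars(s)}
        for s in sorted((s for s in scores if s.excluded), key=lambda s: s.marker)
    ]
    return pd.DataFrame(rows)
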