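"""Trichotomized marker-expression calls and cohort summaries.

Per-sample expression is quantified as the *shift fraction*: the fraction of
stained events lying beyond the isotype control's background distribution
(one-sided, above the isotype high quantile). The call is

    shift fraction > 50%        -> "high"
    10% <= shift fraction <= 50% -> "intermediate"
    shift fraction < 10%        -> "negative"

(boundaries forced by the strict ">50%" / "<10%" definitions), and a sample
counts as *positive* when the call is high or intermediate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, FlowscreenError, InsufficientDataError
from .events import EventTable
from .posthoc import dunn_test
from .stats import StatConfig, fraction_above, positivity_threshold

__all__ = [
    "ExpressionCall",
    "CohortSummary",
    "classify_expression",
    "shift_fraction_from_events",
    "summarize_cohort",
    "stratify_by_call",
    "CALL_ORDER",
]

logger = logging.getLogger(__name__)

CALL_ORDER = ("negative", "intermediate", "high")
HIGH_BOUND = 0.50
NEGATIVE_BOUND = 0.10


@dataclass(frozen=True)
class ExpressionCall:
    sample_id: str
    marker: str
    shift_fraction: float
    call: str
    population: str = "root"


@dataclass(frozen=True)
class CohortSummary:
    """Call counts/percentages for one cohort grouping label."""

    label: str
    n: int
    counts: dict[str, int]
    percentages: dict[str, float]  # nearest-integer, as presented in figures
    pct_positive: float  # high + intermediate, nearest-integer


def classify_expression(shift_fraction: float) -> str:
    """Map a shift fraction in [0, 1] to high / intermediate / negative."""
    if not 0.0 <= shift_fraction <= 1.0 or math.isnan(shift_fraction):
        raise ConfigurationError(f"shift fraction out of [0,1]: {shift_fraction}")
    if shift_fraction > HIGH_BOUND:
        return "high"
    if shift_fraction < NEGATIVE_BOUND:
        return "negative"
    return "intermediate"


def shift_fraction_from_events(
    stained: EventTable,
    isotype: EventTable,
    channel: str,
    config: StatConfig = StatConfig(),
) -> float:
    """Fraction of stained events beyond the isotype background.

    The threshold is the isotype ``positivity_quantile`` on ``channel``;
    events strictly above it are "outside the isotype peak". With
    ``background_subtraction`` on, the isotype's own above-threshold
    fraction is subtracted and the result floored at 0.
    """
    if stained.n_events == 0 or isotype.n_events == 0:
        raise InsufficientDataError("shift fraction requires non-empty stained and isotype tables")
    threshold = positivity_threshold(isotype, channel, config)
    frac = fraction_above(stained, channel, threshold)
    if config.background_subtraction:
        frac = max(0.0, frac - fraction_above(isotype, channel, threshold))
    return frac


def make_call(
    stained: EventTable,
    isotype: EventTable,
    channel: str,
    marker: str,
    config: StatConfig = StatConfig(),
    population: str = "root",
) -> ExpressionCall:
    """Shift fraction + trichotomized call for one sample."""
    frac = shift_fraction_from_events(stained, isotype, channel, config)
    return ExpressionCall(stained.sample_id, marker, frac, classify_expression(frac), population)


def summarize_cohort(
    calls: Iterable[ExpressionCall] | Sequence[str],
    groupings: Mapping[str, str] | None = None,
) -> list[CohortSummary]:
    """Count calls per cohort grouping label.

    ``calls`` is a list of :class:`ExpressionCall` (or bare call strings);
    ``groupings`` maps sample_id -> label (subtype, mutation, risk, ...).
    Without groupings a single "overall" summary is returned. Samples with no
    label are summarized under "unclassified" (warned). Percentages are
    reported to the nearest integer; "positive" = high + intermediate.
    """
    records = []
    for i, c in enumerate(calls):
        if isinstance(c, str):
            c = ExpressionCall(sample_id=f"sample{i}", marker="", shift_fraction=float("nan"), call=c)
        if c.call not in CALL_ORDER:
            raise FlowscreenError(f"unknown call {c.call!r}")
        if groupings is None:
            label = "overall"
        elif c.sample_id in groupings:
            label = str(groupings[c.sample_id])
        else:
            logger.warning("sample %s has no grouping label; assigned 'unclassified'", c.sample_id)
            label = "unclassified"
        records.append((label, c.call))

    out = []
    df = pd.DataFrame(records, columns=["label", "call"])
    for label, sub in df.groupby("label", sort=True):
        counts = {k: int((sub["call"] == k).sum()) for k in CALL_ORDER}
        n = len(sub)
        pcts = {k: round(100.0 * v / n) for k, v in counts.items()}
        positive = counts["high"] + counts["intermediate"]
        out.append(
            CohortSummary(
                label=str(label),
                n=n,
                counts=counts,
                percentages=pcts,
                pct_positive=round(100.0 * positive / n),
            )
        )
    return out


def stratify_by_call(
    values: Mapping[str, float],
    calls: Mapping[str, str],
    p_adjust: str | None = None,
) -> dict:
    """Compare a per-sample measurement across expression-call groups.

    Groups follow the fixed order negative < intermediate < high; empty
    groups are dropped with a warning. With >= 3 groups the omnibus test is
    Kruskal-Wallis with Dunn's post hoc pairwise z-tests; with exactly 2 the
    two-sided Mann-Whitney U-test is used. Returns a dict with per-group n
    and medians, the omnibus statistic/p-value, and a pairwise table.
    """
    groups: dict[str, list[float]] = {k: [] for k in CALL_ORDER}
    for sample, call in calls.items():
        if call not in CALL_ORDER:
            raise FlowscreenError(f"unknown call {call!r} for sample {sample!r}")
        if sample in values:
            groups[call].append(float(values[sample]))
    for k in [k for k, v in groups.items() if not v]:
        logger.warning("group %r has no observations; dropped", k)
        del groups[k]
    if len(groups) < 2:
        raise InsufficientDataError("stratified comparison needs >= 2 non-empty groups")

    medians = {k: float(np.median(v)) for k, v in groups.items()}
    sizes = {k: len(v) for k, v in groups.items()}
    if len(groups) == 2:
        (ka, va), (kb, vb) = groups.items()
        stat, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
        return {
            "test": "mann-whitney",
            "groups": sizes,
            "medians": medians,
            "statistic": float(stat),
            "p_value": float(p),
            "pairwise": pd.DataFrame(
                [{"group_a": ka, "group_b": kb, "U": float(stat), "p": float(p)}]
            ),
        }
    stat, p = sps.kruskal(*groups.values())
    return {
        "test": "kruskal-wallis",
        "groups": sizes,
        "medians": medians,
        "statistic": float(stat),
        "p_value": float(p),
        "pairwise": dunn_test(groups, p_adjust=p_adjust),
    }
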