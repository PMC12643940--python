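"""Survival-cohort preprocessing: lymphocyte filtering and tertile grouping.

Bulk RNA cohorts are contaminated by lymphoid cells that express the marker
of interest themselves; samples whose deconvolution-estimated lymphocyte
fraction exceeds a cutoff (default 15%) are removed before stratification.
Remaining samples are split by marker expression into three contiguous groups
of (near-)equal size — low / mid / high tertiles — ready for a standard
Kaplan-Meier estimator. Deconvolution itself is consumed as input, never
computed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FlowscreenError

__all__ = ["CohortRecord", "filter_lymphocyte", "tertile_groups", "km_prep"]

logger = logging.getLogger(__name__)

TERTILE_LABELS = ("low", "mid", "high")


@dataclass(frozen=True)
class CohortRecord:
    sample_id: str
    expression_value: float
    lymphocyte_fraction: float  # in [0,1]; NaN = missing
    survival_time: float  # days
    event_flag: bool

    def __post_init__(self) -> None:
        lf = self.lymphocyte_fraction
        if not math.isnan(lf) and not 0.0 <= lf <= 1.0:
            raise ConfigurationError(f"{self.sample_id}: lymphocyte fraction {lf} outside [0,1]")
        if self.survival_time < 0:
            raise ConfigurationError(f"{self.sample_id}: negative survival time")


def filter_lymphocyte(
    records: list[CohortRecord],
    cutoff: float = 0.15,
    on_missing: str = "drop",
) -> tuple[list[CohortRecord], dict]:
    """Remove samples with more than ``cutoff`` lymphocytes.

    Retention is ``lymphocyte_fraction <= cutoff`` (strictly-more-than is
    removed). Records with a missing fraction are dropped with a warning, or
    rejected when ``on_missing="error"``. Returns the retained records and a
    report dict with removed/retained counts.
    """
    retained, removed, missing = [], 0, 0
    for r in records:
        if math.isnan(r.lymphocyte_fraction):
            if on_missing == "error":
                raise FlowscreenError(f"{r.sample_id}: missing lymphocyte fraction")
            logger.warning("%s: missing lymphocyte fraction; dropped", r.sample_id)
            missing += 1
        elif r.lymphocyte_fraction > cutoff:
            removed += 1
        else:
            retained.append(r)
    report = {
        "n_input": len(records),
        "n_removed": removed,
        "n_missing": missing,
        "n_retained": len(retained),
        "cutoff": cutoff,
    }
    return retained, report


def tertile_groups(values: list[float] | np.ndarray) -> list[str]:
    """Split samples into three contiguous expression groups of near-equal size.

    Samples are sorted by value (ties keep stable input order); group sizes
    differ by at most 1, remainders going to the lower groups first. Returns
    one label per input position: "low", "mid" or "high".
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ConfigurationError(f"tertile grouping needs n >= 3, got {n}")
    q, r = divmod(n, 3)
    sizes = [q + (1 if i < r else 0) for i in range(3)]
    order = np.argsort(values, kind="stable")
    labels = [""] * n
    start = 0
    for label, size in zip(TERTILE_LABELS, sizes):
        for idx in order[start : start + size]:
            labels[idx] = label
        start += size
    return labels


def km_prep(records: list[CohortRecord], groups: list[str]) -> pd.DataFrame:
    """Tidy (time, event, group) table for a standard Kaplan-Meier estimator.

    No estimation is performed; groups that end up empty are simply absent
    (warned). Row order follows the input records.
    """
    if len(records) != len(groups):
        raise ConfigurationError("records and group labels differ in length")
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.survival_time for r in records],
            "event": [bool(r.event_flag) for r in records],
            "group": list(groups),
        }
    )
    for label in TERTILE_LABELS:
        if label not in set(df["group"]):
            logger.warning("group %r is empty after filtering; omitted", label)
    return df
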