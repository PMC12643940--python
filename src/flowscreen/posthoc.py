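"""Dunn's post hoc test for pairwise comparisons after Kruskal-Wallis.

Dunn (1964): all observations are ranked jointly; for groups i, j with mean
ranks R_i, R_j and sizes n_i, n_j, the statistic is

    z_ij = (R_i - R_j) / sqrt( (N(N+1)/12 - T) * (1/n_i + 1/n_j) )

where N is the total sample size and T = sum(t^3 - t) / (12(N-1)) over tied
groups of size t corrects for ties. Two-sided p-values come from the standard
normal; optional multiplicity adjustment is delegated to
``statsmodels.stats.multitest.multipletests``.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ConfigurationError

__all__ = ["dunn_test"]


def dunn_test(
    groups: Mapping[str, Sequence[float]],
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Pairwise Dunn z-tests between named groups.

    Parameters
    ----------
    groups
        Ordered mapping of group label -> observations (each non-empty).
    p_adjust
        ``None`` for raw p-values, else any method name accepted by
        statsmodels ``multipletests`` (e.g. ``"bonferroni"``, ``"holm"``).

    Returns
    -------
    DataFrame with columns group_a, group_b, z, p (one row per pair, in the
    order of ``itertools.combinations`` over the input labels).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ConfigurationError("Dunn's test needs at least two groups")
    sizes = {k: len(np.asarray(groups[k], dtype=float)) for k in labels}
    if any(n == 0 for n in sizes.values()):
        raise ConfigurationError("Dunn's test: empty group")

    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    ranks = rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for k in labels:
        stop = start + sizes[k]
        mean_ranks[k] = float(np.mean(ranks[start:stop]))
        start = stop

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(2.0 * norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    if p_adjust is not None:
        from statsmodels.stats.multitest import multipletests

        out["p"] = multipletests(out["p"].to_numpy(), method=p_adjust)[1]
    return out
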