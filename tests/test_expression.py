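"""Trichotomized expression calls, cohort summaries, stratified comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from flowscreen import (
    ConfigurationError,
    EventTable,
    InsufficientDataError,
    StatConfig,
    classify_expression,
    shift_fraction_from_events,
    stratify_by_call,
    summarize_cohort,
)
from flowscreen.expression import ExpressionCall
from flowscreen.posthoc import dunn_test
from .conftest import lognormal_table

CALL_RANK = {"negative": 0, "intermediate": 1, "high": 2}


class TestClassify:
    @pytest.mark.parametrize(
        "fraction,call",
        [
            (0.62, "high"),
            (0.501, "high"),
            (0.50, "intermediate"),  # strict ">50%" puts the boundary in intermediate
            (0.10, "intermediate"),  # strict "<10%" keeps the boundary in intermediate
            (0.099, "negative"),
            (0.0, "negative"),
            (1.0, "high"),
        ],
    )
    def test_boundary_table(self, fraction, call):
        assert classify_expression(fraction) == call

    def test_exhaustive_grid_matches_rule_oracle(self):
        for i in range(0, 1001):
            f = i / 1000.0
            expected = "high" if f > 0.5 else ("negative" if f < 0.1 else "intermediate")
            assert classify_expression(f) == expected

    @pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            classify_expression(bad)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert CALL_RANK[classify_expression(lo)] <= CALL_RANK[classify_expression(hi)]


class TestShiftFraction:
    def test_identical_distributions_give_quantile_complement(self, rng):
        iso = lognormal_table(rng, 100, 0.6, 10_000)
        stained = lognormal_table(rng, 100, 0.6, 10_000)
        f = shift_fraction_from_events(stained, iso, "PE")
        assert f == pytest.approx(0.01, abs=0.005)
        assert classify_expression(f) == "negative"

    def test_identical_distributions_with_background_subtraction(self, rng):
        iso = lognormal_table(rng, 100, 0.6, 10_000)
        stained = lognormal_table(rng, 100, 0.6, 10_000)
        cfg = StatConfig(background_subtraction=True)
        assert shift_fraction_from_events(stained, iso, "PE", cfg) == pytest.approx(0.0, abs=0.01)

    def test_complete_separation(self, rng):
        iso = lognormal_table(rng, 100, 0.3, 1000)
        stained = lognormal_table(rng, 100_000, 0.1, 1000)
        f = shift_fraction_from_events(stained, iso, "PE")
        assert f == 1.0
        assert classify_expression(f) == "high"

    def test_mixture_weight_recovered(self, rng):
        """40% of stained events from a far-shifted component -> ~0.40."""
        n = 10_000
        iso = lognormal_table(rng, 100, 0.5, n)
        comp = rng.random(n) < 0.40
        x = np.where(comp, 50_000.0, 100.0) * np.exp(0.5 * rng.standard_normal(n))
        stained = EventTable.from_arrays(x[:, None], ["PE"])
        f = shift_fraction_from_events(stained, iso, "PE")
        assert f == pytest.approx(0.40, abs=0.02)
        assert classify_expression(f) == "intermediate"

    def test_empty_tables_error(self, rng):
        empty = EventTable.from_arrays(np.empty((0, 1)), ["PE"])
        full = lognormal_table(rng, 100, 0.5, 10)
        with pytest.raises(InsufficientDataError):
            shift_fraction_from_events(empty, full, "PE")
        with pytest.raises(InsufficientDataError):
            shift_fraction_from_events(full, empty, "PE")


def calls_from_counts(n_high, n_int, n_neg):
    out = []
    for i, call in enumerate(["high"] * n_high + ["intermediate"] * n_int + ["negative"] * n_neg):
        out.append(ExpressionCall(f"s{i}", "SLAMF6", float("nan"), call))
    return out


class TestSummarize:
    def test_cohort_of_50(self):
        (s,) = summarize_cohort(calls_from_counts(12, 17, 21))
        assert s.n == 50
        assert s.counts == {"negative": 21, "intermediate": 17, "high": 12}
        assert s.pct_positive == 58
        assert s.percentages == {"high": 24, "intermediate": 34, "negative": 42}

    def test_25_of_42_rounds_to_60(self):
        (s,) = summarize_cohort(calls_from_counts(10, 15, 17))
        assert s.n == 42
        assert s.pct_positive == 60

    def test_all_negative(self):
        (s,) = summarize_cohort(calls_from_counts(0, 0, 5))
        assert s.pct_positive == 0

    def test_counts_conserved_per_label(self):
        calls = calls_from_counts(3, 4, 5)
        groupings = {c.sample_id: ("g1" if i % 2 else "g2") for i, c in enumerate(calls)}
        summaries = summarize_cohort(calls, groupings)
        assert sum(s.n for s in summaries) == 12
        for s in summaries:
            assert sum(s.counts.values()) == s.n

    def test_unlabelled_sample_goes_to_unclassified(self, caplog):
        calls = calls_from_counts(1, 1, 1)
        summaries = summarize_cohort(calls, {"s0": "g"})
        labels = {s.label for s in summaries}
        assert "unclassified" in labels
        assert "no grouping label" in caplog.text


def dunn_oracle(groups):
    """Independent brute-force Dunn z-statistics: explicit tie-averaged ranks,
    explicit tie correction, pairwise normal z-tests."""
    labels = list(groups)
    pooled = [(v, k) for k in labels for v in groups[k]]
    # hand-rolled tie-averaged ranking
    order = sorted(range(len(pooled)), key=lambda i: pooled[i][0])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]][0] == pooled[order[i]][0]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n = len(pooled)
    from collections import Counter

    ties = Counter(v for v, _ in pooled)
    tie_term = sum(t**3 - t for t in ties.values()) / (12.0 * (n - 1))
    var = n * (n + 1) / 12.0 - tie_term
    mean_rank = {
        k: sum(r for r, (_, lab) in zip(ranks, pooled) if lab == k) / len(groups[k]) for k in labels
    }
    out = {}
    for ai in range(len(labels)):
        for bi in range(ai + 1, len(labels)):
            a, b = labels[ai], labels[bi]
            se = math.sqrt(var * (1 / len(groups[a]) + 1 / len(groups[b])))
            z = (mean_rank[a] - mean_rank[b]) / se
            out[(a, b)] = (z, 2 * norm.sf(abs(z)))
    return out


class TestStratify:
    def test_identical_groups_have_zero_h(self):
        values = {f"s{i}": v for i, v in enumerate([1, 2, 3, 1, 2, 3, 1, 2, 3])}
        calls = {f"s{i}": c for i, c in enumerate(["negative"] * 3 + ["intermediate"] * 3 + ["high"] * 3)}
        res = stratify_by_call(values, calls)
        assert res["test"] == "kruskal-wallis"
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_complete_separation(self):
        """{1,2,3} vs {101,102,103}: exhaustive pair enumeration gives U in {0, 9}."""
        values = {"a": 1, "b": 2, "c": 3, "d": 101, "e": 102, "f": 103}
        calls = {k: ("negative" if v < 100 else "high") for k, v in values.items()}
        res = stratify_by_call(values, calls)
        assert res["test"] == "mann-whitney"
        # all 9 cross pairs won by the high group; scipy reports the first group's U
        assert res["statistic"] in (0.0, 9.0)
        assert res["medians"] == {"negative": 2.0, "high": 102.0}

    def test_permutation_invariance(self, rng):
        samples = [f"s{i}" for i in range(30)]
        values = {s: float(rng.normal()) for s in samples}
        calls = {s: ["negative", "intermediate", "high"][i % 3] for i, s in enumerate(samples)}
        res1 = stratify_by_call(values, calls)
        shuffled = list(samples)[::-1]
        res2 = stratify_by_call({s: values[s] for s in shuffled}, {s: calls[s] for s in shuffled})
        assert res1["statistic"] == pytest.approx(res2["statistic"])
        assert res1["p_value"] == pytest.approx(res2["p_value"])

    def test_empty_group_dropped_then_error_below_two(self, caplog):
        values = {"a": 1.0, "b": 2.0}
        calls = {"a": "high", "b": "high"}
        with pytest.raises(InsufficientDataError):
            stratify_by_call(values, calls)

    def test_dunn_matches_brute_force_oracle(self, rng):
        groups = {
            "negative": list(rng.normal(0, 1, 8)),
            "intermediate": list(rng.normal(0.5, 1, 6)),
            "high": list(rng.normal(1.5, 1, 7)),
        }
        got = dunn_test(groups)
        oracle = dunn_oracle(groups)
        for row in got.itertuples():
            z, p = oracle[(row.group_a, row.group_b)]
            assert row.z == pytest.approx(z, rel=1e-10)
            assert row.p == pytest.approx(p, rel=1e-10)

    def test_dunn_with_ties_matches_oracle(self):
        groups = {"a": [1, 2, 2, 3], "b": [2, 3, 3, 4], "c": [4, 4, 5, 6]}
        got = dunn_test(groups)
        oracle = dunn_oracle(groups)
        for row in got.itertuples():
            z, p = oracle[(row.group_a, row.group_b)]
            assert row.z == pytest.approx(z, rel=1e-10)
            assert row.p == pytest.approx(p, rel=1e-10)

    def test_dunn_bonferroni_adjustment(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        raw = dunn_test(groups)
        adj = dunn_test(groups, p_adjust="bonferroni")
        np.testing.assert_allclose(adj["p"], np.minimum(raw["p"] * 3, 1.0))
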