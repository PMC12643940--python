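"""Synthetic-data generators: determinism, planted truth, oracle recovery."""

import numpy as np
import pandas as pd
import pytest

from flowscreen import (
    CocultureSimConfig,
    CohortSimConfig,
    ConfigurationError,
    PopulationSpec,
    ScreenSimConfig,
    StatConfig,
    classify_expression,
    normalize_to_control,
    run_screen,
    shift_fraction_from_events,
    simulate_cohort,
    simulate_coculture,
    simulate_events,
    simulate_screen,
)
from flowscreen.simulate import simulate_screen_events
from flowscreen.stats import population_stats, positivity_threshold


def spec(components, n=1000, seed=7):
    return PopulationSpec(components=components, n_events=n, seed=seed)


class TestSimulateEvents:
    def test_degenerate_scale_collapses_to_location(self):
        t = simulate_events(spec([(1.0, {"PE": 250.0}, {"PE": 0.0})], n=100))
        np.testing.assert_allclose(t.values("PE"), 250.0)

    def test_same_seed_is_byte_identical(self):
        s = spec([(0.5, {"PE": 100.0}, {"PE": 0.5}), (0.5, {"PE": 900.0}, {"PE": 0.5})])
        t1, t2 = simulate_events(s), simulate_events(s)
        assert t1.data.equals(t2.data)
        np.testing.assert_array_equal(t1.metadata["component"], t2.metadata["component"])

    def test_component_counts_within_binomial_bounds(self):
        n = 10_000
        t = simulate_events(spec([(0.3, {"PE": 10.0}, {"PE": 0.1}), (0.7, {"PE": 1000.0}, {"PE": 0.1})], n=n))
        k = int(np.sum(t.metadata["component"] == 0))
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(k - 0.3 * n) <= 3 * sd

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            spec([(0.5, {"PE": 1.0}, {"PE": 0.1})])
        with pytest.raises(ConfigurationError):
            spec([(1.0, {"PE": -1.0}, {"PE": 0.1})])


def tiny_screen(markers=4, events=400, seed=3, planted=None):
    return ScreenSimConfig(
        markers=[f"M{i:03d}" for i in range(1, markers + 1)],
        events_per_sample=events,
        planted_effects=planted or {},
        seed=seed,
    )


class TestSimulateScreen:
    def test_truth_table_flags_planted_marker(self):
        _, truth = simulate_screen(tiny_screen(planted={"M002": 10.0}))
        assert truth.set_index("marker").loc["M002", "planted_fold"] == 10.0
        assert (truth.set_index("marker").drop("M002")["planted_fold"] == 1.0).all()

    def test_stats_match_flow_core_on_materialized_events(self):
        """The vectorized stats path must equal MFI/%positive computed by the
        event-table machinery on the same materialized draws."""
        cfg = tiny_screen()
        stats, _ = simulate_screen(cfg)
        stained, isotypes = simulate_screen_events(cfg)
        for (arm, donor_id, marker), t in stained.items():
            thr = positivity_threshold(isotypes[(arm, donor_id)], "PE", StatConfig())
            s = population_stats(t, marker, "PE", thr)
            row = stats[(stats.marker == marker) & (stats.donor == donor_id)].iloc[0]
            assert row.mfi == pytest.approx(s.mfi, rel=1e-12)
            assert row.pct_positive == pytest.approx(s.pct_positive, abs=1e-12)

    def test_planted_fold_recovered(self):
        cfg = tiny_screen(markers=8, events=5000, planted={"M003": 10.0})
        stats, _ = simulate_screen(cfg)
        agg = stats.groupby(["marker", "arm"])["mfi"].mean().unstack()
        fold = agg.loc["M003", "AML"] / agg.loc["M003", "NBM"]
        assert fold == pytest.approx(10.0, rel=0.2)

    def test_planted_marker_ranks_first(self):
        cfg = tiny_screen(markers=20, events=2000, planted={"M011": 8.0})
        stats, _ = simulate_screen(cfg)
        res = run_screen(stats[stats.arm == "AML"], stats[stats.arm == "NBM"])
        assert res.iloc[0]["marker"] == "M011"

    def test_adding_markers_does_not_perturb_existing(self):
        small = simulate_screen(tiny_screen(markers=3))[0]
        large = simulate_screen(tiny_screen(markers=5))[0]
        merged = small.merge(large, on=["marker", "arm", "donor"], suffixes=("_s", "_l"))
        np.testing.assert_array_equal(merged["mfi_s"], merged["mfi_l"])

    def test_determinism(self):
        cfg = tiny_screen()
        pd.testing.assert_frame_equal(simulate_screen(cfg)[0], simulate_screen(cfg)[0])


class TestSimulateCohort:
    def test_deterministic_class_allocation(self):
        """Mix (0.24, 0.34, 0.42) at n=50 -> 12 high / 17 intermediate / 21 negative."""
        cfg = CohortSimConfig(n_samples=50, events_per_sample=100, seed=1)
        _, truth = simulate_cohort(cfg)
        counts = truth["true_call"].value_counts()
        assert counts["high"] == 12 and counts["intermediate"] == 17 and counts["negative"] == 21

    def test_all_negative_mix(self):
        cfg = CohortSimConfig(n_samples=5, class_mix=(0.0, 0.0, 1.0), events_per_sample=100, seed=1)
        _, truth = simulate_cohort(cfg)
        assert (truth["true_call"] == "negative").all()

    def test_true_fractions_respect_band_margins(self):
        cfg = CohortSimConfig(n_samples=30, events_per_sample=10, seed=5)
        _, truth = simulate_cohort(cfg)
        m = cfg.boundary_margin
        for row in truth.itertuples():
            if row.true_call == "high":
                assert row.true_fraction >= 0.5 + m
            elif row.true_call == "intermediate":
                assert 0.1 + m <= row.true_fraction <= 0.5 - m
            else:
                assert row.true_fraction <= 0.1 - m

    def test_classification_recovers_truth(self):
        """classify_expression on simulated samples matches the planted calls
        for >= 95% of samples (fractions kept >= 0.03 from the boundaries)."""
        cfg = CohortSimConfig(n_samples=40, events_per_sample=10_000, seed=11)
        samples, truth = simulate_cohort(cfg)
        correct = 0
        for row in truth.itertuples():
            stained, isotype = samples[row.sample_id]
            frac = shift_fraction_from_events(stained, isotype, "PE")
            correct += classify_expression(frac) == row.true_call
        assert correct >= 0.95 * len(truth)

    def test_determinism(self):
        cfg = CohortSimConfig(n_samples=4, events_per_sample=200, seed=2)
        s1, t1 = simulate_cohort(cfg)
        s2, t2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        for sid in s1:
            assert s1[sid][0].data.equals(s2[sid][0].data)
            assert s1[sid][1].data.equals(s2[sid][1].data)


class TestSimulateCoculture:
    def test_null_killing_gives_near_zero_reduction(self):
        sim = simulate_coculture(CocultureSimConfig(killing_fraction=0.0, seed=4))
        treated = [s.aml_absolute for s in sim["samples"] if s.condition == "treated"]
        control = [s.aml_absolute for s in sim["samples"] if s.is_control]
        res = normalize_to_control(treated, control)
        assert res["pct_reduction"] == pytest.approx(0.0, abs=3.0)

    def test_planted_killing_recovered(self):
        sim = simulate_coculture(CocultureSimConfig(killing_fraction=0.75, seed=4))
        treated = [s.aml_absolute for s in sim["samples"] if s.condition == "treated"]
        control = [s.aml_absolute for s in sim["samples"] if s.is_control]
        res = normalize_to_control(treated, control)
        assert res["pct_reduction"] == pytest.approx(75.0, abs=3.0)

    def test_absolute_count_recovers_planted_cells(self):
        cfg = CocultureSimConfig(killing_fraction=0.0, n_cells=50_000, beads_added=50_000, seed=9)
        sim = simulate_coculture(cfg)
        for s in sim["samples"]:
            true_n = sim["truth"]["true_cells"][s.sample_id]
            assert s.aml_absolute == pytest.approx(true_n, rel=0.05)

    def test_activation_truth_recovered(self):
        from flowscreen import activation_fraction

        cfg = CocultureSimConfig(seed=2)
        sim = simulate_coculture(cfg)
        thr25, thr69 = sim["activation_thresholds"]
        t = sim["tcell_tables"]["control-r1"]
        either = activation_fraction(t, thr25, thr69, "either")
        both = activation_fraction(t, thr25, thr69, "both")
        assert either == pytest.approx(40.0, abs=2.5)
        assert both == pytest.approx(20.0, abs=2.5)

    def test_determinism(self):
        cfg = CocultureSimConfig(killing_fraction=0.5, seed=3)
        s1 = simulate_coculture(cfg)
        s2 = simulate_coculture(cfg)
        assert [x.aml_events for x in s1["samples"]] == [x.aml_events for x in s2["samples"]]
        assert s1["tcell_tables"]["treated-r2"].data.equals(s2["tcell_tables"]["treated-r2"].data)
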