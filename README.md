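# flowscreen

Flow-cytometry analysis for surface-marker discovery in acute myeloid
leukemia (AML): arrayed antibody-screen scoring and ranking, isotype-anchored
expression calls, T-cell subset composition, counting-bead coculture
quantification, and survival-cohort stratification — with a synthetic-data
module that makes every stage testable against planted ground truth.

It is written for researchers who quantify cytometry experiments of this
kind: screens that compare a marker's expression between leukemic and
healthy bone marrow inside a gated primitive compartment, cohort studies
that trichotomize per-patient expression, and killing assays read out as
bead-normalized absolute cell numbers.

## The computations

**Screen ranking.** Within the gated 7-AAD⁻CD3⁻CD19⁻CD34⁺CD38^low
compartment, each of the markers (362 in the original design) is summarized
per donor by MFI (arithmetic mean fluorescence intensity) and %positive
(fraction of events strictly above the isotype control's 99th percentile).
Markers high on healthy marrow (NBM MFI > 10,000 or > 10% positive cells,
both strict) are excluded. The rest are scored by

```
fold change     FC_m = AML_MFI / NBM_MFI      (denominator floored)
absolute shift  Δ_m  = AML_MFI − NBM_MFI
```

with donor MFIs averaged per arm first. Each metric is ranked descending
(fractional ranks for ties) and candidates are ordered by the average of the
two ranks; final ties break by larger shift, then name.

**Expression calls.** Per sample, the shift fraction is the fraction of
stained events beyond the isotype peak (above its 0.99 quantile). Calls:
`> 50%` high, `10–50%` intermediate, `< 10%` negative; positive = high +
intermediate. Groups are compared with Kruskal–Wallis + Dunn's post hoc test
(Mann–Whitney for two groups).

**T-cell subsets.** CD45RA × CCR7 quadrants within CD4⁺/CD8⁺: naive
(CCR7⁺CD45RA⁺), TEMRA (CCR7⁻CD45RA⁺), effector memory (CCR7⁻CD45RA⁻),
central memory (CCR7⁺CD45RA⁻); quadrants partition the parent exactly.

**Coculture killing.** Absolute numbers from counting beads,
`cells = cell_events × beads_added / bead_events`; killing reported as
percent reduction versus the control-condition mean; activation as percent
CD25/CD69-positive T cells; engraftment as percent leukemia-phenotype events
among viable events.

**Survival strata.** Samples with more than 15% estimated lymphocytes are
removed, the rest split into three equal-size expression tertiles, emitted
as a tidy (time, event, group) table for any Kaplan–Meier implementation.

See `docs/methods.md` for boundary semantics, defaults and limitations.

## Worked example

Simulate a 20-marker screen with one marker planted at 8-fold AML elevation,
then rank candidates:

```python
import flowscreen as fs

cfg = fs.ScreenSimConfig(
    markers=[f"M{i:03d}" for i in range(1, 21)],
    events_per_sample=2000,
    planted_effects={"M007": 8.0},
    seed=42,
)
stats, truth = fs.simulate_screen(cfg)
result = fs.run_screen(stats[stats.arm == "AML"], stats[stats.arm == "NBM"])
print(result.head(3)[["final_rank", "marker", "fold_change", "abs_shift", "avg_rank"]])
```

```
 final_rank marker  fold_change   abs_shift  avg_rank
          1   M007     8.244085 1259.003176       1.0
          2   M014     1.176370   30.965123       2.0
          3   M016     1.106609   19.204769       3.0
```

The planted marker M007 is recovered at rank 1 with an empirical fold change
of 8.24 (true 8.0); the null markers sit near fold change 1. Calling
expression on a simulated 50-sample cohort (24% high / 34% intermediate /
42% negative planted):

```python
from flowscreen.expression import make_call

samples, truth = fs.simulate_cohort(fs.CohortSimConfig(n_samples=50, seed=42))
calls = [make_call(stained, iso, "PE", "SLAMF6") for stained, iso in samples.values()]
(summary,) = fs.summarize_cohort(calls)
print(summary.counts, summary.pct_positive)
```

```
{'negative': 21, 'intermediate': 17, 'high': 12} 58
```

12 high + 17 intermediate of 50 samples → 58% positive.

A `flowscreen` CLI wraps the same functions
(`flowscreen simulate screen`, `flowscreen screen`, `flowscreen classify`,
`flowscreen summarize`, `flowscreen subsets`, `flowscreen coculture`,
`flowscreen engraftment`, `flowscreen strata`); each subcommand documents
its expected TSV columns in `--help`.

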