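# Methods

## Scope and model of the data

flowscreen quantifies compensated flow-cytometry data: per-cell fluorescence
intensities on a linear scale, one row per acquired event, one column per
channel. All statistics are computed on the raw linear scale; no spillover
estimation, automated gate learning or display-transform fitting is performed
(an arcsinh transform, if used for display, never affects statistics).

## Gating semantics

A gating strategy is an acyclic tree of named gates; the population at a node
is the conjunction of its own per-channel predicate with every ancestor
predicate. Four gate kinds exist: threshold-above, threshold-below, range,
and 2D quadrant.

Boundary rule, applied identically everywhere: the **positive** side of a
bound is strict (`x > bound`); the negative/low side is its complement
(`x <= bound`); range gates select `lo < x <= hi`. This single convention
makes the four sibling quadrants of a CD45RA x CCR7 plane an exact partition
of their parent, keeps "exactly at the cutoff" retained in the screen
exclusion rule, and sends on-threshold events to the negative side in subset
gating. Low-gates such as CD38low are explicit threshold-below gates with
numeric bounds from configuration; bounds are never inferred from data unless
an isotype table is supplied.

## Isotype-anchored positivity

An isotype (or FMO) control defines nonspecific background. The positivity
threshold on a channel is the empirical quantile of the control distribution
(default 0.99); an event is positive when strictly above it. By construction
the expected false-positive rate on background-only samples is
1 − quantile (≈1%). MFI defaults to the arithmetic mean — the expansion of
"mean fluorescence intensity" — with median and geometric mean available
because cytometry practice varies. Optional background subtraction removes
the control's own above-threshold fraction from %positive, floored at 0;
it defaults to off because the screen's %positive convention does not state
whether background was subtracted.

## Arrayed screen scoring

The screen compares each marker's MFI between leukemic (AML) and healthy
marrow (NBM) donors within a primitive gated compartment
(7-AAD−CD3−CD19−CD34+CD38low):

1. **Exclusion.** Markers already high on healthy cells — donor-aggregated
   NBM MFI > 10,000 a.u. or NBM %positive > 10%, both strict — are removed
   before ranking.
2. **Scoring.** Per-donor MFIs are aggregated per arm (mean of the 3 donors
   per arm by default; the aggregation statistic is configurable because the
   source design aggregates 3 vs 3 donors without stating how), then
   fold change = AML_MFI / NBM_MFI and absolute shift = AML_MFI − NBM_MFI.
   Fold-change denominators below a floor (default: the smallest positive
   aggregated NBM MFI in the screen, else 1.0) are floored with a logged
   warning, so near-zero background never produces unbounded ratios.
3. **Ranking.** Both metrics are ranked descending with fractional (average)
   ranks for ties; candidates are ordered by the average of the two ranks.
   Final ties break by larger absolute shift, then marker name, making
   output order a pure function of the scores. The displayed effect size per
   candidate is the absolute shift.

A known presentational discrepancy: the narrative description of the screen
speaks of a combined metric of MFI and fraction of positive cells, while the
operational definition ranks on MFI fold change and shift only. The
operational definition is implemented; %positive enters only through the
exclusion rule.

## Expression trichotomy

Per-sample expression is the *shift fraction*: the fraction of stained
events strictly above the isotype high quantile ("outside the isotype
peak", interpreted one-sided; negative shifts clamp to 0). Calls:

- shift fraction > 0.50 → **high**
- 0.10 ≤ shift fraction ≤ 0.50 → **intermediate**
- shift fraction < 0.10 → **negative**

The boundary assignments (0.50 and 0.10 both intermediate) are forced by the
strict ">50%" and "<10%" wording. "Positive" = high + intermediate. Cohort
percentages are reported to the nearest integer, matching the usual
presentation; note that with this rounding a 29/50 cohort reads 58% and a
25/42 cohort reads 60% — both denominators appear in published summaries of
the same marker and the package simply reports whatever cohort it is given.

Stratified comparisons of a per-sample measurement across the three call
groups use Kruskal–Wallis with Dunn's post hoc z-tests (group order fixed
negative < intermediate < high); with exactly two non-empty groups the
two-sided Mann–Whitney U-test is used. Dunn's test is implemented in
`flowscreen.posthoc` (rank-sum z statistic with tie correction; multiplicity
adjustment delegated to statsmodels), with raw p-values by default.

## T-cell subsets

Within a CD4+ or CD8+ parent, quadrants on CD45RA x CCR7 define
naive (CCR7+CD45RA+), TEMRA (CCR7−CD45RA+), effector memory (CCR7−CD45RA−)
and central memory (CCR7+CD45RA−). Thresholds come from configuration —
fixed bounds or isotype/FMO-derived via the positivity threshold — because
the cut-point-setting procedure is not specified by the source protocol.
Only the CD45RA x CCR7 scheme is implemented (panels mixing CD45RO are not).

## Coculture quantification

Absolute cell numbers come from counting beads spiked at a known number:
`cells = cell_events x beads_added / bead_events` (zero bead events is an
error, never a silent infinity). Killing is reported as percent of the
control condition mean and as percent reduction. T-cell activation is the
percent of gated CD4+/CD8+ cells positive for CD25 and/or CD69; the default
policy is "either marker positive" because the biaxial presentation of the
two markers is ambiguous between union and intersection — both policies are
supported and logged. Dose–response tables report means and s.e.m. (matching
the usual figure convention) per (antibody, dose), doses ascending.
Engraftment is the percent of events matching the full leukemia phenotype
conjunction (e.g. hCD45+CD3−CD33+CD34+SLAMF6+) among viable events.
Cell concentrations (per µl) are not computed; numbers are per tube.

## Survival-cohort preprocessing

Bulk-RNA cohorts are filtered on a deconvolution-estimated lymphocyte
fraction (consumed as input, never computed): samples with strictly more
than 15% lymphocytes are removed. Remaining samples are split by marker
expression into three contiguous groups whose sizes differ by at most one;
when n is not divisible by 3 the lower groups take the remainder, and ties
in expression keep stable input order — the source does not state its
remainder/tie rule, so this deterministic rule is the package's own,
documented choice. Output is a tidy (time, event, group) table for any
standard Kaplan–Meier implementation; estimation itself is out of scope.

## Synthetic data

Intensities are log-normal mixtures: a component with linear-scale location
m (its median) and log-scale s.d. s draws `m * exp(s * Z)`. Defaults place
the isotype background at 100 a.u. with s.d. 0.6 and the baseline stained
signal at 1.5x background with the same spread, so background and negative
stained populations overlap realistically.

- **Screen simulator** — 362 markers, 3 donors per arm, 5,000 events per
  sample by default, mirroring the screen design. Each (arm, donor) has one
  shared isotype control; each marker's signal is multiplied by a per-donor
  log-normal factor (s.d. 0.1, modest biological variability) and, in AML
  donors, by the planted effect. The fast path returns per-sample MFI and
  %positive directly; a materializing path emits the identical event tables
  (same random sub-streams), and a test asserts both paths agree exactly.
- **Cohort simulator** — class counts (default 24% high / 34% intermediate /
  42% negative at n = 50) are allocated deterministically by largest
  remainder; each sample's true shift fraction is drawn uniformly inside its
  class band, at least 0.03 from the 10%/50% boundaries so the planted call
  is recoverable at 10,000 events (background leakage past the isotype
  quantile adds ≈ +0.01 x (1 − fraction) to the measured fraction).
- **Coculture simulator** — treated wells thin the true AML cell number
  binomially by the planted killing fraction; each well acquires a binomial
  20% of its cells and of the 50,000 spiked beads, so bead arithmetic
  recovers the planted numbers within sampling error. T-cell tables plant
  configurable double-/single-positive CD25/CD69 fractions.

Every generator draws from a dedicated `SeedSequence` sub-stream keyed by
(arm, donor, marker, role) or (sample, role): identical configs and seeds
reproduce byte-identical data, and adding samples never perturbs existing
ones.

What the simulators do **not** emulate: doublets, time drift, spillover,
acquisition dropouts, non-log-normal autofluorescence, plate/batch effects.
Passing recovery tests therefore demonstrates correctness of the
computations under a clean generative model, not robustness to instrument
artifacts.

## Problem sizes used in validation

The planted-marker recovery study runs 200 full-size screens (362 markers,
3 donors/arm, 5,000 events/sample) and requires the 8-fold planted marker to
reach final rank 1 in at least 95%. The null calibration study runs 1,000
screens at 24 markers x 500 events — rank-1 uniformity under the null is
independent of screen size, so the smaller screens are the package's chosen
size for this high-repetition study. Threshold calibration uses 100
independent 10,000-event isotype pairs; because the threshold is itself
estimated from one finite sample, the per-seed tolerance band uses the
two-sample binomial s.d. (sqrt(2 p (1−p)/n)).

## Numerical choices and degenerate inputs

- Empty populations yield flagged-undefined (NaN) MFI/%positive/composition
  rather than errors; empty isotype tables and zero bead events are errors.
- Quantiles use numpy's default linear interpolation.
- Geometric-mean MFI rejects non-positive intensities.
- The FCS reader (`flowscreen.fcs`) supports list-mode FCS 3.0/3.1 with
  float32/float64 or fixed-width integer data, either byte order, and data
  offsets in the header or TEXT segment; analysis segments and non-list
  modes are rejected with a format error. The companion writer emits
  little-endian float32 FCS 3.1, used for round-trip validation.

## Known limitations

- No compensation/spillover handling; inputs are assumed compensated.
- The actual published marker ordering of the discovery screen is not
  reproducible here because the raw screen data are not deposited; the
  ranking machinery is validated on simulated screens with planted truth.
- Printed in vitro/in vivo effect sizes from wet-lab experiments (e.g. 88%
  or 75% killing) depend on undeposited data; the package reproduces the
  *computations* that produced them, demonstrated on synthetic assays with
  planted effects.
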