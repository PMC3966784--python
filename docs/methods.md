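# Methods

This note documents the models and conventions behind `divetag`: what
each stage computes, the choices made where the problem was genuinely
open, and what the synthetic-data generator does and does not emulate.

## The Behavior Log data model

A Behavior Log (BL) is a time-ordered stream of qualifying **dives**
(maximum depth ≥ 50 m and duration ≥ 30 s; start, end, maximum depth,
shape ∈ {Square, V, U}) and **surfacing bouts** (start/end only),
reconstructed from satellite messages.  Timestamps are UTC at 1-s
resolution, which is finer than the 0.01-min precision used in
reporting.  Within a contiguous block each event starts where the
previous one ends; adjacent events whose start/end differ by more than
the contiguity tolerance **τ_gap = 60 s** (configurable) delimit a
message-loss gap.  One minute absorbs timestamp rounding without
swallowing real message losses, whose payloads span many minutes of
record.  Rows violating the qualifying-dive thresholds are rejected
with per-row reasons, never silently dropped.  Reported maximum depths
are carried as-is; the ±1.5% resolution-step quantization is a property
of the sensor (and of the generator), not undone on read.

Surfacing-bout timestamps come from a wet/dry conductivity switch on
some tags and from crossing a 5 m depth threshold on others.  The two
modes differ systematically (the depth threshold pads each bout by
roughly half a minute), so bout-duration analyses are restricted to
wet/dry tags; the package carries the mode label and never adjusts one
mode toward the other.

## Dive classification

Each individual's dives are partitioned by K-means (k = 2) on maximum
depth and duration.  Both features are **z-standardized per
individual** before clustering: depth in meters and duration in minutes
differ by two orders of magnitude, and unstandardized clustering is
depth-dominated (on the calibrated simulations it still reaches ≥ 99%
accuracy because the class separation is large, but standardized
features are the defensible default and are what ships).  Clustering
uses 50 restarts with a fixed seed, so results are deterministic; the
two arbitrary cluster indices are relabeled by mean raw depth (greater
= deep), making the output invariant to label permutation.  A one-way
ANOVA of depth by assigned class accompanies each report.

Borderline flagging: deep dives strictly below their class's 5th
percentile of depth *or* duration, and shallow dives strictly above
their class's 95th percentile of depth *or* duration, are flagged
(linear-interpolation percentiles, computed per individual per class).
The shallow-side rule is deliberately the *upper* tail: a shallow dive
can only be mistaken for a deep one by being unusually deep or long.

Contextual reclassification replaces the visual verification a human
analyst would do against the dive trace with an explicit rule.  A
flagged **deep** dive is reassigned to shallow iff (i) no gap or record
edge abuts it, (ii) it sits in a run of ≥ 3 consecutive deep-labeled
dives (surfacing bouts do not break a run; gaps do), and (iii) its
depth is below ρ = 0.6 of the median depth of unflagged deep dives
within a ±24 h window.  Symmetrically, a flagged **shallow** dive is
promoted iff it is a lone shallow dive bracketed by deep dives and its
depth exceeds 1/ρ times the local unflagged shallow median.  Flagged
dives adjacent to a gap always keep their K-means label, because the
surrounding pattern cannot be judged.  ρ and the window are free
parameters chosen to reproduce the canonical worked case (several
consecutive ~500 m, ~35 min dives amid 1500 m neighbors, where a run of
deep-labeled dives is broken); they are exposed in the configuration.
Reassigned dives keep full provenance (original class, flags) and are
never revisited, making the operation idempotent.  On calibrated
simulations the rule fires on ~0.1–0.2% of dives, matching the order of
magnitude reported for the real data (0.1%).

## Sequence analysis

Surfacing bouts are typed by the classes of the two bracketing dives —
(deep, shallow) → FS, (shallow, shallow) → IS, (shallow, deep) → TS,
(deep, deep) → SS.  A bout at a record edge or adjacent to a gap is
`untyped`; neighbor classes are never guessed across missing record.

The **inter-deep-dive interval** (IDDI) runs from the end of one deep
dive to the start of the next and is computed only when the intervening
record is gap-free; intervals spanning a gap are excluded outright,
never truncated.  Shallow dives are counted when their full extent lies
inside the interval (deep dives bound it, so no dive can straddle).
One consequence worth knowing: gap exclusion is *length-biased*.
Longer intervals contain more events and so are more likely to overlap
a lost message; with a 2% per-event loss rate the surviving IDDI median
sits ~10–16% below the full-distribution median.  This is a property of
the gap-free-interval definition itself, not of this implementation,
and it applies equally to analyses of real tag data.

Deep-dive rate = deep dives / BL hours, computed per whale; group
values are means of per-whale rates, never pooled counts.

## Diel assignment

Solar elevation is computed from the NOAA solar calculator's
Julian-century formula chain (geometric mean longitude/anomaly,
equation of center, apparent longitude, corrected obliquity,
declination, equation of time, hour angle).  Events are keyed to their
**start time** and the position estimate nearest in time (ties to the
earlier fix); elevation ≥ 0° is day.  Elevation exactly 0 is a
measure-zero case assigned to day by convention.  Geometric
(non-refracted) elevation is the default; atmospheric refraction
(≈ 0.57° at the horizon, shifting sunrise/sunset by 2–3 min) is
available behind a flag and only matters within minutes of the
terminator.  Long dives can span the terminator; their whole duration
is credited to the class of their start, consistent with the keying
rule.

## Movements

Distances are haversine on a sphere of radius 6371.0088 km; the < 0.5%
error against an ellipsoid is immaterial at kilometer-level reporting.
The best daily position is the highest Argos quality class
(3 > 2 > 1 > 0 > A > B) per whale-UTC-date, ties broken by proximity to
local solar noon so the chosen fix is representative of mid-day, then
by time.  Region occupancy uses an even-odd point-in-polygon test on a
closed lon/lat ring, with boundary points (edges and vertices) counted
inside; region polygons are user-supplied configuration — none ship
with the package.

## Statistical conventions

Depths, durations, bout durations and IDDIs are strongly right-skewed,
so individuals are summarized by medians (linear interpolation) with
ranges, and the group by the unweighted mean and SD of the
per-individual values across the 8 whales.  The group SD uses the **n
denominator**: recomputing the published group SDs from the printed
per-individual medians reproduces every SD printed at meaningful
precision (137.8 m deep depth, 6.9 min deep duration, 18.3 m shallow
depth, 30.8 min IDDI) under that convention, while the n−1 form gives
147.4, 7.4, 19.6 and 32.9 and cannot have produced them.  The few
published sub-unit SDs (0.99 shallow dives per IDDI, 0.05 dives/h) and
the IDDI group mean differ in their last digit when recomputed from the
printed (rounded) medians; they were evidently computed from unrounded
values, and the tests check them to within one unit of the last printed
digit.

Hypothesis tests are the field-standard nonparametrics: two-sided
Mann-Whitney U for the sensor-mode bout-duration comparison (exact null
at small tie-free samples, tie-corrected normal approximation
otherwise); Kruskal-Wallis across bout types followed by Dunn-style
pairwise Z comparisons with tie-corrected rank variance and a
Bonferroni family (the specific post-hoc family is a documented choice;
empty types are excluded with a warning, as happens when a whale
performs no back-to-back deep dives); paired t-tests on per-whale
day/night values with df = n_whales − 1, one-tailed for deep-dive depth
(night deeper) and duration (day longer) and two-sided for time-budget
proportions, with tails configurable.  Zero-variance paired differences
raise rather than returning an infinite t.  Diel time budgets credit
each event's full duration to the class of its start; within each diel
class the deep/shallow/surfacing fractions sum to 1 by construction.

## The synthetic-data generator

The simulator emits the stereotypical dive cycle as a grammar — deep
dive → FS → (shallow dive → IS)^(k−1) → shallow dive → TS → next deep
dive, with k = 0 producing a single SS bout between back-to-back deep
dives — plus the observational artifacts the pipeline must survive.

Component choices:

- **Depths and durations** are lognormal (median m, log-space σ),
  truncated at the qualifying thresholds and quantized to resolution
  steps of at most ±1.5% (largest power of two ≤ 3% of the value).
  Lognormal reproduces the observed right skew — recorded maxima sit
  far above medians (e.g. 2992 m against a 1488 m median) — with two
  parameters.  σ is fitted to the **upper** log-range (median → printed
  maximum, scaled by the expected extreme z of n draws).  The observed
  minima sit further from the median in log space than the maxima; a
  symmetric fit would inflate the upper tail far beyond the printed
  maxima (implied shallow-duration maxima of ~2 h against a printed
  41–67 min) and manufacture deep/shallow overlap the real data did not
  have.  The cost is a lower tail that under-covers the printed minima,
  which only affects trivially separable short dives.
- **Shallow dives per interval** k is negative binomial (dispersion
  r = 5), overdispersed relative to Poisson as the observed 0–21 range
  around a mean of ~4 requires, with an explicit small probability
  (1.5%) of k = 0 (back-to-back deep dives).
- **Diel modulation**: night adds +142 m to deep depth and −4.9 min to
  deep duration (the published effect sizes), multiplies surfacing-bout
  medians by 2.5, and scales the shallow-count mean by 0.75 — together
  reproducing the qualitative time-budget contrast (more surface time
  at night, more shallow diving by day).  Extended (> 1 h) bouts occur
  with a strongly night-biased probability (0.6% night vs 0.03% day),
  mirroring the observation that essentially all hour-plus surfacings
  happened at night.  Parameter draws use the diel state at cycle
  start; truth records the per-event state.
- **Message loss** deletes geometric runs of consecutive events (mean
  3 — an Argos message carries several events), extended so that every
  loss removes more record than τ_gap; losses are therefore always
  detectable gaps, and events + gaps tile the record exactly.
  **Duty cycling** silences alternating UTC dates after day 28.
- **Tracks** are Ornstein-Uhlenbeck walks (σ = 40 km, τ = 5 d) around
  the deployment point — site fidelity with occasional excursions —
  sampled at ~3 Poisson-timed fixes/day with Argos quality classes
  drawn from a fixed distribution.

Eight presets carry the published per-individual medians/ranges, BL
hours, deployment dates and sensor modes.  Calibration is at the
component level: emitted IDDIs and deep-dive rates are *emergent* from
k, shallow durations and bout durations, and sit somewhat below/above
their published counterparts respectively (the printed per-whale IDDI
medians are not exactly consistent with the printed component medians
under this simple grammar).  Recovery tests therefore compare pipeline
output against the scenario's **implied medians** — Monte-Carlo
medians drawn directly from the component distributions (fixed internal
seed, even day/night mix) — not against the published table.

What the generator does *not* emulate: within-cycle autocorrelation and
behavioral regimes (dive-duration to recovery coupling is available but
defaults to 0), dive-shape structure (all simulated dives are
"Square"), depth-dependent Argos error, seasonal migration, and any
response to acoustic disturbance.  Passing the round-trip tests shows
the pipeline recovers the statistical structure it assumes; it does not
validate the pipeline against behaviors outside that structure.

## Test design and problem sizes

Simulation-backed tests use sizes chosen to keep the suite fast while
leaving comfortable statistical margins: classification fidelity runs
the eight presets at 336 h each (~4000 dives pooled; accuracy ≥ 99%,
per-whale ANOVA p < 10⁻⁴, reclassified fraction < 1%).  Parameter
recovery runs diel-neutral, gap-free variants (the diel offsets are
tested separately by the detection study, and gap exclusion biases the
IDDI median as described above) at 500 h × 3 seeds per whale, taking
the median across seeds: a single IDDI-median draw at ~150 intervals
has a standard error near 5–7% of its value, so the 3-seed median is
what makes a ±10% comparison meaningful.  The count-valued
shallow-per-interval median is compared within one unit — the sample
median of a discrete variable whose CDF sits near 0.5 at the median
(P(k ≤ 1) ≈ 0.48 for the sparsest whale) flips between adjacent
integers at any realistic n.  The diel-detection study runs 100
replicate eight-whale studies at 336 h per whale and requires both
paired one-tailed t-tests (df = 7) to fire at α = 0.05 in ≥ 80% of
replicates; measured power is ~100%.

## Known limitations

- The contextual reclassification rule reproduces the canonical worked
  case but is only a surrogate for expert judgment; its parameters (ρ,
  window, run length) are honest free parameters.
- Sub-tolerance (< 60 s) message losses are indistinguishable from
  contiguous record by construction; real data may contain them.
- The solar implementation is the NOAA formula chain, accurate to well
  under 0.1° for |lat| ≤ 72; it is not a high-precision ephemeris and
  degrades toward the poles.
- IDDI medians from gappy records are length-bias-shrunken (see above);
  comparisons across records with different loss rates should account
  for this.
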