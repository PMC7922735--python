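# Methods

## The problem

Egg-production methods for assessing spawning biomass of batch-spawning fish
need the *spawning fraction* — the proportion of mature females spawning per
day. It is estimated from the incidence of postovulatory follicles (POFs): the
theca + granulosa envelope left in the ovary after ovulation, which degenerates
over hours to days. Turning POF incidence into a daily spawning fraction
requires an *aging key*: which histological stage a POF is in, and how many
hours after the nightly spawning peak each stage spans. POF resorption is
species-specific and strongly temperature-dependent, so a key calibrated in
cool Atlantic water misdates POFs in a warm sea. `pofkit` implements the full
key-construction pipeline for European anchovy at warm (24–25 °C) conditions,
plus a synthetic field-collection generator used to validate every step.

## The staging key

Six stages are encoded as canonical vectors over six categorical
histomorphological traits (vacuolation, granulosa cell shape, nuclear state,
lumen, overall shape, theca). The classifier:

1. an exact match of a canonical row returns its stage;
2. a vector differing from exactly one row in a single trait is attributed to
   that row's stage (degeneration is a continuum; single traits lag or lead);
3. anything else raises `UnclassifiableFeaturesError` naming the conflicting
   fields — never a silent default.

Because every pair of canonical rows differs in at least four traits, rule 2
is unambiguous for all single-trait perturbations (property-tested). When
several rows ever tie (future key edits), the documented precedence applies:
vacuoles and overall shape dominate (the peculiar degradation indices), then
nuclear state. Sub-variants of stages I and VI ("BIS" morphs) are treated as
within-stage variation, not extra stages.

The forward key is a `StageSchedule` of six positive durations with half-open
windows `[break[k-1], break[k])`, so each elapsed time maps to exactly one
stage; `t >= total persistence` is "resorbed". Default durations are
**(4, 6, 12, 8, 5, 5) h** (total 40 h at the 25 °C reference): stage I lasting
~4 h and disappearing within ~7 h of the peak, stages I–II gone by ~10 h,
stage III centred at 16 h and persisting past 22 h, and stages IV–VI filling
the 22–40 h band with stage V centred near 32.5 h. Temperature scaling
multiplies every duration by `(1 + r)^(T_ref − T)` with `r = 0.03` per °C
(the coefficient reported for sardine, exposed as a config knob).

## The synthetic-data generator

Conditions emulated (the generator's defaults *are* the study conditions):

| parameter | default | meaning |
|---|---|---|
| `asp_hour` | 22.0 | clock hour of the daily spawning peak |
| `spawn_sd`, `spawn_window` | 1.0 h, ±1.5 h | truncated-normal jitter of individual spawn times: nightly spawning confined to a ~3 h window around the peak |
| `spawning_fraction` | 0.35 | per-night spawning probability (not reported for the study population; a typical anchovy DEPM value) |
| `n_females` | 2000 | sampled females per collection |
| `schedule`, `T`, `T_ref` | (4,6,12,8,5,5) h, 25 °C, 25 °C | the aging key above |
| `area0`, `area_profile` | 30 000 µm², (1.00, 0.99, 0.90, 0.55, 0.45, 0.28) | per-stage mean POF section area as a fraction of stage I; the 0.99 and 0.28 anchors are the printed ones, intermediate values are calibration defaults |
| `area_cv`, `gonad_area`, `gonad_cv` | 0.40, 40 mm², 0.25 | lognormal individual variation |
| `effort_weights` | (4,4,33,8,50,25,32,38,27,9,8,8) | diel catch effort, proportional to the field study's catches per 2-h interval |
| `duration_sigma` | (0.025, 0.025, 0.025, 0.8, 0.8, 0.8) | per-stage lognormal sigma of mean-one duration multipliers (truncated at 2.0 / 2.5 σ) |
| `annotation_error` | 0.0 | probability of mislabeling to an *adjacent* stage |

Each female spawns independently on each of the three nights preceding
capture; capture clock times follow the effort weights; one POF observation is
emitted per spawning event while its age is inside the (per-POF) persistence
window, with truth columns (`truth_age_h`, `truth_cohort_day`, `truth_stage`)
segregated so the pipeline can be run blind.

**Why stage-dependent duration dispersion.** A deterministic key confines each
stage to a clock window equal to its duration, but field collections show
stages IV–VI throughout the diel cycle while stages I–III stay confined near
the spawning peak. The mechanism is that, after a full day, the thermal
history accumulated through diel vertical migration desynchronises resorption
among individuals; early degeneration, observed within hours of a
synchronised spawning night, stays tight. The generator reproduces this with
nearly deterministic durations for stages I–III (σ = 0.025, bounded so the
stage-III window cannot leak into the night bins) and widely dispersed
durations for IV–VI (σ = 0.8, i.e. central 95% multiplier range ≈ 0.2–4).
The σ values were calibrated once, at design time, so that the generator
robustly exhibits the qualitative field pattern (late stages present in every
diel bin, stage I confined to within ~7 h of the peak) across seeds; they were
not revisited afterwards. A side effect of the heavy-tailed late durations is
length-biased sampling: the *empirical* mean age of observed stage-IV POFs
sits above the stage's schedule midpoint even though the durations are
mean-one. This is a property of real collections too, and the
occurrence-weighted age estimator (below) is insensitive to it.

What the generator does **not** emulate: spatial structure, diel
vertical-migration temperature trajectories (temperature is constant within a
run), within-cohort replicate POFs in one section (one observation per
spawning event; the field study's ~8 POFs per slide are replicate sections of
the same cohort and carry no extra information under this model), batch
intervals longer than one night, and reader-specific annotation biases.
Passing tests therefore validate the *estimators* under the assumed sampling
model, not the histology itself.

## The analysis chain

**Binning and standardization.** Captures pool into twelve half-open 2-h diel
bins. Per-bin stage counts are standardized first by the number of females
with POFs in the bin (removing catch-effort differences), then renormalized to
per-bin stage proportions (`std_occurrence`, summing to one over stages).

**Cohort-day detection.** A stage whose diel occurrence has a contiguous
*circular* block of ≥ 3 empty **sampled** bins (≥ 6 h of absence; `k`
configurable) is detectable only in a portion of the cycle and belongs to the
youngest cohort (Day 0); otherwise it persists more than a day and belongs to
the previous night (Day 1). Unsampled bins are ignored so sparse effort never
masquerades as absence. One day is assigned per stage; a finer split of an
old stage's occurrence across two days is not attempted.

**Age estimation.** Each bin's offset from the spawning peak is a *clock*
quantity and wraps the 24-h circle, so offsets are averaged circularly:
offsets are unwrapped to within ±12 h of the occurrence's weighted circular
mean before taking the occurrence-weighted mean, and Day-1 stages then get
+24 h. A naive linear `(midpoint − peak) mod 24` average is biased by up to
~4 h for wrap-around stages (III, VI). Day-0 offsets are anchored on a cut
3 h before the peak (`pre_peak_window`), so samples taken just before the
nominal peak — early spawners of the same night — count as small negative
offsets rather than ~+23 h; mean ages can therefore be marginally negative in
pathological inputs, and `max_persistence` extends to the end of the latest
occupied bin. Weights are the per-bin stage proportions (uniform rescalings
leave the estimate unchanged).

**Confidence intervals.** Percentile bootstrap, 1000 replicates, seeded, with
two deliberate features: resampling is by *female* (cluster), respecting
within-ovary correlation; and capture times are interval-censored, so each
replicate represents a bin by a uniform draw within it rather than the fixed
midpoint (a smoothed bootstrap). Without the second feature, CIs for tightly
estimated stages (e.g. III) are a few tenths of an hour wide and cannot cover
even the small residual discretization bias of 2-h binning. The detected
cohort day is held fixed across replicates.

**Morphometrics.** Kruskal–Wallis H always carries the standard tie
correction (areas are continuous but rounded in practice); an exact
permutation p-value by full enumeration is available for pooled n ≤ 12 and is
tested against an independent enumeration oracle. Pairwise comparisons use
Dunn's rank-based z with Bonferroni adjustment over the observed pairs — the
post hoc method is not named in the source material, so it is pluggable
(`adjust=` argument) and hand-implemented (no post hoc package in the
dependency set). Relative occupied area is mm² POF per mm² gonad section,
averaged over all sampled females per bin (females without the stage count as
zero; unsampled bins stay missing, never zero, never interpolated).

**Resorption rates.** The relative-area trajectory of a stage, in elapsed
order from the peak, is differenced over successive *adjacent* sampled bins
and divided by 2 h — but only from the stage's occupancy maximum onward.
Before the maximum the stage is still filling with newly arriving follicles,
and differences there measure cohort influx, not resorption; including the
filling limb makes the stage-I rate noise-dominated and sign-unstable. A
stage whose maximum falls on its last traceable bin is reported as an
explicit inestimable result, not NaN.

## Numerical and design choices

- Diel bins are half-open `[2k, 2k+2)`; clock arithmetic is modulo 24 with a
  single local timezone and no daylight-saving handling.
- All writers are byte-stable (fixed column order, `%.6g` floats, ISO-8601
  datetimes); the run manifest hashes config + seed + input digests +
  version, excluding wall-clock time.
- The two-step occurrence standardization is stated ambiguously in the field
  literature (two sequential divisions without a final normalization target);
  per-bin stage proportions are used because the diel composition figures are
  per-bin compositions. The age estimator is invariant to the alternative
  reading (division by the grand POF total), which differs only by a uniform
  rescale.
- `annotation_error` defaults to 0: the classifier itself is deterministic,
  and a nonzero default would leak mislabeled stage-II POFs into stage I's
  diel window, contradicting the confinement the key is built on. Tests
  exercise the error model explicitly.
- Degenerate inputs: a collection with no POFs yields an empty recovery
  report, renders a report with explicit "no POFs" sections, and never
  crashes; a stage observed nowhere raises; POF counts recorded in a bin with
  no POF-bearing females is a data-integrity error.

## Problem sizes used in the test-bed

Validation runs use `n_females = 2000` (≈ 1100 POFs) for cohort-structure and
recovery checks — 20 seeds with 1000-replicate bootstraps — and
`n_females = 3600` (≈ 2000 POFs, matching the field collection's ~1940) for
area-pattern checks; the resorption-rate ordering check uses 8000 females so
the stage-I declining limb is traced by a few hundred carriers.

## Known limitations

- The printed field statistics (H(5, n = 1940) = 1056.59, the pairwise
  p-value matrix, the field mean ages 32.25 h / 34.54 h) depend on
  unpublished raw measurements and are not reproducible here; the pipeline
  reproduces their qualitative pattern on synthetic collections instead, and
  the simulated analogues land close (H ≈ 1030–1080, stage V ≈ 32 h,
  stage VI ≈ 34–42 h depending on seed).
- Mean-age estimates for stages V–VI carry a small negative bias (~1 h):
  ages beyond 48 h cannot be distinguished from their −24 h alias under a
  two-day cohort convention.
- The cohort-day rule is threshold-based; with very sparse effort (< 1 female
  expected in several adjacent night bins) a Day-1 stage can be mislabeled
  Day 0. The absence-block length is configurable for such designs.
- One POF observation per spawning event: within-ovary replicate counts, and
  hence any over-dispersion they induce, are not modelled (CIs already
  cluster by female, which absorbs this at the estimator level).
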