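# Methods

This note documents the models, estimators and design choices behind
`groupflow`, in the package's own words. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Pipeline overview

A session's raw material is (a) per-student 1-Hz cardiac samples — Unix
timestamp, bpm, R–R interval in ms — and (b) end-of-session questionnaire
rows. The pipeline is: artifact filtering → span segmentation → span group
statistics → questionnaire scoring → session summary → (per arm)
z-normalization → calibration fits, flow-zone classification, correlation
batteries, agreement analysis, and the nonlinear balance battery.

## Cardiac stage

**Artifact filter.** Samples whose R–R interval falls outside
`[300, 2000]` ms (≈ 30–200 bpm) are removed and counted. This plausibility
filter plus an optional per-span linear detrend replaces the proprietary
signal-conditioning of commercial HRV software; it removes the spike
artifacts of missed/spurious beat detections but not subtler ectopy.

**Spans.** Sessions are partitioned into half-open, 0-based spans
`[start + k·L, start + (k+1)·L)` with `L = 300 s` by default — the standard
5-minute HRV epoch for children. A sample exactly on a boundary opens the
later span; spans with no samples are reported empty, not dropped, so the
partition property (span counts sum to the sample count) always holds.

**HRg / SDg.** HRg is the mean over students of each student's mean bpm in
the span. The study literature never fixes whether SDg is a within- or
between-student dispersion; the default mode `within_student` (mean of the
per-student bpm SDs) was chosen because SDg is interpreted as an index of
parasympathetic modulation, a within-person construct. The alternative
`between_students` (SD across student means) is one flag away. Sample
(n−1) SDs are used in both modes, consistent with all questionnaire/table
statistics; with it the published control-arm flow SD (6.42) reproduces
exactly.

**Poincaré SD1/SD2.** `sd1 = sqrt(mean(diff(rr)²)/2)` (equivalently
RMSSD/√2, the RMS perpendicular distance of lag-1 points to the identity
line) and `sd2 = sqrt(2·var(rr) − sd1²)` with the population variance. Taking
the second moment of successive differences about zero rather than about
their mean makes the closed-form identities exact — a strictly alternating
series has `sd1 = step/√2` and `sd2 = 0` — which the tests exploit; for long
stationary series the two conventions coincide. A radicand negative within
1e−9 is clamped to zero; more negative values are an error, not a silent NaN.
Note that the study context reports the *teacher's* S1 noticeably greater
than S2, the reverse of the usual SD1 < SD2 ordering; this package implements
the standard ellipse convention and makes no attempt to reproduce that
unverifiable reading.

## Questionnaire stage

FKS: 13 seven-point core items (6 progression, 4 absorption, 3 relevance)
plus 3 nine-point items per A-dimension. A-dimension means require ≥ 2 of 3
items answered, otherwise the dimension is missing — conservative and
logged, never imputed. EduFlow: 4 × 4 seven-point items; the percent score
divides the total by a configurable `scale_max`, default **84**. The scale's
arithmetic maximum is 112 (16 items × 7), yet the instrument's published
maximum is 84; the default follows the published number and the
contradiction is deliberately surfaced as a parameter rather than resolved.
None of the replicated statistics depend on this choice, because the percent
columns of the source tables are used as printed.

**Barriers** `(Ā1 − Ā2)/Ā3` uses unweighted means of per-student dimension
means (not pooled items) — the natural group-level reading when students are
the sampling unit; requires `Ā3 > 0`. The statistic as written is invariant
to scaling all three means jointly but not to scaling challenge/skills
alone; both identities are property-tested.

**z-normalization** subtracts the window mean and divides by the population
SD (so a two-point series maps to (−1, +1)); the default window is one study
arm across all of its sessions, matching how the standardized scatter plots
are constructed. Zero-variance windows are an error.

## Agreement (teacher vs. group)

Differences are oriented `teacher − group`, so a teacher under-reporting
flow yields a negative bias. Limits of agreement use a fixed multiplier of
1.96 (the conventional 95% band), configurable. The RMSE about the
zero-difference line satisfies `rmse² = bias² + (n−1)/n·sd_diff²`
(property-tested) and is reported scale-relative as `rmse/scale_max·100`.
The four published per-group RMSEs are not recomputable (the teacher's raw
scores were never published); only the RMSE→percent conversion is, and that
is the only acceptance-checked agreement quantity.

## Flow-zone decision layer

The live advisory system's internal geometry is unpublished. The classifier
here is a declared reconstruction faithful to its documented shape: predicted
flow `= c0 + c1·zHRg + c2·zHRg² + w·zSDg`, jointly least-squares fitted on a
calibration arm, binned by three increasing cutpoints defaulting to the
quartiles of the calibration predictions. Boundary ties go to the higher
zone (deterministic). The advisory mapping is total: High → none, Medium →
repeat once, Low → repeat twice, No Flow → break then repeat twice. The
acceptance surface is the advisory mapping and label-distribution
arithmetic; the printed per-session labels are treated as given data, since
no published information pins down the original thresholds.

The paired calibration curves — barriers concave in zHRg, flow convex —
are fitted as least-squares quadratics reporting the leading-coefficient
sign and the multiple correlation `r = √R²`.

## Nonlinear balance battery

**Entropy.** All individual balance-item (A3) responses in a session form
one distribution (pooling the three items; per-item mode available);
`H = −Σ pᵢ log₂ pᵢ` in bits with `pᵢ = nᵢ/N`, zero-count terms dropped.
Group means exclude the two sessions the 5th-grade cohort ran with different
tooling (sessions 8–9), the exclusion recorded in the output.

**Trajectories.** The lag-1 return map of the session-mean balance series,
with the attractor ("vortex") operationalized as the series centroid
`(mean, mean)` — no dynamical-systems fitting is attempted. Dispersion about
it is summarized by the mean point-to-centroid radius and the summed path
length; `compare_trajectories` reports per-arm means, differences and ratios
descriptively, with no inferential claim.

## Statistical batteries

Spearman correlations use average-rank ties, rho as Pearson on ranks, and a
two-sided p from the t approximation with n−2 df (the source's software
default is unknowable; this is the common one). An exact permutation p is
available for n ≤ 10. The published experimental-arm HRg–SDg coefficient
(0.594) recomputes to 0.605 under average ranks (one tied SDg value); both
are within 0.02 and the package reports its own computation. The battery is
reported uncorrected, as in the source tables, with an additional
Holm-corrected column clearly labelled as non-source.

The arm contrast uses the pooled-variance Student t (Welch optional) and
Cohen's d with the pooled SD. The printed inferential triple
(t = −4.032, df = 28, d = 1.48) is not reproducible from the printed
session columns — 16 + 16 sessions give df = 30 and t ≈ −4.51 — so the
implementation reports its own statistics and only the means/SDs (which do
reproduce) are acceptance-checked.

## Synthetic-data generator

What it emulates, with defaults matching the study conditions: two arms of
14 students, 9 one-hour sessions (first = rehearsal), 1-Hz sampling,
5-minute spans.

| parameter | unit | default | rationale |
|---|---|---|---|
| `hr_baseline_mean` | bpm | 85 | centre of the published session HRg range |
| `session_hr_offset_range` | bpm | ±12 | uniform draws reproduce the ~74–99 bpm spread |
| `hr_between_student_sd` | bpm | 8 | plausible between-child variation |
| `hr_within_student_sd` | bpm | 3 | short-epoch within-child fluctuation |
| `rr_ar1_coeff` | — | 0.95 | persistent R–R dynamics ⇒ SD2 > SD1, as real HRV |
| `flow_hr_coupling` | scale pts / z | ∓0.6 (control/experimental) | differential-correlation structure |
| `barriers_hr_coupling` | scale pts / z | ±0.6 | mirror coupling, split between A1 (+) and A2 (−) |
| `likert_targets` | native scale | A1 4.2, A2 6.7, A3 5.1; D-dims 3.25 (ctrl) / 3.8 (exp) | land near the published barriers (~−0.5) and flow (62%/73%) levels |
| `teacher_bias`, `teacher_noise_sd` | scale pts | 0, 0 | set negative/positive per scenario |

Mechanics: the R–R series is a stationary AR(1) Gaussian on the interval
(not on bpm) with stationary SD calibrated first-order so the bpm SD matches
`hr_within_student_sd`; Likert responses come from a normal law discretized
onto the scale points with edge bins absorbing the tails, moment-matched to
the target mean/SD by a fixed-point iteration on the latent (μ, σ) — the
mean matches to numerical precision for interior targets, the SD as closely
as discreteness allows; teacher recall is `group mean + bias + noise`,
clipped to the scale. One master seed; each (group, session, purpose)
substream is derived by stable hashing, so adding sessions never perturbs
earlier data. The documented coupling detectability threshold is
|coupling| ≥ 0.3 on the default 16-session configuration; the Monte-Carlo
tests run at 0.6.

What it does **not** emulate — and hence what passing tests do not show
about real data: the advisory feedback loop (advice altering later spans;
arms differ only via configured couplings, because no quantitative effect
model of teacher actions exists), respiration coupling, circadian drift,
ectopic beats, missing-data mechanisms beyond uniform dropout, and any
per-student response structure beyond the documented moments (the source
publishes only group means).

## Numerical choices and degenerate inputs

- Population variance inside `poincare_sd` and `z_normalize`; sample SD
  everywhere else.
- Exact rational counts feed the entropy (no rounding of pᵢ).
- Constant series are errors in `spearman` and `z_normalize`, not NaNs; the
  report bundle is asserted NaN-free.
- Degenerate quartile cutpoints in the zone calibration are spread by 1e−9
  deterministically.
- Monte-Carlo test sizes (200–500 seeds; 30–120 s synthetic sessions with
  6–14 students) were chosen so each check resolves its estimand within the
  stated 3-standard-error tolerance while the whole suite stays fast; the
  estimands themselves do not depend on session length.

## Known limitations

- The flow-zone thresholds are a reconstruction; label sequences from
  `classify_flow_zone` are not expected to match the originally issued
  labels, which are carried as data.
- Frequency-domain HRV, detrended fluctuation analysis and ectopic-beat
  interpolation are out of scope, as are psychometric validation of the
  scales and regression-based agreement extensions.
- Per-session entropy values in the published entropy table cannot be
  recomputed (raw counts unpublished); only the mean rows are verified.
- The grand session-mean balance average computes to 5.10 from the 34
  published session means, while 5.11 is printed for the vortex marker;
  which sessions enter the printed average is unclear, so both readings are
  reported and neither asserted as ground truth.
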