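# Methods

This note documents the models, numerical choices and limitations of the
`spafnirs` pipeline in enough detail to judge what its results do and do
not show.

## Protocol model and segmentation

A session is 55 minutes divided into 9 contiguous intervals. Only three
boundaries are fixed by the bedside protocol description: baseline
[0, 5) min, first therapeutic touch [5, 10) min, and the first singing
interval [10, 20) min. The described sequence (baseline, touch, 10 min of
singing, 5 min of holding, then a repeat of touch–singing–holding) sums to
less than 55 minutes, so the default layout inserts a 5-minute rest after
each holding period: baseline[0,5), touch[5,10), singing[10,20), hold[20,25),
rest[25,30), touch[30,35), singing[35,45), hold[45,50), rest[50,55). The
layout is a configuration default, overridable per study; the anchored
intervals 2 and 3 are the only ones any statistic in the pipeline depends
on.

Sample k of a signal at rate fs lives at time k/fs seconds from protocol
start; interval membership is half-open [start, end), so a sample exactly
on a boundary belongs to the later interval. Segmentation is a partition:
each in-protocol sample belongs to exactly one interval.

## Preprocessing

**Downsampling.** StO₂ (1 Hz) is reduced to the vitals rate (0.25 Hz) by a
linear-phase FIR low-pass (Hamming-window design, cutoff 0.8 × the output
Nyquist = 0.1 Hz, ≤ 101 taps) applied forward and backward (`filtfilt`) for
zero phase, followed by decimation. DC and slow physiological content
(< 0.1 Hz) pass within 1%; content at 0.4 Hz is attenuated by well over
20 dB. Interior missing values are bridged linearly before filtering and
re-marked missing afterwards (an output sample is missing if any of its
source samples was).

**Smoothing.** SpO₂ and PR are smoothed with a 2nd-degree Savitzky–Golay
filter. The nominal 32 s window spans 8 samples at 0.25 Hz — an even count,
which the SG construction cannot use — so the effective window is the
nearest odd width, 9 samples (36 s). Edges use the polynomial of the first/
last full window (scipy's `interp` convention), so polynomials of degree
≤ 2 are reproduced exactly everywhere. Windows containing missing values
refit the polynomial on the present points; if more than a third of a
window is missing its output is missing.

**Motion artifacts.** The three acceleration axes are summed (the literal
x+y+z sum; the vector norm is a config alternative) and a centered moving
sample SD with a 50 s window is computed, edge windows shrinking rather
than padding (for even windows the centre convention is w/2 samples before,
w/2 after, matching pandas). Accelerometer samples whose moving SD strictly
exceeds a threshold T are flagged, and the flag is carried to the 0.25 Hz
grid by logical OR over the accelerometer samples each grid point covers.
Flagged grid points are set missing in all four physiological channels
simultaneously. Because high-motion epochs differ strongly between bedside
sessions, T defaults to an automatic per-session value, 3 × the median
moving SD — a robust scale estimate that sits far above quiescent motion
but well below burst amplitudes — with an explicit per-session override.
An interval losing more than half its samples is flagged in the quality
report; the session is retained.

## Derived measures

FTOE = (SpO₂ − StO₂)/SpO₂, elementwise, missing wherever either input is
missing or SpO₂ = 0 (counted in the quality report, never an error). At
constant SpO₂, FTOE is strictly decreasing in StO₂, which is why the
positive-response subgroup shows rising StO₂ together with falling FTOE.

Interval summaries are medians over non-missing samples; an interval with
less than 50% valid samples yields a missing median (guarding against
artifact-dominated intervals). "Normalizing to the interval-2 median" is
implemented as subtraction, giving Δ-style curves through zero over the
first-touch baseline; a division mode exists behind a flag. Evoked changes
are interval-median differences, Δ = median(interval 3) − median(interval
2) — the most robust reading of a block-average analysis; endpoint
differences are not used. Block averages are pointwise medians and 25th/
75th percentiles across subjects (linear interpolation between order
statistics — stated because quartiles of groups of ~10 depend on the rule).

## Response classification

The two-sample Wilcoxon rank-sum test compares interval-3 against
interval-2 StO₂(AC) samples (exact null distribution when the pooled count
is ≤ 20 without ties, otherwise the tie-corrected normal approximation).
The baseline is interval 2 alone — the interval immediately preceding the
intervention. Subgroup membership follows the *direction* of the median
difference alone; significance is recorded separately, so every subject
with enough data is assigned even when a few changes fail to reach
α = 0.05. At least 10 non-missing samples per interval are required;
otherwise — or on an exactly zero median difference — the subject is
indeterminate with a machine-readable reason.

Within-interval samples are strongly autocorrelated, and the test treats
them as exchangeable; the per-subject p-values are therefore
anticonservative and serve as a descriptive screen, not confirmatory
inference. This fidelity-over-purity choice is deliberate: the procedure is
the published one, and the subgroup labels depend only on the direction,
which autocorrelation does not bias.

## Group statistics

- **Signed-rank effect size**: r_rb = (T⁺ − T⁻)/(T⁺ + T⁻) on midranked
  |differences|, zeros dropped. All-same-sign differences give r_rb = ±1.
- **Mann–Whitney effect size**: U counts pairs in which the covariate is
  larger in the *second* subgroup, ties at half weight;
  r_rb = 2U/(n₁n₂) − 1. Positive r_rb therefore means "larger in subgroup
  2" (for sex coded male = 1: more males in subgroup 2). This fixed
  orientation makes the sign reproducible; the magnitude is
  orientation-invariant. (A reference table reporting W = 53.500 for the
  sex row differs by 0.5 from U = 53 under half-tie counting; U is the
  quantity this package reports, and the matching r_rb = 0.514 is exact.)
- **Contingency suite** on rows = subgroup (1, 2) × columns = sex
  (female, male), counts (a, b; c, d): Pearson χ² without continuity
  correction; log OR = ln(bc/ad) — the log odds of being male in subgroup 1
  relative to subgroup 2 — with Wald 95% CI
  log OR ± 1.96·√(1/a + 1/b + 1/c + 1/d); a zero cell leaves the log OR
  undefined and flagged rather than silently 0.5-corrected. Kendall τ-b
  uses the closed 2×2 form (C − D)/√((M − Tx)(M − Ty)) with sex coded
  female = 1/male = 0; its z and p come from the tie-corrected asymptotic
  test on the expanded pairs.
- **Effect-size confidence intervals** use a normal approximation on the
  Fisher-transformed r_rb with the null-hypothesis variance
  (2(2n+1)/(3n(n+1)) for the signed-rank form, (n₁+n₂+1)/(3n₁n₂) for the
  Mann–Whitney form); |r_rb| = 1 collapses the interval to a point.
  CI methods for rank-biserial correlations vary between packages, so
  these endpoints should be treated as approximate; a bootstrap could
  replace them where the CI itself matters.
- **No multiple-testing correction** is applied anywhere by default — the
  analysis is exploratory and single-cohort; `benjamini_hochberg` exists
  for sensitivity checks.

The haematocrit/length Spearman screen pools AC and PFC Δ values (two rows
per subject), as the corresponding published analysis did; the resulting
p-values ignore the induced within-subject dependence and inherit its
anticonservatism.

## Coupling GAM

Model: ΔStO₂ = β₀ + f(ΔSpO₂, ΔPR) + ε, per optode site and subgroup, on
time-resolved baseline-normalized triples pooled across the subgroup's
subjects (complete cases only, provenance retained). The link is the
identity with Gaussian errors: ΔStO₂ is real-valued and roughly symmetric,
and nothing in the data motivates another monotone link.

The smooth is a P-spline tensor product: cubic B-spline bases with 5
functions per margin (knots at covariate quantiles, clamped boundaries),
combined by row-wise Kronecker product into 25 terms, with second-order
difference penalties along each margin direction and one smoothing
parameter per margin. The basis has unit row sums, so the all-ones
coefficient direction duplicates the intercept and is unpenalized; it is
projected out exactly (sum-to-zero reparametrization), which both fixes
identifiability and removes the only structural singularity. Smoothing
parameters minimize GCV, n·RSS/(n − edf)², over a 10-point log grid per
margin (exhaustive 100-point search — each candidate is a 25-coefficient
dense solve, so this is cheap and fully deterministic). Effective degrees
of freedom are the trace of the hat matrix.

Explained deviance is 100·(1 − RSS/RSS_null), the Gaussian analogue of R².
The smooth-term p-value is an approximate F-test on (edf − 1, n − edf)
degrees of freedom; like all penalized-GAM term tests it is approximate
and used as a screen. Partial effects are surface slices at the centre of
the other covariate's grid; a profile is classified *increasing*/
*decreasing* when ≥ 90% of its first differences share a sign, *none* when
its range is below 0.05 response units, and its curvature read from second
differences over the central 60% of the grid. Pooling across subjects
ignores within-subject autocorrelation, exactly as the model equation
does; explained deviance from pooled time series should not be read as a
subject-level effect size.

## Synthetic cohort generator

The generator's defaults encode the study conditions the pipeline assumes:
17 subjects; P(female) = 10/17; subgroup 1 sampled with sex-dependent log
odds (ln(2/5) for males, +2.303 for females — reproducing an 8F/2M vs
2F/5M-style imbalance on average); first-singing StO₂ amplitudes of
+3.2%/−1.2% for subgroups 1/2 with a haematocrit term
10·(Hct − 0.45) %StO₂ and residual SD 0.5% (the latent scatter is kept
below the published across-subject SDs because those include measurement
noise, which the generator adds separately); second-singing responses
scaled by a habituation factor 0.5; prefrontal responses at 0.75 × the
auditory amplitude. Systemic coupling differs by subgroup: positive
responders couple mainly through SpO₂ (gain 0.25 %/% plus a small
quadratic PR term), negative responders mainly through PR (3 bpm/%).

The response template is a trapezoid (60 s linear onset/offset, plateau) —
the humming begins and subsides gradually, but its true kinetics are
unknown, so the shape is configurable. Noise is 1/f (spectral shaping of
white Gaussian noise, normalized SD) plus white noise: defaults 0.3 + 0.3
%StO₂, 0.15 + 0.15 %SpO₂, 1 + 1 bpm — chosen once as plausible for
clinically stable preterm monitoring; they put the SD of the
interval-median noise near 0.15%, far below the planted amplitudes. Motion
bursts arrive as a Poisson process (2/h default), last 10 s, add
amplitude-10 noise to all three acceleration axes and coincident spikes to
the physiological channels; the planted spans are retained as ground
truth. Baselines (StO₂ 70%, SpO₂ 97%, PR 150 bpm) are generator settings
chosen as physiologically typical, not empirical claims.

What the generator does *not* emulate: desaturation/bradycardia events,
cares and handling between intervals, sensor drift or re-positioning,
state-dependent response variability, and realistic cross-channel noise
correlation. Recovery tests on synthetic cohorts therefore demonstrate
that the pipeline's inference machinery is correct under its own
assumptions — not that those assumptions hold in NICU data.

## Problem sizes and determinism

Simulation-based checks use cohorts of 17 sessions (55 min at native
rates) across up to 50 generator seeds, and GAM recovery checks use 500–
600 pooled samples — sizes at which every Monte-Carlo bound in the test
suite is stable. All randomness flows from explicit `numpy` Generator
seeds; the pipeline writes a config-hash + seed manifest, and repeated
runs produce hash-identical bundles.

## Known limitations

- The rank-sum, signed-rank and pooled-GAM inferences all ignore temporal
  autocorrelation (by design, matching the published procedure); a
  subject-level random-intercept extension is the natural next step.
- The 45-vs-55-minute interval layout beyond interval 3 is an assumption.
- SNIRF import is minimal (first two channels → AC/PFC StO₂) and
  read-only.
- r_rb confidence intervals are approximate (see above).
- The motion-mask auto-threshold assumes bursts are rare (median ≈
  quiescent level); continuous high motion would need a manual T.
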