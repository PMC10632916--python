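# Methods

This note documents the models, conventions and numerical choices behind
`hypnoval`, in the order the pipeline applies them.

## Hypnogram model and harmonization

A hypnogram is an immutable sequence of stage tokens with a clock anchor and
an epoch length of 30 or 60 s. Epoch *i* covers the half-open interval
[start + i·len, start + (i+1)·len); indices are 0-based; durations are
epoch counts × len/60 minutes. Four vocabularies are declared: FIVE
(W/N1/N2/N3/REM, reference PSG), FOUR (W/LS/DS/REM, stage-capable devices),
THREE (W/NREM/REM) and TWO (W/SLEEP). ART (reference artifact) and ABSENT
(device missing / no-presence) pass through every mapping and are excluded
from pairing.

Stage collapsing follows the standard identification of consumer-device
stages: N1+N2 → LS, N3 → DS (`FOUR_DEFAULT`). The alternate identification
N1 → LS, N2+N3 → DS (`FOUR_ALT`) is provided because it is a live hypothesis
when a device's "deep sleep" definition is opaque; comparing MCC under both
identifications is the empirical way to decide which one a device uses.

60-s hypnograms are converted to 30 s by next-minute imputation: minute
*i*'s first half keeps label *i*, its second half takes label *i+1* (the
next adjacent minute), and the last minute duplicates itself. The
alternative reading — duplicate the own minute throughout — is available by
simply repeating labels; the chosen rule is the literal "next adjacent"
reading and only differs at stage transitions.

Cropping to an analysis period retains epochs fully contained in the
period (a boundary that splits an epoch excludes it). Pairing snaps the
test stream to the reference 30-s grid (offsets ≤ 15 s round to the nearest
boundary; larger offsets are the alignment module's job) and drops any pair
in which either member is ART or ABSENT — the valid-pair rule. Mapping and
cropping commute, which the property tests exercise.

## Summary measures

Within an analysis period: sleep onset is the first epoch labeled any sleep
token ("first incidence of sleep"); SOL is the clock time from the period
start to that epoch, minus any artifact time before onset; WASO counts wake
epochs from onset to the period's end, terminal wake included, so that
wake = SOL + WASO; stage durations are label counts × epoch minutes. ART
and ABSENT epochs inside the period count toward neither sleep nor wake and
are tracked as `artifact_min`, giving the exact identity
SOL + TST + WASO + artifact = AP on epoch-aligned periods. A night with no
sleep epoch reports TST = 0, WASO = 0, SOL = AP − artifact and a `no_sleep`
flag.

Sleep efficiency uses the analysis-period duration as its denominator by
default, with the total recording time selectable
(`seff_denominator="TRT"`). Published summary tables in this literature are
internally consistent with the AP denominator even where the prose defines
SEFF against TRT, and the AP form is also the one that makes SEFF invariant
to how much pre/post-recording padding a montage happens to include.

The device-detected analysis period (AP-A) is taken from device metadata
when present; otherwise it is inferred as the span from the first to one
past the last non-ABSENT epoch, which is exactly how the synthetic
generator encodes bed occupancy.

## Summary agreement

Differences are d = device − reference. The Bland–Altman panel uses the
sample SD (ddof = 1); LOA = bias ± 1.96·SD; CI of the bias uses SE = SD/√n
and each LOA's CI uses SE = SD·√(3/n) (the large-sample approximation);
MDC = 1.96·SD, the Bland–Altman convention. SMAPE uses the
|x−y|/(|x|+|y|) form, which is bounded by 100% (the /2-denominator variant
is not); a 0/0 pair is perfect agreement and contributes 0. SAD divides
the mean absolute difference by the root of the average of the two sample
variances; it is symmetric in x and y and invariant to common rescaling.
The ICC is the single-measure consistency coefficient from the two-way
model, (MS_rows − MS_err)/(MS_rows + MS_err) for k = 2 raters, computed
from the ANOVA mean squares directly; negative values are reported as-is
(display layers may suppress them). Shapiro–Wilk on the differences is
report-only: no downstream correction is applied when it fails, matching
standard practice in this literature at small n.

Magnitude classes on |d|: < 0.1 negligible, [0.1, 0.3) small, [0.3, 0.5)
moderate, ≥ 0.5 large. Satisfactory-agreement flags compare a measure's
ICC (strict >) against published inter-scorer reliability: WASO 0.84,
REM 0.75, NREM 0.65, LS 0.67, DS 0.63.

## Epoch-by-epoch concordance

Alignment searches integer lags in [−10, +10] epochs, maximizing the
exact-label concordance of valid pairs at the finest common vocabulary;
ties prefer the smaller |lag|, then the negative lag. Positive lag means
the device content trails the reference. Alignment is per night; the
concordance objective needs hypnogram-like run structure to have a peaked
cross-correlation, which is why the simulator produces bout-structured
nights rather than i.i.d. labels.

Confusion matrices (rows = reference, columns = test) are built at TWO,
THREE or FOUR resolution by mapping both pair members down. Binary metrics
take SLEEP as the positive class, so sensitivity is sleep-prediction and
specificity wake-prediction accuracy. Per-stage metrics are one-vs-rest:
REM/LS/DS on the FOUR-resolution pairs, NREM on THREE — mirroring the
standard report layout. MCC is the 2×2 formula and is identical to the
Pearson correlation of the two indicator vectors; when a marginal is zero
it is undefined and propagates as NaN, excluded from aggregation with an
explicit count. Participant aggregation reports mean, sample SD and the
normal-approximation CI mean ± 1.96·SD/√n, CI ends clamped to the metric's
natural range for display. Pooling sums per-participant matrices; metrics
of the pooled matrix equal metrics of the concatenated pairs. Satisfactory
flags compare mean MCC (strict >) against inter-rater benchmarks:
sleep/wake 0.70, REM 0.69, NREM 0.48, LS 0.40, DS 0.57 (MCC and kappa
nearly coincide in the positive quadrant, so kappa benchmarks transfer).

## Slow-wave activity

Band powers come from non-overlapping Hamming-tapered 4-s windows; the
one-sided periodogram is power-normalized so that summing the PSD over the
0.75–4.5 Hz bins (inclusive) times the bin width returns band power in µV²
— a full-scale in-band tone of amplitude A returns A²/2, verified at
sampling rates 128/256/500 Hz within the 5% window-leakage tolerance.
Since 30/4 = 7.5 is not an integer, the windowing restarts at each 30-s
epoch boundary: each epoch owns exactly seven windows covering its first
28 s, and the trailing 2 s are dropped. This layout was chosen over
continuous windowing (7 or 8 windows per epoch depending on phase) because
it is deterministic, grid-aligned with the hypnogram, and loses only 6.7%
of the data. Mean NREM SWA averages the per-epoch values over N1/N2/N3
(or LS/DS) epochs. The deep-sleep association is an OLS regression of
device DS duration on mean NREM SWA across participants, reporting slope,
intercept, r² and the two-sided p for zero slope.

## Synthetic cohort generator

The generator's defaults encode the emulated study conditions: 35 subjects,
600-min recordings, lights-off periods of 543 ± 36 min, subject-level sleep
efficiency targets drawn from N(0.71, 0.10) truncated to [0.45, 0.95],
sleep onset latency around 15 min, and a sleep-stage mix of N3 20%,
N2 47.5%, N1 18%, REM 14.4% of TST with a between-subject N3-share SD of
7.85 percentage points — older adults vary widely in deep-sleep amounts,
and that between-subject dispersion is what gives deep-sleep/SWA
regressions their signal.

Nights are first-order Markov chains on 30-s epochs inside the lights-off
period (wake outside it). All sleep stages share one wake-entry probability
(default 0.0136/epoch, mean sleep bouts ≈ 37 min), making the wake/sleep
dynamics exactly a two-state chain. The subject's wake-exit probability is
solved by bisection against the *realized* sleep fraction of the night
simulated under common random numbers: with the uniforms fixed, the
realized fraction is near-monotone in the exit rate, and targeting the
realization (rather than the expectation) keeps the within-night occupancy
noise out of the cohort's realized SEFF spread, so the realized SD stays
near the configured 0.10. Within sleep, the stage is redrawn from the
subject's stage mix at rate 0.10/epoch (mean stage bouts ≈ 5 min) and on
each wake-to-sleep transition, which makes the conditional stationary
distribution exactly the configured mix. Reference artifacts are i.i.d.
ART epochs at rate 0.005. The chain has no ultradian REM-cycle
architecture — a deliberate non-goal: the evaluator measures epoch-level
and summary-level agreement, neither of which depends on cycle placement.

Device corruption applies, in order: per-epoch confusion sampling from the
profile's rows (ART reference epochs use the wake row — the device cannot
see artifacts); optional majority smoothing to a minimum run length; a
clock lag within ±10 epochs; re-gridding to 60-s epochs by majority of the
two halves with ties to the first half; geometric ABSENT runs; and ABSENT
outside the device-detected period, which is the manual period perturbed
by the profile's start/end errors. The four presets calibrate the binary
marginals (sleep sensitivity 0.95–0.99, wake specificity 0.22–0.58) and
per-stage sensitivities to the published validation profile of each device
class; the split of errors among wrong sleep stages is assumed and
documented in the preset tables. Presets leave run-length smoothing off so
the epoch-level calibration is exact.

EEG is synthesized per epoch as 0.75–4.5 Hz bandpass-filtered white noise
scaled to a stage-dependent target power (defaults N3 400, N2 120, N1 60,
REM 40, W 30 µV² with log-normal dispersion σ = 0.3) over a small
broadband background. Cohort simulation can draw subject-level SWA
multipliers log-normally (σ = 0.4, a realistic ~50% between-subject spread)
with a configured correlation (default 0.77) against the cohort's realized
N3 durations; regressing a device's DS durations on mean NREM SWA then has
a known coupling to recover, with population r² ≈ 0.6.

All randomness flows from explicit seeds; per-subject streams are spawned
from the master seed via `numpy.random.SeedSequence`.

## Problem sizes and tolerances

The test suite and the acceptance script use: 200 nights for generator
moments (tolerances ±0.03 on means, ±0.03 on the SEFF SD); 100 nights for
closed-loop profile recovery (±0.03, preset specificity ±0.04); 200
repetitions of 900-epoch nights at 20% corruption for lag recovery (≥ 99%
exact); 500 random instances per metric oracle; 10,000 differences for
LOA coverage (95% ± 1%); and six replicate 17-subject cohorts for the
DS–SWA regression, whose mean r² is checked against 0.6 ± 0.15 — at n = 17
a single cohort's r² has sampling SD ≈ 0.15, so the mean over replicates is
the stable quantity. EEG-bearing cohorts use 300-min nights at 64 Hz;
band-power calibration is sampling-rate-invariant, so shorter nights only
widen the per-night SWA noise, which the regression tolerances absorb.

## Known limitations

- The Markov night model has no REM cycling, no latency-to-persistent-sleep
  structure and exponential bout lengths; it reproduces occupancy statistics
  and error-propagation behavior, not sleep microarchitecture. Passing
  tests show the *evaluator* is correct and the generator matches its
  configured moments — not that any real device behaves like a preset.
- Device presets pin only the published marginals; real confusion structure
  (e.g. REM-vs-LS asymmetries conditioned on time of night) is richer.
- The reader accepts only the package's own CSV/JSON dialects; vendor
  exports and EDF annexes are out of scope.
- Normality flags are informational; no multiple-testing control is applied
  anywhere, matching the reporting conventions of device-validation papers.
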