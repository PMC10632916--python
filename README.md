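# hypnoval

Validation of contactless sleep trackers and actigraphy against
polysomnography (PSG).

Consumer sleep technologies — bedside radars, undermattress ballistographic
sensors, wrist actigraphs — report sleep as an epoch-labeled hypnogram plus
all-night summary numbers. Evaluating them against gold-standard PSG is a
method-comparison problem with several standard but fiddly steps: harmonizing
stage vocabularies (five PSG stages vs four device stages), epoch resolutions
(30 s vs 60 s) and clocks; choosing the analysis period (the device-detected
in-bed interval, AP-A, vs the experimenter's lights-off period, AP-M);
computing the all-night summary measures; and quantifying agreement both at
the summary level and epoch by epoch. `hypnoval` implements that full
evaluation pipeline for researchers validating sleep-tracking devices,
together with a seeded synthetic cohort generator that emulates an
older-adult in-lab validation study, so every stage is testable without any
protected data.

## What it computes

**All-night summary measures** for a hypnogram *h* under an analysis period
AP: TST (total sleep time), SOL (sleep-onset latency), WASO (wake after
sleep onset, with wake = SOL + WASO), stage durations (LS, DS, REM, NREM),
and sleep efficiency SEFF = 100·TST/AP.

**Summary agreement** between device estimates *y* and PSG estimates *x*
over *n* participants:

- Bland–Altman: bias = mean(d), d = y − x; 95% limits of agreement
  bias ± 1.96·SD(d) with confidence intervals; minimum detectable change
  MDC = 1.96·SD(d);
- SMAPE = (100/n) Σ |xᵢ − yᵢ| / (|xᵢ| + |yᵢ|), bounded in [0, 100] %;
- SAD = mean|d| / √((s²ₓ + s²ᵧ)/2) — both unitless, enabling cross-measure
  device ranking;
- Pearson ρ, single-measure consistency ICC from the two-way model
  (MS_rows − MS_err)/(MS_rows + MS_err), paired and two-sample Cohen's *d*,
  Shapiro–Wilk normality of the differences, and satisfactory-agreement
  flags against published inter-scorer ICC benchmarks.

**Epoch-by-epoch concordance**: cross-correlation lag alignment within a
±10-epoch window; confusion matrices at 2-stage (sleep/wake), 3-stage
(wake/NREM/REM) and 4-stage (wake/LS/DS/REM) resolution; sensitivity,
specificity, accuracy, F1 and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), which is robust to
the heavy sleep/wake imbalance of overnight recordings; per-participant
aggregation (mean, SD, 95% CI) and pooled matrices.

**Slow-wave activity** (SWA): EEG power in 0.75–4.5 Hz from Hamming-tapered
4-s FFT windows, averaged per 30-s epoch and over NREM sleep, and the
cross-participant regression of device deep-sleep duration on mean NREM SWA.

**Synthetic cohorts**: Markov-chain PSG nights calibrated to a target sleep
efficiency distribution (default mean 0.71, SD 0.10) and stage mix (N3 20%,
N2 47.5%, N1 18%, REM 14.4% of TST); device streams corrupted by per-stage
confusion profiles, clock lag, 60-s re-gridding, missing-data runs and
analysis-period error; per-epoch EEG with stage-dependent delta power.

## Worked example

```python
from hypnoval import (CohortConfig, EvaluationConfig, device_preset,
                      run_evaluation, simulate_cohort)

cfg = CohortConfig(n_subjects=12, seed=5)
profiles = [device_preset(n) for n in
            ("aws_like", "wsa_like", "emfit_like", "somnofy_like")]
nights = simulate_cohort(cfg, profiles, seed=5)
bundle = run_evaluation(nights, EvaluationConfig(windows=("TRT",)))
ebe = bundle["ebe_metrics"]
print(ebe[ebe.stage == "SLEEP_WAKE"]
      .set_index("device")[["sensitivity_mean", "specificity_mean", "mcc_mean"]]
      .round(2))
```

prints

```
              sensitivity_mean  specificity_mean  mcc_mean
aws_like                  0.95              0.32      0.36
emfit_like                0.99              0.22      0.36
somnofy_like              0.97              0.59      0.64
wsa_like                  0.95              0.36      0.41
```

i.e. the undermattress presets detect nearly every sleep epoch (sensitivity
≥ 0.95) but call most in-bed wake "sleep" (specificity 0.22–0.36), while the
bedside-radar preset discriminates wake far better — the class-imbalance-
robust MCC makes that visible where raw accuracy would not. The
`examples/` directory has one short narrative script per capability
(summaries, agreement, concordance, SWA, full evaluation + ranking), and the
same pipeline is scriptable from a shell:

```
hypnoval simulate --out cohort/ --seed 5
hypnoval evaluate --manifest cohort/manifest.json --out results/ --seed 5
hypnoval report --results results/
```

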