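"""Synthetic cohort generator: PSG nights, device observations, and EEG.

The generator emulates the statistical structure of an older-adult in-lab
validation cohort so that every pipeline stage is testable without real data:

* Reference (PSG) nights are first-order Markov chains over {W, N1, N2, N3,
  REM} on 30-s epochs inside a lights-off analysis period.  Each subject's
  wake-exit rate is solved by bisection so the night's expected sleep
  efficiency hits a subject-level target drawn from the configured cohort
  distribution (mean 0.71, SD 0.10 — mildly disturbed sleep, as under a
  first-night effect); stage proportions within sleep follow the configured
  mix (N3 20%, N2 47.5%, N1 18%, REM 14.4% of TST).
* Device streams corrupt the reference through a per-stage confusion table,
  optional run-length smoothing, a clock lag, re-gridding to 60-s epochs,
  missing/no-presence (ABSENT) runs, and an erroneous automatically detected
  analysis period — the error modes the evaluation pipeline must undo.
* EEG is per-epoch band-limited delta noise whose stage-dependent power and
  subject-level multiplier support slow-wave-activity recovery tests.

All randomness flows from explicit seeds; per-subject streams are spawned
deterministically from the master seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .hypnogram import (
    AnalysisPeriod,
    Hypnogram,
    HypnogramError,
    map_stages,
    write_analysis_period,
    write_hypnogram,
)
from .spectral import EEGSignal

__all__ = [
    "CohortConfig",
    "DeviceProfile",
    "SyntheticNight",
    "simulate_psg_hypnogram",
    "simulate_device_hypnogram",
    "simulate_eeg",
    "simulate_cohort",
    "write_cohort",
    "device_preset",
    "DEVICE_PRESETS",
]

_STAGES = ("W", "N1", "N2", "N3", "REM")
_DEFAULT_START = datetime(2021, 6, 1, 21, 30, 0)


@dataclass
class CohortConfig:
    """Cohort-level generator parameters (defaults emulate the study cohort)."""

    n_subjects: int = 35
    trt_min: float = 600.0
    ap_min_mean: float = 543.0
    ap_min_sd: float = 36.0
    seff_mean: float = 0.71
    seff_sd: float = 0.10
    # fractions of total sleep time; normalized at use
    stage_props: dict[str, float] = field(
        default_factory=lambda: {"N3": 0.1998, "N2": 0.4749, "N1": 0.1812, "REM": 0.1441}
    )
    sol_mean_min: float = 15.0
    # between-subject SD of the N3 share of sleep (cohorts of older adults
    # differ widely in deep-sleep amounts; ~8 percentage points of TST)
    n3_prop_sd: float = 0.0785
    # per-epoch probability of leaving sleep for wake (sets wake-bout structure)
    wake_entry_prob: float = 0.0136
    # per-epoch probability of switching sleep stage (redraw from stage_props)
    stage_switch_rate: float = 0.10
    artifact_rate: float = 0.005
    seed: int = 0

    def props_normalized(self) -> dict[str, float]:
        total = sum(self.stage_props.values())
        if not math.isclose(total, 1.0, abs_tol=0.05):
            raise ValueError(f"stage_props sum {total} far from 1")
        return {k: v / total for k, v in self.stage_props.items()}


@dataclass
class DeviceProfile:
    """Error profile of one device; rows of ``confusion`` must sum to 1.

    ``confusion`` maps each four-stage reference label (W/LS/DS/REM) to a
    probability table over predicted labels (W/LS/DS/REM for stage-capable
    devices, W/SLEEP for binary actigraphy-like ones).
    """

    name: str
    epoch_len: int = 30
    confusion: dict[str, dict[str, float]] = field(default_factory=dict)
    lag_epochs: int = 0
    ap_start_error_min: float = 0.0
    ap_end_error_min: float = 0.0
    ap_error_sd_min: float = 5.0
    p_absent: float = 0.0
    absent_mean_run: float = 10.0
    smoothing_run: int = 1

    def __post_init__(self) -> None:
        if abs(self.lag_epochs) > 10:
            raise ValueError(f"|lag_epochs| must be <= 10, got {self.lag_epochs}")
        if self.epoch_len not in (30, 60):
            raise ValueError(f"epoch_len must be 30 or 60, got {self.epoch_len}")
        for row_label, row in self.confusion.items():
            s = sum(row.values())
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ValueError(
                    f"confusion row {row_label!r} of profile {self.name!r} sums to {s}, not 1"
                )


@dataclass
class SyntheticNight:
    """One simulated subject: PSG truth, device observations, periods, EEG."""

    subject_id: str
    psg: Hypnogram
    ap_manual: AnalysisPeriod
    devices: dict[str, Hypnogram]
    ap_auto: dict[str, AnalysisPeriod]
    eeg: EEGSignal | None = None
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reference (PSG) nights
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _run_chain(a: float, b: float, switch: float, u_trans: np.ndarray,
               u_switch: np.ndarray, stage_draws: np.ndarray) -> np.ndarray:
    """Wake/sleep chain under common random numbers; returns stage indices.

    0 = wake; 1..4 = sleep stage index into the configured mix.  ``a`` is
    the per-epoch wake-exit probability, ``b`` the sleep-exit probability,
    ``switch`` the within-sleep stage-redraw rate.  Because the uniforms are
    fixed, the realized sleep fraction is (near-)monotone in ``a``, which
    makes bisection on the realized fraction well behaved.
    """
    n = len(u_trans)
    out = np.zeros(n, dtype=np.int8)
    state = 0
    for i in range(n):
        if state == 0:
            if u_trans[i] < a:
                state = stage_draws[i]
        else:
            if u_trans[i] < b:
                state = 0
            elif u_switch[i] < switch:
                state = stage_draws[i]
        out[i] = state
    return out


def _solve_wake_exit(target_seff: float, b: float, switch: float,
                     u_trans: np.ndarray, u_switch: np.ndarray,
                     stage_draws: np.ndarray) -> tuple[float, np.ndarray]:
    """Bisect the wake-exit probability until the realized sleep fraction
    of the common-random-numbers night hits the subject's target."""
    n = len(u_trans)

    def frac(a: float) -> tuple[float, np.ndarray]:
        states = _run_chain(a, b, switch, u_trans, u_switch, stage_draws)
        return float(np.count_nonzero(states) / n), states

    lo, hi = 1e-5, 0.999
    f_hi, states_hi = frac(hi)
    if f_hi < target_seff:
        raise HypnogramError(
            f"SEFF target {target_seff} infeasible with wake-entry prob {b}"
        )
    best_a, best_states, best_err = hi, states_hi, abs(f_hi - target_seff)
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        f_mid, states_mid = frac(mid)
        err = abs(f_mid - target_seff)
        if err < best_err:
            best_a, best_states, best_err = mid, states_mid, err
        if f_mid < target_seff:
            lo = mid
        else:
            hi = mid
    return best_a, best_states


def simulate_psg_hypnogram(
    c: CohortConfig, subject_seed: int, subject_id: str = "S000",
    start: datetime = _DEFAULT_START,
) -> tuple[Hypnogram, AnalysisPeriod, dict]:
    """One reference night: FIVE-vocabulary hypnogram over the TRT + AP-M.

    Epochs outside the lights-off period are wake; inside it a Markov chain
    alternates wake and sleep bouts with the subject's solved wake-exit rate,
    and sleep epochs carry stages redrawn from the configured mix at the
    stage-switch rate.  Returns (hypnogram, manual analysis period, truth
    record of the parameters actually used).
    """
    rng = np.random.default_rng(subject_seed)
    props = c.props_normalized()
    # subject-level stage mix: N3 share varies between subjects, the other
    # stages share the remainder in their configured ratios
    if c.n3_prop_sd > 0:
        n3 = _truncated_normal(rng, props["N3"], c.n3_prop_sd, 0.03, 0.40)
        rest = 1.0 - props["N3"]
        props = {s: (n3 if s == "N3" else p * (1.0 - n3) / rest)
                 for s, p in props.items()}
    stage_names = [s for s in _STAGES if s != "W"]
    stage_p = np.array([props[s] for s in stage_names])

    n_trt = int(round(c.trt_min * 2))  # 30-s epochs
    ap_min = _truncated_normal(rng, c.ap_min_mean, c.ap_min_sd,
                               0.6 * c.ap_min_mean, c.trt_min)
    n_ap = min(int(round(ap_min * 2)), n_trt)
    offset = (n_trt - n_ap) // 2

    seff_target = _truncated_normal(rng, c.seff_mean, c.seff_sd, 0.45, 0.95)
    b = c.wake_entry_prob
    u_trans = rng.random(n_ap)
    u_switch = rng.random(n_ap)
    # stage indices 1..n_sleep_stages drawn from the configured mix
    stage_draws = 1 + rng.choice(len(stage_names), size=n_ap, p=stage_p).astype(np.int8)
    a, states = _solve_wake_exit(seff_target, b, c.stage_switch_rate,
                                 u_trans, u_switch, stage_draws)

    labels = ["W"] * n_trt
    for j, s in enumerate(states):
        labels[offset + j] = "W" if s == 0 else stage_names[s - 1]
    # reference artifact epochs (scorer-rejected), inside the AP only
    if c.artifact_rate > 0:
        art = rng.random(n_ap) < c.artifact_rate
        for j, is_art in enumerate(art):
            if is_art:
                labels[offset + j] = "ART"

    h = Hypnogram(start=start, epoch_len=30, labels=tuple(labels),
                  vocabulary="FIVE", subject_id=subject_id, source="reference")
    ap = AnalysisPeriod(
        t_start=start + timedelta(seconds=30 * offset),
        t_end=start + timedelta(seconds=30 * (offset + n_ap)),
        kind="manual",
    )
    truth = {
        "seff_target": seff_target, "ap_min": n_ap / 2.0,
        "wake_exit_prob": a, "wake_entry_prob": b,
        "stage_props": props, "subject_seed": subject_seed,
    }
    return h, ap, truth


# ---------------------------------------------------------------------------
# Device observations
# ---------------------------------------------------------------------------

def _mode_filter(labels: list[str], window: int) -> list[str]:
    """Sliding majority filter enforcing a minimum run length (ties keep self)."""
    if window <= 1:
        return labels
    half = window // 2
    n = len(labels)
    out = list(labels)
    for i in range(n):
        seg = labels[max(0, i - half): min(n, i + half + 1)]
        counts: dict[str, int] = {}
        for lab in seg:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        if counts.get(labels[i], 0) < best:
            out[i] = max(counts, key=lambda k: (counts[k], k == labels[i]))
    return out


def _snap_to_grid(t: datetime, anchor: datetime, step: int) -> datetime:
    k = round((t - anchor).total_seconds() / step)
    return anchor + timedelta(seconds=k * step)


def simulate_device_hypnogram(
    ref: Hypnogram, p: DeviceProfile, seed: int,
    ap_manual: AnalysisPeriod | None = None,
) -> tuple[Hypnogram, AnalysisPeriod]:
    """Corrupt a reference night into one device's observed stream + its AP-A.

    Order of corruption: stage confusion sampling on the 30-s grid, run-length
    (majority) smoothing, clock lag, re-gridding to the device epoch length
    (majority of the two 30-s halves, ties to the first half), ABSENT runs,
    and ABSENT outside the device-detected period, which is the manual period
    perturbed by the profile's start/end errors.
    """
    if ref.epoch_len != 30:
        raise HypnogramError("device simulation expects a 30-s reference")
    rng = np.random.default_rng(seed)
    four = map_stages(ref, "FOUR_DEFAULT") if ref.vocabulary == "FIVE" else ref
    if ap_manual is None:
        ap_manual = ref.span()

    # device-detected period: manual period +/- timing errors, snapped to grid
    t0 = ap_manual.t_start + timedelta(
        minutes=float(rng.normal(p.ap_start_error_min, p.ap_error_sd_min)))
    t1 = ap_manual.t_end + timedelta(
        minutes=float(rng.normal(p.ap_end_error_min, p.ap_error_sd_min)))
    t0 = max(_snap_to_grid(t0, ref.start, 30), ref.start)
    t1 = min(_snap_to_grid(t1, ref.start, 30), ref.end)
    if t1 <= t0:
        t0, t1 = ap_manual.t_start, ap_manual.t_end
    ap_auto = AnalysisPeriod(t0, t1, kind="automatic")

    # 1. per-epoch confusion sampling
    labels: list[str] = []
    for lab in four.labels:
        row_label = "W" if lab in ("ART", "ABSENT") else lab
        row = p.confusion[row_label]
        keys = list(row.keys())
        labels.append(keys[rng.choice(len(keys), p=np.array(list(row.values())))])

    # 2. minimum-run-length smoothing
    labels = _mode_filter(labels, p.smoothing_run)

    # 3. clock lag: device content trails (lag>0) or leads (lag<0) the reference
    if p.lag_epochs:
        n = len(labels)
        shifted = ["ABSENT"] * n
        for i in range(n):
            j = i - p.lag_epochs
            if 0 <= j < n:
                shifted[i] = labels[j]
        labels = shifted

    # 4. spontaneous ABSENT (missing / no-presence) runs
    if p.p_absent > 0:
        i = 0
        while i < len(labels):
            if rng.random() < p.p_absent:
                run = 1 + rng.geometric(1.0 / p.absent_mean_run)
                for j in range(i, min(i + run, len(labels))):
                    labels[j] = "ABSENT"
                i += run
            else:
                i += 1

    # 5. no observation outside the device-detected period
    i0 = int((ap_auto.t_start - ref.start).total_seconds() // 30)
    i1 = int((ap_auto.t_end - ref.start).total_seconds() // 30)
    for i in range(len(labels)):
        if i < i0 or i >= i1:
            labels[i] = "ABSENT"

    vocab = "TWO" if any("SLEEP" in row for row in p.confusion.values()) else "FOUR"

    # 6. re-grid to the device's native epoch length
    if p.epoch_len == 60:
        # majority label of the two 30-s halves; a 1-1 tie goes to the first
        # half, so the rule reduces to keeping the first half's label
        labels = [labels[2 * k] for k in range(len(labels) // 2)]

    dev = Hypnogram(start=ref.start, epoch_len=p.epoch_len, labels=tuple(labels),
                    vocabulary=vocab, subject_id=ref.subject_id, source="device")
    return dev, ap_auto


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

_DEFAULT_SWA_BY_STAGE = {
    # (mean band power uV^2, lognormal sigma) per 30-s epoch
    "N3": (400.0, 0.3), "N2": (120.0, 0.3), "N1": (60.0, 0.3),
    "REM": (40.0, 0.3), "W": (30.0, 0.3), "ART": (30.0, 0.3), "ABSENT": (30.0, 0.3),
    "LS": (100.0, 0.3), "DS": (400.0, 0.3),
}


def simulate_eeg(
    ref: Hypnogram,
    swa_by_stage: dict[str, tuple[float, float]] | None = None,
    multiplier: float = 1.0,
    seed: int = 0,
    fs: float = 128.0,
    background_sd: float = 2.0,
) -> EEGSignal:
    """Band-limited delta noise per 30-s epoch with stage-dependent power.

    Each epoch's 0.75–4.5 Hz variance is drawn log-normally around the stage
    mean, scaled by the subject-level ``multiplier`` (the hook that couples a
    subject's slow-wave activity to their deep-sleep duration in cohort
    simulation), on top of a small broadband background.
    """
    from scipy import signal as sp_signal

    table = swa_by_stage or _DEFAULT_SWA_BY_STAGE
    for stage, (mean, _) in table.items():
        if mean < 0:
            raise ValueError(f"non-positive SWA mean for stage {stage!r}")
    rng = np.random.default_rng(seed)
    spe = int(round(fs * 30))
    n_ep = len(ref.labels)
    sos = sp_signal.butter(4, [0.75, 4.5], btype="bandpass", fs=fs, output="sos")
    # one long band-limited noise stream, then per-epoch variance scaling
    band = sp_signal.sosfiltfilt(sos, rng.standard_normal(n_ep * spe))
    band = band.reshape(n_ep, spe)
    means = np.array([table[lab][0] for lab in ref.labels])
    sigmas = np.array([table[lab][1] for lab in ref.labels])
    targets = means * multiplier * rng.lognormal(-0.5 * sigmas**2, sigmas)
    v = band.var(axis=1)
    scale = np.where((v > 0) & (targets > 0), np.sqrt(targets / np.maximum(v, 1e-30)), 0.0)
    out = band * scale[:, None]
    if background_sd > 0:
        out = out + rng.standard_normal(out.shape) * background_sd
    return EEGSignal(fs=fs, samples=out.ravel(), start=ref.start, channel="F3-M2")


# ---------------------------------------------------------------------------
# Device presets
# ---------------------------------------------------------------------------
# Calibrated so the binary marginals (sleep sensitivity, wake specificity)
# and per-stage sensitivities match the published validation profile of each
# device class; the split of errors among wrong sleep stages is assumed.

DEVICE_PRESETS: dict[str, dict] = {
    # undermattress sensor, 60-s epochs, detects bed presence early/late
    "wsa_like": dict(
        epoch_len=60,
        confusion={
            "W":   {"W": 0.37, "LS": 0.40, "DS": 0.13, "REM": 0.10},
            "LS":  {"W": 0.05, "LS": 0.54, "DS": 0.21, "REM": 0.20},
            "DS":  {"W": 0.05, "LS": 0.12, "DS": 0.79, "REM": 0.04},
            "REM": {"W": 0.05, "LS": 0.40, "DS": 0.15, "REM": 0.40},
        },
        lag_epochs=2, ap_start_error_min=-20.0, ap_end_error_min=15.0,
        ap_error_sd_min=10.0, p_absent=0.001,
    ),
    # undermattress sensor, 30-s epochs, very low wake specificity
    "emfit_like": dict(
        epoch_len=30,
        confusion={
            "W":   {"W": 0.22, "LS": 0.50, "DS": 0.18, "REM": 0.10},
            "LS":  {"W": 0.01, "LS": 0.63, "DS": 0.20, "REM": 0.16},
            "DS":  {"W": 0.01, "LS": 0.48, "DS": 0.39, "REM": 0.12},
            "REM": {"W": 0.01, "LS": 0.55, "DS": 0.19, "REM": 0.25},
        },
        lag_epochs=-1, ap_start_error_min=-30.0, ap_end_error_min=20.0,
        ap_error_sd_min=12.0, p_absent=0.002,
    ),
    # bedside radar, 30-s epochs, uses ambient light so its period is accurate
    "somnofy_like": dict(
        epoch_len=30,
        confusion={
            "W":   {"W": 0.58, "LS": 0.28, "DS": 0.08, "REM": 0.06},
            "LS":  {"W": 0.03, "LS": 0.67, "DS": 0.18, "REM": 0.12},
            "DS":  {"W": 0.03, "LS": 0.38, "DS": 0.54, "REM": 0.05},
            "REM": {"W": 0.03, "LS": 0.27, "DS": 0.08, "REM": 0.62},
        },
        lag_epochs=1, ap_start_error_min=-2.0, ap_end_error_min=2.0,
        ap_error_sd_min=3.0, p_absent=0.001,
    ),
    # wrist actigraphy, 60-s epochs, binary sleep/wake vocabulary
    "aws_like": dict(
        epoch_len=60,
        confusion={
            "W":   {"W": 0.34, "SLEEP": 0.66},
            "LS":  {"W": 0.05, "SLEEP": 0.95},
            "DS":  {"W": 0.05, "SLEEP": 0.95},
            "REM": {"W": 0.05, "SLEEP": 0.95},
        },
        lag_epochs=0, ap_start_error_min=0.0, ap_end_error_min=0.0,
        ap_error_sd_min=2.0, p_absent=0.0,
    ),
}


def device_preset(name: str) -> DeviceProfile:
    """Instantiate a named device profile preset."""
    if name not in DEVICE_PRESETS:
        raise KeyError(f"unknown device preset {name!r}; have {sorted(DEVICE_PRESETS)}")
    return DeviceProfile(name=name, **DEVICE_PRESETS[name])


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    c: CohortConfig,
    profiles: list[DeviceProfile],
    seed: int | None = None,
    with_eeg: bool = False,
    eeg_coupling: float = 0.77,
    eeg_sigma_m: float = 0.4,
    eeg_fs: float = 128.0,
) -> list[SyntheticNight]:
    """Simulate ``c.n_subjects`` nights, each observed by every profile.

    Per-subject seeds are spawned deterministically from the master seed.
    When ``with_eeg`` is set, subject-level slow-wave-activity multipliers
    are drawn log-normally with correlation ``eeg_coupling`` against the
    cohort's realized N3 durations, so deep-sleep/SWA regressions have a
    known configured coupling to recover.
    """
    master = c.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    subject_seeds = ss.generate_state(4 * c.n_subjects).reshape(c.n_subjects, 4)

    nights: list[SyntheticNight] = []
    for j in range(c.n_subjects):
        sid = f"S{j:03d}"
        psg_seed, dev_seed_base, eeg_seed, _ = (int(x) % (2**31) for x in subject_seeds[j])
        psg, ap_m, truth = simulate_psg_hypnogram(c, psg_seed, subject_id=sid)
        devices: dict[str, Hypnogram] = {}
        ap_auto: dict[str, AnalysisPeriod] = {}
        for k, prof in enumerate(profiles):
            dev, ap_a = simulate_device_hypnogram(
                psg, prof, seed=(dev_seed_base + 1000003 * k) % (2**31),
                ap_manual=ap_m)
            devices[prof.name] = dev
            ap_auto[prof.name] = ap_a
        truth["eeg_seed"] = eeg_seed
        nights.append(SyntheticNight(subject_id=sid, psg=psg, ap_manual=ap_m,
                                     devices=devices, ap_auto=ap_auto, truth=truth))

    if with_eeg and nights:
        rng = np.random.default_rng(np.random.SeedSequence([master, 77]).generate_state(1)[0])
        n3 = np.array([sum(lab == "N3" for lab in nt.psg.labels) / 2.0 for nt in nights])
        z = (n3 - n3.mean()) / n3.std() if n3.std() > 0 else np.zeros_like(n3)
        eps = rng.standard_normal(len(nights))
        logm = eeg_sigma_m * (eeg_coupling * z
                              + math.sqrt(max(0.0, 1 - eeg_coupling**2)) * eps)
        for nt, lm in zip(nights, logm):
            nt.truth["swa_multiplier"] = float(np.exp(lm))
            nt.eeg = simulate_eeg(nt.psg, multiplier=float(np.exp(lm)),
                                  seed=nt.truth["eeg_seed"], fs=eeg_fs)
    return nights


def write_cohort(nights: list[SyntheticNight], out_dir: str | Path,
                 config: CohortConfig | None = None) -> Path:
    """Write a cohort as hypnogram CSVs + period JSONs + a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": [], "devices": sorted({d for nt in nights for d in nt.devices})}
    if config is not None:
        manifest["config"] = {
            "n_subjects": config.n_subjects, "trt_min": config.trt_min,
            "ap_min_mean": config.ap_min_mean, "ap_min_sd": config.ap_min_sd,
            "seff_mean": config.seff_mean, "seff_sd": config.seff_sd,
            "seed": config.seed,
        }
    for nt in nights:
        sdir = out / nt.subject_id
        sdir.mkdir(exist_ok=True)
        write_hypnogram(nt.psg, sdir / "psg.csv")
        write_analysis_period(nt.ap_manual, sdir / "ap_manual.json")
        entry = {"subject_id": nt.subject_id, "psg": f"{nt.subject_id}/psg.csv",
                 "ap_manual": f"{nt.subject_id}/ap_manual.json", "devices": {}}
        for name, dev in nt.devices.items():
            write_hypnogram(dev, sdir / f"{name}.csv")
            write_analysis_period(nt.ap_auto[name], sdir / f"{name}_ap.json")
            entry["devices"][name] = {
                "hypnogram": f"{nt.subject_id}/{name}.csv",
                "ap_auto": f"{nt.subject_id}/{name}_ap.json",
            }
        manifest["subjects"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return out / "manifest.json"
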