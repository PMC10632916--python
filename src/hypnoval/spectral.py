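"""Slow-wave-activity (SWA) quantification from a single EEG channel.

SWA is the EEG power in the 0.75–4.5 Hz delta band during NREM sleep, a
continuous physiological correlate of deep sleep that avoids the arbitrary
amplitude criterion of visual N3 scoring.  The pipeline is: FFT periodograms
of Hamming-tapered 4-s windows, summed over the delta band to a per-window
band power (µV²); averaged into 30-s epochs aligned with the hypnogram grid
(seven non-overlapping 4-s windows per epoch — the first 28 s; the trailing
2 s are dropped); averaged over NREM epochs to a per-night mean SWA; and an
OLS regression of device deep-sleep duration on mean NREM SWA across
participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy import signal, stats

from .hypnogram import Hypnogram

__all__ = [
    "EEGSignal",
    "SWASeries",
    "SpectralError",
    "band_power_4s",
    "swa_per_30s",
    "swa_from_eeg",
    "mean_swa_nrem",
    "ds_swa_regression",
    "SWA_BAND",
    "WINDOWS_PER_EPOCH",
]

SWA_BAND = (0.75, 4.5)  # Hz, inclusive band edges
WINDOW_S = 4
WINDOWS_PER_EPOCH = 7  # 7 x 4 s = 28 s of each 30-s epoch


class SpectralError(Exception):
    pass


@dataclass
class EEGSignal:
    """Single-channel EEG: sampling rate (Hz), samples (µV), clock anchor."""

    fs: float
    samples: np.ndarray
    start: datetime | None = None
    channel: str = "F3-M2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs < 64:
            raise SpectralError(f"sampling rate {self.fs} Hz too low (need >= 64)")
        if len(self.samples) < int(self.fs * WINDOW_S):
            raise SpectralError("signal shorter than one 4-s window")


@dataclass
class SWASeries:
    """Per-30-s-epoch delta band power (µV²), grid-aligned with a hypnogram."""

    values: np.ndarray
    start: datetime | None = None
    epoch_len: int = 30
    n_dropped_windows: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def band_power_4s(sig: EEGSignal) -> np.ndarray:
    """Delta-band power of each non-overlapping Hamming-tapered 4-s window.

    Each window is tapered and periodogram-scaled so that summing the PSD
    over the 0.75–4.5 Hz bins (inclusive) returns band power in µV²: an
    in-band tone of amplitude A yields ≈ A²/2 (Parseval with window power
    normalization).  A trailing partial window is dropped.
    """
    nwin = int(round(sig.fs * WINDOW_S))
    if abs(sig.fs * WINDOW_S - nwin) > 1e-9:
        raise SpectralError(f"fs*{WINDOW_S} must be an integer window length, fs={sig.fs}")
    n_windows = len(sig.samples) // nwin
    if n_windows == 0:
        raise SpectralError("signal shorter than one 4-s window")
    x = sig.samples[: n_windows * nwin].reshape(n_windows, nwin)
    freqs, psd = signal.periodogram(
        x, fs=sig.fs, window="hamming", detrend=False, scaling="density", axis=-1
    )
    df = freqs[1] - freqs[0]
    band = (freqs >= SWA_BAND[0]) & (freqs <= SWA_BAND[1])
    return psd[:, band].sum(axis=1) * df


def swa_per_30s(powers, start: datetime | None = None) -> SWASeries:
    """Average consecutive 4-s band powers into 30-s epochs (7 windows each).

    The windowing layout restarts at each 30-s epoch boundary, so each epoch
    owns exactly seven 4-s windows covering its first 28 s.  Trailing windows
    short of a full epoch are dropped and their count reported.
    """
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise SpectralError("empty band-power sequence")
    n_epochs = len(powers) // WINDOWS_PER_EPOCH
    dropped = len(powers) - n_epochs * WINDOWS_PER_EPOCH
    if n_epochs == 0:
        raise SpectralError(
            f"need at least {WINDOWS_PER_EPOCH} windows for one 30-s epoch, got {len(powers)}"
        )
    vals = powers[: n_epochs * WINDOWS_PER_EPOCH].reshape(n_epochs, WINDOWS_PER_EPOCH).mean(axis=1)
    return SWASeries(values=vals, start=start, n_dropped_windows=dropped)


def swa_from_eeg(sig: EEGSignal) -> SWASeries:
    """Full per-epoch SWA pipeline: per-epoch 4-s windowing, then averaging.

    Windows are taken from the first 28 s of each 30-s epoch, so the layout
    matches :func:`swa_per_30s` exactly.
    """
    nwin = int(round(sig.fs * WINDOW_S))
    samples_per_epoch = int(round(sig.fs * 30))
    n_epochs = len(sig.samples) // samples_per_epoch
    if n_epochs == 0:
        raise SpectralError("signal shorter than one 30-s epoch")
    used = sig.samples[: n_epochs * samples_per_epoch].reshape(n_epochs, samples_per_epoch)
    # first 28 s of each epoch as 7 windows of 4 s, all windowed in one call
    windows = used[:, : WINDOWS_PER_EPOCH * nwin].reshape(
        n_epochs * WINDOWS_PER_EPOCH, nwin)
    freqs, psd = signal.periodogram(
        windows, fs=sig.fs, window="hamming", detrend=False, scaling="density", axis=-1
    )
    df = freqs[1] - freqs[0]
    band = (freqs >= SWA_BAND[0]) & (freqs <= SWA_BAND[1])
    powers = psd[:, band].sum(axis=1) * df
    return swa_per_30s(powers, start=sig.start)


_NREM_TOKENS = {"N1", "N2", "N3", "LS", "DS", "NREM"}


def mean_swa_nrem(swa: SWASeries, h: Hypnogram) -> float:
    """Mean delta power over the night's NREM epochs (N1/N2/N3 or LS/DS).

    The SWA series and hypnogram must share the 30-s grid; the overlap of the
    two sequences is used.  Returns NaN (flagged undefined) when the night
    has no NREM epoch.
    """
    n = min(len(swa.values), len(h.labels))
    mask = np.array([h.labels[i] in _NREM_TOKENS for i in range(n)])
    if not mask.any():
        return float("nan")
    return float(swa.values[:n][mask].mean())


def ds_swa_regression(ds_min, swa):
    """OLS of per-participant deep-sleep duration on mean NREM SWA.

    Returns (slope, intercept, r², two-sided p for zero slope).  This is the
    cross-participant check of whether a device's deep-sleep durations track
    the physiological slow-wave activity measured by PSG.
    """
    ds_min = np.asarray(ds_min, dtype=float)
    swa = np.asarray(swa, dtype=float)
    if len(ds_min) != len(swa) or len(ds_min) < 3:
        raise SpectralError("regression requires >= 3 aligned (DS, SWA) pairs")
    if np.ptp(swa) == 0:
        raise SpectralError("regression undefined: constant predictor")
    res = stats.linregress(swa, ds_min)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
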