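"""All-night sleep summary measures from a hypnogram under an analysis period.

Definitions follow standard polysomnography conventions: TST is the total time
spent asleep within the analysis period (AP); SOL (sleep-onset latency) the
time from the start of the AP to the first sleep-labeled epoch; WASO (wake
after sleep onset) the wake time from sleep onset to the end of the AP,
terminal wake included, so that wake = SOL + WASO; SEFF (sleep efficiency) is
TST as a percentage of the AP duration by default (total recording time is
selectable as the denominator).  Artifact and absent epochs inside the AP
count toward neither sleep nor wake and are tracked as ``artifact_min``, so
that SOL + TST + WASO + artifact = AP exactly on an epoch-aligned period.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from datetime import timedelta

from .hypnogram import (
    AnalysisPeriod,
    Hypnogram,
    HypnogramError,
    SLEEP_TOKENS,
    crop_to_period,
)

__all__ = ["SleepSummary", "compute_summary", "infer_ap_auto"]

_LS_TOKENS = {"N1", "N2", "LS"}
_DS_TOKENS = {"N3", "DS"}


@dataclass
class SleepSummary:
    """One night's sleep summary under one analysis period.  Minutes except SEFF (%)."""

    ap_min: float
    trt_min: float
    tst_min: float
    sol_min: float
    waso_min: float
    seff_pct: float
    ls_min: float
    ds_min: float
    rem_min: float
    nrem_min: float
    wake_min: float
    artifact_min: float = 0.0
    no_sleep: bool = False

    def to_row(self) -> dict[str, float]:
        """Flat row keyed by measure name (AP, TST, SOL, WASO, SEFF, REM, NREM, LS, DS)."""
        return {
            "AP": self.ap_min,
            "TRT": self.trt_min,
            "TST": self.tst_min,
            "SOL": self.sol_min,
            "WASO": self.waso_min,
            "SEFF": self.seff_pct,
            "REM": self.rem_min,
            "NREM": self.nrem_min,
            "LS": self.ls_min,
            "DS": self.ds_min,
            "WAKE": self.wake_min,
        }

    def as_dict(self) -> dict:
        return asdict(self)


def compute_summary(
    h: Hypnogram,
    ap: AnalysisPeriod | None = None,
    seff_denominator: str = "AP",
    trt_min: float | None = None,
) -> SleepSummary:
    """Compute TST/SOL/WASO/SEFF and stage durations for one night.

    Parameters
    ----------
    h : Hypnogram
        Vocabulary FIVE or FOUR (THREE/TWO also accepted; stage fields that
        are not resolvable at that vocabulary are reported as 0 and folded
        into NREM/TST as appropriate).
    ap : AnalysisPeriod, optional
        Defaults to the hypnogram's full span.
    seff_denominator : {"AP", "TRT"}
        Sleep-efficiency denominator: AP duration (default) or total
        recording time (``trt_min``, falling back to the uncropped span).
    trt_min : float, optional
        Total recording time in minutes for the TRT denominator.
    """
    if seff_denominator not in ("AP", "TRT"):
        raise ValueError(f"seff_denominator must be 'AP' or 'TRT', got {seff_denominator!r}")
    full_span_min = h.duration_min
    if ap is None:
        ap = h.span()
    else:
        h = crop_to_period(h, ap)
    if len(h) == 0:
        raise HypnogramError("empty analysis period")

    epoch_min = h.epoch_len / 60.0
    ap_min = ap.duration_min
    trt = trt_min if trt_min is not None else full_span_min

    labels = h.labels
    onset_idx = next((i for i, lab in enumerate(labels) if lab in SLEEP_TOKENS), None)

    n_art = sum(1 for lab in labels if lab in ("ART", "ABSENT"))
    artifact_min = n_art * epoch_min

    if onset_idx is None:
        # no sleep: the whole period is latency, except artifact time, so the
        # SOL + TST + WASO + artifact = AP identity still holds
        return SleepSummary(
            ap_min=ap_min, trt_min=trt, tst_min=0.0, sol_min=ap_min - artifact_min,
            waso_min=0.0,
            seff_pct=0.0, ls_min=0.0, ds_min=0.0, rem_min=0.0, nrem_min=0.0,
            wake_min=sum(1 for lab in labels if lab == "W") * epoch_min,
            artifact_min=artifact_min, no_sleep=True,
        )

    # SOL measured from the AP start to the first sleep epoch's clock time, so
    # a device stream that starts after lights-off still charges the gap as
    # latency.  On a fully covering, epoch-aligned hypnogram this equals
    # onset_idx * epoch_min.  Artifact epochs before onset count toward
    # neither latency nor wake (they stay in artifact_min), preserving the
    # SOL + TST + WASO + artifact = AP identity.
    art_before_onset = sum(1 for lab in labels[:onset_idx] if lab in ("ART", "ABSENT"))
    sol_min = ((h.epoch_start(onset_idx) - ap.t_start).total_seconds() / 60.0
               - art_before_onset * epoch_min)

    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1

    ls_min = sum(counts.get(t, 0) for t in _LS_TOKENS) * epoch_min
    ds_min = sum(counts.get(t, 0) for t in _DS_TOKENS) * epoch_min
    rem_min = counts.get("REM", 0) * epoch_min
    # NREM token appears in THREE-vocabulary streams; SLEEP in binary ones
    nrem_min = ls_min + ds_min + counts.get("NREM", 0) * epoch_min
    tst_min = nrem_min + rem_min + counts.get("SLEEP", 0) * epoch_min

    waso_min = sum(1 for lab in labels[onset_idx:] if lab == "W") * epoch_min
    wake_min = sol_min + waso_min

    denom = ap_min if seff_denominator == "AP" else trt
    seff_pct = 100.0 * tst_min / denom if denom > 0 else 0.0

    return SleepSummary(
        ap_min=ap_min, trt_min=trt, tst_min=tst_min, sol_min=sol_min,
        waso_min=waso_min, seff_pct=seff_pct, ls_min=ls_min, ds_min=ds_min,
        rem_min=rem_min, nrem_min=nrem_min, wake_min=wake_min,
        artifact_min=artifact_min, no_sleep=False,
    )


def infer_ap_auto(h_device: Hypnogram) -> AnalysisPeriod:
    """Device-detected analysis period: first to one-past-last non-ABSENT epoch.

    Stands in for the in-bed period consumer devices report as metadata; the
    synthetic generator marks out-of-bed epochs ABSENT, so occupancy bounds
    recover the device's own period.
    """
    idx = [i for i, lab in enumerate(h_device.labels) if lab != "ABSENT"]
    if not idx:
        raise HypnogramError("cannot infer analysis period: all epochs ABSENT")
    t0 = h_device.epoch_start(idx[0])
    t1 = h_device.epoch_start(idx[-1]) + timedelta(seconds=h_device.epoch_len)
    return AnalysisPeriod(t0, t1, kind="automatic")
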