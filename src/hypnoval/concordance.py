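"""Epoch-by-epoch concordance between a device hypnogram and reference PSG.

Covers cross-correlation lag alignment within a ±10-epoch window, confusion
matrices at 2/3/4-stage resolution, per-class one-vs-rest metrics (sensitivity,
specificity, accuracy, F1, Matthews correlation coefficient — MCC is robust to
the heavy sleep/wake class imbalance of an overnight recording), participant
aggregation with normal-approximation CIs, pooling of per-participant matrices,
and satisfactory-agreement flags against published inter-rater reliability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .hypnogram import (
    EpochPairs,
    Hypnogram,
    MAPPING_SCHEMES,
    ResolutionError,
    pair_epochs,
)

__all__ = [
    "LagResult",
    "ConfusionMatrix",
    "EBEMetrics",
    "ConcordanceError",
    "align_by_lag",
    "confusion_matrix",
    "pool_matrices",
    "binary_metrics",
    "one_vs_rest_metrics",
    "aggregate_participants",
    "is_satisfactory_ebe",
    "EBE_MCC_THRESHOLDS",
    "RESOLUTION_CLASSES",
]

# Satisfactory epoch-by-epoch agreement: MCC must exceed the inter-rater kappa
# reported for human scorers (MCC and kappa nearly coincide in the positive
# quadrant, so the kappa benchmarks transfer).
EBE_MCC_THRESHOLDS: dict[str, float] = {
    "SLEEP_WAKE": 0.70,
    "REM": 0.69,
    "NREM": 0.48,
    "LS": 0.40,
    "DS": 0.57,
}

# Ordered class lists per analysis resolution (rows = reference).
RESOLUTION_CLASSES: dict[str, list[str]] = {
    "TWO": ["W", "SLEEP"],
    "THREE": ["W", "NREM", "REM"],
    "FOUR": ["W", "LS", "DS", "REM"],
}

_RESOLUTION_SCHEME = {"TWO": "TWO", "THREE": "THREE"}


class ConcordanceError(Exception):
    pass


@dataclass
class LagResult:
    """Best-alignment lag and the pairs formed at that lag.

    ``lag_epochs`` is the number of 30-s epochs by which the test stream
    trails the reference: positive lag means the device's content appears
    later than PSG, and pairing compares ref[i] with test[i + lag].
    """

    lag_epochs: int
    concordance_at_lag: float
    aligned_pairs: EpochPairs


@dataclass
class ConfusionMatrix:
    """Reference-by-test epoch-label cross-tabulation at a declared resolution."""

    classes: list[str]
    counts: np.ndarray  # rows = reference, columns = test
    scope: str = "per_participant"  # or "pooled"
    resolution: str = "FOUR"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ConcordanceError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise ConcordanceError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EBEMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def _shift_labels(labels: tuple[str, ...], lag: int) -> tuple[str, ...]:
    """Shift content by ``lag`` epochs on the same clock grid, padding with ABSENT."""
    n = len(labels)
    out = ["ABSENT"] * n
    for i in range(n):
        j = i - lag
        if 0 <= j < n:
            out[i] = labels[j]
    return tuple(out)


def align_by_lag(ref: Hypnogram, test: Hypnogram, max_lag: int = 10) -> LagResult:
    """Find the lag in [−max_lag, max_lag] maximizing exact-label concordance.

    For each candidate lag the test stream is shifted on the shared 30-s grid,
    valid pairs are formed, and the fraction of exactly matching labels is
    computed at the finest common resolution.  Ties are broken toward the
    smaller |lag|, then toward the negative lag.
    """
    if ref.epoch_len != 30 or test.epoch_len != 30:
        raise ResolutionError("lag alignment requires both hypnograms at 30-s resolution")
    base = pair_epochs(ref, test)
    if len(base) + len(base.dropped_indices) < 2 * max_lag + 1:
        raise ConcordanceError(
            f"overlap of {len(base) + len(base.dropped_indices)} epochs too short "
            f"for lag search of +/-{max_lag}"
        )
    best: tuple[float, int, int, EpochPairs] | None = None
    for lag in range(-max_lag, max_lag + 1):
        shifted = _dc_replace(test, labels=_shift_labels(test.labels, -lag))
        try:
            pairs = pair_epochs(ref, shifted)
        except ResolutionError:
            continue
        if len(pairs) == 0:
            continue
        conc = sum(r == t for r, t in pairs) / len(pairs)
        # sort key: maximize concordance; tie -> smaller |lag|; tie -> negative lag
        key = (conc, -abs(lag), -lag)
        if best is None or key > (best[0], best[1], best[2]):
            best = (conc, -abs(lag), -lag, pairs)
    if best is None:
        raise ConcordanceError("no valid pairs at any candidate lag")
    conc, neg_abs_lag, neg_lag, pairs = best
    return LagResult(lag_epochs=-neg_lag, concordance_at_lag=conc, aligned_pairs=pairs)


def _map_token(tok: str, resolution: str) -> str:
    if resolution == "FOUR":
        if tok in RESOLUTION_CLASSES["FOUR"]:
            return tok
        table, _ = MAPPING_SCHEMES["FOUR_DEFAULT"]
        if tok in table:
            return table[tok]
        raise ConcordanceError(f"label {tok!r} not expressible at FOUR resolution")
    table, _ = MAPPING_SCHEMES[_RESOLUTION_SCHEME[resolution]]
    # allow already-coarse or finer tokens
    if tok in RESOLUTION_CLASSES[resolution]:
        return tok
    if tok in table:
        return table[tok]
    raise ConcordanceError(f"label {tok!r} not expressible at {resolution} resolution")


def confusion_matrix(pairs: EpochPairs, resolution: str = "FOUR") -> ConfusionMatrix:
    """Cross-tabulate valid pairs after mapping both sides to ``resolution``."""
    if resolution not in RESOLUTION_CLASSES:
        raise ConcordanceError(f"unknown resolution {resolution!r}")
    classes = RESOLUTION_CLASSES[resolution]
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, t in pairs:
        counts[index[_map_token(r, resolution)], index[_map_token(t, resolution)]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts,
                           scope="per_participant", resolution=resolution)


def pool_matrices(ms: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Sum per-participant matrices elementwise into a pooled matrix."""
    if not ms:
        raise ConcordanceError("cannot pool an empty list of matrices")
    first = ms[0]
    for m in ms[1:]:
        if m.classes != first.classes or m.resolution != first.resolution:
            raise ConcordanceError("cannot pool matrices with different classes/resolution")
    total = np.sum([m.counts for m in ms], axis=0)
    return ConfusionMatrix(classes=list(first.classes), counts=total,
                           scope="pooled", resolution=first.resolution)


def _metrics_2x2(tn: int, fp: int, fn: int, tp: int) -> EBEMetrics:
    nan = float("nan")
    sens = tp / (tp + fn) if (tp + fn) > 0 else nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else nan
    total = tn + fp + fn + tp
    acc = (tp + tn) / total if total > 0 else nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else nan
    return EBEMetrics(sensitivity=sens, specificity=spec, accuracy=acc, f1=f1, mcc=mcc)


def binary_metrics(cm: ConfusionMatrix, positive: str = "SLEEP") -> EBEMetrics:
    """Binary metrics from a 2x2 matrix with ``positive`` as the positive class.

    Sensitivity is the positive-class (sleep) prediction accuracy, specificity
    the negative-class (wake) prediction accuracy.  MCC is NaN when a marginal
    is zero (undefined, reported as missing).
    """
    if len(cm.classes) != 2:
        raise ConcordanceError(f"binary_metrics needs a 2x2 matrix, got {len(cm.classes)} classes")
    if positive not in cm.classes:
        raise ConcordanceError(f"positive class {positive!r} not among {cm.classes}")
    p = cm.classes.index(positive)
    n = 1 - p
    c = cm.counts
    return _metrics_2x2(tn=int(c[n, n]), fp=int(c[n, p]), fn=int(c[p, n]), tp=int(c[p, p]))


def one_vs_rest_metrics(cm: ConfusionMatrix, target_class: str) -> EBEMetrics:
    """Collapse a multi-class matrix to target-vs-rest and score it binarily."""
    if target_class not in cm.classes:
        raise ConcordanceError(f"class {target_class!r} not among {cm.classes}")
    k = cm.classes.index(target_class)
    c = cm.counts
    tp = int(c[k, k])
    fn = int(c[k, :].sum() - tp)
    fp = int(c[:, k].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return _metrics_2x2(tn=tn, fp=fp, fn=fn, tp=tp)


def aggregate_participants(values, clamp: tuple[float, float] | None = None):
    """Mean, sample SD, and normal-approximation 95% CI across participants.

    NaN entries (undefined per-participant metrics, e.g. from a zero marginal)
    are excluded; the count of exclusions is returned.  ``clamp`` optionally
    bounds the CI ends to the metric's natural range for display.
    """
    arr = np.asarray(values, dtype=float)
    missing = int(np.isnan(arr).sum())
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise ConcordanceError(f"aggregation requires >= 2 non-missing values, got {len(arr)}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = 1.96 * sd / math.sqrt(len(arr))
    lo, hi = mean - half, mean + half
    if clamp is not None:
        lo = max(lo, clamp[0])
        hi = min(hi, clamp[1])
    return {"mean": mean, "sd": sd, "ci95": (lo, hi), "n": len(arr), "n_missing": missing}


def is_satisfactory_ebe(stage: str, mcc: float) -> bool:
    """Whether a stage's MCC clears the inter-rater benchmark (strict >)."""
    if stage not in EBE_MCC_THRESHOLDS:
        raise ConcordanceError(f"no epoch-by-epoch threshold for stage {stage!r}")
    return mcc > EBE_MCC_THRESHOLDS[stage]
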