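"""Hypnogram data model, I/O, stage-vocabulary mapping, and epoch arithmetic.

A hypnogram is an epoch-labeled sleep-stage time series: one categorical label
per fixed scoring interval (30 s for polysomnography, 60 s for some consumer
devices), anchored to a clock time.  Everything downstream — all-night summary
measures, Bland-Altman agreement, epoch-by-epoch concordance — operates on this
object.

Coordinates: 0-based epoch indices; epoch *i* covers the half-open interval
``[start + i*epoch_len, start + (i+1)*epoch_len)``; durations are reported in
minutes as ``n_epochs * epoch_len / 60``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

__all__ = [
    "Hypnogram",
    "AnalysisPeriod",
    "EpochPairs",
    "STAGE_TOKENS",
    "VOCABULARIES",
    "MAPPING_SCHEMES",
    "HypnogramError",
    "ParseError",
    "MappingError",
    "ResolutionError",
    "read_hypnogram",
    "write_hypnogram",
    "read_analysis_period",
    "write_analysis_period",
    "map_stages",
    "upsample_to_30s",
    "crop_to_period",
    "pair_epochs",
    "SLEEP_TOKENS",
]

# Stage tokens.  W/N1/N2/N3/REM are the AASM five-stage vocabulary; LS (light
# sleep), DS (deep sleep), NREM and SLEEP are derived tokens used by collapsed
# vocabularies; ART marks reference artifact epochs, ABSENT marks device
# missing / no-presence epochs.  ART and ABSENT are excluded from pairing.
STAGE_TOKENS = frozenset(
    {"W", "N1", "N2", "N3", "REM", "LS", "DS", "NREM", "SLEEP", "ART", "ABSENT"}
)

SLEEP_TOKENS = frozenset({"N1", "N2", "N3", "REM", "LS", "DS", "NREM", "SLEEP"})

# Declared vocabularies: tag -> allowed token set.  ART/ABSENT are admitted in
# every vocabulary (they survive any mapping), though ART normally appears only
# in reference streams and ABSENT only in device streams.
VOCABULARIES: dict[str, frozenset[str]] = {
    "FIVE": frozenset({"W", "N1", "N2", "N3", "REM", "ART", "ABSENT"}),
    "FOUR": frozenset({"W", "LS", "DS", "REM", "ART", "ABSENT"}),
    "THREE": frozenset({"W", "NREM", "REM", "ART", "ABSENT"}),
    "TWO": frozenset({"W", "SLEEP", "ART", "ABSENT"}),
}

# Stage-collapsing schemes.  FOUR_DEFAULT merges N1 and N2 into light sleep and
# takes N3 as deep sleep (the standard reading of consumer-device stage labels);
# FOUR_ALT is the alternate assumption where only N1 is light sleep and both N2
# and N3 count as deep sleep.  THREE merges light and deep sleep into NREM; TWO
# collapses everything but wake into SLEEP.  ART and ABSENT always map to
# themselves.
_FOUR_DEFAULT = {"W": "W", "N1": "LS", "N2": "LS", "N3": "DS", "REM": "REM"}
_FOUR_ALT = {"W": "W", "N1": "LS", "N2": "DS", "N3": "DS", "REM": "REM"}
_THREE = {
    "W": "W", "REM": "REM",
    "N1": "NREM", "N2": "NREM", "N3": "NREM", "LS": "NREM", "DS": "NREM",
}
_TWO = {
    "W": "W",
    "N1": "SLEEP", "N2": "SLEEP", "N3": "SLEEP", "REM": "SLEEP",
    "LS": "SLEEP", "DS": "SLEEP", "NREM": "SLEEP", "SLEEP": "SLEEP",
}

MAPPING_SCHEMES: dict[str, tuple[dict[str, str], str]] = {
    # name -> (token mapping, output vocabulary tag)
    "FOUR_DEFAULT": (_FOUR_DEFAULT, "FOUR"),
    "FOUR_ALT": (_FOUR_ALT, "FOUR"),
    "THREE": (_THREE, "THREE"),
    "TWO": (_TWO, "TWO"),
}


class HypnogramError(Exception):
    """Base error for hypnogram construction and manipulation."""


class ParseError(HypnogramError):
    """Malformed hypnogram or analysis-period file."""


class MappingError(HypnogramError):
    """Stage-mapping scheme not applicable to a hypnogram's vocabulary."""


class ResolutionError(HypnogramError):
    """Epoch-resolution or clock-overlap mismatch between two hypnograms."""


@dataclass(frozen=True)
class AnalysisPeriod:
    """Half-open clock interval ``[t_start, t_end)`` scoping summary measures.

    ``kind`` records provenance: ``"automatic"`` for a device-detected in-bed
    period (AP-A) or ``"manual"`` for the lights-off-to-lights-on period set by
    the experimenter (AP-M).
    """

    t_start: datetime
    t_end: datetime
    kind: str = "manual"

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise HypnogramError(
                f"AnalysisPeriod requires t_start < t_end, got {self.t_start} .. {self.t_end}"
            )
        if self.kind not in ("automatic", "manual"):
            raise HypnogramError(f"unknown AnalysisPeriod kind {self.kind!r}")

    @property
    def duration_min(self) -> float:
        return (self.t_end - self.t_start).total_seconds() / 60.0


@dataclass(frozen=True)
class Hypnogram:
    """Epoch-labeled stage sequence with clock anchor.

    Parameters
    ----------
    start : datetime
        Clock time of the first epoch's left edge.
    epoch_len : int
        Epoch length in seconds, 30 or 60.
    labels : tuple of str
        One stage token per epoch, all members of the declared vocabulary.
    vocabulary : str
        One of ``FIVE``, ``FOUR``, ``THREE``, ``TWO``.
    subject_id : str
        Opaque participant identifier.
    source : str
        ``reference`` (PSG), ``device``, or ``actigraphy``.
    """

    start: datetime
    epoch_len: int
    labels: tuple[str, ...]
    vocabulary: str = "FIVE"
    subject_id: str = ""
    source: str = "reference"

    def __post_init__(self) -> None:
        if self.epoch_len not in (30, 60):
            raise HypnogramError(f"epoch_len must be 30 or 60 s, got {self.epoch_len}")
        if self.vocabulary not in VOCABULARIES:
            raise HypnogramError(f"unknown vocabulary {self.vocabulary!r}")
        object.__setattr__(self, "labels", tuple(self.labels))
        allowed = VOCABULARIES[self.vocabulary]
        for i, lab in enumerate(self.labels):
            if lab not in allowed:
                raise HypnogramError(
                    f"label {lab!r} at epoch {i} not in vocabulary {self.vocabulary}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def end(self) -> datetime:
        """One-past-the-last epoch boundary."""
        return self.start + timedelta(seconds=self.epoch_len * len(self.labels))

    @property
    def duration_min(self) -> float:
        return self.epoch_len * len(self.labels) / 60.0

    def epoch_start(self, i: int) -> datetime:
        return self.start + timedelta(seconds=i * self.epoch_len)

    def span(self) -> AnalysisPeriod:
        """The full recording span as a manual analysis period."""
        return AnalysisPeriod(self.start, self.end, kind="manual")


@dataclass
class EpochPairs:
    """Index-aligned (reference, test) label pairs after valid-pair exclusion.

    ``ref_indices`` holds the reference-hypnogram epoch index of each retained
    pair; ``dropped_indices`` the reference indices excluded because either
    member was ART or ABSENT.
    """

    ref_labels: list[str]
    test_labels: list[str]
    ref_indices: list[int]
    dropped_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ref_labels)

    def __iter__(self):
        return iter(zip(self.ref_labels, self.test_labels))


# ---------------------------------------------------------------------------
# I/O — plain-text hypnogram dialect
# ---------------------------------------------------------------------------

def _parse_iso(ts: str, where: str) -> datetime:
    try:
        dt = datetime.fromisoformat(ts)
    except ValueError as exc:
        raise ParseError(f"{where}: bad ISO-8601 timestamp {ts!r}") from exc
    return dt


def read_hypnogram(path: str | Path, dialect: str = "csv") -> Hypnogram:
    """Read a hypnogram from the package's CSV or JSON dialect.

    CSV dialect: two header comment lines ``#start=<ISO-8601>`` and
    ``#epoch_s=<30|60>``, a ``stage`` column header, then one stage token per
    row.  JSON twin: ``{"start": ..., "epoch_s": ..., "stages": [...]}``.
    Optional keys ``vocabulary``, ``subject_id`` and ``source`` are honoured in
    both dialects (CSV via extra ``#key=value`` header lines).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if dialect == "json":
        return _hypnogram_from_json(text, str(path))
    if dialect != "csv":
        raise ParseError(f"unknown hypnogram dialect {dialect!r}")

    meta: dict[str, str] = {}
    labels: list[str] = []
    saw_header = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            continue
        if not saw_header:
            if line != "stage":
                raise ParseError(f"{path}:{lineno}: expected column header 'stage', got {line!r}")
            saw_header = True
            continue
        if line not in STAGE_TOKENS:
            raise ParseError(f"{path}:{lineno}: unknown stage token {line!r}")
        labels.append(line)

    for key in ("start", "epoch_s"):
        if key not in meta:
            raise ParseError(f"{path}: missing required header #{key}=")
    start = _parse_iso(meta["start"], str(path))
    try:
        epoch_len = int(meta["epoch_s"])
    except ValueError as exc:
        raise ParseError(f"{path}: bad #epoch_s value {meta['epoch_s']!r}") from exc

    vocab = meta.get("vocabulary") or _infer_vocabulary(labels)
    try:
        return Hypnogram(
            start=start,
            epoch_len=epoch_len,
            labels=tuple(labels),
            vocabulary=vocab,
            subject_id=meta.get("subject_id", ""),
            source=meta.get("source", "reference"),
        )
    except HypnogramError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _hypnogram_from_json(text: str, where: str) -> Hypnogram:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{where}: invalid JSON") from exc
    for key in ("start", "epoch_s", "stages"):
        if key not in obj:
            raise ParseError(f"{where}: missing key {key!r}")
    labels = list(obj["stages"])
    for i, lab in enumerate(labels):
        if lab not in STAGE_TOKENS:
            raise ParseError(f"{where}: unknown stage token {lab!r} at index {i}")
    vocab = obj.get("vocabulary") or _infer_vocabulary(labels)
    try:
        return Hypnogram(
            start=_parse_iso(obj["start"], where),
            epoch_len=int(obj["epoch_s"]),
            labels=tuple(labels),
            vocabulary=vocab,
            subject_id=obj.get("subject_id", ""),
            source=obj.get("source", "reference"),
        )
    except HypnogramError as exc:
        raise ParseError(f"{where}: {exc}") from exc


def _infer_vocabulary(labels: Sequence[str]) -> str:
    """Smallest declared vocabulary containing every observed token."""
    seen = set(labels)
    for tag in ("TWO", "THREE", "FOUR", "FIVE"):
        if seen <= VOCABULARIES[tag]:
            return tag
    raise ParseError(f"labels {sorted(seen)} fit no declared vocabulary")


def write_hypnogram(h: Hypnogram, path: str | Path, dialect: str = "csv") -> None:
    """Write ``h`` in the CSV or JSON dialect; read∘write round-trips exactly."""
    path = Path(path)
    if dialect == "json":
        obj = {
            "start": h.start.isoformat(),
            "epoch_s": h.epoch_len,
            "stages": list(h.labels),
            "vocabulary": h.vocabulary,
            "subject_id": h.subject_id,
            "source": h.source,
        }
        path.write_text(json.dumps(obj) + "\n", encoding="utf-8")
        return
    if dialect != "csv":
        raise ParseError(f"unknown hypnogram dialect {dialect!r}")
    lines = [
        f"#start={h.start.isoformat()}",
        f"#epoch_s={h.epoch_len}",
        f"#vocabulary={h.vocabulary}",
    ]
    if h.subject_id:
        lines.append(f"#subject_id={h.subject_id}")
    lines.append(f"#source={h.source}")
    lines.append("stage")
    lines.extend(h.labels)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_analysis_period(path: str | Path) -> AnalysisPeriod:
    """Read an AnalysisPeriod JSON file: {"t_start":…, "t_end":…, "kind":…}."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON") from exc
    for key in ("t_start", "t_end"):
        if key not in obj:
            raise ParseError(f"{path}: missing key {key!r}")
    return AnalysisPeriod(
        t_start=_parse_iso(obj["t_start"], str(path)),
        t_end=_parse_iso(obj["t_end"], str(path)),
        kind=obj.get("kind", "manual"),
    )


def write_analysis_period(ap: AnalysisPeriod, path: str | Path) -> None:
    obj = {"t_start": ap.t_start.isoformat(), "t_end": ap.t_end.isoformat(), "kind": ap.kind}
    Path(path).write_text(json.dumps(obj) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Harmonization operations
# ---------------------------------------------------------------------------

def map_stages(h: Hypnogram, scheme: str) -> Hypnogram:
    """Collapse a hypnogram to a coarser stage vocabulary.

    ``scheme`` is one of ``FOUR_DEFAULT``, ``FOUR_ALT``, ``THREE``, ``TWO``.
    Label count, start and epoch length are unchanged; ART/ABSENT pass through.
    Raises :class:`MappingError` if any of ``h``'s tokens is not covered by the
    scheme (e.g. applying ``FOUR_DEFAULT`` to an already-binary hypnogram).
    """
    if scheme not in MAPPING_SCHEMES:
        raise MappingError(f"unknown mapping scheme {scheme!r}")
    table, out_vocab = MAPPING_SCHEMES[scheme]
    out: list[str] = []
    for lab in h.labels:
        if lab in ("ART", "ABSENT"):
            out.append(lab)
        elif lab in table:
            out.append(table[lab])
        else:
            raise MappingError(
                f"scheme {scheme} not applicable: token {lab!r} (vocabulary {h.vocabulary})"
            )
    # applicability also requires the *declared* vocabulary be refinable, even
    # if no offending token happens to occur in this particular night
    for tok in VOCABULARIES[h.vocabulary] - {"ART", "ABSENT"}:
        if tok not in table:
            raise MappingError(
                f"scheme {scheme} not applicable to vocabulary {h.vocabulary}"
            )
    return replace(h, labels=tuple(out), vocabulary=out_vocab)


def upsample_to_30s(h: Hypnogram) -> Hypnogram:
    """Convert a 60-s hypnogram to 30-s resolution by next-minute imputation.

    Each 60-s epoch *i* becomes two 30-s epochs: the first half keeps label
    *i*, the second half takes the label of the next minute (*i*+1) when it
    exists, else repeats label *i*.  A hypnogram already at 30 s is returned
    unchanged with a warning.
    """
    if h.epoch_len == 30:
        warnings.warn("hypnogram already at 30-s resolution; returning unchanged")
        return h
    labels: list[str] = []
    n = len(h.labels)
    for i, lab in enumerate(h.labels):
        labels.append(lab)
        labels.append(h.labels[i + 1] if i + 1 < n else lab)
    return replace(h, epoch_len=30, labels=tuple(labels))


def crop_to_period(h: Hypnogram, ap: AnalysisPeriod) -> Hypnogram:
    """Retain the epochs fully contained in ``[ap.t_start, ap.t_end)``.

    Epochs split by a period boundary are excluded (containment rule); the
    result's start is the first retained epoch's clock time.  Raises
    :class:`HypnogramError` when no epoch survives.
    """
    step = h.epoch_len
    kept: list[str] = []
    first_start: datetime | None = None
    for i, lab in enumerate(h.labels):
        e_start = h.epoch_start(i)
        e_end = e_start + timedelta(seconds=step)
        if e_start >= ap.t_start and e_end <= ap.t_end:
            if first_start is None:
                first_start = e_start
            kept.append(lab)
    if first_start is None:
        raise HypnogramError(
            f"analysis period {ap.t_start}..{ap.t_end} contains no complete epoch of the hypnogram"
        )
    return replace(h, start=first_start, labels=tuple(kept))


def _grid_offset_epochs(ref: Hypnogram, test: Hypnogram) -> int:
    """Offset of test's grid relative to ref's, in ref epochs (snapped).

    Both must be at the same resolution.  The test start is snapped to the
    nearest ref grid boundary; a residual of more than half an epoch is the
    alignment module's concern and handled there via lag search.
    """
    delta = (test.start - ref.start).total_seconds()
    return round(delta / ref.epoch_len)


def pair_epochs(ref: Hypnogram, test: Hypnogram) -> EpochPairs:
    """Form valid (reference, test) label pairs on the shared 30-s clock grid.

    Pairs cover the clock-time intersection of the two recordings; pairs in
    which either member is ART or ABSENT are dropped and their reference
    indices reported.  Both hypnograms must already be at 30-s resolution
    (upsample first) and overlap in clock time.
    """
    if ref.epoch_len != test.epoch_len:
        raise ResolutionError(
            f"epoch length mismatch: ref {ref.epoch_len} s vs test {test.epoch_len} s; "
            "upsample to 30 s before pairing"
        )
    off = _grid_offset_epochs(ref, test)
    # ref index i pairs with test index i - off
    lo = max(0, off)
    hi = min(len(ref), len(test) + off)
    if lo >= hi:
        raise ResolutionError("hypnograms do not overlap in clock time")
    pairs = EpochPairs([], [], [])
    for i in range(lo, hi):
        r, t = ref.labels[i], test.labels[i - off]
        if r in ("ART", "ABSENT") or t in ("ART", "ABSENT"):
            pairs.dropped_indices.append(i)
            continue
        pairs.ref_labels.append(r)
        pairs.test_labels.append(t)
        pairs.ref_indices.append(i)
    return pairs
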