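from datetime import datetime, timedelta

import pytest

from hypnoval.hypnogram import AnalysisPeriod, Hypnogram

T0 = datetime(2021, 6, 1, 22, 0, 0)


def make_hyp(labels, epoch_len=30, start=T0, vocabulary=None, **kw) -> Hypnogram:
    if vocabulary is None:
        seen = set(labels)
        if seen & {"N1", "N2", "N3"}:
            vocabulary = "FIVE"
        elif seen & {"LS", "DS"}:
            vocabulary = "FOUR"
        elif "NREM" in seen:
            vocabulary = "THREE"
        elif "REM" in seen:
            vocabulary = "FOUR"
        else:
            vocabulary = "TWO"
    return Hypnogram(start=start, epoch_len=epoch_len, labels=tuple(labels),
                     vocabulary=vocabulary, **kw)


def period(start_epoch: int, end_epoch: int, epoch_len=30, start=T0, kind="manual"):
    return AnalysisPeriod(
        t_start=start + timedelta(seconds=start_epoch * epoch_len),
        t_end=start + timedelta(seconds=end_epoch * epoch_len),
        kind=kind,
    )


@pytest.fixture
def t0():
    return T0
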