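"""Build a tiny hypnogram, collapse its stage vocabulary, and summarize it.

A hypnogram is one sleep-stage label per 30-s epoch.  Consumer devices report
four stages (wake / light sleep / deep sleep / REM), so PSG's five stages are
collapsed (N1+N2 -> LS, N3 -> DS) before any comparison.  The summary
measures are the clinical all-night numbers: TST, SOL, WASO, SEFF.
"""

from datetime import datetime

from hypnoval import Hypnogram, compute_summary, map_stages

h = Hypnogram(
    start=datetime(2021, 6, 1, 23, 0),
    epoch_len=30,
    labels=("W", "W", "N1", "N2", "N2", "N3", "N3", "REM", "W", "N2"),
    vocabulary="FIVE",
    subject_id="demo",
)

four = map_stages(h, "FOUR_DEFAULT")
print("five-stage:", " ".join(h.labels))
print("four-stage:", " ".join(four.labels))

s = compute_summary(h)
print(f"TST  {s.tst_min:5.1f} min   total sleep inside the analysis period")
print(f"SOL  {s.sol_min:5.1f} min   lights-off to the first sleep epoch")
print(f"WASO {s.waso_min:5.1f} min   wake after sleep onset (terminal wake included)")
print(f"SEFF {s.seff_pct:5.1f} %     TST as a share of the analysis period")
print(f"LS/DS/REM  {s.ls_min}/{s.ds_min}/{s.rem_min} min")
# SOL + TST + WASO partitions the 5-minute period exactly.
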