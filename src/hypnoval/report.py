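"""Full evaluation orchestration: per-device, per-period, per-window reports.

Runs the complete validation of every device stream against the reference
PSG of a cohort (real files or a simulated cohort in memory) and emits the
standard report shapes: summary-agreement tables per analysis-period mode,
epoch-by-epoch metric tables per analysis window, pooled confusion matrices,
unitless agreement matrices (SMAPE / SAD / MCC) for cross-device ranking, a
satisfactory-agreement flag table, and a JSON run log.  Every number in the
bundle is produced by a library operation; this layer only arranges and
rounds them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    PairedMeasures,
    compute_agreement,
    is_satisfactory_summary,
    SUMMARY_ICC_THRESHOLDS,
)
from .concordance import (
    EBE_MCC_THRESHOLDS,
    aggregate_participants,
    align_by_lag,
    confusion_matrix,
    is_satisfactory_ebe,
    one_vs_rest_metrics,
    binary_metrics,
    pool_matrices,
    ConcordanceError,
)
from .hypnogram import (
    AnalysisPeriod,
    Hypnogram,
    crop_to_period,
    map_stages,
    read_analysis_period,
    read_hypnogram,
    upsample_to_30s,
    HypnogramError,
)
from .summary import compute_summary, infer_ap_auto
from .simulate import SyntheticNight

__all__ = ["EvaluationConfig", "load_cohort", "run_evaluation", "rank_devices"]

_SUMMARY_MEASURES = ["AP", "TST", "SOL", "WASO", "SEFF"]
_STAGE_MEASURES = ["REM", "NREM", "LS", "DS"]


@dataclass
class EvaluationConfig:
    """What to evaluate and how; defaults reproduce the standard analysis."""

    devices: list[str] | None = None
    ap_modes: tuple[str, ...] = ("AP_A", "AP_M")
    windows: tuple[str, ...] = ("TRT", "LIGHTS_OFF")
    resolutions: tuple[str, ...] = ("TWO", "THREE", "FOUR")
    stage_mapping: str = "FOUR_DEFAULT"
    seff_denominator: str = "AP"
    max_lag: int = 10
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ap_modes or not self.windows or not self.resolutions:
            raise ValueError("ap_modes, windows and resolutions must be non-empty")


def load_cohort(manifest_path: str | Path) -> list[SyntheticNight]:
    """Load a cohort directory written by :func:`hypnoval.simulate.write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    nights: list[SyntheticNight] = []
    for entry in manifest["subjects"]:
        psg = read_hypnogram(root / entry["psg"])
        ap_m = read_analysis_period(root / entry["ap_manual"])
        devices: dict[str, Hypnogram] = {}
        ap_auto: dict[str, AnalysisPeriod] = {}
        for name, spec in entry["devices"].items():
            devices[name] = read_hypnogram(root / spec["hypnogram"])
            if "ap_auto" in spec:
                ap_auto[name] = read_analysis_period(root / spec["ap_auto"])
            else:
                ap_auto[name] = infer_ap_auto(devices[name])
        nights.append(SyntheticNight(subject_id=entry["subject_id"], psg=psg,
                                     ap_manual=ap_m, devices=devices, ap_auto=ap_auto))
    return nights


def _device_vocab(h: Hypnogram) -> str:
    return "TWO" if h.vocabulary == "TWO" else "FOUR"


def _summary_rows(nights, device, ap_mode, cfg) -> dict[str, tuple[list, list]]:
    """Per-measure (reference values, device values) across participants."""
    out: dict[str, tuple[list, list]] = {}
    for nt in nights:
        if device not in nt.devices:
            continue
        dev = nt.devices[device]
        ap_dev = nt.ap_auto.get(device) if ap_mode == "AP_A" else nt.ap_manual
        if ap_dev is None:
            ap_dev = infer_ap_auto(dev)
        try:
            ref_sum = compute_summary(nt.psg, nt.ap_manual,
                                      seff_denominator=cfg.seff_denominator,
                                      trt_min=nt.psg.duration_min)
            dev_sum = compute_summary(dev, ap_dev,
                                      seff_denominator=cfg.seff_denominator,
                                      trt_min=dev.duration_min)
        except HypnogramError:
            continue
        measures = list(_SUMMARY_MEASURES)
        if _device_vocab(dev) == "FOUR":
            measures += _STAGE_MEASURES
        r_row, d_row = ref_sum.to_row(), dev_sum.to_row()
        for m in measures:
            xs, ys = out.setdefault(m, ([], []))
            xs.append(r_row[m])
            ys.append(d_row[m])
    return out


def _ebe_per_subject(nt: SyntheticNight, device: str, window: str, cfg: EvaluationConfig):
    """Aligned pairs and per-resolution confusion matrices for one subject."""
    dev = nt.devices[device]
    if dev.epoch_len == 60:
        dev = upsample_to_30s(dev)
    vocab = _device_vocab(dev)
    ref = map_stages(nt.psg, cfg.stage_mapping) if nt.psg.vocabulary == "FIVE" else nt.psg
    if vocab == "TWO":
        ref = map_stages(ref, "TWO")
        dev_cmp = dev
    else:
        dev_cmp = dev
    if window == "LIGHTS_OFF":
        ref = crop_to_period(ref, nt.ap_manual)
        dev_cmp = crop_to_period(dev_cmp, nt.ap_manual)
    lag = align_by_lag(ref, dev_cmp, max_lag=cfg.max_lag)
    resolutions = [r for r in cfg.resolutions
                   if vocab == "FOUR" or r == "TWO"]
    cms = {r: confusion_matrix(lag.aligned_pairs, r) for r in resolutions}
    return lag, cms


def _stage_metric_rows(cms) -> dict[str, dict[str, float]]:
    """Stage -> metric dict from one subject's confusion matrices."""
    rows: dict[str, dict[str, float]] = {}
    if "TWO" in cms:
        rows["SLEEP_WAKE"] = binary_metrics(cms["TWO"], positive="SLEEP").as_dict()
    if "THREE" in cms:
        rows["NREM"] = one_vs_rest_metrics(cms["THREE"], "NREM").as_dict()
    if "FOUR" in cms:
        rows["REM"] = one_vs_rest_metrics(cms["FOUR"], "REM").as_dict()
        rows["LS"] = one_vs_rest_metrics(cms["FOUR"], "LS").as_dict()
        rows["DS"] = one_vs_rest_metrics(cms["FOUR"], "DS").as_dict()
    return rows


_METRIC_NAMES = ["sensitivity", "specificity", "accuracy", "mcc", "f1"]


def run_evaluation(nights: list[SyntheticNight], cfg: EvaluationConfig | None = None) -> dict:
    """Evaluate every device of a cohort; return (and optionally write) the bundle.

    The bundle holds: ``summary_agreement`` (per device, measure and period
    mode: bias, limits of agreement, MDC, rho, ICC, Cohen's d, SMAPE, SAD,
    normality, satisfactory flag), ``ebe_metrics`` (per device, stage and
    window: participant mean/SD/95% CI of sensitivity, specificity, accuracy,
    MCC, F1), ``pooled_confusion`` matrices, ``agreement_matrices``
    (SMAPE/SAD/MCC, devices x measures), ``flags`` and a ``run_log``.
    """
    cfg = cfg or EvaluationConfig()
    devices = cfg.devices or sorted({d for nt in nights for d in nt.devices})

    summary_rows = []
    flags_rows = []
    for device in devices:
        for ap_mode in cfg.ap_modes:
            per_measure = _summary_rows(nights, device, ap_mode, cfg)
            for measure, (xs, ys) in per_measure.items():
                if len(xs) < 3:
                    continue
                rep = compute_agreement(PairedMeasures(measure, np.array(xs), np.array(ys)))
                summary_rows.append({
                    "device": device, "measure": measure, "ap_mode": ap_mode,
                    "n": rep.n, "bias": rep.bias, "sd_diff": rep.sd_diff,
                    "loa_low": rep.loa_low, "loa_high": rep.loa_high,
                    "ci_bias_low": rep.ci_bias[0], "ci_bias_high": rep.ci_bias[1],
                    "mdc": rep.mdc, "rho": rep.rho, "icc": rep.icc,
                    "cohen_d": rep.cohen_d, "smape": rep.smape, "sad": rep.sad,
                    "normality_p": rep.normality_p,
                    "satisfactory": rep.satisfactory,
                })
                if measure in SUMMARY_ICC_THRESHOLDS and np.isfinite(rep.icc):
                    flags_rows.append({
                        "device": device, "kind": "summary_icc", "target": measure,
                        "ap_mode_or_window": ap_mode, "value": rep.icc,
                        "threshold": SUMMARY_ICC_THRESHOLDS[measure],
                        "satisfactory": is_satisfactory_summary(measure, rep.icc),
                    })

    ebe_rows = []
    pooled: dict[tuple[str, str, str], object] = {}
    mcc_cells: dict[tuple[str, str], float] = {}
    for device in devices:
        for window in cfg.windows:
            per_subject_metrics: dict[str, dict[str, list[float]]] = {}
            per_res_cms: dict[str, list] = {}
            lags = []
            for nt in nights:
                if device not in nt.devices:
                    continue
                try:
                    lag, cms = _ebe_per_subject(nt, device, window, cfg)
                except (ConcordanceError, HypnogramError):
                    continue
                lags.append(lag.lag_epochs)
                for res, cm in cms.items():
                    per_res_cms.setdefault(res, []).append(cm)
                for stage, md in _stage_metric_rows(cms).items():
                    bucket = per_subject_metrics.setdefault(
                        stage, {m: [] for m in _METRIC_NAMES})
                    for m in _METRIC_NAMES:
                        bucket[m].append(md[m])
            for res, cms_list in per_res_cms.items():
                pooled[(device, window, res)] = pool_matrices(cms_list)
            for stage, bucket in per_subject_metrics.items():
                row = {"device": device, "window": window, "stage": stage}
                for m in _METRIC_NAMES:
                    try:
                        agg = aggregate_participants(
                            bucket[m], clamp=(-1.0, 1.0) if m == "mcc" else (0.0, 1.0))
                    except ConcordanceError:
                        continue
                    row[f"{m}_mean"] = agg["mean"]
                    row[f"{m}_sd"] = agg["sd"]
                    row[f"{m}_ci_low"], row[f"{m}_ci_high"] = agg["ci95"]
                    row["n"] = agg["n"]
                    row[f"{m}_n_missing"] = agg["n_missing"]
                ebe_rows.append(row)
                if "mcc_mean" in row:
                    if window == "TRT":
                        mcc_cells[(device, stage)] = row["mcc_mean"]
                    flags_rows.append({
                        "device": device, "kind": "ebe_mcc", "target": stage,
                        "ap_mode_or_window": window, "value": row["mcc_mean"],
                        "threshold": EBE_MCC_THRESHOLDS[stage],
                        "satisfactory": is_satisfactory_ebe(stage, row["mcc_mean"]),
                    })

    summary_df = pd.DataFrame(summary_rows)
    ebe_df = pd.DataFrame(ebe_rows)
    flags_df = pd.DataFrame(flags_rows)

    # unitless agreement matrices: devices x measures (SMAPE, SAD) and stages (MCC)
    matrices = {}
    for metric in ("smape", "sad"):
        cells = {}
        for r in summary_rows:
            if r["ap_mode"] == ("AP_A" if "AP_A" in cfg.ap_modes else cfg.ap_modes[0]):
                cells[(r["device"], r["measure"])] = r[metric]
        matrices[metric.upper()] = _cells_to_frame(cells)
    matrices["MCC"] = _cells_to_frame(mcc_cells)

    bundle = {
        "summary_agreement": summary_df,
        "ebe_metrics": ebe_df,
        "pooled_confusion": pooled,
        "agreement_matrices": matrices,
        "flags": flags_df,
        "run_log": {
            "version": __version__,
            "seed": cfg.seed,
            "devices": devices,
            "ap_modes": list(cfg.ap_modes),
            "windows": list(cfg.windows),
            "resolutions": list(cfg.resolutions),
            "stage_mapping": cfg.stage_mapping,
            "seff_denominator": cfg.seff_denominator,
            "n_subjects": len(nights),
        },
    }
    if cfg.out_dir is not None:
        _write_bundle(bundle, Path(cfg.out_dir))
    return bundle


def _cells_to_frame(cells: dict[tuple[str, str], float]) -> pd.DataFrame:
    if not cells:
        return pd.DataFrame()
    devices = sorted({d for d, _ in cells})
    cols = sorted({m for _, m in cells})
    return pd.DataFrame(
        [[cells.get((d, m), np.nan) for m in cols] for d in devices],
        index=devices, columns=cols,
    )


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    round2 = lambda df: df.round(2)
    bundle["summary_agreement"].pipe(round2).to_csv(out_dir / "summary_agreement.csv", index=False)
    bundle["ebe_metrics"].pipe(round2).to_csv(out_dir / "ebe_metrics.csv", index=False)
    bundle["flags"].round(3).to_csv(out_dir / "satisfactory_flags.csv", index=False)
    for name, df in bundle["agreement_matrices"].items():
        df.round(2).to_csv(out_dir / f"agreement_matrix_{name.lower()}.csv")
    for (device, window, res), cm in bundle["pooled_confusion"].items():
        pd.DataFrame(cm.counts, index=cm.classes, columns=cm.classes).to_csv(
            out_dir / f"confusion_{device}_{window}_{res}.csv")
    (out_dir / "run_log.json").write_text(
        json.dumps(bundle["run_log"], indent=1, sort_keys=True) + "\n", encoding="utf-8")


def rank_devices(bundle: dict) -> pd.DataFrame:
    """Rank devices per measure: SMAPE and SAD ascending, MCC descending.

    Ties share the minimum rank.  Measures missing for a device are excluded
    from that device's ranking with a NaN.
    """
    rows = []
    for metric, ascending in (("SMAPE", True), ("SAD", True), ("MCC", False)):
        df = bundle["agreement_matrices"].get(metric)
        if df is None or df.empty:
            continue
        ranks = df.rank(axis=0, ascending=ascending, method="min")
        for measure in df.columns:
            for device in df.index:
                rows.append({"metric": metric, "measure": measure, "device": device,
                             "value": df.loc[device, measure],
                             "rank": ranks.loc[device, measure]})
    out = pd.DataFrame(rows)
    if len({r["device"] for r in rows}) < 2:
        raise ValueError("device ranking requires at least 2 devices")
    return out
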