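"""End-to-end orchestration: condition a raw trace, detect and segment
events, phenotype the accepted ones, and (given group labels) run the
cohort statistics. All outputs are plain TSV tables stamped with the
config hash."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .detect import QCCode, detect_pulses, qc_event, segment_subpulses
from .phenotype import phenotype_event
from .preprocess import downsample, estimate_baseline, moving_average
from .stats import compare_groups, comparisons_frame, power_report
from .trace import RawTrace, read_trace

__all__ = [
    "PipelineResult",
    "condition_trace",
    "process_trace",
    "run_pipeline",
    "match_events_to_truth",
    "write_table",
]

log = logging.getLogger("mechanonps")


@dataclass
class PipelineResult:
    events: pd.DataFrame
    subpulses: pd.DataFrame
    features: pd.DataFrame
    comparisons: pd.DataFrame | None
    power: pd.DataFrame | None
    counts: dict = field(default_factory=dict)
    config_hash: str = ""


def condition_trace(trace: RawTrace, config: PipelineConfig) -> RawTrace:
    """Moving-average low-pass filter then block-mean downsampling."""
    pp = config.preprocess
    return downsample(moving_average(trace, pp.filter_window), pp.downsample_factor)


def process_trace(
    trace: RawTrace, config: PipelineConfig, group: str = "", event_id_offset: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Full single-trace analysis; returns (events, subpulses, features,
    QC counts). Per-event failures are logged and skipped, never fatal."""
    det = config.detection
    conditioned = condition_trace(trace, config)
    window = int(round(config.preprocess.baseline_window_s * conditioned.sample_rate))
    baseline = estimate_baseline(conditioned, window)
    detect_kwargs = dict(
        k=det.k_threshold,
        abs_threshold=det.abs_threshold,
        merge_horizon_s=det.merge_horizon_s,
        min_run_s=det.min_run_s,
    )
    events = detect_pulses(conditioned, baseline, **detect_kwargs)
    if events:
        # second pass: re-estimate the baseline with the detected pulse spans
        # masked out, removing the one-sided median bias, then re-detect
        margin = max(2, int(round(0.01 * conditioned.sample_rate)))
        exclude = np.zeros(len(conditioned), dtype=bool)
        for ev in events:
            exclude[max(ev.start - margin, 0) : ev.end + margin] = True
        baseline = estimate_baseline(conditioned, window, exclude=exclude)
        events = detect_pulses(conditioned, baseline, **detect_kwargs)
    event_rows, subpulse_rows, feature_rows = [], [], []
    counts: dict[str, int] = {code.value: 0 for code in QCCode}
    for i, event in enumerate(events):
        event_id = event_id_offset + i
        try:
            subpulses = segment_subpulses(
                event,
                conditioned,
                baseline,
                config.geometry,
                k=det.k_threshold,
                abs_threshold=det.abs_threshold,
                min_gap_samples=det.min_gap_samples,
                edge_trim_frac=det.edge_trim_frac,
            )
            flag = qc_event(event, subpulses, config.geometry, baseline.noise_scale)
        except Exception:
            log.exception("event %d: segmentation failed", event_id)
            counts["low_snr"] += 1
            continue
        counts[flag.code.value] += 1
        event_rows.append(
            {
                "event_id": event_id,
                "group": group,
                "start_s": conditioned.time_at(event.start),
                "end_s": conditioned.time_at(event.end),
                "qc_code": flag.code.value,
                "qc_detail": flag.detail,
            }
        )
        for sp in subpulses:
            subpulse_rows.append(
                {
                    "event_id": event_id,
                    "kind": sp.kind,
                    "order": sp.order,
                    "t_start_s": sp.t_start,
                    "t_end_s": sp.t_end,
                    "depth_a": sp.depth,
                    "level_a": sp.level,
                    "n_samples": sp.n_samples,
                }
            )
        if flag.code is not QCCode.OK:
            continue
        try:
            ph = phenotype_event(
                subpulses,
                config.geometry,
                event_id=event_id,
                min_points=config.fit.min_points,
                tau_band=config.fit.tau_band,
            )
        except Exception:
            log.exception("event %d: phenotyping failed", event_id)
            continue
        feature_rows.append(
            {
                "event_id": event_id,
                "group": group,
                "t_start_s": ph.t_start,
                "d0_um": ph.d0 * 1e6,
                "u_flow_mm_s": ph.u_flow * 1e3,
                "t_cont_ms": ph.t_cont * 1e3,
                "strain": ph.strain,
                "wcdi": ph.wcdi,
                "tau_ms": ph.recovery.tau * 1e3,
                "tau_ci_low_ms": ph.recovery.tau_ci95[0] * 1e3,
                "tau_ci_high_ms": ph.recovery.tau_ci95[1] * 1e3,
                "r2": ph.recovery.r_squared,
                "n_recovery_points": ph.recovery.n_points,
                "valid": ph.recovery.valid,
                "tau_in_band": ph.recovery.in_band,
            }
        )
    event_cols = ["event_id", "group", "start_s", "end_s", "qc_code", "qc_detail"]
    sub_cols = [
        "event_id", "kind", "order", "t_start_s", "t_end_s",
        "depth_a", "level_a", "n_samples",
    ]
    feat_cols = [
        "event_id", "group", "t_start_s", "d0_um", "u_flow_mm_s", "t_cont_ms",
        "strain", "wcdi", "tau_ms", "tau_ci_low_ms", "tau_ci_high_ms",
        "r2", "n_recovery_points", "valid", "tau_in_band",
    ]
    return (
        pd.DataFrame(event_rows, columns=event_cols),
        pd.DataFrame(subpulse_rows, columns=sub_cols),
        pd.DataFrame(feature_rows, columns=feat_cols),
        counts,
    )


def run_pipeline(
    config: PipelineConfig,
    traces: list[tuple[RawTrace | str | Path, str]],
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Analyze labelled traces end to end. ``traces`` is a list of
    (trace-or-path, group-label) pairs; with two or more distinct labels the
    cohort comparisons and the power report are produced as well."""
    all_events, all_subpulses, all_features = [], [], []
    counts: dict[str, int] = {}
    offset = 0
    for item, group in traces:
        trace = read_trace(item) if isinstance(item, (str, Path)) else item
        ev, sp, ft, ct = process_trace(trace, config, group, event_id_offset=offset)
        offset += len(ev) if len(ev) else 0
        all_events.append(ev)
        all_subpulses.append(sp)
        all_features.append(ft)
        for key, val in ct.items():
            counts[key] = counts.get(key, 0) + val
    events = pd.concat(all_events, ignore_index=True)
    subpulses = pd.concat(all_subpulses, ignore_index=True)
    features = pd.concat(all_features, ignore_index=True)

    comparisons = power = None
    groups = [g for g in features["group"].unique() if g]
    if len(groups) >= 2 and len(features):
        metrics = [m for m in config.stats.metrics if m in features.columns]
        usable = features[features["valid"]] if "tau_ms" in metrics else features
        results = compare_groups(
            usable, metrics, alpha=config.stats.alpha,
            adjustment=config.stats.adjustment,
        )
        comparisons = comparisons_frame(results)
        power = power_report(results)

    h = config.config_hash()
    result = PipelineResult(events, subpulses, features, comparisons, power, counts, h)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(events, outdir / "events.tsv", h)
        write_table(subpulses, outdir / "subpulses.tsv", h)
        write_table(features, outdir / "features.tsv", h)
        if comparisons is not None:
            write_table(comparisons, outdir / "comparisons.tsv", h)
            write_table(power, outdir / "power_report.tsv", h)
        _write_run_log(outdir / "run.log", config, counts, h)
    return result


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str) -> Path:
    """TSV with a leading config-hash comment so any table can be traced to
    the exact parameter set that produced it."""
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# config_hash: {config_hash}\n")
        df.to_csv(f, sep="\t", index=False, float_format="%.12g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _write_run_log(path: Path, config: PipelineConfig, counts: dict, h: str) -> None:
    with open(path, "w") as f:
        f.write(f"config_hash: {h}\n")
        f.write(f"detected_events: {sum(counts.values())}\n")
        for code, n in sorted(counts.items()):
            f.write(f"qc_{code}: {n}\n")


def match_events_to_truth(
    features: pd.DataFrame, truth: pd.DataFrame, tol_s: float = 0.05
) -> pd.DataFrame:
    """Join recovered phenotypes to simulator ground truth by event start
    time (within ``tol_s``). Unmatched rows on either side are dropped."""
    feats = features.sort_values("t_start_s").reset_index(drop=True)
    tr = truth.sort_values("event_start_s").reset_index(drop=True)
    idx = np.searchsorted(tr["event_start_s"].to_numpy(), feats["t_start_s"].to_numpy())
    rows = []
    for i, pos in enumerate(idx):
        best, best_dt = None, tol_s
        for j in (pos - 1, pos):
            if 0 <= j < len(tr):
                dt = abs(feats.at[i, "t_start_s"] - tr.at[j, "event_start_s"])
                if dt < best_dt:
                    best, best_dt = j, dt
        if best is not None:
            merged = {**tr.iloc[best].to_dict(), **feats.iloc[i].to_dict()}
            rows.append(merged)
    return pd.DataFrame(rows)
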