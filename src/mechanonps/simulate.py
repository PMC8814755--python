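"""Forward model: synthetic mechano-NPS current traces with known ground truth.

A cell transiting the channel produces a 12-subpulse current-deficit train:

1. sizing subpulse — duration ``L_sizing / u_flow``, depth
   ``I_baseline * blockade_fraction(d0, sizing)``;
2. contraction subpulse — duration ``t_cont`` (the mechanically informative
   quantity), depth a fixed multiple of the sizing depth (its amplitude is
   never used downstream, only its duration);
3. ten recovery subpulses — the cell leaves the constriction deformed into a
   bullet shape that under-blocks the pore relative to a sphere; as it relaxes
   (Kelvin-Voigt creep) the subpulse depth grows back toward the sizing depth:

       depth_k = depth_sphere * [1 - deficit * exp(-t_k / tau)],

   with ``t_k`` the subpulse midpoint measured from contraction exit and
   ``deficit`` the fractional under-blockade at the instant of release.

Nodes between segments are wide enough (85 um) that the cell barely blocks
current there; they are simulated at exact baseline, which delimits subpulses
unambiguously. Baseline current carries optional linear drift and i.i.d.
Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry, blockade_fraction
from .trace import RawTrace

__all__ = [
    "AcquisitionConfig",
    "CellGroundTruth",
    "GroupParams",
    "SubpulseSpec",
    "SegmentSchedule",
    "event_schedule",
    "recovery_depth",
    "simulate_event",
    "sample_cohort",
    "simulate_trace",
    "sigma_for_snr",
    "stiff_viscous_group",
    "soft_fast_group",
    "compute_wcdi_true",
]

TAU_BOUNDS = (0.005, 2.0)  # generation sanity bounds on tau, seconds


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings: 50 kHz sampling of a DC current baseline."""

    sample_rate: float = 50_000.0
    baseline_current: float = 10e-6
    noise_sigma: float = 5e-9
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class CellGroundTruth:
    """Per-cell latent parameters driving one simulated transit."""

    d0: float  # free diameter, m
    u_flow: float  # pre-contraction velocity, m/s
    t_cont: float  # contraction transit time, s
    tau: float  # recovery time constant, s
    entry_time: float = 0.0  # s
    deformed_blockade_deficit: float = 0.3  # fraction in [0, 1)

    def validate(self, geometry: ChannelGeometry) -> None:
        if not self.d0 > geometry.contraction_segment.width:
            raise ValueError("cell diameter must exceed the contraction width")
        if self.d0 >= geometry.effective_diameter(geometry.sizing_segment):
            raise ValueError("cell diameter would occlude the sizing segment")
        if not (TAU_BOUNDS[0] <= self.tau <= TAU_BOUNDS[1]):
            raise ValueError(f"tau outside generation bounds {TAU_BOUNDS}")
        if not (self.u_flow > 0 and self.t_cont > 0):
            raise ValueError("u_flow and t_cont must be positive")
        if not (0 <= self.deformed_blockade_deficit < 1):
            raise ValueError("deformed blockade deficit must be in [0, 1)")


@dataclass(frozen=True)
class SubpulseSpec:
    """Scheduled (ground-truth) subpulse: kind, absolute interval, depth (A)."""

    kind: str  # sizing | contraction | recovery
    order: int  # recovery index 1..n, else 0
    t_start: float
    t_end: float
    depth: float


@dataclass(frozen=True)
class SegmentSchedule:
    """Ground-truth subpulse boundaries and depths for one transit."""

    subpulses: tuple[SubpulseSpec, ...]

    @property
    def t_start(self) -> float:
        return self.subpulses[0].t_start

    @property
    def t_end(self) -> float:
        return self.subpulses[-1].t_end

    @property
    def sizing_depth(self) -> float:
        return self.subpulses[0].depth

    @property
    def contraction_exit(self) -> float:
        return next(s for s in self.subpulses if s.kind == "contraction").t_end

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def recovery_depth(t: float, tau: float, deficit: float, sphere_depth: float) -> float:
    """Recovery-subpulse depth a time ``t`` after release from the constriction."""
    return sphere_depth * (1.0 - deficit * math.exp(-t / tau))


def event_schedule(
    truth: CellGroundTruth,
    geometry: ChannelGeometry,
    acq: AcquisitionConfig,
    contraction_depth_factor: float = 3.0,
) -> SegmentSchedule:
    """Lay out the 12-subpulse schedule for one cell, absolute times."""
    truth.validate(geometry)
    u = truth.u_flow
    node_dwell = geometry.node.length / u
    sizing_dur = geometry.sizing_segment.length / u
    sphere = acq.baseline_current * blockade_fraction(
        truth.d0, geometry.sizing_segment, geometry
    )

    t = truth.entry_time
    pulses = [SubpulseSpec("sizing", 0, t, t + sizing_dur, sphere)]
    t += sizing_dur + node_dwell
    pulses.append(
        SubpulseSpec(
            "contraction", 0, t, t + truth.t_cont, contraction_depth_factor * sphere
        )
    )
    t += truth.t_cont
    t_exit = t
    for k, seg in enumerate(geometry.recovery_segments, start=1):
        t += node_dwell
        dur = seg.length / u
        mid = t + dur / 2.0 - t_exit
        depth = recovery_depth(mid, truth.tau, truth.deformed_blockade_deficit, sphere)
        pulses.append(SubpulseSpec("recovery", k, t, t + dur, depth))
        t += dur
    return SegmentSchedule(tuple(pulses))


def simulate_event(
    truth: CellGroundTruth,
    geometry: ChannelGeometry,
    acq: AcquisitionConfig,
    contraction_depth_factor: float = 3.0,
) -> tuple[np.ndarray, SegmentSchedule]:
    """Render one transit as a current-deficit sample array (positive values
    to be subtracted from the baseline), plus its ground-truth schedule."""
    sched = event_schedule(truth, geometry, acq, contraction_depth_factor)
    fs = acq.sample_rate
    n = int(round((sched.t_end - truth.entry_time) * fs)) + 1
    deficit = np.zeros(n)
    for sp in sched.subpulses:
        i0 = int(round((sp.t_start - truth.entry_time) * fs))
        i1 = int(round((sp.t_end - truth.entry_time) * fs))
        deficit[i0:i1] = sp.depth
    return deficit, sched


@dataclass(frozen=True)
class GroupParams:
    """Sampling distributions for one cohort.

    Diameters, contraction transit times and recovery time constants are
    lognormal (median, sigma of log); velocity is normal. ``tau_range``
    truncates tau draws to the band the device can observe.
    """

    name: str
    d0_median: float = 10.8e-6
    d0_sigma: float = 0.06
    t_cont_median: float = 0.20
    t_cont_sigma: float = 0.20
    tau_median: float = 0.20
    tau_sigma: float = 0.35
    u_flow_mean: float = 12e-3
    u_flow_sd: float = 0.5e-3
    event_rate: float = 0.5  # cells/s (nominal spacing, never causes overlap)
    deficit: float = 0.3
    tau_range: tuple[float, float] = (0.020, 0.800)

    def __post_init__(self) -> None:
        for val, label in [
            (self.d0_median, "d0_median"),
            (self.t_cont_median, "t_cont_median"),
            (self.tau_median, "tau_median"),
            (self.u_flow_mean, "u_flow_mean"),
            (self.event_rate, "event_rate"),
        ]:
            if not val > 0:
                raise ValueError(f"{label} must be positive")
        if not (0 <= self.deficit < 1):
            raise ValueError("deficit must be in [0, 1)")
        lo, hi = self.tau_range
        if not (TAU_BOUNDS[0] <= lo < hi <= TAU_BOUNDS[1]):
            raise ValueError(f"tau_range must lie within {TAU_BOUNDS}")


def stiff_viscous_group(name: str = "AP-1060-like") -> GroupParams:
    """Stiff, slow-recovering cohort (ATRA-resistant-like contrast)."""
    return GroupParams(name, t_cont_median=0.25, tau_median=0.30)


def soft_fast_group(name: str = "NB4-like") -> GroupParams:
    """Soft, fast-recovering cohort (ATRA-sensitive-like contrast)."""
    return GroupParams(name, t_cont_median=0.15, tau_median=0.10)


_MIN_EVENT_GAP = 0.3  # s of clear baseline between consecutive events


def _event_duration(truth: CellGroundTruth, geometry: ChannelGeometry) -> float:
    u = truth.u_flow
    node = geometry.node.length / u
    rec = sum(s.length / u for s in geometry.recovery_segments)
    return (
        geometry.sizing_segment.length / u
        + truth.t_cont
        + (1 + geometry.n_recovery) * node
        + rec
    )


def sample_cohort(
    params: GroupParams,
    n: int,
    seed: int | np.random.SeedSequence,
    geometry: ChannelGeometry | None = None,
    overlap_fraction: float = 0.0,
    start_time: float = 1.0,
) -> list[CellGroundTruth]:
    """Draw ``n`` cells, reproducibly. Entry times are spaced so events never
    overlap unless ``overlap_fraction > 0`` (coincidence-rejection tests)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    geometry = geometry or ChannelGeometry()
    rng = np.random.default_rng(seed)
    de_sizing = geometry.effective_diameter(geometry.sizing_segment)
    d_lo = geometry.contraction_segment.width * 1.05
    d_hi = 0.95 * de_sizing
    tau_lo = max(params.tau_range[0], TAU_BOUNDS[0])
    tau_hi = min(params.tau_range[1], TAU_BOUNDS[1])

    def draw_until(sampler, ok, label):
        for _ in range(10_000):
            x = sampler()
            if ok(x):
                return x
        raise ValueError(f"could not draw a valid {label}; check {params.name} params")

    cells: list[CellGroundTruth] = []
    n_overlap = int(round(overlap_fraction * max(n - 1, 0)))
    overlap_idx = (
        set(rng.choice(np.arange(1, n), size=n_overlap, replace=False))
        if n_overlap
        else set()
    )
    t_prev = start_time
    dur_prev = 0.0
    for i in range(n):
        d0 = draw_until(
            lambda: math.exp(rng.normal(math.log(params.d0_median), params.d0_sigma)),
            lambda x: d_lo < x < d_hi,
            "diameter",
        )
        t_cont = draw_until(
            lambda: math.exp(
                rng.normal(math.log(params.t_cont_median), params.t_cont_sigma)
            ),
            lambda x: x > 0,
            "t_cont",
        )
        tau = draw_until(
            lambda: math.exp(rng.normal(math.log(params.tau_median), params.tau_sigma)),
            lambda x: tau_lo <= x <= tau_hi,
            "tau",
        )
        u = draw_until(
            lambda: rng.normal(params.u_flow_mean, params.u_flow_sd),
            lambda x: x > 0.1 * params.u_flow_mean,
            "u_flow",
        )
        truth = CellGroundTruth(d0, u, t_cont, tau, 0.0, params.deficit)
        dur = _event_duration(truth, geometry)
        if i == 0:
            entry = start_time
        elif i in overlap_idx:
            entry = t_prev + 0.35 * dur_prev
        else:
            spacing = max(1.0 / params.event_rate, dur_prev + _MIN_EVENT_GAP)
            entry = t_prev + spacing
        cells.append(replace(truth, entry_time=entry))
        t_prev, dur_prev = entry, dur
    return cells


def compute_wcdi_true(truth: CellGroundTruth, geometry: ChannelGeometry) -> float:
    """Ground-truth whole-cell deformability index for a simulated cell."""
    lc = geometry.contraction_segment.length
    return (lc / (truth.u_flow * geometry.h_channel)) * (truth.d0 / truth.t_cont)


def sigma_for_snr(
    snr: float,
    geometry: ChannelGeometry | None = None,
    acq: AcquisitionConfig | None = None,
    d0: float = 10.8e-6,
) -> float:
    """Raw-sample noise sigma giving the requested sizing-depth SNR for a
    typical cell of diameter ``d0``."""
    geometry = geometry or ChannelGeometry()
    acq = acq or AcquisitionConfig()
    depth = acq.baseline_current * blockade_fraction(d0, geometry.sizing_segment, geometry)
    return depth / snr


def simulate_trace(
    cohorts: list[tuple[GroupParams, int]],
    acq: AcquisitionConfig,
    geometry: ChannelGeometry | None = None,
    duration: float | None = None,
    overlap_fraction: float = 0.0,
    contraction_depth_factor: float = 3.0,
) -> tuple[RawTrace, pd.DataFrame]:
    """Simulate a full trace: baseline + drift + noise + superposed events.

    Cohorts are laid out sequentially in time. Returns the trace and a
    ground-truth table with one row per cell (all latent parameters plus the
    true wCDI, event boundaries and contraction-exit time).
    """
    geometry = geometry or ChannelGeometry()
    ss = np.random.SeedSequence(acq.seed)
    children = ss.spawn(len(cohorts) + 1)
    noise_rng = np.random.default_rng(children[-1])

    rows = []
    events: list[tuple[CellGroundTruth, SegmentSchedule, np.ndarray]] = []
    t_offset = 0.0
    cell_id = 0
    for (params, n), child in zip(cohorts, children[:-1]):
        cells = sample_cohort(
            params, n, child, geometry, overlap_fraction=overlap_fraction
        )
        for truth in cells:
            truth = replace(truth, entry_time=truth.entry_time + t_offset)
            deficit, sched = simulate_event(
                truth, geometry, acq, contraction_depth_factor
            )
            events.append((truth, sched, deficit))
            rows.append(
                {
                    "cell_id": cell_id,
                    "group": params.name,
                    "entry_time_s": truth.entry_time,
                    "d0_m": truth.d0,
                    "u_flow_m_s": truth.u_flow,
                    "t_cont_s": truth.t_cont,
                    "tau_s": truth.tau,
                    "deficit": truth.deformed_blockade_deficit,
                    "wcdi_true": compute_wcdi_true(truth, geometry),
                    "event_start_s": sched.t_start,
                    "event_end_s": sched.t_end,
                    "contraction_exit_s": sched.contraction_exit,
                    "sizing_depth_a": sched.sizing_depth,
                }
            )
            cell_id += 1
        if events:
            t_offset = events[-1][1].t_end + _MIN_EVENT_GAP

    fs = acq.sample_rate
    last_end = max((sched.t_end for _, sched, _ in events), default=0.0)
    total = duration if duration is not None else last_end + 1.0
    n_samples = int(round(total * fs))
    if events and last_end * fs > n_samples - 1:
        raise ValueError("events extend past the requested trace duration")

    if acq.noise_sigma > 0:
        samples = noise_rng.normal(0.0, acq.noise_sigma, n_samples)
    else:
        samples = np.zeros(n_samples)
    samples += acq.baseline_current
    if acq.drift_slope != 0.0:
        samples += acq.drift_slope * (np.arange(n_samples) / fs)
    for truth, sched, deficit in events:
        i0 = int(round(truth.entry_time * fs))
        samples[i0 : i0 + deficit.size] -= deficit

    truth_df = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "group",
            "entry_time_s",
            "d0_m",
            "u_flow_m_s",
            "t_cont_s",
            "tau_s",
            "deficit",
            "wcdi_true",
            "event_start_s",
            "event_end_s",
            "contraction_exit_s",
            "sizing_depth_a",
        ],
    )
    trace = RawTrace(samples, fs, 0.0, meta={"seed": acq.seed})
    return trace, truth_df
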