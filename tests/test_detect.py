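"""Pulse detection, subpulse segmentation and event QC."""

import numpy as np
import pytest

from mechanonps import (
    AcquisitionConfig,
    BaselineEstimate,
    PipelineConfig,
    PulseEvent,
    QCCode,
    RawTrace,
    Subpulse,
    detect_pulses,
    estimate_baseline,
    qc_event,
    segment_subpulses,
)
from mechanonps.pipeline import condition_trace
from mechanonps.simulate import sigma_for_snr, simulate_trace, stiff_viscous_group


def _conditioned(trace, cfg):
    ds = condition_trace(trace, cfg)
    return ds, estimate_baseline(ds)


class TestDetect:
    def test_flat_noisy_trace_no_events(self):
        rng = np.random.default_rng(3)
        t = RawTrace(1e-6 + rng.normal(0, 5e-9, 50_000), 2500.0)
        est = estimate_baseline(t)
        assert detect_pulses(t, est, k=5.0) == []

    def test_three_events_boundaries_match_schedule(self, geometry, config, snr20_acq):
        trace, truth = simulate_trace([(stiff_viscous_group(), 3)], snr20_acq, geometry)
        ds, est = _conditioned(trace, config)
        events = detect_pulses(ds, est, abs_threshold=1e-9)
        assert len(events) == 3
        period = 1.0 / ds.sample_rate
        for ev, (_, row) in zip(events, truth.iterrows()):
            assert abs(ds.time_at(ev.start) - row.event_start_s) <= 2 * period
            assert abs(ds.time_at(ev.end) - row.event_end_s) <= 2 * period

    def test_zero_noise_requires_absolute_threshold(self, geometry, config, noiseless_acq):
        trace, _ = simulate_trace([(stiff_viscous_group(), 1)], noiseless_acq, geometry)
        ds, est = _conditioned(trace, config)
        assert est.noise_scale == 0.0
        with pytest.raises(ValueError, match="threshold"):
            detect_pulses(ds, est, abs_threshold=None)
        assert len(detect_pulses(ds, est, abs_threshold=1e-9)) == 1

    def test_overlapping_events_merged_and_flagged(self, geometry, config, snr20_acq):
        trace, truth = simulate_trace(
            [(stiff_viscous_group(), 2)], snr20_acq, geometry, overlap_fraction=1.0
        )
        ds, est = _conditioned(trace, config)
        events = detect_pulses(ds, est, abs_threshold=1e-9)
        assert len(events) == 1
        sub = segment_subpulses(events[0], ds, est, geometry, abs_threshold=1e-9)
        flag = qc_event(events[0], sub, geometry, est.noise_scale)
        assert flag.code is QCCode.COINCIDENCE

    def test_isolated_spikes_discarded(self):
        rng = np.random.default_rng(4)
        x = 1e-6 + rng.normal(0, 2e-9, 25_000)
        x[5000] -= 1e-7  # single-sample artifact, not a transit
        t = RawTrace(x, 2500.0)
        est = estimate_baseline(t)
        assert detect_pulses(t, est, k=5.0, min_run_s=0.002) == []


class TestSegment:
    def test_noiseless_event_recovers_schedule_exactly(self, geometry, config, noiseless_acq):
        trace, truth = simulate_trace([(stiff_viscous_group(), 1)], noiseless_acq, geometry)
        ds, est = _conditioned(trace, config)
        (event,) = detect_pulses(ds, est, abs_threshold=1e-9)
        sub = segment_subpulses(event, ds, est, geometry, abs_threshold=1e-9)
        assert [sp.kind for sp in sub] == ["sizing", "contraction"] + ["recovery"] * 10
        assert [sp.order for sp in sub[2:]] == list(range(1, 11))
        # depths match the scheduled (simulated) values to numerical rounding
        row = truth.iloc[0]
        assert sub[0].depth == pytest.approx(row.sizing_depth_a, rel=1e-9)
        assert sub[1].depth == pytest.approx(3 * row.sizing_depth_a, rel=1e-9)
        assert qc_event(event, sub, geometry, 0.0).code is QCCode.OK

    def test_truncated_event_flagged(self, geometry, config, noiseless_acq):
        trace, truth = simulate_trace([(stiff_viscous_group(), 1)], noiseless_acq, geometry)
        # cut the trace in the middle of the event
        cut = int((truth.iloc[0].event_start_s + 0.2) * trace.sample_rate)
        short = RawTrace(trace.samples[:cut], trace.sample_rate)
        ds = condition_trace(short, config)
        est = estimate_baseline(ds, window=2000)
        events = detect_pulses(ds, est, abs_threshold=1e-9)
        assert len(events) == 1 and events[0].truncated
        sub = segment_subpulses(events[0], ds, est, geometry, abs_threshold=1e-9)
        assert qc_event(events[0], sub, geometry, 0.0).code is QCCode.TRUNCATED

    def test_depth_errors_scale_with_noise(self, geometry, config):
        # depth error over a plateau interior is ~ noise_scale/sqrt(len)
        acq = AcquisitionConfig(noise_sigma=sigma_for_snr(20), seed=31)
        trace, truth = simulate_trace([(stiff_viscous_group(), 30)], acq, geometry)
        ds, est = _conditioned(trace, config)
        events = detect_pulses(ds, est)
        assert len(events) == 30
        # second-pass baseline with event spans masked, as the pipeline does
        exclude = np.zeros(len(ds), dtype=bool)
        for ev in events:
            exclude[max(ev.start - 25, 0) : ev.end + 25] = True
        est = estimate_baseline(ds, exclude=exclude)
        ratios = []
        for ev, (_, row) in zip(events, truth.iterrows()):
            sub = segment_subpulses(ev, ds, est, geometry)
            sizing = sub[0]
            err = abs(sizing.depth - row.sizing_depth_a)
            bound = 3 * est.noise_scale / np.sqrt(max(sizing.n_samples, 1))
            ratios.append(err / bound)
        # the filter correlates neighbouring conditioned samples, so the
        # i.i.d. bound is optimistic by a modest constant factor
        assert np.median(ratios) < 1.0
        assert max(ratios) < 5.0


class TestQC:
    def _clean_subpulses(self):
        # hand-built event at u = 12 mm/s on a 10 uA baseline
        baseline, depth, u = 1e-5, 1.2e-7, 12e-3
        size_dur, node_dur, rec_dur = 800e-6 / u, 50e-6 / u, 290e-6 / u
        sub = [Subpulse("sizing", 0, 0.0, size_dur, depth, baseline - depth, 160)]
        t = size_dur + node_dur
        t_exit = t + 0.16
        sub.append(Subpulse("contraction", 0, t, t_exit, 3 * depth, baseline - 3 * depth, 400))
        t = t_exit
        for k in range(1, 11):
            t += node_dur
            d = depth * (1 - 0.3 * np.exp(-(t + rec_dur / 2 - t_exit) / 0.15))
            sub.append(Subpulse("recovery", k, t, t + rec_dur, d, baseline - d, 60))
            t += rec_dur
        return sub

    def test_clean_event_ok(self, geometry):
        sub = self._clean_subpulses()
        ev = PulseEvent(10, 1000)
        assert qc_event(ev, sub, geometry, 1e-9).code is QCCode.OK

    def test_decreasing_recovery_depths_rejected(self, geometry):
        sub = self._clean_subpulses()
        bad = sub[6]
        sub[6] = Subpulse(bad.kind, bad.order, bad.t_start, bad.t_end,
                          bad.depth * 0.5, bad.level, bad.n_samples)
        ev = PulseEvent(10, 1000)
        assert qc_event(ev, sub, geometry, 1e-9).code is QCCode.LOW_SNR

    def test_missing_subpulses_rejected(self, geometry):
        # a mid-train recovery plateau lost to noise: count short, span intact
        sub = self._clean_subpulses()
        del sub[6]
        ev = PulseEvent(10, 1000)
        assert qc_event(ev, sub, geometry, 1e-9).code is QCCode.MISSING_SUBPULSES

    def test_two_deep_plateaus_is_coincidence(self, geometry):
        sub = self._clean_subpulses()
        extra = Subpulse("recovery", 5, sub[6].t_start, sub[6].t_end,
                         3.4e-7, 1e-5 - 3.4e-7, 60)
        sub[6] = extra
        ev = PulseEvent(10, 1000)
        assert qc_event(ev, sub, geometry, 1e-9).code is QCCode.COINCIDENCE
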