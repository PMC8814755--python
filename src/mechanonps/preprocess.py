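"""Trace conditioning: moving-average low-pass filter, block-mean
downsampling (50 kHz -> 2.5 kHz by default), and robust baseline/noise
estimation.

The moving average is centered with shrinking windows at the edges, so
length is preserved and constants pass through unchanged. Downsampling is
by block means rather than naive decimation, consistent with the preceding
low-pass filter. The baseline is a centered rolling median with a window
much longer than any pulse, which is robust to the asymmetric negative
excursions cells produce; the noise scale is 1.4826 * MAD of the residual
on non-excursion samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import RawTrace

__all__ = ["BaselineEstimate", "moving_average", "downsample", "estimate_baseline"]


@dataclass
class BaselineEstimate:
    baseline: np.ndarray  # same length as the trace, amperes
    noise_scale: float  # robust per-sample sigma, amperes

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if not np.all(np.isfinite(self.baseline)):
            raise ValueError("baseline must be finite everywhere")


def moving_average(trace: RawTrace, window: int) -> RawTrace:
    """Centered moving mean of length ``window``; shrinking windows at the
    edges preserve trace length."""
    n = len(trace)
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    x = trace.samples
    # subtract the grand mean before the cumulative sum: partial sums then
    # stay near zero and the windowed means lose no precision to cancellation
    m = x.mean()
    s = np.empty(n + 1)
    s[0] = 0.0
    np.cumsum(x - m, out=s[1:])
    idx = np.arange(n)
    lo = np.clip(idx - (window - 1) // 2, 0, n)
    hi = np.clip(idx + window // 2 + 1, 0, n)
    out = (s[hi] - s[lo]) / (hi - lo) + m
    return RawTrace(out, trace.sample_rate, trace.start_time, dict(trace.meta))


def downsample(trace: RawTrace, factor: int) -> RawTrace:
    """Block means of consecutive ``factor``-sized blocks; the new sample
    rate is ``old / factor`` and length ``floor(n / factor)``."""
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return RawTrace(
            trace.samples.copy(), trace.sample_rate, trace.start_time, dict(trace.meta)
        )
    n_out = len(trace) // factor
    blocks = trace.samples[: n_out * factor].reshape(n_out, factor)
    return RawTrace(
        blocks.mean(axis=1),
        trace.sample_rate / factor,
        trace.start_time,
        dict(trace.meta),
    )


def estimate_baseline(
    trace: RawTrace,
    window: int | None = None,
    exclude: np.ndarray | None = None,
) -> BaselineEstimate:
    """Rolling-median baseline plus a robust noise scale.

    ``window`` defaults to 2 s of samples, much longer than a cell transit.
    Samples deviating by more than 4 robust sigma (the pulses) are excluded
    from the final noise estimate. Raises if the trace is shorter than the
    window or if excursions leave no baseline support.

    ``exclude`` masks known pulse spans (boolean, True = in pulse) out of
    the median: a single pass is biased by up to ~0.5 sigma wherever
    one-sided excursions contaminate the window, so callers that already
    know the event locations should re-estimate with them excluded.
    """
    n = len(trace)
    if window is None:
        window = int(round(2.0 * trace.sample_rate))
    if window < 1:
        raise ValueError("baseline window must be >= 1 sample")
    if n <= window:
        raise ValueError(f"trace length {n} must exceed baseline window {window}")
    x = trace.samples
    if exclude is not None:
        masked = x.astype(float).copy()
        masked[exclude] = np.nan
        series = pd.Series(masked)
    else:
        series = pd.Series(x)
    baseline = (
        series
        .rolling(window, center=True, min_periods=max(1, window // 4))
        .median()
        .to_numpy()
    )
    if exclude is not None:
        baseline = (
            pd.Series(baseline).interpolate(limit_direction="both").to_numpy()
        )
        if not np.all(np.isfinite(baseline)):
            raise ValueError("no baseline support: trace is almost all excursion")
    resid = x - baseline
    if exclude is not None:
        resid = resid[~exclude]
        if resid.size < max(10, n // 100):
            raise ValueError("no baseline support: trace is almost all excursion")
    scale0 = 1.4826 * np.median(np.abs(resid))
    if scale0 == 0.0:
        scale = 0.0
    else:
        keep = np.abs(resid) <= 4.0 * scale0
        scale = float(1.4826 * np.median(np.abs(resid[keep])))
    # baseline support: pulses are one-sided negative excursions, so the
    # residual should essentially never sit far above the rolling median;
    # when the trace is mostly in-pulse the median drops into the pulses and
    # the true-baseline samples surface as positive excursions
    above = np.mean(resid > 4.0 * scale) if scale > 0 else np.mean(resid > 0)
    if above > 0.15:
        raise ValueError("no baseline support: trace is almost all excursion")
    return BaselineEstimate(baseline, scale)
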