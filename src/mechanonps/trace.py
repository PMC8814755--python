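"""Raw current traces and their on-disk formats.

A :class:`RawTrace` is a uniformly sampled current series in amperes.
Two dialects are accepted on disk:

* text — a small self-describing TSV: ``#``-prefixed header block
  (``sample_rate_hz``, ``start_time_s``, ``units``, ``schema_version``)
  followed by ``time_s<TAB>current_a`` rows, >= 15 significant digits;
* binary — an HDF5 container with the same metadata as attributes and a
  single ``current_a`` dataset; round-trips bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["RawTrace", "TraceFormatError", "read_trace", "write_trace"]

_SCHEMA_VERSION = 1


class TraceFormatError(ValueError):
    """Malformed trace file (missing header fields, non-uniform sampling...)."""


@dataclass
class RawTrace:
    """Uniformly sampled current series.

    Parameters
    ----------
    samples : array of current values in amperes.
    sample_rate : sampling rate in Hz.
    start_time : time of the first sample in seconds.
    meta : free-form acquisition provenance.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError("sample rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    def time_at(self, index: float) -> float:
        """Time of a (possibly fractional) sample index."""
        return self.start_time + index / self.sample_rate


def write_trace(trace: RawTrace, path: str | Path) -> Path:
    """Write a trace; dialect chosen by suffix (.h5/.hdf5 binary, else text)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("current_a", data=trace.samples)
            dset.attrs["units"] = "ampere"
            f.attrs["sample_rate_hz"] = float(trace.sample_rate)
            f.attrs["start_time_s"] = float(trace.start_time)
            f.attrs["schema_version"] = _SCHEMA_VERSION
        return path
    with open(path, "w") as f:
        f.write("# mechanonps trace\n")
        f.write(f"# schema_version: {_SCHEMA_VERSION}\n")
        f.write(f"# sample_rate_hz: {trace.sample_rate!r}\n")
        f.write(f"# start_time_s: {trace.start_time!r}\n")
        f.write("# units: ampere\n")
        f.write("time_s\tcurrent_a\n")
        df = pd.DataFrame(
            {"time_s": trace.times(), "current_a": trace.samples}
        )
        df.to_csv(f, sep="\t", index=False, header=False, float_format="%.17g")
    return path


def _read_text(path: Path) -> RawTrace:
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as f:
        for line in f:
            n_header += 1
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    header[key.strip()] = value.strip()
                continue
            if line.startswith("time_s"):
                break
            raise TraceFormatError(
                f"{path}: line {n_header}: expected header or column names"
            )
    for key in ("sample_rate_hz", "start_time_s", "units"):
        if key not in header:
            raise TraceFormatError(f"{path}: missing header field '{key}'")
    if header["units"] != "ampere":
        raise TraceFormatError(f"{path}: unsupported units {header['units']!r}")
    rate = float(header["sample_rate_hz"])
    start = float(header["start_time_s"])
    df = pd.read_csv(
        path,
        sep="\t",
        skiprows=n_header,
        header=None,
        names=["time_s", "current_a"],
        float_precision="round_trip",
    )
    t = df["time_s"].to_numpy()
    if t.size > 1:
        dt = np.diff(t)
        period = 1.0 / rate
        bad = np.flatnonzero((dt > 1.5 * period) | (dt <= 0))
        if bad.size:
            raise TraceFormatError(
                f"{path}: line {n_header + int(bad[0]) + 2}: non-uniform time column "
                f"(step {dt[bad[0]]:.3e} s vs period {period:.3e} s)"
            )
    return RawTrace(df["current_a"].to_numpy(), rate, start, meta={"path": str(path)})


def read_trace(path: str | Path) -> RawTrace:
    """Read either trace dialect; the binary dialect is sniffed, not inferred
    from the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            for key in ("sample_rate_hz", "start_time_s"):
                if key not in f.attrs:
                    raise TraceFormatError(f"{path}: missing attribute '{key}'")
            samples = f["current_a"][...]
            return RawTrace(
                samples,
                float(f.attrs["sample_rate_hz"]),
                float(f.attrs["start_time_s"]),
                meta={"path": str(path)},
            )
    return _read_text(path)
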