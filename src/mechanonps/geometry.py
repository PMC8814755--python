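"""Channel geometry and the resistive-pulse volume-blockade model.

A mechano-NPS channel is a single microfluidic channel of uniform height,
segmented by wide "nodes" into sensing segments: one sizing segment, one
narrow contraction segment that compresses the cell, and a series of wider
recovery segments where the deformed cell relaxes back toward a sphere.
A cell occupying a segment displaces electrolyte and drops the measured
current; the relative drop (blockade fraction) encodes cell volume.

Sizing uses the Deblois-Bean volume-blockade relation with the standard
cubic shape correction,

    dI/I = d^3 / (D_e^2 * L) * [1 - 0.8 (d/D_e)^3]^-1,

where ``d`` is the particle diameter, ``L`` the segment length, and
``D_e = 2*sqrt(w*h/pi)`` the effective circular diameter of the rectangular
``w x h`` cross-section. The relation is strictly increasing in ``d`` for
``d < D_e``, so diameters are recovered by bracketed root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "Segment",
    "ChannelGeometry",
    "blockade_fraction",
    "diameter_from_blockade",
]


@dataclass(frozen=True)
class Segment:
    """One sensing segment: in-plane width and length, in meters."""

    width: float
    length: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.length > 0):
            raise ValueError(
                f"segment dimensions must be positive, got {self.width} x {self.length}"
            )


def _default_recovery() -> tuple[Segment, ...]:
    return tuple(Segment(13e-6, 290e-6) for _ in range(10))


@dataclass(frozen=True)
class ChannelGeometry:
    """Device geometry; defaults are the 12.9 um-high channel with a
    7 x 2000 um contraction segment, a 13 x 800 um sizing segment,
    ten 13 x 290 um recovery segments, and 85 x 50 um nodes."""

    h_channel: float = 12.9e-6
    sizing_segment: Segment = Segment(13e-6, 800e-6)
    contraction_segment: Segment = Segment(7e-6, 2000e-6)
    node: Segment = Segment(85e-6, 50e-6)
    recovery_segments: tuple[Segment, ...] = field(default_factory=_default_recovery)

    def __post_init__(self) -> None:
        if self.h_channel <= 0:
            raise ValueError("channel height must be positive")
        if not self.recovery_segments:
            raise ValueError("at least one recovery segment is required")
        if self.contraction_segment.width >= self.sizing_segment.width:
            raise ValueError("contraction segment must be narrower than sizing segment")
        for seg in self.recovery_segments:
            if not math.isclose(seg.width, self.sizing_segment.width, rel_tol=1e-9):
                raise ValueError("recovery segments must share the sizing-segment width")
        widest = max(
            self.sizing_segment.width,
            self.contraction_segment.width,
            max(s.width for s in self.recovery_segments),
        )
        if self.node.width <= widest:
            raise ValueError("nodes must be wider than every sensing segment")

    @property
    def n_recovery(self) -> int:
        return len(self.recovery_segments)

    def effective_diameter(self, segment: Segment) -> float:
        """Effective circular diameter of a rectangular cross-section (m)."""
        return 2.0 * math.sqrt(segment.width * self.h_channel / math.pi)


def blockade_fraction(d: float, segment: Segment, geometry: ChannelGeometry) -> float:
    """Relative current drop dI/I for a sphere of diameter ``d`` in ``segment``.

    Strictly increasing in ``d`` on [0, D_e); raises for ``d >= D_e`` (the
    particle would occlude the pore) and for negative diameters.
    """
    if d < 0:
        raise ValueError("diameter must be non-negative")
    if d == 0:
        return 0.0
    de = geometry.effective_diameter(segment)
    if d >= de:
        raise ValueError(
            f"diameter {d:.3e} m >= effective pore diameter {de:.3e} m: "
            "unphysical occlusion"
        )
    ratio3 = (d / de) ** 3
    return d**3 / (de**2 * segment.length) / (1.0 - 0.8 * ratio3)


def diameter_from_blockade(
    depth_fraction: float, segment: Segment, geometry: ChannelGeometry
) -> float:
    """Invert :func:`blockade_fraction`: the unique diameter producing the
    given relative current drop, by bracketed root finding (Brent)."""
    if not depth_fraction > 0:
        raise ValueError("depth fraction must be positive")
    de = geometry.effective_diameter(segment)
    d_hi = de * (1.0 - 1e-9)
    f_max = blockade_fraction(d_hi, segment, geometry)
    if depth_fraction >= f_max:
        raise ValueError(
            f"depth fraction {depth_fraction:.3e} outside attainable range "
            f"(< {f_max:.3e} for this segment)"
        )
    return brentq(
        lambda d: blockade_fraction(d, segment, geometry) - depth_fraction,
        0.0,
        d_hi,
        xtol=1e-21,
        rtol=4 * 2.220446049250313e-16,
    )
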