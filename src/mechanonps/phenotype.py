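"""Per-cell mechanical phenotype from an accepted event's subpulses.

From the 12-subpulse anatomy this module extracts:

* free diameter ``d0`` — inversion of the sizing-subpulse blockade fraction;
* pre-contraction velocity ``u_flow = L_sizing / sizing duration``;
* contraction transit time ``t_cont`` — the contraction-subpulse duration;
* strain ``eps = (d0 - w_c) / d0`` with ``w_c`` the contraction width (the
  12.9 um channel height exceeds typical cell diameters, so deformation is
  width-limited);
* whole-cell deformability index
  ``wCDI = (l_c / (u_flow * h_channel)) * (d0 / t_cont)`` — dimensionless,
  higher = softer, inversely related to cortical tension;
* recovery time constant ``tau`` — a cell released from the constriction is
  a Kelvin-Voigt solid undergoing a step change in stress, so its strain
  (and hence in-segment current) relaxes exponentially:

      I(t) = I_inf + A * exp(-t / tau).

  With the fully-recovered level ``I_inf`` fixed to the sizing-subpulse
  level (sizing and recovery segments share width and height), the model is
  linear in logs, ``ln[I(t) - I_inf] = ln A - t/tau``, and tau comes from
  ordinary least squares with a delta-method 95% CI on -1/slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .detect import Subpulse
from .geometry import ChannelGeometry, diameter_from_blockade

__all__ = [
    "RecoveryFit",
    "CellPhenotype",
    "compute_velocity",
    "compute_strain",
    "compute_wcdi",
    "fit_recovery",
    "phenotype_event",
]

TAU_SANITY_BAND = (0.005, 2.0)  # s; the observed range is 20-800 ms plus margin


@dataclass(frozen=True)
class RecoveryFit:
    """Kelvin-Voigt recovery fit result.

    ``valid`` is False (never an exception) when tau is unidentifiable:
    fewer than ``min_points`` usable subpulses or a non-negative slope.
    ``in_band`` flags estimates outside the sanity band for review.
    """

    tau: float = float("nan")
    tau_ci95: tuple[float, float] = (float("nan"), float("nan"))
    i_inf: float = float("nan")
    i0_amp: float = float("nan")
    n_points: int = 0
    r_squared: float = float("nan")
    valid: bool = False
    in_band: bool = False


@dataclass(frozen=True)
class CellPhenotype:
    d0: float  # m
    u_flow: float  # m/s
    t_cont: float  # s
    strain: float
    wcdi: float
    recovery: RecoveryFit
    event_id: int = -1
    t_start: float = float("nan")  # event start time, provenance


def compute_velocity(sizing: Subpulse, geometry: ChannelGeometry) -> float:
    """Pre-contraction velocity from the sizing-subpulse duration."""
    dur = sizing.duration
    if not dur > 0:
        raise ValueError("sizing subpulse duration must be positive")
    return geometry.sizing_segment.length / dur


def compute_strain(d0: float, geometry: ChannelGeometry) -> float:
    """Applied strain eps = (d0 - w_c)/d0; errors if the cell is not deformed."""
    if not d0 > 0:
        raise ValueError("diameter must be positive")
    wc = geometry.contraction_segment.width
    if d0 <= wc:
        raise ValueError(
            f"d0 = {d0:.3e} m does not exceed the contraction width {wc:.3e} m"
        )
    return (d0 - wc) / d0


def compute_wcdi(
    d0: float, u_flow: float, t_cont: float, geometry: ChannelGeometry
) -> float:
    """Whole-cell deformability index; dimensionless and unit-system invariant."""
    if not (d0 > 0 and u_flow > 0 and t_cont > 0):
        raise ValueError("d0, u_flow and t_cont must all be positive")
    lc = geometry.contraction_segment.length
    return (lc / (u_flow * geometry.h_channel)) * (d0 / t_cont)


def fit_recovery(
    recovery_subpulses: list[Subpulse],
    i_inf: float,
    t0: float,
    min_points: int = 4,
    tau_band: tuple[float, float] = TAU_SANITY_BAND,
) -> RecoveryFit:
    """Estimate tau from recovery-subpulse levels by the linearized fit.

    ``t0`` is the contraction-exit time; each subpulse contributes its
    midpoint time ``t_k = midpoint - t0`` and ``y_k = ln(level_k - i_inf)``.
    Points with ``level_k <= i_inf`` (log undefined: the cell already looks
    fully recovered there) are excluded. The 95% CI comes from the slope's
    standard error by the delta method with a t(n-2) quantile.
    """
    pts = [
        (sp.midpoint - t0, sp.level)
        for sp in recovery_subpulses
        if sp.level > i_inf
    ]
    n = len(pts)
    if n < min_points:
        return RecoveryFit(i_inf=i_inf, n_points=n)
    t = np.array([p[0] for p in pts])
    y = np.log(np.array([p[1] for p in pts]) - i_inf)
    res = sps.linregress(t, y)
    if not res.slope < 0:
        return RecoveryFit(i_inf=i_inf, n_points=n)
    tau = -1.0 / res.slope
    se_tau = res.stderr / res.slope**2
    tcrit = sps.t.ppf(0.975, n - 2)
    ci = (tau - tcrit * se_tau, tau + tcrit * se_tau)
    return RecoveryFit(
        tau=float(tau),
        tau_ci95=(float(ci[0]), float(ci[1])),
        i_inf=float(i_inf),
        i0_amp=float(math.exp(res.intercept)),
        n_points=n,
        r_squared=float(res.rvalue**2),
        valid=True,
        in_band=tau_band[0] <= tau <= tau_band[1],
    )


def phenotype_event(
    subpulses: list[Subpulse],
    geometry: ChannelGeometry,
    event_id: int = -1,
    min_points: int = 4,
    tau_band: tuple[float, float] = TAU_SANITY_BAND,
) -> CellPhenotype:
    """Assemble the full phenotype for one QC-accepted event.

    The fully-recovered current ``I_inf`` is taken from the sizing subpulse
    (same cross-section as the recovery segments). Recovery levels are
    re-referenced to the sizing-plateau local baseline so slow drift cancels
    out of the fit. An unidentifiable tau yields ``recovery.valid = False``
    rather than an error.
    """
    sizing = next(sp for sp in subpulses if sp.kind == "sizing")
    contraction = next(sp for sp in subpulses if sp.kind == "contraction")
    recovery = sorted(
        (sp for sp in subpulses if sp.kind == "recovery"), key=lambda sp: sp.order
    )

    local_baseline = sizing.level + sizing.depth
    frac = sizing.depth / local_baseline
    d0 = diameter_from_blockade(frac, geometry.sizing_segment, geometry)
    u_flow = compute_velocity(sizing, geometry)
    t_cont = contraction.duration
    strain = compute_strain(d0, geometry)
    wcdi = compute_wcdi(d0, u_flow, t_cont, geometry)

    i_inf = local_baseline - sizing.depth
    referenced = [
        Subpulse(
            sp.kind, sp.order, sp.t_start, sp.t_end,
            sp.depth, local_baseline - sp.depth, sp.n_samples,
        )
        for sp in recovery
    ]
    fit = fit_recovery(
        referenced, i_inf, contraction.t_end, min_points=min_points, tau_band=tau_band
    )
    return CellPhenotype(
        d0=d0,
        u_flow=u_flow,
        t_cont=t_cont,
        strain=strain,
        wcdi=wcdi,
        recovery=fit,
        event_id=event_id,
        t_start=sizing.t_start,
    )
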