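# Methods

`mechanonps` analyses mechano-node-pore-sensing (mechano-NPS) recordings: a
cell suspension is driven through a single microfluidic channel of uniform
height that is divided by wide "nodes" into a sizing segment, a narrow
contraction segment, and a train of recovery segments. A DC four-terminal
measurement across the channel reports a current that drops whenever a cell
occupies a sensing segment, so each transit produces one pulse composed of
2 + n_recovery subpulses. This note records the models, the estimators, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Sizing model

A sphere of diameter `d` inside a segment of length `L` blocks a fraction of
the current given by the Deblois–Bean volume-blockade relation with the
standard cubic shape correction,

    ΔI/I = d³ / (D_e² · L) · [1 − 0.8 (d/D_e)³]⁻¹ ,

where `D_e = 2·sqrt(w·h/π)` is the effective circular diameter of the
rectangular `w × h` cross-section. The relation is strictly increasing on
`[0, D_e)`; `diameter_from_blockade` inverts it by Brent root finding to
machine precision. The simulator and the phenotype stage share the same
relation, so sizing is self-consistent by construction; absolute sizing
accuracy on real data depends on how well this relation describes the
device, which the package cannot test.

Default geometry (all configurable): channel height 12.9 µm; sizing segment
13 × 800 µm; contraction segment 7 × 2000 µm; ten recovery segments
13 × 290 µm; nodes 85 × 50 µm. Currents are held in amperes and lengths in
meters internally; TSV outputs use the human-scale units named in their
column headers.

## Per-cell phenotype

For a QC-accepted event with sizing subpulse (depth `ΔI_s`, duration `T_s`)
and contraction subpulse of duration `t_cont`:

* free diameter `d0` — inversion of `ΔI_s / I_baseline`, where the local
  baseline is `level + depth` of the sizing plateau;
* velocity `u_flow = L_sizing / T_s`;
* strain `ε = (d0 − w_c)/d0` with `w_c` the contraction width. The channel
  height (12.9 µm) exceeds typical cell diameters, so deformation is
  width-limited; for ~10.8 µm cells this gives the device's operating
  strain of ε ≈ 0.35.
* whole-cell deformability index
  `wCDI = (l_c / (u_flow · h_channel)) · (d0 / t_cont)`, dimensionless,
  higher = softer; it is invariant under a global rescaling of length and
  time units (tested).

## Recovery-time estimation

The cell is modelled as a homogeneous Kelvin–Voigt solid. Release from the
constriction is a step change in compressive stress, so strain — and after
the transform into the current domain, the in-segment current — relaxes
exponentially with time constant τ:

    I(t) = I_∞ + A·e^(−t/τ),  A > 0.

`I_∞`, the fully-recovered level, is fixed to the sizing-subpulse level:
sizing and recovery segments share width and height, so a recovered sphere
blocks both identically. This removes a third free parameter. Recovery
levels are re-referenced to the sizing-plateau local baseline
(`level_k := baseline_sizing − depth_k`) so that slow baseline drift
cancels out of the fit.

Taking logarithms linearizes the model,
`ln[I(t_k) − I_∞] = ln A − t_k/τ`, and τ comes from ordinary least squares
with `t_k` the subpulse midpoint minus the contraction-exit time (midpoints
minimize within-segment averaging bias). Points with `level ≤ I_∞` are
excluded (log undefined — the cell already looks recovered there); at least
4 usable points are required, and a non-negative slope yields
`valid = False` rather than an error. The 95% CI on τ = −1/slope comes from
the slope's standard error by the delta method with a t(n−2) quantile.
Estimates outside a [5 ms, 2 s] sanity band (the observed biological range
is 20–800 ms) keep `valid = True` but are flagged for review.

On noiseless exponentials the fit is exact to floating-point rounding for
any τ in [5, 2000] ms and agrees with a 1 ms-grid nonlinear least-squares
search within grid resolution (both tested). Under 5% amplitude noise the
log-space estimator and level-space NLS agree to ~5% median; the
linearization upweights late, low-amplitude points, which is the main
source of the difference.

## Trace conditioning and event detection

Raw traces (50 kHz) are conditioned by a centered 20-sample moving average
(0.4 ms) followed by block-mean downsampling by 20 to 2.5 kHz — block means
rather than naive decimation, so the downsampler is consistent with the
preceding low-pass filter. The filter window matches the downsampling block
so the 2.5 kHz series is effectively block-averaged. No spectral filtering,
mains notch, or adaptive filtering is attempted.

The baseline is a centered rolling median (window 2 s, far longer than any
transit) and the noise scale is 1.4826·MAD of the residual outside ±4σ
excursions. A single pass is biased upward by up to ~0.5σ wherever the
one-sided negative pulses contaminate the window, so the pipeline runs a
second pass with the detected event spans masked out of the median; the
noiseless path is unaffected, and the noisy path's depth errors then sit at
the `noise/√(plateau length)` scale.

Events are maximal runs where the deficit `baseline − I` exceeds
`k·noise_scale` (default k = 5; an absolute fallback threshold of 1 nA
applies to noiseless traces), merged across sub-threshold gaps shorter than
the node-dwell horizon (50 ms ≈ node length / minimum plausible velocity)
and pruned of isolated spikes shorter than 2 ms. Within an event, plateaus
are separated by near-baseline node intervals (nodes are 85 µm wide, so a
cell there barely blocks current). Plateau depth is the trimmed interior
mean (10% per edge, which covers the ~0.8 ms filter smear); plateau
boundaries are refined to the half-depth crossing by linear interpolation —
the moving-average + block-mean smear is symmetric about the true edge, so
the half-height crossing is an unbiased edge estimate accurate to well
under one downsampled sample, where a plain threshold crossing would bias
`t_cont` by ~0.8 ms.

QC accepts an event only when the full anatomy of a single transit is
present: exactly 2 + n_recovery plateaus; the contraction plateau the
unique deepest and in position; recovery depths non-decreasing within 3σ
and never exceeding the sizing depth beyond noise; a physically invertible
sizing fraction; and timing consistency — the sizing duration fixes the
velocity, which fixes every recovery-plateau duration (±2% or two sample
periods) and the whole-event span (±10%). The timing checks are what catch
merged coincident transits whose superposition happens to produce a
plausible plateau count. Coincident cells are rejected, never deconvolved.
All intervals are half-open, 0-based, with `time = index / sample_rate`.

## Cohort statistics

Group comparisons use two-sample Student t-tests (pooled variance — Welch
available behind a flag) at α = 0.05 for two groups, and Tukey–Kramer
simultaneous all-pairs comparisons (scipy's studentized-range
implementation) for three or more; Tukey–Kramer is used because group sizes
are unequal in practice. A Bonferroni correction divides α by the number of
planned t-tests when the analysis plan declares several. Box summaries use
linearly interpolated quartiles and McGill notches,
`median ± 1.57·IQR/√n`, the conventional 95% CI for the median. Post-hoc
power for each test comes from the noncentral-t distribution at the
observed Cohen's d, and for under-powered tests (< 0.80) the minimum effect
size reaching power 0.80 is reported, found by bracketed root finding; the
root is cached per (n_a, n_b, α) since it does not depend on the data.
Power is cross-checked against statsmodels' independent implementation in
the tests.

## Synthetic-data generator

The generator is the package's ground-truth instrument: baseline current
(default 10 µA) with optional linear drift and i.i.d. Gaussian noise, plus
superposed per-cell deficit trains. Per cell, the 12 subpulses follow the
geometry at the sampled velocity; the contraction subpulse depth is a fixed
multiple (default 3×) of the sizing depth — its amplitude is never used
downstream, only its duration; the recovery subpulse k has constant depth
`ΔI_s·[1 − deficit·e^(−t_k/τ)]` evaluated at its midpoint, where `deficit`
(default 0.3) is the fractional under-blockade of the just-released
bullet-shaped cell relative to a sphere. Nodes are rendered at exact
baseline.

Cohort defaults emulate the stiff/viscous vs soft/fast contrast between an
ATRA-resistant and an ATRA-sensitive APL line: diameters lognormal with
median 10.8 µm (σ_log 0.06), which realises the ε ≈ 0.35 operating strain;
velocities N(12, 0.5) mm/s; contraction transit times lognormal with
medians 250 ms (stiff) vs 150 ms (soft), σ_log 0.2 — deformation dwell in
this device is in the 150–200 ms range, and the ratio produces a 0.6×
median wCDI contrast; recovery τ lognormal with medians 300 vs 100 ms,
σ_log 0.35, truncated to the observable 20–800 ms band. Events are spaced
~2 s apart (0.5 cells/s) unless an overlap fraction is requested for
coincidence-rejection tests.

What the generator does **not** emulate: 1/f and mains noise, electrode
drift beyond a linear term, velocity changes along the channel (the cell
re-accelerates to `u_flow` after the constriction in the model), bullet-
shape electrostatics beyond the single deficit factor, cell–wall friction
variation, debris, and partial-depth artifacts. Passing tests therefore
demonstrate the correctness of the estimators and the pipeline logic under
the stated signal model, not robustness to every artifact of real
recordings.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to be
informative while remaining quick on a single CPU: the noiseless round trip
uses 50 cells; the τ Monte Carlo 1000 replicates; detection operating
characteristics 1000 events (tests) or 300 events (script) at SNR 20 plus a
10-minute event-free trace; the statistics calibration 10 000/5000 null
replicates (tests) or 5000/2000 (script); the cohort contrast 20 seeds at
n = 200/group (tests) or 5 seeds at n = 120/group (script). All random
draws derive from explicit seeds; identical seeds give byte-identical
traces and output tables.

## Known limitations

* The blockade relation and its inversion assume a spherical cell in a
  rectangular channel with the effective-diameter approximation; systematic
  sizing error on real devices is not estimable from simulation.
* `I_∞` from the sizing level assumes the cell fully recovers within the
  recovery train and that sizing/recovery segments are electrically
  identical; a cell still deformed at the last segment biases τ downward
  slightly (the exclusion of `level ≤ I_∞` points guards the log, not the
  bias).
* The linearized τ estimator is not the maximum-likelihood estimator under
  additive current noise; at 5% amplitude noise it differs from NLS by ~5%
  median, well inside the Monte-Carlo error target.
* Coincident transits are rejected, not deconvolved; heavily overlapping
  pairs whose merged pulse mimics a single clean transit in count, depth
  order *and* timing would be mis-accepted, though none occur in the tested
  regimes.
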