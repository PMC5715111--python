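# Methods

This note documents the models implemented in `epimech`, the estimation
procedures and their numerical choices, what the synthetic generators do
and do not emulate, and the known limitations.

## Physical model and assumptions

The squeeze-film tension relation treats the confluent monolayer's apical
surface as a compliant sheet under isotropic tension *T*, probed by a
sphere oscillating at acoustic frequency with amplitude small compared to
the gap, which in turn is small compared to the sphere radius. The
closed-form result used here is

Δf = (4 / k_c R) · sqrt(π f_far h_m T³ / 6µ) · (h_far/h_m − 1),

and for dissipation

µ_eff = −(12T/R)(λ/h_m) / (π f_far² dφ/df),  λ = ½ sqrt(R h_m).

Assumptions inherited by the implementation:

- **Isotropic tension.** A polarized, fully developed monolayer of
  polygonal cells under line tension is treated as having an isotropic
  in-plane tension; the code never attempts to resolve anisotropy.
- **Viscoelasticity neglected in the tension fit.** Monolayer dissipation
  perturbs the tension estimate by less than about 10%; the fit result
  carries this as a caveat string in its metadata rather than a computed
  correction.
- **Small oscillation amplitude.** The drive amplitude (~10 nm) is
  metadata; the calibration validator only requires it to be positive. It
  must be far below the smallest analysed gap (500 nm) for the linearised
  model to hold.
- **f_far is per-measurement.** The reference frequency is extracted from
  the largest-gap sweep of the same series (default 6 µm), not a global
  constant, because the phase is zeroed at π/2 at that gap in the
  protocol. A final sweep recorded 10 µm away can serve as a drift check
  but is not used as the fit reference.
- **Eq. for µ_eff uses f_far²,** not the locally shifted resonance. At the
  2 µm evaluation gap the shift is ~1–3% of f_far, so this choice matters
  at the few-percent level; the implementation follows the closed form as
  stated.

## Estimation procedures

**π/2 extraction.** Each sweep's phase-frequency record is fitted with a
second-order polynomial over the samples with |φ − π/2| ≤ 0.3 rad
(configurable) and solved for φ = π/2; of the real roots, the one nearest
the sample closest to the crossing is kept and must lie inside the sweep
range. Fewer than 4 points in the window, or no crossing, is a hard error.
On any phase curve that is itself polynomial of degree ≤ 2 the extraction
is exact to machine precision.

**Phase slope.** dφ/df comes from a third-order polynomial fitted to the
2 µm sweep, differentiated at that sweep's f_π/2. The fit window is
|φ − π/2| ≤ 0.5 rad: a cubic over the full 10 kHz span misfits the
arctangent tails and biases the slope by ~1.4% for a Q≈3 oscillator,
whereas the 0.5 rad window keeps the bias below 0.5% (checked against the
closed-form slope −2Q/f₀ at resonance). The window is wider than the
quadratic's because the cubic can absorb more curvature. If no sweep
exists exactly at 2 µm the nearest gap is used with a warning; slope
estimates are stable (≲2%) across 1.5–2.5 µm for constant-Q data.

**Tension fit.** Nonlinear least squares in Hz-space (unweighted — no
weighting scheme is part of the protocol) over the single parameter *T*,
seeded by the closed-form inversion of the shift formula at the smallest
gap, with bounded restarts at 0.1× and 10× the seed. The standard error is
the linearised-Jacobian estimate with residual variance rss/(n−1). Gaps
are trusted as given by the positioning system; a diagnostic mode co-fits
a global gap offset δh to probe contact-point error and is off by default.
Monotonicity violations of the measured shift curve warn rather than fail:
noisy data are adjudicated by the fit, not the curve builder.

**Hertz fit.** The pre-contact baseline (mean force over the farthest 25%
of separations) is subtracted; contact is first located where the force
exceeds max(5× baseline noise, 10⁻⁴ of the force range), requiring at
least 10 supra-threshold points. Because the modulus enters the model
linearly, E is profiled out in closed form and the contact point is found
by 1-D bounded minimisation of the profiled residual (search window
−50 nm/+500 nm around the threshold crossing, which detects contact late).
This is the same joint (E, contact) least-squares optimum as a 2-D search,
but numerically exact on noiseless data. The fit region is restricted to
~1 µm indentation. No bottom-effect (finite cell height) correction is
applied; the half-space model is used as-is.

**Junction morphometry.** The forward difference of a uniformly sampled
intensity profile approximates its derivative, with each difference
assigned to the midpoint of its sample interval; the junction length is
the distance between the positive and negative derivative extrema. Tied
extreme values (linear ramps produce plateaus of equal differences) are
resolved by averaging the tied midpoints, which makes trapezoidal profiles
exact. A centred moving average (default 5 samples, odd) smooths the
derivative before extremum detection; 1 disables it. Edge angles are
measured between the undirected contact line and edge line and reported as
the deviation from perpendicularity, θ = |α − 90°|. The raw inter-line
angle α is ambiguous between an interior angle and its supplement, but
|α − 90°| is identical under both readings, so no convention flag is
needed. Edges parallel to the contact (θ → 90°) are degenerate and
rejected, as are tabulated angles outside [0°, 90°).

**Force balance.** f = √3·T·l and the F_NA/F_SA balance are exact closed
forms, linear in T; antisymmetry under the index swaps (1↔2, 3↔4) and
(1↔3, 2↔4) and exact cancellation for symmetric pairs are enforced by
tests. Whether a cell pair is sufficiently hexagonal for the balance to
apply is the user's responsibility; the code validates only numeric
ranges.

**Statistics.** Unpaired two-tailed Welch t-tests
(`scipy.stats.ttest_ind(equal_var=False)`) with Welch–Satterthwaite
degrees of freedom; groups are summarised as mean ± SD with n. No
multiple-testing correction is applied, matching per-comparison reporting
at α = 0.05; raw p-values are always emitted. Two zero-variance groups
with equal means return p = 1 by convention; with unequal means they are
rejected as degenerate.

## File formats and units

Files use lab units (nm, nN, degrees, mPa·s); memory is SI. Conversion is
a pure scale factor, exact to double precision, and every accepted file
re-serialises losslessly. Readers reject malformed input (missing columns,
non-monotone frequency axes, duplicate gaps, phase records that never
cross π/2, angles ≥ 90°) instead of coercing it. The phase convention is
radians decreasing through resonance; `phase_increasing=True` (CLI
`--phase-increasing`) negates phases on load for instruments with the
opposite convention.

## Synthetic generators

`simulate_sweep_series` builds, for each gap, a damped-oscillator phase
response φ(f) = π − atan2(f·f₀/Q, f₀² − f²) — equal to π/2 at f₀ and
decreasing — whose resonance ladder f₀(h) = f_far + Δf(h) follows the
tension model, and whose local quality factor is derived per gap from the
slope the viscosity relation demands, so the entire pipeline is
invertible. Defaults are the study conditions: control tension
2.2 nN µm⁻¹, viscosity 1.8 mPa·s, k_c = 1 N m⁻¹, R = 12.5 µm,
f_far = 35 kHz, µ = 0.7 mPa·s (aqueous medium at 37 °C; the medium
viscosity is configurable since protocols differ), 12 gaps from 6 µm to
500 nm, 401 samples over 10 kHz. Noise enters as Gaussian perturbations of
the per-gap resonance (shift noise, Hz) and of each phase sample (rad);
amplitude records are the matching resonance peak plus configurable
spurious Lorentzians for the peak-selection logic. Seeding is
counter-based per sweep (`default_rng([seed, sweep_index, stream])`), so
extending the gap ladder leaves existing sweeps bit-identical.

The other generators produce Hertzian force curves (flat baseline, 3/2-power
rise, seeded force noise over a 2 µm approach + 1 µm indentation ramp),
hexagonal cell-pair geometry tables (regular at irregularity 0 — all edges
equal, flanking angles 30° from the contact normal — with seeded uniform
perturbations otherwise; default edge 7.3 µm and n = 14 pairs, the
control-like scale), and trapezoidal intensity profiles whose
derivative-extremum separation equals the requested length exactly.

What the generators do **not** emulate: drift and 1/f instrument noise,
spurious structure in the *phase* channel, anisotropic or
position-dependent tension, microvilli/brush layers, poroelastic or
frequency-dependent rheology, finite cell height under indentation, and
real segmentation errors in junction tracing. Passing round-trip tests
therefore demonstrates estimator correctness against the stated forward
physics, not robustness to every artefact of real recordings.

## Problem sizes and tolerances

Monte-Carlo contracts use 200 replicates (100 in the from-scratch results
script) at the default noise levels — 5 Hz shift noise, 0.01 rad phase
noise, 0.1 nN force noise — sizes at which the bias bounds (1% tension,
10% noisy viscosity, 3% modulus) are stable across seeds. Noiseless
round trips are asserted at 10⁻⁶ relative for the forward-model curves and
1% through the full phase-extraction pipeline, whose quadratic-window fit
contributes an O(10⁻⁴) systematic. Fit optimisers run with xtol/ftol
10⁻¹⁴–10⁻¹⁵ so that oracle-equivalence checks (golden-section and grid
searches) pass at 0.1–0.5%.

## Known limitations

- The tension model's closed form is used outside any check of its
  lubrication-regime validity (A ≪ h_m ≪ R); grossly violating geometries
  are only caught by the calibration validators.
- The effective viscosity inherits the tension estimate's error linearly
  and the slope's error inversely; near-zero slopes produce unstable
  values (guarded by the sign/zero checks, not regularised).
- The Hertz analysis assumes a single elastic layer; soft thin cells over
  glass will read stiff.
- Junction force estimates use one tension value per monolayer; local
  tension heterogeneity is not represented.
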