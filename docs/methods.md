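# Methods

## Model

`thalabeta` simulates a three-population neural-mass model of the
visual thalamus. Each population — a retinal relay stage, the
thalamocortical relay nucleus (TCR, excitatory) and the thalamic
reticular nucleus (TRN, inhibitory) — is a second-order critically
damped synaptic filter followed by a logistic potential-to-rate
conversion, the standard neural-mass construction. Writing each
population as a pair (x₁, x₂ = ẋ₁):

    ẍ_ret = (H_e/τ_e)·P(t)                        − (2/τ_e)·ẋ_ret − x_ret/τ_e²
    ẍ_tcr = (H_e/τ_e)·S(C₃·x_ret − C₂·x_trn)      − (2/τ_e)·ẋ_tcr − x_tcr/τ_e²
    ẍ_trn = (H_i/τ_i)·S(C₁·x_tcr)                 − (2/τ_i)·ẋ_trn − x_trn/τ_i²

    S(v) = 2e₀ / (1 + exp(−ν(v − s₀)))

The analysed output is the net synaptic input to the relay nucleus,
V(t) = C₃·x_ret − C₂·x_trn (mV), the model's EEG-like signal.

Frozen at a constant rate, the linear part of each population has the
double eigenvalue −1/τ: a critically damped kernel whose time constant
sets the population's preferred timescale. The TCR→TRN→TCR negative
feedback loop (gains C₁, C₂) then oscillates near
1/(2π√(τ_e·τ_i)) ≈ 10–13 Hz — the alpha band — which is the premise of
the whole exercise.

`ModelParameters` defaults: H_e = 3.25 mV, H_i = 22 mV, τ_e = 10 ms,
ν = 0.56 mV⁻¹, s₀ = 6 mV, e₀ = 25 s⁻¹, C₁ = 35, C₂ = 15, C₃ = 7,
μ_r ∈ [0, 100] spikes/s (86 by default), φ_r = 1 (spikes/s)².
Connectivity gains are used as raw dimensionless numbers. Time
constants are stored in ms and converted to seconds once when the
right-hand side is built, so every rate in the equations is in s⁻¹.

The TRN sigmoid is fed by the relay potential (`trn_input="tcr"`),
which is the circuit the model describes — the TCR excites the TRN.
A `trn_input="trn_self"` switch feeds the TRN its own potential
instead, for exploring the self-input variant; it is not used by any
default pipeline.

## Amyloid coupling

Amyloid burden enters through a single scalar, the PET standardized
uptake value ratio β_a (SUVR). A decreasing logistic converts load to
a synaptic rate, whose reciprocal is the TRN inhibitory time constant:

    S1(β) = S_min + (S_max − S_min) / (1 + exp(r_β·(β − β₀)))
    τ_i(β) = 1 / S1(β)        for β ≥ β_off
    τ_i(β) = 1 / S_max        for β < β_off   (clinically normal: clamped)

with calibration r_β = 2·ln(S_max)/(β_off − β_max) and
β₀ = (β_off + β_max)/2. Defaults: β_off = 1.4 (clinical cutoff),
β_max = 2.65 (population maximum), S_max = 0.07 ms⁻¹,
S_min = 0.02 ms⁻¹, giving r_β = 4.2548, β₀ = 2.025, and
τ_i ∈ [14.29, 50] ms. The hard clamp below the cutoff encodes the
clinical convention that sub-threshold amyloid is pathologically
silent; the residual discontinuity at β_off is the logistic tail,
about 0.7 ms here, and is asserted bounded in the tests.

Severity banding on SUVR: normal < 1.4 ≤ moderate ≤ 1.95 <
moderate-severe ≤ 2.15 < severe. On the calibrated curve
τ_i(1.95) ≈ 20.4 ms; τ_i reaches 28 ms at β_a ≈ 2.208 (root-finding on
the monotone curve), i.e. inside the severe band.

## Stochastic simulation

The exogenous drive P(t) is Gaussian white noise with mean μ_r and
variance φ_r, discretized by a zero-order hold: one independent draw
per integration step, held constant across the step. The reference
integrator is classical fixed-step RK4 at dt = 1 ms on that held-noise
grid. A held-noise system is an ordinary ODE between steps, so the
scheme is well defined, convergent and exactly reproducible; an
adaptive RK45 mode over the same held noise is provided as a
cross-check of the stepping scheme (`method="rk45"`).

Repeats: 20 independent noise realizations per condition, each seeded
`base_seed + repeat_index` into a Philox counter-based generator, so
any single repeat can be regenerated in isolation and results are
portable across platforms. All repeats (and, in sweeps, all grid
points) are integrated as columns of one vectorized RK4 pass;
elementwise arithmetic makes this identical to integrating them one at
a time, and the tests assert a one-point sweep is bit-identical to a
direct run.

Initial condition: the zero state. The first 2 s are discarded before
analysis (the zero-drive system relaxes with time constants of
10–50 ms, so 2 s is conservative). Divergence (any |state| > 10⁶ mV)
raises an error naming the blow-up time; no divergence occurs anywhere
on the swept ranges (β_a ∈ [0, 5], C₁ ∈ [0, 100], μ_r ∈ [0, 100]),
which the suite checks at the corners.

Step-size hygiene is assessed in the deterministic limit (φ_r = 0,
constant drive at μ_r): halving dt changes the post-transient output
by 0.1 % relative RMS. Under stochastic drive a trajectory-level
comparison across step sizes is not a refinement oracle: the
oscillator's phase is sensitive to any perturbation of the drive path,
so discretization error and accumulated phase drift are conflated
(0.3–1.8 % over 30 s depending on the realization) while spectral
summaries remain stable.

## Spectral analysis

The output of each repeat is band-pass filtered with a zero-phase
(forward–backward) order-4 Butterworth filter, 1–40 Hz — wide enough
not to shape the alpha peak — and transformed with Welch's averaged
periodogram: 4-s Hann segments, 50 % overlap, 0.25 Hz resolution on
the 28-s post-transient record. Per-repeat PSDs are averaged;
averaging the raw traces first would cancel oscillations of random
phase, so the trace average is retained only for inspection.

Alpha-band (8–13 Hz) readouts: peak power = maximum PSD density on the
closed band; dominant frequency = its location, ties resolved to the
lowest frequency; sub-band powers = trapezoidal integrals over the
five 1-Hz bins 8–9 … 12–13 Hz, with interpolated bin edges so the
sub-bands tile the band integral exactly. An 8–13 Hz passband
(`--band 8:13`) reproduces the narrow-filter reading of the pipeline.

## Sweeps

Three drivers vary one knob with the others fixed:

* β_a over 1.4–5.0 (default step 0.2, plus the spot loads 0.001, 1.92,
  2.10, 2.14, 3.00), at several drive levels — the alpha-slowing
  experiment. τ_i(β_a) is the only coupling, which the suite verifies
  by sweeping τ_i directly and recovering the identical curve.
* C₁ over 0–100 at fixed β_a = 2.10 (moderate-to-severe load).
* μ_r over 0–100 at fixed β_a = 2.10.

Grid point j, repeat i uses seed `base + j·n_repeats + i`. Results are
tidy long-format tables (value, τ_i, peak power, dominant frequency,
sub-band powers) plus a flat key-value manifest recording every
effective parameter and seed; optional figures overlay the PSDs and
bar-chart the sub-band powers.

Monotone trends are assessed by Spearman rank correlation of the
repeat-averaged peak power across grid points, not by point values:
the spectra are Monte-Carlo estimates and only the direction of the
effect is a stable claim. Measured at the defaults: ρ ≈ −0.75 to −0.89
for the β_a sweeps (with the peak power collapsing by four orders of
magnitude and flattening above β_a ≈ 3), ρ = +1 for the C₁ and μ_r
sweeps.

## What the noise generator does and does not emulate

The white-noise drive stands in for retinal sensory input; with the
model's synaptic filtering it produces an alpha-band rhythm with
realistic-looking stochastic amplitude modulation. It does not emulate
real EEG: there is no 1/f background from other sources, no line
noise, no artifacts, no volume conduction, and amyloid is a single
scalar rather than a regional map. Passing tests therefore demonstrate
the model's internal phenomenology — alpha slowing under the amyloid
mapping — not agreement with patient recordings.

## Problem sizes

Simulations run 30 s at dt = 1 ms with a 2-s transient. The long
amyloid-grid trend (19 grid points × 4 drive levels) is run with 5
repeats per point in the test suite; the baseline-oscillation,
spot-load and connectivity/drive checks use the full 20 repeats. The
suite completes in about a minute on one core.

## Known limitations

* No cortical module: the circuit stops at the thalamus, so cortical
  feedback effects on alpha are outside the model.
* e₀ = 25 s⁻¹ is kept as tabulated even though related models use
  2.5 s⁻¹; it is a configuration value, not hard-coded.
* The below-cutoff clamp makes τ_i(β_a) non-smooth at β_off = 1.4.
* The adaptive-RK45 mode inherits the phase sensitivity discussed
  above; it matches the reference integrator closely on deterministic
  drives (< 5 % relative RMS over 6 s) but is not bit-reproducible
  across SciPy versions the way the fixed-step path is.
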