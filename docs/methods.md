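# Methods

This note documents the models, numerical choices and limitations of
`cvpgrad`: what the simulator emulates, how the estimators are formulated,
and which design decisions were genuinely open.

## Units and conventions

Gradient amplitudes in mT/m, time in µs, slice positions in mm, fields in
Hz, k-space in 1/m.  γ/2π = 42.577 MHz/T (¹H), so a 1 mT/m gradient shifts
the Larmor frequency by 42.577 Hz per mm of offset.  Sample indices are
0-based; time stamps refer to sample centers; every HDF5 dataset carries its
units as attributes.

## Gradient-chain simulator

The chain is modeled as an LTI system followed by an optional memoryless
nonlinearity:

* **transport delay** τ (µs): linear phase `exp(-iωτ)`;
* **first-order low-pass** with bandwidth `lowpass_bandwidth` (kHz),
  emulating the amplifier/coil pole;
* **eddy-current terms** `(a, T)`: each subtracts `a · iωT/(1+iωT)` — the
  classic droop/overshoot high-pass with time constant `T` (ms) and
  dimensionless fraction `a`;
* **mechanical resonances** `(a, f₀, τ_d)`: additive term
  `a · iω · ω₀ / ((1/τ_d + iω)² + ω₀²)`, the Fourier transform of a
  slew-excited damped sinusoid `sin(ω₀t)·exp(-t/τ_d)`.  All terms are
  transparent at DC so plateaus are delivered at their commanded value.
* **sign asymmetry** `a`: the LTI output is scaled pointwise by `1 + a/2`
  where positive and `1 − a/2` where negative, i.e.
  `out = g + |g|·a/2`.  This is the minimal model of an amplifier whose
  positive and negative drive gains differ; it is memoryless by design (see
  Limitations).
* **concomitant field**: `c(r,t) = κ₀ (1 + κ₁ r) G_out(t)²` in Hz, with κ₀
  in Hz/(mT/m)² and κ₁ in 1/m.  The only property the compensation logic
  relies on — invariance under sign inversion of the gradient — holds for
  any quadratic model; the exact Maxwell geometry is deliberately not
  modeled.
* **B0 eddy terms** `(a, T)`: a spatially constant ΔB0(t) as a high-pass
  response (Hz per mT/m) to the commanded gradient.

Responses are computed by FFT with generous zero padding (outputs extended
up to 10 ms past the last event by default) so lingering oscillations
overlap later readouts — the effect the compensated schemes exist to
separate.

### FID signal model

Each acquisition step passes *all* of its gradient events (slice selection
with rephaser, prephaser, test gradient) through the chain.  The spin phase
at position r integrates `2π·f(r,t)` from the excitation instant onward, so
events played before excitation contribute only their lingering fields.
The slice profile is ideal-rectangular, averaged at `intra_slice_points`
(default 64) sub-positions across the thickness; this produces the
dephasing envelope and the rephasing maxima the weighting relies on without
an RF/Bloch simulation.  All field terms are affine in r, so the envelope
is computed once per (prephaser, step) and shared across slices.  Complex
Gaussian noise (std `noise_sigma` per channel) requires an explicit seed —
a reproducibility contract enforced at call time.

Background q-terms are not injected separately: they arise physically from
the slice-selection event's chain response and B0 eddy terms, and they
differ between early-excitation steps (1–2) and late-excitation steps (3–4)
because the slice-selection event moves.

### Scheme timing

A single timeline is shared by all steps of a scheme — early
slice-selection slot, prephaser slot, late slice-selection slot, test
gradient/readout — so the prephaser and readout timing is identical in all
steps.  Steps 1–2 excite in the early slot (prephaser acts between
excitation and test gradient), steps 3–4 in the late slot (prephaser acts
before excitation, only its lingering fields reach the readout).  CVP plays
bare references in steps 2/4; FCVP repeats steps 1/3 with the test and
prephaser signs inverted.  Prephaser amplitudes are chosen so their moments
uniformly span the extrema of the test gradient's cumulative moment, which
distributes the rephasing maxima across the readout.

## Estimation

Phase → frequency: the FID phase is unwrapped along t per trace (off-center
slices exceed ±π within a few samples), differentiated with central
differences (one-sided at the edges) and divided by 2π.  A moving median of
length 3 (odd lengths only; symmetric shrinking window at the edges)
suppresses single-sample outliers.  Each frequency sample is weighted by
the signal magnitude at the same sample.

The per-time-point linear systems stack observations step-major, then
prephasing step, then slice.  The P blocks are `[1, 42.577·r_m]`, which
absorbs γ/2π so solutions are directly [ΔB0 in Hz, G in mT/m].  The
weighted system is solved through an SVD least-squares factorization of the
row-scaled matrix (never the explicit normal-equation inverse); the
per-time condition number of the weighted matrix is reported.  Time points
where all weights vanish yield NaN with a `valid=False` mask — they are
never interpolated silently.

A CVP acquisition contains a VP acquisition (steps 1–2); an FCVP
acquisition can be evaluated with the VP or CVP equations if the sign
inversion of its steps 2/4 is carried into the design matrix.  The mapping
table lives in `cvpgrad.estimation`'s module docstring and is tested.

ΔB0(t) estimates are produced but should be treated as indicative only:
B0 cross-terms of real gradient chains drift, and nothing in these methods
stabilizes them.

## GSTF

The stacked convolution model `measured_i = h * nominal_i` is Tikhonov-
regularized and solved in the DFT domain, where the circulant-embedded
system diagonalizes:  `H = Σ Xᵢ* Yᵢ / (Σ |Xᵢ|² + λ)` with
`λ = regularization · max(Σ|Xᵢ|²)`.  Probing triangles with staggered ramp
durations keep the joint input spectrum free of zeros in band.  The
frequency grid is odd-length and symmetric, so a real impulse response
gives an exactly Hermitian spectrum.

Prediction multiplies the (time-zero-padded) nominal spectrum by H,
interpolated linearly onto the nominal frequency grid and set to zero
beyond the GSTF support — i.e. the prediction is band-limited to the
measured response; no polynomial interpolation between time grids is ever
used.  Dwell-time mismatches between grids are absorbed by an explicit
delay knob: the spectrum's stored `delay_correction` plus a per-call
`extra_delay` are applied as a linear phase ramp.  Resampling to a
different output dwell is Fourier-based.

## EPI reconstruction

Trajectories are the cumulative trapezoid integral of the (optionally
delayed) readout waveform, evaluated at the ADC sample centers and scaled
by γ/2π; phase-encode positions come from the nominal blips.  The
integration origin is fixed by convention at the echo center of the central
line under the *nominal* waveform, which makes nominal, predicted and
measured trajectories directly comparable (the drift of measured echo
centers is then visible rather than silently re-zeroed).

Because phase encode stays on the nominal Cartesian grid, reconstruction
factorizes exactly: a 1-D non-uniform DFT along readout per line (adjoint
with density compensation `|Δk|`, or conjugate-gradient least squares on
the full forward model) followed by a uniform DFT along phase encode.  For
this sampling pattern that is the exact operator a gridding NUFFT would
approximate, at 64×64 sizes it is fast, and it avoids approximation error
in the benchmark numbers.  Coils are combined root-sum-of-squares.
Trajectory excursions beyond the nominal Nyquist box raise a warning and
are kept.

The navigator correction estimates one constant odd/even phase from three
non-phase-encoded reference echoes: the middle (opposite-polarity) echo is
time-reversed and its inner product with the mean of its neighbors gives
the offset applied (negated) to every second imaging echo.  A normalized
inner product below 0.2 flags a low-confidence estimate.

Residual delays are found by scanning reconstruction delays, summing the
image magnitude outside a circular mask covering the phantom, fitting a
quartic and taking the real root of its derivative with the smallest fitted
value.  The default scan is ±10 µs in 0.5 µs steps.  Over such a wide
interval the cost curve is only quartic-like near its minimum, so the fit
accepts an optional `fit_window` (the benchmarks use 9 points around the
scan argmin); with it, injected delays are recovered to better than
0.05 µs.  Γ uses a rectangular ROI placed in the ghost-only region; ROI₂ is
the same ROI shifted by half the matrix along phase encode (wrapping).

## Benchmark study conditions

The benchmark scenarios in `cvpgrad.benchmarks` fix the study conditions:
9 slices spanning ±20 mm (3 mm thick), 5 prephasing steps, a 10 mT/m
trapezoid (150/300/150 µs) measured at 2 µs dwell, a 30 mT/m six-lobe
EPI-style train (100 µs ramps, 320 µs flat tops), and a 64×64, 200 mm FOV
EPI acquisition at 5 µs ADC dwell (23.5 mT/m plateaus, 520 µs echo
spacing, readout frequency ≈ 0.96 kHz next to a 1.0 kHz simulated coil
resonance).  The "clean" chain used for recovery benchmarks is a 15 kHz
low-pass with a 2 µs delay: a hard-cornered infinite-bandwidth waveform is
not recoverable to the stated tolerance by *any* phase-derivative method at
finite dwell (the derivative stencil smooths G by [1,2,1]/4, leaving
~(dt²/4)·G″ corner error), whereas every real gradient chain is band
limited.  Recovery errors are evaluated on interior samples (2 trimmed at
each end) because the stencil is one-sided at the window edges.  The
mechanism scenarios use a resonance of 0.5% relative amplitude at 1.1 kHz
(2 ms damping), κ₀ = 0.05 Hz/(mT/m)² with κ₁ = 142 /m, and a 2% sign
asymmetry; the ghost-ordering scenario uses a 0.4%-amplitude 1.0 kHz
resonance, 3 µs delay and 0.2% asymmetry.

What the simulator does *not* emulate — RF/Bloch slice profiles, B0 drift
between steps, coil sensitivity structure beyond smooth test maps,
concomitant geometry beyond an affine-in-r quadratic term, and
history-dependent amplifier behavior — bounds what passing benchmarks say
about real data: they validate the estimators' algebra and the mechanism
separation, not scanner-specific magnitudes.

## Known limitations

* The sign-asymmetry model is memoryless.  Any memoryless nonlinearity has
  an even residual `e(G)` with `e(+G₀) = e(−G₀)`, so on a symmetric EPI
  train the FCVP−CVP difference it produces is lobe-sign-*invariant*
  (≈ −|G|·a/2).  Real amplifiers show lobe-alternating differences, which
  requires history-dependent (dynamic) nonlinearity; reproducing that
  signature would need a hysteresis-type amplifier model, which is out of
  scope here.  The benchmarks report the plateau-mean FCVP−CVP difference
  on positive and negative lobes separately so the behavior is visible
  either way.
* Higher-order spatial field terms are not estimated; the design matrices
  stop at [1, r].  Extending P with more basis functions is an extension
  point, not a feature.
* B0 cross-term correction is intentionally absent (see Estimation).
* The deposited-data adapter maps generic MAT-v7.3/HDF5 layouts by key
  patterns and fails with a descriptive key listing otherwise; it does not
  ship vendor-format readers.
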