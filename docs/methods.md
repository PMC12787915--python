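# Methods

This note documents the models behind `wavegraft`, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not establish about real recordings.

## Measurement model

### ΔF/F0 baseline

Each pixel's baseline F0 is its own temporal percentile (default 10th) over
the analyzed movie, and the output is `(F − F0)/F0`. The percentile baseline
is robust to transients occupying a minority of frames and needs no spatial
structure. A pixel whose baseline is ≤ ε (10⁻⁶) keeps the raw difference
(denominator 1): this makes the operation exactly idempotent — re-applying
it to an already-converted stack, whose baseline is 0, is the identity —
and keeps degenerate all-zero pixels at 0 instead of raising.

### Kalman stack filter

The temporal denoiser is the fixed-gain recursion `E₀ = X₀`,
`E_t = g·E_{t−1} + (1−g)·X_t`, `g ∈ [0, 1)` (default 0.8). It is the
deterministic steady state of the classical per-pixel Kalman stack filter
once its variance estimate converges; we use the fixed-gain form because it
is fully parameterized by one number, exactly linear, and has a closed-form
noise figure (steady-state variance reduction `(1−g)/(1+g)`, a factor of 9
at g = 0.8) that the tests verify by simulation. Gain 0 is the identity.
The cost is causal lag: fast transients are attenuated, which is visible in
the SNR analysis below.

### Histogram-band SNR

Signal quality is scored on one frame as
`(# pixels with intensity in the signal band) / (# pixels in the union of
the noise bands)`, with default bands 230–280 (signal) versus 150–230 and
280–400 (noise) in the arbitrary-unit scale of EMCCD recordings. It is a
counting statistic on the intensity histogram, invariant to pixel
permutation. Two caveats are intrinsic: the statistic is only meaningful on
frames whose true signal level lies inside the signal band, and its absolute
value depends on the band placement and the recording's intensity scale —
so the tests assert only the raw < filtered *ordering* on synthetic frames,
never absolute SNR values.

### Activation map

A pixel activates at the first time `I(t) ≥ (1 + θ/100)·⟨I⟩` where `⟨I⟩` is
its own temporal mean over the analyzed window; θ defaults to 20%. The
per-pixel relative threshold adapts to heterogeneous staining and
illumination, unlike a single absolute cutoff. Crossings are refined by
linear interpolation between the straddling frames, so downstream velocity
fits are not quantization-limited. A pixel with zero temporal range never
activates (a constant trace has no rise), and pixels that never cross carry
a NaN sentinel. The intended chain is ΔF/F0 → blur → activation map: on raw
counts the threshold `1.2·⟨F⟩` sits high on the transient's rising edge
(the baseline dominates the mean), which delays apparent activation by 2–3
frames, while on ΔF/F0 data the crossing happens within a fraction of a
frame of wave arrival. With the default chain (blur σ = 2 px, θ = 20%),
activation lands within ±1 frame of the simulator's true arrival for ≥ 99%
of swept pixels at transient amplitude/noise ≥ 3.

### Kymograph and conduction velocity

The movie is resliced along a rectangle's long axis: for each position s
along the axis and frame t, intensity is averaged across the rectangle's
short axis (height h), reducing uncorrelated noise variance by ≈ h. Rotated
rectangles are sampled bilinearly. Axes are fixed as (space vertical, time
horizontal); the angle α of a wavefront line is measured against the *time*
axis, so the conduction velocity is `v = tan α` in px/frame (an equivalent
convention measures the complementary angle against the space axis and
writes 1/tan). Per wavefront — one per stimulus pulse when a train is given
— the rising-edge time at each spatial position is detected with the same
relative-threshold rule as the activation map, and `time = s/v + c` is
fitted by least squares; velocities are averaged across fronts.

Degenerate fits are flagged, not silently reported: a front whose total
traversal is below one frame (an effectively instantaneous wave) returns
infinite velocity, and a fit whose RMS residual exceeds a configurable bound
(default 3 frames) is likewise flagged. The residual flag matters in
practice: at 1 Hz stimulation with a crossing time close to the period, the
previous wave's decay tail overlaps the next front at the far end of a
full-width reslice and biases the fit — restricting the rectangle to the
first ~60% of the propagation path (or checking the degenerate flag)
avoids this.

### Peak matching and the transmission fraction

Fluorescence peaks are local maxima filtered at a prominence threshold
(default 25–30% of the trace range), kept greedily in decreasing-prominence
order under a minimum-separation constraint, ties breaking toward the
earlier peak. A reference (host) wave at time r counts as *transmitted* when
a graft peak lies in `(r, r + w]`; matching is greedy earliest-first and
each graft peak serves at most one reference wave. The window w defaults to
0.8× the reference period — wide enough for multi-hundred-millisecond
nascent-contact delays, short enough never to reach the next beat (windows
that would overlap are rejected). The transmission fraction is reported
exactly (e.g. 20/42 = 0.476) together with a conventionally rounded
percentage; rounding conventions are made explicit because they visibly
matter at this sample size.

The transmission delay per matched wave is the graft peak time minus the
peak time of a monolayer ROI *adjacent to the graft* (same position along
the propagation axis — an upstream reference adds wave travel time to every
delay). The report carries the per-wave list, mean, SD, and the median; the
median is the robust headline number because an intrinsic pacemaker beat
that happens to fall inside a window contributes an arbitrary delay that
contaminates the mean but not the bulk of the distribution.

### Coincidence null

Whether the observed synchrony could be chance is scored as
`P(K ≥ n_transmitted)` under independence, two ways:

- **Closed form**: each of the n reference windows is hit independently
  with `p₁ = min(1, w·rate)`, so K ~ Binomial(n, p₁) and the tail is exact.
- **Monte-Carlo**: jittered periodic graft trains (period 1/rate, uniform
  phase, Gaussian jitter, default SD 10% of the period) are re-matched
  against the same windows over many seeded draws.

The two nulls coincide in the far tail — the regime where the statistic is
used — but differ in the bulk: a periodic train has a fixed spike budget
and greedy consumption, so its window-hit count is underdispersed relative
to the binomial. Both are therefore reported with method labels, and the
Monte-Carlo requires an explicit seed (reproducibility contract).

### Cell-chain contact model

Excitation crossing a chain of N cells traverses N intercellular contacts;
assuming contact traversal dominates intracellular conduction, the
per-contact time is the transit time divided by N. N comes either from
direct cell counting or from path distance ÷ mean spread cell size
(default 100 µm, rounding half-up with a floor of one cell). The monolayer
per-contact time uses Region-1→Region-2 peak-time differences over m waves:
`value = mean(Δt)/N`, `σ = sd(Δt)/(√m·N)`, floored at the frame-quantization
limit `Δt_frame/(√12·N)`. The graft sits directly on the monolayer, so its
transmission delay is a single contact traversal (N = 1). The efficiency
ratio is `graft/monolayer` per-contact time — the fold reduction in contact
efficiency — with first-order error propagation
`σ_R = R·√((σ_g/g)² + (σ_m/m)²)`.

### Confocal raster decoding

With H rows scanned in T seconds, each row is treated as acquired
instantaneously at `ℓ·T/H` (the within-row dwell, < one line time, is a
documented approximation). Band centers come from prominence-filtered
maxima of the row-wise mean profile with parabolic sub-pixel refinement
(integer-pixel reading available behind a flag, mimicking on-screen cursor
measurements); widths are measured at half prominence. Then
`period = spacing × T/H` and `duration = width × T/H`; the frame-level
decode uses the median over adjacent spacings and over band widths. Periods
are reported rounded to 2 decimals and durations to 1, alongside full
precision. The `t₂ = k·t₁` commensurability check (scan time an integer
multiple of the stimulation period, default tolerance 1% of the multiple)
states whether bands from successive frames will align vertically.

Known bias: the half-prominence width underestimates the true
full-width-at-half-maximum when adjacent transients overlap, because the
inter-band valley floor raises the half-prominence level (≈ −10% at a
0.3 s transient under a 0.74 s period, < −5% once transients are well
separated). Period decoding is unaffected (band *spacing* does not depend
on the valley) and is empirically unbiased to < 2%.

## Synthetic data: what it emulates and what it does not

The movie generator renders, at 34.6 frames/s on a default 128×128 grid
(the 512×512 acquisition geometry downscaled 4×, 10 µm/px):

- a planar wave per stimulus, arrival `a_k(c) = onset_k + (c − c₀)/v·Δt`,
  with a difference-of-exponentials calcium transient
  `K(t) = (1 − e^{−t/τ_r})·e^{−t/τ_d}` (unit peak; τ_r = 50 ms,
  τ_d = 300 ms — a standard minimal transient shape), peak ΔF/F0 0.35 over
  a baseline of 190 arbitrary units;
- a disk graft ROI (radius 5 px) that follows each stimulus with Bernoulli
  probability p (default 0.5) at the local wave arrival plus a fixed delay
  (default 10 frames), and otherwise free-runs on a jittered pacemaker
  clock. The intrinsic period defaults to 2.2 s — slower than the 1 Hz
  drive, consistent with a cell whose overall firing is dominated by driven
  beats — and every driven beat resets the clock (overdrive suppression),
  with a 250 ms refractory guard;
- additive Gaussian read noise (default σ = 10), optional Poisson
  resampling; all randomness from one integer seed; a GroundTruth manifest
  records arrivals, transmitted flags, firing times, and the true
  velocity/delay/fraction.

The raster generator samples a spatially uniform periodically firing sheet
row-by-row (1024 rows / 36 s by default), with the movie kernel rescaled so
its FWHM equals the requested transient duration.

Not emulated: curved or re-entrant wavefronts, ionic/reaction–diffusion
dynamics, motion, photobleaching, EMCCD gain statistics, fiber optics or
3D structure, and spatial heterogeneity of staining. Passing recovery tests
therefore establishes that the *estimators are correct for the model they
assume* (planar waves, stationary noise, point-like graft), not that they
are robust to every artifact of real recordings; the external-denoiser hook
and the ROI-level API are the intended path for real data.

## Default study conditions and scenario choices

- Stimulation: 1 Hz, 20 ms pulses, 42-pulse trains (transmission-fraction
  statistics are computed over 42 waves).
- Matching window 0.8 s (0.8× the 1 s period).
- The delay-recovery condition uses the `paper-like-graft` preset
  unchanged; the delay is read as the median over matched waves.
- The efficiency-ratio recovery movies program ratios of 10× and 40× by
  setting the graft delay to R× the monolayer per-contact time
  (10 cells over 1 mm at 8 px/frame). A 2.5 s stimulation period is used
  for these movies so that the largest programmed delay (~1.4 s) still
  falls inside a legal matching window; this is a property of that synthetic
  experiment, not of the default presets. Recovery is within ~3% at both
  ratios (15% tolerance asserted).
- Simulation sizes (128×128 grids, ≤ 1500 frames, 64×64 for single-wave
  checks) were chosen as the smallest at which the estimators' quantization
  floors are well below the asserted tolerances.

## Numerical conventions

- Coordinates `(t, row, col)`, 0-based, row 0 at the top, half-open ranges.
- Computation in float64; derived maps written as float32 TIFF, never
  clipped or rescaled; raw acquisitions kept at native bit depth.
- Rounding half-up for cell counts; fractions to 3 decimals; percentages to
  0 decimals; decoded periods/durations to 2/1 decimals — always alongside
  full precision.
- Peak-prominence ties break toward the earlier peak; greedy matching is
  earliest-first; each candidate serves one reference event.
- Degenerate inputs raise named errors (constant traces, empty noise bands,
  overlapping windows, missing wavefronts) rather than returning silent
  defaults; the two deliberate exceptions are documented above (ΔF/F0 of a
  zero-baseline pixel, never-activated pixels as NaN).

## Known limitations

- The coincidence closed form treats window hits as independent; it is
  exact only against a Poisson-like null and approximates the pacemaker
  null in the far tail.
- The SNR statistic depends on band placement; it is a relative quality
  score, not an absolute detector metric.
- Transmission-delay estimation assumes the graft's transient shape matches
  the monolayer's (same kernel); systematically slower graft kinetics would
  bias peak-to-peak delays.
- Velocity fits assume planarity along the reslice axis; curved fronts need
  a different geometry.
- Raster decoding assumes unidirectional top-to-bottom scanning and a
  sheet that fires synchronously within the averaging region.
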