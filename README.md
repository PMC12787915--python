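# wavegraft

Quantitative analysis of early graft–host electrophysiological integration
from calcium-imaging movies.

When freshly seeded ("graft") cardiomyocytes are placed on a synchronized
host monolayer, the first functional question is whether, and how well, the
host's excitation waves propagate into the graft cell through the nascent
intercellular contacts. `wavegraft` implements the full measurement chain
used to answer that question from fluorescence recordings of a
calcium-sensitive dye:

- **Denoising and SNR** — per-pixel ΔF/F0 conversion against a temporal
  percentile baseline, a fixed-gain recursive (Kalman stack) filter
  `E_t = g·E_{t−1} + (1−g)·X_t`, per-frame Gaussian blur, and a
  histogram-band SNR (signal-band pixel count ÷ noise-band pixel count),
  with a plug-in hook for external (e.g. learned) denoisers.
- **Activation maps** — a pixel activates when it exceeds its own temporal
  mean by a relative threshold, `I(t) ≥ (1 + θ/100)·⟨I⟩`, with sub-frame
  interpolation; adaptive per pixel rather than one absolute cutoff.
- **Kymographs and conduction velocity** — space×time reslice of the movie
  along the propagation direction; a planar wave is a tilted line whose
  slope is the conduction velocity, `v = tan α` px/frame with α measured to
  the time axis (fits flagged degenerate when the wave crosses in < 1
  frame).
- **Stimulus-locked synchronization** — greedy earliest-first matching of
  graft peaks to host waves within a window, the transmission fraction
  `n_transmitted / n_reference`, and a coincidence null (exact binomial tail
  and a seeded pacemaker Monte-Carlo) for "could this synchrony be chance?".
- **Cell-chain contact efficiency** — wave transit across N cells ≈ N
  intercellular contact traversals, so per-contact time = transit time / N;
  the graft/monolayer ratio of per-contact times is the fold reduction in
  contact efficiency of nascent vs mature junctions, with first-order error
  propagation.
- **Confocal raster decoding** — a slow raster scan (H rows in T seconds)
  converts time to row position; a sheet firing with period P paints bands
  `P·H/T` rows apart, so band spacing × line time decodes the firing period
  and band width decodes the calcium-transient duration from one frame.
- **Synthetic data** — a seeded generator for all of the above: planar
  stimulus-locked waves, a graft ROI with Bernoulli transmission + fixed
  delay + jittered intrinsic pacemaker, camera noise, and raster frames of a
  firing sheet — each with a ground-truth manifest.

## Worked example

```python
import numpy as np
import wavegraft as wg

sc = wg.scenario_presets(seed=7)["paper-like-graft"]   # 1 Hz x 42 stimuli, p=0.5, 10-frame delay
stack, truth = wg.simulate_movie(sc)

mono  = wg.roi_mean_trace(stack, wg.RectRegion(72, 91, 10, 10))  # monolayer next to graft
graft = wg.roi_mean_trace(stack, sc.graft_roi)

report = wg.classify_synchronization(
    wg.detect_peaks(wg.normalize_trace(mono)),
    wg.detect_peaks(wg.normalize_trace(graft)), window_s=0.8)
report = wg.coincidence_probability(report, graft_rate_hz=1 / sc.spont_period_s)
delay  = wg.transmission_delay((mono, graft))

clean = wg.gaussian_blur(wg.subtract_background(stack), 2.0)
kymo  = wg.reslice_kymograph(clean, wg.RectRegion(40, 0, 10, 80))
fit   = wg.fit_wavefront(kymo, stim=sc.stim)
```

With seed 7 this prints:

```
waves=42 transmitted=27 fraction=0.643 (64%) p=2.18e-04
delay median 10.0 frames = 289 ms
velocity 4.00 px/frame = 1385 um/s over 42 waves
```

Reading: of 42 host waves, 27 elicited a time-locked graft response (the
true transmitted count drawn by the generator was 22; the extra matches are
intrinsic pacemaker beats that happened to fall inside windows — which is
exactly what the coincidence null quantifies, here p ≈ 2×10⁻⁴ that a fully
uncoupled pacemaker would match this often). The median transmission delay
recovers the programmed 10 frames, and the wavefront fit recovers the
programmed 4 px/frame conduction velocity across all 42 waves.

Confocal decoding is a one-liner on the printed scan geometry:

```python
frame = wg.RasterScanFrame(np.zeros((1024, 4)), frame_time_s=36.0)
wg.decode_period(21, frame)    # DecodedTime(value_s=0.73828125, rounded_s=0.74)
wg.decode_duration(29, frame)  # DecodedTime(value_s=1.01953125, rounded_s=1.0)
```

A command-line interface mirrors the library:

```sh
wavegraft simulate --preset paper-like-graft --seed 7 --out movie.tif --truth truth.json
wavegraft preprocess --in movie.tif --out clean.tif --snr-report snr.json
wavegraft activation-map --in clean.tif --out actmap.tif --png actmap.png
wavegraft kymograph --in clean.tif --rect 40,0,10,80 --out kymo.tif --fit fit.json
wavegraft sync-report --in movie.tif --graft-roi 64,96,5 --ref-roi 72,91,10,10 --out sync.json
wavegraft confocal-decode --in raster.tif --frame-time 36 --out decode.json
```

## Layout

```
src/wavegraft/
  stacks_io.py             TIFF stack I/O, metadata sidecars, core data types
  preprocess.py            ΔF/F0, Kalman stack filter, blur, SNR, traces
  wave_mapping.py          activation maps, kymographs, velocity, delay
  synchrony_efficiency.py  peak matching, coincidence null, cell-chain model
  confocal_decode.py       raster-scan temporal decoding
  synthetic_data.py        seeded generators with ground-truth manifests
  cli.py                   the `wavegraft` command
docs/methods.md            models, parameters, numerical choices, limitations
```
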