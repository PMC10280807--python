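# Methods

This note documents the models, estimators and numerical choices behind
`voltimage`, and what the synthetic-data generator does and does not
emulate.

## Signal model

A negative-going genetically encoded voltage indicator (GEVI)
reports membrane potential as a *negative-going* fluorescence change that
is approximately linear in voltage over the physiological range.  The
generator's forward model is

```
F(t) = f0 · (1 + k(t)) · exp(−t/τ_bleach) + background + ε(t)
k(t) = kinetic_filter[ (slope/100) · (V(t) − V_rest) ]
```

with `slope` in %ΔF/F per mV (negative for negative-going sensors), a
single-exponential photobleach, and i.i.d. Gaussian noise `ε` with SD
`noise_sd·f0` (a shot-noise-limited approximation; the camera-noise floor
and photon statistics of real recordings are not modelled in detail).

The kinetic filter is a weighted pair of first-order relaxations
(fast/slow components with fractional weight `frac_fast_on`).  Each
component uses the exact zero-order-hold recursion
`y[n] = x[n] + (y[n−1] − x[n])·exp(−Δt/τ)`, so a voltage step reproduces
the closed form `a(1−e^{−t/τ_fast}) + b(1−e^{−t/τ_slow})` to machine
precision — this is the oracle used in the tests.  The time constant
switches between the on and off values depending on whether the drive is
moving away from or back toward baseline.  A single two-state filter
cannot honor separate fast-fraction values for onset and decay exactly;
the onset fraction is used for weighting.  Default kinetics (τ_fast_on
0.67 ms, τ_slow_on 3.26 ms, τ_fast_off 0.89 ms, τ_slow_off 6.27 ms)
follow the improved-variant step-response values; the default in-vivo
sensitivity is −0.2 %/mV, while characterization examples use the
patch-clamp subthreshold value of −0.54 %/mV.

**Membrane potential.**  V(t) is a resting level plus: action potentials
(triangular rise over 2h/3, exponential decay with τ = (2h/3)/ln 2, so
the waveform FWHM equals the half-width parameter h, default 0.7 ms);
difference-of-exponential PSPs; and sinusoidal 3–5 Hz oscillation
episodes.  Spike times follow the peak-sample convention and are
quantized to the frame grid, so every AP peaks exactly on a sample.
Refractory enforcement drops spikes closer than 5 ms.  No conductances,
adaptation, or spike-threshold dynamics are modelled — passing tests
shows the *analysis* stack recovers what the generator put in, not that
the generator is a faithful neuron model.

**Coupled populations.**  Each cell pair (i, j) with weight w_ij shares a
Poisson stream of common excitatory events (rate `shared_event_rate`,
default the minimum per-cell rate).  Every event independently triggers a
spike in each member with probability w_ij; members that do not spike
receive a subthreshold depolarizing bump of amplitude
`codep_bump_mv · w_ij` (default 3 mV/unit weight, difference of
exponentials, 2 ms rise / 20 ms decay).  Independent Poisson spiking tops
each cell up to its nominal rate (`max(0, r − Σ_j w_ij·ρ)`).  Both
near-coincident spiking and measurable co-depolarization therefore grow
with w.  Two consequences worth knowing:

* Coincidences scale like ρ·w², and subthreshold co-depolarization around
  reference spikes like w²(1−w) — above w ≈ 0.6 nearly every shared event
  makes the target spike and the subthreshold signal vanishes.  Round-trip
  tests therefore impose weights in [0.15, 0.6].
* In an all-to-all coupled network, a reference's spikes correlate with
  events of *other* pairs, diluting pair specificity; the pair-specific
  round trip uses a star topology (one target, many mutually uncoupled
  references), mirroring a target-centred analysis.

**Plate movies.**  96-well-style field-stimulation recordings: 8 pulses
at 8.3 Hz imaged at 1497 Hz, disk-shaped cells (~3 px radius) over
background pixels at 10% of cell brightness, per-pixel gain jitter,
per-pixel single-exponential bleaching, Gaussian noise, and a
rising×decaying exponential response per pulse whose amplitude is the
control value (−4% ΔF/F by default) times a per-variant sensitivity
multiplier.  The sidecar lists the truly responsive (row, col) pixels.

## Preprocessing

* Bleach correction fits `p1·e^{−t·p2}` (t in seconds, nonlinear least
  squares, log-linear initialization) excluding half-open sample windows
  after each stimulus; the fitted value at frame 0 is the pixel baseline
  F0, and the plate background is the 1st percentile (linear
  interpolation) of the F0 map.
* Three ΔF/F conventions: inverted 1-s moving average (positive spikes),
  and 5-s / 20-ms / 50-ms running medians (negative spikes).  Window
  lengths round to the nearest odd sample count; edges use reflect
  padding.  ΔF/F is a fraction internally; reports are in percent.
* Noise: (a) sign-symmetrized SD — discard negative samples, randomize
  signs of the rest (zeros included; a constant retained sample is
  degenerate and reports 0); (b) spike-excluded SD over samples outside
  [−2 ms, +4 ms] windows around spikes.

## Spike detection

**KDE detector** (positive-spike traces): high-pass by subtracting a 5-ms
running median; candidate peaks are local maxima (strictly greater than
both neighbors; plateaus take their first sample); Gaussian KDE with the
Silverman bandwidth estimates the peak-amplitude density P(x), the same
procedure on the inverted trace gives Pnoise(x), and S = P − Pnoise.  The
threshold th1 is the largest grid point (512 points on [0, max p_k])
where S crosses above Pnoise — i.e. where the spike-dominated amplitude
region begins, balancing type I/II errors.  Expected false positives at a
threshold are counted as supra-threshold inverted-trace peaks; if the
count at th1 exceeds `floor(fp_rate_cap·duration)` (18 for 0.1 Hz ×
180 s), the fallback th2 — the smallest value admitting at most the cap —
replaces it.  Initial spikes define a mean AP template (−2/+4 ms, the
same window as the noise exclusion); one correction pass subtracts the
template contribution of the largest strictly-larger neighbor within
±2 ms from each candidate (raw amplitudes decide "larger"); corrected
amplitudes are re-thresholded.  SNR = mean detected amplitude / spike-
excluded noise SD.

**Fixed-threshold detector** (negative-spike traces): samples below
−k·SDnoise (k = 4) group into consecutive runs; each run yields one spike
at its extremum (doublet rule).  On Gaussian noise the pre-merge false
rate is Φ(−4)·fs per second (≈0.95/min at 500 Hz), which the tests verify
against the detector output.

**QC profiles.**  Hippocampal: SNR > 5, spike count > 90 (0.5 Hz over
180 s), < 1% of ISIs below 2 ms, template FWHM < 0.85 ms — all strict, as
stated.  ALM: SNR ≥ 3 only.  The generator's optical spike waveform is
broadened by the linear step-response kinetics and typically exceeds the
0.85-ms gate that real fast-interneuron recordings meet; synthetic QC
demonstrations therefore gate on the other criteria or the ALM profile.
The ALM high-frequency SNR is implemented as the mean spike-sample value
divided by the RMS deviation of the trace from its median — the printed
source formula is typographically corrupted, and this reading is flagged
as an interpretation.  Trough-to-peak amplitudes are computed only for
spikes arriving < 20 ms after their predecessor.

## Subthreshold analytics

* Oscillations: 4th-order Butterworth band-pass (3–5 Hz default), applied
  forward-backward (zero phase); outliers exceed 3 × 1.4826·MAD from the
  median of the filtered trace; the episode amplitude is the mean
  |outlier value| in percent.  A stationary sinusoid is never an outlier
  (its MAD is amplitude/√2); note Gaussian noise alone crosses a 3·scaled-
  MAD threshold at the ~0.3% rate, so isolated outlier samples outside
  genuine episodes are expected and harmless to the mean when episodes
  are present.
* d′ = (μS − μN)/√(½(σS² + σN²)) with population SDs.  The synPSP
  procedure regresses a line on 40 ms of pre-onset baseline per trial,
  converts to ΔF/F against it, takes per-trial means of a 10-ms pre-onset
  noise window and a 4–14 ms post-onset signal window, and summarizes
  d′ against amplitude (−15…+15 mV in 5 mV steps) by an OLS slope, d′/mV.
* F–V curves use the mean over the last 200 ms of each 1-s step (steady
  state) by default, since the characterized variant lacks a transient
  peak; a peak mode exists for sensors with one.  The subthreshold slope
  is the OLS slope over steps within [−90, −50] mV plus the zero-response
  point at the −70 mV holding level, reported as |slope| in %/mV.
* Double-exponential kinetics: constrained least squares (a, b ≥ 0,
  bounds on τ), components sorted so τ_fast < τ_slow, %fast =
  100·a/(a+b).  A single exponential that fits no worse replaces the
  double fit (b = 0, τ_slow = NaN); fits with τ_fast ≈ τ_slow (within 5%)
  are flagged non-identifiable.

## Plate screen

Pulse-aligned averaging uses the stimulus record for the onset frame, not
data-driven detection.  Responsiveness per pixel: two-sided Mann–Whitney
between the 20 ms of averaged-response frames before the pulse and the
10/20/40 ms after it; responsive iff any p < 0.001 (expected null
false-positive fraction ≤ 3·α by the union bound).  Wells with fewer than
four responsive pixels are discarded before pooling.  The averaged
response is fit with y(t) = A·(1−e^{−t/τon})·e^{−t/τoff}; |ΔF/F0|max is
the fitted extremum, at t* = τon·ln(1+τoff/τon).  PDI resamples the
control pixel pool with replacement 10 000 times and reports
100·(mean − 1st percentile of the bootstrap *means*)/mean; the printed
formula is ambiguous between bootstrap means and pooled resampled values,
so both are implemented and the means variant is the default.  Control
normalization is the ratio of pool medians of |ΔF/F0| with a two-sided
rank-sum p (exact for tie-free pools of ≤ 20, asymptotic with tie
correction otherwise).  QC gates use strict comparisons exactly as
printed: control mean < 3.6% fails, PDI > 30% fails, < 100 responsive
pixels fails.

## Synchrony and co-depolarization

CCGs histogram all pairwise lags t_b − t_a (0.5-ms bins, ±50 ms, grid
symmetric about a zero-lag bin).  The FWHM of the central peak is
interpolated after subtracting the mean count in the 15–25 ms band and is
undefined (NaN) when the peak does not exceed that baseline by three
Poisson SDs.  The coincidence fraction counts pooled spikes with a
partner within ±5 ms; its control redraws each train uniformly over the
record (count-preserving; an ISI shuffle is available).  Synchrony
strength is the per-ms coincidence rate in |Δt| ≤ 1.5 ms divided by the
per-ms rate in 15 ≤ |Δt| ≤ 25 ms (a ratio by default; a difference mode
exists).  Co-depolarization averages target ΔF/F segments around
reference spikes that have no target spike within ±10 ms (configurable;
round-trip tests widen the exclusion to the full ±30 ms analysis window
so the subthreshold average stays AP-free), subtracts a pre-spike
baseline window, and reports the peak within ±10 ms of lag zero in
percent.  The per-target correlation analysis needs more than 10
references; the distance-matched control pairs each reference's synchrony
with the co-depolarization of a different reference chosen by greedy
|Δdistance| matching without replacement.  Note that a single target's
control correlation has SD ≈ 0.4 at 16 references — conclusions rest on
averages across targets/populations, as in the tests.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical configuration and seed give
bitwise-identical output, and the pipeline manifest records the derived
sub-seeds and a parameter hash.  The test-suite and acceptance-script
problem sizes are the package's chosen study conditions: 180-s
single-cell recordings at 1 kHz for detector statistics, 60 min of 500-Hz
noise for the fixed-threshold false-positive rate, 16×16–22×22-pixel
wells at 1497 Hz for the screen, 300-s 17-cell star populations for the
synchrony round trip, and 10-sweep averages for noisy kinetics fits (as a
step-protocol characterization would average repeats).

## Known limitations

* The linear F–V model has no saturation, so AP-sized excursions scale
  linearly; real sensors compress at large depolarizations.
* The kinetic filter approximates asymmetric on/off double-exponential
  kinetics with a direction-switched two-component filter.
* Optical effects (PSF, focus, motion, photocurrent cross-talk) are out
  of scope; input movies are assumed motion-corrected.
* The generator's noise is Gaussian and white; correlated noise (hemo-
  dynamics, motion residue) is absent, so detector false-positive rates
  on real data can exceed the Gaussian predictions verified here.
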