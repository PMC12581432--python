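# Methods

This note documents the models, estimators and numerical choices behind the
package, and what the synthetic-data generators do and do not emulate.

## Signal model and units

All analyses operate on a uniformly sampled single-channel extracellular
voltage trace in millivolts, seconds internally. Spectral power is reported
in µV² because the slice-inclusion rule is stated in µV²; the conversion
(mV² → µV², ×10⁶) happens once inside the spectrum computation.
Oscillation and event analyses default to two-minute windows; window
selection (artifact screening) is the caller's responsibility.

## Spectral estimation

The power spectrum is a Welch estimate: 4096-sample blocks at 5 kHz
(1.2207 Hz bin spacing, printed as 1.221), Hann taper, 50% overlap, linear
detrend per block. Per-bin power is the one-sided density times the bin
width, so (i) a pure sinusoid of amplitude A yields band-summed power
≈ A²/2, and (ii) the total over (0, Nyquist] matches the time-domain
variance (Parseval). Integrated band power is the discrete sum of bins
with 20 ≤ f ≤ 80 Hz (edges inclusive); it is a bin sum, not a density
integral, which is the dialect under which the 10 µV² inclusion threshold
applies. Bins below 1 Hz are excluded from all band metrics. Peak-bin ties
resolve to the lowest frequency. HBW locates the two half-maximum crossings
flanking the peak by linear interpolation between adjacent bins; when the
spectrum never crosses half-maximum (flat spectrum, peak on a pedestal) the
value is missing, never zero.

Note on Parseval checks: the per-block linear detrend removes genuine
sub-bin-scale (< ~1.2 Hz) power, so spectrum-total-vs-variance comparisons
are only exact for inputs without such content; the validation suite uses a
white-background synthetic trace for that property.

## Autocorrelation synchrony

The autocorrelogram is the biased, normalized autocorrelation (ac(0) = 1,
|ac| ≤ 1) of the mean-subtracted two-minute trace, computed by FFT
convolution. The 2nd-positive-peak statistic is the raw local maximum
nearest one gamma period (search window 0.5–1.5 periods); the zero-lag
maximum counts as the first positive peak. The alternative two-period
convention is a config switch.

The decay constant τ is the least-squares fit of A·exp(−lag/τ) to peak
ordinates of the oscillatory autocorrelation component:

* a one-period moving-average baseline is subtracted first. For a damped
  cosine this rescales every peak by the same constant — τ is untouched —
  while cancelling the slowly varying autocorrelation background that
  sub-gamma noise contributes;
* only the first peak (the strong one) is located by local-max search;
  later ordinates are read at exact one-period steps from it. A per-peak
  max search would select positive noise excursions and bias short τ
  upward by tens of percent (measured on the generator);
* the fit is nonlinear least squares on the linear scale, which tolerates
  tail ordinates at or below zero; log-space fitting would be undefined
  there and over-weights the noisy tail.

Requires ≥ 3 ordinates and a decaying sequence; otherwise the value is
missing with a reason code. A single two-minute autocorrelogram carries an
irreducible "ghost oscillation" noise floor of σ ≈ 0.007 (finite-sample
correlation of the oscillation with itself), so short decay constants
(τ ≈ 10 ms, whose 2nd peak is ≈ 0.004) are only resolvable from
group-averaged autocorrelograms; `average_autocorrelograms` supports this,
mirroring per-group aggregation across slices. Recovery on the generator is
within ±10% for τ ∈ {10, 20, 30, 50} ms when averaging 20/10/8/8 segments
respectively.

## Multi-unit extraction and phase coupling

Gamma phase is the Hilbert (analytic-signal) phase of the 15–45 Hz
component, shifted so 0° falls at the filtered-trace trough; a cycle runs
trough→trough. All band filters are frequency-domain masks (forward FFT,
zero out-of-band bins, 1 Hz raised-cosine edge taper, inverse FFT) — the
filter class of common acquisition software, zero-phase by construction,
which matters for event timing.

Units are extracted from the 500–3000 Hz component. At 5 kHz sampling the
3000 Hz edge exceeds Nyquist; the top is clipped to 0.9·Nyquist (2250 Hz)
and the full band is honored for fs ≥ 6667 Hz. Wavelet denoising is a
4-level sym4 decomposition with per-level soft universal thresholds
(σ from the MAD of each detail level). Soft thresholding shrinks amplitudes
by roughly the threshold, so measured unit amplitudes underestimate raw
spike heights; all amplitude rules operate on the denoised trace
consistently. Events are local extrema of the absolute denoised trace above
0.0125 mV with a 1 ms refractory (larger event wins); detection runs on the
absolute value because extracellular spikes may be negative-going. A known
limitation: the band-pass ringing of very large spikes (~20% of spike
height) can itself exceed the floor one refractory interval away and
double-count; at the amplitudes the generators emulate this is rare.
Phase analysis uses the upper-quartile-amplitude subset (ties at the 75th
percentile included). Profiles use 20 bins of 18°; activation is the
cumulative firing probability from 0°. The average gamma cycle resamples
each trough-to-trough cycle to 360 points (requires ≥ 10 cycles).
Spike features: height is baseline-to-extremum of the ±2 ms snippet
(baseline from the snippet's outer quarters), width at half height by
linear interpolation; snippets clipped at the edge are excluded from width
statistics but still counted.

## Sharp wave-ripple detection

Sharp waves: local maxima of the ≤45 Hz low-passed trace above
mean + 3·SD, with SD over the entire filtered segment including events (an
optional median/MAD mode exists, off by default); maxima closer than 100 ms
merge to the larger. Under this literal rule the false-positive rate on
event-free Gaussian noise is set by Rice's threshold-crossing formula
(ν·e^{−4.5} ≈ 0.3/s for white noise low-passed at 45 Hz); in practice the
rule works because real backgrounds are strongly low-frequency-weighted
(small ν) and events inflate the SD. SW area integrates (trace − mean)
between the mean-crossings flanking the maximum (trapezoid); events whose
crossings fall outside the segment are flagged edge-clipped with missing
area. Ripples: a 125 ms window centered on the SW maximum is band-passed at
120–300 Hz; troughs within [−15, +10] ms around the maximum are measured by
triple-point-minimax — mean of the two flanking maxima minus the trough —
and kept when the amplitude exceeds 3·SD of the band-passed window and the
rising/falling asymmetry |r − f|/max(r, f) is below 0.75 (the plain-ratio
reading is a config alternative). Trough times are refined by parabolic
interpolation; ripple frequency is the mean reciprocal inter-trough
interval (missing with fewer than two troughs). Incidence is event count
over segment duration.

## Evoked fEPSP metrics

Windows (config defaults): 1.5 ms artifact blanking, fiber volley
1.5–3.5 ms, fEPSP 4–20 ms post-stimulus, baseline from the 5 ms before the
stimulus with a 0.5 ms pre-trigger guard. These follow standard CA3→CA1
latencies; no published windows exist for this protocol. fEPSP amplitude is
baseline-to-extremum (negative-going by default, configurable); the slope
is a least-squares line over the contiguous onset-limb samples between 20%
and 80% of amplitude (mV/ms ≡ V/s). Transmission rate averages per-sweep
|slope|/FV (units (V/s)/mV = ms⁻¹), excluding sweeps with non-positive FV.
Paired-pulse ratio is slope₂/slope₁; response 1 is measured in a window
truncated 0.5 ms before stimulus 2, and at intervals under 60 ms a
difference-of-exponentials template fitted to response 1 is subtracted
before measuring response 2 (mono-exponential tail fit as fall-back). The
template fit is what keeps the 10 ms interval accurate: only ~2 ms of decay
exist there, where a bare tail extrapolation is unstable. Slices with fEPSP
amplitude below 1 mV at the highest intensity are flagged for exclusion.

## Group statistics

Comparisons route through Shapiro–Wilk (α = 0.05, both groups) to a pooled
two-sample Student t or a two-sided Mann–Whitney U (both delegated to
scipy.stats; the routing and the summary-based computations are this
package's logic). From published summaries, SD = SEM·√n and
df = n₁ + n₂ − 2. Gamma power is log₁₀-transformed before comparison.
Cohen's d uses the pooled SD; its 95% CI is the normal approximation
d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))), which reproduces published
intervals to two decimals and is antisymmetric under group swap (the
noncentral-t construction is not). Per-phase-bin comparisons are Welch
t-tests without multiplicity correction, reported as contiguous significant
ranges; a Holm option exists but is off by default, matching the original
uncorrected usage.

## Synthetic-data generators

Each generator is a pure function of its config (seed included); identical
seeds give bit-identical traces. They emulate the statistical structure of
the recordings, not the biophysics — no conductance-based network, no
receptor-level mechanism.

**Gamma LFP.** Cycle-concatenated phase (so the true phase of every sample
is known exactly — the point of cycle-based rather than filtered-noise
synthesis), cycle periods jittered by a configurable fraction (default
0.02), multiplied by a zero-mean Ornstein–Uhlenbeck envelope whose
correlation time is the ground-truth τ (default 25 ms, matching published
slice values of ~13–32 ms) and whose SD sets the band power
(default 100 µV RMS → ≈ 5000 µV², log power ≈ 3.7, inside the published
3.1–3.8 range). The envelope is low-passed at 150 Hz: the raw OU process
has 1/f² spectral tails that would otherwise bleed into the unit band
(≈ 2% of envelope power removed; the exponential autocorrelation at
gamma-period lags is essentially untouched). Where the envelope is
negative the physical waveform is phase-shifted by half a cycle; the
ground-truth phase records this, and spike placement compensates for it.
Background: 1/f^1.5 noise (default 20 µV RMS) high-passed at 1 Hz,
emulating an AC-coupled recording chain. Not emulated: harmonics,
non-sinusoidal cycle shape, slow drift, epileptiform events — so passing
recovery tests demonstrates estimator correctness under realistic SNR, not
robustness to every artifact class.

**Phase-locked units.** Poisson count (default 5 Hz compound rate), phases
von Mises (μ, κ) on the effective cycle, biphasic derivative-of-Gaussian
templates (default 0.05 mV, 0.3 ms) whose spectral energy sits inside the
unit band.

**SW-R train.** Renewal event times: 200 ms dead time plus exponential
gaps with mean 1/incidence − 0.2 s, so the long-run rate equals the
configured incidence exactly. Events are Gaussian sharp waves
(default 0.2 mV, σ = 10 ms) with a flat-top (Tukey) ripple burst (default
200 Hz, 5 cycles) at the maximum — flat-top because envelope modulation
shifts trough times and would bias the inter-trough frequency estimate.
Background: 1/f² noise, steeper than the gamma background, reflecting the
low-frequency-dominated spectrum of the spontaneous (non-drug) slice state;
this also gives the 3·SD rule its practically low false-positive rate.

**fEPSP sweeps.** Per intensity (10–50 µA): a 0.4 ms biphasic artifact at
the trigger, a narrow negative Gaussian fiber volley at 2.4 ms
(amplitude = gain·intensity), and a negative difference-of-exponentials
fEPSP from 4.5 ms (rise 1.5 ms, decay 8 ms). Paired-pulse sweeps scale the
second fEPSP by a configured facilitation per interval (10–500 ms), so the
measured PPR has an exact truth.

## Validation problem sizes

The test suite and acceptance script run two-minute segments at 5 kHz
(600 000 samples) for single-segment checks; τ recovery averages 20/10/8/8
such segments for τ = 10/20/30/50 ms; phase-preference recovery uses a
30 Hz compound unit rate over two minutes so the circular-mean standard
error stays within the ±15° tolerance at κ = 0.5; the type-I calibration
uses 2000 null replications of n = 15 per group.

## Known limitations

* Artifact and epileptiform-discharge screening is out of scope; segments
  are assumed pre-selected.
* τ from a single two-minute segment is noisy for τ below ~2 gamma periods
  (see above); report group-averaged fits for short decay constants.
* The triple-point-minimax reading, the wavelet dialect, the FFT-mask
  taper width, and the asymmetry formula are pinned conventions exposed in
  config — other toolchains' readings of the same named operations may
  differ in detail.
* Unit detection does not sort spikes; "units" are unsorted multi-unit
  events and may include interneurons and pyramidal cells alike.
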