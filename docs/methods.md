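# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Containers and conventions

Multichannel recordings travel as little-endian int16 flat binary,
interleaved by sample frame, with a `key=value` sidecar meta file
(`nChans`, `sampleRateHz`, `dtype=int16`, `voltsPerBit`, `channelIds`,
optional `geometry`, `units`). The dialect is deliberately a small,
self-describing subset of the SpikeGLX format; full compatibility with
vendor files is not attempted. Quantization scale is chosen per file so the
largest sample uses the int16 range; round-trip error is bounded by half a
bit. All on-disk times are seconds; all intervals are half-open
`[start, end)`; delimited tables are comma-separated UTF-8 with a mandatory
header. Behavioral states come from the closed vocabulary {idle, running}.

## Synthetic data

The generators exist so that detectors and statistics can be validated
against exact ground truth. Each takes a dataclass of parameters including
a mandatory seed and drives a single `numpy` PCG64 stream; identical
parameters give bit-identical output.

**Patch traces** (`gen_patch_trace`). Synaptic events are a homogeneous
Poisson process per polarity; each event adds a difference-of-exponentials
kernel `exp(-t/τ_d) − exp(-t/τ_r)` normalized to unit peak (defaults
τ_r = 1.5 ms, τ_d = 15 ms, a typical CA3 PSC shape), outward positive /
inward negative as under a low-chloride internal at −50 mV. Amplitudes are
Gaussian (outward 20 ± 5 pA, inward 15 ± 4 pA, clipped at 20 % of the
mean); defaults put the signal-to-noise at ~10 with the 2 pA noise floor.
Default rates (outward 4 Hz, inward 0.25 Hz) match a neonatal-like,
GABA-dominated recording. Network bursts are slow outward Hann envelopes
(25 pA, 400 ms by default, 0.02 Hz) with nested fast outward events at
20 Hz. Noise is white Gaussian.

**MEA grids** (`gen_mea_recording`). An 8×8 grid at 20 kHz with ~1.2 ms
biphasic spike waveforms at Poisson background rates, optional per-channel
burst episodes, and dentate-gyrus trigger spikes on a designated electrode.
Each trigger launches a negative slow deflection that recruits a contiguous
channel set outward from the DG electrode: cells are ranked by
(Chebyshev ring, Euclidean distance, row, col), which guarantees every
prefix of the recruitment order is 8-connected; channel *k* activates at
`onset_lag + k / speed` and stays depolarized until `wave_dur_ms`
(default 120 ms) after the trigger, with raised-cosine edges. Wave
amplitude defaults to 8 noise SD so recruited channels sit safely beyond
the ±2 SD cluster threshold even after the wave itself inflates the
per-channel SD.

**Awake LFP** (`gen_lfp`). A 7 Hz theta cosine plus gamma whose carrier is
unit-RMS narrowband Gaussian noise (40–70 Hz) — real gamma is stochastic
broadband activity, and a deterministic carrier would be harmonically
locked to theta, giving every simulation a fixed artificial phase-profile
signature — multiplied by the envelope
`A·(1 + m·cos(θ_theta − φ0))`, `m ∈ [0, 1]`. Ripples are Hann-windowed
sinusoids (center within 150–200 Hz, durations uniform 40–140 ms by
default) placed by a Poisson process strictly inside idle epochs with a
250 ms refractory gap (sharp-wave ripples do not overlap in vivo; without
the gap adjacent truth events merge into single detections). Noise is a
white + 1/f-amplitude mix per channel; epochs alternate idle/running
blocks. The default rate of 1250 Hz resolves the ripple band while keeping
simulations cheap.

What the generators do **not** emulate: real PSC kinetic variability and
rundown, electrode drift and line noise, spatially correlated MEA noise,
non-stationary theta frequency, sharp-wave (stratum-radiatum) components of
SWRs, and movement artifacts. Passing tests therefore demonstrate correct
implementation of the analyses, not robustness to every property of real
recordings.

## Synaptic-event detection

The amplitude criterion is twice the baseline RMS noise. The noise estimate
is MAD/0.6745 of a > 1 kHz high-passed copy (events live well below 1 kHz),
divided by the filter's white-noise power gain (computed from the frequency
response) so that the estimate is unbiased for a white noise floor; it is
accurate to a few percent in the presence of realistic event rates.

A raw-sample threshold at 2×RMS fires continuously on wide-band noise, and
the original workflow resolved this with manual verification. Here the
threshold is instead applied to a scaled-template statistic (Clements &
Bekkers style): the least-squares amplitude of the unit-peak PSC kernel at
every offset. This preserves the 2×RMS *amplitude* semantics while the
statistic's noise floor is ~9× below the sample noise, making chance
crossings negligible. Detection then proceeds in three refinement steps,
each motivated by a measured failure mode at study-like rates (4 Hz):

1. **Masked-median baseline.** The local baseline is a running median over
   the preceding 500 ms. A first detection pass marks event supports; the
   median is recomputed with those samples masked, since event-dense
   stretches otherwise drag the baseline and mirror large events into
   spurious opposite-polarity detections. A 50 ms window (a common choice
   for sparse minis) adapts during each event's decay and is far worse in
   this regime; the window is configurable.
2. **Amplitude refinement.** Overlapping kernels bias single-template
   amplitude estimates, so amplitudes are refined by coordinate descent on
   the joint least-squares fit (three sweeps); events whose refined
   amplitude falls below threshold are dropped.
3. **Peeling rescan.** The fitted model is subtracted and the residual
   rescanned, recovering small events hidden under opposite-polarity
   neighbours; a candidate is accepted only if the raw residual itself also
   crosses the threshold at the expected peak, which rejects the broad,
   shallow lobes of template misfit.

Cross-polarity detections within the 5 ms refractory window merge to the
larger event. Measured recovery at the study-like operating point
(4 Hz outward / 0.25 Hz inward, SNR ≥ 5, 300 s): within ±5 % per polarity.

Network bursts: the trace is low-passed at 20 Hz, referenced to its median,
and candidate intervals are taken where the slow envelope exceeds half the
10 pA threshold; candidates merge across gaps < 100 ms and are accepted
only if the peak reaches 10 pA and the supra-half-threshold extent lasts
100 ms. Both printed rules hold exactly for every reported burst.

Cell summaries apply the inclusion rules: event frequency ≥ 0.008 Hz
(0.5/min; per polarity by default, switchable to total), series resistance
< 30 MΩ and ≤ 20 % change when metadata is supplied, and a warning when
less than 5 min and fewer than 200 events were analyzed. Drug effects are
reported as drug/baseline ratios per measure with raw paired values
retained, because paired tests are run on raw data, not ratios.

## MEA analysis

Spikes: channel-wise 300–3000 Hz band-pass (upper edge clipped at 0.45×
rate), threshold 4 robust SD on the absolute signal, 1 ms refractory,
timestamp at the absolute peak. These stand in for an acquisition package's
unpublished "default parameters" and are config-exposed.

Poisson surprise: `S = −log10 P(N ≥ n)` for `N ~ Poisson(λt)` via the
incomplete-gamma identity `P(N ≥ n) = P(n, λt)`, with a log-space
summation fallback when the tail underflows (S ≳ 300). Burst detection is
Legéndy–Salcman: candidate cores are maximal runs of inter-spike intervals
below half the channel mean ISI, grown forward (10-spike lookahead) and
trimmed at the start to maximize S, then accepted at S ≥ 10 with ≥ 10
spikes spanning ≥ 0.1 s; accepted bursts cannot overlap. λ is the channel's
whole-recording mean rate. At λ = 1 Hz the S ≥ 10 / n ≥ 10 acceptance
region requires 10 spikes inside ≈ 0.75 s, an event with probability
~10⁻⁸ per train-hour — false positives are effectively impossible, and the
calibration test checks exactly that against the analytic tail.

Activity clusters: traces are polyphase-resampled to 5 kHz
(linear-extrapolated padding avoids edge transients) and demeaned with 1 s
windows at 50 % overlap, interpolating the window means between centers —
this removes drift exactly for linear trends while a 4 ms transient loses
< 10 % of its amplitude. Per-channel SDs are computed over the whole
preprocessed recording (channels have heterogeneous gains; a global-SD
switch exists). At a query time the grid masks `value > +2 SD` and
`value < −2 SD` are labelled with 8-connectivity (the 2-D default of the
standard connected-component routine) and only the largest component per
polarity is kept. The lag grid is 21 points at 5 ms spacing running 0–100 ms
*after* each trigger — the downstream summaries (first 20 ms maximum,
normalized 30–70 ms mean, normalization to the first four bins "following
the spike") only make sense on a post-trigger grid, though a centered
−50…+50 ms grid is available via `lag_start_ms`. The per-bin scalar is the
larger of the positive and negative cluster sizes, with the polarity used
recorded per bin for audit. Normalized curves divide by the mean of bins
0–15 ms; an all-zero early window leaves the normalized curve NaN-flagged
rather than inventing a value. Triggers whose window leaves the recording
are skipped and logged.

## LFP analysis

Preprocessing is a zero-phase 350 Hz Butterworth low-pass plus per-channel
mean subtraction. Behavioral intervals are tiled with non-overlapping 3 s
segments (remainders dropped, so epochs stay independent and never straddle
a state boundary).

Wavelet power uses the canonical complex Morlet family at 7 cycles, fixed
across frequencies. Convolution is done directly with the wavelet arrays:
at 3 Hz × 7 cycles a wavelet (~3.7 s) outlasts a 3 s segment, so segments
are reflection-padded and samples without full wavelet support are excluded
per frequency through an explicit validity mask, capped at 45 % of the
segment per side so a central core always remains. Band power is the mean
of `|W|²` over valid times and a 1 Hz frequency grid (2 Hz for the
phase-profile gamma grid, where 36 frequencies are averaged anyway and the
half-step saves half the cost). Band edges follow the analysis convention:
theta 3–12 Hz, low theta 3–6, high theta 7–13, gamma 20–90.

The coupling profile takes θ as the angle of the 7 Hz Morlet coefficient
and gamma power as the mean `|W|²` over 20–90 Hz, bins samples into eight
equal phase bins partitioning [−π, π) (bin 1 starts at −π), and averages
per bin. Two groups' profiles are compared by nested quadratic regression:
`power = aθ² + bθ + c` per group vs one shared fit, with
`F = [(SS_shared − SS_sep)/(df_shared − df_sep)] / (SS_sep/df_sep)`.

The parametric F p-value assumes independent residuals, but the eight bins
of one epoch's profile share that epoch's gamma-power level and the smooth
wobble induced by wavelet time-smoothing (at 20 Hz the 7-cycle wavelet
averages over ~350 ms ≈ 2.5 theta cycles), so pooled profiles are
pseudoreplicated and the parametric test rejects far too often under the
null. `compare_quadratic_fits` therefore reports the classical statistic
as-is, and `compare_quadratic_fits_permutation` calibrates the same F by
permuting whole per-epoch profiles (unit-mean normalized) between groups —
epochs are the exchangeable unit under the null. Measured at the default
operating point: ~3 % null rejections at α = 0.05 with full power against
a modulation-depth difference of 0.8 vs 0. The permutation variant is the
recommended inferential route; the parametric p is retained for
comparability with common curve-fitting software.

Ripple detection follows the Kay envelope method: 150–200 Hz band-pass per
selected channel, square, sum across channels, Gaussian-smooth (σ = 4 ms),
square root, z-score against the idle-epoch distribution. Candidates must
hold z ≥ 2 for ≥ 15 ms (the minimum-duration rule applies to the
above-threshold core; applying it after extension admits large numbers of
noise events), then extend to the surrounding zero crossings of z, merge
when overlapping, and are confined to idle epochs. Detector output is
invariant to common positive rescaling of all channels, and raising the
threshold can only reduce the event count. Ripple statistics are the
occurrence rate over total idle time, the arithmetic mean duration, and
the percentage of ripples strictly longer than 100 ms.

A known, quantified limitation: with boundary extension to the mean, the
band-limited noise envelope (correlation time ≈ 20 ms) stays above its own
mean past a true ripple edge with appreciable probability, so measured
durations carry an approximately exponential overshoot tail — across
realistic configurations 12–18 % of events land more than 20 ms from the
embedded truth duration even at 10× SNR, and dense-event configurations
trade this overshoot for a systematic undershoot on long events (Hann
tails below the detection reference are invisible in principle). Median
duration error stays within a few ms. Users needing tight per-event
durations should treat the extended boundaries as indicative, not exact.

## Statistics

Two-way ANOVA uses Type-II sums of squares (each main effect adjusted for
the other, interaction last) — appropriate for the mildly unbalanced cell
counts of these designs and switchable to Type-III. Empty design cells are
an error naming the cell. Mann–Whitney and Wilcoxon use exact null
distributions for tie-free samples of n ≤ 12 per group and the
tie-corrected normal approximation otherwise; all-zero paired differences
are flagged degenerate with p = 1 rather than erroring. Holm-Šídák:
`adj_(i) = 1 − (1 − p_(i))^(m−i+1)` on the sorted p-values with a running
maximum for monotonicity; adjusted values never fall below raw. Learning
curves are compared by per-subject least-squares slopes over a designated
trial window (subjects with fewer than two trials excluded with a warning)
followed by an unpaired two-tailed t test.

## Problem sizes

The shipped tests and the acceptance script run the full analyses at
reduced problem sizes chosen to keep the whole suite in the minutes range
on a laptop: patch recovery uses 20 seeds × 300 s at 10 kHz; MEA spread
10 seeds × 10 s at 20 kHz (full 64-channel grids); CFC discrimination
100 seed-pairs of 24 s LFP at 1250 Hz; ripple recovery a single 120 s idle
recording with ~55 embedded events; statistical calibration 500 null
permutations. Rates, SNRs and effect sizes are the study-like defaults
documented above, not tuned per test.
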