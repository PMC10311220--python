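# Methods

This note documents the models and procedures behind each module, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic generators do and do not emulate.

## Spike detection (`neuroagg.ephys`)

Raw extracellular voltage is bandpass filtered with a 4th-order Butterworth
(default 200–3000 Hz) applied forward–backward (`sosfiltfilt`), so the
filter is zero-phase and spike times are not shifted by group delay. The
noise level is estimated as the RMS of the filtered trace and the detection
threshold is `threshold_multiplier × RMS` (default 6). For a zero-mean
filtered trace the RMS equals the standard deviation, which makes the
common "k SD from the RMS" phrasing well defined; this matches the
semantics of mainstream MEA acquisition software. Because dense spiking
inflates the RMS, a robust alternative (`robust_noise=True`, MAD/0.6745) is
available, but the plain RMS remains the default.

Each contiguous supra-threshold excursion yields one spike, timestamped at
its extremum sample rather than the first crossing — extremum timing is
stable under noise, whereas first-crossing timing jitters with the local
noise slope. A configurable dead time (default 1 ms) prevents a single
excursion fragmented by noise from producing multiple detections. Detection
polarity defaults to negative, the dominant polarity of extracellular
somatic spikes. Because the threshold scales with the noise estimate,
detection is equivariant under positive rescaling of the trace.

Per-electrode firing metrics follow the ISI-exclusion convention: the mean
ISI averages only intervals ≤ 100 ms (configurable), so the derived firing
rate `1/mean_ISI` reflects within-train tempo rather than silences; when no
ISI qualifies the mean ISI and rate are NaN while spikes/min is still
reported. An electrode is "active" with at least 2 spikes (more than one
spike over the recording).

**Spectrograms.** `spectrogram` is a thin wrapper over Welch-style STFT
(`scipy.signal.spectrogram`), truncated to 0–100 Hz by default. A narrow
biphasic spike carries almost no power below 100 Hz, so slow bursting
rhythms are exposed on the *rectified envelope*: with `rectify=True` the
absolute value of the signal is analysed, and `smooth` (Gaussian sd in
seconds, e.g. 0.03) suppresses the pulse-train harmonics of the rectified
waveform so the fundamental within-burst firing rhythm dominates. The
two-epoch "super burst" generator (short bursts with 0.2 s intra-burst
ISI followed by a long dense burst at 0.07 s ISI) shifts the dominant
envelope band from 2–10 Hz to 10–20 Hz across the epochs, which the test
suite verifies on a noiseless rendering.

## Burst detection (`neuroagg.bursts`)

Bursts use the max-interval convention: a candidate opens at the first ISI
≤ `isi_init` (100 ms), extends while ISIs stay ≤ `isi_continue` (250 ms),
closes at the first longer gap, and is kept when it holds ≥ `min_spikes`
(5). The phrase "minimum ISI to initiate" is read as the maximum allowable
initiation ISI; the literal reading (an ISI ≥ 100 ms starts a burst) would
contradict a *maximum* continuation ISI of 250 ms and is rejected. A closed
burst cannot be reopened by its closing gap; scanning resumes at the spike
after the gap, so bursts are disjoint and ordered. For short trains this
state machine provably returns exactly the maximal contiguous windows
satisfying the rules; the test suite checks equivalence against a
brute-force window enumeration on 1,000 random trains.

The interburst interval is measured end-to-start (gap between consecutive
bursts), matching "interval between bursts" semantics; start-to-start users
can derive it from the burst table. Burstiness is the fraction of spikes
inside bursts: 0 bursts → 0, all spiking in bursts → exactly 1. Burstiness
on an empty train is an error, not 0 — a silent electrode is not a tonic
one.

## Colocalization (`neuroagg.coloc`)

Channels are background-subtracted with a rolling ball (default diameter
25 px) via `skimage.restoration.rolling_ball` — the upper envelope of a
ball rolled under the intensity surface, i.e. a grayscale opening with a
ball-shaped structuring element; a flat-disk opening is available behind
`ball_method="opening"`. The residual is clipped at zero.

Mander's coefficients are computed as **area ratios on binary
co-occurrence masks** (`M1 = |A∧B|/|A|`, `M2 = |A∧B|/|B|`), not the
intensity-weighted textbook variant — the area-ratio definition is the one
used for axon/dendrite segregation scoring. Signal masks default to
per-channel Otsu thresholds after background subtraction (a constant
channel is an error, as no two-class split exists); fixed strict-`>`
thresholds support exact tests. An empty mask makes its coefficient NaN,
never 0. PCC is the product-moment correlation over all pixels. By default
PCC and TOS are computed on the background-subtracted images, consistent
with subtraction preceding all scoring; both orders are supported by
toggling `background_subtract`.

TOS selects the brightest `top_fraction` (default 10%) of pixels per
channel — ties broken by stable pixel order so the selected count is
deterministic — and rescales their co-occurrence `nAB` against the
independence expectation `e = nA·nB/N`:

```
TOS = (nAB − e) / (min(nA, nB) − e)           if nAB ≥ e
TOS = (nAB − e) / (e − max(0, nA + nB − N))   otherwise
```

giving +1 at maximal co-occurrence, 0 at independence, −1 at maximal
exclusion. When the attainable range collapses to a point (denominator 0)
the score is defined as 0.

## Morphometry (`neuroagg.morpho`)

**Sholl.** Crossings at radii `step, 2·step, …` (default step 5 µm, up to
the arbor's extent) are exact circle–segment intersection counts: a
quadratic solve per edge, with tangencies counting once and a vertex lying
exactly on a circle counting once across its incident edges (coincident
intersection points are deduplicated at 1e-6 µm). Raw counts are reported,
not normalized curves. A soma-only arbor yields an all-zero profile. The
profile and all morphometrics are invariant under rigid motion of the
tracing.

**Branch morphometrics.** Main branches are the subtrees rooted at soma
children, measured from the soma to the farthest terminal. A junction is a
non-soma node with ≥ 2 children whose side path — the second-longest child
path, measured to the farthest terminal of that side subtree — is at least
`min_junction_branch` (5 µm, the stated filter for junction counting). A
soma child is excluded from the main-branch count when it bears no
qualifying junction *and* its extent is below `min_main_branch` (default
10 µm); the original scoring excludes "notably small" junction-free
projections without stating a size, so the floor is explicit and
configurable here. Total process length sums every traced segment,
including sub-5 µm stubs and excluded stubs — the 5 µm filter's stated
scope is junction counting only.

**Zone densities.** The aggregate perimeter is modeled as a circle (center
+ radius); each point is assigned by its distance to the perimeter
`d = |p − c| − R` into bands `inner ≤ d < outer` (defaults 50–200,
200–400, 400–600 µm). Densities divide counts by the analytic annulus area
`π[(R+outer)² − (R+inner)²]` in mm². Points inside the aggregate (d < 0)
are unassigned with a warning; band counts plus unassigned always equal the
total.

## Synthetic data (`neuroagg.synth`)

Every generator is a pure function of its spec including the seed.

- **Spike trains**: bursts are placed deterministically at regular
  intra-burst ISI with fixed gaps; noise spikes are rejection-sampled at
  least 0.3 s from burst windows and from each other, so they can neither
  extend a burst (continuation ISI is 0.25 s) nor chain into one. The
  detection round trip therefore recovers burst count and per-burst spike
  counts exactly. A separate benchmark helper
  (`gen_benchmark_spike_times`) draws dense random spike times (minimum
  gap 5 ms) for detector recall/precision tests, where the 0.3 s guard
  would cap the count.
- **Voltage**: spikes render as a biphasic template (leading lobe twice
  the trailing lobe, opposite sign; default width 1.2 ms) whose extremum
  sample sits at the spike time, over i.i.d. Gaussian noise. The standard
  benchmark — 100 spikes at 12× the noise sd over 10 s at 12.5 kHz — is a
  regime where the 6×RMS rule has essentially zero expected false
  positives (a 6σ Gaussian tail over 1.25e5 samples) and every spike
  clears threshold after filtering. No published amplitude or noise
  statistics exist for the motivating recordings, so these defaults are
  plausible placeholders, not calibrations.
- **Image pairs**: foreground pixels are sampled without replacement with
  an integer overlap count, so true M1/M2 are exact rationals and the
  noiseless round trip is exact to machine precision rather than
  statistical.
- **Arbors**: planar (z = 0) radial trunks of exact segment lengths with
  one side branch per interior trunk node; angles are jittered, lengths
  are not, so the morphometric ground truth is computed constructively
  from the spec's lengths (an independent recursion over the construction
  plan, not the coordinate-based analysis code). Side-branch length is
  settable to straddle the 5 µm junction filter (4.9/5.1 µm edge cases).

What the generators do **not** emulate: biophysical spike waveform
diversity, electrode crosstalk or MEA geometry, 1/f or line noise,
fluorescence point-spread functions and shading, tortuous or 3-D arbor
geometry, and irregular aggregate perimeters. Passing round-trip tests
therefore demonstrates correctness of the metrics under their stated
assumptions (i.i.d. Gaussian noise, aligned noise-free masks, exact planar
trees), not robustness to every artifact of real recordings and
micrographs.

## Pipeline (`neuroagg.pipeline`)

The pipeline's contract ends at tidy per-electrode/per-burst/per-cell
tables shaped for downstream statistics; hypothesis testing (ANOVA,
Kolmogorov–Smirnov, multiple-comparison corrections) is deliberately left
to standard statistics packages. Aggregation implements the two analysis
modes — culture-based (mean within culture, then across culture means) and
cell-based (pooled values) — which coincide when each culture contributes
one value; ephys metrics aggregate over active electrodes only, and
cultures contributing no values are dropped from culture-based summaries
with a logged warning. CSV headers are versioned and guarded by golden
tests; outputs carry no timestamps, so a rerun with the same configuration
and manifest is byte-identical. The run summary records a configuration
hash that excludes the output directory (bookkeeping, not analysis).

## Problem sizes in the test suite

Tests run on deliberately small instances chosen to exercise every rule
exactly: 10-second benchmark traces at 12.5 kHz, 1,000 random ≤ 12-spike
trains for the burst oracle, 100 noiseless 64×64 image pairs spanning
overlap 0–1, 50 random arbors against a 0.01 µm dense-sampling Sholl
oracle, and 100 arbors for the morphometric round trip. These sizes keep
the whole suite under a few seconds while leaving no rule untested at its
boundary (ISIs at 100/250 ms, side branches at 4.9/5.1 µm, thresholds at
equality).
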