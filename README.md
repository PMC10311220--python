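# neuroagg

Quantitative characterization of 2D (dissociated) versus 3D (aggregated)
neural cultures. The package implements the analysis chain used to compare
such cultures on three axes:

- **Electrophysiology** — multi-electrode array (MEA) voltage traces are
  bandpass filtered (200–3000 Hz, zero-phase), spikes are detected at
  6× the RMS of the filtered signal, and per-electrode firing metrics are
  computed with a 100 ms ISI-exclusion rule. Bursts are detected with the
  max-interval convention (≥ 5 spikes, initiation ISI ≤ 100 ms,
  continuation ISI ≤ 250 ms) and summarized as bursts/min, spikes per
  burst, burst duration, interburst interval, and **burstiness**
  `B = N_within-burst / N_total ∈ [0, 1]`. Spectrograms (0–100 Hz) expose
  slow bursting rhythms.
- **Neuronal polarization** — axon/dendrite channel pairs (e.g. Tuj1/MAP2)
  are background-subtracted with a 25-pixel rolling ball and scored with
  Mander's area-overlap coefficients `M1 = |A∧B|/|A|`, `M2 = |A∧B|/|B|`,
  Pearson correlation over all pixels, and the threshold overlap score
  (TOS) of the top 10% brightest pixel sets.
- **Astrocyte morphology** — hand-traced arbors (SWC) are analyzed with
  exact-geometry Sholl profiles (circle–segment intersection counts) and
  branch morphometrics (main branches, longest main branch, junction count
  with a 5 µm side-branch filter, total process length), plus astrocyte
  densities in annular zones (50–200, 200–400, 400–600 µm) around a
  circular aggregate.

Because this kind of study rarely ships raw recordings, the package includes
a first-class **synthetic-data generator** (`neuroagg.synth`): every
generated input — burst-structured spike trains, voltage traces with
embedded biphasic waveforms, image pairs with constructively exact pixel
overlaps, branching arbor trees — is paired with its exact ground truth, so
each analysis stage is testable end to end by round trip.

## Worked example

```python
from neuroagg import (SpikeTrainSpec, gen_spike_train,
                      detect_bursts, burst_metrics, rate_metrics)

spec = SpikeTrainSpec(n_bursts=6, spikes_per_burst=8, intra_burst_isi=0.03,
                      inter_burst_gap=2.0, n_noise_spikes=10,
                      duration=60.0, seed=42)
train, truth = gen_spike_train(spec)
bursts = detect_bursts(train)
m = burst_metrics(train, bursts)
r = rate_metrics(train)
print(f"spikes: {train.n_spikes}, bursts detected: {len(bursts)}")
print(f"burstiness: {m.burstiness:.4f}")
print(f"bursts/min: {m.bursts_per_minute:.2f}, mean spikes/burst: {m.mean_spikes_per_burst:.1f}")
print(f"mean ISI (<=100 ms): {r.mean_isi*1e3:.1f} ms -> rate {r.mean_firing_rate:.2f} Hz")
```

prints

```
spikes: 58, bursts detected: 6
burstiness: 0.8276
bursts/min: 6.00, mean spikes/burst: 8.0
mean ISI (<=100 ms): 30.0 ms -> rate 33.33 Hz
```

58 spikes were generated (6×8 in bursts plus 10 isolated), the detector
recovers exactly the 6 constructed bursts, and burstiness is 48/58 ≈ 0.83.
The mean ISI uses only intra-burst intervals (30 ms) because every other
gap exceeds the 100 ms exclusion cutoff, giving a within-train firing rate
of 1/0.030 s ≈ 33.3 Hz.

The same round-trip style works for voltage: rendering 100 spikes at
−60 µV over σ = 5 µV noise (10 s at 12.5 kHz) and running `detect_spikes`
recovers 100/100 spikes within 0.4 ms with no false positives.

## Command line

`neuroagg` exposes each stage as a subcommand:

```sh
neuroagg simulate arbor --seed 2 --out sim/        # synthetic data + ground truth
neuroagg spikes --in voltage.h5 --band 200 3000 --k 6 --out spikes.csv
neuroagg bursts --in spikes.csv --duration 600 --out results
neuroagg coloc --a tuj1.tif --b map2.tif --ball 25 --top 0.10 --mask otsu
neuroagg sholl --swc cell.swc --step 5
neuroagg morpho --swc cell.swc
neuroagg zones --points cells.csv --center 0 0 --radius 250
neuroagg report --manifest manifest.yaml --out-dir out/   # full pipeline
```

`report` runs the whole pipeline over a YAML manifest of inputs and writes
tidy per-electrode, per-burst, per-cell, colocalization and zone tables
plus a JSON run summary; reruns with the same configuration are
byte-identical. Per-culture aggregation supports both analysis modes:
*culture-based* (average within each culture, then across cultures) and
*cell-based* (pool all individual values).

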