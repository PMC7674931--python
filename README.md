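# kindlekit

Quantification toolkit for **amygdala rapid kindling (ARK)** experiments in
rodents — the electrical-stimulation model of temporal lobe epilepsy in which
20 sub-convulsive stimuli (10/day over 2 days, 10 s at 60 Hz each) plus a
21st *test* stimulus progressively intensify evoked limbic seizures.  The
package implements the complete quantification stack such a study needs,
as a tested, reusable library with a CLI:

* **Seizure severity** (`kindlekit.severity`) — the 0–8 limbic index (LI;
  Racine scale as modified by Pinel & Rovner), scored as the maximum class
  realized by the behaviors observed in a window; the *fully kindled*
  criterion (≥2 class-4 or ≥1 class-5 seizures); Mann–Whitney group
  comparisons and Friedman + Dunn progression tests on the ordinal scores.
* **Afterdischarge detection** (`kindlekit.eeg_events`) — an afterdischarge
  (AD) is epileptiform EEG outlasting the stimulus, operationalized as a
  stretch whose envelope (rectified signal, 200 ms moving average) is at
  least **2×** the pre-stimulus background for at least **3 s**.  First and
  second ADs per channel feed a presence/absence 2×2 Pearson χ² comparing
  the 1st and 21st stimulus.
* **Spectral features** (`kindlekit.spectral`) — per channel and band
  (delta (0,4], theta (4,8], alpha (8,14], beta (14,30], gamma (30,100],
  whole (0,100] Hz): median frequency (smallest *f* with cumulative power
  ≥ 50 % of the band total), total power, peak power, and frequency at
  peak, computed on the first AD (stimulated groups, after trimming the
  capacitor-discharge sag) or the basal signal from 30 s on (sham groups).
* **Neuroethology** (`kindlekit.neuroethology`) — second-by-second
  behavioral sequences summarized per code (frequency, mean bout duration,
  proportional time) and tested dyad-by-dyad: each ordered behavior pair
  (A, B) gets a 2×2 transition table and is flagged significant when
  χ² ≥ 3.84, log₁₀χ² ≥ 0.25, and observed > expected.  Significant dyads
  become the arrows of exportable flowcharts (DOT / JSON / SVG).
* **Synthetic cohorts** (`kindlekit.synthdata`) — fully labelled data with
  the structure the analyses assume: 1/f background EEG with planted
  polyspike ADs of known onset/duration/amplitude-ratio, Markov-chain
  ethograms with injectable behavioral clusters, and sigmoid kindling
  severity with a treatment-suppression effect at the test stimulus.
* **Pipeline** (`kindlekit.pipeline`, `kindlekit` CLI) — simulate → detect →
  occurrence χ² → FFT → behavior → severity, deterministically for a fixed
  seed, every output stamped with the config hash.

## Worked example

Plant one afterdischarge (3.5× background, 6 s) in a synthetic record and
recover it:

```python
from kindlekit.synthdata import ProtocolConfig, ADGroundTruth, generate_eeg
from kindlekit.eeg_events import detect_afterdischarges, estimate_background
from kindlekit.spectral import power_spectrum, band_features, DEFAULT_BANDS

proto = ProtocolConfig(pre_window_s=30.0, post_window_s=60.0)
stim_off = proto.pre_window_s + proto.stimulus_duration_s
rec, truth = generate_eeg(
    proto, [ADGroundTruth("HIP", 1, stim_off + 2.0, stim_off + 8.0, 3.5)], seed=42
)

print(f"background envelope (HIP): {estimate_background(rec, 'HIP'):.3f}")
for ev in detect_afterdischarges(rec, "HIP"):
    print(f"AD {ev.order}: {ev.onset_s:.2f}-{ev.offset_s:.2f} s "
          f"(duration {ev.duration_s:.2f} s, peak {ev.peak_ratio:.1f}x background)")
```

prints

```
background envelope (HIP): 0.742
AD 1: 41.99-48.01 s  (duration 6.02 s, peak 5.7x background)
```

— the planted event at 42–48 s is recovered within tens of milliseconds,
and its peak envelope exceeds the planted 3.5× ratio because the 1/f noise
adds to the burst.  Band features of the recovered discharge:

```python
seg = rec.channel("HIP")[int(truth[0].onset_s * 2000):int(truth[0].offset_s * 2000)]
freqs, power = power_spectrum(seg, 2000.0)
for band in DEFAULT_BANDS:
    f = band_features(freqs, power, band, allow_empty_energy=True)
    print(f"{band.name:>5}: median {f.median_frequency_hz:6.2f} Hz  "
          f"peak at {f.frequency_at_peak_hz:6.2f} Hz  total power {f.total_power:.4f}")
```

```
delta: median   3.17 Hz  peak at   3.50 Hz  total power 2.3364
theta: median   6.33 Hz  peak at   6.83 Hz  total power 6.1993
alpha: median  10.33 Hz  peak at  11.83 Hz  total power 4.0906
 beta: median  15.67 Hz  peak at  15.50 Hz  total power 0.3283
gamma: median  57.67 Hz  peak at  40.17 Hz  total power 0.1392
whole: median   6.67 Hz  peak at   6.83 Hz  total power 13.0936
```

The polyspike train (5 spikes/s, 50 ms biphasic spikes) concentrates its
energy below ~15 Hz, as the theta-dominant medians show; the sub-band total
powers sum to the whole-band total because the band edges are half-open.

The full simulate-and-analyze pipeline is one command:

```sh
kindlekit run-all --seed 7 --out run7/
```

which writes `events.csv`, `occurrence.json`, `spectral_features.csv`,
`spectral_comparisons.json`, `dyads.csv`, per-group flowcharts, severity
statistics, and a Markdown report whose every number traces to a stage
output file.

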