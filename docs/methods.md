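# Methods

This note documents the models, numerical conventions, and design choices
behind `kindlekit`, in the spirit of the methods documentation of packages
like `statsmodels` or `msprime`: what each procedure assumes, which knobs
matter, and what the synthetic data does and does not emulate.

## Severity scoring

The limbic index (LI) is the ordinal 0–8 seizure-severity scale used for
kindled limbic seizures (Racine's scale as extended by Pinel & Rovner):
0 immobility, 1 facial automatisms, 2 head myoclonus, 3 forelimb myoclonus,
4 rearing, 5 rearing and falling, 6 more than three fallings, 7 wild
running/jumping, 8 tonic–clonic seizure.  A scoring window receives the
**maximum** class among the behaviors observed in it — the standard kindling
convention, since the scale indexes the worst event reached.  The mapping
from ethogram glossary codes to classes ships as an editable table
(`SeverityScale`, YAML-serializable); class 6 is triggered either by the
dedicated `FALL_MULTIPLE` code or by counting four or more `FALL`
observations in one window ("more than three fallings").

*Fully kindled*: an animal with ≥ 2 class-4 seizures or ≥ 1 class-≥5 seizure
over the protocol.  The rule is monotone in the score multiset (raising a
score can never un-kindle).

**Group statistics.**  Severity is ordinal, so all comparisons are
rank-based.

* Mann–Whitney U: exact null distribution when both n ≤ 8 and the data are
  tie-free; otherwise the normal approximation with mid-rank tie correction
  and **no continuity correction**, so exchangeable samples give p = 1
  exactly.  Fully tied data (zero rank variance) is defined as p = 1.
* Friedman test across the repeated stimuli: mid-ranks within each animal
  with the standard tie correction.  A fully tied matrix is defined as
  statistic 0 / p 1 (the textbook tie-corrected formula degenerates to 0/0
  there).  The reported p is the χ²(k−1) tail approximation; at very small
  n·k this is anticonservative relative to the exact permutation null
  (e.g. for 3 animals × 3 stimuli at the maximal statistic 6 the exact
  permutation tail is 1/36 ≈ 0.028 while the χ² tail is 0.0498) — a
  documented property of the approximation, not an implementation defect.
* Dunn's post-hoc after Friedman: z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/(6n)) for each
  stimulus pair, two-sided normal p, Bonferroni-adjusted by default (the
  number of pairs); other corrections were deliberately not added because
  the adjusted p is only used as a flag.

## Afterdischarge detection

An afterdischarge is operationalized by two thresholds: envelope at least
`amplitude_ratio_min` (default **2×**) times the pre-stimulus background,
sustained for at least `min_duration_s` (default **3 s**).

Choices the rule's prose leaves open, and how they are resolved:

* **Amplitude** = the envelope: rectified signal smoothed with a 200 ms
  moving average.  200 ms is long enough to bridge the inter-spike dips of
  a polyspike discharge (spike rates of a few per second) and short enough
  to keep onset resolution well under the 3 s duration threshold.
* **Background** = the *median* (not mean) of the baseline-window envelope,
  robust to isolated baseline artifacts.  The baseline window is the
  pre-stimulus stretch (≥ 5 s required).
* **Within-event gaps**: supra-threshold regions separated by ≤ 0.5 s
  (`merge_gap_s`) are merged — successive bursts of one discharge.
* The threshold is a *ratio*, so detection is invariant to global rescaling
  of the record (amplifier gain does not matter).
* The threshold comparison carries a 10⁻⁹ relative slack and the duration
  check a half-sample slack: "at least k times / at least d seconds" is
  inclusive, and a calibration burst at exactly the boundary must not be
  lost to floating-point or sampling-grid rounding.  Boundary scans on
  noiseless calibration tones recover the acceptance boundaries at exactly
  2.0× and 3.0 s.
* Events are numbered by onset per channel; orders 1 and 2 are the first
  and second discharges entering the occurrence analysis.  Events reaching
  the record end are kept if their observed part satisfies both thresholds.

**Capacitor-artifact trimming.**  Stimulus-isolation capacitors discharge
into the electrode after the stimulus, dragging the early signal mean below
baseline.  Leading samples of the first-AD segment are removed until the
100 ms running mean re-enters baseline mean ± 2 SD, never removing more
than half the segment; a segment whose mean never recovers is returned
empty with a flag rather than raising.

**Occurrence analysis.**  Presence/absence of the order-1 (and order-2) AD
per channel, stimulus 1 vs the test stimulus, in a 2×2 table tested by
Pearson χ² on 1 df **without** continuity correction (Yates available by
flag).  Zero marginal rows/columns leave the statistic undefined and raise
with a diagnostic.

## Spectral features

Power spectra are plain FFTs of the demeaned segment (no taper by default;
Hann by flag), one-sided, normalized so the bin powers sum to the segment
variance — Parseval holds to machine precision, and only relative
comparisons are used downstream.  Segments must be ≥ 1 s (coarser
resolution leaves the delta band with too few bins).

Bands are half-open `(low, high]`: delta (0,4], theta (4,8], alpha (8,14],
beta (14,30], gamma (30,100].  The *whole* band is defined as (0,100] so
that the five sub-band totals partition it exactly; frequencies above
100 Hz are excluded throughout to avoid high-frequency artifact.  Median
frequency is computed on the discrete cumulative sum without interpolation
and reported at bin centers, so it is quantized to the resolution
`sampling_rate / n_samples`.  Band powers are not normalized by band width
or total power (a normalization flag exists but relative group contrasts
are unaffected).

Analysis segments: stimulated animals contribute the first afterdischarge
after the test stimulus (capacitor-trimmed); sham animals contribute the
whole record from exactly 30 s onward ("after ~30 s" implemented as exactly
30 s).  A stimulated animal without a first AD is a *missing value*
propagated to the group comparison (dropped with a reported count), not an
error; a group left with < 2 values skips the comparison with a
diagnostic.

## Neuroethology (sequential behavior analysis)

Behavior is coded one glossary code per second; *bouts* are maximal runs of
one code, so self-transitions cannot occur and flowcharts have no
self-loops.  Per period, each code gets frequency (bout count), mean bout
duration, and proportional time; pooled (multi-animal) summaries add counts
and durations without letting transitions cross animal boundaries.

For each ordered pair (A, B), all bout transitions are cross-classified as
{A→B, A→¬B, ¬A→B, ¬A→¬B}; the Pearson χ² on that table (expected from the
marginals) measures the association between "leaves A" and "enters B".  A
dyad is significant when **χ² ≥ 3.84** (the 95th percentile of χ²(1)),
**log₁₀χ² ≥ 0.25**, and observed > expected — the attraction condition,
so only facilitating couplings draw flowchart arrows.  Notes:

* The log threshold's base and argument are conventions; log₁₀ of χ² is
  assumed.  With that reading χ² ≥ 3.84 already implies log₁₀χ² ≥ 0.58, so
  the second criterion never binds; both are still checked independently.
* No multiple-testing correction across dyads by default (the fixed
  per-dyad threshold is the procedure); a Bonferroni flag raises the χ²
  cutoff to the adjusted quantile.
* The 2×2-from-margins construction ignores that self-transitions are
  structurally impossible, which inflates the statistic on very small code
  alphabets (measured: ~23 % null flag rate with 4 equiprobable codes).
  At ethogram-realistic alphabets (8+ codes) the null flag rate is ~7 %,
  within the nominal regime; the permutation- and null-rate tests therefore
  run at 8 codes.  Users comparing tiny alphabets should prefer the
  Bonferroni flag.
* A dyad whose 2×2 table has a zero margin (e.g. only 2 bouts) is reported
  with χ² = NaN and significant = False.

**Flowcharts.**  Nodes are behaviors (height ∝ frequency, base ∝ mean bout
duration, linearly scaled per period and clamped to [0.3, 3.0] drawing
units; color = behavioral category from a shipped, overridable YAML map:
exploratory / grooming / limbic / fear-aversion / procursive / other).
Edges are significant dyads (width ∝ χ², color = source category).  One
cell per period in PRE → STIMULUS → POST order.  Export: canonical DOT and
JSON round-trip losslessly (parse → rebuild → identical canonical text);
SVG (matplotlib, fixed hash salt for byte-determinism) is rendering-only.
A JSON schema ships with the package and a structural validator enforces it.

## Synthetic data

The generator is phenomenological — it produces data with the statistical
structure the analyses assume, not a biophysical model of kindling.

* **Protocol constants** (defaults): 21 stimuli (20 acquisition + 1 test),
  10 s stimulus at 60 Hz, 30 min inter-stimulus interval, 5 min PRE/POST
  windows (PRE shortened to 20 s at the test stimulus), 2000 Hz sampling,
  channels PC/HIP/AMYG.
* **Background EEG**: Gaussian noise shaped to 1/f (exponent 1) and
  band-limited to 0.1–1000 Hz, matching the recording high-/low-pass
  filters; default SD 1.0 arbitrary unit (detection is ratio-based, so the
  scale is immaterial).  The stimulus artifact is a 60 Hz biphasic square
  train at 8 SD over the stimulus window.
* **Afterdischarges**: jittered spike trains (default 5 spikes/s, mid-range
  of plausible 2–8 /s) convolved with a biphasic kernel (Gaussian
  derivative, 50 ms width within the 30–80 ms range), scaled so the burst's
  own core envelope equals the requested multiple of the background
  envelope.  No published parameterization of AD morphology exists; these
  are generator defaults, exposed in the API.  Planted events must lie in
  the post-stimulus window and be disjoint per channel; ground truth is
  returned verbatim with onset-ordered numbering.
* **Ethograms**: first-order Markov chains over bouts with geometric
  (memoryless) dwell times, mean 3 s by default; clusters (e.g. the
  grooming chain GRF→GRH→GRL) are injected by raising specific transition
  probabilities.  Alternative dwell laws are pluggable.
* **Severity**: stimulated groups follow a sigmoid mean LI over the
  acquisition stimuli (plateau 4.5, midpoint stimulus 10, slope 0.35 —
  reproducing the canonical rise from near-0 to class ~4 by stimulus 20),
  with unit-SD Gaussian jitter, rounded and clipped to 0–8; the POST window
  scores 80 % of the STIMULUS mean, PRE scores 0.  The odor-treated
  stimulated group has mean LI *and* AD-presence probability multiplied by
  the suppression factor (default 0.1) at the test stimulus only.  Sham
  groups score 0 and receive no planted events.  AD presence rises from
  ~0.61 (stimulus 1) to ~0.95 (test) per channel.
* **Seeding**: one global seed expands into per-(group, animal, channel,
  stimulus) substreams via `numpy.random.SeedSequence` spawn keys (strings
  folded by CRC-32), so identical (config, seed) reproduce identical bytes
  and any single record can be re-materialized lazily and consistently.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no electrode artifacts other than the stimulus
train and capacitor sag, no non-stationary background (drowsiness, movement),
no spike-wave morphology evolution across kindling, no correlation between
channels (each is an independent noise stream), no behavioral lateralization
or circadian structure, and severity jitter independent across stimuli.
Parameter-recovery results (detector sensitivity ≥ 0.95, ≤ 0.05 false
events/record) certify the *implementation* under the stated noise model,
not detector performance on recordings with different artifact content.

## Problem sizes used in the test suite

Validation simulations are sized for a single-CPU run: detector recovery
uses 100 seeds with 60 s post-stimulus windows; dyad null/power studies use
100 seeds of 300 s sequences; the end-to-end suppression study uses 50
seeds of n = 10/group cohorts on a single-channel (HIP) protocol — channels
are independent in the generator, so one channel carries the full
per-structure analysis.  All stimulation and analysis constants stay at
their defaults in these runs.

## Known limitations

* EDF files are read (via `mne`) but not written; the EEG interchange
  format is CSV with a JSON sidecar for the stimulus window.
* The Friedman p-value is asymptotic; for very small designs use the exact
  permutation distribution externally.
* The dyad χ² inherits the structural-zero bias described above on tiny
  code alphabets.
* `trim_capacitor_artifact` assumes the sag is a *leading* mean shift; sag
  recurring mid-discharge is not trimmed.
* Occurrence χ² requires non-degenerate margins; fully concordant
  presence/absence patterns are reported as undefined rather than forced.
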