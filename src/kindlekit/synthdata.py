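"""Synthetic cohorts: EEG with planted afterdischarges, ethograms, severity.

No raw recordings from kindling experiments of this design are publicly
deposited, so every downstream module is exercised on fully labelled
synthetic data that carries the statistical structure the analyses assume:

* **EEG** — 1/f-shaped Gaussian background band-limited to the recording
  filters (0.1-1000 Hz), a 60 Hz biphasic artifact over the 10 s stimulus
  window, and planted polyspike afterdischarges (spike trains convolved with
  a biphasic kernel) whose envelope is calibrated to a requested multiple of
  the background envelope.  Ground truth (onset/offset/ratio per event) is
  returned verbatim, which makes detector parameter-recovery studies exact.
* **Behavior** — second-by-second ethogram codes realized as a first-order
  Markov chain over bouts with geometric (memoryless) dwell times;
  behavioral clusters (e.g. a grooming chain GRF->GRH->GRL) are injected by
  raising specific transition probabilities.
* **Severity** — per-animal limbic-index progressions over the 21-stimulus
  rapid-kindling protocol (20 acquisition stimuli + 1 test stimulus), with a
  sigmoid-increasing group mean for stimulated animals and a multiplicative
  treatment-suppression effect at the test stimulus for the odor-exposed
  stimulated group.

The generator is phenomenological, not a biophysical neural-mass model.
One global seed expands into per-animal/-stimulus/-channel substreams
through a counter-based `SeedSequence` scheme, so identical (config, seed)
pairs reproduce identical bytes and partial regeneration (one animal's EEG
on demand) stays consistent with the full cohort.
"""

from __future__ import annotations

import json
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eeg_events import ENVELOPE_WINDOW_S, EEGRecording, envelope
from .neuroethology import BehaviorSequence
from .severity import GROUPS, SeverityRecord

__all__ = [
    "ProtocolConfig",
    "ADGroundTruth",
    "NoiseSpec",
    "CohortBundle",
    "substream",
    "generate_eeg",
    "make_tone_burst_recording",
    "generate_behavior_sequence",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Constants of the rapid-kindling protocol (defaults = study protocol)."""

    n_stimuli: int = 21  # 20 acquisition + 1 test stimulus
    stimulus_duration_s: float = 10.0
    inter_stimulus_min: float = 30.0
    pre_window_s: float = 300.0
    pre_window_test_s: float = 20.0  # shortened PRE at the test stimulus
    post_window_s: float = 300.0
    sampling_rate_hz: float = 2000.0
    stim_frequency_hz: float = 60.0
    channels: tuple[str, ...] = ("PC", "HIP", "AMYG")

    def __post_init__(self) -> None:
        for name in (
            "stimulus_duration_s", "pre_window_s", "pre_window_test_s",
            "post_window_s", "inter_stimulus_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampling_rate_hz < 200.0:
            raise ValueError(
                "sampling rate must be at least twice the highest analyzed "
                "frequency (100 Hz)"
            )
        if self.n_stimuli < 1:
            raise ValueError("protocol needs at least one stimulus")

    def pre_window_for(self, stimulus_index: int) -> float:
        return (
            self.pre_window_test_s
            if stimulus_index == self.n_stimuli and self.n_stimuli > 1
            else self.pre_window_s
        )


@dataclass(frozen=True)
class ADGroundTruth:
    """Planted afterdischarge: where it is and how big (relative to background)."""

    channel: str
    order: int
    onset_s: float
    offset_s: float
    amplitude_ratio: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("ground-truth offset must exceed onset")
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude ratio must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise model: 1/f-shaped Gaussian within the recording band."""

    background_sd: float = 1.0
    one_over_f_exponent: float = 1.0
    low_cut_hz: float = 0.1    # recording high-pass
    high_cut_hz: float = 1000.0  # recording low-pass


def substream(seed: int, *key: int | str) -> np.random.Generator:
    """Deterministic child RNG for a (seed, key...) pair.

    String key parts are folded to integers with CRC-32 so channel names and
    group labels can key substreams stably across runs.
    """
    parts = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=parts))


def _one_over_f_noise(n: int, fs: float, spec: NoiseSpec, rng: np.random.Generator
                      ) -> np.ndarray:
    """Gaussian noise with 1/f^a spectrum band-limited to the recording filters."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    band = (freqs >= spec.low_cut_hz) & (freqs <= spec.high_cut_hz)
    gain[band] = freqs[band] ** (-spec.one_over_f_exponent / 2.0)
    x = np.fft.irfft(spectrum * gain, n=n)
    sd = x.std()
    if sd > 0:
        x *= spec.background_sd / sd
    return x


def _polyspike_burst(
    duration_s: float, fs: float, rng: np.random.Generator,
    spike_rate_hz: float = 5.0, spike_width_s: float = 0.05,
) -> np.ndarray:
    """Unit-scale polyspike burst: jittered spike train * biphasic kernel.

    Default spike rate 5 /s and width 50 ms sit mid-range of the 2-8 /s and
    30-80 ms morphology bounds; no published parameterization exists, so
    these are generator defaults, exposed here.
    """
    n = int(round(duration_s * fs))
    train = np.zeros(n)
    period = 1.0 / spike_rate_hz
    t = 2.0 * spike_width_s  # discharge starts at event onset
    while t < duration_s:
        jittered = t + rng.uniform(-0.1, 0.1) * period
        i = int(jittered * fs)
        if 0 <= i < n:
            train[i] = rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        t += period
    # biphasic kernel: first derivative of a Gaussian
    half = int(round(3 * spike_width_s * fs))
    tt = np.arange(-half, half + 1) / fs
    sigma = spike_width_s / 2.0
    kernel = -tt / sigma**2 * np.exp(-(tt**2) / (2 * sigma**2))
    kernel /= np.abs(kernel).max()
    return np.convolve(train, kernel, mode="same")


def generate_eeg(
    protocol: ProtocolConfig,
    ad_spec: Sequence[ADGroundTruth],
    noise_spec: NoiseSpec | None = None,
    seed: int = 0,
    *,
    stimulus_index: int = 1,
    stimulate: bool = True,
    artifact_amplitude_sd: float = 8.0,
) -> tuple[EEGRecording, list[ADGroundTruth]]:
    """Generate one multi-channel record around one stimulus.

    Layout: PRE window, stimulus window (60 Hz artifact when ``stimulate``),
    POST window.  Ground-truth events must lie in the post-stimulus window
    and be disjoint per channel; their onsets/offsets are absolute record
    times.  The returned ground truth is the validated input, orders
    renumbered by onset per channel.  Identical arguments and seed give
    bit-identical output.
    """
    noise_spec = noise_spec or NoiseSpec()
    fs = protocol.sampling_rate_hz
    pre = protocol.pre_window_for(stimulus_index)
    stim_on = pre
    stim_off = pre + protocol.stimulus_duration_s
    total_s = pre + protocol.stimulus_duration_s + protocol.post_window_s
    n = int(round(total_s * fs))

    by_channel: dict[str, list[ADGroundTruth]] = {c: [] for c in protocol.channels}
    for ev in ad_spec:
        if ev.channel not in by_channel:
            raise ValueError(f"ground-truth channel {ev.channel!r} not in protocol channels")
        if ev.onset_s < stim_off or ev.offset_s > total_s:
            raise ValueError(
                f"event [{ev.onset_s}, {ev.offset_s}) s outside the post-stimulus "
                f"window [{stim_off}, {total_s}) s"
            )
        by_channel[ev.channel].append(ev)
    truth: list[ADGroundTruth] = []
    for channel, events in by_channel.items():
        events.sort(key=lambda e: e.onset_s)
        for prev, nxt in zip(events, events[1:]):
            if nxt.onset_s < prev.offset_s:
                raise ValueError(
                    f"planted events overlap on channel {channel}: "
                    f"[{prev.onset_s}, {prev.offset_s}) and [{nxt.onset_s}, {nxt.offset_s})"
                )
        truth.extend(replace(ev, order=k) for k, ev in enumerate(events, start=1))

    samples = np.empty((len(protocol.channels), n))
    for ci, channel in enumerate(protocol.channels):
        rng = substream(seed, stimulus_index, channel)
        x = _one_over_f_noise(n, fs, noise_spec, rng)
        background_env = float(np.median(envelope(x[: int(stim_on * fs)], fs)))
        if stimulate:
            ts = np.arange(int(stim_on * fs), int(stim_off * fs))
            square = np.sign(np.sin(2 * np.pi * protocol.stim_frequency_hz * ts / fs))
            x[ts] += artifact_amplitude_sd * noise_spec.background_sd * square
        for ev in by_channel[channel]:
            i0, i1 = int(round(ev.onset_s * fs)), int(round(ev.offset_s * fs))
            burst = _polyspike_burst(ev.offset_s - ev.onset_s, fs, rng)[: i1 - i0]
            burst_env = envelope(burst, fs)
            core = slice(
                int(ENVELOPE_WINDOW_S * fs), max(1, burst.size - int(ENVELOPE_WINDOW_S * fs))
            )
            med = float(np.median(burst_env[core]))
            if med > 0 and background_env > 0:
                burst *= ev.amplitude_ratio * background_env / med
            x[i0 : i0 + burst.size] += burst
        samples[ci] = x

    recording = EEGRecording(
        channel_labels=protocol.channels,
        sampling_rate_hz=fs,
        samples=samples,
        stimulus_onset_s=stim_on,
        stimulus_offset_s=stim_off,
    )
    truth.sort(key=lambda e: (e.channel, e.onset_s))
    return recording, truth


def generate_behavior_sequence(
    codes: Sequence[str],
    transition_matrix: np.ndarray,
    dwell_mean_s: Mapping[str, float] | float,
    duration_s: int,
    seed: int = 0,
    *,
    animal_id: str = "a0",
    stimulus_index: int = 1,
    period: str = "PRE",
) -> BehaviorSequence:
    """One code per second from a bout-level Markov chain.

    ``transition_matrix[i, j]`` is P(next bout = codes[j] | current bout =
    codes[i]); rows must sum to 1.  Bout dwell times are geometric with the
    given per-code (or shared scalar) means, all >= 1 s.  A single-code
    profile yields a constant sequence.
    """
    matrix = np.asarray(transition_matrix, dtype=float)
    k = len(codes)
    if matrix.shape != (k, k):
        raise ValueError(f"transition matrix shape {matrix.shape} does not match {k} codes")
    if (matrix < 0).any() or not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    means = (
        {c: float(dwell_mean_s) for c in codes}
        if np.isscalar(dwell_mean_s)
        else {c: float(dwell_mean_s[c]) for c in codes}
    )
    if any(m < 1.0 for m in means.values()):
        raise ValueError("dwell-time means must be >= 1 s (1 s coding resolution)")
    if duration_s < 1:
        raise ValueError("duration must be at least 1 s")

    rng = substream(seed, stimulus_index, period, animal_id)
    state = int(rng.integers(k))
    seconds: list[str] = []
    while len(seconds) < duration_s:
        code = codes[state]
        dwell = int(rng.geometric(1.0 / means[code]))
        seconds.extend([code] * dwell)
        if k > 1:
            state = int(rng.choice(k, p=matrix[state]))
    return BehaviorSequence.from_codes(
        seconds[:duration_s], animal_id=animal_id,
        stimulus_index=stimulus_index, period=period,
    )


def make_tone_burst_recording(
    burst_ratio: float,
    burst_duration_s: float,
    *,
    sampling_rate_hz: float = 2000.0,
    tone_hz: float = 10.0,
    pre_s: float = 30.0,
    stimulus_s: float = 10.0,
    post_s: float = 60.0,
    burst_start_after_stimulus_s: float = 5.0,
    channel: str = "HIP",
) -> EEGRecording:
    """Deterministic single-channel calibration record: tone + amplified burst.

    A steady sinusoid provides the background (its rectified 200 ms-averaged
    envelope is 2/pi times the amplitude, constant when the window spans
    whole half-cycles); during the burst window the amplitude is multiplied
    by ``burst_ratio``, so the burst envelope is exactly ``burst_ratio``
    times background.  Noiseless, hence exact: used to map the detector's
    acceptance boundaries in amplitude ratio and duration.
    """
    fs = sampling_rate_hz
    total_s = pre_s + stimulus_s + post_s
    t = np.arange(int(round(total_s * fs))) / fs
    x = np.sin(2 * np.pi * tone_hz * t)
    b0 = pre_s + stimulus_s + burst_start_after_stimulus_s
    in_burst = (t >= b0) & (t < b0 + burst_duration_s)
    x[in_burst] *= burst_ratio
    return EEGRecording(
        channel_labels=(channel,),
        sampling_rate_hz=fs,
        samples=x[np.newaxis, :],
        stimulus_onset_s=pre_s,
        stimulus_offset_s=pre_s + stimulus_s,
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class GroupEffects:
    """Kindling progression and treatment effect of the simulated study.

    ``kindling_slope`` shapes the sigmoid rise of mean severity over the 20
    acquisition stimuli; ``tmt_suppression`` multiplies both mean severity
    and afterdischarge-presence probability of the odor-exposed stimulated
    group at the test stimulus only (1.0 = no effect, 0.0 = full
    suppression).
    """

    kindling_slope: float = 0.35
    tmt_suppression: float = 0.1
    max_mean_li: float = 4.5
    midpoint_stimulus: float = 10.0
    ad_presence_floor: float = 0.6
    ad_presence_gain: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.tmt_suppression <= 1.0:
            raise ValueError("suppression factor must lie in [0, 1]")

    def mean_li(self, stimulus_index: int) -> float:
        return self.max_mean_li / (
            1.0 + np.exp(-self.kindling_slope * (stimulus_index - self.midpoint_stimulus))
        )

    def ad_presence_p(self, stimulus_index: int) -> float:
        return self.ad_presence_floor + self.ad_presence_gain / (
            1.0 + np.exp(-self.kindling_slope * (stimulus_index - self.midpoint_stimulus))
        )


#: Default per-period behavior profiles: codes, transition structure, dwells.
_BEHAVIOR_CODES = ("IM", "SN", "WA", "SC", "ER", "GRF", "GRH", "GRL")


def _default_transition_matrix(k: int, rng: np.random.Generator | None = None
                               ) -> np.ndarray:
    """Near-uniform off-diagonal transitions with a grooming chain raised."""
    matrix = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(matrix, 0.0)
    codes = _BEHAVIOR_CODES
    # grooming cluster: GRF -> GRH -> GRL chain
    for a, b in (("GRF", "GRH"), ("GRH", "GRL")):
        i, j = codes.index(a), codes.index(b)
        matrix[i] *= 0.4
        matrix[i, j] += 0.6
        matrix[i] /= matrix[i].sum()
    return matrix


@dataclass
class CohortBundle:
    """A generated cohort; EEG records materialize lazily and reproducibly."""

    protocol: ProtocolConfig
    effects: GroupEffects
    noise: NoiseSpec
    n_per_group: int
    seed: int
    severity_records: list[SeverityRecord]
    behavior: dict[tuple[str, str, int, str], BehaviorSequence]
    ad_truth: dict[tuple[str, str, int], list[ADGroundTruth]]
    eeg_stimuli: tuple[int, ...]

    def animals(self, group: str) -> list[str]:
        return [f"{group}-{i:02d}" for i in range(self.n_per_group)]

    def eeg(self, group: str, animal_id: str, stimulus_index: int
            ) -> tuple[EEGRecording, list[ADGroundTruth]]:
        """Materialize one animal's record around one stimulus (deterministic)."""
        truth = self.ad_truth.get((group, animal_id, stimulus_index), [])
        return generate_eeg(
            self.protocol,
            truth,
            self.noise,
            seed=int(substream(self.seed, group, animal_id).integers(2**31)),
            stimulus_index=stimulus_index,
            stimulate=group.startswith("Stim"),
        )


def _sample_ad_events(
    protocol: ProtocolConfig, presence_p: float, rng: np.random.Generator
) -> list[ADGroundTruth]:
    """Per-channel planted first (and possibly second) afterdischarges."""
    stim_off = protocol.pre_window_s + protocol.stimulus_duration_s
    events: list[ADGroundTruth] = []
    for channel in protocol.channels:
        if rng.uniform() >= presence_p:
            continue
        onset = stim_off + rng.uniform(1.0, 3.0)
        duration = rng.uniform(4.0, 8.0)
        events.append(
            ADGroundTruth(
                channel=channel, order=1, onset_s=onset,
                offset_s=onset + duration,
                amplitude_ratio=rng.uniform(3.0, 4.0),
            )
        )
        if rng.uniform() < 0.6:
            onset2 = onset + duration + rng.uniform(2.0, 5.0)
            duration2 = rng.uniform(3.0, 6.0)
            events.append(
                ADGroundTruth(
                    channel=channel, order=2, onset_s=onset2,
                    offset_s=onset2 + duration2,
                    amplitude_ratio=rng.uniform(2.5, 3.5),
                )
            )
    return events


def generate_cohort(
    protocol: ProtocolConfig | None = None,
    effects: GroupEffects | None = None,
    n_per_group: int = 8,
    seed: int = 0,
    *,
    noise: NoiseSpec | None = None,
    eeg_stimuli: tuple[int, ...] = (1, 21),
    behavior_stimuli: tuple[int, ...] = (1, 21),
    groups: tuple[str, ...] = GROUPS,
) -> CohortBundle:
    """Generate the four-group study: severity, behavior, and AD ground truth.

    Stimulated groups follow a sigmoid-increasing mean severity over the
    acquisition stimuli; the odor-exposed stimulated group has severity and
    afterdischarge-presence probability multiplied by the suppression factor
    at the test stimulus only.  Sham (NoStim) groups carry severity 0 and no
    planted events.  ``eeg_stimuli`` / ``behavior_stimuli`` restrict which
    stimuli get ground-truth events and ethograms (a problem-size control;
    severity is always generated for the full protocol).
    """
    protocol = protocol or ProtocolConfig()
    effects = effects or GroupEffects()
    noise = noise or NoiseSpec()
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}; expected subset of {GROUPS}")

    test_stim = protocol.n_stimuli
    severity: list[SeverityRecord] = []
    behavior: dict[tuple[str, str, int, str], BehaviorSequence] = {}
    ad_truth: dict[tuple[str, str, int], list[ADGroundTruth]] = {}
    matrix = _default_transition_matrix(len(_BEHAVIOR_CODES))

    for group in groups:
        stimulated = group.startswith("Stim")
        treated = group.endswith("TMT")
        for a in range(n_per_group):
            animal = f"{group}-{a:02d}"
            rng = substream(seed, group, a, "severity")
            for s in range(1, protocol.n_stimuli + 1):
                mu = effects.mean_li(s) if stimulated else 0.0
                if stimulated and treated and s == test_stim:
                    mu *= effects.tmt_suppression
                for period, factor in (("PRE", 0.0), ("STIMULUS", 1.0), ("POST", 0.8)):
                    if factor == 0.0 or mu == 0.0:
                        li = 0
                    else:
                        li = int(np.clip(round(factor * mu + rng.normal(0.0, 1.0)), 0, 8))
                    severity.append(
                        SeverityRecord(
                            animal_id=animal, group=group, stimulus_index=s,
                            period=period, li_class=li,
                        )
                    )
            for s in behavior_stimuli:
                for period, dur in (
                    ("PRE", int(protocol.pre_window_for(s))),
                    ("STIMULUS", int(protocol.stimulus_duration_s)),
                    ("POST", int(protocol.post_window_s)),
                ):
                    behavior[(group, animal, s, period)] = generate_behavior_sequence(
                        _BEHAVIOR_CODES, matrix, 3.0, dur,
                        seed=int(substream(seed, group, a, "behavior").integers(2**31)),
                        animal_id=animal, stimulus_index=s, period=period,
                    )
            if stimulated:
                for s in eeg_stimuli:
                    p = effects.ad_presence_p(s)
                    if treated and s == test_stim:
                        p *= effects.tmt_suppression
                    ad_truth[(group, animal, s)] = _sample_ad_events(
                        protocol, p, substream(seed, group, a, "ad", s)
                    )

    return CohortBundle(
        protocol=protocol, effects=effects, noise=noise,
        n_per_group=n_per_group, seed=seed,
        severity_records=severity, behavior=behavior,
        ad_truth=ad_truth, eeg_stimuli=tuple(eeg_stimuli),
    )


# ---------------------------------------------------------------------------
# On-disk layout


def write_behavior_csv(
    sequences: Mapping[tuple[str, str, int, str], BehaviorSequence], path: str | Path
) -> None:
    rows = []
    for (group, animal, stimulus, period), seq in sorted(sequences.items()):
        for t, code in seq.events:
            rows.append(
                {
                    "animal_id": animal, "group": group, "stimulus_index": stimulus,
                    "period": period, "t_s": t, "code": code,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_behavior_csv(path: str | Path) -> dict[tuple[str, str, int, str], BehaviorSequence]:
    frame = pd.read_csv(path, dtype={"animal_id": str})
    out: dict[tuple[str, str, int, str], BehaviorSequence] = {}
    keys = ["group", "animal_id", "stimulus_index", "period"]
    for (group, animal, stimulus, period), sub in frame.groupby(keys, sort=True):
        sub = sub.sort_values("t_s")
        out[(group, animal, int(stimulus), period)] = BehaviorSequence(
            animal_id=animal, stimulus_index=int(stimulus), period=period,
            events=tuple(zip(sub["t_s"].astype(int), sub["code"].astype(str))),
        )
    return out


def write_cohort(bundle: CohortBundle, out_dir: str | Path, *, write_eeg: bool = False
                 ) -> Path:
    """Write severity/behavior CSVs, ground-truth JSON, and a manifest YAML."""
    from .severity import write_severity_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_severity_csv(bundle.severity_records, out / "severity.csv")
    write_behavior_csv(bundle.behavior, out / "behavior.csv")
    truth_payload = {
        f"{g}/{a}/{s}": [vars(ev) for ev in events]
        for (g, a, s), events in sorted(bundle.ad_truth.items())
    }
    (out / "ad_ground_truth.json").write_text(
        json.dumps(truth_payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    if write_eeg:
        from .io import write_eeg_csv

        eeg_dir = out / "eeg"
        eeg_dir.mkdir(exist_ok=True)
        for (group, animal, stimulus) in sorted(bundle.ad_truth):
            rec, _ = bundle.eeg(group, animal, stimulus)
            write_eeg_csv(rec, eeg_dir / f"{animal}_stim{stimulus:02d}.csv")
    manifest = {
        "seed": bundle.seed,
        "n_per_group": bundle.n_per_group,
        "eeg_stimuli": list(bundle.eeg_stimuli),
        "protocol": {
            "n_stimuli": bundle.protocol.n_stimuli,
            "stimulus_duration_s": bundle.protocol.stimulus_duration_s,
            "pre_window_s": bundle.protocol.pre_window_s,
            "pre_window_test_s": bundle.protocol.pre_window_test_s,
            "post_window_s": bundle.protocol.post_window_s,
            "sampling_rate_hz": bundle.protocol.sampling_rate_hz,
            "stim_frequency_hz": bundle.protocol.stim_frequency_hz,
            "channels": list(bundle.protocol.channels),
        },
        "effects": vars(bundle.effects),
        "noise": vars(bundle.noise),
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
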