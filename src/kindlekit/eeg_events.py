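"""Afterdischarge detection and occurrence statistics.

An afterdischarge (AD) is self-sustained epileptiform EEG activity that
outlasts the electrical stimulus.  The operational rule is amplitude- and
duration-based: an electrographic seizure is a stretch of signal whose
amplitude is at least twice the pre-stimulus background and which lasts at
least 3 s.  "Amplitude" is operationalized as the envelope — the rectified
signal smoothed with a 200 ms moving average — and the background scale is
the *median* of the baseline envelope (robust to baseline spikes).

Detection scans the envelope from stimulus offset to the end of the
post-stimulus window, keeps contiguous supra-threshold regions, merges
regions separated by gaps up to ``merge_gap_s`` (successive polyspike
bursts of one discharge), discards regions shorter than the minimum
duration, and numbers the survivors by onset; the first and second events
per channel are the ones entering the occurrence analysis.  Detection is by
construction invariant to global rescaling of the signal (the threshold is
a ratio).

Occurrence statistics: per channel, a 2x2 presence/absence table comparing
the 1st and 21st stimulus over one group's animals, tested with an
uncorrected Pearson chi-square on 1 degree of freedom (Yates correction
available by flag).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

__all__ = [
    "EEGRecording",
    "AfterdischargeEvent",
    "DetectorParams",
    "OccurrenceTable",
    "envelope",
    "estimate_background",
    "trim_capacitor_artifact",
    "detect_afterdischarges",
    "occurrence_chi2",
]

#: Envelope smoothing window (s); single definition shared by detector and
#: synthetic-data calibration.
ENVELOPE_WINDOW_S = 0.2


@dataclass
class EEGRecording:
    """Multi-channel EEG around one electrical stimulus.

    ``samples`` is channels x time; the stimulus window [onset, offset) lies
    inside the record.  Time is seconds from record start, 0-based.
    """

    channel_labels: tuple[str, ...]
    sampling_rate_hz: float
    samples: np.ndarray
    stimulus_onset_s: float
    stimulus_offset_s: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows for "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0 <= self.stimulus_onset_s < self.stimulus_offset_s <= self.duration_s:
            raise ValueError("stimulus window must lie inside the record")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording (has {self.channel_labels})"
            ) from None
        return self.samples[idx]


@dataclass(frozen=True)
class AfterdischargeEvent:
    """One detected afterdischarge on one channel."""

    channel: str
    order: int  # 1-based onset order; 1 and 2 are the analyzed events
    onset_s: float
    offset_s: float
    peak_ratio: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("event offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class DetectorParams:
    """Detection thresholds; defaults are the published rule (2x, >=3 s)."""

    amplitude_ratio_min: float = 2.0
    min_duration_s: float = 3.0
    merge_gap_s: float = 0.5


def envelope(signal: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Rectified signal smoothed with a 200 ms moving average."""
    width = max(1, int(round(ENVELOPE_WINDOW_S * sampling_rate_hz)))
    return uniform_filter1d(np.abs(np.asarray(signal, dtype=float)), width, mode="nearest")


def estimate_background(
    recording: EEGRecording, channel: str, baseline_window_s: float | None = None
) -> float:
    """Robust background amplitude: median of the pre-stimulus envelope.

    The baseline window is the ``baseline_window_s`` seconds immediately
    preceding stimulus onset (whole pre-stimulus stretch when omitted) and
    must contain at least 5 s of data.
    """
    x = recording.channel(channel)
    fs = recording.sampling_rate_hz
    end = int(round(recording.stimulus_onset_s * fs))
    if baseline_window_s is None:
        start = 0
    else:
        start = end - int(round(baseline_window_s * fs))
        if start < 0:
            raise ValueError("baseline window extends before the record start")
    if (end - start) / fs < 5.0:
        raise ValueError(
            f"baseline window of {(end - start) / fs:.2f} s is shorter than the 5 s minimum"
        )
    return float(np.median(envelope(x[start:end], fs)))


def trim_capacitor_artifact(
    segment: np.ndarray,
    sampling_rate_hz: float,
    baseline_mean: float,
    baseline_sd: float,
    *,
    mean_window_s: float = 0.1,
    max_trim_fraction: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Remove the leading capacitor-discharge sag from an AD segment.

    Stimulus isolation capacitors discharge into the electrode after the
    stimulus, dragging the signal mean below the basal level at the start of
    the first afterdischarge.  Leading samples are chopped off until the
    100 ms running mean returns to within ``baseline_mean ± 2·baseline_sd``;
    never more than half the segment is removed (hard cap).

    Returns ``(trimmed, all_sag)``; ``all_sag`` flags a segment whose mean
    never recovers (the trimmed output is then empty, not an error).
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("cannot trim an empty segment")
    width = max(1, int(round(mean_window_s * sampling_rate_hz)))
    running_mean = uniform_filter1d(x, width, mode="nearest")
    ok = np.abs(running_mean - baseline_mean) <= 2.0 * baseline_sd
    recovered = np.flatnonzero(ok)
    if recovered.size == 0:
        return x[:0], True
    cut = int(recovered[0])
    cap = int(max_trim_fraction * x.size)
    cut = min(cut, cap)
    return x[cut:], False


def _supra_threshold_regions(
    above: np.ndarray, fs: float, merge_gap_s: float, min_duration_s: float
) -> list[tuple[int, int]]:
    """Half-open sample regions where ``above`` holds, gap-merged and filtered."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    regions = list(zip(starts.tolist(), ends.tolist()))
    merged: list[tuple[int, int]] = []
    gap_samples = merge_gap_s * fs
    for s, e in regions:
        if merged and s - merged[-1][1] <= gap_samples:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    # >= comparison with half-sample slack so a planted burst of exactly the
    # minimum duration is not lost to discretization of its envelope ramp
    min_samples = min_duration_s * fs - 0.5
    return [(s, e) for s, e in merged if e - s >= min_samples]


def detect_afterdischarges(
    recording: EEGRecording,
    channel: str,
    params: DetectorParams | None = None,
    *,
    baseline_window_s: float | None = None,
) -> list[AfterdischargeEvent]:
    """Detect afterdischarges on one channel after the stimulus.

    The search window runs from stimulus offset to the end of the record.
    Events spanning the record end are truncated and kept if the observed
    part satisfies both thresholds.  Survivors are numbered by onset;
    orders 1 and 2 are the analyzed first/second discharges.
    """
    params = params or DetectorParams()
    fs = recording.sampling_rate_hz
    background = estimate_background(recording, channel, baseline_window_s)
    if background <= 0:
        raise ValueError(
            f"background envelope on channel {channel} is zero; "
            "amplitude-ratio detection is undefined"
        )
    start = int(round(recording.stimulus_offset_s * fs))
    env = envelope(recording.channel(channel)[start:], fs)
    # relative 1e-9 slack: "at least k times background" is inclusive, and a
    # noiseless calibration burst at exactly the threshold must not be lost
    # to floating-point rounding
    above = env >= params.amplitude_ratio_min * background * (1.0 - 1e-9)
    regions = _supra_threshold_regions(above, fs, params.merge_gap_s, params.min_duration_s)
    events = []
    for order, (s, e) in enumerate(sorted(regions), start=1):
        events.append(
            AfterdischargeEvent(
                channel=channel,
                order=order,
                onset_s=(start + s) / fs,
                offset_s=(start + e) / fs,
                peak_ratio=float(env[s:e].max() / background),
            )
        )
    return events


@dataclass
class OccurrenceTable:
    """2x2 presence/absence counts of an AD, stimulus 1 vs 21, one channel."""

    channel: str
    present: dict[int, int] = field(default_factory=dict)  # stimulus -> count
    absent: dict[int, int] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        stimuli = sorted(set(self.present) | set(self.absent))
        return np.array(
            [[self.present.get(s, 0), self.absent.get(s, 0)] for s in stimuli],
            dtype=int,
        )


def occurrence_chi2(
    table: OccurrenceTable | np.ndarray, *, yates: bool = False
) -> dict[str, float]:
    """Pearson chi-square (df=1) on a 2x2 presence/absence table.

    No continuity correction by default; Yates correction by flag.  A zero
    marginal row or column leaves the statistic undefined and is an error.
    """
    arr = table.as_array() if isinstance(table, OccurrenceTable) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"occurrence table must be 2x2, got shape {arr.shape}")
    if (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("occurrence table needs non-negative counts and a positive total")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError(
            "a zero marginal makes the chi-square undefined "
            f"(row sums {arr.sum(axis=1).tolist()}, column sums {arr.sum(axis=0).tolist()})"
        )
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def occurrence_from_events(
    channel: str,
    events_by_stimulus: dict[int, Sequence[Sequence[AfterdischargeEvent]]],
    *,
    order: int = 1,
) -> OccurrenceTable:
    """Tabulate presence/absence of the order-``order`` AD per stimulus.

    ``events_by_stimulus`` maps stimulus index to the per-animal event lists
    of one group (one entry per stimulated animal, possibly empty).
    """
    table = OccurrenceTable(channel=channel)
    for stimulus, per_animal in events_by_stimulus.items():
        n_present = sum(
            any(ev.order == order and ev.channel == channel for ev in evs)
            for evs in per_animal
        )
        table.present[stimulus] = n_present
        table.absent[stimulus] = len(per_animal) - n_present
    return table
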