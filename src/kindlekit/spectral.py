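"""Band-wise FFT features of afterdischarge / basal EEG segments.

For every channel the analysis extracts four features from the one-sided
power spectrum of a segment — the first afterdischarge after the test
stimulus for stimulated animals, or the basal signal from 30 s onward for
sham animals — within each of the classical EEG bands:

    delta (0,4] Hz, theta (4,8], alpha (8,14], beta (14,30], gamma (30,100],
    and the whole band (0,100].

Band edges are half-open ``(low, high]`` so a bin at exactly 4 Hz belongs to
delta only and the five sub-bands partition the whole band without double
counting.  The features are

* ``total_power``    - summed bin power in the band,
* ``peak_power``     - largest single-bin power,
* ``frequency_at_peak_hz`` - that bin's frequency,
* ``median_frequency_hz``  - smallest frequency up to which at least half of
  the band's energy has accumulated (discrete cumulative sum, no
  interpolation, reported at bin centers).

Power is normalized so that the bins of the full one-sided spectrum sum to
the variance of the demeaned segment (Parseval); only relative comparisons
are ever used downstream, so the scale convention is documented rather than
consequential.  No taper is applied by default (plain FFT of the demeaned
segment); a Hann window is available by flag.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .severity import compare_groups

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "SpectralFeatureSet",
    "power_spectrum",
    "band_features",
    "select_analysis_segment",
    "compare_feature",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "median_frequency_hz",
    "total_power",
    "peak_power",
    "frequency_at_peak_hz",
)


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band (low, high] in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: need 0 <= low < high")

    def mask(self, frequencies: np.ndarray) -> np.ndarray:
        return (frequencies > self.low_hz) & (frequencies <= self.high_hz)


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
    BandDefinition("whole", 0.0, 100.0),
)


@dataclass(frozen=True)
class SpectralFeatureSet:
    band: BandDefinition
    median_frequency_hz: float
    total_power: float
    peak_power: float
    frequency_at_peak_hz: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def power_spectrum(
    segment: np.ndarray, sampling_rate_hz: float, window: str = "none"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a demeaned segment.

    Frequency resolution is ``sampling_rate / n_samples``.  Bin powers are
    scaled so their sum equals the (windowed) segment variance.  Segments
    shorter than 1 s are rejected: at coarser than 1 Hz resolution the delta
    band holds too few bins for its features to be defined.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    if x.size < sampling_rate_hz:
        raise ValueError(
            f"segment of {x.size / sampling_rate_hz:.3f} s is shorter than the "
            "1 s minimum required for band features"
        )
    x = x - x.mean()
    if window == "hann":
        taper = np.hanning(x.size)
        x = x * taper / np.sqrt(np.mean(taper**2))
    elif window != "none":
        raise ValueError(f"unknown window {window!r}; use 'none' or 'hann'")
    n = x.size
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum) ** 2 / n**2
    # one-sided: double every bin that has a negative-frequency twin
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is unique
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    return freqs, power


def band_features(
    frequencies: np.ndarray,
    power: np.ndarray,
    band: BandDefinition,
    *,
    allow_empty_energy: bool = False,
) -> SpectralFeatureSet:
    """Extract the four band features from a spectrum.

    A band with no bins is an error.  A band whose bins exist but carry zero
    total energy is an error unless ``allow_empty_energy``, in which case an
    all-NaN/zero feature set is returned (flagged by NaN median frequency).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = band.mask(frequencies)
    if np.count_nonzero(mask) < 2:
        raise ValueError(
            f"band {band.name} ({band.low_hz}, {band.high_hz}] Hz holds "
            f"{np.count_nonzero(mask)} bins; need >= 2 (increase segment length)"
        )
    f = frequencies[mask]
    p = power[mask]
    total = float(p.sum())
    if total <= 0:
        if allow_empty_energy:
            return SpectralFeatureSet(band, float("nan"), 0.0, 0.0, float("nan"))
        raise ValueError(f"band {band.name} carries no energy in this spectrum")
    peak_idx = int(np.argmax(p))
    cumulative = np.cumsum(p)
    median_idx = int(np.searchsorted(cumulative, 0.5 * total))
    return SpectralFeatureSet(
        band=band,
        median_frequency_hz=float(f[median_idx]),
        total_power=total,
        peak_power=float(p[peak_idx]),
        frequency_at_peak_hz=float(f[peak_idx]),
    )


def select_analysis_segment(
    samples: np.ndarray,
    sampling_rate_hz: float,
    group_kind: str,
    events: Sequence | None = None,
    *,
    basal_start_s: float = 30.0,
    trimmer=None,
) -> np.ndarray | None:
    """Pick the segment the spectral features are computed on.

    ``group_kind='stimulated'``: the samples of the first (order-1)
    afterdischarge in ``events``, optionally passed through ``trimmer`` (a
    callable removing the leading capacitor-discharge sag).  Returns ``None``
    — a recorded missing value, not an error — when no order-1 event exists.

    ``group_kind='sham'``: the whole signal from ``basal_start_s`` to the end
    of the record (the first ~30 s are discarded to establish a basal
    period); the record must outlast ``basal_start_s``.
    """
    x = np.asarray(samples, dtype=float)
    if group_kind == "sham":
        start = int(round(basal_start_s * sampling_rate_hz))
        if x.size <= start:
            raise ValueError(
                f"sham record of {x.size / sampling_rate_hz:.1f} s is shorter than "
                f"the {basal_start_s:.0f} s basal-period offset"
            )
        return x[start:]
    if group_kind != "stimulated":
        raise ValueError(f"group_kind must be 'stimulated' or 'sham', got {group_kind!r}")
    first = None
    for ev in events or ():
        if getattr(ev, "order", None) == 1:
            first = ev
            break
    if first is None:
        return None
    i0 = int(round(first.onset_s * sampling_rate_hz))
    i1 = int(round(first.offset_s * sampling_rate_hz))
    segment = x[i0:i1]
    if trimmer is not None:
        segment = trimmer(segment)
    return segment


def compare_feature(
    group_a: Sequence[float], group_b: Sequence[float]
) -> dict[str, float] | None:
    """Two-sided Mann-Whitney on one feature between two groups.

    Missing values (NaN/None) are dropped; the number dropped is reported.
    Returns ``None`` (comparison skipped) when fewer than two non-missing
    values remain in either group.
    """
    raw_a = [v for v in group_a]
    raw_b = [v for v in group_b]
    a = np.asarray([v for v in raw_a if v is not None], dtype=float)
    b = np.asarray([v for v in raw_b if v is not None], dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    n_missing = len(raw_a) + len(raw_b) - a.size - b.size
    if a.size < 2 or b.size < 2:
        return None
    out = compare_groups(a, b)
    out["n_a"] = int(a.size)
    out["n_b"] = int(b.size)
    out["n_missing"] = int(n_missing)
    return out
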