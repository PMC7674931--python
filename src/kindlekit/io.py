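"""Reading and writing EEG records and derived tables.

EEG interchange format is headered CSV (``time_s`` column plus one column
per channel); a JSON sidecar ``<stem>.meta.json`` carries the stimulus
window so a round trip needs no extra arguments.  EDF files are read
through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_events import AfterdischargeEvent, EEGRecording

__all__ = ["read_eeg", "write_eeg_csv", "write_events_csv", "read_events_csv"]

#: Highest frequency any analysis touches (upper edge of the gamma band).
MAX_ANALYZED_HZ = 100.0


def _check_nyquist(sampling_rate_hz: float, context: str) -> None:
    if sampling_rate_hz / 2.0 <= MAX_ANALYZED_HZ:
        raise ValueError(
            f"{context}: sampling rate {sampling_rate_hz} Hz cannot resolve the "
            f"{MAX_ANALYZED_HZ:.0f} Hz analysis band (Nyquist "
            f"{sampling_rate_hz / 2:.0f} Hz)"
        )
    if sampling_rate_hz < 2000.0:
        warnings.warn(
            f"{context}: sampling rate {sampling_rate_hz} Hz is below the nominal "
            f"2000 Hz; accepted — the {MAX_ANALYZED_HZ:.0f} Hz band upper bound "
            f"still lies below Nyquist ({sampling_rate_hz / 2:.0f} Hz)"
        )


def write_eeg_csv(recording: EEGRecording, path: str | Path) -> Path:
    """Write a record as CSV (time_s + one column per channel) + meta sidecar."""
    path = Path(path)
    n = recording.samples.shape[1]
    frame = pd.DataFrame({"time_s": np.arange(n) / recording.sampling_rate_hz})
    for label, row in zip(recording.channel_labels, recording.samples):
        frame[label.lower()] = row
    frame.to_csv(path, index=False, float_format="%.6g")
    meta = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channels": list(recording.channel_labels),
        "stimulus_onset_s": recording.stimulus_onset_s,
        "stimulus_offset_s": recording.stimulus_offset_s,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return path


def _read_eeg_csv(
    path: Path,
    required_channels: tuple[str, ...] | None,
    stimulus_onset_s: float | None,
    stimulus_offset_s: float | None,
) -> EEGRecording:
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: EEG CSV must carry a 'time_s' column (line 1)")
    channel_cols = [c for c in frame.columns if c != "time_s"]
    if not channel_cols:
        raise ValueError(f"{path}: EEG CSV has no channel columns")

    meta_path = path.with_suffix(".meta.json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))

    t = frame["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer the sampling rate")
    dt = np.median(np.diff(t))
    if dt <= 0 or not np.isfinite(dt):
        raise ValueError(f"{path}: unparseable sampling rate (non-increasing time_s)")
    fs = float(meta.get("sampling_rate_hz", 1.0 / dt))

    labels = tuple(meta.get("channels", [c.upper() for c in channel_cols]))
    if required_channels:
        have = {l.upper() for l in labels}
        missing = [c for c in required_channels if c.upper() not in have]
        if missing:
            raise ValueError(
                f"{path}: missing required channel(s) {missing}; file has {sorted(have)}"
            )
    onset = stimulus_onset_s if stimulus_onset_s is not None else meta.get("stimulus_onset_s")
    offset = (
        stimulus_offset_s if stimulus_offset_s is not None else meta.get("stimulus_offset_s")
    )
    if onset is None or offset is None:
        raise ValueError(
            f"{path}: stimulus window unknown — pass stimulus_onset_s/offset_s or "
            "provide the .meta.json sidecar"
        )
    _check_nyquist(fs, str(path))
    return EEGRecording(
        channel_labels=labels,
        sampling_rate_hz=fs,
        samples=frame[channel_cols].to_numpy(dtype=float).T,
        stimulus_onset_s=float(onset),
        stimulus_offset_s=float(offset),
    )


def _read_eeg_edf(
    path: Path,
    required_channels: tuple[str, ...] | None,
    stimulus_onset_s: float | None,
    stimulus_offset_s: float | None,
) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    if required_channels:
        have = {l.upper() for l in labels}
        missing = [c for c in required_channels if c.upper() not in have]
        if missing:
            raise ValueError(f"{path}: missing required channel(s) {missing}")
    if stimulus_onset_s is None or stimulus_offset_s is None:
        raise ValueError(f"{path}: stimulus window must be given for EDF input")
    fs = float(raw.info["sfreq"])
    _check_nyquist(fs, str(path))
    return EEGRecording(
        channel_labels=labels,
        sampling_rate_hz=fs,
        samples=raw.get_data(),
        stimulus_onset_s=stimulus_onset_s,
        stimulus_offset_s=stimulus_offset_s,
    )


def read_eeg(
    path: str | Path,
    format: str | None = None,
    *,
    required_channels: tuple[str, ...] | None = None,
    stimulus_onset_s: float | None = None,
    stimulus_offset_s: float | None = None,
) -> EEGRecording:
    """Read an EEG record from CSV or EDF (format inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "CSV":
        return _read_eeg_csv(path, required_channels, stimulus_onset_s, stimulus_offset_s)
    if fmt == "EDF":
        return _read_eeg_edf(path, required_channels, stimulus_onset_s, stimulus_offset_s)
    raise ValueError(f"unknown EEG format {fmt!r}; use CSV or EDF")


_EVENT_COLUMNS = [
    "animal_id", "stimulus_index", "channel", "order", "onset_s", "offset_s", "peak_ratio",
]


def write_events_csv(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> list[dict]:
    frame = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in _EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: events CSV lacks columns {missing}")
    return frame.to_dict("records")


def events_from_rows(rows: list[dict]) -> list[AfterdischargeEvent]:
    return [
        AfterdischargeEvent(
            channel=str(r["channel"]), order=int(r["order"]),
            onset_s=float(r["onset_s"]), offset_s=float(r["offset_s"]),
            peak_ratio=float(r["peak_ratio"]),
        )
        for r in rows
    ]
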