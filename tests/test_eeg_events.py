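"""Afterdischarge detection rule and occurrence chi-square."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter1d

from kindlekit.eeg_events import (
    DetectorParams,
    EEGRecording,
    OccurrenceTable,
    detect_afterdischarges,
    envelope,
    estimate_background,
    occurrence_chi2,
    trim_capacitor_artifact,
)
from kindlekit.synthdata import NoiseSpec, generate_eeg, make_tone_burst_recording

FS = 2000.0


def _recording(samples: np.ndarray, stim_on=30.0, stim_off=40.0) -> EEGRecording:
    return EEGRecording(("HIP",), FS, samples[np.newaxis, :], stim_on, stim_off)


# --- background -----------------------------------------------------------


def test_background_of_unit_sine_is_mean_rectified_value():
    """The envelope of a unit sine is its mean rectified value, 2/pi."""
    t = np.arange(int(100 * FS)) / FS
    rec = _recording(np.sin(2 * np.pi * 10 * t))
    assert estimate_background(rec, "HIP") == pytest.approx(2 / np.pi, rel=0.05)


def test_background_matches_bruteforce_median(fast_protocol):
    rec, _ = generate_eeg(fast_protocol, [], NoiseSpec(), seed=3)
    x = rec.channel("PC")
    n_baseline = int(rec.stimulus_onset_s * FS)
    width = int(round(0.2 * FS))
    oracle = float(np.median(uniform_filter1d(np.abs(x[:n_baseline]), width, mode="nearest")))
    assert estimate_background(rec, "PC") == oracle


def test_background_window_too_short():
    rec = _recording(np.ones(int(100 * FS)))
    with pytest.raises(ValueError, match="5 s"):
        estimate_background(rec, "HIP", baseline_window_s=3.0)


def test_detection_on_zero_signal_is_an_error():
    rec = _recording(np.zeros(int(100 * FS)))
    with pytest.raises(ValueError, match="zero"):
        detect_afterdischarges(rec, "HIP")


# --- capacitor-artifact trimming -----------------------------------------


def test_trim_removes_leading_dc_sag():
    """A 0.5 s sag 5 SD below baseline is chopped off, within one window."""
    rng = np.random.default_rng(0)
    clean = rng.normal(0.0, 1.0, int(4 * FS))
    sag = clean.copy()
    sag[: int(0.5 * FS)] -= 5.0
    trimmed, flag = trim_capacitor_artifact(sag, FS, 0.0, 1.0)
    assert not flag
    removed_s = (sag.size - trimmed.size) / FS
    assert removed_s == pytest.approx(0.5, abs=0.1)


def test_trim_is_identity_at_baseline():
    x = np.random.default_rng(1).normal(0.0, 1.0, int(2 * FS))
    trimmed, flag = trim_capacitor_artifact(x, FS, 0.0, 1.0)
    assert trimmed.size == x.size and not flag


def test_trim_all_sag_returns_empty_with_flag():
    x = np.full(int(2 * FS), -10.0)
    trimmed, flag = trim_capacitor_artifact(x, FS, 0.0, 1.0)
    assert trimmed.size == 0 and flag


def test_trim_never_removes_more_than_half():
    x = np.concatenate([np.full(int(3 * FS), -10.0), np.zeros(int(1 * FS))])
    trimmed, flag = trim_capacitor_artifact(x, FS, 0.0, 1.0)
    assert trimmed.size >= x.size // 2
    assert not flag


# --- detection rule -------------------------------------------------------


def test_detects_burst_meeting_both_thresholds():
    rec = make_tone_burst_recording(3.0, 5.0)
    events = detect_afterdischarges(rec, "HIP")
    assert len(events) == 1
    ev = events[0]
    assert ev.order == 1
    assert ev.onset_s == pytest.approx(45.0, abs=0.25)
    assert ev.offset_s == pytest.approx(50.0, abs=0.25)
    assert ev.peak_ratio == pytest.approx(3.0, rel=1e-6)


def test_rejects_burst_below_amplitude_threshold():
    rec = make_tone_burst_recording(1.5, 10.0)
    assert detect_afterdischarges(rec, "HIP") == []


def test_rejects_burst_below_duration_threshold():
    rec = make_tone_burst_recording(3.0, 2.0)
    assert detect_afterdischarges(rec, "HIP") == []


def test_detection_invariant_to_global_rescaling():
    rec = make_tone_burst_recording(3.0, 5.0)
    scaled = EEGRecording(
        rec.channel_labels, rec.sampling_rate_hz, rec.samples * 7.3e-4,
        rec.stimulus_onset_s, rec.stimulus_offset_s,
    )
    ev1 = detect_afterdischarges(rec, "HIP")
    ev2 = detect_afterdischarges(scaled, "HIP")
    assert [(e.onset_s, e.offset_s) for e in ev1] == [(e.onset_s, e.offset_s) for e in ev2]
    assert ev1[0].peak_ratio == pytest.approx(ev2[0].peak_ratio)


@pytest.mark.parametrize("param, values", [
    ("min_duration_s", [1.0, 3.0, 6.0, 12.0]),
    ("amplitude_ratio_min", [1.2, 2.0, 3.5, 5.0]),
])
def test_detection_monotone_in_thresholds(param, values):
    """Stricter thresholds can only lose events, never gain them."""
    rec = make_tone_burst_recording(4.0, 5.0)
    counts = [
        len(detect_afterdischarges(rec, "HIP", DetectorParams(**{param: v})))
        for v in values
    ]
    assert counts == sorted(counts, reverse=True)


def test_first_and_second_events_numbered_by_onset(fast_protocol):
    from kindlekit.synthdata import ADGroundTruth

    stim_off = fast_protocol.pre_window_s + fast_protocol.stimulus_duration_s
    planted = [
        ADGroundTruth("HIP", 2, stim_off + 15.0, stim_off + 19.0, 3.5),
        ADGroundTruth("HIP", 1, stim_off + 2.0, stim_off + 7.0, 3.5),
    ]
    rec, truth = generate_eeg(fast_protocol, planted, seed=7)
    events = detect_afterdischarges(rec, "HIP")
    assert [e.order for e in events] == [1, 2]
    assert events[0].onset_s < events[1].onset_s
    # ground truth is renumbered by onset too
    assert [t.order for t in truth] == [1, 2]


def test_detection_is_deterministic(fast_protocol):
    from kindlekit.synthdata import ADGroundTruth

    stim_off = fast_protocol.pre_window_s + fast_protocol.stimulus_duration_s
    planted = [ADGroundTruth("HIP", 1, stim_off + 2.0, stim_off + 8.0, 3.0)]
    rec, _ = generate_eeg(fast_protocol, planted, seed=9)
    assert detect_afterdischarges(rec, "HIP") == detect_afterdischarges(rec, "HIP")


# --- occurrence chi-square ------------------------------------------------


def _chi2_closed_form(table: np.ndarray) -> float:
    (a, b), (c, d) = table.astype(float)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


@pytest.mark.parametrize(
    "table, chi2",
    [
        ([[10, 0], [10, 0]], None),       # identical rows: zero column margin
        ([[9, 1], [4, 6]], 5.4945),       # direct sum of (O-E)^2/E
        ([[10, 0], [0, 10]], 20.0),       # complete separation
        ([[5, 5], [5, 5]], 0.0),
    ],
)
def test_occurrence_chi2_examples(table, chi2):
    arr = np.array(table)
    if chi2 is None:
        # [[10,0],[10,0]]: the 'absent' column margin is zero -> undefined
        with pytest.raises(ValueError, match="marginal"):
            occurrence_chi2(arr)
        return
    res = occurrence_chi2(arr)
    assert res["df"] == 1
    assert res["chi2"] == pytest.approx(chi2, abs=1e-3)


def test_occurrence_chi2_identical_rows_is_null():
    res = occurrence_chi2(np.array([[7, 3], [7, 3]]))
    assert res["chi2"] == pytest.approx(0.0)
    assert res["p"] == pytest.approx(1.0)


def test_occurrence_chi2_matches_closed_form_sampled(rng):
    for _ in range(300):
        arr = rng.integers(0, 11, size=(2, 2))
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            continue
        assert occurrence_chi2(arr)["chi2"] == pytest.approx(_chi2_closed_form(arr))


def test_occurrence_chi2_yates_flag_reduces_statistic():
    arr = np.array([[9, 1], [4, 6]])
    assert occurrence_chi2(arr, yates=True)["chi2"] < occurrence_chi2(arr)["chi2"]


def test_occurrence_table_shape():
    table = OccurrenceTable("HIP", present={1: 7, 21: 2}, absent={1: 1, 21: 6})
    arr = table.as_array()
    assert arr.tolist() == [[7, 1], [2, 6]]
    assert occurrence_chi2(table)["chi2"] > 3.84
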