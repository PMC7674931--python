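"""Synthetic-cohort generator: determinism, calibration, recovery."""

import numpy as np
import pytest

from kindlekit.eeg_events import detect_afterdischarges, envelope, estimate_background
from kindlekit.neuroethology import dyad_interactions, summarize
from kindlekit.severity import compare_groups
from kindlekit.synthdata import (
    ADGroundTruth,
    GroupEffects,
    ProtocolConfig,
    generate_behavior_sequence,
    generate_cohort,
    generate_eeg,
    read_behavior_csv,
    write_cohort,
)
from scipy.ndimage import uniform_filter1d


def _stim_off(protocol):
    return protocol.pre_window_s + protocol.stimulus_duration_s


# --- EEG ------------------------------------------------------------------


def test_identical_seed_gives_bit_identical_eeg(fast_protocol):
    planted = [ADGroundTruth("PC", 1, 45.0, 50.0, 3.0)]
    rec1, t1 = generate_eeg(fast_protocol, planted, seed=5)
    rec2, t2 = generate_eeg(fast_protocol, planted, seed=5)
    assert np.array_equal(rec1.samples, rec2.samples)
    assert t1 == t2
    rec3, _ = generate_eeg(fast_protocol, planted, seed=6)
    assert not np.array_equal(rec1.samples, rec3.samples)


def test_event_free_record_triggers_no_detection(fast_protocol):
    """Without planted events the detector stays silent and no 2x-background
    elevation is sustained at the 3 s event scale (seed-checked)."""
    rec, truth = generate_eeg(fast_protocol, [], seed=0)
    assert truth == []
    for ch in fast_protocol.channels:
        assert detect_afterdischarges(rec, ch) == []
        fs = rec.sampling_rate_hz
        bg = estimate_background(rec, ch)
        post = rec.channel(ch)[int(rec.stimulus_offset_s * fs):]
        sustained = uniform_filter1d(envelope(post, fs), int(3 * fs), mode="nearest")
        assert sustained.max() < 2.0 * bg


def test_planted_ad_is_recovered(fast_protocol):
    start = _stim_off(fast_protocol) + 2.0
    planted = [ADGroundTruth("HIP", 1, start, start + 5.0, 3.0)]
    rec, truth = generate_eeg(fast_protocol, planted, seed=0)
    events = detect_afterdischarges(rec, "HIP")
    assert len(events) == 1
    assert events[0].order == 1
    assert events[0].onset_s == pytest.approx(truth[0].onset_s, abs=0.25)


def test_two_planted_ads_ordered_by_onset(fast_protocol):
    off = _stim_off(fast_protocol)
    planted = [
        ADGroundTruth("HIP", 1, off + 2.0, off + 7.0, 3.0),
        ADGroundTruth("HIP", 2, off + 12.0, off + 17.0, 3.0),
    ]
    rec, truth = generate_eeg(fast_protocol, planted, seed=1)
    events = detect_afterdischarges(rec, "HIP")
    assert [e.order for e in events] == [1, 2]
    for ev, tr in zip(events, truth):
        assert ev.onset_s == pytest.approx(tr.onset_s, abs=0.5)


def test_planted_envelope_reaches_requested_ratio(fast_protocol):
    off = _stim_off(fast_protocol)
    planted = [ADGroundTruth("HIP", 1, off + 2.0, off + 8.0, 3.0)]
    rec, _ = generate_eeg(fast_protocol, planted, seed=2)
    fs = rec.sampling_rate_hz
    bg = estimate_background(rec, "HIP")
    env = envelope(rec.channel("HIP"), fs)
    core = env[int((off + 3.0) * fs): int((off + 7.0) * fs)]
    assert np.median(core) / bg == pytest.approx(3.0, rel=0.25)


def test_overlapping_planted_events_rejected(fast_protocol):
    off = _stim_off(fast_protocol)
    planted = [
        ADGroundTruth("HIP", 1, off + 2.0, off + 8.0, 3.0),
        ADGroundTruth("HIP", 2, off + 7.0, off + 12.0, 3.0),
    ]
    with pytest.raises(ValueError, match="overlap"):
        generate_eeg(fast_protocol, planted, seed=0)


def test_event_outside_post_window_rejected(fast_protocol):
    planted = [ADGroundTruth("HIP", 1, 5.0, 10.0, 3.0)]  # inside PRE
    with pytest.raises(ValueError, match="post-stimulus"):
        generate_eeg(fast_protocol, planted, seed=0)


def test_ground_truth_validation():
    with pytest.raises(ValueError):
        ADGroundTruth("HIP", 1, 10.0, 5.0, 3.0)
    with pytest.raises(ValueError):
        ADGroundTruth("HIP", 1, 5.0, 10.0, -1.0)


def test_protocol_validation():
    with pytest.raises(ValueError, match="sampling"):
        ProtocolConfig(sampling_rate_hz=150.0)
    with pytest.raises(ValueError):
        ProtocolConfig(post_window_s=0.0)


# --- behavior -------------------------------------------------------------


def test_single_code_profile_is_constant():
    seq = generate_behavior_sequence(["IM"], np.array([[1.0]]), 2.0, 50, seed=0)
    summary = summarize(seq)
    assert summary.frequency == {"IM": 1}
    assert summary.mean_duration_s == {"IM": 50.0}


def test_non_stochastic_matrix_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        generate_behavior_sequence(["A", "B"], np.array([[0.5, 0.4], [0.5, 0.5]]), 2.0, 10)


def test_sub_second_dwell_rejected():
    with pytest.raises(ValueError, match="dwell"):
        generate_behavior_sequence(["A", "B"], np.eye(2)[::-1], 0.5, 10)


def test_behavior_sequence_deterministic():
    m = np.array([[0.0, 1.0], [1.0, 0.0]])
    s1 = generate_behavior_sequence(["A", "B"], m, 2.0, 100, seed=3)
    s2 = generate_behavior_sequence(["A", "B"], m, 2.0, 100, seed=3)
    assert s1 == s2


def test_forced_transition_is_flagged():
    """A planted P(A->B) = 0.9 coupling is picked up as a significant dyad."""
    codes = ["A", "B", "C", "D"]
    m = np.full((4, 4), 1 / 3)
    np.fill_diagonal(m, 0.0)
    m[0] = [0.0, 0.9, 0.05, 0.05]
    seq = generate_behavior_sequence(codes, m, 2.0, 300, seed=4)
    dyads = {(d.pre_code, d.post_code): d for d in dyad_interactions(seq)}
    assert dyads[("A", "B")].significant


# --- cohort ---------------------------------------------------------------


def test_cohort_validation():
    with pytest.raises(ValueError, match="n_per_group"):
        generate_cohort(n_per_group=0)
    with pytest.raises(ValueError, match="suppression"):
        GroupEffects(tmt_suppression=1.5)


def test_sham_groups_carry_zero_severity_and_no_events():
    bundle = generate_cohort(n_per_group=2, seed=0, behavior_stimuli=())
    for r in bundle.severity_records:
        if r.group.startswith("NoStim"):
            assert r.li_class == 0
    assert all(not k[0].startswith("NoStim") for k in bundle.ad_truth)


def test_stimulated_severity_progresses():
    bundle = generate_cohort(n_per_group=6, seed=1, behavior_stimuli=(), eeg_stimuli=())
    by_stim = {}
    for r in bundle.severity_records:
        if r.group == "Stim+Water" and r.period == "STIMULUS":
            by_stim.setdefault(r.stimulus_index, []).append(r.li_class)
    early = np.mean(by_stim[1] + by_stim[2] + by_stim[3])
    late = np.mean(by_stim[18] + by_stim[19] + by_stim[20])
    assert late > early + 2.0


def test_suppression_acts_only_at_test_stimulus():
    bundle = generate_cohort(
        effects=GroupEffects(tmt_suppression=0.0),
        n_per_group=6, seed=2, behavior_stimuli=(), eeg_stimuli=(),
    )
    at = {}
    for r in bundle.severity_records:
        if r.period == "STIMULUS" and r.group.startswith("Stim"):
            at.setdefault((r.group, r.stimulus_index), []).append(r.li_class)
    assert np.mean(at[("Stim+TMT", 21)]) == 0.0
    assert np.mean(at[("Stim+TMT", 20)]) > 2.0
    assert np.mean(at[("Stim+Water", 21)]) > 2.0


def test_no_suppression_keeps_groups_exchangeable():
    """With suppression 1.0 the treated and control stimulated groups are
    exchangeable: the Mann-Whitney rejection rate at the test stimulus stays
    at the nominal level (binomial 2-sigma bound over 200 seeds)."""
    rejections = 0
    for seed in range(200):
        bundle = generate_cohort(
            effects=GroupEffects(tmt_suppression=1.0),
            n_per_group=10, seed=seed, behavior_stimuli=(), eeg_stimuli=(),
            groups=("Stim+Water", "Stim+TMT"),
        )
        a, b = [], []
        for r in bundle.severity_records:
            if r.period == "STIMULUS" and r.stimulus_index == 21:
                (a if r.group == "Stim+Water" else b).append(r.li_class)
        if compare_groups(a, b)["p"] < 0.05:
            rejections += 1
    assert rejections / 200 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 200)


def test_cohort_deterministic_and_eeg_lazy(fast_protocol):
    b1 = generate_cohort(fast_protocol, n_per_group=2, seed=3, behavior_stimuli=(1,))
    b2 = generate_cohort(fast_protocol, n_per_group=2, seed=3, behavior_stimuli=(1,))
    assert b1.severity_records == b2.severity_records
    assert b1.ad_truth == b2.ad_truth
    assert b1.behavior == b2.behavior
    key = next(iter(b1.ad_truth))
    r1, _ = b1.eeg(*key)
    r2, _ = b2.eeg(*key)
    assert np.array_equal(r1.samples, r2.samples)


def test_write_cohort_and_behavior_round_trip(tmp_path, fast_protocol):
    bundle = generate_cohort(fast_protocol, n_per_group=2, seed=4, behavior_stimuli=(1,))
    out = write_cohort(bundle, tmp_path / "cohort")
    assert (out / "severity.csv").exists()
    assert (out / "manifest.yaml").exists()
    assert (out / "ad_ground_truth.json").exists()
    loaded = read_behavior_csv(out / "behavior.csv")
    assert loaded == bundle.behavior
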