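"""Night-detector contracts: spatial means, the closer-to-next-stage rule,
oracle equivalence of the run search, and recovery of synthetic switches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seedlingrgbd as sg
from seedlingrgbd.night import (NightEventInputs, detect_night_switch,
                                evaluate_episodes, extract_night_episode,
                                literal_sign_bin, make_daylight_pseudo_episodes,
                                spatial_mean, validate_on_daylight)
from seedlingrgbd.records import DepthMap


def _inputs_from_means(sa, snight, sb):
    """Build 2x2 constant frames realising the given spatial-mean series."""
    return NightEventInputs(sa=[np.full((2, 2), v) for v in sa],
                            snight=[np.full((2, 2), v) for v in snight],
                            sb=[np.full((2, 2), v) for v in sb])


# -- spatial mean -----------------------------------------------------------

def test_spatial_mean_constants():
    assert spatial_mean(np.full((7, 7), 500.0)) == 500.0
    half = np.zeros((4, 4))
    half[:2] = 100.0
    assert spatial_mean(half) == 50.0


def test_spatial_mean_equals_double_loop():
    rng = np.random.default_rng(0)
    arr = rng.uniform(0, 800, (9, 11))
    brute = 0.0
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            brute += arr[i, j]
    brute /= arr.size
    assert spatial_mean(arr) == pytest.approx(brute, rel=1e-12)


def test_spatial_mean_rejects_missing_values():
    d = DepthMap(np.ones((3, 3)), np.eye(3, dtype=bool))
    with pytest.raises(ValueError, match="inpaint"):
        spatial_mean(d)


# -- detector ---------------------------------------------------------------

def test_detector_on_worked_example():
    """Night means drift from the stage-A level (500) to stage-B (480):
    first frame of the first run of four closer-to-B frames is index 3."""
    sa = [500.0] * 6
    sb = [480.0] * 6
    dn = [500, 500, 490, 478, 479, 481, 480, 480]
    trace = detect_night_switch(_inputs_from_means(sa, dn, sb))
    assert trace.mda == 500.0 and trace.mdb == 480.0
    assert trace.bin.tolist() == [0, 0, 0, 1, 1, 1, 1, 1]
    assert trace.idx == 3
    assert trace.pt == len(sa) + 3


def test_no_detection_when_night_stays_at_stage_a():
    trace = detect_night_switch(_inputs_from_means([500] * 4, [500] * 8, [480] * 4))
    assert not trace.detected
    assert trace.idx is None and trace.pt is None
    assert trace.bin.sum() == 0


def test_tie_counts_as_not_yet_closer():
    # exactly halfway between the two levels -> bin stays 0
    trace = detect_night_switch(_inputs_from_means([500] * 4, [490] * 8, [480] * 4))
    assert not trace.detected


def test_run_length_longer_than_night_rejected():
    with pytest.raises(ValueError, match="fewer"):
        detect_night_switch(_inputs_from_means([500] * 2, [490] * 3, [480] * 2))


def test_inputs_must_be_non_empty_and_same_shape():
    with pytest.raises(ValueError, match="sa"):
        NightEventInputs(sa=[], snight=[np.ones((2, 2))], sb=[np.ones((2, 2))])
    with pytest.raises(ValueError, match="shape"):
        NightEventInputs(sa=[np.ones((2, 2))], snight=[np.ones((3, 3))],
                         sb=[np.ones((2, 2))])


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.integers(0, 10_000_000))
def test_first_run_index_matches_exhaustive_window_search(seed):
    """Oracle equivalence on random inputs: the detector's Idx equals a
    brute-force scan of every length-4 window of the closer-to-B vector."""
    rng = np.random.default_rng(seed)
    n_night = int(rng.integers(4, 24))
    sa = rng.uniform(400, 600, size=int(rng.integers(1, 6)))
    sb = rng.uniform(400, 600, size=int(rng.integers(1, 6)))
    dn = rng.uniform(400, 600, size=n_night)
    inputs = _inputs_from_means(sa, dn, sb)
    trace = detect_night_switch(inputs, run_length=4)
    mda, mdb = np.mean(sa), np.mean(sb)
    bits = [1 if abs(v - mda) - abs(v - mdb) > 0 else 0 for v in dn]
    expected = next((k for k in range(n_night - 3)
                     if all(bits[k : k + 4])), None)
    assert trace.idx == expected
    if expected is not None:
        assert trace.pt == len(sa) + expected
        assert len(sa) <= trace.pt <= len(sa) + n_night - 4


def test_literal_pseudocode_sign_is_frame_independent():
    """Without absolute values, sign(GA-GB) = sign(MDB-MDA) for every night
    frame — a constant vector that cannot localise the switch."""
    rng = np.random.default_rng(1)
    dn = rng.uniform(400, 600, 16)
    inputs = _inputs_from_means([500] * 4, dn, [480] * 4)
    bits = literal_sign_bin(inputs)
    assert len(set(bits.tolist())) == 1
    assert bits[0] == np.sign(480.0 - 500.0)  # == sign(MDB - MDA)


# -- synthetic-episode recovery --------------------------------------------

def test_noise_free_switch_recovered_exactly():
    p = sg.SceneParams(depth_noise_std_mm=0.0, missing_prob=0.0,
                       missing_blob_prob=0.0)
    for offset in (0, 10, 27):
        seq = sg.generate_switch_episode(p, 5, transition="FA:OC",
                                         night_offset=offset)
        inputs, truth = extract_night_episode(seq, "FA:OC")
        trace = detect_night_switch(inputs)
        assert truth == offset
        assert trace.idx == truth
        assert trace.pt == len(inputs.sa) + truth


def test_episode_extraction_rejects_daytime_switch(quick_seq):
    # quick_seq's SOIL->FA switch happens in daylight
    t = sg.plant_switch_oracle(quick_seq, "SOIL:FA")
    assert quick_seq.frame_at(t).is_day
    with pytest.raises(ValueError, match="day"):
        extract_night_episode(quick_seq, "SOIL:FA")


def test_missing_transition_raises_no_such_event(quick_params):
    p = quick_params.replace(soil_frames_mean=10_000)
    seq = sg.generate_sequence(p, 2)
    with pytest.raises(sg.NoSuchEvent):
        extract_night_episode(seq, "FA:OC")


def test_larger_depth_steps_never_hurt_localisation():
    """Monte-Carlo trend: mean |detected - truth| is non-increasing in the
    step magnitude at fixed noise."""
    mean_shift = []
    for step in (3.0, 6.0, 12.0):
        p = sg.SceneParams(oc_depth_step_mm=step, depth_noise_std_mm=2.0)
        shifts = []
        for s in range(12):
            seq = sg.generate_switch_episode(p, 300 + s, transition="FA:OC")
            inputs, truth = extract_night_episode(seq, "FA:OC")
            trace = detect_night_switch(inputs)
            shifts.append(abs(trace.idx - truth) if trace.detected
                          else len(inputs.snight))
        mean_shift.append(np.mean(shifts))
    assert mean_shift[0] >= mean_shift[1] - 0.5
    assert mean_shift[1] >= mean_shift[2] - 0.5
    assert mean_shift[2] <= 1.0


# -- daylight validation protocol -------------------------------------------

def test_daylight_validation_perfect_in_noise_free_regime(quick_params):
    p = quick_params.replace(depth_noise_std_mm=0.0, missing_prob=0.0,
                             missing_blob_prob=0.0)
    seqs = [sg.generate_sequence(p, s, variety=v)
            for s, v in enumerate(sorted(sg.VARIETIES))]
    report = validate_on_daylight(seqs, pseudo_night_len=16, context_len=24)
    assert report.n_events > 0
    assert report.fraction_within_tolerance == 1.0
    assert report.mean_abs_shift == 0.0


def test_daylight_validation_without_switches_warns_and_is_empty(quick_params):
    p = quick_params.replace(soil_frames_mean=10_000)
    seq = sg.generate_sequence(p, 3)
    with pytest.warns(UserWarning, match="no usable"):
        report = validate_on_daylight([seq])
    assert report.n_events == 0


def test_pseudo_episode_truth_sits_inside_pseudo_night(quick_seq):
    for inputs, truth, key in make_daylight_pseudo_episodes(
            quick_seq, pseudo_night_len=16, context_len=24):
        assert 0 <= truth < len(inputs.snight)
        assert len(inputs.sa) > 0 and len(inputs.sb) > 0
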