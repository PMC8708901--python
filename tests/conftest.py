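"""Shared fixtures: fast scene presets and session-scoped trained models."""

from __future__ import annotations

import numpy as np
import pytest

import seedlingrgbd as sg
from seedlingrgbd.experiment import TrainConfig, evaluate, run_comparison

# Desk-scale training scene: one long day block so every stage is seen in
# daylight, short stage durations, and the same depth/noise regime as the
# full-scale default (step 10 mm, noise 2 mm, 2 % dropouts).
TRAIN_SCENE = dict(frames_day=128, frames_night=32, day_block=128,
                   soil_frames_mean=30, fa_frames_mean=35, oc_frames_mean=35)

TRAIN_CONFIG = TrainConfig(epochs=12, batch_size=32, repetitions=3,
                           seeds=[0, 1, 2], patience=5, window_stride=2)


def make_split_sequences(params: sg.SceneParams, n_varieties: int = 2,
                         seed0: int = 1000) -> dict[str, list[sg.SequenceRecord]]:
    varieties = sorted(sg.VARIETIES)[:n_varieties]
    seqs: dict[str, list[sg.SequenceRecord]] = {
        "train": [], "validation": [], "test": []}
    s = seed0
    for split in seqs:
        for v in varieties:
            seqs[split].append(sg.generate_sequence(
                params, s, variety=v, pot_id=f"{v}_{split}"))
            s += 1
    return seqs


@pytest.fixture(scope="session")
def quick_params() -> sg.SceneParams:
    """Small scene for fast sequence-level tests (128 frames, 4 stages)."""
    return sg.SceneParams(frames_day=96, frames_night=32,
                          soil_frames_mean=24, fa_frames_mean=28,
                          oc_frames_mean=28)


@pytest.fixture(scope="session")
def quick_seq(quick_params) -> sg.SequenceRecord:
    return sg.generate_sequence(quick_params, 42, variety="Flavert")


@pytest.fixture(scope="session")
def full_seq() -> sg.SequenceRecord:
    """One full-scale default sequence (616 frames, 424 day + 192 night)."""
    return sg.generate_sequence(sg.SceneParams(), 7, variety="Flavert")


@pytest.fixture(scope="session")
def fusion_comparison():
    """RGB-only vs image-fusion CNNs on the depth-coded-OC preset.

    The cotyledon-opening transition is rendered invisible in RGB
    (oc_rgb_contrast=0), so any gain of the 4-channel model over the
    RGB-only model must come from the depth channel.  Three repetitions
    per variant.
    """
    params = sg.SceneParams(oc_rgb_contrast=0.0, **TRAIN_SCENE)
    seqs = make_split_sequences(params)
    results, table = run_comparison(["cnn"], ["none_rgb", "image"], seqs,
                                    TRAIN_CONFIG)
    return {r.fusion: r for r in results}, table


@pytest.fixture(scope="session")
def default_trained():
    """One image-fusion CNN trained on the default (RGB-visible) preset."""
    from seedlingrgbd.experiment import build_windows, fit_depth_scaler, train_model
    from seedlingrgbd.models import ModelSpec

    params = sg.SceneParams(**TRAIN_SCENE)
    seqs = make_split_sequences(params, seed0=2000)
    scaler = fit_depth_scaler(seqs["train"])
    cfg = TrainConfig(epochs=12, batch_size=32, repetitions=1, seeds=[0],
                      patience=5, window_stride=2)
    data = {split: build_windows(s, scaler, length=1, stride=cfg.window_stride)
            for split, s in seqs.items()}
    clf, _ = train_model(ModelSpec(backbone="cnn", fusion="image"), data, cfg, 0)
    acc, cm = evaluate(clf, data["test"])
    return clf, acc, cm
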