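"""Protocol contracts: accuracy metrics, variety-stratified splits,
flip doubling, reproducible training, and leakage guards."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seedlingrgbd as sg
from seedlingrgbd.experiment import (ConfusionMatrix, TrainConfig,
                                     WindowDataset, accuracy, build_windows,
                                     evaluate, fit_depth_scaler,
                                     split_by_variety, train_model)
from seedlingrgbd.models import ModelSpec


# -- confusion matrix and accuracy -----------------------------------------

def test_diagonal_matrix_has_accuracy_one():
    cm = ConfusionMatrix(np.diag([5, 8, 2, 1]))
    assert accuracy(cm) == 1.0


def test_uniform_matrix_has_chance_accuracy():
    cm = ConfusionMatrix(np.full((4, 4), 5))
    assert accuracy(cm) == pytest.approx(0.25)  # 20 / 80


def test_empty_matrix_rejected():
    with pytest.raises(ValueError, match="empty"):
        accuracy(ConfusionMatrix())


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_matrix_accuracy_equals_per_item_recount(seed):
    """Oracle equivalence: trace/total equals direct per-item correct/total."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 200))
    y_true = rng.integers(0, 4, n)
    y_pred = rng.integers(0, 4, n)
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    brute = sum(int(t == p) for t, p in zip(y_true, y_pred)) / n
    assert accuracy(cm) == pytest.approx(brute)
    assert cm.total == n
    for k in range(4):
        c = cm.class_counts(k)
        assert c["TP"] + c["TN"] + c["FP"] + c["FN"] == n


def test_macro_one_vs_rest_accuracy():
    cm = ConfusionMatrix(np.array([[3, 1, 0, 0], [0, 4, 0, 0],
                                   [0, 0, 5, 0], [0, 0, 0, 7]]))
    per_class = []
    for k in range(4):
        c = cm.class_counts(k)
        per_class.append((c["TP"] + c["TN"]) / cm.total)
    assert cm.macro_ovr_accuracy() == pytest.approx(np.mean(per_class))


def test_adjacent_error_fraction():
    counts = np.zeros((4, 4), dtype=int)
    counts[1, 2] = 3  # adjacent
    counts[0, 3] = 1  # distant
    np.fill_diagonal(counts, 10)
    assert ConfusionMatrix(counts).adjacent_error_fraction() == pytest.approx(0.75)
    assert ConfusionMatrix(np.diag([1, 1, 1, 1])).adjacent_error_fraction() == 1.0


# -- splits -----------------------------------------------------------------

def _entries(variety, n):
    return [{"variety": variety, "path": f"{variety}/{i}", "pot_id": f"{variety}_{i}"}
            for i in range(n)]


def test_split_by_variety_from_flat_list():
    splits = split_by_variety(_entries("Flavert", 3))
    assert [len(splits[s]) for s in ("train", "validation", "test")] == [1, 1, 1]


def test_split_by_variety_requires_three_sequences():
    with pytest.raises(ValueError, match="at least 3"):
        split_by_variety(_entries("Linex", 2))


def test_splits_are_pairwise_disjoint():
    splits = split_by_variety(_entries("Flavert", 5) + _entries("Linex", 4))
    sets = {s: {e["path"] for e in v} for s, v in splits.items()}
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert not (sets[a] & sets[b])
    for s in sets.values():
        assert {e.split("/")[0] for e in s} == {"Flavert", "Linex"}


def test_split_by_variety_validates_manifest(tmp_path, quick_params):
    config = {"varieties": ["Flavert", "Linex"],
              "sequences_per_variety": {"train": 2, "validation": 1, "test": 1}}
    manifest = sg.generate_dataset(config, tmp_path / "ds", 0,
                                   params=quick_params, write_images=False)
    splits = split_by_variety(manifest)
    assert len(splits["train"]) == 4
    assert len(splits["test"]) == 2


# -- data plumbing ----------------------------------------------------------

def test_flip_doubled_duplicates_and_mirrors():
    rng = np.random.default_rng(0)
    ds = WindowDataset(rng.random((3, 6, 6, 4)), np.array([0, 1, 2]))
    doubled = ds.flip_doubled()
    assert len(doubled) == 6
    assert np.array_equal(doubled.y, [0, 1, 2, 0, 1, 2])
    assert np.array_equal(doubled.X[3], ds.X[0][:, ::-1, :])


def test_build_windows_shapes(quick_seq):
    scaler = fit_depth_scaler([quick_seq])
    single = build_windows([quick_seq], scaler, length=1)
    assert single.X.shape[1:] == (66, 66, 4)
    assert len(single) == quick_seq.n_day
    temporal = build_windows([quick_seq], scaler, length=4)
    assert temporal.X.shape[1:] == (4, 66, 66, 4)
    assert len(temporal) == quick_seq.n_day - 3


def test_window_ids_prevent_split_leakage(quick_seq):
    scaler = fit_depth_scaler([quick_seq])
    a = build_windows([quick_seq], scaler, length=1)
    flipped = sg.augment_flip(quick_seq)
    flipped.pot_id = "other"
    b = build_windows([flipped], scaler, length=1)
    assert not (set(a.ids) & set(b.ids))


# -- training ---------------------------------------------------------------

def _toy_splits(n_train=24, n_eval=12, seed=0):
    """Stage encoded as a distinct solid colour: linearly separable."""
    rng = np.random.default_rng(seed)

    def make(n):
        y = rng.integers(0, 4, n)
        X = np.zeros((n, 66, 66, 4))
        cols = np.eye(4)[:, :3] * 0.8 + 0.1
        X[:, :, :, :3] = cols[y][:, None, None, :]
        X += rng.normal(0, 0.02, X.shape)
        X[:, :, :, 3] = 0.5
        return WindowDataset(X, y.astype(np.intp))

    return {"train": make(n_train), "validation": make(n_eval),
            "test": make(n_eval)}


def test_one_epoch_smoke_run_records_history():
    splits = _toy_splits(10, 6)
    cfg = TrainConfig(epochs=1, batch_size=4, repetitions=1, seeds=[0])
    clf, history = train_model(ModelSpec(backbone="cnn", fusion="image"),
                               splits, cfg, 0)
    assert len(history["train_loss"]) == 1
    assert len(history["val_acc"]) == 1


def test_separable_toy_reaches_perfect_accuracy():
    splits = _toy_splits(24, 12)
    cfg = TrainConfig(epochs=20, batch_size=8, repetitions=1, seeds=[0],
                      patience=20)
    clf, _ = train_model(ModelSpec(backbone="cnn", fusion="image"),
                         splits, cfg, 0)
    acc, _ = evaluate(clf, splits["test"])
    assert acc == 1.0


def test_training_is_reproducible_for_fixed_seed():
    splits = _toy_splits(10, 6)
    cfg = TrainConfig(epochs=2, batch_size=4, repetitions=1, seeds=[0])
    spec = ModelSpec(backbone="cnn", fusion="image")
    a, _ = train_model(spec, splits, cfg, seed=1)
    b, _ = train_model(spec, splits, cfg, seed=1)
    for wa, wb in zip(a.get_weights(), b.get_weights()):
        assert np.array_equal(wa, wb)


def test_identical_model_evaluated_twice_has_zero_std():
    splits = _toy_splits(10, 6)
    clf = sg.build_model(ModelSpec(backbone="cnn", fusion="image"), seed=0)
    a, _ = evaluate(clf, splits["test"])
    b, _ = evaluate(clf, splits["test"])
    assert np.std([a, b], ddof=1) == 0.0


def test_train_config_invariants():
    with pytest.raises(ValueError, match="repetitions"):
        TrainConfig(repetitions=0)
    with pytest.raises(ValueError, match="one seed per repetition"):
        TrainConfig(repetitions=3, seeds=[1, 2])
    cfg = TrainConfig(repetitions=2)
    assert len(cfg.seeds) == 2
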