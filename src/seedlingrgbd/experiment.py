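"""Training and evaluation protocol for the fusion classifiers.

Mirrors the study protocol: per-variety train/validation/test splits (every
variety contributes sequences to all three splits, no sequence is shared),
horizontal-flip doubling of the training set, repetitions with one seed
each, model selection by best validation accuracy, and reporting as
mean +- sample standard deviation per split together with the test-split
confusion matrix summed over repetitions.

The headline accuracy is overall (micro) accuracy, trace/total of the 4x4
confusion matrix — identical to per-item correct/total.  A one-vs-rest
macro average of (TP+TN)/(TP+TN+FP+FN) is provided as a secondary metric.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import FusionClassifier, ModelSpec, build_model
from .nn import Adam
from .preprocess import DepthScaler, inpaint_depth, window_sequence
from .records import GrowthStage, SequenceRecord

__all__ = ["TrainConfig", "ConfusionMatrix", "ExperimentResult",
           "WindowDataset", "accuracy", "split_by_variety", "build_windows",
           "fit_depth_scaler", "train_model", "evaluate", "run_comparison"]

N_CLASSES = 4


# ---------------------------------------------------------------------------
# metrics


class ConfusionMatrix:
    """4x4 count table; rows are true stages, columns predicted stages."""

    def __init__(self, counts=None):
        self.counts = (np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
                       if counts is None else np.asarray(counts, dtype=np.int64))
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=np.intp)
        y_pred = np.asarray(y_pred, dtype=np.intp)
        counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_counts(self, k: int) -> dict[str, int]:
        """One-vs-rest TP/TN/FP/FN for class k (TP+TN+FP+FN == total)."""
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts)) / self.total

    def macro_ovr_accuracy(self) -> float:
        """Mean over classes of one-vs-rest (TP+TN)/(TP+TN+FP+FN)."""
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        accs = []
        for k in range(N_CLASSES):
            c = self.class_counts(k)
            accs.append((c["TP"] + c["TN"]) / self.total)
        return float(np.mean(accs))

    def adjacent_error_fraction(self) -> float:
        """Fraction of misclassifications landing on an adjacent stage.

        The four stages are developmentally ordered; a competent model's
        confusions should sit on |true - predicted| == 1.
        """
        err = self.counts.copy()
        np.fill_diagonal(err, 0)
        n_err = err.sum()
        if n_err == 0:
            return 1.0
        i, j = np.indices(err.shape)
        return float(err[np.abs(i - j) == 1].sum() / n_err)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def to_dict(self) -> dict:
        return {"counts": self.counts.tolist(),
                "labels": [s.name for s in GrowthStage]}


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy of a confusion matrix: trace / total."""
    return cm.accuracy()


# ---------------------------------------------------------------------------
# data plumbing


@dataclass
class WindowDataset:
    """Model-ready arrays: X is (N, H, W, 4) or (N, T, H, W, 4)."""

    X: np.ndarray
    y: np.ndarray
    ids: list[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)

    def flip_doubled(self) -> "WindowDataset":
        """Deterministic augmentation: original plus horizontal mirror."""
        flipped = self.X[..., ::-1, :]  # width axis; all channels together
        return WindowDataset(np.concatenate([self.X, flipped]),
                             np.concatenate([self.y, self.y]),
                             self.ids + [(i, "flip") for i in self.ids])


def fit_depth_scaler(sequences: list[SequenceRecord]) -> DepthScaler:
    """Dataset-global depth min/max from (inpainted) train-split frames."""
    maps = (inpaint_depth(f.depth) for s in sequences for f in s.frames)
    return DepthScaler.fit(maps)


def build_windows(sequences: list[SequenceRecord], scaler: DepthScaler,
                  length: int = 1, stride: int = 1) -> WindowDataset:
    """Window every sequence and stack into model-ready arrays."""
    xs, ys, ids = [], [], []
    for seq in sequences:
        for w in window_sequence(seq, scaler, length=length, stride=stride):
            arr = w.stack()  # (T, H, W, 4)
            xs.append(arr[0] if length == 1 else arr)
            ys.append(int(w.stage))
            ids.append((seq.pot_id, w.time_indices[-1]))
    if not xs:
        return WindowDataset(np.empty((0,)), np.empty((0,), dtype=np.intp), [])
    return WindowDataset(np.stack(xs), np.asarray(ys, dtype=np.intp), ids)


def split_by_variety(manifest) -> dict[str, list[dict]]:
    """Assign sequences to train/validation/test within each variety.

    Accepts a :class:`~seedlingrgbd.simulate.DatasetManifest` (whose
    existing split assignment is validated) or a flat list of sequence
    entries (dicts with at least ``variety`` and ``path``), in which case
    the last two sequences of each variety become validation and test.
    Every variety must contribute at least 3 sequences.
    """
    if hasattr(manifest, "splits"):
        manifest.validate()
        splits = {s: list(v) for s, v in manifest.splits.items()}
        varieties = {e["variety"] for v in splits.values() for e in v}
        for split, entries in splits.items():
            missing = varieties - {e["variety"] for e in entries}
            if missing:
                raise ValueError(
                    f"varieties {sorted(missing)} contribute no sequence to "
                    f"the {split} split")
        return splits
    entries = list(manifest)
    by_var: dict[str, list[dict]] = {}
    for e in entries:
        by_var.setdefault(e["variety"], []).append(e)
    splits = {"train": [], "validation": [], "test": []}
    for variety, seqs in sorted(by_var.items()):
        if len(seqs) < 3:
            raise ValueError(
                f"variety {variety!r} has {len(seqs)} sequences; at least 3 "
                "are needed to cover train/validation/test")
        seqs = sorted(seqs, key=lambda e: str(e.get("pot_id", e["path"])))
        splits["train"].extend(seqs[:-2])
        splits["validation"].append(seqs[-2])
        splits["test"].append(seqs[-1])
    return splits


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Optimisation protocol; defaults are the package's standard choices."""

    epochs: int = 50
    batch_size: int = 64
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    repetitions: int = 10
    seeds: list[int] | None = None
    patience: int = 10
    window_stride: int = 1
    flip_augment: bool = True

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.seeds is None:
            self.seeds = list(range(self.repetitions))
        if len(self.seeds) != self.repetitions:
            raise ValueError("one seed per repetition is required")


def _epoch_accuracy(clf: FusionClassifier, data: WindowDataset,
                    batch_size: int) -> float:
    if len(data) == 0:
        return float("nan")
    preds = []
    for i in range(0, len(data), batch_size):
        preds.append(clf.predict(data.X[i : i + batch_size]))
    return float((np.concatenate(preds) == data.y).mean())


def train_model(spec: ModelSpec, splits: dict[str, WindowDataset],
                config: TrainConfig, seed: int):
    """Train one classifier; returns (classifier, history).

    Training data is flip-doubled (when configured), minibatches are
    reshuffled each epoch from the run seed, and the weights with the best
    validation accuracy are restored at the end.  A NaN loss aborts with
    diagnostics.
    """
    train = splits["train"]
    val = splits.get("validation")
    if len(train) == 0:
        raise ValueError("empty training split")
    if config.flip_augment:
        train = train.flip_doubled()
    clf = build_model(spec, seed=seed)
    opt = Adam(clf.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 211]))
    history = {"train_loss": [], "train_acc": [], "val_acc": []}
    best = (-np.inf, clf.get_weights())
    bad_epochs = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            opt.zero_grad()
            loss = clf.loss(train.X[idx], train.y[idx], training=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: loss={loss.data} at epoch {epoch}, "
                    f"batch {i // config.batch_size} (lr={config.learning_rate})")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(
            _epoch_accuracy(clf, train, config.batch_size))
        if val is not None and len(val) > 0:
            va = _epoch_accuracy(clf, val, config.batch_size)
            history["val_acc"].append(va)
            if va > best[0]:
                best = (va, clf.get_weights())
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > config.patience:
                    break
    if val is not None and len(val) > 0 and best[0] > -np.inf:
        clf.set_weights(best[1])
    return clf, history


def evaluate(clf: FusionClassifier, data: WindowDataset,
             batch_size: int = 64) -> tuple[float, ConfusionMatrix]:
    preds = []
    for i in range(0, len(data), batch_size):
        preds.append(clf.predict(data.X[i : i + batch_size]))
    y_pred = np.concatenate(preds) if preds else np.empty(0, dtype=np.intp)
    cm = ConfusionMatrix.from_predictions(data.y, y_pred)
    return cm.accuracy(), cm


# ---------------------------------------------------------------------------
# comparison harness


@dataclass
class ExperimentResult:
    """Per-variant outcome over repetitions."""

    backbone: str
    fusion: str
    accuracies: dict[str, list[float]]  # split -> one accuracy per repetition
    test_confusion: ConfusionMatrix
    seeds: list[int] = field(default_factory=list)

    def mean(self, split: str) -> float:
        return float(np.mean(self.accuracies[split]))

    def std(self, split: str) -> float:
        a = self.accuracies[split]
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    def row(self) -> dict:
        out = {"backbone": self.backbone, "fusion": self.fusion}
        for split in self.accuracies:
            out[f"{split}_mean"] = round(self.mean(split), 4)
            out[f"{split}_std"] = round(self.std(split), 4)
        return out


def run_comparison(backbones, fusions, sequences: dict[str, list[SequenceRecord]],
                   config: TrainConfig) -> tuple[list[ExperimentResult], pd.DataFrame]:
    """Train every (backbone, fusion) variant over the configured repetitions.

    ``sequences`` maps split names to in-memory sequence records.  Windows
    are rebuilt per backbone (single frames for the CNN, 4-frame windows
    for the temporal models); the depth scaler is fitted on the training
    split only.  Returns the per-variant results and a mean+-std summary
    table.
    """
    if not backbones or not fusions:
        raise ValueError("need at least one backbone and one fusion")
    scaler = fit_depth_scaler(sequences["train"])
    cache: dict[int, dict[str, WindowDataset]] = {}

    def windows_for(length: int) -> dict[str, WindowDataset]:
        if length not in cache:
            cache[length] = {
                split: build_windows(seqs, scaler, length=length,
                                     stride=config.window_stride)
                for split, seqs in sequences.items()
            }
        return cache[length]

    results: list[ExperimentResult] = []
    for backbone in backbones:
        for fusion in fusions:
            spec = ModelSpec(backbone=backbone, fusion=fusion)
            data = windows_for(spec.sequence_length)
            accs: dict[str, list[float]] = {s: [] for s in data}
            total_cm = ConfusionMatrix()
            for seed in config.seeds:
                clf, _ = train_model(spec, data, config, seed)
                for split, ds in data.items():
                    acc, cm = evaluate(clf, ds, config.batch_size)
                    accs[split].append(acc)
                    if split == "test":
                        total_cm = total_cm + cm
            results.append(ExperimentResult(backbone, fusion, accs, total_cm,
                                            seeds=list(config.seeds)))
    table = pd.DataFrame([r.row() for r in results])
    return results, table
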