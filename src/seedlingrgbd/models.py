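"""Declarative model specs and the six fusion-classifier variants.

Three backbones — a memoryless CNN, a time-distributed CNN followed by a
GRU (TD-CNN-GRU), and a transformer over whole-frame tokens — each in an
RGB-only, image-fusion (4-channel stacked input) or feature-fusion
(separate RGB and depth streams merged before the classification head)
configuration.

The CNN backbone is the small AlexNet-like stack used throughout: four
3x3 convolutions with 64, 128, 256 and 256 filters, each followed by ReLU
and 2x2 max-pooling, then a 512-unit dense layer with ReLU and dropout
p = 0.5, and a 4-way softmax head.  All weights are trained from scratch
(the 4-channel input rules out RGB-pretrained weights); ``desk`` presets
shrink widths for laptop-scale runs while keeping the topology.

Depth-only classification is supported (``fusion="none_depth"``) purely as
a negative control: on this problem a depth-alone classifier performs at
chance, which is why decision-level fusion is not offered.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import softmax as np_softmax

from . import nn
from .autograd import Tensor, concat, softmax_cross_entropy

__all__ = ["CnnBlockSpec", "TransformerSpec", "ModelSpec", "FusionClassifier",
           "build_model", "predict", "BACKBONES", "FUSIONS"]

BACKBONES = ("cnn", "td_cnn_gru", "transformer")
FUSIONS = ("none_rgb", "none_depth", "image", "feature")

IMAGE_HW = 66
N_CLASSES = 4


@dataclass(frozen=True)
class CnnBlockSpec:
    """The shared convolutional feature extractor + dense classifier stage."""

    filters: tuple[int, ...] = (64, 128, 256, 256)
    kernel: int = 3
    dense_units: int = 512
    dropout: float = 0.5

    @classmethod
    def desk(cls) -> "CnnBlockSpec":
        """Reduced widths for CPU-scale experiments (same topology)."""
        return cls(filters=(8, 16, 32, 32), dense_units=64)

    def param_count(self, channels: tuple[int, ...], image_hw: int = IMAGE_HW,
                    n_classes: int = N_CLASSES) -> int:
        """Closed-form parameter count of a CNN classifier built from this
        spec, one entry in ``channels`` per input stream (streams share no
        weights; each stream has its own dense feature layer and the head
        consumes the concatenated features)."""
        total, flat_total = 0, 0
        for c in channels:
            hw = image_hw
            for f in self.filters:
                total += f * c * self.kernel ** 2 + f
                c = f
                hw //= 2
            flat_total += c * hw * hw
        total += flat_total * self.dense_units + self.dense_units
        total += self.dense_units * n_classes + n_classes
        return total


@dataclass(frozen=True)
class TransformerSpec:
    """Whole-frame-token transformer configuration.

    The named ``paper`` preset keeps the 32-layer depth; head count, model
    width and positional encoding are not externally constrained, so the
    defaults (4 heads, width 128, learned positions) are package choices.
    """

    n_layers: int = 32
    d_model: int = 128
    heads: int = 4
    batch_size: int = 64

    @classmethod
    def paper(cls) -> "TransformerSpec":
        return cls(n_layers=32)

    @classmethod
    def desk(cls) -> "TransformerSpec":
        return cls(n_layers=2, d_model=32, heads=2)


@dataclass(frozen=True)
class ModelSpec:
    """One of the architecture x fusion combinations.

    ``fusion``:
      - ``none_rgb``: RGB only (3 input channels)
      - ``none_depth``: depth only (negative control, 1 channel)
      - ``image``: early fusion, RGB and depth stacked into 4 channels
      - ``feature``: two streams (RGB 3-channel, depth 1-channel) with
        features merged before the classification head
    """

    backbone: str = "cnn"
    fusion: str = "image"
    cnn: CnnBlockSpec = field(default_factory=CnnBlockSpec.desk)
    transformer: TransformerSpec = field(default_factory=TransformerSpec.desk)
    gru_units: int = 64
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; one of {BACKBONES}")
        if self.fusion not in FUSIONS:
            raise ValueError(f"unknown fusion {self.fusion!r}; one of {FUSIONS}")
        seq = 1 if self.backbone == "cnn" else 4
        object.__setattr__(self, "sequence_length",
                           seq if self.sequence_length is None else self.sequence_length)
        if self.backbone == "cnn" and self.sequence_length != 1:
            raise ValueError("the memoryless CNN consumes single frames")

    @property
    def channels(self) -> tuple[int, ...]:
        """Input channels per stream."""
        return {"none_rgb": (3,), "none_depth": (1,),
                "image": (4,), "feature": (3, 1)}[self.fusion]

    @property
    def n_streams(self) -> int:
        return len(self.channels)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if isinstance(d.get("cnn"), dict):
            d["cnn"] = CnnBlockSpec(**{**d["cnn"],
                                       "filters": tuple(d["cnn"]["filters"])})
        if isinstance(d.get("transformer"), dict):
            d["transformer"] = TransformerSpec(**d["transformer"])
        return cls(**d)

    @classmethod
    def parse(cls, text: str, preset: str = "desk") -> "ModelSpec":
        """Parse a ``backbone:fusion`` string such as ``"cnn:image"``."""
        backbone, _, fusion = text.partition(":")
        kw = {}
        if preset == "paper":
            kw = {"cnn": CnnBlockSpec(), "transformer": TransformerSpec.paper()}
        return cls(backbone=backbone, fusion=fusion or "image", **kw)


def _split_streams(spec: ModelSpec, batch: np.ndarray):
    """Channel-split a fused (..., H, W, C) batch for stream-wise models."""
    if spec.fusion == "feature":
        return batch[..., :3], batch[..., 3:4]
    if spec.fusion == "none_rgb":
        return (batch[..., :3],)
    if spec.fusion == "none_depth":
        return (batch[..., 3:4],)
    return (batch,)


class FusionClassifier:
    """A trainable growth-stage classifier built from a :class:`ModelSpec`.

    The handle owns the weights, a dropout generator and the forward pass;
    the training loop lives in :mod:`seedlingrgbd.experiment`.  Inference
    (:meth:`predict_proba`) disables dropout and is deterministic.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([abs(self.seed), 101]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([abs(self.seed), 103]))
        # For the memoryless CNN with feature fusion, streams are conv-only
        # and their flattened conv features merge before one shared dense
        # layer; every other configuration gives each stream its own dense
        # feature layer.
        shared_merge = spec.backbone == "cnn" and spec.n_streams > 1
        self.streams = [
            nn.CnnFeatureExtractor(c, spec.cnn.filters, IMAGE_HW,
                                   None if shared_merge else spec.cnn.dense_units,
                                   spec.cnn.dropout, rng)
            for c in spec.channels
        ] if spec.backbone != "transformer" else []
        self.shared_dense = None
        if spec.backbone == "cnn":
            if shared_merge:
                flat = sum(s.flat_dim for s in self.streams)
                self.shared_dense = nn.Dense(flat, spec.cnn.dense_units, rng)
            head_in = spec.cnn.dense_units
        elif spec.backbone == "td_cnn_gru":
            self.grus = [nn.GRU(spec.cnn.dense_units, spec.gru_units, rng)
                         for _ in spec.channels]
            head_in = spec.gru_units * spec.n_streams
        else:
            ts = spec.transformer
            self.encoders = [
                nn.TransformerEncoder(IMAGE_HW * IMAGE_HW * c, ts.d_model,
                                      ts.heads, ts.n_layers,
                                      spec.sequence_length, rng)
                for c in spec.channels
            ]
            head_in = ts.d_model * spec.n_streams
        self.head = nn.Dense(head_in, N_CLASSES, rng)

    # -- plumbing ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for group in (getattr(self, "streams", []), getattr(self, "grus", []),
                      getattr(self, "encoders", [])):
            for m in group:
                params.extend(m.parameters())
        if getattr(self, "shared_dense", None) is not None:
            params.extend(self.shared_dense.parameters())
        params.extend(self.head.parameters())
        return params

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()

    def save(self, path) -> None:
        """Checkpoint: npz weights with the spec embedded as JSON."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, spec=json.dumps(self.spec.to_dict()), seed=self.seed,
                 **arrays)

    @classmethod
    def load(cls, path) -> "FusionClassifier":
        with np.load(path, allow_pickle=False) as z:
            spec = ModelSpec.from_dict(json.loads(str(z["spec"])))
            clf = cls(spec, seed=int(z["seed"]))
            n = len([k for k in z.files if k.startswith("w")])
            clf.set_weights([z[f"w{i}"] for i in range(n)])
        return clf

    # -- forward ----------------------------------------------------------
    def _check_batch(self, batch) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        t = self.spec.sequence_length
        want = ((t, IMAGE_HW, IMAGE_HW, 4) if t > 1
                else (IMAGE_HW, IMAGE_HW, 4))
        if batch.shape[1:] != want:
            raise ValueError(
                f"expected batch of shape (N, {', '.join(map(str, want))}) "
                f"for {self.spec.backbone}/{self.spec.fusion}, got {batch.shape}")
        return batch

    @staticmethod
    def _nchw(arr: np.ndarray) -> Tensor:
        return Tensor(np.ascontiguousarray(arr.transpose(0, 3, 1, 2)))

    def forward(self, batch: np.ndarray, training: bool = False) -> Tensor:
        """Fused (N, [T,] 66, 66, 4) batch -> logits Tensor (N, 4).

        The batch always carries the full 4 fused channels; the spec's
        fusion mode selects which channels each stream consumes.
        """
        batch = self._check_batch(batch)
        spec = self.spec
        streams = _split_streams(spec, batch)
        rng = self._dropout_rng
        if spec.backbone == "cnn":
            feats = [ext(self._nchw(s), rng, training)
                     for ext, s in zip(self.streams, streams)]
            if self.shared_dense is not None:
                from .autograd import dropout as _dropout
                h = self.shared_dense(concat(feats, axis=1)).relu()
                merged = _dropout(h, spec.cnn.dropout, rng, training)
            else:
                merged = feats[0]
        elif spec.backbone == "td_cnn_gru":
            outs = []
            for ext, gru, s in zip(self.streams, self.grus, streams):
                steps = [ext(self._nchw(s[:, t]), rng, training)
                         for t in range(spec.sequence_length)]
                outs.append(gru(steps))
            merged = outs[0] if len(outs) == 1 else concat(outs, axis=1)
        else:
            outs = []
            n = batch.shape[0]
            for enc, s in zip(self.encoders, streams):
                tokens = Tensor(s.reshape(n, spec.sequence_length, -1))
                outs.append(enc(tokens))
            merged = outs[0] if len(outs) == 1 else concat(outs, axis=1)
        return self.head(merged)

    def loss(self, batch: np.ndarray, labels: np.ndarray,
             training: bool = True) -> Tensor:
        return softmax_cross_entropy(self.forward(batch, training), labels)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities (N, 4); dropout off, rows sum to 1."""
        logits = self.forward(batch, training=False)
        return np_softmax(logits.data, axis=1)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return self.predict_proba(batch).argmax(axis=1)


def build_model(spec: ModelSpec, seed: int = 0) -> FusionClassifier:
    """Instantiate a trainable classifier from a declarative spec."""
    return FusionClassifier(spec, seed=seed)


def predict(classifier: FusionClassifier, batch: np.ndarray) -> np.ndarray:
    """Per-item probability vectors for a batch (functional convenience)."""
    return classifier.predict_proba(batch)
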