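"""On-disk dataset layout, reports and run configuration.

Layout per sequence directory::

    index.csv                 # time_index, is_day, stage, rgb_path, depth_path
    rgb_0000.png   ...        # 8-bit RGB, day frames only
    depth_0000.png ...        # 16-bit grayscale, 1 unit = 1 mm, 0 = missing

The 0 sentinel makes missing pixels survive the round trip; valid depth is
stored to the nearest millimetre.  A dataset root additionally carries one
``manifest.json`` (see :class:`~seedlingrgbd.simulate.DatasetManifest`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .records import DepthMap, Frame, GrowthStage, SequenceRecord, TRANSITIONS

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_report",
    "config_hash",
    "RunConfig",
]


def _write_depth_png(depth: DepthMap, path: Path) -> None:
    vals = np.round(depth.values).astype(np.int64)
    vals = np.clip(vals, 1, 65535)  # 0 is reserved for the missing sentinel
    vals[depth.missing_mask] = 0
    Image.fromarray(vals.astype(np.uint16)).save(path)


def _read_depth_png(path: Path) -> DepthMap:
    arr = np.asarray(Image.open(path)).astype(np.uint16)
    mask = arr == 0
    return DepthMap(arr.astype(np.float64), mask)


def write_sequence(seq: SequenceRecord, out_dir, write_images: bool = True) -> Path:
    """Write one sequence directory; returns the path of its CSV index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in seq.frames:
        rgb_path = f"rgb_{f.time_index:04d}.png" if f.is_day else ""
        depth_path = f"depth_{f.time_index:04d}.png"
        if write_images:
            if f.is_day:
                Image.fromarray(f.rgb).save(out / rgb_path)
            _write_depth_png(f.depth, out / depth_path)
        rows.append({
            "time_index": f.time_index,
            "is_day": int(f.is_day),
            "stage": f.stage.name,
            "rgb_path": rgb_path,
            "depth_path": depth_path,
        })
    csv_path = out / "index.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path


def read_sequence(seq_dir, *, variety: str | None = None,
                  pot_id: str | None = None) -> SequenceRecord:
    """Load a sequence directory back into memory.

    Frames are returned ordered by time_index regardless of CSV row order;
    depth PNG value 0 decodes to a missing pixel.  Switch times are
    reconstructed from the label column (first frame of each new stage).
    """
    seq_dir = Path(seq_dir)
    csv_path = seq_dir / "index.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no index.csv in {seq_dir}")
    df = pd.read_csv(csv_path, keep_default_na=False)
    df = df.sort_values("time_index")
    frames: list[Frame] = []
    for row in df.itertuples(index=False):
        stage = GrowthStage.from_name(str(row.stage))
        depth_file = seq_dir / row.depth_path
        if not depth_file.exists():
            raise FileNotFoundError(f"missing depth frame {depth_file}")
        depth = _read_depth_png(depth_file)
        rgb = None
        if int(row.is_day):
            rgb_file = seq_dir / row.rgb_path
            if not rgb_file.exists():
                raise FileNotFoundError(f"missing RGB frame {rgb_file}")
            rgb = np.asarray(Image.open(rgb_file).convert("RGB"))
        frames.append(Frame(depth=depth, time_index=int(row.time_index),
                            is_day=bool(int(row.is_day)), stage=stage, rgb=rgb))
    switch_times = {}
    for (a, b) in TRANSITIONS:
        for prev, cur in zip(frames, frames[1:]):
            if prev.stage == a and cur.stage == b:
                switch_times[(a, b)] = cur.time_index
                break
    return SequenceRecord(frames=frames,
                          variety=variety or seq_dir.parent.name,
                          pot_id=pot_id or seq_dir.name,
                          switch_times=switch_times)


def config_hash(config) -> str:
    """Stable short hash of a (nested) configuration mapping."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(results, path, *, config=None, seeds=None) -> Path:
    """Write an analysis report as JSON (or CSV for tabular results).

    JSON reports embed the configuration hash and the seeds used, so any
    result file identifies the run that produced it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".csv":
        pd.DataFrame(results).to_csv(path, index=False)
        return path
    payload = {
        "config_hash": config_hash(config) if config is not None else None,
        "seeds": list(seeds) if seeds is not None else None,
        "results": results,
    }
    path.write_text(json.dumps(payload, indent=1, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialise {type(obj)}")


@dataclass
class RunConfig:
    """Top-level configuration for a CLI run; round-trips through YAML."""

    data_dir: str = "dataset"
    out_dir: str = "outputs"
    checkpoint_dir: str = "checkpoints"
    preset: str = "default"
    seed: int = 0
    verbosity: str = "info"
    scene: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    night: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def hash(self) -> str:
        return config_hash(self)
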