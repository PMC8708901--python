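"""RGB-D preprocessing: depth inpainting, channel scaling, windowing, flips.

Depth inpainting is a deterministic boundary-propagation fill: missing
pixels adjacent to valid ones are replaced by the mean of their valid
8-neighbours, and the front sweeps inwards until the mask is empty.  The
fill is conservative — valid pixels are bit-identical before and after —
and bounded: every filled value lies inside the [min, max] of the valid
pixels bordering the hole.

Channel scaling maps RGB to [0, 1] by /255 and depth affinely to [0, 1]
using a *dataset-level* (train-split) min/max, applied unchanged to the
validation and test splits so that no per-frame statistics leak labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .records import DepthMap, Frame, GrowthStage, SequenceRecord

__all__ = [
    "inpaint_depth",
    "DepthScaler",
    "FusedInput",
    "Window",
    "scale_channels",
    "window_sequence",
    "augment_flip",
]

_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)


def inpaint_depth(depth: DepthMap) -> DepthMap:
    """Fill missing depth pixels from their valid neighbourhood.

    Raises ValueError on an all-missing frame (there is nothing to
    propagate from).
    """
    if not depth.has_missing:
        return depth.copy()
    valid = ~depth.missing_mask
    if not valid.any():
        raise ValueError("cannot inpaint an all-missing depth frame")
    values = depth.values.copy()
    values[~valid] = 0.0
    while not valid.all():
        vsum = ndimage.convolve(values * valid, _NEIGH, mode="constant")
        vcnt = ndimage.convolve(valid.astype(np.float64), _NEIGH, mode="constant")
        front = ~valid & (vcnt > 0)
        values[front] = vsum[front] / vcnt[front]
        valid |= front
    return DepthMap(values, np.zeros_like(valid))


@dataclass
class DepthScaler:
    """Dataset-global affine depth normalisation (mm -> [0, 1])."""

    dmin: float = 0.0
    dmax: float = 1000.0

    @classmethod
    def fit(cls, depth_maps) -> "DepthScaler":
        """Estimate min/max over an iterable of (inpainted) DepthMaps."""
        lo, hi = np.inf, -np.inf
        for d in depth_maps:
            v = d.values if isinstance(d, DepthMap) else np.asarray(d)
            lo = min(lo, float(v.min()))
            hi = max(hi, float(v.max()))
        if not np.isfinite(lo):
            raise ValueError("cannot fit a DepthScaler on an empty collection")
        return cls(dmin=lo, dmax=hi)

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.dmax == self.dmin:
            warnings.warn("degenerate depth range; depth channel set to 0.5")
            return np.full_like(np.asarray(values, dtype=np.float64), 0.5)
        return (np.asarray(values, dtype=np.float64) - self.dmin) / (self.dmax - self.dmin)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=np.float64) * (self.dmax - self.dmin) + self.dmin


@dataclass
class FusedInput:
    """A single 4-channel (R, G, B, D) frame scaled to [0, 1]."""

    channels: np.ndarray
    scaler: DepthScaler = field(default_factory=DepthScaler)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[2] != 4:
            raise ValueError("FusedInput needs an (H, W, 4) channel stack")
        if np.isnan(self.channels).any():
            raise ValueError("FusedInput must not contain missing values")

    @property
    def rgb(self) -> np.ndarray:
        return self.channels[:, :, :3]

    @property
    def depth(self) -> np.ndarray:
        return self.channels[:, :, 3]

    def depth_mm(self) -> np.ndarray:
        """Invert the affine depth scaling back to millimetres."""
        return self.scaler.inverse(self.depth)


def scale_channels(rgb: np.ndarray, depth: DepthMap | np.ndarray,
                   scaler: DepthScaler) -> FusedInput:
    """Stack one RGB frame and one inpainted depth frame into a FusedInput."""
    if isinstance(depth, DepthMap):
        if depth.has_missing:
            raise ValueError("depth must be inpainted before scaling")
        depth = depth.values
    rgb = np.asarray(rgb, dtype=np.float64) / 255.0
    d = scaler.transform(depth)
    if rgb.shape[:2] != d.shape:
        raise ValueError("rgb and depth must share spatial shape")
    return FusedInput(np.concatenate([rgb, d[:, :, None]], axis=2), scaler)


@dataclass
class Window:
    """Four consecutive day frames, labelled by the stage of the last one."""

    inputs: list[FusedInput]
    stage: GrowthStage
    time_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.inputs) < 1:
            raise ValueError("a window needs at least one frame")

    def __len__(self) -> int:
        return len(self.inputs)

    def stack(self) -> np.ndarray:
        """(T, H, W, 4) array of the window's fused frames."""
        return np.stack([fi.channels for fi in self.inputs])


def window_sequence(seq: SequenceRecord, scaler: DepthScaler,
                    length: int = 4, stride: int = 1,
                    span_nights: bool = True) -> list[Window]:
    """Slide fixed-length windows over a sequence's day frames.

    Day frames are taken in order; night frames never enter windows.  By
    default consecutive *day* frames may bridge a night gap (the camera's
    day sampling is treated as one stream, giving ``(n_day-length)//stride
    + 1`` windows); with ``span_nights=False`` windows are restricted to
    runs of day frames that are consecutive in time_index.
    """
    if length < 1 or stride < 1:
        raise ValueError("length and stride must be >= 1")
    days = seq.day_frames
    fused = [scale_channels(f.rgb, inpaint_depth(f.depth), scaler) for f in days]
    if span_nights:
        runs = [list(range(len(days)))]
    else:
        runs, cur = [], [0]
        for i in range(1, len(days)):
            if days[i].time_index == days[i - 1].time_index + 1:
                cur.append(i)
            else:
                runs.append(cur)
                cur = [i]
        runs.append(cur)
    windows: list[Window] = []
    for run in runs:
        for start in range(0, len(run) - length + 1, stride):
            idx = run[start : start + length]
            windows.append(Window(
                inputs=[fused[i] for i in idx],
                stage=days[idx[-1]].stage,
                time_indices=[days[i].time_index for i in idx],
            ))
    return windows


def _flip_fused(fi: FusedInput) -> FusedInput:
    return FusedInput(fi.channels[:, ::-1, :].copy(), fi.scaler)


def augment_flip(item):
    """Horizontal mirror, applied identically to RGB and depth channels.

    Accepts a FusedInput, Window, Frame or SequenceRecord and returns a new
    object of the same type; labels are unchanged.  Flipping twice is the
    identity.
    """
    if isinstance(item, FusedInput):
        return _flip_fused(item)
    if isinstance(item, Window):
        return Window([_flip_fused(fi) for fi in item.inputs], item.stage,
                      list(item.time_indices))
    if isinstance(item, Frame):
        depth = DepthMap(item.depth.values[:, ::-1].copy(),
                         item.depth.missing_mask[:, ::-1].copy())
        rgb = item.rgb[:, ::-1, :].copy() if item.rgb is not None else None
        return Frame(depth=depth, time_index=item.time_index,
                     is_day=item.is_day, stage=item.stage, rgb=rgb)
    if isinstance(item, SequenceRecord):
        return SequenceRecord([augment_flip(f) for f in item.frames],
                              variety=item.variety, pot_id=item.pot_id,
                              switch_times=dict(item.switch_times))
    raise TypeError(f"cannot flip object of type {type(item).__name__}")
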