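"""Core domain types: growth stages, depth maps, frames and pot sequences.

A *sequence* is one pot followed through a full time-lapse run at one frame
per 15 minutes.  RGB images exist only while the growth-chamber lights are
on (the photoperiod); the active-IR depth channel is available day and
night.  Growth stages form a total order::

    SOIL < FA < OC < FL

(soil, first appearance of the cotyledon, opening of the cotyledons,
appearance of the first leaf).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthStage",
    "TRANSITIONS",
    "DepthMap",
    "Frame",
    "SequenceRecord",
]


class GrowthStage(enum.IntEnum):
    """Ordered developmental stage of a seedling seen from the top."""

    SOIL = 0
    FA = 1  # first appearance of the cotyledon
    OC = 2  # opening of the cotyledons
    FL = 3  # appearance of the first leaf

    @classmethod
    def from_name(cls, name: str) -> "GrowthStage":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown growth stage {name!r}; expected one of "
                f"{[s.name for s in cls]}"
            ) from None


#: The three stage transitions, in developmental order.
TRANSITIONS: tuple[tuple[GrowthStage, GrowthStage], ...] = (
    (GrowthStage.SOIL, GrowthStage.FA),
    (GrowthStage.FA, GrowthStage.OC),
    (GrowthStage.OC, GrowthStage.FL),
)


def parse_transition(spec) -> tuple[GrowthStage, GrowthStage]:
    """Normalise a transition given as ``"FA:OC"``, ``("FA","OC")`` or stages."""
    if isinstance(spec, str):
        parts = spec.replace("->", ":").split(":")
        if len(parts) != 2:
            raise ValueError(f"cannot parse transition {spec!r}; use 'FA:OC'")
        a, b = (GrowthStage.from_name(p.strip()) for p in parts)
    else:
        a, b = spec
        a = GrowthStage(a) if not isinstance(a, str) else GrowthStage.from_name(a)
        b = GrowthStage(b) if not isinstance(b, str) else GrowthStage.from_name(b)
    if (a, b) not in TRANSITIONS:
        raise ValueError(f"{a.name}->{b.name} is not a valid stage transition")
    return a, b


@dataclass
class DepthMap:
    """Single-channel metric depth with an explicit missing-value mask.

    ``values`` holds camera-to-surface distance in millimetres (top-view
    geometry: plant growth *decreases* depth).  ``missing_mask`` is True
    where the sensor returned no valid reading.
    """

    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("depth values must be a 2-D array")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values shape")
        valid = ~self.missing_mask
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("valid depth pixels must be finite")
        if np.any(self.values[valid] < 0):
            raise ValueError("depth must be non-negative (camera distance, mm)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def copy(self) -> "DepthMap":
        return DepthMap(self.values.copy(), self.missing_mask.copy())


@dataclass
class Frame:
    """One time point of a pot: optional RGB, depth, and annotation.

    ``rgb`` is an (H, W, 3) uint8 array and is present iff ``is_day``:
    night frames carry depth only.
    """

    depth: DepthMap
    time_index: int
    is_day: bool
    stage: GrowthStage
    rgb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stage = GrowthStage(self.stage)
        if self.is_day and self.rgb is None:
            raise ValueError("day frames must carry an RGB image")
        if not self.is_day and self.rgb is not None:
            raise ValueError("night frames must not carry an RGB image")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb)
            if self.rgb.dtype != np.uint8:
                raise ValueError("rgb must be 8-bit (uint8)")
            if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
                raise ValueError("rgb must have shape (H, W, 3)")
            if self.rgb.shape[:2] != self.depth.shape:
                raise ValueError("rgb and depth must share spatial shape")


@dataclass
class SequenceRecord:
    """An ordered RGB-D frame series for one pot.

    ``switch_times`` maps each realised stage transition, e.g.
    ``(GrowthStage.FA, GrowthStage.OC)``, to the time_index of the first
    frame of the new stage.
    """

    frames: list[Frame]
    variety: str = "unknown"
    pot_id: str = "pot0"
    switch_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a sequence must contain at least one frame")
        t = [f.time_index for f in self.frames]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time_index must be strictly increasing")
        stages = [int(f.stage) for f in self.frames]
        if any(b < a for a, b in zip(stages, stages[1:])):
            raise ValueError("stage labels must be monotone non-decreasing")
        for (a, b), ti in self.switch_times.items():
            pos = next((i for i, f in enumerate(self.frames)
                        if f.time_index == ti), None)
            ok = (pos is not None and self.frames[pos].stage == b
                  and (pos == 0 or self.frames[pos - 1].stage == a))
            if not ok:
                raise ValueError(
                    f"switch_times entry {a.name}->{b.name} at t={ti} is "
                    "inconsistent with frame labels (must be the first "
                    f"frame of {b.name})"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def frame_at(self, time_index: int) -> Frame | None:
        for f in self.frames:
            if f.time_index == time_index:
                return f
        return None

    @property
    def day_frames(self) -> list[Frame]:
        return [f for f in self.frames if f.is_day]

    @property
    def night_frames(self) -> list[Frame]:
        return [f for f in self.frames if not f.is_day]

    @property
    def n_day(self) -> int:
        return sum(1 for f in self.frames if f.is_day)

    @property
    def n_night(self) -> int:
        return len(self.frames) - self.n_day

    def stages(self) -> np.ndarray:
        return np.array([int(f.stage) for f in self.frames])
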