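"""Synthetic RGB-Depth seedling time-lapse generator.

Emulates the statistical structure of a top-view growth-chamber dataset:
66x66 registered RGB-D pot crops at one frame per 15 min, a 16 h / 8 h
photoperiod (64 day frames / 32 night frames per cycle), four ordered
growth stages, an *abrupt* depth step when the cotyledons open (the canopy
rises several millimetres over >=10 % of the pixels, i.e. the camera
distance drops), *gradual* RGB appearance change within every stage,
per-pixel depth noise, missing-value artifacts (i.i.d. dropouts plus
occasional reflectance-like blobs), and no RGB at night.

The generator is the test-bed for the whole pipeline: every downstream
stage (preprocessing, fusion classifiers, night-event detection) is
exercised against sequences produced here, with the true switch frames
recorded at generation time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .records import TRANSITIONS, DepthMap, Frame, GrowthStage, SequenceRecord, parse_transition

__all__ = [
    "SceneParams",
    "VARIETIES",
    "DatasetManifest",
    "NoSuchEvent",
    "generate_sequence",
    "generate_dataset",
    "generate_switch_episode",
    "plant_switch_oracle",
    "table1_config",
]

#: The six bean varieties of the emulated study, with per-variety
#: heterogeneity of cotyledon size, shape (ellipse aspect) and hue.
VARIETIES: dict[str, dict] = {
    "Flavert": {"size": 1.00, "aspect": 1.00, "hue": 0},
    "RedHawk": {"size": 1.12, "aspect": 0.85, "hue": -15},
    "Linex": {"size": 0.90, "aspect": 1.15, "hue": 10},
    "Caprice": {"size": 1.05, "aspect": 0.95, "hue": 20},
    "Deezer": {"size": 0.85, "aspect": 1.10, "hue": -8},
    "Vanilla": {"size": 1.15, "aspect": 1.05, "hue": 15},
}


class NoSuchEvent(KeyError):
    """Raised when a queried stage transition never occurs in a sequence."""


@dataclass
class SceneParams:
    """Parameters of the synthetic scene and acquisition.

    Depth convention: values are camera-to-surface distance in mm, so a
    growing plant *decreases* depth.  Defaults emulate the study setting:
    616 frames per sequence (424 day + 192 night), a ~10 mm canopy rise at
    cotyledon opening covering >=10 % of the 66x66 pixels, ~2 mm per-pixel
    depth noise (low-cost active-IR sensor), and ~2 % missing pixels.
    """

    height: int = 66
    width: int = 66
    frames_day: int = 424
    frames_night: int = 192
    day_block: int = 64  # 16 h photoperiod at 15 min / frame
    night_block: int = 32  # 8 h night
    camera_distance_mm: float = 500.0
    soil_depth_texture_mm: float = 0.8
    fa_height_mm: float = 3.0
    oc_depth_step_mm: float = 10.0
    fl_extra_height_mm: float = 2.0
    fa_radius_px: float = 5.0
    oc_radius_px: float = 14.0
    fl_lobe_radius_px: float = 6.0
    depth_noise_std_mm: float = 2.0
    missing_prob: float = 0.02
    missing_blob_prob: float = 0.10  # per-frame chance of one contiguous blob
    missing_blob_radius_px: float = 5.0
    # Mean stage durations in frames (FL lasts until the end of the run);
    # actual durations are drawn uniformly within +-30 % of the mean.
    soil_frames_mean: float = 180.0
    fa_frames_mean: float = 140.0
    oc_frames_mean: float = 140.0
    duration_jitter: float = 0.30
    # RGB contrast of the OC transition; 0 makes cotyledon opening
    # invisible in RGB (depth-coded preset used for fusion-benefit checks).
    oc_rgb_contrast: float = 1.0

    def __post_init__(self) -> None:
        for name in ("missing_prob", "missing_blob_prob", "duration_jitter",
                     "oc_rgb_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("height", "width", "frames_day", "day_block",
                     "night_block", "camera_distance_mm", "fa_height_mm",
                     "oc_depth_step_mm", "fl_extra_height_mm",
                     "fa_radius_px", "oc_radius_px", "fl_lobe_radius_px",
                     "soil_frames_mean", "fa_frames_mean", "oc_frames_mean"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("frames_night", "depth_noise_std_mm",
                     "soil_depth_texture_mm", "missing_blob_radius_px"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n_frames(self) -> int:
        return self.frames_day + self.frames_night

    def replace(self, **kw) -> "SceneParams":
        return dataclasses.replace(self, **kw)


def _day_flags(params: SceneParams) -> np.ndarray:
    """Boolean is_day vector: 64-day/32-night blocks, leftovers appended."""
    flags: list[bool] = []
    day_left, night_left = params.frames_day, params.frames_night
    while day_left > 0 or night_left > 0:
        take = min(params.day_block, day_left)
        flags.extend([True] * take)
        day_left -= take
        take = min(params.night_block, night_left)
        flags.extend([False] * take)
        night_left -= take
    return np.array(flags, dtype=bool)


def _sample_switch_times(params: SceneParams, rng: np.random.Generator) -> list[int]:
    """Frame indices of the first FA, OC and FL frame (clipped to the run)."""
    j = params.duration_jitter
    durations = [
        rng.uniform(1 - j, 1 + j) * params.soil_frames_mean,
        rng.uniform(1 - j, 1 + j) * params.fa_frames_mean,
        rng.uniform(1 - j, 1 + j) * params.oc_frames_mean,
    ]
    times, acc = [], 0.0
    for d in durations:
        acc += d
        times.append(int(round(acc)))
    return times


def _stage_of(t: int, switch_times: list[int]) -> GrowthStage:
    s = 0
    for st in switch_times:
        if t >= st:
            s += 1
    return GrowthStage(min(s, 3))


def _ellipse(params: SceneParams, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    return ((xx - cx) / max(rx, 1e-6)) ** 2 + ((yy - cy) / max(ry, 1e-6)) ** 2 <= 1.0


def _stage_height_maps(params: SceneParams, variety: dict, rng: np.random.Generator) -> list[np.ndarray]:
    """Canopy height above soil (mm) for each stage; constant within a stage."""
    size, aspect = variety["size"], variety["aspect"]
    cx = params.width / 2 + rng.uniform(-3, 3)
    cy = params.height / 2 + rng.uniform(-3, 3)
    h, w = params.height, params.width
    zero = np.zeros((h, w))
    fa_r = params.fa_radius_px * size
    fa = np.where(_ellipse(params, cx, cy, fa_r * aspect, fa_r / aspect),
                  params.fa_height_mm, 0.0)
    oc_r = params.oc_radius_px * size
    oc_mask = _ellipse(params, cx, cy, oc_r * aspect, oc_r / aspect)
    oc = np.where(oc_mask, params.fa_height_mm + params.oc_depth_step_mm, 0.0)
    ang = rng.uniform(0, 2 * np.pi)
    lr = params.fl_lobe_radius_px * size
    off = oc_r * 0.9
    lobe = _ellipse(params, cx + off * np.cos(ang), cy + off * np.sin(ang), lr, lr)
    fl = oc + np.where(lobe, params.fl_extra_height_mm, 0.0) \
        + np.where(oc_mask, params.fl_extra_height_mm * 0.5, 0.0)
    return [zero, fa, oc, fl]


_SOIL_RGB = np.array([118.0, 86.0, 62.0])
_STAGE_RGB = {
    GrowthStage.FA: np.array([46.0, 98.0, 44.0]),
    GrowthStage.OC: np.array([52.0, 150.0, 56.0]),
    GrowthStage.FL: np.array([70.0, 170.0, 80.0]),
}


def _rgb_frame(params: SceneParams, variety: dict, stage: GrowthStage,
               frac: float, geom: dict, soil_tex: np.ndarray) -> np.ndarray:
    """Render the RGB appearance; `frac` in [0,1] is progress within stage.

    RGB changes gradually in every stage (the blob widens and greens as the
    stage progresses) while the depth footprint is stage-constant.  With
    oc_rgb_contrast = 0 the OC stage keeps the fully-grown FA appearance,
    so cotyledon opening is visible in depth only.
    """
    img = _SOIL_RGB[None, None, :] + soil_tex[:, :, None]
    hue = variety["hue"]
    tint = np.array([hue * 0.3, hue, hue * 0.2])
    if stage != GrowthStage.SOIL:
        size, aspect = variety["size"], variety["aspect"]
        cx, cy = geom["cx"], geom["cy"]

        def paint(r_full: float, colour: np.ndarray, grow: float,
                  dx: float = 0.0, dy: float = 0.0) -> None:
            r = r_full * size * (0.45 + 0.55 * grow)
            m = _ellipse(params, cx + dx, cy + dy, r * aspect, r / aspect)
            img[m] = colour + tint

        if stage == GrowthStage.FA:
            paint(params.fa_radius_px, _STAGE_RGB[GrowthStage.FA], frac)
        elif stage == GrowthStage.OC:
            c = params.oc_rgb_contrast
            # blend between "still looks like full-grown FA" (c=0) and the
            # wide bright open-cotyledon appearance (c=1)
            r = params.fa_radius_px + c * (params.oc_radius_px - params.fa_radius_px)
            colour = (1 - c) * _STAGE_RGB[GrowthStage.FA] + c * _STAGE_RGB[GrowthStage.OC]
            paint(r, colour, 1.0 if c == 0 else frac if c == 1 else max(frac, 1 - c))
        else:  # FL
            paint(params.oc_radius_px, _STAGE_RGB[GrowthStage.OC], 1.0)
            ang, off = geom["lobe_ang"], params.oc_radius_px * size * 0.9
            paint(params.fl_lobe_radius_px, _STAGE_RGB[GrowthStage.FL], frac,
                  dx=off * np.cos(ang), dy=off * np.sin(ang))
    return np.clip(img, 0, 255).astype(np.uint8)


def _missing_mask(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random((params.height, params.width)) < params.missing_prob
    if params.missing_blob_prob > 0 and rng.random() < params.missing_blob_prob:
        cx = rng.uniform(0, params.width)
        cy = rng.uniform(0, params.height)
        r = params.missing_blob_radius_px * rng.uniform(0.5, 1.5)
        mask |= _ellipse(params, cx, cy, r, r)
    return mask


def generate_sequence(params: SceneParams, seed: int, *, variety: str = "Flavert",
                      pot_id: str = "pot0",
                      forced_switch_times: list[int] | None = None) -> SequenceRecord:
    """Generate one labelled RGB-D pot sequence.

    Deterministic: the same (params, seed, variety) yields bit-identical
    frames.  ``forced_switch_times`` overrides the sampled [FA, OC, FL]
    onset frames (used to place a switch inside a night).
    """
    if variety not in VARIETIES:
        raise ValueError(f"unknown variety {variety!r}; known: {sorted(VARIETIES)}")
    vparams = VARIETIES[variety]
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 17]))
    flags = _day_flags(params)
    switch_times = (list(forced_switch_times) if forced_switch_times is not None
                    else _sample_switch_times(params, rng))
    if len(switch_times) != 3 or any(b <= a for a, b in zip(switch_times, switch_times[1:])):
        raise ValueError("switch times must be three increasing frame indices")

    soil_tex_rgb = ndimage.gaussian_filter(rng.standard_normal((params.height, params.width)), 2.0) * 18.0
    soil_tex_depth = ndimage.gaussian_filter(rng.standard_normal((params.height, params.width)), 3.0)
    soil_tex_depth *= params.soil_depth_texture_mm
    heights = _stage_height_maps(params, vparams, rng)
    geom = {
        "cx": params.width / 2, "cy": params.height / 2,
        "lobe_ang": rng.uniform(0, 2 * np.pi),
    }

    stage_bounds = [0] + [min(t, params.n_frames) for t in switch_times] + [params.n_frames]
    frames: list[Frame] = []
    for t in range(params.n_frames):
        stage = _stage_of(t, switch_times)
        base = params.camera_distance_mm + soil_tex_depth - heights[int(stage)]
        if params.depth_noise_std_mm > 0:
            base = base + rng.normal(0.0, params.depth_noise_std_mm, base.shape)
        mask = _missing_mask(params, rng) if params.missing_prob > 0 or params.missing_blob_prob > 0 \
            else np.zeros(base.shape, dtype=bool)
        depth = DepthMap(np.clip(base, 0.0, None), mask)
        rgb = None
        if flags[t]:
            lo, hi = stage_bounds[int(stage)], stage_bounds[int(stage) + 1]
            frac = float(np.clip((t - lo) / max(hi - 1 - lo, 1), 0.0, 1.0))
            rgb = _rgb_frame(params, vparams, stage, frac, geom, soil_tex_rgb)
        frames.append(Frame(depth=depth, time_index=t, is_day=bool(flags[t]),
                            stage=stage, rgb=rgb))

    realised: dict[tuple[GrowthStage, GrowthStage], int] = {}
    for (a, b), t in zip(TRANSITIONS, switch_times):
        if 0 < t < params.n_frames:
            realised[(a, b)] = t
    return SequenceRecord(frames=frames, variety=variety, pot_id=pot_id,
                          switch_times=realised)


def plant_switch_oracle(seq: SequenceRecord, transition) -> int:
    """Ground-truth time_index of a stage transition, recorded at generation.

    Raises :class:`NoSuchEvent` if the transition never occurs.
    """
    key = parse_transition(transition)
    if key not in seq.switch_times:
        raise NoSuchEvent(
            f"transition {key[0].name}->{key[1].name} does not occur in this sequence"
        )
    return seq.switch_times[key]


def generate_switch_episode(params: SceneParams, seed: int, *,
                            transition="FA:OC", variety: str = "Flavert",
                            night_offset: int | None = None) -> SequenceRecord:
    """Generate a short sequence with exactly one switch placed in a night.

    The sequence spans one day block, one night block and one day block;
    ``night_offset`` (default: drawn uniformly from [0, night_block-5])
    places the switch that many frames into the night.  Used to exercise
    the depth-only night detector against known ground truth.
    """
    a, b = parse_transition(transition)
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)), 23]))
    p = params.replace(frames_day=2 * params.day_block, frames_night=params.night_block)
    if night_offset is None:
        night_offset = int(rng.integers(0, p.night_block - 4))
    if not 0 <= night_offset <= p.night_block - 1:
        raise ValueError("night_offset outside the night block")
    t_switch = p.day_block + night_offset
    # onset times for FA, OC, FL: place the requested switch at t_switch,
    # earlier stages before frame 0, later stages past the end
    n = p.n_frames
    onsets = {GrowthStage.FA: n + 1, GrowthStage.OC: n + 2, GrowthStage.FL: n + 3}
    order = [GrowthStage.FA, GrowthStage.OC, GrowthStage.FL]
    bi = order.index(b)
    for s in order[:bi]:
        onsets[s] = -1  # already reached before the episode starts
    onsets[b] = t_switch
    forced = [onsets[GrowthStage.FA], onsets[GrowthStage.OC], onsets[GrowthStage.FL]]
    # shift "already reached" onsets to distinct negative values for ordering
    forced = [(-3 + i) if v == -1 else v for i, v in enumerate(forced)]
    return generate_sequence(params.replace(frames_day=p.frames_day,
                                            frames_night=p.frames_night),
                             seed, variety=variety,
                             forced_switch_times=forced)


# ---------------------------------------------------------------------------
# dataset-level generation


@dataclass
class DatasetManifest:
    """Per-split, per-variety inventory of generated sequences."""

    root: str
    splits: dict[str, list[dict]] = field(default_factory=dict)

    def sequences(self, split: str) -> list[dict]:
        return self.splits.get(split, [])

    def n_images(self, split: str) -> int:
        return sum(e["n_day"] + e["n_night"] for e in self.splits.get(split, []))

    def validate(self) -> None:
        seen: set[str] = set()
        for split, entries in self.splits.items():
            for e in entries:
                if e["path"] in seen:
                    raise ValueError(f"sequence {e['path']} appears in two splits")
                seen.add(e["path"])

    def to_dict(self) -> dict:
        return {"root": self.root, "splits": self.splits}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(root=d["root"], splits=d["splits"])


def table1_config() -> dict:
    """The study-scale dataset layout: 6 varieties x (10 train + 1 val + 1 test)."""
    return {
        "varieties": sorted(VARIETIES),
        "sequences_per_variety": {"train": 10, "validation": 1, "test": 1},
    }


def generate_dataset(config: dict, out_dir, seed: int,
                     params: SceneParams | None = None,
                     write_images: bool = True) -> DatasetManifest:
    """Generate a full train/validation/test dataset on disk.

    ``config`` lists varieties and per-variety sequence counts per split
    (see :func:`table1_config`).  Each sequence goes to
    ``<out>/<split>/<variety>/<pot_id>/`` as PNG frames plus a CSV index;
    a JSON manifest is written at the root.  With ``write_images=False``
    only the CSV indexes and manifest are written (frame files are listed
    but not rendered) — useful for layout checks.
    """
    from . import dataio  # local import: dataio imports records only

    params = params or SceneParams()
    out = Path(out_dir)
    varieties = config["varieties"]
    spv = config["sequences_per_variety"]
    unknown = set(varieties) - set(VARIETIES)
    if unknown:
        raise ValueError(f"unknown varieties in config: {sorted(unknown)}")
    manifest = DatasetManifest(root=str(out), splits={s: [] for s in spv})
    counter = 0
    for split, n_seq in spv.items():
        for variety in varieties:
            for i in range(n_seq):
                pot_id = f"{variety}_{split}_{i:02d}"
                seq_seed = abs(int(seed)) * 100003 + counter
                counter += 1
                seq = generate_sequence(params, seq_seed, variety=variety,
                                        pot_id=pot_id)
                seq_dir = out / split / variety / pot_id
                dataio.write_sequence(seq, seq_dir, write_images=write_images)
                manifest.splits[split].append({
                    "variety": variety,
                    "pot_id": pot_id,
                    "path": str(seq_dir.relative_to(out)),
                    "n_day": seq.n_day,
                    "n_night": seq.n_night,
                    "seed": seq_seed,
                    "switch_times": {f"{a.name}:{b.name}": t
                                     for (a, b), t in seq.switch_times.items()},
                })
    manifest.validate()
    out.mkdir(parents=True, exist_ok=True)
    manifest.save(out / "manifest.json")
    return manifest
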