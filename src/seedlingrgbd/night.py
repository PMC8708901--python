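"""Depth-only detection of growth-stage switches during the night.

RGB cameras are blind during the dark period, so a stage switch that
happens at night is only seen by RGB annotation on the first frame of the
next day — up to 8 h late.  The depth channel keeps recording, and the
opening of the cotyledons (in particular) raises the canopy abruptly,
dropping the spatial-mean camera distance by several millimetres.  The
detector localises the switch frame inside the night from depth alone:

1. compute the spatial mean depth of every frame of the last day at stage
   A (``Sa``), of the night (``Snight``) and of the first day at stage B
   (``Sb``);
2. average the day series into the stage levels ``MDA`` and ``MDB``;
3. for each night frame k, compare closeness ``GA(k) = |DN(k) - MDA|``
   against ``GB(k) = |DN(k) - MDB|``;
4. mark k with 1 when the frame is strictly closer to stage B, and report
   the first frame of the first run of four consecutive 1s (one hour of
   frames), i.e. the first time the depth is *persistently* closer to the
   next stage;
5. the switch time ``Pt`` is that index plus ``len(Sa)`` (0-based into the
   concatenation Sa || Snight).

Note on the closeness step: comparing the *signed* differences
``DN - MDA`` and ``DN - MDB`` is degenerate — their difference is the
constant ``MDB - MDA`` whatever the night frame — so closeness must be
measured with absolute differences.  :func:`literal_sign_bin` exposes the
signed variant purely to document that pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import inpaint_depth
from .records import DepthMap, SequenceRecord, parse_transition
from .simulate import NoSuchEvent

__all__ = ["NightEventInputs", "NightEventTrace", "NightValidationReport",
           "spatial_mean", "detect_night_switch", "literal_sign_bin",
           "extract_night_episode", "make_daylight_pseudo_episodes",
           "validate_on_daylight"]


def _as_array(frame) -> np.ndarray:
    if isinstance(frame, DepthMap):
        if frame.has_missing:
            raise ValueError(
                "depth frame contains missing values; inpaint before the "
                "night detector (preprocess.inpaint_depth)")
        return frame.values
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("depth frames must be 2-D")
    if np.isnan(arr).any():
        raise ValueError(
            "depth frame contains missing values; inpaint before the "
            "night detector (preprocess.inpaint_depth)")
    return arr


def spatial_mean(frame) -> float:
    """Arithmetic mean depth (mm) over all pixels of one inpainted frame."""
    return float(_as_array(frame).mean())


@dataclass
class NightEventInputs:
    """Depth frames around one night: last day at stage A, the night, first
    day at stage B.  All frames must be inpainted and share one shape."""

    sa: list
    snight: list
    sb: list

    def __post_init__(self) -> None:
        for name in ("sa", "snight", "sb"):
            seq = getattr(self, name)
            if len(seq) == 0:
                raise ValueError(f"{name} must be non-empty")
            setattr(self, name, [_as_array(f) for f in seq])
        shapes = {a.shape for part in (self.sa, self.snight, self.sb) for a in part}
        if len(shapes) != 1:
            raise ValueError(f"all frames must share one spatial shape, got {shapes}")


@dataclass
class NightEventTrace:
    """Every intermediate quantity of the night detector, for inspection."""

    da_bar: np.ndarray  # spatial mean of each Sa frame
    db_bar: np.ndarray  # spatial mean of each Sb frame
    dn_bar: np.ndarray  # spatial mean of each night frame
    mda: float  # temporal mean of da_bar (stage-A depth level)
    mdb: float  # temporal mean of db_bar (stage-B depth level)
    ga: np.ndarray  # |dn_bar - mda| per night frame
    gb: np.ndarray  # |dn_bar - mdb| per night frame
    bin: np.ndarray  # 1 where strictly closer to stage B
    idx: int | None  # first index of a run of `run_length` ones, or None
    pt: int | None  # idx + len(sa), or None when nothing was detected
    run_length: int = 4

    @property
    def detected(self) -> bool:
        return self.idx is not None


def detect_night_switch(inputs: NightEventInputs,
                        run_length: int = 4) -> NightEventTrace:
    """Locate the first night frame persistently closer to the next stage.

    Ties (equally close to both stages) count as "not yet closer to B".
    Returns a full trace; ``idx``/``pt`` are None when no run of
    ``run_length`` consecutive closer-to-B frames exists.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    if len(inputs.snight) < run_length:
        raise ValueError(
            f"night has {len(inputs.snight)} frames, fewer than the "
            f"required run of {run_length}")
    da_bar = np.array([a.mean() for a in inputs.sa])
    db_bar = np.array([a.mean() for a in inputs.sb])
    dn_bar = np.array([a.mean() for a in inputs.snight])
    mda = float(da_bar.mean())
    mdb = float(db_bar.mean())
    ga = np.abs(dn_bar - mda)
    gb = np.abs(dn_bar - mdb)
    binv = ((ga - gb) > 0).astype(np.int8)
    idx = None
    run = 0
    for k, v in enumerate(binv):
        run = run + 1 if v else 0
        if run == run_length:
            idx = k - run_length + 1
            break
    pt = None if idx is None else len(inputs.sa) + idx
    return NightEventTrace(da_bar, db_bar, dn_bar, mda, mdb, ga, gb, binv,
                           idx, pt, run_length)


def literal_sign_bin(inputs: NightEventInputs) -> np.ndarray:
    """The signed-difference variant, kept only to document its degeneracy.

    With ``GA = DN - MDA`` and ``GB = DN - MDB`` (no absolute values),
    ``GA - GB == MDB - MDA`` for every night frame: the sign vector is
    constant and carries no information about *when* the switch happened.
    """
    dn_bar = np.array([a.mean() for a in inputs.snight])
    mda = float(np.mean([a.mean() for a in inputs.sa]))
    mdb = float(np.mean([a.mean() for a in inputs.sb]))
    ga = dn_bar - mda
    gb = dn_bar - mdb
    return np.sign(ga - gb).astype(np.int8)


# ---------------------------------------------------------------------------
# episode extraction and validation


def _day_night_runs(seq: SequenceRecord) -> list[tuple[bool, list[int]]]:
    """Contiguous runs of frame positions sharing one day/night flag."""
    runs: list[tuple[bool, list[int]]] = []
    for i, f in enumerate(seq.frames):
        if runs and runs[-1][0] == f.is_day:
            runs[-1][1].append(i)
        else:
            runs.append((f.is_day, [i]))
    return runs


def extract_night_episode(seq: SequenceRecord, transition):
    """Build detector inputs for a switch that happened during a night.

    Returns ``(NightEventInputs, truth_offset)`` where ``truth_offset`` is
    the 0-based position of the true switch frame within the night.  Depth
    frames are inpainted here.  Raises :class:`NoSuchEvent` when the
    transition is absent and ValueError when it did not happen at night.
    """
    key = parse_transition(transition)
    if key not in seq.switch_times:
        raise NoSuchEvent(f"transition {key[0].name}->{key[1].name} absent")
    t_switch = seq.switch_times[key]
    pos = next(i for i, f in enumerate(seq.frames) if f.time_index == t_switch)
    if seq.frames[pos].is_day:
        raise ValueError("switch happened during the day; use the daylight "
                         "validation path instead")
    runs = _day_night_runs(seq)
    night_i = next(i for i, (day, idxs) in enumerate(runs)
                   if not day and pos in idxs)
    if night_i == 0 or night_i == len(runs) - 1:
        raise ValueError("switch night lacks a preceding or following day")
    a, b = key
    # Sa/Sb are by definition stage-A / stage-B frames; clip the adjacent
    # day runs so another switch in the same day cannot contaminate the
    # stage depth levels.
    sa_idx = [i for i in runs[night_i - 1][1] if seq.frames[i].stage == a]
    night_idx = runs[night_i][1]
    sb_idx = [i for i in runs[night_i + 1][1] if seq.frames[i].stage == b]
    if not sa_idx or not sb_idx:
        raise ValueError("adjacent days carry no frames at the switch stages")
    dep = [inpaint_depth(seq.frames[i].depth) for i in sa_idx + night_idx + sb_idx]
    n_sa, n_night = len(sa_idx), len(night_idx)
    inputs = NightEventInputs(sa=dep[:n_sa],
                              snight=dep[n_sa : n_sa + n_night],
                              sb=dep[n_sa + n_night :])
    return inputs, night_idx.index(pos)


def make_daylight_pseudo_episodes(seq: SequenceRecord, *,
                                  pseudo_night_len: int = 32,
                                  context_len: int = 64):
    """Turn annotated day-time switches into pseudo night episodes.

    Ground truth during real nights cannot be annotated from RGB, so the
    detector is validated on *daylight* switches instead: the depth frames
    of a window containing the switch are treated as the "night", the
    preceding frames as Sa and the following frames as Sb, and the
    detector sees depth only.  Yields ``(NightEventInputs, truth_offset,
    transition)`` tuples.
    """
    half = pseudo_night_len // 2
    n = len(seq.frames)
    for key, t_switch in sorted(seq.switch_times.items(), key=lambda kv: kv[1]):
        a, b = key
        pos = next(i for i, f in enumerate(seq.frames) if f.time_index == t_switch)
        if not seq.frames[pos].is_day:
            continue
        start = pos - half
        end = start + pseudo_night_len
        if start < 1 or end > n - 1:
            continue  # switch too close to the sequence boundary
        # context frames are restricted to the switch's own stages so a
        # neighbouring switch cannot contaminate the stage depth levels
        sa_idx = [i for i in range(max(start - context_len, 0), start)
                  if seq.frames[i].stage == a]
        sb_idx = [i for i in range(end, min(end + context_len, n))
                  if seq.frames[i].stage == b]
        if not sa_idx or not sb_idx:
            continue  # not enough context around this switch
        dep = [inpaint_depth(seq.frames[i].depth)
               for i in sa_idx + list(range(start, end)) + sb_idx]
        inputs = NightEventInputs(
            sa=dep[: len(sa_idx)],
            snight=dep[len(sa_idx) : len(sa_idx) + pseudo_night_len],
            sb=dep[len(sa_idx) + pseudo_night_len :])
        yield inputs, pos - start, key


@dataclass
class NightValidationReport:
    """Outcome of the daylight-ground-truth validation protocol."""

    n_events: int
    n_detected: int
    fraction_within_tolerance: float
    mean_abs_shift: float
    std_abs_shift: float
    tolerance: int
    events: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_detected": self.n_detected,
            "fraction_within_tolerance": self.fraction_within_tolerance,
            "mean_abs_shift": self.mean_abs_shift,
            "std_abs_shift": self.std_abs_shift,
            "tolerance": self.tolerance,
            "events": self.events,
        }


def _summarise(events: list[dict], tolerance: int) -> NightValidationReport:
    shifts = [e["abs_shift"] for e in events if e["detected"]]
    within = [e for e in events if e["detected"] and e["abs_shift"] <= tolerance]
    n = len(events)
    return NightValidationReport(
        n_events=n,
        n_detected=len(shifts),
        fraction_within_tolerance=(len(within) / n) if n else 0.0,
        mean_abs_shift=float(np.mean(shifts)) if shifts else float("nan"),
        std_abs_shift=float(np.std(shifts, ddof=1)) if len(shifts) > 1 else 0.0,
        tolerance=tolerance,
        events=events,
    )


def evaluate_episodes(episodes, run_length: int = 4,
                      tolerance: int = 4) -> NightValidationReport:
    """Run the detector on (inputs, truth_offset[, tag]) episodes and score."""
    events = []
    for ep in episodes:
        inputs, truth = ep[0], ep[1]
        tag = ep[2] if len(ep) > 2 else None
        trace = detect_night_switch(inputs, run_length=run_length)
        ev = {
            "transition": (f"{tag[0].name}:{tag[1].name}"
                           if isinstance(tag, tuple) else tag),
            "truth": int(truth),
            "detected": trace.detected,
            "idx": trace.idx,
            "pt": trace.pt,
            "abs_shift": abs(trace.idx - truth) if trace.detected else None,
        }
        events.append(ev)
    return _summarise(events, tolerance)


def validate_on_daylight(sequences, run_length: int = 4, tolerance: int = 4,
                         pseudo_night_len: int = 32,
                         context_len: int = 64) -> NightValidationReport:
    """Daylight-ground-truth validation over a collection of sequences.

    For every annotated day-time switch the depth channel around the
    switch is re-cast as a pseudo night episode and the detector's output
    is compared against the RGB-derived ground truth.  Reports the
    fraction of events localised within ``tolerance`` frames plus the mean
    and standard deviation of the absolute shift.  An input set without
    any usable switch yields an empty report (n_events = 0).
    """
    episodes = []
    for seq in sequences:
        episodes.extend(make_daylight_pseudo_episodes(
            seq, pseudo_night_len=pseudo_night_len, context_len=context_len))
    if not episodes:
        import warnings

        warnings.warn("no usable day-time switches found; empty report")
    return evaluate_episodes(episodes, run_length=run_length,
                             tolerance=tolerance)
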