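"""LED scheduling, frame-rate arithmetic and stream (de)multiplexing.

A RAP camera records one interleaved stream; which sample each frame shows is
set purely by which LED was lit.  For ``n`` samples in round-robin, each
sample is captured once every ``n`` frames, so the per-sample rate is
``base_fps / n``.  Block schedules interleave a subset of wells for a fixed
number of frames before moving on (e.g. 80 wells imaged 100 frames each in
rows of eight -> 8000 frames).  Demultiplexing splits the stream back into
per-sample stacks; remultiplexing is its exact inverse, used for round-trip
tests and simulation output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stacks import FrameStack

__all__ = [
    "LEDSchedule",
    "MultiplexedStream",
    "per_sample_fps",
    "max_parallel_samples",
    "bandwidth_limited_fps",
    "assay_duration",
    "make_schedule",
    "demultiplex",
    "remultiplex",
    "plate_well_ids",
]

_MB = 2**20  # binary MB: the convention under which a 1280x1024x1 B frame is 1.25 MB


def per_sample_fps(base_fps: float, n_samples: int) -> float:
    """Frame rate per sample when ``n_samples`` share a camera round-robin."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if base_fps <= 0:
        raise ValueError("base frame rate must be positive")
    return base_fps / n_samples


def max_parallel_samples(base_fps: float, per_well_fps: float) -> int:
    """How many samples can share the camera at a required per-well rate."""
    if per_well_fps <= 0 or base_fps <= 0:
        raise ValueError("frame rates must be positive")
    return int(base_fps // per_well_fps)


def bandwidth_limited_fps(
    disk_rate_mb_s: float, frame: tuple[int, int, int]
) -> float:
    """Sustained base frame rate imposed by disk throughput.

    ``frame`` is (width px, height px, bytes per pixel); frame size uses the
    binary-MB convention (2^20 bytes), under which a 1280x1024 single-byte
    frame is exactly 1.25 MB and 150 MB/s sustains 120 fps.
    """
    w, h, b = frame
    if disk_rate_mb_s <= 0 or w < 1 or h < 1 or b < 1:
        raise ValueError("disk rate and frame dimensions must be positive")
    frame_mb = w * h * b / _MB
    return disk_rate_mb_s / frame_mb


def assay_duration(
    n_wells: int, frames_per_well: int, base_fps: float
) -> tuple[int, float]:
    """Total frames and wall-clock seconds of a sequential-block assay.

    Returns ``(total_frames, seconds)``; e.g. 80 wells x 100 frames at a
    120 fps base rate is 8000 frames in 66.7 s (reported as 67 s).
    """
    if n_wells < 1 or frames_per_well < 0 or base_fps <= 0:
        raise ValueError("well count and frame rate must be positive")
    total = n_wells * frames_per_well
    return total, total / base_fps


@dataclass(frozen=True)
class LEDSchedule:
    """Assignment of stream frames to samples.

    Either ``pattern`` (one round-robin cycle: each sample exactly once) or
    ``assignments`` (an explicit per-frame list, e.g. block mode) is set.
    """

    base_fps: float
    pattern: tuple[str, ...] | None = None
    assignments: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.base_fps <= 0:
            raise ValueError("base frame rate must be positive")
        if (self.pattern is None) == (self.assignments is None):
            raise ValueError("exactly one of pattern / assignments must be given")
        if self.pattern is not None:
            if len(self.pattern) == 0:
                raise ValueError("pattern must be non-empty")
            if len(set(self.pattern)) != len(self.pattern):
                raise ValueError("round-robin pattern must list each sample exactly once")
        if self.assignments is not None and len(self.assignments) == 0:
            raise ValueError("assignment list must be non-empty")

    @property
    def mode(self) -> str:
        return "round_robin" if self.pattern is not None else "block"

    @property
    def sample_ids(self) -> tuple[str, ...]:
        seq = self.pattern if self.pattern is not None else self.assignments
        seen: dict[str, None] = {}
        for s in seq:  # type: ignore[union-attr]
            seen.setdefault(s, None)
        return tuple(seen)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def assignment_for(self, n_frames: int) -> tuple[str, ...]:
        """Per-frame sample ids for a stream of ``n_frames`` frames."""
        if self.pattern is not None:
            n = len(self.pattern)
            if n_frames % n:
                raise ValueError(
                    f"stream of {n_frames} frames is not a whole number of "
                    f"{n}-frame cycles; cycle {n_frames // n} is truncated "
                    f"after {n_frames % n} frame(s)"
                )
            return self.pattern * (n_frames // n)
        if n_frames != len(self.assignments):  # type: ignore[arg-type]
            raise ValueError(
                f"stream has {n_frames} frames but the schedule assigns "
                f"{len(self.assignments)}"  # type: ignore[arg-type]
            )
        return self.assignments  # type: ignore[return-value]

    def to_dict(self) -> dict:
        d: dict = {"mode": self.mode, "base_fps": self.base_fps}
        if self.pattern is not None:
            d["pattern"] = list(self.pattern)
        else:
            d["assignments"] = list(self.assignments)  # type: ignore[arg-type]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LEDSchedule":
        return cls(
            base_fps=float(d["base_fps"]),
            pattern=tuple(d["pattern"]) if "pattern" in d else None,
            assignments=tuple(d["assignments"]) if "assignments" in d else None,
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "LEDSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_schedule(
    sample_ids: Sequence[str],
    base_fps: float,
    mode: str = "round_robin",
    frames_per_well: int | None = None,
    wells_per_block: int | None = None,
) -> LEDSchedule:
    """Build a round-robin or block schedule over ``sample_ids``.

    Block mode interleaves each consecutive group of ``wells_per_block`` ids
    for ``frames_per_well`` cycles before moving to the next group; a final
    smaller group is allowed.
    """
    ids = list(sample_ids)
    if not ids:
        raise ValueError("sample list must be non-empty")
    if mode == "round_robin":
        return LEDSchedule(base_fps=base_fps, pattern=tuple(ids))
    if mode == "block":
        if not frames_per_well or not wells_per_block:
            raise ValueError("block mode needs frames_per_well and wells_per_block")
        assignment: list[str] = []
        for start in range(0, len(ids), wells_per_block):
            group = ids[start : start + wells_per_block]
            assignment.extend(group * frames_per_well)
        return LEDSchedule(base_fps=base_fps, assignments=tuple(assignment))
    raise ValueError(f"unknown schedule mode {mode!r}")


@dataclass
class MultiplexedStream:
    """A raw interleaved frame sequence plus the schedule that explains it."""

    frames: np.ndarray  # (T, rows, cols)
    schedule: LEDSchedule
    pixel_pitch_um: float = 4.8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, rows, cols)")
        # validates length against the schedule
        self.schedule.assignment_for(self.frames.shape[0])

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.schedule.base_fps


def demultiplex(stream: MultiplexedStream) -> dict[str, FrameStack]:
    """Split an interleaved stream into one :class:`FrameStack` per sample.

    Frames keep the timestamps they had in the stream; each stack's ``fps``
    is the sample's effective rate (base_fps / n in round-robin mode,
    base_fps / block size within a block segment).
    """
    assignment = np.asarray(stream.schedule.assignment_for(stream.n_frames))
    times = stream.timestamps
    out: dict[str, FrameStack] = {}
    for sid in stream.schedule.sample_ids:
        idx = np.flatnonzero(assignment == sid)
        t = times[idx]
        if len(idx) > 1:
            fps = 1.0 / float(np.median(np.diff(t)))
        else:
            fps = stream.schedule.base_fps
        out[sid] = FrameStack(
            frames=stream.frames[idx],
            fps=fps,
            pixel_pitch_um=stream.pixel_pitch_um,
            sample_id=sid,
            times=t,
        )
    return out


def remultiplex(
    stacks: Mapping[str, FrameStack],
    schedule: LEDSchedule,
    n_frames: int | None = None,
) -> MultiplexedStream:
    """Interleave per-sample stacks back into one stream per the schedule."""
    if n_frames is None:
        if schedule.assignments is not None:
            n_frames = len(schedule.assignments)
        else:
            counts = []
            for sid in schedule.pattern:  # type: ignore[union-attr]
                if sid not in stacks:
                    raise ValueError(f"schedule sample {sid!r} missing from stacks")
                counts.append(stacks[sid].n_frames)
            n_frames = len(schedule.pattern) * min(counts)  # type: ignore[arg-type]
    assignment = schedule.assignment_for(n_frames)
    cursors = {sid: 0 for sid in schedule.sample_ids}
    frames = []
    pitch = None
    for i, sid in enumerate(assignment):
        if sid not in stacks:
            raise ValueError(f"schedule sample {sid!r} missing from stacks")
        stack = stacks[sid]
        k = cursors[sid]
        if k >= stack.n_frames:
            raise ValueError(
                f"stack for sample {sid!r} exhausted at stream frame {i} "
                f"(has {stack.n_frames} frames)"
            )
        frames.append(stack.frames[k])
        cursors[sid] = k + 1
        pitch = stack.pixel_pitch_um
    return MultiplexedStream(
        frames=np.stack(frames),
        schedule=schedule,
        pixel_pitch_um=pitch if pitch is not None else 4.8,
    )


def plate_well_ids(
    rows: str = "ABCDEFGH", cols: int = 12, exclude: Iterable[str] = ()
) -> list[str]:
    """Row-major well names of a multiwell plate, minus excluded wells.

    Lets partially obscured plates (wells blocked by camera hardware or
    unlit by the LED arrays) be represented simply as excluded ids.
    """
    excl = set(exclude)
    return [f"{r}{c}" for r in rows for c in range(1, cols + 1) if f"{r}{c}" not in excl]
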