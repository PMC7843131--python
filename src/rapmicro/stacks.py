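"""In-memory containers for frames and time-lapse stacks."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["ImageFrame", "FrameStack"]


@dataclass
class ImageFrame:
    """A single 2-D intensity grid with acquisition metadata.

    ``pixels`` is (rows, cols); intensities are 8-bit counts or floats on the
    same 0-255 scale.  ``meta`` carries sample id, lateral displacement y (mm),
    timestamp (s), LED colour tag and any applied warp factors.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = 4.8
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"pixels must be a 2-D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **meta: Any) -> "ImageFrame":
        new = replace(self, pixels=pixels)
        new.meta = {**self.meta, **meta}
        return new


@dataclass
class FrameStack:
    """A time-ordered sequence of frames for one sample.

    ``frames`` has shape (T, rows, cols).  ``times`` defaults to uniform
    sampling ``k / fps`` but may be explicit (e.g. after demultiplexing a
    block-scheduled stream, where a sample's frames inherit stream times).
    """

    frames: np.ndarray
    fps: float
    pixel_pitch_um: float = 4.8
    sample_id: str = ""
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(
                f"frames must be (T, rows, cols) with T >= 1, got {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.frames.shape[0],):
                raise ValueError("times must have one entry per frame")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def timestamps(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return np.arange(self.n_frames) / self.fps

    def with_frames(self, frames: np.ndarray, times: np.ndarray | None = None) -> "FrameStack":
        return FrameStack(
            frames=frames,
            fps=self.fps,
            pixel_pitch_um=self.pixel_pitch_um,
            sample_id=self.sample_id,
            times=times,
        )
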