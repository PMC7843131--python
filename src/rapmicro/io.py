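"""File I/O conventions: multi-page TIFF stacks with JSON sidecar metadata.

TIFF is the canonical stack format (8-bit for raw video, 32-bit float for
derived maps); schedules, ground truth and run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .stacks import FrameStack

__all__ = ["read_stack", "write_stack", "read_json", "write_json"]


def write_stack(path: str | Path, stack: FrameStack, as_uint8: bool = True) -> None:
    """Write a stack as a multi-page TIFF plus a ``.json`` metadata sidecar."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    if as_uint8:
        frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    else:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    meta: dict[str, Any] = {
        "fps": stack.fps,
        "pixel_pitch_um": stack.pixel_pitch_um,
        "sample_id": stack.sample_id,
    }
    if stack.times is not None:
        meta["times_s"] = [float(t) for t in stack.times]
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_stack(
    path: str | Path,
    fps: float | None = None,
    pixel_pitch_um: float | None = None,
) -> FrameStack:
    """Read a multi-page TIFF stack; the sidecar supplies fps/pitch if present.

    Explicit ``fps`` / ``pixel_pitch_um`` arguments override the sidecar.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fps = fps if fps is not None else meta.get("fps")
    if fps is None:
        raise ValueError(f"no frame rate for {path}: pass fps= or provide a sidecar")
    times = meta.get("times_s")
    return FrameStack(
        frames=frames,
        fps=float(fps),
        pixel_pitch_um=float(
            pixel_pitch_um if pixel_pitch_um is not None else meta.get("pixel_pitch_um", 4.8)
        ),
        sample_id=str(meta.get("sample_id", path.stem)),
        times=np.asarray(times, dtype=float) if times is not None else None,
    )


def write_json(path: str | Path, obj: Any) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
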