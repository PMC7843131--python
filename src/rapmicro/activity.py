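"""Motion analysis for dye-free cardiac monolayer imaging and *C. elegans*
activity assays.

Cardiac pipeline: a running background subtraction ``|P_t - P_{t-n}|``
(default lag n=6 frames) turns tissue motion into intensity; a 20x20 px ROI
trace of that signal shows one peak at contraction and one at relaxation per
beat; per-pixel activation times (half-maximum upstroke crossings of the
smoothed motion signal) form an activation map from which conduction speed
and direction are obtained by a planar fit.

Worm pipeline: on a stack normalized to 0-255, pixels whose intensity changes
by more than 65 units (about 25% of the range) between sequential frames are
counted and averaged over frame pairs — a robust proxy for thrashing
activity.  Group differences are assessed with a two-tailed two-sample t-test
(Welch by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .stacks import FrameStack

__all__ = [
    "ActivityTrace",
    "ActivationMap",
    "ConductionVelocity",
    "WellActivity",
    "GroupComparison",
    "motion_signal",
    "roi_trace",
    "activation_map",
    "conduction_velocity",
    "worm_activity",
    "compare_groups",
]


@dataclass
class ActivityTrace:
    """Mean motion intensity over an ROI versus time."""

    times: np.ndarray  # s
    values: np.ndarray  # intensity units
    roi_center: tuple[int, int]  # (row, col)
    roi_size: tuple[int, int] = (20, 20)  # (height, width) px

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ActivationMap:
    """Per-pixel activation time (s) of a propagating contraction wave.

    Unactivated pixels (motion below the noise floor) are NaN.
    """

    times_s: np.ndarray  # (rows, cols), NaN = unactivated
    fps: float
    pixel_pitch_um: float
    params: dict = field(default_factory=dict)

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.times_s)


@dataclass
class ConductionVelocity:
    """Planar-fit wave speed and propagation direction."""

    speed_mm_s: float | None
    direction_deg: float | None
    gradient_s_per_px: tuple[float, float]
    quasi_simultaneous: bool = False


@dataclass
class WellActivity:
    """Supra-threshold pixel-change activity of one well."""

    sample_id: str
    pixels_per_frame: float
    fraction: float
    threshold: float
    n_frames: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.pixels_per_frame < 0:
            raise ValueError("pixels_per_frame must be non-negative")


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def motion_signal(stack: FrameStack, n: int = 6) -> FrameStack:
    """Running background subtraction ``|P_t - P_{t-n}|`` per pixel.

    Output frame k corresponds to input frame k+n (length shrinks by n);
    timestamps are inherited from the later frame of each pair.  Values are
    widened to float before subtraction so 8-bit data cannot wrap around.
    """
    if n < 1:
        raise ValueError("frame offset n must be at least 1")
    if stack.n_frames <= n:
        raise ValueError(
            f"stack of {stack.n_frames} frames is too short for lag n={n}"
        )
    frames = np.asarray(stack.frames, dtype=np.float32)
    out = np.abs(frames[n:] - frames[:-n])
    return stack.with_frames(out, times=stack.timestamps[n:])


def roi_trace(
    motion: FrameStack,
    center: tuple[int, int],
    size: tuple[int, int] = (20, 20),
) -> ActivityTrace:
    """Mean of the motion signal over a rectangular ROI, per frame."""
    rows, cols = motion.frame_shape
    h, w = size
    r0 = center[0] - h // 2
    c0 = center[1] - w // 2
    if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
        raise ValueError(
            f"ROI {size} at {center} falls outside the {rows}x{cols} frame"
        )
    values = motion.frames[:, r0 : r0 + h, c0 : c0 + w].mean(axis=(1, 2))
    return ActivityTrace(
        times=motion.timestamps, values=values, roi_center=center, roi_size=size
    )


def activation_map(
    motion: FrameStack,
    smooth_px: float = 1.0,
    smooth_frames: int = 3,
    level: float = 0.5,
    noise_floor_frac: float = 0.05,
) -> ActivationMap:
    """Per-pixel upstroke time of the (smoothed) motion signal.

    Each pixel activates at the first time its spatio-temporally smoothed
    motion crosses ``level`` x its own temporal maximum, with the crossing
    linearly interpolated between frames.  Pixels whose maximum stays below
    ``noise_floor_frac`` x the global maximum are marked unactivated (NaN).
    ``smooth_px`` is a Gaussian sigma in px (0 disables), ``smooth_frames``
    a moving-mean length (1 disables).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    sm = np.asarray(motion.frames, dtype=np.float64)
    if smooth_px > 0:
        sm = ndimage.gaussian_filter(sm, sigma=(0.0, smooth_px, smooth_px))
    if smooth_frames > 1:
        sm = ndimage.uniform_filter1d(sm, size=smooth_frames, axis=0, mode="nearest")

    times = motion.timestamps
    pix_max = sm.max(axis=0)
    global_max = float(pix_max.max())
    act = np.full(motion.frame_shape, np.nan)
    if global_max <= 0:
        warnings.warn("motion stack is all-quiet; activation map is empty", stacklevel=2)
        return ActivationMap(
            act, motion.fps, motion.pixel_pitch_um,
            {"smooth_px": smooth_px, "smooth_frames": smooth_frames, "level": level},
        )
    floor = noise_floor_frac * global_max
    active = pix_max >= max(floor, np.finfo(float).tiny)

    thr = level * pix_max
    above = sm >= thr[None, :, :]
    first = np.argmax(above, axis=0)  # first frame index at/above threshold
    rr, cc = np.nonzero(active)
    k = first[rr, cc]
    t_act = times[k].astype(float)
    # linear interpolation between frames k-1 and k where possible
    has_prev = k > 0
    rp, cp, kp = rr[has_prev], cc[has_prev], k[has_prev]
    v1 = sm[kp, rp, cp]
    v0 = sm[kp - 1, rp, cp]
    th = thr[rp, cp]
    denom = v1 - v0
    frac = np.where(denom > 0, (th - v0) / np.where(denom > 0, denom, 1.0), 1.0)
    frac = np.clip(frac, 0.0, 1.0)
    t_interp = times[kp - 1] + frac * (times[kp] - times[kp - 1])
    t_act[has_prev] = t_interp
    act[rr, cc] = t_act
    return ActivationMap(
        act, motion.fps, motion.pixel_pitch_um,
        {
            "smooth_px": smooth_px,
            "smooth_frames": smooth_frames,
            "level": level,
            "noise_floor_frac": noise_floor_frac,
        },
    )


def conduction_velocity(
    amap: ActivationMap,
    pixel_pitch_um: float | None = None,
    min_gradient_s_per_px: float = 1e-6,
) -> ConductionVelocity:
    """Speed and direction of a planar wave from an activation map.

    Fits activation time as an affine function of pixel position (x = col,
    y = row) by least squares over activated pixels.  The fitted gradient g
    has units s/px; speed is ``pixel_pitch / |g|`` and the propagation
    direction is the gradient orientation.  A gradient below
    ``min_gradient_s_per_px`` is reported as quasi-simultaneous activation.
    """
    pitch = pixel_pitch_um if pixel_pitch_um is not None else amap.pixel_pitch_um
    mask = amap.activated
    rr, cc = np.nonzero(mask)
    if len(rr) < 10:
        raise ValueError(f"need at least 10 activated pixels, got {len(rr)}")
    if np.ptp(rr) == 0 and np.ptp(cc) == 0:
        raise ValueError("activated pixels are collinear (single point)")
    t = amap.times_s[rr, cc]
    a = np.column_stack([cc.astype(float), rr.astype(float), np.ones(len(rr))])
    coef, *_ = np.linalg.lstsq(a, t, rcond=None)
    gx, gy = float(coef[0]), float(coef[1])
    gmag = float(np.hypot(gx, gy))
    if gmag < min_gradient_s_per_px:
        return ConductionVelocity(None, None, (gx, gy), quasi_simultaneous=True)
    speed_mm_s = (pitch / 1000.0) / gmag
    direction = float(np.degrees(np.arctan2(gy, gx)))
    return ConductionVelocity(speed_mm_s, direction, (gx, gy))


def worm_activity(stack: FrameStack, threshold: float = 65.0) -> WellActivity:
    """Supra-threshold pixel-change count averaged over sequential frame pairs.

    Expects a stack already normalized to the 0-255 range (see
    :func:`rapmicro.warp.normalize_stack`).  For every consecutive frame pair
    the pixels with ``|dI| > threshold`` (strict) are counted; the total is
    divided by the number of pairs.  Also reported as a fraction of the
    pixels in a frame.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to measure activity")
    frames = np.asarray(stack.frames, dtype=np.float32)
    diffs = np.abs(frames[1:] - frames[:-1])
    count = int(np.count_nonzero(diffs > threshold))
    n_pairs = stack.n_frames - 1
    per_frame = count / n_pairs
    npx = frames.shape[1] * frames.shape[2]
    return WellActivity(
        sample_id=stack.sample_id,
        pixels_per_frame=per_frame,
        fraction=per_frame / npx,
        threshold=threshold,
        n_frames=stack.n_frames,
    )


def compare_groups(
    a: Sequence[WellActivity],
    b: Sequence[WellActivity],
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sample two-tailed t-test on per-well activity (Welch by default).

    Identical zero-variance groups are reported as p = 1 by convention.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two wells")
    va = np.array([w.pixels_per_frame for w in a], dtype=float)
    vb = np.array([w.pixels_per_frame for w in b], dtype=float)
    if va.std() == 0 and vb.std() == 0:
        t = 0.0
        p = 1.0 if va.mean() == vb.mean() else 0.0
    else:
        res = stats.ttest_ind(va, vb, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        t_statistic=t,
        p_value=p,
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
        n_a=len(va),
        n_b=len(vb),
    )
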