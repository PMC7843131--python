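"""Seeded synthetic-data generator for the RAP imaging pipeline.

Produces per-sample ground-truth videos of the two demonstration
preparations — beating cardiac monolayers (a traveling intensity wave with a
contraction edge and a relaxation edge per beat) and thrashing *C. elegans*
(dark undulating curves on a bright background) — renders them through the
off-axis optical distortion with brightness falloff, blur and noise, and
interleaves them into a multiplexed stream per an LED schedule.  Every
randomized step derives from a single seed, and ground truth (activation
times, wave speed, worm centrelines, schedule assignments) is always emitted
beside the pixels so downstream accuracy tests never rely on external data.

Scenes are rendered at reduced grid sizes that preserve the physical field of
view (e.g. a 2x2 mm well viewed on a 48x48 grid) so that full-plate streams
stay cheap to generate; the schedule arithmetic (wells, frames per well,
block structure, frame rates) matches the real acquisition exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .mux import LEDSchedule, MultiplexedStream, make_schedule, remultiplex
from .optics import PRESETS, OpticalConfig
from .stacks import FrameStack, ImageFrame
from .warp import forward_project

__all__ = [
    "MonolayerParams",
    "WormParams",
    "PlateParams",
    "simulate_monolayer",
    "simulate_worms",
    "render_plate",
    "grid_image",
    "make_preset",
    "PRESET_NAMES",
]


# --------------------------------------------------------------------------
# scene parameter sets


@dataclass(frozen=True)
class MonolayerParams:
    """A beating cardiac monolayer as a traveling biphasic intensity wave.

    Defaults describe a 2x2 mm field imaged at 40 fps: a planar contraction
    wave at 20 mm/s and a 1 s beat cycle; each pixel brightens along a smooth
    contraction edge, holds through a plateau (a fixed fraction of the
    period) and returns along a relaxation edge, so the per-pixel motion
    signal is biphasic.
    """

    frame_shape: tuple[int, int] = (80, 80)
    fps: float = 40.0
    duration_s: float = 2.0
    pixel_pitch_um: float = 25.0
    speed_mm_s: float = 20.0
    direction_deg: float = 0.0
    period_s: float = 1.0
    amplitude: float = 80.0
    baseline: float = 120.0
    onset_s: float = 0.2
    contraction_width_s: float = 0.04
    relaxation_width_s: float = 0.06
    plateau_frac: float = 0.3
    noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0 or self.fps <= 0 or self.period_s <= 0:
            raise ValueError("speed, fps and period must be positive")
        if not 0 <= self.amplitude <= 255 or not 0 <= self.baseline <= 255:
            raise ValueError("amplitude and baseline must fit the 8-bit range")


@dataclass(frozen=True)
class WormParams:
    """Thrashing worms in one well: dark sinusoidal bodies on bright liquid.

    Defaults emulate a well of a 96-well assay imaged at 15 fps for 100
    frames: five ~1 mm worms (24 px at the scaled 42 um/px rendering of a
    2x2 mm field) thrashing at the wild-type rate of ~2 Hz, with a slow
    centroid drift.
    """

    frame_shape: tuple[int, int] = (48, 48)
    fps: float = 15.0
    n_frames: int = 100
    pixel_pitch_um: float = 42.0
    worm_count: int = 5
    body_length_px: float = 24.0
    thrash_hz: float = 2.0
    drift_step_px: float = 0.5
    amplitude_frac: float = 0.2
    n_body_waves: float = 1.5
    body_width_px: float = 3.0
    background: float = 230.0
    body_contrast: float = 160.0
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thrash_hz < 0 or self.fps <= 0:
            raise ValueError("frequency must be >= 0 and fps positive")
        if self.worm_count < 0:
            raise ValueError("worm count must be non-negative")


@dataclass(frozen=True)
class PlateParams:
    """How a set of scenes is rendered into one multiplexed acquisition.

    ``displacements`` maps sample ids to lateral offsets y (mm) of their
    objectives from the mirror axis; brightness falls off as ``exp(-k*y)``,
    optical blur grows linearly with y (um FWHM in the sample plane), an
    optional per-LED-colour focus offset adds defocus blur, and additive
    Gaussian noise is clipped to the 8-bit range.
    """

    displacements: Mapping[str, float]
    schedule: LEDSchedule
    optics: OpticalConfig = field(default_factory=lambda: PRESETS["config2"])
    falloff_per_mm: float = 0.005
    blur_fwhm0_um: float = 9.1
    blur_fwhm_slope_um_per_mm: float = 0.19
    led_colour: Mapping[str, str] | None = None
    colour_focus_offset_um: Mapping[str, float] = field(
        default_factory=lambda: {"red": 0.0, "blue": 981.0}
    )
    noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        mirror_radius = 110.0  # mm, 220 mm reflector
        for sid, y in self.displacements.items():
            if not 0.0 <= y <= mirror_radius:
                raise ValueError(
                    f"displacement {y} mm of sample {sid!r} outside the mirror radius"
                )
        if self.falloff_per_mm < 0:
            raise ValueError("falloff coefficient must be non-negative")


# --------------------------------------------------------------------------
# cardiac monolayer


def _biphasic_pulse(
    tau: np.ndarray, p: MonolayerParams
) -> np.ndarray:
    """Unit pulse over one cycle: erf rise, plateau, erf fall."""
    t_rise = 0.1 * p.period_s
    t_fall = t_rise + p.plateau_frac * p.period_s
    rise = erf((tau - t_rise) / p.contraction_width_s)
    fall = erf((tau - t_fall) / p.relaxation_width_s)
    return 0.5 * (rise - fall)


def simulate_monolayer(p: MonolayerParams) -> tuple[FrameStack, dict]:
    """Render a beating monolayer and return (stack, ground truth).

    Ground truth holds the per-pixel activation-time field (s, time of the
    contraction edge of the first beat), the wave speed (mm/s) and direction.
    """
    support = 0.1 * p.period_s + p.plateau_frac * p.period_s + 3.0 * p.relaxation_width_s
    if support >= p.period_s:
        raise ValueError(
            f"pulse support ({support:.3f} s) does not fit the {p.period_s} s cycle"
        )
    rows, cols = p.frame_shape
    n_frames = int(round(p.duration_s * p.fps))
    phi = math.radians(p.direction_deg)
    pitch_mm = p.pixel_pitch_um / 1000.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    proj_mm = (xx * math.cos(phi) + yy * math.sin(phi)) * pitch_mm
    delay = (proj_mm - proj_mm.min()) / p.speed_mm_s
    act = p.onset_s + delay  # arrival of the wave front at each pixel

    t = np.arange(n_frames) / p.fps
    tau = np.mod(t[:, None, None] - act[None, :, :], p.period_s)
    started = t[:, None, None] >= act[None, :, :]
    pulse = _biphasic_pulse(tau, p) * started
    frames = p.baseline + p.amplitude * pulse
    if p.noise_std > 0:
        rng = np.random.default_rng(p.seed)
        frames = frames + rng.normal(0.0, p.noise_std, frames.shape)
    frames = np.clip(frames, 0.0, 255.0).astype(np.float32)
    stack = FrameStack(
        frames=frames, fps=p.fps, pixel_pitch_um=p.pixel_pitch_um, sample_id="monolayer"
    )
    truth = {
        "activation_time_s": act + 0.1 * p.period_s,  # half-max of the rise edge
        "speed_mm_s": p.speed_mm_s,
        "direction_deg": p.direction_deg,
        "period_s": p.period_s,
    }
    return stack, truth


# --------------------------------------------------------------------------
# thrashing worms


def _worm_centreline(
    center: np.ndarray, alpha: float, phase: float, p: WormParams
) -> np.ndarray:
    """Sampled (row, col) points of one worm's body at a given phase."""
    s = np.arange(-p.body_length_px / 2.0, p.body_length_px / 2.0 + 0.25, 0.5)
    lateral = (
        p.amplitude_frac
        * p.body_length_px
        * np.sin(2.0 * np.pi * p.n_body_waves * s / p.body_length_px + phase)
    )
    axis = np.array([math.cos(alpha), math.sin(alpha)])
    perp = np.array([-axis[1], axis[0]])
    pts = center[None, :] + s[:, None] * axis[None, :] + lateral[:, None] * perp[None, :]
    return pts  # (n_points, 2) as (row, col)


def simulate_worms(p: WormParams) -> tuple[FrameStack, dict]:
    """Render thrashing worms and return (stack, per-frame centrelines).

    Bodies are drawn with a Gaussian radial intensity profile around the
    rasterized centreline (via a Euclidean distance transform), which
    anti-aliases the edges; overlapping bodies take the darker value by
    construction of the shared distance field.
    """
    rows, cols = p.frame_shape
    margin = p.body_length_px / 2.0 * (1.0 + p.amplitude_frac) + 2.0
    if 2 * margin >= min(rows, cols) and p.worm_count > 0:
        raise ValueError(
            f"worms of length {p.body_length_px} px do not fit a {rows}x{cols} frame"
        )
    rng = np.random.default_rng(p.seed)
    centers = np.column_stack(
        [
            rng.uniform(margin, rows - margin, p.worm_count),
            rng.uniform(margin, cols - margin, p.worm_count),
        ]
    )
    alphas = rng.uniform(0.0, 2.0 * np.pi, p.worm_count)
    phases = rng.uniform(0.0, 2.0 * np.pi, p.worm_count)
    dphase = 2.0 * np.pi * p.thrash_hz / p.fps
    sigma = p.body_width_px / 2.0

    frames = np.empty((p.n_frames, rows, cols), dtype=np.float32)
    centrelines = []
    for k in range(p.n_frames):
        mask = np.ones((rows, cols), dtype=bool)  # True = background
        frame_lines = []
        for w in range(p.worm_count):
            pts = _worm_centreline(centers[w], alphas[w], phases[w] + k * dphase, p)
            frame_lines.append(pts)
            idx = np.round(pts).astype(int)
            np.clip(idx[:, 0], 0, rows - 1, out=idx[:, 0])
            np.clip(idx[:, 1], 0, cols - 1, out=idx[:, 1])
            mask[idx[:, 0], idx[:, 1]] = False
        if p.worm_count:
            dist = ndimage.distance_transform_edt(mask)
            frame = p.background - p.body_contrast * np.exp(
                -(dist**2) / (2.0 * sigma**2)
            )
        else:
            frame = np.full((rows, cols), p.background)
        if p.noise_std > 0:
            frame = frame + rng.normal(0.0, p.noise_std, frame.shape)
        frames[k] = np.clip(frame, 0.0, 255.0)
        centrelines.append(frame_lines)
        if p.drift_step_px > 0 and p.worm_count:
            angles = rng.uniform(0.0, 2.0 * np.pi, p.worm_count)
            step = p.drift_step_px * np.column_stack([np.cos(angles), np.sin(angles)])
            centers = centers + step
            centers[:, 0] = np.clip(centers[:, 0], margin, rows - margin)
            centers[:, 1] = np.clip(centers[:, 1], margin, cols - margin)
    stack = FrameStack(
        frames=frames, fps=p.fps, pixel_pitch_um=p.pixel_pitch_um, sample_id="worms"
    )
    return stack, {"centrelines": centrelines, "thrash_hz": p.thrash_hz}


# --------------------------------------------------------------------------
# plate rendering


def render_plate(
    scenes: Mapping[str, FrameStack], plate: PlateParams
) -> tuple[MultiplexedStream, dict]:
    """Render scenes through the RAP optics and interleave them per schedule.

    For each scheduled frame the sample's next scene frame is forward
    projected at its displacement y, attenuated by ``exp(-k*y)``, blurred
    (baseline + y-dependent + optional chromatic defocus term), and noised.
    Returns the stream together with ground truth: the per-frame assignment
    and every distortion parameter actually applied.
    """
    schedule = plate.schedule
    missing = [s for s in schedule.sample_ids if s not in scenes]
    if missing:
        raise ValueError(f"schedule samples missing from scenes: {missing}")
    for sid in schedule.sample_ids:
        if sid not in plate.displacements:
            raise ValueError(f"no displacement given for sample {sid!r}")

    rng = np.random.default_rng(plate.seed)
    na = plate.optics.numerical_aperture
    rendered: dict[str, FrameStack] = {}
    truth_samples: dict[str, dict] = {}
    for sid in schedule.sample_ids:
        scene = scenes[sid]
        y = float(plate.displacements[sid])
        falloff = math.exp(-plate.falloff_per_mm * y)
        blur_fwhm = plate.blur_fwhm0_um + plate.blur_fwhm_slope_um_per_mm * y
        colour = (plate.led_colour or {}).get(sid, "red")
        focus_offset = plate.colour_focus_offset_um.get(colour, 0.0)
        blur_fwhm += 2.0 * na * focus_offset  # defocus disc ~ offset * 2NA
        sigma_px = blur_fwhm / 2.3548 / scene.pixel_pitch_um
        out = np.empty_like(np.asarray(scene.frames, dtype=np.float32))
        for k, f in enumerate(scene.frames):
            img = forward_project(
                ImageFrame(f, pixel_pitch_um=scene.pixel_pitch_um),
                plate.optics,
                y,
            ).pixels
            img = img * falloff
            if sigma_px > 0.05:
                img = ndimage.gaussian_filter(img, sigma=sigma_px)
            out[k] = img
        if plate.noise_std > 0:
            out = out + rng.normal(0.0, plate.noise_std, out.shape)
        np.clip(out, 0.0, 255.0, out=out)
        rendered[sid] = scene.with_frames(out.astype(np.float32), times=scene.times)
        truth_samples[sid] = {
            "y_mm": y,
            "falloff": falloff,
            "blur_fwhm_um": blur_fwhm,
            "blur_sigma_px": sigma_px,
            "led_colour": colour,
        }
    stream = remultiplex(rendered, schedule)
    truth = {
        "assignments": list(schedule.assignment_for(stream.n_frames)),
        "samples": truth_samples,
        "seed": plate.seed,
    }
    return stream, truth


# --------------------------------------------------------------------------
# calibration target


def grid_image(
    shape: tuple[int, int] = (480, 480),
    pitch_um: float = 200.0,
    line_width_um: float = 20.0,
    pixel_pitch_um: float = 4.8,
    bright: float = 220.0,
    dark: float = 20.0,
    edge_sigma_px: float = 0.6,
) -> ImageFrame:
    """Synthetic image of a square calibration grid (dark lines, bright cells).

    A 200 um-pitch opaque grid is the standard target for validating the
    distortion model: its cells must come back square after rectification.
    Edges are softened with erf profiles so warping does not alias.
    """
    rows, cols = shape
    pitch_px = pitch_um / pixel_pitch_um
    half_line_px = line_width_um / pixel_pitch_um / 2.0

    def transmission(u: np.ndarray) -> np.ndarray:
        # distance (px) to the nearest line centre, lines at multiples of pitch
        d = np.abs((u / pitch_px + 0.5) % 1.0 - 0.5) * pitch_px
        return 0.5 * (1.0 + erf((d - half_line_px) / (edge_sigma_px * math.sqrt(2.0))))

    r = np.arange(rows) - (rows - 1) / 2.0
    c = np.arange(cols) - (cols - 1) / 2.0
    t2 = transmission(r)[:, None] * transmission(c)[None, :]
    pixels = (dark + (bright - dark) * t2).astype(np.float32)
    return ImageFrame(pixels, pixel_pitch_um=pixel_pitch_um, meta={"pitch_um": pitch_um})


# --------------------------------------------------------------------------
# presets


PRESET_NAMES = ("fig2-cardiac", "fig2-worms", "fig3-plate")

_PLATE_EXCLUDE = tuple(f"F{c}" for c in range(1, 13)) + ("E9", "E10", "E11", "E12")


def _well_displacement(well: str, rows: str = "ABCDEFGH", cols: int = 12) -> float:
    """Radial distance (mm) of a well from the plate centre (9 mm pitch)."""
    r = rows.index(well[0])
    c = int(well[1:]) - 1
    dr = (r - (len(rows) - 1) / 2.0) * 9.0
    dc = (c - (cols - 1) / 2.0) * 9.0
    return math.hypot(dr, dc)


def make_preset(
    name: str, seed: int = 0
) -> tuple[dict[str, FrameStack], PlateParams, dict]:
    """Build the scenes and plate description of a named scenario.

    ``fig2-cardiac``: four monolayer dishes round-robin at a 160 fps base
    rate (40 fps/dish), objectives ~40 mm off axis.
    ``fig2-worms``: four worm dishes round-robin at 60 fps (15 fps/dish).
    ``fig3-plate``: the 80-well assay — 100 frames per well at 120 fps in
    blocks of eight (8000 frames), wild-type (5 Hz) and slow-mutant (2 Hz)
    wells alternating.

    Returns ``(scenes, plate, meta)`` where meta holds per-sample scene
    ground truth and group labels.
    """
    ss = np.random.SeedSequence(seed)
    if name == "fig2-cardiac":
        ids = [f"dish{i + 1}" for i in range(4)]
        schedule = make_schedule(ids, base_fps=160.0)
        periods = (0.8, 1.0, 1.2, 1.4)
        speeds = (15.0, 20.0, 25.0, 18.0)
        scenes: dict[str, FrameStack] = {}
        meta: dict = {"scenes": {}}
        for sid, child, period, speed in zip(ids, ss.spawn(4), periods, speeds):
            p = MonolayerParams(
                period_s=period,
                speed_mm_s=speed,
                seed=int(child.generate_state(1)[0] % 2**31),
            )
            stack, truth = simulate_monolayer(p)
            stack.sample_id = sid
            scenes[sid] = stack
            meta["scenes"][sid] = {"speed_mm_s": speed, "period_s": period}
        plate = PlateParams(
            displacements={sid: 40.0 for sid in ids},
            schedule=schedule,
            optics=PRESETS["config1"],
            seed=int(ss.generate_state(1)[0] % 2**31),
        )
        return scenes, plate, meta
    if name == "fig2-worms":
        ids = [f"dish{i + 1}" for i in range(4)]
        schedule = make_schedule(ids, base_fps=60.0)
        scenes = {}
        meta = {"scenes": {}}
        for sid, child in zip(ids, ss.spawn(4)):
            p = WormParams(seed=int(child.generate_state(1)[0] % 2**31))
            stack, truth = simulate_worms(p)
            stack.sample_id = sid
            scenes[sid] = stack
            meta["scenes"][sid] = {"thrash_hz": p.thrash_hz}
        plate = PlateParams(
            displacements={sid: 40.0 for sid in ids},
            schedule=schedule,
            optics=PRESETS["config1"],
            seed=int(ss.generate_state(1)[0] % 2**31),
        )
        return scenes, plate, meta
    if name == "fig3-plate":
        return _worm_plate(seed)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def _worm_plate(
    seed: int,
    wells: list[str] | None = None,
    frames_per_well: int = 100,
    wells_per_block: int = 8,
    base_fps: float = 120.0,
    wt_hz: float = 5.0,
    mutant_hz: float = 2.0,
) -> tuple[dict[str, FrameStack], PlateParams, dict]:
    from .mux import plate_well_ids

    if wells is None:
        wells = plate_well_ids(exclude=_PLATE_EXCLUDE)  # 80 wells
    schedule = make_schedule(
        wells,
        base_fps=base_fps,
        mode="block",
        frames_per_well=frames_per_well,
        wells_per_block=wells_per_block,
    )
    per_well_fps = base_fps / wells_per_block
    ss = np.random.SeedSequence(seed)
    scenes = {}
    groups: dict[str, str] = {}
    for i, (sid, child) in enumerate(zip(wells, ss.spawn(len(wells)))):
        strain = "wt" if i % 2 == 0 else "mutant"
        groups[sid] = strain
        p = WormParams(
            fps=per_well_fps,
            n_frames=frames_per_well,
            thrash_hz=wt_hz if strain == "wt" else mutant_hz,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        stack, _ = simulate_worms(p)
        stack.sample_id = sid
        scenes[sid] = stack
    plate = PlateParams(
        displacements={sid: _well_displacement(sid) for sid in wells},
        schedule=schedule,
        optics=PRESETS["config2"],
        seed=int(ss.generate_state(1)[0] % 2**31),
    )
    meta = {"groups": groups, "wt_hz": wt_hz, "mutant_hz": mutant_hz}
    return scenes, plate, meta


def worm_discrimination_experiment(
    seed: int = 0,
    n_per_group: int = 8,
    frames_per_well: int = 100,
    wt_hz: float = 5.0,
    mutant_hz: float = 2.0,
) -> tuple[dict[str, FrameStack], PlateParams, dict]:
    """A two-strain subset plate: n wells of each strain, alternating.

    The wild-type versus slow-mutant comparison at the assay's acquisition
    settings (15 fps per well, 100 frames, blocks of eight at 120 fps).
    """
    from .mux import plate_well_ids

    wells = plate_well_ids()[: 2 * n_per_group]
    return _worm_plate(
        seed,
        wells=wells,
        frames_per_well=frames_per_well,
        wt_hz=wt_hz,
        mutant_hz=mutant_hz,
    )
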