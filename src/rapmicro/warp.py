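"""Forward simulation and inversion (rectification) of the RAP image warp.

An off-axis sample is imaged with an anisotropic magnification: ``M*S`` along
the image axis y' parallel to the lateral displacement and ``M`` along x'.
``forward_project`` applies that distortion to an ideal frame (relative to
the on-axis magnification ``f_M/f_L``, so y=0 is the identity) and
``rectify`` applies the exact inverse, recovering a square grid from its
stretched image.  Also provides the standard preprocessing used before the
activity analyses: whole-stack min-max normalization and centered cropping.

Convention: the y' axis is the image row axis; interpolation is bilinear with
constant fill outside the source field.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .optics import OpticalConfig
from .stacks import FrameStack, ImageFrame

__all__ = ["forward_project", "rectify", "normalize_stack", "crop_center"]


def _warp_factors(config: OpticalConfig, y_mm: float) -> tuple[float, float]:
    """Relative scale factors (rows, cols) of the off-axis image.

    Normalized by the on-axis magnification so that y=0 maps to (1, 1):
    rows (y') scale by ``M*S / M0 = S*V/f_M``, cols (x') by ``V/f_M``.
    """
    m_par, m_orth = config.combined_magnification(y_mm)
    m0 = config.on_axis_magnification
    return m_par / m0, m_orth / m0


def _scale_about_center(
    pixels: np.ndarray, scale_rows: float, scale_cols: float, fill: float
) -> np.ndarray:
    """Anisotropic scaling about the geometric image centre, bilinear."""
    rows, cols = pixels.shape
    for dim, s in ((rows, scale_rows), (cols, scale_cols)):
        if dim * s < 2.0:
            raise ValueError(
                f"scale factor {s:.4g} would shrink a {dim}-px axis below 2 px"
            )
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    # affine_transform maps output coords to input: in = diag(1/s) @ out + offset
    matrix = np.array([1.0 / scale_rows, 1.0 / scale_cols])
    offset = np.array([cr * (1.0 - 1.0 / scale_rows), cc * (1.0 - 1.0 / scale_cols)])
    out = ndimage.affine_transform(
        np.asarray(pixels, dtype=np.float64),
        matrix,
        offset=offset,
        order=1,
        mode="constant",
        cval=fill,
    )
    return out


def forward_project(
    frame: ImageFrame, config: OpticalConfig, y_mm: float, fill: float = 0.0
) -> ImageFrame:
    """Simulate the off-axis distortion of an ideal frame.

    Stretches the frame by ``S*V/f_M`` along rows (y') and ``V/f_M`` along
    cols (x') about the image centre.  Output keeps the input grid size;
    pixels that fall outside the source take ``fill``.
    """
    s_rows, s_cols = _warp_factors(config, y_mm)
    out = _scale_about_center(frame.pixels, s_rows, s_cols, fill)
    return frame.with_pixels(
        out, y_mm=y_mm, scale_rows=s_rows, scale_cols=s_cols, warp="forward"
    )


def rectify(
    frame: ImageFrame, config: OpticalConfig, y_mm: float, fill: float = 0.0
) -> ImageFrame:
    """Undo the off-axis distortion: compress by S along y', undo the global M.

    Exact inverse map of :func:`forward_project`, so all samples of a plate
    end up on the common on-axis scale ``f_M/f_L``.
    """
    s_rows, s_cols = _warp_factors(config, y_mm)
    out = _scale_about_center(frame.pixels, 1.0 / s_rows, 1.0 / s_cols, fill)
    return frame.with_pixels(
        out, y_mm=y_mm, scale_rows=1.0 / s_rows, scale_cols=1.0 / s_cols, warp="rectify"
    )


def rectify_stack(
    stack: FrameStack, config: OpticalConfig, y_mm: float, fill: float = 0.0
) -> FrameStack:
    """Rectify every frame of a stack with one set of warp factors."""
    s_rows, s_cols = _warp_factors(config, y_mm)
    out = np.stack(
        [
            _scale_about_center(f, 1.0 / s_rows, 1.0 / s_cols, fill)
            for f in stack.frames
        ]
    )
    return stack.with_frames(out, times=stack.times)


def normalize_stack(stack: FrameStack) -> FrameStack:
    """Min-max rescale a whole stack to [0, 255] with a single affine map.

    One transform is fitted over *all* frames so that temporal intensity
    signals keep their shape; per-frame rescaling would distort the motion
    metrics computed downstream.  A constant stack has no contrast to
    normalize: it maps to all zeros with a warning.
    """
    frames = np.asarray(stack.frames, dtype=np.float64)
    lo, hi = frames.min(), frames.max()
    if hi == lo:
        warnings.warn(
            "stack has zero dynamic range; normalization returns an all-zero stack",
            stacklevel=2,
        )
        out = np.zeros_like(frames, dtype=np.float32)
    else:
        out = ((frames - lo) * (255.0 / (hi - lo))).astype(np.float32)
    return stack.with_frames(out, times=stack.times)


def _crop_offsets(size: int, crop: int) -> int:
    # centered; an odd remainder leaves the extra pixel on the high-index side
    return (size - crop) // 2


def crop_center(obj, width: int, height: int):
    """Centered crop to ``width x height`` px (width = cols, height = rows).

    Works on an :class:`ImageFrame`, a :class:`FrameStack` or a bare 2-D/3-D
    array; raises if the requested size exceeds the frame.
    """
    if width < 1 or height < 1:
        raise ValueError("crop size must be at least 1x1")

    def crop2d(pixels: np.ndarray) -> np.ndarray:
        rows, cols = pixels.shape[-2:]
        if height > rows or width > cols:
            raise ValueError(
                f"requested crop {width}x{height} exceeds frame size {cols}x{rows}"
            )
        r0 = _crop_offsets(rows, height)
        c0 = _crop_offsets(cols, width)
        return pixels[..., r0 : r0 + height, c0 : c0 + width]

    if isinstance(obj, ImageFrame):
        return obj.with_pixels(crop2d(obj.pixels))
    if isinstance(obj, FrameStack):
        return obj.with_frames(crop2d(obj.frames), times=obj.times)
    arr = np.asarray(obj)
    if arr.ndim not in (2, 3):
        raise TypeError("expected an ImageFrame, FrameStack or 2-D/3-D array")
    return crop2d(arr)
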