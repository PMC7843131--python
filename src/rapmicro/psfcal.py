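"""Lateral PSF width estimation from the contrast of a periodic grid target.

An opaque grid of known geometry (default 20 um lines on a 40 um period,
i.e. 25 line pairs/mm) imaged with a finite-width PSF shows reduced
modulation: the gaps darken and the lines brighten as the PSF widens.  The
forward model renders the binary transmission profile, convolves it with a
normalized PSF (isotropic Gaussian parameterized by its FWHM by default) and
reports the bright/dark intensity ratio

    contrast = I(gap centre) / I(line centre) > 1,

which decreases strictly monotonically with FWHM.  Inverting that relation
by bisection turns a measured contrast into a PSF FWHM estimate.

Note on conventions: contrast is defined bright/dark here so that sharper
images give larger values; measured values quoted the other way around are
simply reciprocals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = ["GridTarget", "PSFEstimate", "contrast_from_fwhm", "fwhm_from_contrast"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GridTarget:
    """Periodic opaque-line target: ``line_width`` um lines on a ``period``."""

    line_width_um: float = 20.0
    period_um: float = 40.0
    dimensionality: int = 1  # 1: profile across lines; 2: crossed grid

    def __post_init__(self) -> None:
        if not 0 < self.line_width_um < self.period_um:
            raise ValueError(
                f"need 0 < line width ({self.line_width_um}) < period ({self.period_um})"
            )
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")


@dataclass
class PSFEstimate:
    fwhm_um: float
    contrast: float
    grid: GridTarget
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fwhm_um <= 0:
            raise ValueError("FWHM must be positive")


def _profile_intensities(
    fwhm_um: float, grid: GridTarget, sampling_um: float, n_periods: int
) -> tuple[float, float]:
    """1-D blurred-grid intensity at the gap centre and the line centre.

    The profile is rendered over a whole number of periods and convolved
    with wrap-around boundary handling, which makes it exactly periodic —
    equivalent to an infinite grid with no edge effects.
    """
    n_per = max(2, int(round(grid.period_um / sampling_um)))
    dx = grid.period_um / n_per  # snap sampling so the period is exact
    n = n_per * n_periods
    x = (np.arange(n) + 0.5) * dx
    # opaque lines centred at integer multiples of the period; each sample
    # cell holds its transmissive area fraction (anti-aliased edges), which
    # removes the O(dx) edge-quantization error of a binary profile
    phase = np.abs(((x / grid.period_um) + 0.5) % 1.0 - 0.5) * grid.period_um
    profile = np.clip((phase - grid.line_width_um / 2.0) / dx + 0.5, 0.0, 1.0)
    sigma_px = fwhm_um * _FWHM_TO_SIGMA / dx
    # wide truncation: deep line-centre minima are set by far Gaussian tails
    blurred = ndimage.gaussian_filter1d(profile, sigma=sigma_px, mode="wrap", truncate=8.0)
    line_idx = int(np.argmin(np.abs(x - n_periods // 2 * grid.period_um)))
    gap_idx = int(np.argmin(np.abs(x - (n_periods // 2 + 0.5) * grid.period_um)))
    return float(blurred[gap_idx]), float(blurred[line_idx])


def contrast_from_fwhm(
    fwhm_um: float,
    grid: GridTarget = GridTarget(),
    sampling_um: float | None = None,
    n_periods: int = 20,
) -> float:
    """Predicted bright/dark contrast of the grid for a Gaussian PSF FWHM.

    Strictly decreasing in ``fwhm_um``.  For the crossed 2-D grid the
    Gaussian is separable, so the darkest point (a line crossing) and the
    brightest point (a cell centre) are products of the 1-D values.  Raises
    once the modulation falls below machine resolution (PSF >> period).
    """
    if fwhm_um <= 0:
        raise ValueError("FWHM must be positive")
    if sampling_um is None:
        # a fixed fine grid (independent of fwhm where possible) keeps the
        # model self-consistent across a bisection sweep
        sampling_um = min(grid.period_um / 400.0, fwhm_um / 20.0)
    if sampling_um > fwhm_um / 10.0:
        raise ValueError("sampling must be at most fwhm/10 to resolve the PSF")
    i_gap, i_line = _profile_intensities(fwhm_um, grid, sampling_um, n_periods)
    if grid.dimensionality == 2:
        i_gap, i_line = i_gap * i_gap, i_line * i_line
    if i_line <= 0.0:
        return np.inf
    contrast = i_gap / i_line
    if contrast - 1.0 < 1e-12:
        raise ValueError(
            "contrast saturated: PSF much wider than the grid period leaves no modulation"
        )
    return contrast


def fwhm_from_contrast(
    contrast: float,
    grid: GridTarget = GridTarget(),
    tol_um: float = 0.05,
) -> PSFEstimate:
    """Invert the contrast model by bisection on the monotone relation.

    ``contrast`` must be the bright/dark ratio (> 1) and lie inside the
    range attainable on this grid; the result is accurate to ``tol_um``.
    """
    if contrast <= 1.0:
        raise ValueError(
            f"contrast must exceed 1 (bright/dark ratio), got {contrast}; "
            "no finite PSF yields zero modulation"
        )
    lo = grid.period_um / 50.0
    c_lo = contrast_from_fwhm(lo, grid)
    while not np.isfinite(c_lo):  # narrower PSFs leave the line centre at 0
        lo *= 1.5
        c_lo = contrast_from_fwhm(lo, grid)
    if contrast > c_lo:
        raise ValueError(
            f"contrast {contrast} above the attainable range (1, {c_lo:.4g}] "
            f"for FWHM >= {lo:.3g} um on this grid"
        )
    hi = grid.period_um
    while True:
        try:
            c_hi = contrast_from_fwhm(hi, grid)
        except ValueError:
            raise ValueError(
                f"contrast {contrast} below the resolvable range on this grid "
                f"(saturates near FWHM {hi:.3g} um)"
            ) from None
        if c_hi < contrast:
            break
        hi *= 1.5
        if hi > 50.0 * grid.period_um:
            raise ValueError(
                f"contrast {contrast} below the attainable range on this grid"
            )
    fwhm = optimize.brentq(
        lambda w: contrast_from_fwhm(w, grid) - contrast,
        lo,
        hi,
        xtol=min(tol_um, 0.05) / 2.0,
    )
    return PSFEstimate(
        fwhm_um=float(fwhm),
        contrast=contrast,
        grid=grid,
        settings={"psf": "gaussian", "tol_um": tol_um},
    )
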