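"""Closed-form geometric and scalar optics of a random-access parallel (RAP)
microscope.

A RAP instrument images many spatially separated samples with a single camera
placed at the focal point of a large parabolic mirror.  Each sample sits under
its own single-element objective, whose optical axis is laterally displaced by
a distance ``y`` from the mirror axis.  Off-axis imaging through the parabola
introduces two geometric effects that this module describes in closed form:

* the chief ray meets the detector at an oblique incidence angle
  ``theta = 2*atan(y / (2*f_M))``, which stretches the image by
  ``S = 1/cos(theta)`` along the displacement direction;
* the mirror-to-focus distance ``V(y)`` grows with ``y``, which scales the
  isotropic magnification ``M = V/f_L``.

All angles are handled in radians internally (degrees only at presentation),
and units are fixed per quantity: mm for lengths, um for the circle of
confusion and PSF widths, nm for wavelengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "OpticalConfig",
    "PRESETS",
    "chief_ray_angle",
    "chief_ray_angle_deg",
    "stretch_factor",
    "focus_distance",
    "magnification",
    "combined_magnification",
    "defocus_span",
    "depth_of_field",
    "numerical_aperture",
    "diffraction_psf_width",
]


def chief_ray_angle(y_mm: float, f_m_mm: float) -> float:
    """Incidence angle (radians) of the chief ray at the detector plane.

    ``theta = 2 * atan(y / (2 f_M))`` for a parabolic mirror of focal length
    ``f_M`` and an objective displaced laterally by ``y``.  Monotone
    increasing in ``y``; zero on axis.
    """
    if f_m_mm <= 0:
        raise ValueError(f"mirror focal length must be positive, got {f_m_mm}")
    if y_mm < 0:
        raise ValueError(f"lateral displacement must be non-negative, got {y_mm}")
    return 2.0 * math.atan(y_mm / (2.0 * f_m_mm))


def chief_ray_angle_deg(y_mm: float, f_m_mm: float) -> float:
    """Chief-ray incidence angle in degrees (presentation convenience)."""
    return math.degrees(chief_ray_angle(y_mm, f_m_mm))


def stretch_factor(y_mm: float, f_m_mm: float) -> float:
    """Anisotropic stretch ``S = 1 / cos(theta)`` of an off-axis image.

    The image plane is normal to the chief ray, so its projection onto the
    detector is stretched along the displacement direction by ``S >= 1``.
    Raises if the geometry degenerates (``theta >= 90 deg``).
    """
    theta = chief_ray_angle(y_mm, f_m_mm)
    if theta >= math.pi / 2.0:
        raise ValueError("chief ray parallel to the detector plane (theta >= 90 deg)")
    return 1.0 / math.cos(theta)


def focus_distance(y_mm: float, f_m_mm: float) -> float:
    """Distance ``V`` (mm) from the mirror surface at height ``y`` to the focus.

    For a parabola of focal length ``f_M`` the surface sag at ``y`` is
    ``y^2 / (4 f_M)``, so ``V = sqrt(y^2 + (f_M - y^2/(4 f_M))^2)``.
    ``V(0) = f_M`` and V grows monotonically on ``[0, 2 f_M]``.
    """
    if f_m_mm <= 0:
        raise ValueError(f"mirror focal length must be positive, got {f_m_mm}")
    if y_mm < 0:
        raise ValueError(f"lateral displacement must be non-negative, got {y_mm}")
    return math.hypot(y_mm, f_m_mm - y_mm**2 / (4.0 * f_m_mm))


def magnification(y_mm: float, f_l_mm: float, f_m_mm: float) -> float:
    """Isotropic magnification ``M = V(y) / f_L`` of a sample at displacement y."""
    if f_l_mm <= 0:
        raise ValueError(f"objective focal length must be positive, got {f_l_mm}")
    return focus_distance(y_mm, f_m_mm) / f_l_mm


def combined_magnification(
    y_mm: float, f_l_mm: float, f_m_mm: float
) -> tuple[float, float]:
    """Magnification along (parallel, orthogonal) to the displacement axis.

    Returns ``(M*S, M)``: the stretch acts only along the image axis y'
    parallel to the displacement, so the parallel component always dominates
    (equality on axis only).
    """
    m = magnification(y_mm, f_l_mm, f_m_mm)
    s = stretch_factor(y_mm, f_m_mm)
    return (m * s, m)


def defocus_span(sensor_width_mm: float, theta_rad: float) -> float:
    """Defocus distance ``Df = Ds * sin(theta)`` across the sensor (mm).

    Because the image plane is tilted by ``theta`` relative to the detector,
    the image moves through focus from one side of the sensor to the other;
    ``Df`` is the along-chief-ray focus span over the sensor width ``Ds``.
    """
    if sensor_width_mm <= 0:
        raise ValueError("sensor width must be positive")
    if not 0.0 <= theta_rad < math.pi / 2.0:
        raise ValueError("theta must lie in [0, pi/2)")
    return sensor_width_mm * math.sin(theta_rad)


def depth_of_field(
    f_mm: float, f_number: float, coc_um: float, u_mm: float | None = None
) -> float:
    """Depth of field (mm) from ``DOF = 2 u^2 N c / f^2``.

    With the subject at the focal plane (``u = f``, the default) the formula
    reduces to ``2 N c``.  ``c`` is given in um and the result in mm.
    """
    if f_mm <= 0 or f_number <= 0 or coc_um <= 0:
        raise ValueError("focal length, f-number and circle of confusion must be positive")
    u = f_mm if u_mm is None else u_mm
    if u <= 0:
        raise ValueError("subject distance must be positive")
    return 2.0 * u**2 * f_number * (coc_um / 1000.0) / f_mm**2


def numerical_aperture(diameter_mm: float, f_l_mm: float) -> float:
    """NA of a thin lens from its marginal-ray half-angle.

    ``NA = sin(atan(D / (2 f_L)))``, which requires ``D < 2 f_L``.
    """
    if diameter_mm <= 0 or f_l_mm <= 0:
        raise ValueError("diameter and focal length must be positive")
    if diameter_mm >= 2.0 * f_l_mm:
        raise ValueError(
            f"aperture diameter {diameter_mm} mm must be smaller than 2*f_L = {2 * f_l_mm} mm"
        )
    return math.sin(math.atan(diameter_mm / (2.0 * f_l_mm)))


def diffraction_psf_width(wavelength_nm: float, na: float) -> float:
    """Diffraction-limited lateral PSF width ``0.6 * lambda / NA`` in um."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if not 0.0 < na < 1.0:
        raise ValueError("NA must lie in (0, 1)")
    return 0.6 * (wavelength_nm / 1000.0) / na


@dataclass(frozen=True)
class OpticalConfig:
    """Scalar optical parameters of one RAP instrument.

    Lengths in mm, pixel pitch / circle of confusion / PSF in um, wavelength
    in nm.  Unit conversion happens here, at construction, never downstream.
    """

    f_m_mm: float = 100.0
    f_l_mm: float = 100.0
    lens_diameter_mm: float = 25.0
    sensor_px: tuple[int, int] = (640, 480)  # (width, height)
    pixel_pitch_um: float = 4.8
    wavelength_nm: float = 622.5
    f_number: float = 12.0
    coc_um: float = 36.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for label, v in (
            ("f_m_mm", self.f_m_mm),
            ("f_l_mm", self.f_l_mm),
            ("lens_diameter_mm", self.lens_diameter_mm),
            ("pixel_pitch_um", self.pixel_pitch_um),
            ("f_number", self.f_number),
            ("coc_um", self.coc_um),
        ):
            if v <= 0:
                raise ValueError(f"{label} must be strictly positive, got {v}")
        w, h = self.sensor_px
        if w < 1 or h < 1:
            raise ValueError(f"sensor pixel counts must be positive, got {self.sensor_px}")
        if not 350.0 <= self.wavelength_nm <= 780.0:
            raise ValueError(
                f"wavelength {self.wavelength_nm} nm outside the visible range [350, 780]"
            )
        na = self.numerical_aperture  # validates D < 2 f_L
        if not 0.0 < na < 1.0:
            raise ValueError(f"derived NA {na} outside (0, 1)")

    @property
    def sensor_width_mm(self) -> float:
        return self.sensor_px[0] * self.pixel_pitch_um / 1000.0

    @property
    def sensor_height_mm(self) -> float:
        return self.sensor_px[1] * self.pixel_pitch_um / 1000.0

    @property
    def numerical_aperture(self) -> float:
        return numerical_aperture(self.lens_diameter_mm, self.f_l_mm)

    @property
    def on_axis_magnification(self) -> float:
        """Magnification of an on-axis sample, f_M / f_L."""
        return self.f_m_mm / self.f_l_mm

    # thin wrappers so callers holding a config do not re-pass focal lengths
    def chief_ray_angle(self, y_mm: float) -> float:
        return chief_ray_angle(y_mm, self.f_m_mm)

    def stretch(self, y_mm: float) -> float:
        return stretch_factor(y_mm, self.f_m_mm)

    def magnification(self, y_mm: float) -> float:
        return magnification(y_mm, self.f_l_mm, self.f_m_mm)

    def combined_magnification(self, y_mm: float) -> tuple[float, float]:
        return combined_magnification(y_mm, self.f_l_mm, self.f_m_mm)

    def derived(self, y_mm: float = 0.0) -> dict[str, float]:
        """All derived scalar quantities, optionally at a displacement y."""
        theta = self.chief_ray_angle(y_mm)
        m_par, m_orth = self.combined_magnification(y_mm)
        na = self.numerical_aperture
        return {
            "y_mm": y_mm,
            "theta_deg": math.degrees(theta),
            "stretch": self.stretch(y_mm),
            "focus_distance_mm": focus_distance(y_mm, self.f_m_mm),
            "magnification_parallel": m_par,
            "magnification_orthogonal": m_orth,
            "sensor_width_mm": self.sensor_width_mm,
            "defocus_span_mm": defocus_span(self.sensor_width_mm, theta),
            "numerical_aperture": na,
            "depth_of_field_mm": depth_of_field(self.f_l_mm, self.f_number, self.coc_um),
            "diffraction_psf_um": diffraction_psf_width(self.wavelength_nm, na),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "OpticalConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown optical config keys: {sorted(unknown)}")
        d = dict(d)
        if "sensor_px" in d:
            d["sensor_px"] = tuple(int(v) for v in d["sensor_px"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "OpticalConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: The two published instrument configurations: a 1x four-dish system on a
#: 640x480 camera and a 1.4x 96-well system on a 1280x1024 camera.
PRESETS: dict[str, OpticalConfig] = {
    "config1": OpticalConfig(
        f_m_mm=100.0,
        f_l_mm=100.0,
        lens_diameter_mm=25.0,
        sensor_px=(640, 480),
        pixel_pitch_um=4.8,
        name="config1",
    ),
    "config2": OpticalConfig(
        f_m_mm=100.0,
        f_l_mm=72.0,
        lens_diameter_mm=6.0,
        sensor_px=(1280, 1024),
        pixel_pitch_um=4.8,
        name="config2",
    ),
}
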