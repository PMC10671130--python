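"""Color-space conversions: spectra -> CIE XYZ -> sRGB / CIELAB / LCh(ab).

Methylene blue's two resonance states (free/solvated vs hydrogen-bonded to
gelatin) have distinct visible spectra and hence distinct colors.  This module
turns a measured spectrum, or an 8-bit scanner triple, into the
device-independent CIE coordinates used to tell the two states apart:

* spectra are integrated against the CIE 1931 2-degree color-matching
  functions (optionally weighted by an illuminant for transmittance data),
* XYZ maps to sRGB through the standard IEC 61966-2-1 matrix and gamma,
* XYZ maps to CIELAB against the D65 white point, and CIELAB to the
  cylindrical LCh(ab) form (lightness, chroma, hue angle).

All conversions are plain functions over small frozen dataclasses so they can
be composed and property-tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._cie_data import CMF_1931_2DEG, D65_SPD, D65_WHITE, SRGB_TO_XYZ, XYZ_TO_SRGB

__all__ = [
    "Spectrum",
    "XYZColor",
    "RGBUnit",
    "RGB8",
    "LabColor",
    "LChColor",
    "SpectrumDomainError",
    "spectrum_to_xyz",
    "xyz_to_srgb",
    "srgb_to_xyz",
    "xyz_to_lab",
    "lab_to_lch",
    "unit_rgb_to_8bit",
    "rgb8_to_unit",
]

VISIBLE_RANGE = (360.0, 830.0)


class SpectrumDomainError(ValueError):
    """Spectrum lies entirely outside the visible wavelength range."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled optical spectrum.

    Parameters
    ----------
    wavelengths : sequence of float
        Strictly increasing wavelengths in nm, within [360, 830].
    values : sequence of float
        Nonnegative relative intensity (``emission``) or transmittance
        (``transmittance``), same length as ``wavelengths``.
    mode : {"emission", "transmittance"}
        How the values are interpreted when integrating against an
        illuminant.
    """

    wavelengths: tuple
    values: tuple
    mode: Literal["emission", "transmittance"] = "emission"

    def __init__(self, wavelengths: Sequence[float], values: Sequence[float],
                 mode: str = "emission"):
        wl = np.asarray(wavelengths, dtype=float)
        vals = np.asarray(values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be equal-length 1-D series")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite entries")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be nonnegative")
        if wl[0] < VISIBLE_RANGE[0] or wl[-1] > VISIBLE_RANGE[1]:
            raise ValueError(
                f"wavelengths must lie within [{VISIBLE_RANGE[0]:.0f}, "
                f"{VISIBLE_RANGE[1]:.0f}] nm")
        if mode not in ("emission", "transmittance"):
            raise ValueError(f"unknown spectrum mode {mode!r}")
        object.__setattr__(self, "wavelengths", tuple(wl))
        object.__setattr__(self, "values", tuple(vals))
        object.__setattr__(self, "mode", mode)


@dataclass(frozen=True)
class XYZColor:
    """CIE 1931 tristimulus values, Y = 1 for the reference white."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise ValueError("XYZ components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class RGBUnit:
    """sRGB components on [0, 1]; ``clipped`` marks gamut clipping."""

    r: float
    g: float
    b: float
    clipped: bool = False

    def __post_init__(self):
        for c in (self.r, self.g, self.b):
            if not (0.0 <= c <= 1.0):
                raise ValueError("unit RGB components must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b])


@dataclass(frozen=True)
class RGB8:
    """8-bit sRGB triple as produced by a flatbed scanner."""

    r: int
    g: int
    b: int

    def __post_init__(self):
        for c in (self.r, self.g, self.b):
            if not (isinstance(c, (int, np.integer)) and 0 <= c <= 255):
                raise ValueError("8-bit RGB components must be integers in [0, 255]")


@dataclass(frozen=True)
class LabColor:
    """CIELAB: l lightness 0-100, a red-green axis, b blue-yellow axis."""

    l: float
    a: float
    b: float

    def __post_init__(self):
        if not (0.0 <= self.l <= 100.0 + 1e-9):
            raise ValueError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class LChColor:
    """Cylindrical CIELAB: lightness, chroma >= 0, hue angle in [0, 360)."""

    l: float
    c: float
    h: float

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("chroma must be nonnegative")
        if not (0.0 <= self.h < 360.0):
            raise ValueError("hue must lie in [0, 360)")


def _illuminant_on(wl: np.ndarray, illuminant: str) -> np.ndarray:
    if illuminant == "D65":
        return np.interp(wl, D65_SPD[:, 0], D65_SPD[:, 1], left=0.0, right=0.0)
    if illuminant == "E":
        return np.ones_like(wl)
    raise ValueError(f"unknown illuminant {illuminant!r} (use 'D65' or 'E')")


def spectrum_to_xyz(spectrum: Spectrum, illuminant: str = "D65") -> XYZColor:
    """Integrate a spectrum against the CIE 1931 2-degree observer.

    The color-matching functions (and, for transmittance spectra, the
    illuminant power) are linearly interpolated from the embedded 5 nm tables
    onto the spectrum's own wavelength grid and integrated by the trapezoid
    rule.  The result is scaled by 1 / integral(illuminant * y-bar) over the
    full table so that the illuminant alone — equivalently a transmittance of
    1 everywhere — maps to the illuminant's white point with Y = 1.
    """
    wl = np.asarray(spectrum.wavelengths)
    vals = np.asarray(spectrum.values)
    cmf_wl = CMF_1931_2DEG[:, 0]
    if wl[-1] < cmf_wl[0] or wl[0] > cmf_wl[-1]:
        raise SpectrumDomainError(
            "spectrum lies entirely outside the color-matching-function "
            f"support [{cmf_wl[0]:.0f}, {cmf_wl[-1]:.0f}] nm")
    cmf = np.column_stack([
        np.interp(wl, cmf_wl, CMF_1931_2DEG[:, i], left=0.0, right=0.0)
        for i in (1, 2, 3)
    ])
    # Normalization constant from the illuminant over the full CMF grid.
    illum_full = _illuminant_on(cmf_wl, illuminant)
    k = 1.0 / np.trapezoid(illum_full * CMF_1931_2DEG[:, 2], cmf_wl)
    if spectrum.mode == "transmittance":
        weight = vals * _illuminant_on(wl, illuminant)
    else:
        weight = vals
    xyz = k * np.trapezoid(weight[:, None] * cmf, wl, axis=0)
    return XYZColor(float(xyz[0]), float(xyz[1]), float(xyz[2]))


def _srgb_companding(linear: np.ndarray) -> np.ndarray:
    linear = np.asarray(linear, dtype=float)
    a = 0.055
    return np.where(linear <= 0.0031308,
                    12.92 * linear,
                    (1 + a) * np.clip(linear, 0, None) ** (1 / 2.4) - a)


def _srgb_inverse_companding(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    a = 0.055
    return np.where(v <= 0.04045, v / 12.92, ((v + a) / (1 + a)) ** 2.4)


def xyz_to_srgb(xyz: XYZColor) -> RGBUnit:
    """XYZ -> gamma-companded sRGB, clipping out-of-gamut components.

    Clipping is applied after companding; the ``clipped`` flag records
    whether any pre-clip component fell outside [0, 1].
    """
    linear = XYZ_TO_SRGB @ xyz.as_array()
    out_of_gamut = bool(np.any(linear < -1e-12) or np.any(linear > 1 + 1e-12))
    companded = _srgb_companding(np.clip(linear, 0.0, None))
    out_of_gamut = out_of_gamut or bool(np.any(companded > 1 + 1e-12))
    clipped_vals = np.clip(companded, 0.0, 1.0)
    return RGBUnit(float(clipped_vals[0]), float(clipped_vals[1]),
                   float(clipped_vals[2]), clipped=out_of_gamut)


def srgb_to_xyz(rgb: RGBUnit) -> XYZColor:
    """Inverse-compand unit sRGB and apply the linear sRGB->XYZ matrix."""
    xyz = SRGB_TO_XYZ @ _srgb_inverse_companding(rgb.as_array())
    return XYZColor(float(xyz[0]), float(xyz[1]), float(xyz[2]))


def xyz_to_lab(xyz: XYZColor, whitepoint: XYZColor | None = None) -> LabColor:
    """Standard CIELAB with the cube-root / linear-segment function.

    ``whitepoint`` defaults to the D65 2-degree white the sRGB standard is
    defined against.
    """
    wp = whitepoint.as_array() if whitepoint is not None else np.array(D65_WHITE)
    if np.any(wp <= 0):
        raise ValueError("whitepoint components must be positive")
    t = xyz.as_array() / wp
    delta = 6.0 / 29.0
    f = np.where(t > delta ** 3, np.cbrt(t), t / (3 * delta ** 2) + 4.0 / 29.0)
    l = 116.0 * f[1] - 16.0
    return LabColor(float(l), float(500.0 * (f[0] - f[1])),
                    float(200.0 * (f[1] - f[2])))


def lab_to_lch(lab: LabColor) -> LChColor:
    """CIELAB -> LCh(ab): c = hypot(a, b), h = atan2(b, a) mapped to [0, 360).

    Achromatic colors (a = b = 0) take h = 0 by convention.
    """
    c = math.hypot(lab.a, lab.b)
    h = 0.0 if c == 0.0 else math.degrees(math.atan2(lab.b, lab.a)) % 360.0
    return LChColor(lab.l, c, h)


def unit_rgb_to_8bit(rgb: RGBUnit) -> RGB8:
    """Quantize unit sRGB to 8 bits with half-up rounding: floor(255 x + 0.5)."""
    q = [int(math.floor(c * 255.0 + 0.5)) for c in (rgb.r, rgb.g, rgb.b)]
    return RGB8(*q)


def rgb8_to_unit(rgb: RGB8) -> RGBUnit:
    """8-bit sRGB -> unit interval (x / 255)."""
    return RGBUnit(rgb.r / 255.0, rgb.g / 255.0, rgb.b / 255.0)
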