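"""sRGB ↔ CIELab conversion and the cylindrical LCh coordinates.

Colour means extracted from calibrated images are encoded sRGB on a 0–255
scale.  They are converted to CIELab via CIE XYZ using the standard sRGB
decoding and primaries, with a configurable reference white (illuminant /
observer pair).  Chroma and hue angle are derived from ``a*``/``b*``::

    C* = sqrt(a*^2 + b*^2)
    h  = atan2(b*, a*)   (degrees, wrapped to [0, 360))

The default reference white is D65 with the 10 degree observer.  Note that
encoded sRGB is itself defined relative to D65/2 degrees, so pure white
(255, 255, 255) lands at L*=100 but with a small non-zero b* under the
D65/10 white; this mismatch is intentional and documented (no chromatic
adaptation transform is applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor
from skimage.color.colorconv import xyz_tristimulus_values

__all__ = [
    "IlluminantSpec",
    "LabColour",
    "LChColour",
    "D65_10",
    "D65_2",
    "D55_10",
    "srgb_to_lab",
    "lab_to_srgb",
    "lab_to_lch",
    "lch_to_lab",
    "delta_e_cie76",
    "LAB_COLUMNS",
    "LCH_COLUMNS",
]

#: CSV column names for the five colour predictors, in canonical order.
LAB_COLUMNS = ("L_star", "a_star", "b_star")
LCH_COLUMNS = ("C_star", "h_deg")


@dataclass(frozen=True)
class IlluminantSpec:
    """Reference white for the XYZ → Lab step.

    Parameters
    ----------
    name : str
        Label of the form ``"<illuminant>_<observer>"``, e.g. ``"D65_10"``.
    illuminant, observer : str
        CIE illuminant name and observer angle in degrees, as understood by
        scikit-image.
    """

    name: str
    illuminant: str
    observer: str

    @property
    def white_point(self) -> np.ndarray:
        """XYZ tristimulus values of the reference white, Y normalised to 100."""
        wp = np.asarray(
            xyz_tristimulus_values(illuminant=self.illuminant, observer=self.observer),
            dtype=float,
        )
        return wp / wp[1] * 100.0


D65_10 = IlluminantSpec("D65_10", "D65", "10")
D65_2 = IlluminantSpec("D65_2", "D65", "2")
D55_10 = IlluminantSpec("D55_10", "D55", "10")

_ILLUMINANTS = {s.name: s for s in (D65_10, D65_2, D55_10)}


def get_illuminant(spec: "IlluminantSpec | str") -> IlluminantSpec:
    """Resolve an illuminant given by name or pass an IlluminantSpec through."""
    if isinstance(spec, IlluminantSpec):
        return spec
    try:
        return _ILLUMINANTS[spec]
    except KeyError:
        illum, _, obs = str(spec).partition("_")
        if illum and obs:
            return IlluminantSpec(str(spec), illum, obs)
        raise ValueError(f"unknown illuminant spec {spec!r}") from None


@dataclass(frozen=True)
class LabColour:
    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class LChColour:
    L: float
    C: float
    h: float
    #: True when C == 0 and the hue angle is reported as 0 by convention.
    hue_undefined: bool = field(default=False, compare=False)


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("rgb input must have 3 channels in the last axis")
    if np.any(arr < 0.0) or np.any(arr > 255.0):
        raise ValueError("rgb channels must lie in [0, 255]")
    return arr


def srgb_to_lab(
    rgb,
    illuminant: "IlluminantSpec | str" = D65_10,
    adaptation: str = "none",
) -> np.ndarray:
    """Convert encoded sRGB (0–255) to CIELab.

    Accepts a single triple or any array with 3 channels in the last axis;
    returns an array of the same shape with (L*, a*, b*).

    ``adaptation="xyz_scaling"`` applies a diagonal (von-Kries-style)
    scaling in XYZ from the sRGB native white (D65/2) to the target white
    before the Lab step, so pure white maps to exactly (100, 0, 0) under
    any illuminant.  The default applies no adaptation.
    """
    spec = get_illuminant(illuminant)
    arr = _validate_rgb(rgb)
    scalar = arr.ndim == 1
    if adaptation == "none":
        lab = _skcolor.rgb2lab(
            arr / 255.0, illuminant=spec.illuminant, observer=spec.observer
        )
    elif adaptation == "xyz_scaling":
        xyz = _skcolor.rgb2xyz(arr / 255.0)
        xyz = xyz * (spec.white_point / 100.0) / (D65_2.white_point / 100.0)
        lab = _skcolor.xyz2lab(xyz, illuminant=spec.illuminant, observer=spec.observer)
    else:
        raise ValueError(f"unknown adaptation {adaptation!r}")
    return lab[()] if not scalar else np.asarray(lab, dtype=float)


def lab_to_srgb(lab, illuminant: "IlluminantSpec | str" = D65_10) -> np.ndarray:
    """Inverse of :func:`srgb_to_lab`; returns encoded sRGB on 0–255.

    Out-of-gamut Lab inputs are clipped into [0, 255] by the sRGB encoder.
    """
    spec = get_illuminant(illuminant)
    arr = np.asarray(lab, dtype=float)
    rgb = _skcolor.lab2rgb(arr, illuminant=spec.illuminant, observer=spec.observer)
    return np.asarray(rgb, dtype=float) * 255.0


def lab_to_lch(lab) -> "LChColour | tuple[np.ndarray, np.ndarray]":
    """Derive chroma C* and hue angle h (degrees in [0, 360)) from Lab.

    For a single (L, a, b) triple an :class:`LChColour` is returned, with
    ``hue_undefined`` flagged when a = b = 0 (hue reported as 0 by
    convention).  For arrays, a pair ``(C, h)`` of arrays is returned.
    """
    arr = np.asarray(lab, dtype=float)
    L, a, b = arr[..., 0], arr[..., 1], arr[..., 2]
    C = np.hypot(a, b)
    h = np.degrees(np.arctan2(b, a)) % 360.0
    h = np.where(C == 0.0, 0.0, h)
    if arr.ndim == 1:
        return LChColour(float(L), float(C), float(h), hue_undefined=bool(C == 0.0))
    return C, h


def lch_to_lab(lch: "LChColour | np.ndarray") -> np.ndarray:
    """Inverse of :func:`lab_to_lch` (identity on C > 0 inputs)."""
    if isinstance(lch, LChColour):
        L, C, h = lch.L, lch.C, lch.h
    else:
        arr = np.asarray(lch, dtype=float)
        L, C, h = arr[..., 0], arr[..., 1], arr[..., 2]
    hr = np.radians(h)
    return np.stack(
        [np.asarray(L, dtype=float), C * np.cos(hr), C * np.sin(hr)], axis=-1
    )


def delta_e_cie76(lab1, lab2) -> np.ndarray:
    """CIE76 colour difference: Euclidean distance in CIELab."""
    d = np.asarray(lab1, dtype=float) - np.asarray(lab2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))
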