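"""Colour-checker calibration by per-channel polynomial regression.

Each image contains a 24-chip colour checker with known sRGB reference
values.  A calibration model maps measured chip colours to the reference
via least squares in encoded (gamma) sRGB space on the 0–255 scale,
matching the workflow of chart-based calibration plugins.  Two term bases
are available per output channel:

* ``linear``:                [1, R, G, B]
* ``quadratic_cross_band``:  [1, R, G, B, R^2, G^2, B^2, RG, RB, GB]

Calibration quality is summarised as the mean CIE76 Delta-E between
calibrated and reference chip colours (converted to CIELab).  Because
camera exposure and white balance drift between acquisition conditions,
a model is fitted independently per light condition; applying a model to
an image from a different condition is possible but logged as a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .colours import D65_10, delta_e_cie76, get_illuminant, srgb_to_lab

__all__ = [
    "CheckerMeasurement",
    "CheckerCalibrator",
    "measure_chips",
    "fit_calibration",
    "apply_calibration",
    "load_checker_reference",
]

logger = logging.getLogger(__name__)

_BASES = {
    "linear": ("1", "R", "G", "B"),
    "quadratic_cross_band": ("1", "R", "G", "B", "R2", "G2", "B2", "RG", "RB", "GB"),
}


def load_checker_reference() -> np.ndarray:
    """Reference sRGB values (24, 3) of the classic 24-chip checker."""
    from importlib.resources import files

    data = json.loads(files("carotlab.data").joinpath("colorchecker_srgb.json").read_text())
    chips = sorted(data["chips"], key=lambda c: c["chip_id"])
    return np.array([c["srgb"] for c in chips], dtype=float)


@dataclass(frozen=True)
class CheckerMeasurement:
    """Mean measured RGB of one chip together with its reference value."""

    chip_id: int
    measured_rgb: tuple
    reference_rgb: tuple

    def __post_init__(self):
        if not 1 <= self.chip_id <= 24:
            raise ValueError("chip_id must be in 1..24")
        for v in (*self.measured_rgb, *self.reference_rgb):
            if not 0 <= v <= 255:
                raise ValueError("chip channels must lie in [0, 255]")


def _decode_srgb(c):
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _encode_srgb(c):
    c = np.clip(np.asarray(c, dtype=float), 0.0, None)
    return np.where(c <= 0.0031308, c * 12.92, 1.055 * c ** (1 / 2.4) - 0.055)


def _design_matrix(rgb01: np.ndarray, method: str) -> np.ndarray:
    R, G, B = rgb01[..., 0], rgb01[..., 1], rgb01[..., 2]
    cols = [np.ones_like(R), R, G, B]
    if method == "quadratic_cross_band":
        cols += [R * R, G * G, B * B, R * G, R * B, G * B]
    return np.stack(cols, axis=-1)


class CheckerCalibrator(TransformerMixin, BaseEstimator):
    """Least-squares chart calibration in encoded sRGB space.

    Parameters
    ----------
    method : {"quadratic_cross_band", "linear"}
        Term basis of the per-channel regression.
    fit_space : {"encoded_srgb", "linear_srgb"}
        Space the regression operates in.  The default fits encoded
        (gamma) values directly, as chart plugins do; ``linear_srgb``
        decodes to linear light for the fit and re-encodes on transform.
    illuminant : IlluminantSpec or str
        Reference white used when converting chips to Lab for the mean
        Delta-E quality metric.
    delta_e_metric : {"cie76"}
        Colour-difference metric for the quality summary.

    Attributes
    ----------
    coefficients_ : ndarray, shape (n_terms, 3)
        Fitted weights per output channel.
    basis_ : tuple of str
        Ordered term labels.
    mean_delta_ : float
        Mean Delta-E over chips after calibration.
    light_condition_ : str or None
        Label of the condition the model was fitted on, if provided.
    """

    def __init__(
        self,
        method="quadratic_cross_band",
        illuminant=D65_10,
        delta_e_metric="cie76",
        fit_space="encoded_srgb",
    ):
        self.method = method
        self.illuminant = illuminant
        self.delta_e_metric = delta_e_metric
        self.fit_space = fit_space

    def _to_fit_space(self, rgb255):
        c = np.asarray(rgb255, dtype=float) / 255.0
        return _decode_srgb(c) if self.fit_space == "linear_srgb" else c

    def _from_fit_space(self, c01):
        if self.fit_space == "linear_srgb":
            c01 = _encode_srgb(np.clip(c01, 0.0, None))
        return np.clip(c01, 0.0, 1.0) * 255.0

    # measured/reference are (n_chips, 3) arrays on the 0-255 scale
    def fit(self, measured, reference, light_condition=None):
        if self.method not in _BASES:
            raise ValueError(f"unknown calibration method {self.method!r}")
        if self.delta_e_metric != "cie76":
            raise ValueError("only the CIE76 delta-E metric is implemented")
        if self.fit_space not in ("encoded_srgb", "linear_srgb"):
            raise ValueError(f"unknown fit_space {self.fit_space!r}")
        X = np.asarray(measured, dtype=float)
        Y = np.asarray(reference, dtype=float)
        if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("measured and reference must both be (n_chips, 3)")
        n_terms = len(_BASES[self.method])
        if X.shape[0] < n_terms:
            raise ValueError(
                f"{self.method} calibration needs at least {n_terms} chips, got {X.shape[0]}"
            )
        D = _design_matrix(self._to_fit_space(X), self.method)
        rank = np.linalg.matrix_rank(D)
        if rank < n_terms:
            raise np.linalg.LinAlgError(
                f"rank-deficient calibration design (rank {rank} < {n_terms} terms): "
                "measured chip colours do not span the term basis"
            )
        coef, *_ = np.linalg.lstsq(D, self._to_fit_space(Y), rcond=None)
        self.coefficients_ = coef
        self.basis_ = _BASES[self.method]
        self.light_condition_ = light_condition
        calibrated = self._from_fit_space(D @ coef)
        spec = get_illuminant(self.illuminant)
        self.mean_delta_ = float(
            np.mean(delta_e_cie76(srgb_to_lab(calibrated, spec), srgb_to_lab(Y, spec)))
        )
        return self

    def transform(self, rgb, light_condition=None):
        """Map RGB values (any array with 3 trailing channels, 0–255) through
        the fitted calibration; output is clipped to [0, 255]."""
        check_is_fitted(self, "coefficients_")
        if (
            light_condition is not None
            and self.light_condition_ is not None
            and light_condition != self.light_condition_
        ):
            logger.warning(
                "applying calibration fitted on condition %s to condition %s",
                self.light_condition_,
                light_condition,
            )
        arr = np.asarray(rgb, dtype=float)
        D = _design_matrix(self._to_fit_space(arr), self.method)
        return self._from_fit_space(D @ self.coefficients_)

    def transform_image(self, image: np.ndarray, light_condition=None) -> np.ndarray:
        """Calibrate an 8-bit image, returning float values on 0–255."""
        return self.transform(image, light_condition=light_condition)

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coefficients_")
        return {
            "method": self.method,
            "fit_space": self.fit_space,
            "basis": list(self.basis_),
            "coefficients": self.coefficients_.tolist(),
            "mean_delta": self.mean_delta_,
            "light_condition": self.light_condition_,
            "illuminant": get_illuminant(self.illuminant).name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CheckerCalibrator":
        model = cls(
            method=d["method"],
            illuminant=d.get("illuminant", D65_10),
            fit_space=d.get("fit_space", "encoded_srgb"),
        )
        model.coefficients_ = np.asarray(d["coefficients"], dtype=float)
        model.basis_ = tuple(d["basis"])
        model.mean_delta_ = float(d["mean_delta"])
        model.light_condition_ = d.get("light_condition")
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CheckerCalibrator":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def measure_chips(image, layout, margin_fraction: float = 0.2, reference=None):
    """Mean interior colour of every enabled chip in ``layout``.

    Parameters
    ----------
    image : ndarray, H x W x 3
    layout : sequence of dict
        Each with ``chip_id`` and pixel rectangle ``x, y, w, h`` (0-based,
        x rightward, y downward); optional ``enabled`` flag (default True).
    margin_fraction : float in [0, 0.5)
        Fraction of each side trimmed from every rectangle edge before
        averaging, excluding chip borders and overlay strokes.
    reference : ndarray (24, 3), optional
        Reference sRGB per chip_id; defaults to the shipped checker values.

    Returns
    -------
    list of CheckerMeasurement
    """
    if not 0.0 <= margin_fraction < 0.5:
        raise ValueError("margin_fraction must be in [0, 0.5)")
    img = np.asarray(image, dtype=float)
    if reference is None:
        reference = load_checker_reference()
    out = []
    for chip in layout:
        if not chip.get("enabled", True):
            continue
        x, y, w, h = (int(chip[k]) for k in ("x", "y", "w", "h"))
        mx, my = int(round(w * margin_fraction)), int(round(h * margin_fraction))
        x0, x1 = x + mx, x + w - mx
        y0, y1 = y + my, y + h - my
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"chip {chip['chip_id']}: empty interior after margin trim")
        if x0 < 0 or y0 < 0 or x1 > img.shape[1] or y1 > img.shape[0]:
            raise ValueError(f"chip {chip['chip_id']} lies outside the image")
        mean = img[y0:y1, x0:x1].reshape(-1, 3).mean(axis=0)
        cid = int(chip["chip_id"])
        out.append(
            CheckerMeasurement(
                chip_id=cid,
                measured_rgb=tuple(mean),
                reference_rgb=tuple(np.asarray(reference[cid - 1], dtype=float)),
            )
        )
    return out


def fit_calibration(measurements, method="quadratic_cross_band", **kwargs) -> CheckerCalibrator:
    """Fit a :class:`CheckerCalibrator` from chip measurements."""
    measured = np.array([m.measured_rgb for m in measurements], dtype=float)
    reference = np.array([m.reference_rgb for m in measurements], dtype=float)
    return CheckerCalibrator(method=method, **kwargs).fit(measured, reference)


def apply_calibration(model: CheckerCalibrator, rgb, light_condition=None):
    """Functional alias for :meth:`CheckerCalibrator.transform`."""
    return model.transform(rgb, light_condition=light_condition)
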