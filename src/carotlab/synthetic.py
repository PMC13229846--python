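"""Synthetic carrot-disk study generator.

Emulates the full field study the analysis pipeline consumes: 16 cultivars
(white, yellow, orange, red, purple, purple-yellow flesh) x 6 replicate
roots, each disk photographed under six light conditions (two lighting
environments, with/without polarising filters, crossed with relative
exposure steps), plus a rendered 24-chip colour checker in every image and
a wet-lab absorbance table that is the analytic inverse of the pigment
equations, so the chemistry stage recovers the generated truth exactly in
the noiseless case.

Generative model
----------------
* Disk flesh colour: cultivar mean CIELab + per-disk Gaussian biological
  noise.  Cultivar means are hand-set to occupy the four empirically
  observed colour clusters (white: highest L*, purple: low values on all
  parameters, yellow: high b*, orange/red: high a*; the purple-yellow
  cultivar sits with the orange/red group).
* Pigment content: linear in the five colour parameters,
  ``content = intercept + beta . (L*, a*, b*, C*, h) + eps`` — the
  generative inverse of the PLS link fitted downstream.  Truth values are
  *not* clamped at zero: measured contents from blank-subtracted assays
  can be slightly negative, and clamping would bias link recovery.  The
  absorbance table inverts ``max(content, 0)``.
* Individual carotenoids are composition fractions of total carotenoids
  (roughly 58% beta-carotene, 16% alpha-carotene, a few percent lutein,
  lycopene confined to the red cultivar) plus noise; they are not part of
  the linear link.
* Light-condition distortion: per-channel gain ``2^(step * stops)``
  applied in linear light, a small per-environment channel offset in
  encoded space, an optional gamma tweak, and a specular-glare highlight
  on each disk whose amplitude is zero for polarised (PF) environments.

A fixed design seed fully determines every image byte and table value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemistry import (
    CYANIDIN_3_GLUCOSIDE_EF,
    CYANIDIN_3_GLUCOSIDE_MW,
    fresh_weight_factor,
)
from .colours import D65_10, lab_to_srgb

__all__ = [
    "CultivarSpec",
    "LightCondition",
    "StudyDesign",
    "SyntheticImage",
    "LayoutError",
    "default_cultivars",
    "default_conditions",
    "identity_conditions",
    "default_design",
    "generate_truth",
    "generate_study",
    "invert_pigment_equations",
    "DEFAULT_PIGMENT_LINKS",
    "DEFAULT_PIGMENT_NOISE_SD",
]


class LayoutError(ValueError):
    """Requested disk count cannot be placed without overlaps."""


#: Generative colour -> pigment links: (intercept, coefficients over
#: (L*, a*, b*, C*, h deg)), in mg/100 g FW.  Chosen once by least squares
#: from the hand-set cultivar colour anchors to realistic per-cultivar
#: content targets (orange ~8-12, red ~15, purple-yellow ~5, white ~0 for
#: total carotenoids; purple 35-55, purple-yellow ~5 for anthocyanins).
DEFAULT_PIGMENT_LINKS = {
    "tcc": (-24.03, (0.2749, 0.1498, -0.7675, 0.8450, -0.0054)),
    "tac": (90.08, (-1.0326, -0.4455, 0.4426, -0.6845, -0.0012)),
}

#: Within-cultivar biological + assay noise SD per pigment (mg/100 g FW).
DEFAULT_PIGMENT_NOISE_SD = {
    "tcc": 2.2,
    "tac": 11.5,
    "lutein": 0.08,
    "lycopene": 0.08,
    "alpha_carotene": 0.30,
    "beta_carotene": 0.60,
}

#: Composition fractions of total carotenoids for individual carotenoids.
_COMPOSITION = {"beta_carotene": 0.58, "alpha_carotene": 0.16, "lutein": 0.04}

_ALLOWED_EXPOSURES = (1 / 25, 1 / 50, 1 / 100, 1 / 60, 1 / 30)


@dataclass(frozen=True)
class CultivarSpec:
    """One cultivar: flesh colour distribution and pigment panel."""

    code: str
    colour_group: str  # white | yellow | orange | red | purple | purple_yellow
    mean_lab: tuple
    lab_sd: tuple = (2.0, 1.5, 1.5)
    pigment_means: dict = field(default_factory=dict)
    pigment_sds: dict = field(default_factory=dict)
    moisture_fraction: float = 0.88

    def __post_init__(self):
        if any(s < 0 for s in self.lab_sd):
            raise ValueError("lab_sd must be non-negative elementwise")
        if any(v < 0 for v in self.pigment_means.values()):
            raise ValueError("pigment_means must be non-negative")
        groups = {"white", "yellow", "orange", "red", "purple", "purple_yellow"}
        if self.colour_group not in groups:
            raise ValueError(f"unknown colour_group {self.colour_group!r}")


@dataclass(frozen=True)
class LightCondition:
    """Named acquisition condition with its global colour distortion."""

    name: str
    environment: str  # WF (no filter) or PF (polarising filter)
    exposure_step: int
    exposure_time_s: float
    gain: tuple = (1.0, 1.0, 1.0)  # per-channel, linear light
    offset: tuple = (0.0, 0.0, 0.0)  # per-channel, encoded 0-255 scale
    gamma: float = 1.0
    glare_amplitude: float = 0.0  # encoded units added at the highlight peak

    def __post_init__(self):
        if self.environment not in ("WF", "PF"):
            raise ValueError("environment must be WF or PF")
        expected = f"{self.environment}{self.exposure_step:+d}" if self.exposure_step else f"{self.environment}0"
        if self.name != expected:
            raise ValueError(
                f"condition name {self.name!r} must encode environment and step ({expected!r})"
            )
        if not any(np.isclose(self.exposure_time_s, t) for t in _ALLOWED_EXPOSURES):
            raise ValueError(f"exposure_time_s {self.exposure_time_s} not in {_ALLOWED_EXPOSURES}")
        if self.environment == "PF" and self.glare_amplitude != 0.0:
            raise ValueError("polarisation suppresses specular glare: PF glare must be 0")

    @property
    def is_identity(self) -> bool:
        return (
            tuple(self.gain) == (1.0, 1.0, 1.0)
            and tuple(self.offset) == (0.0, 0.0, 0.0)
            and self.gamma == 1.0
            and self.glare_amplitude == 0.0
        )


_CULTIVAR_TABLE = [
    # code, group, (L, a, b), moisture
    ("W1", "white", (85.0, 1.5, 9.0), 0.895),
    ("Y1", "yellow", (72.0, 4.0, 52.0), 0.890),
    ("Y2", "yellow", (70.0, 7.0, 58.0), 0.885),
    ("O1", "orange", (57.0, 31.0, 42.0), 0.880),
    ("O2", "orange", (54.0, 36.0, 46.0), 0.878),
    ("O3", "orange", (58.0, 30.0, 40.0), 0.882),
    ("O4", "orange", (56.0, 33.0, 44.0), 0.879),
    ("O5", "orange", (53.0, 37.0, 47.0), 0.876),
    ("O6", "orange", (52.0, 38.0, 48.0), 0.875),
    ("O7", "orange", (53.0, 36.0, 45.0), 0.877),
    ("O8", "orange", (56.0, 34.0, 43.0), 0.881),
    ("O9", "orange", (51.0, 39.0, 46.0), 0.874),
    ("R1", "red", (44.0, 42.0, 29.0), 0.870),
    ("P1", "purple", (22.0, 14.0, -6.0), 0.868),
    ("P2", "purple", (26.0, 17.0, -3.0), 0.872),
    ("PY1", "purple_yellow", (50.0, 30.0, 40.0), 0.883),
]


def _link_value(link, lab) -> float:
    intercept, coefs = link
    L, a, b = lab
    C = float(np.hypot(a, b))
    h = float(np.degrees(np.arctan2(b, a)) % 360.0)
    return intercept + float(np.dot(coefs, (L, a, b, C, h)))


def default_cultivars(links=None, noise_sd=None) -> list:
    """The 16 default cultivars with pigment means implied by the link."""
    links = links or DEFAULT_PIGMENT_LINKS
    noise_sd = noise_sd or DEFAULT_PIGMENT_NOISE_SD
    out = []
    for code, group, lab, moisture in _CULTIVAR_TABLE:
        tcc = max(_link_value(links["tcc"], lab), 0.0)
        tac = max(_link_value(links["tac"], lab), 0.0)
        means = {"tcc": tcc, "tac": tac}
        for pig, frac in _COMPOSITION.items():
            means[pig] = frac * tcc
        means["lutein"] += 0.45 if group == "purple_yellow" else 0.0
        means["lycopene"] = 1.66 if group == "red" else 0.0
        out.append(
            CultivarSpec(
                code=code,
                colour_group=group,
                mean_lab=lab,
                pigment_means=means,
                pigment_sds=dict(noise_sd),
                moisture_fraction=moisture,
            )
        )
    return out


def default_conditions(stops_per_step: float = 0.3, glare_amplitude: float = 22.0) -> list:
    """The six study light conditions with their default distortions."""

    def gains(step, tint):
        g = 2.0 ** (step * stops_per_step)
        return tuple(g * t for t in tint)

    wf_tint, pf_tint = (1.02, 1.0, 0.97), (0.98, 1.0, 1.03)
    wf_off, pf_off = (3.0, 1.0, -2.0), (-2.0, 0.0, 2.0)
    spec = [
        ("WF", -1, 1 / 25),
        ("WF", 0, 1 / 50),
        ("WF", +1, 1 / 100),
        ("PF", 0, 1 / 100),
        ("PF", +1, 1 / 60),
        ("PF", +2, 1 / 30),
    ]
    out = []
    for env, step, t in spec:
        name = f"{env}{step:+d}" if step else f"{env}0"
        out.append(
            LightCondition(
                name=name,
                environment=env,
                exposure_step=step,
                exposure_time_s=t,
                gain=gains(step, wf_tint if env == "WF" else pf_tint),
                offset=wf_off if env == "WF" else pf_off,
                glare_amplitude=glare_amplitude if env == "WF" else 0.0,
            )
        )
    return out


def identity_conditions() -> list:
    """The six named conditions with distortion = identity (for round trips)."""
    return [
        replace(c, gain=(1.0, 1.0, 1.0), offset=(0.0, 0.0, 0.0), gamma=1.0, glare_amplitude=0.0)
        for c in default_conditions()
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to generate one deterministic synthetic study."""

    cultivars: tuple = ()
    n_replicates: int = 6
    light_conditions: tuple = ()
    seed: int = 0
    #: None -> per-cultivar lab_sd; a scalar overrides all channels.
    colour_noise_sd: float | None = None
    pigment_links: dict = field(default_factory=lambda: dict(DEFAULT_PIGMENT_LINKS))
    pigment_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_PIGMENT_NOISE_SD))
    absorbance_noise_sd: float = 0.0
    pixel_noise_sd: float = 1.2
    #: cultivar -> number of replicates with an anthocyanin assay
    tac_assay_counts: dict = field(
        default_factory=lambda: {"P1": 6, "P2": 3, "PY1": 6, "R1": 1}
    )
    illuminant: object = D65_10

    def __post_init__(self):
        object.__setattr__(self, "cultivars", tuple(self.cultivars) or tuple(default_cultivars()))
        object.__setattr__(
            self, "light_conditions", tuple(self.light_conditions) or tuple(default_conditions())
        )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        names = [c.name for c in self.light_conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate light condition names")


def default_design(seed: int = 0, **overrides) -> StudyDesign:
    return StudyDesign(seed=seed, **overrides)


@dataclass
class SyntheticImage:
    """Rendered scene: checker + disks, with layout and per-disk truth."""

    pixels: np.ndarray  # uint8, H x W x 3
    cultivar: str
    light_condition: str
    roi_polygons: dict  # disk_id -> (m, 2) vertices [x, y]
    checker_layout: list  # chip dicts: chip_id, x, y, w, h, reference srgb
    truth_lab: dict  # disk_id -> (L, a, b) before distortion


# ----------------------------------------------------------------------
# sRGB transfer helpers (encoded <-> linear, vectorised, 0..1 scale)

def _decode(c):
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _encode(c):
    c = np.clip(np.asarray(c, dtype=float), 0.0, None)
    return np.where(c <= 0.0031308, c * 12.92, 1.055 * c ** (1 / 2.4) - 0.055)


def distort_rgb(rgb255: np.ndarray, condition: LightCondition) -> np.ndarray:
    """Apply a condition's global colour distortion to encoded RGB (0-255)."""
    lin = _decode(np.asarray(rgb255, dtype=float) / 255.0)
    lin = lin * np.asarray(condition.gain, dtype=float)
    enc = _encode(lin) * 255.0 + np.asarray(condition.offset, dtype=float)
    if condition.gamma != 1.0:
        enc = 255.0 * np.clip(enc / 255.0, 0.0, 1.0) ** condition.gamma
    return np.clip(enc, 0.0, 255.0)


# ----------------------------------------------------------------------
# truth and wet-lab tables

def _draw_disks(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cv in design.cultivars:
        sd = (
            np.full(3, float(design.colour_noise_sd))
            if design.colour_noise_sd is not None
            else np.asarray(cv.lab_sd, dtype=float)
        )
        for rep in range(1, design.n_replicates + 1):
            lab = np.asarray(cv.mean_lab, dtype=float) + rng.normal(0.0, sd)
            C = float(np.hypot(lab[1], lab[2]))
            h = float(np.degrees(np.arctan2(lab[2], lab[1])) % 360.0)
            row = {
                "cultivar": cv.code,
                "replicate": rep,
                "colour_group": cv.colour_group,
                "disk_id": f"{cv.code}-{rep}",
                "L_true": lab[0],
                "a_true": lab[1],
                "b_true": lab[2],
                "C_true": C,
                "h_true": h,
                "moisture_fraction": cv.moisture_fraction,
            }
            x = np.array([lab[0], lab[1], lab[2], C, h])
            for pig in ("tcc", "tac"):
                intercept, coefs = design.pigment_links[pig]
                noise = rng.normal(0.0, design.pigment_noise_sd.get(pig, 0.0))
                row[pig] = intercept + float(np.dot(coefs, x)) + noise
            tcc_pos = max(row["tcc"], 0.0)
            for pig, frac in _COMPOSITION.items():
                base = frac * tcc_pos
                if pig == "lutein" and cv.colour_group == "purple_yellow":
                    base += 0.45
                row[pig] = base + rng.normal(0.0, design.pigment_noise_sd.get(pig, 0.0))
            lyco = 1.66 if cv.colour_group == "red" else 0.005
            row["lycopene"] = lyco + rng.normal(
                0.0, design.pigment_noise_sd.get("lycopene", 0.0)
            )
            rows.append(row)
    return pd.DataFrame(rows)


_CHL_MATRIX = np.array([[11.75, -2.35], [-3.96, 18.61]])  # (A662, A645) -> (Ca, Cb)

#: Default bench factors for the synthetic assays.
TCC_ASSAY = {"extract_volume_mL": 10.0, "sample_mass_g": 0.05, "path_length_cm": 1.0}
TAC_ASSAY = {
    "extract_volume_mL": 10.0,
    "sample_mass_g": 0.5,
    "DF": 40.0,
    "MW": CYANIDIN_3_GLUCOSIDE_MW,
    "EF": CYANIDIN_3_GLUCOSIDE_EF,
    "path_length_cm": 1.0,
    # fixed plausible baseline readings; only the differential matters
    "A520_pH45": 0.050,
    "A700_pH1": 0.012,
    "A700_pH45": 0.008,
}


def invert_pigment_equations(
    pigment_panel: dict,
    *,
    moisture_fraction: float,
    chlorophyll_a: float = 0.0,
    chlorophyll_b: float = 0.0,
    tcc_assay: dict | None = None,
    tac_assay: dict | None = None,
):
    """Absorbances that reproduce the requested contents through the forward
    pigment equations.

    Parameters
    ----------
    pigment_panel : dict
        ``{"tcc": mg/100 g FW}`` and optionally ``"tac"``.  Negative
        targets are flagged and inverted as zero.
    chlorophyll_a, chlorophyll_b : float
        Target chlorophyll concentrations (ug/mL); the default 0 is the
        chlorophyll-free inversion used for carrot tissue.

    Returns
    -------
    (tcc_readings, tac_readings, flags)
        Dicts of absorbances plus the bench factors used; ``tac_readings``
        is None when the panel has no ``"tac"`` entry.
    """
    flags = []
    tcc_p = dict(TCC_ASSAY, **(tcc_assay or {}))
    target = pigment_panel.get("tcc", 0.0)
    if target < 0:
        flags.append("tcc_target_negative_clamped")
        target = 0.0
    factor = fresh_weight_factor(
        tcc_p["extract_volume_mL"], tcc_p["sample_mass_g"], moisture_fraction
    )
    cxc = target / factor
    A662, A645 = np.linalg.solve(_CHL_MATRIX, [chlorophyll_a, chlorophyll_b])
    if A662 < 0 or A645 < 0:
        flags.append("chlorophyll_not_representable_zeroed")
        A662 = A645 = 0.0
        chlorophyll_a = chlorophyll_b = 0.0
    A470 = (227.0 * cxc + 2.27 * chlorophyll_a + 81.4 * chlorophyll_b) / 1000.0
    ell = tcc_p["path_length_cm"]
    tcc_readings = {
        "A662": float(A662) * ell,
        "A645": float(A645) * ell,
        "A470": float(A470) * ell,
        "path_length_cm": ell,
        "extract_volume_mL": tcc_p["extract_volume_mL"],
        "sample_mass_g": tcc_p["sample_mass_g"],
        "moisture_fraction": moisture_fraction,
    }

    tac_readings = None
    if "tac" in pigment_panel and pigment_panel["tac"] is not None:
        tac_p = dict(TAC_ASSAY, **(tac_assay or {}))
        tac_target = pigment_panel["tac"]
        if tac_target < 0:
            flags.append("tac_target_negative_clamped")
            tac_target = 0.0
        factor = fresh_weight_factor(
            tac_p["extract_volume_mL"], tac_p["sample_mass_g"], moisture_fraction
        )
        tac_mg_L = tac_target / factor
        A = tac_mg_L * tac_p["EF"] / (tac_p["MW"] * tac_p["DF"] * 1000.0)
        ell = tac_p["path_length_cm"]
        A520_pH1 = A * ell + (tac_p["A520_pH45"] - tac_p["A700_pH45"]) + tac_p["A700_pH1"]
        tac_readings = {
            "A520_pH1": float(A520_pH1),
            "A700_pH1": tac_p["A700_pH1"],
            "A520_pH45": tac_p["A520_pH45"],
            "A700_pH45": tac_p["A700_pH45"],
            "DF": tac_p["DF"],
            "MW": tac_p["MW"],
            "EF": tac_p["EF"],
            "tac_path_length_cm": ell,
            "tac_extract_volume_mL": tac_p["extract_volume_mL"],
            "tac_sample_mass_g": tac_p["sample_mass_g"],
        }
    return tcc_readings, tac_readings, flags


def _wetlab_table(design: StudyDesign, disks: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _, d in disks.iterrows():
        panel = {"tcc": d["tcc"]}
        n_tac = design.tac_assay_counts.get(d["cultivar"], 0)
        if d["replicate"] <= n_tac:
            panel["tac"] = d["tac"]
        tcc_r, tac_r, _ = invert_pigment_equations(
            panel, moisture_fraction=d["moisture_fraction"]
        )
        row = {"cultivar": d["cultivar"], "replicate": d["replicate"], "disk_id": d["disk_id"]}
        row.update(tcc_r)
        if tac_r is not None:
            row.update(tac_r)
        if design.absorbance_noise_sd > 0:
            for key in ("A662", "A645", "A470", "A520_pH1", "A520_pH45"):
                if key in row and pd.notna(row[key]):
                    row[key] = max(row[key] + rng.normal(0, design.absorbance_noise_sd), 0.0)
        # HPLC contents enter as a provided table (no absorbance inversion)
        for pig in ("lutein", "lycopene", "alpha_carotene", "beta_carotene"):
            row[pig] = d[pig]
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# scene rendering

_CHIP_W, _CHIP_H, _CHIP_GAP = 24, 18, 6
_CHECKER_ORIGIN = (12, 10)  # x, y
_DISK_RADIUS = 15
_DISK_ROW0_Y = 130
_DISK_DY = 42
_DISK_COL0_X = 40
_DISK_DX = 70
_DISKS_PER_ROW = 3
_MAX_IMAGE_HEIGHT = 512
_BACKGROUND = np.array([70.0, 90.0, 150.0])  # blue background


def checker_layout(reference: np.ndarray) -> list:
    x0, y0 = _CHECKER_ORIGIN
    layout = []
    for i in range(24):
        r, c = divmod(i, 6)
        layout.append(
            {
                "chip_id": i + 1,
                "x": x0 + c * (_CHIP_W + _CHIP_GAP),
                "y": y0 + r * (_CHIP_H + _CHIP_GAP),
                "w": _CHIP_W,
                "h": _CHIP_H,
                "reference_srgb": [float(v) for v in reference[i]],
            }
        )
    return layout


def _scene_geometry(n_disks: int):
    rows = int(np.ceil(n_disks / _DISKS_PER_ROW))
    cols = min(n_disks, _DISKS_PER_ROW)
    width = max(200, _DISK_COL0_X + (cols - 1) * _DISK_DX + _DISK_RADIUS + 8)
    x0, y0 = _CHECKER_ORIGIN
    checker_w = 6 * _CHIP_W + 5 * _CHIP_GAP
    checker_h = 4 * _CHIP_H + 3 * _CHIP_GAP
    width = max(width, x0 + checker_w + 8)
    height = _DISK_ROW0_Y + (rows - 1) * _DISK_DY + _DISK_RADIUS + 8
    if _DISK_ROW0_Y - _DISK_RADIUS <= y0 + checker_h:
        raise LayoutError("disks would overlap the colour checker")
    if height > _MAX_IMAGE_HEIGHT:
        raise LayoutError(
            f"cannot place {n_disks} disks without overflowing the scene "
            f"(height {height} > {_MAX_IMAGE_HEIGHT})"
        )
    centres = []
    for i in range(n_disks):
        r, c = divmod(i, _DISKS_PER_ROW)
        centres.append((_DISK_COL0_X + c * _DISK_DX, _DISK_ROW0_Y + r * _DISK_DY))
    return height, width, centres


def roi_polygon_for_disk(centre, radius=_DISK_RADIUS - 4, n_vertices=16) -> np.ndarray:
    ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([centre[0] + radius * np.cos(ang), centre[1] + radius * np.sin(ang)])


def _render_image(
    design: StudyDesign,
    cultivar_disks: pd.DataFrame,
    condition: LightCondition,
    reference: np.ndarray,
    rng: np.random.Generator,
) -> SyntheticImage:
    n = len(cultivar_disks)
    height, width, centres = _scene_geometry(n)
    img = np.empty((height, width, 3), dtype=float)
    img[:] = distort_rgb(_BACKGROUND, condition)

    layout = checker_layout(reference)
    for chip in layout:
        fill = distort_rgb(np.asarray(chip["reference_srgb"]), condition)
        img[chip["y"] : chip["y"] + chip["h"], chip["x"] : chip["x"] + chip["w"]] = fill

    yy, xx = np.mgrid[0:height, 0:width]
    rois, truth = {}, {}
    for (_, d), centre in zip(cultivar_disks.iterrows(), centres):
        lab = np.array([d["L_true"], d["a_true"], d["b_true"]])
        fill = distort_rgb(lab_to_srgb(lab, design.illuminant), condition)
        dist2 = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2
        disk_mask = dist2 <= _DISK_RADIUS**2
        img[disk_mask] = fill
        if condition.glare_amplitude > 0:
            gx, gy = centre[0] + 4, centre[1] - 4
            g2 = (xx - gx) ** 2 + (yy - gy) ** 2
            glare = condition.glare_amplitude * np.exp(-g2 / (2 * 4.0**2))
            img[disk_mask] += glare[disk_mask, None]
        rois[d["disk_id"]] = roi_polygon_for_disk(centre)
        truth[d["disk_id"]] = tuple(lab)

    if design.pixel_noise_sd > 0:
        img += rng.normal(0.0, design.pixel_noise_sd, img.shape)
    # dithered quantisation: keeps region means unbiased at 8 bits
    img += rng.uniform(-0.5, 0.5, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticImage(
        pixels=pixels,
        cultivar=str(cultivar_disks["cultivar"].iloc[0]),
        light_condition=condition.name,
        roi_polygons=rois,
        checker_layout=layout,
        truth_lab=truth,
    )


# ----------------------------------------------------------------------
# top-level generation

def generate_truth(design: StudyDesign) -> pd.DataFrame:
    """Disk-level ground truth (one row per cultivar x replicate)."""
    rng = np.random.default_rng(design.seed)
    return _draw_disks(design, rng)


def generate_study(design: StudyDesign, checker_reference: np.ndarray | None = None):
    """Generate the full synthetic study.

    Returns
    -------
    images : list of SyntheticImage
        One per (light condition, cultivar), each containing
        ``n_replicates`` disks and the 24-chip checker.
    truth : DataFrame
        One row per disk per light condition with ground-truth colour and
        pigment contents (identical biology across conditions of a disk).
    wetlab : DataFrame
        One row per disk: absorbance readings that invert the pigment
        equations, bench factors, and HPLC carotenoid contents.
    """
    if checker_reference is None:
        from .calibration import load_checker_reference

        checker_reference = load_checker_reference()
    rng = np.random.default_rng(design.seed)
    disks = _draw_disks(design, rng)
    wetlab = _wetlab_table(design, disks, rng)
    images = []
    truth_rows = []
    for condition in design.light_conditions:
        for cv in design.cultivars:
            sub = disks[disks["cultivar"] == cv.code]
            images.append(_render_image(design, sub, condition, checker_reference, rng))
            block = sub.copy()
            block.insert(0, "light_condition", condition.name)
            truth_rows.append(block)
    truth = pd.concat(truth_rows, ignore_index=True)
    return images, truth, wetlab
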