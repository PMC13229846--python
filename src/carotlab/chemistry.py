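"""Spectrophotometric pigment quantification and content-based filtering.

Two assays are implemented:

* total carotenoids from acetone-extract absorbances at 662/645/470 nm
  (Lichtenthaler equations), with chlorophyll a/b as intermediates::

      Ca    = 11.75 A662 - 2.35 A645                      [ug/mL]
      Cb    = 18.61 A645 - 3.96 A662                      [ug/mL]
      Cx+c  = (1000 A470 - 2.27 Ca - 81.4 Cb) / 227       [ug/mL]

* total monomeric anthocyanins by the pH-differential method, from
  520/700 nm absorbances at pH 1.0 and pH 4.5::

      A   = (A520 - A700)_{pH 1.0} - (A520 - A700)_{pH 4.5}
      TAC = A * MW * DF * 1000 / EF                       [mg/L]

  with cyanidin-3-glucoside constants MW = 449.2 g/mol and
  EF = 26900 L/(mol cm) as defaults (always explicit parameters).

Assays are run on freeze-dried material; contents are rescaled to fresh
weight (FW) as

    mg/100 g FW = (conc * extract_volume / dry_mass) * (1 - moisture) * 0.1

where ``conc`` is ug/mL (carotenoids) or mg/L / 1000 (anthocyanins), the
bracket is mass of pigment per gram of dry tissue, and the moisture factor
maps dry grams to fresh grams.  All bench factors are explicit inputs so
any bookkeeping convention can be reproduced.

Absorbances are normalised to a 1 cm optical path (A / path_length) before
the equations are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "AbsorbanceReadings",
    "ChlorophyllCarotenoidResult",
    "AnthocyaninAssay",
    "TACResult",
    "lichtenthaler_tcc",
    "ph_differential_tac",
    "apply_content_filters",
    "fresh_weight_factor",
    "PIGMENTS",
    "CYANIDIN_3_GLUCOSIDE_MW",
    "CYANIDIN_3_GLUCOSIDE_EF",
    "CONTENT_THRESHOLD",
    "DETECTION_LIMIT",
]

#: Pigments handled by the filtering rules.
PIGMENTS = ("tcc", "tac", "lutein", "lycopene", "alpha_carotene", "beta_carotene")

CYANIDIN_3_GLUCOSIDE_MW = 449.2  # g/mol
CYANIDIN_3_GLUCOSIDE_EF = 26900.0  # L mol^-1 cm^-1

#: Total-pigment rows below this content (mg/100 g FW) are omitted from modelling.
CONTENT_THRESHOLD = 0.25
#: HPLC device detection limit for individual carotenoids (mg/100 g FW).
DETECTION_LIMIT = 0.025

_NEG_TOL = -1e-9


@dataclass(frozen=True)
class AbsorbanceReadings:
    """Carotenoid-assay absorbances plus the bench factors for FW conversion."""

    A662: float
    A645: float
    A470: float
    path_length_cm: float = 1.0
    extract_volume_mL: float = 10.0
    sample_mass_g: float = 0.05  # freeze-dried mass
    moisture_fraction: float = 0.88

    def __post_init__(self):
        if min(self.A662, self.A645, self.A470) < 0:
            raise ValueError("absorbances must be non-negative")
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be positive")
        if not (0.0 <= self.moisture_fraction < 1.0):
            raise ValueError("moisture_fraction must be in [0, 1)")
        if self.extract_volume_mL <= 0 or self.sample_mass_g <= 0:
            raise ValueError("extract volume and sample mass must be positive")


@dataclass(frozen=True)
class ChlorophyllCarotenoidResult:
    Ca: float  # chlorophyll a, ug/mL
    Cb: float  # chlorophyll b, ug/mL
    Cxc: float  # total carotenoids, ug/mL
    tcc_mg_per_100g_fw: float


@dataclass(frozen=True)
class AnthocyaninAssay:
    """pH-differential absorbances and assay constants."""

    A520_pH1: float
    A700_pH1: float
    A520_pH45: float
    A700_pH45: float
    DF: float = 40.0
    MW: float = CYANIDIN_3_GLUCOSIDE_MW
    EF: float = CYANIDIN_3_GLUCOSIDE_EF
    path_length_cm: float = 1.0

    def __post_init__(self):
        if self.DF < 1:
            raise ValueError("dilution factor DF must be >= 1")
        if self.MW <= 0 or self.EF <= 0:
            raise ValueError("MW and EF must be positive")
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be positive")


@dataclass(frozen=True)
class TACResult:
    tac_mg_per_L: float
    tac_mg_per_100g_fw: float


def fresh_weight_factor(
    extract_volume_mL: float, sample_mass_g: float, moisture_fraction: float
) -> float:
    """Multiplier taking ug/mL of extract to mg/100 g fresh weight."""
    return extract_volume_mL / sample_mass_g * (1.0 - moisture_fraction) * 0.1


def _clamp_small_negative(value: float, what: str) -> float:
    if value < _NEG_TOL:
        raise ValueError(f"negative {what} ({value:.6g}): inconsistent readings")
    return max(value, 0.0)


def lichtenthaler_tcc(readings: AbsorbanceReadings) -> ChlorophyllCarotenoidResult:
    """Total carotenoid concentration and fresh-weight content.

    Chlorophyll a/b and total carotenoids follow the three equations in the
    module docstring; the concentration is converted to mg/100 g FW with
    :func:`fresh_weight_factor`.  A total-carotenoid value below -1e-9
    raises (mutually inconsistent readings); tiny negatives are clamped to
    zero.
    """
    ell = readings.path_length_cm
    A662, A645, A470 = readings.A662 / ell, readings.A645 / ell, readings.A470 / ell
    Ca = 11.75 * A662 - 2.35 * A645
    Cb = 18.61 * A645 - 3.96 * A662
    Ca = _clamp_small_negative(Ca, "chlorophyll a")
    Cb = _clamp_small_negative(Cb, "chlorophyll b")
    Cxc = (1000.0 * A470 - 2.27 * Ca - 81.4 * Cb) / 227.0
    Cxc = _clamp_small_negative(Cxc, "total carotenoid concentration")
    fw = Cxc * fresh_weight_factor(
        readings.extract_volume_mL, readings.sample_mass_g, readings.moisture_fraction
    )
    return ChlorophyllCarotenoidResult(Ca=Ca, Cb=Cb, Cxc=Cxc, tcc_mg_per_100g_fw=fw)


def average_duplicate_assays(assays) -> AnthocyaninAssay:
    """Average duplicate extractions at the absorbance level.

    All non-absorbance constants (DF, MW, EF, path) must agree.
    """
    assays = list(assays)
    first = assays[0]
    for a in assays[1:]:
        if (a.DF, a.MW, a.EF, a.path_length_cm) != (
            first.DF,
            first.MW,
            first.EF,
            first.path_length_cm,
        ):
            raise ValueError("duplicate assays must share DF, MW, EF and path length")
    return replace(
        first,
        A520_pH1=float(np.mean([a.A520_pH1 for a in assays])),
        A700_pH1=float(np.mean([a.A700_pH1 for a in assays])),
        A520_pH45=float(np.mean([a.A520_pH45 for a in assays])),
        A700_pH45=float(np.mean([a.A700_pH45 for a in assays])),
    )


def ph_differential_tac(
    assay,
    sample_mass_g: float,
    extract_volume_mL: float,
    moisture_fraction: float,
) -> TACResult:
    """Total monomeric anthocyanin content from a pH-differential assay.

    ``assay`` may be a single :class:`AnthocyaninAssay` or a sequence of
    duplicate extractions, which are averaged at the absorbance level
    before the differential absorbance is formed.
    """
    if not isinstance(assay, AnthocyaninAssay):
        assay = average_duplicate_assays(assay)
    A = (
        (assay.A520_pH1 - assay.A700_pH1) - (assay.A520_pH45 - assay.A700_pH45)
    ) / assay.path_length_cm
    A = _clamp_small_negative(A, "differential absorbance")
    tac_mg_L = A * assay.MW * assay.DF * 1000.0 / assay.EF
    # mg/L == ug/mL, so the same fresh-weight factor applies directly
    fw = tac_mg_L * fresh_weight_factor(
        extract_volume_mL, sample_mass_g, moisture_fraction
    )
    return TACResult(tac_mg_per_L=tac_mg_L, tac_mg_per_100g_fw=fw)


#: Reason codes emitted by :func:`apply_content_filters`.
REASON_BELOW_THRESHOLD = "below_content_threshold"
REASON_BELOW_DETECTION = "below_detection_limit"
REASON_PURPLE_EXCLUDED = "purple_cultivar_excluded"
REASON_RED_EXCLUDED = "red_cultivar_excluded"
REASON_NOT_MODELLED = "pigment_not_modelled"


def apply_content_filters(
    records: pd.DataFrame,
    pigment: str,
    *,
    content_threshold: float = CONTENT_THRESHOLD,
    detection_limit: float = DETECTION_LIMIT,
    purple_cultivars=("P1", "P2"),
    red_cultivars=("R1",),
):
    """Apply the content/cultivar omission rules before modelling.

    Rules by pigment group:

    * ``tcc`` / ``tac`` — rows below ``content_threshold`` mg/100 g FW are
      removed (guards against false positives from strongly coloured
      cultivars with minimal content).  For ``tac`` the red cultivar is
      additionally excluded (single sample, minimal content).
    * individual carotenoids (``lutein``, ``alpha_carotene``,
      ``beta_carotene``) — fully purple cultivars are excluded; otherwise
      rows are retained down to the HPLC ``detection_limit``.
    * ``lycopene`` — not modelled (present in one cultivar only): all rows
      are dropped.

    Parameters
    ----------
    records : DataFrame
        Must carry a ``cultivar`` column and a column named after
        ``pigment`` holding contents in mg/100 g FW.

    Returns
    -------
    (kept, dropped) : pair of DataFrames
        ``dropped`` carries a ``filter_reason`` column with one reason code
        per removed row (cultivar-level exclusions take precedence over
        content thresholds).
    """
    if pigment not in PIGMENTS:
        raise ValueError(f"unknown pigment {pigment!r}; expected one of {PIGMENTS}")
    if pigment not in records.columns:
        raise ValueError(f"records lack a {pigment!r} content column")
    df = records.copy()
    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    values = df[pigment].astype(float)

    if pigment == "lycopene":
        reason[:] = REASON_NOT_MODELLED
    elif pigment in ("tcc", "tac"):
        if pigment == "tac":
            reason[df["cultivar"].isin(red_cultivars)] = REASON_RED_EXCLUDED
        low = values < content_threshold
        reason[low & reason.isna()] = REASON_BELOW_THRESHOLD
    else:  # individual carotenoids
        reason[df["cultivar"].isin(purple_cultivars)] = REASON_PURPLE_EXCLUDED
        low = values < detection_limit
        reason[low & reason.isna()] = REASON_BELOW_DETECTION

    missing = values.isna()
    reason[missing & reason.isna()] = "content_missing"

    dropped = df[reason.notna()].copy()
    dropped["filter_reason"] = reason[reason.notna()]
    kept = df[reason.isna()].copy()
    return kept, dropped
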