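# Methods

## Colour measurement model

Disk colour is the arithmetic mean of encoded sRGB values (0–255) over a
hand-drawn polygonal region of interest, after chart calibration. A pixel
belongs to the region iff its centre (col + 0.5, row + 0.5) lies inside
the polygon under the even-odd fill rule; the same polygon is applied to
all six light-condition images of a sample, mirroring a macro workflow.
The per-region SD is the population SD (the n vs n−1 distinction is
immaterial at disk pixel counts of several hundred). Peel and background
exclusion is the user's responsibility via polygon placement.

Calibration is fitted **per light condition** in encoded (gamma) sRGB
space on the 0–255 scale — the space chart-calibration plugins operate
in — by unweighted least squares per output channel over a term basis:
`[1, R, G, B]` (linear) or the 10-term quadratic cross-band basis
`[1, R, G, B, R², G², B², RG, RB, GB]`; a linear-light fit space is
available behind the ``fit_space`` flag for distortions that are linear
in scene radiance. Chips are measured as interior
means after trimming a 20% margin per side (rounded to whole pixels).
Quality is the mean CIE76 ΔE\*ab between calibrated and reference chips;
CIE76 is the simplest defensible colour-difference metric and is the
package default (the metric hook is explicit in the API). Quadratic can
never fit worse than linear on the same chips (nested least squares);
both are exposed. Applying a model to an image from a different condition
is allowed but logged as a warning. Out-of-gamut mapped values are
clipped to [0, 255]. No automatic checker localisation is attempted; the
chip layout is supplied as JSON rectangles.

Calibrated means are converted encoded sRGB → linear RGB (standard
piecewise decoding) → XYZ (sRGB primaries) → CIELab. The default
reference white is **D65 with the 10° observer**. Encoded sRGB is defined
against D65/2°, so pure white lands at L\* = 100 but b\* ≈ −0.97 under
the D65/10° white; no chromatic adaptation transform is applied by
default (a diagonal von-Kries-style XYZ scaling to the target white is
available via ``adaptation="xyz_scaling"``), and D65/2° and D55/10° are
selectable. Chroma and hue are C\* = √(a\*² + b\*²) and
h° = atan2(b\*, a\*) in degrees wrapped to [0, 360); at a\* = b\* = 0 the
hue is reported as 0 with an explicit `hue_undefined` flag. Conversion is
delegated to scikit-image; the test suite cross-checks it against an
independently coded matrix pipeline.

## Pigment chemistry

Total carotenoids (µg/mL of extract), with chlorophyll a/b intermediates:

    Ca   = 11.75 A662 − 2.35 A645
    Cb   = 18.61 A645 − 3.96 A662
    Cx+c = (1000 A470 − 2.27 Ca − 81.4 Cb) / 227

Total monomeric anthocyanins by the pH-differential method:

    A   = (A520 − A700)_{pH 1.0} − (A520 − A700)_{pH 4.5}
    TAC = A · MW · DF · 1000 / EF          [mg/L]

Defaults: MW = 449.2 g/mol and EF = 26 900 L mol⁻¹ cm⁻¹
(cyanidin-3-glucoside, the standard constants for this assay), DF = 40.
All constants are explicit parameters, never hard-coded into the
computation. Absorbances are normalised to a 1 cm optical path
(A / path_length, default path 1.0 cm) since microplate well paths vary.
Duplicate anthocyanin extractions are averaged at the absorbance level
before the differential is formed. Tiny negative concentrations
(> −10⁻⁹, floating-point artefacts) are clamped to zero; larger negatives
raise, since they indicate mutually inconsistent readings.

Fresh-weight conversion: assays run on freeze-dried tissue, so

    mg/100 g FW = conc · (V / m_dry) · (1 − moisture) · 0.1

with `conc` in µg/mL (≡ mg/L), extract volume V in mL, dry sample mass
m_dry in g and the cultivar-average moisture fraction. The exact bench
bookkeeping differs between labs, so every factor is an explicit input;
the synthetic generator supplies per-cultivar moisture (0.868–0.895),
and real use requires measured values.

### Content filters

Before modelling, per pigment (threshold values are parameters):

* total carotenoids / anthocyanins: rows < 0.25 mg/100 g FW are dropped
  (`below_content_threshold`) — guards against false positives from
  strongly coloured cultivars with minimal content of the other pigment
  class;
* anthocyanins: the red cultivar is excluded (`red_cultivar_excluded`;
  single sample, minimal content) before the threshold rule;
* individual carotenoids (lutein, α-, β-carotene): fully purple cultivars
  excluded (`purple_cultivar_excluded`); other rows retained down to the
  HPLC detection limit 0.025 mg/100 g (`below_detection_limit`);
* lycopene: not modelled at all (present in one cultivar only).

The filter returns the kept and dropped partitions, the latter with one
reason code per row, so sample counts are conserved and auditable.

## Chemometrics

The predictor matrix is always (L\*, a\*, b\*, C\*, h°) in that fixed
order. Single and multiple linear regressions are provided for
comparison; multiple linear regression standardises predictors so
coefficient magnitudes are comparable across light conditions, reports
t-test stars at 0.05/0.01/0.001 (no multiple-testing correction, matching
field convention), and **fails loudly on exact collinearity**, naming the
dependent columns — the failure mode that motivates PLS here.

PLS is the univariate NIPALS sequence: z-score X and y (SD with ddof = 1);
per component, the weight vector w ∝ Xᵀy_resid maximises covariance
between X-scores and the response residual; X is deflated by t pᵀ after
each component. The standardised coefficients B = W(PᵀW)⁻¹q are
back-transformed to original units with an implicit intercept via
centring, so every fitted model is an explicit 5-coefficient vector plus
intercept. With as many components as predictors, PLS reproduces OLS
exactly; the suite asserts this and cross-checks reduced-rank fits
against scikit-learn's `PLSRegression` (used only as a test oracle).
Latent-path and coefficient-path predictions agree to < 10⁻⁹ by
construction. The default is 5 components (all five colour predictors);
requesting more than the predictor count raises.

Cross-validation: a seeded random permutation splits samples into 10
near-equal segments (no stratification by cultivar); each segment is
predicted from a model calibrated on the other nine, with
**standardisation re-estimated inside every training fold** to avoid
leakage — a choice that slightly raises RMSEP relative to global
standardisation and is therefore stated prominently. Predictions are
reverted to original scale; RMSEP is the RMSE over all held-out
predictions and rRMSEP is RMSEP / mean(observed) × 100 (range-relative is
available behind a flag). Explained variance is reported both as the
squared Pearson correlation of fitted vs observed and as 1 − SSE/SST;
tables carry both.

Published reference coefficient vectors for the colour→pigment models are
shipped as a versioned data file keyed `eq8`–`eq11` and
`table3:<pigment>`. The two printed versions of the total-carotenoid
model under the default light condition disagree (L\* term −1.71 vs
+1.211); both are shipped verbatim and `compare_to_reference` reports
signed deltas, cosine similarity and sign agreement without arbitrating.

## Synthetic study generator

The generator emulates the study the pipeline was designed for: 16
cultivars — white (W1), yellow (Y1, Y2), orange (O1–O9), red (R1), purple
(P1, P2), purple with yellow core (PY1) — × 6 replicate disks × 6 light
conditions (WF−1, WF0, WF+1 without filter; PF0, PF+1, PF+2 polarised,
exposure times 1/25–1/100 s), with a rendered 24-chip checker in every
image and 96 truth rows per condition.

* **Colour**: per-disk CIELab ~ N(cultivar mean, lab SD (2.0, 1.5, 1.5)).
  Cultivar means are hand-set to occupy the four empirical colour
  clusters (white highest L\*, purple low on all parameters, yellow high
  b\*, orange/red high a\*, PY1 among the orange/red group); only this
  qualitative ordering is taken from observation, no numeric values.
* **Pigments**: content = intercept + β·(L\*, a\*, b\*, C\*, h°) + ε, the
  generative inverse of the PLS link. The default β vectors were chosen
  once, by least squares from the cultivar colour anchors to realistic
  per-cultivar content targets (orange ≈ 8–12, red ≈ 15, PY1 ≈ 5, white
  ≈ 0 mg/100 g total carotenoids; purple 35–55, PY1 ≈ 5 anthocyanins),
  and frozen. Noise SDs: 2.2 (TCC) and 11.5 (TAC) mg/100 g — the order of
  the calibration RMSE a field study of this kind reports. Truth values
  are **not clamped at zero** (blank-subtracted assays can read slightly
  negative; clamping would bias link recovery); the absorbance table
  inverts max(content, 0). Individual carotenoids are composition
  fractions of total carotenoids (58% β-, 16% α-carotene, 4% lutein with
  a +0.45 mg bonus for PY1; lycopene 1.66 mg only in the red cultivar)
  plus noise — deliberately *not* part of the linear link.
* **Wet lab**: absorbances are the analytic inverse of the pigment
  equations (chlorophyll-free by default; a chlorophyll-bearing inversion
  solves the 2 × 2 system), so the chemistry stage recovers the truth to
  < 10⁻⁹ relative error at zero absorbance noise (the default; an SD
  parameter exists for robustness tests). Anthocyanin assays exist only
  for the anthocyanin-bearing cultivars (6 samples for P1 and PY1, 3 for
  P2, 1 for R1), reproducing realistic assay availability.
* **Distortion**: per-channel gain 2^(step·k) applied in linear light
  (k = 0.3 stops/step default) with a small per-environment channel tint
  and encoded-space offset — the simplest model that makes per-condition
  calibration necessary — plus a Gaussian specular-glare highlight on
  each disk (amplitude 22 encoded units, σ = 4 px) for unpolarised (WF)
  conditions only; polarisation suppresses specular reflection, so PF
  glare is fixed at 0 and validated. Glare strictly raises mean disk
  L\*, matching the physics it emulates.
* **Rendering**: disks are flat-filled circles (radius 15 px) with
  optional pixel texture noise (SD 1.2) and *dithered* 8-bit
  quantisation, keeping region means unbiased; scenes are ~200 × 220 px.
  A fixed design seed makes every image byte and table value
  reproducible. Overfull layouts (disks that would not fit the scene)
  raise a layout error rather than overlapping.

What the generator does **not** emulate: carrot texture and radial
pigment gradients, peel/background segmentation difficulty, camera
optics (vignetting, chromatic aberration, demosaicing), specular shape
variety, and illuminant spectra (the D55-acquisition / D65-conversion
mismatch of real studies appears only as the documented white-point
choice). Passing tests therefore demonstrate correctness of the
computational chain and recoverability under the stated generative
assumptions — not field performance on real roots.

## Problem sizes and numerical choices

The default test/acceptance problem sizes are one full study (96 disks ×
6 conditions, ~200 × 220 px scenes), 50 simulated studies for link
recovery, 20 for RMSEP calibration, and 200 random 30 × 5 designs for
the PLS = OLS limit — sizes at which every statistical check is stable
yet the whole suite runs in seconds. Rank deficiency is detected via
matrix rank with NumPy defaults; NIPALS stops early if the residual
covariance norm falls below 10⁻¹²; ΔE and coefficient identities are
asserted at 10⁻⁶–10⁻⁹ as appropriate to double precision. CV fold
assignment uses a seeded shuffled K-fold; the seed is a required, logged
parameter everywhere randomness exists.

## Known limitations

* Real-image ingestion expects pre-existing ROI polygons and a chip
  layout; there is no automatic checker or disk detection.
* The anthocyanin fresh-weight conversion assumes the same dry-mass
  bookkeeping as the carotenoid assay; labs using fresh-tissue extraction
  should set moisture = 0 and pass fresh mass.
* CIE76 ΔE understates perceptual differences in saturated regions
  compared to CIEDE2000 (out of scope).
* PLS here is univariate (one pigment per model); multiblock or kernel
  variants are out of scope.
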