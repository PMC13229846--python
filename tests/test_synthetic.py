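"""Synthetic study generator: determinism, inversion, rendering physics."""

import numpy as np
import pytest

from carotlab.calibration import fit_calibration, measure_chips
from carotlab.chemistry import (
    AbsorbanceReadings,
    AnthocyaninAssay,
    lichtenthaler_tcc,
    ph_differential_tac,
)
from carotlab.chemometrics import fit_pls
from carotlab.colours import delta_e_cie76, srgb_to_lab
from carotlab.roi import rasterise_polygon, roi_colour
from carotlab.synthetic import (
    DEFAULT_PIGMENT_LINKS,
    CultivarSpec,
    LayoutError,
    LightCondition,
    StudyDesign,
    default_design,
    generate_study,
    generate_truth,
    identity_conditions,
    invert_pigment_equations,
)


def small_design(**kw):
    kw.setdefault("seed", 3)
    kw.setdefault("n_replicates", 2)
    return StudyDesign(**kw)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        out1 = generate_study(small_design())
        out2 = generate_study(small_design())
        for a, b in zip(out1[0], out2[0]):
            assert np.array_equal(a.pixels, b.pixels)
        assert out1[1].equals(out2[1])
        assert out1[2].equals(out2[2])

    def test_different_seed_differs(self):
        t1 = generate_truth(default_design(seed=1))
        t2 = generate_truth(default_design(seed=2))
        assert not np.allclose(t1["tcc"], t2["tcc"])


class TestStudyShape:
    def test_96_truth_rows_per_light_condition(self):
        _, truth, _ = generate_study(default_design(seed=0))
        counts = truth.groupby("light_condition").size()
        assert (counts == 96).all() and len(counts) == 6

    def test_one_image_per_cultivar_condition(self):
        images, _, _ = generate_study(small_design())
        assert len(images) == 16 * 6
        im = images[0]
        assert im.pixels.dtype == np.uint8
        assert len(im.roi_polygons) == 2
        assert len(im.checker_layout) == 24

    def test_rois_inside_image_bounds(self):
        images, _, _ = generate_study(small_design())
        h, w, _ = images[0].pixels.shape
        for poly in images[0].roi_polygons.values():
            assert (poly[:, 0] > 0).all() and (poly[:, 0] < w).all()
            assert (poly[:, 1] > 0).all() and (poly[:, 1] < h).all()

    def test_layout_overflow_raises(self):
        with pytest.raises(LayoutError):
            generate_study(StudyDesign(seed=0, n_replicates=40))


class TestValidation:
    def test_pf_glare_must_be_zero(self):
        with pytest.raises(ValueError, match="glare"):
            LightCondition("PF0", "PF", 0, 1 / 100, glare_amplitude=5.0)

    def test_name_must_encode_environment_and_step(self):
        with pytest.raises(ValueError, match="name"):
            LightCondition("WF0", "WF", 1, 1 / 100)

    def test_exposure_time_whitelist(self):
        with pytest.raises(ValueError, match="exposure_time"):
            LightCondition("WF0", "WF", 0, 1 / 10)

    def test_cultivar_invariants(self):
        with pytest.raises(ValueError, match="lab_sd"):
            CultivarSpec("X1", "orange", (50, 30, 40), lab_sd=(-1, 1, 1))
        with pytest.raises(ValueError, match="colour_group"):
            CultivarSpec("X1", "chartreuse", (50, 30, 40))


class TestInversion:
    def test_chlorophyll_free_inverse_of_carotenoid_equation(self):
        tcc_r, _, flags = invert_pigment_equations({"tcc": 5.0}, moisture_fraction=0.88)
        assert flags == []
        cxc = 5.0 / (10.0 / 0.05 * 0.12 * 0.1)
        assert tcc_r["A470"] == pytest.approx(227.0 * cxc / 1000.0)
        assert tcc_r["A662"] == 0.0 and tcc_r["A645"] == 0.0

    def test_zero_anthocyanin_target_balances_ph_readings(self):
        _, tac_r, _ = invert_pigment_equations(
            {"tcc": 1.0, "tac": 0.0}, moisture_fraction=0.88
        )
        d1 = tac_r["A520_pH1"] - tac_r["A700_pH1"]
        d45 = tac_r["A520_pH45"] - tac_r["A700_pH45"]
        assert d1 == pytest.approx(d45)

    def test_forward_inverse_round_trip_100_draws(self, rng):
        for _ in range(100):
            panel = {"tcc": rng.uniform(0, 25), "tac": rng.uniform(0, 90)}
            moisture = rng.uniform(0.80, 0.93)
            tcc_r, tac_r, flags = invert_pigment_equations(panel, moisture_fraction=moisture)
            assert flags == []
            got_tcc = lichtenthaler_tcc(AbsorbanceReadings(**tcc_r)).tcc_mg_per_100g_fw
            assay = AnthocyaninAssay(
                A520_pH1=tac_r["A520_pH1"],
                A700_pH1=tac_r["A700_pH1"],
                A520_pH45=tac_r["A520_pH45"],
                A700_pH45=tac_r["A700_pH45"],
                DF=tac_r["DF"],
                MW=tac_r["MW"],
                EF=tac_r["EF"],
                path_length_cm=tac_r["tac_path_length_cm"],
            )
            got_tac = ph_differential_tac(
                assay,
                sample_mass_g=tac_r["tac_sample_mass_g"],
                extract_volume_mL=tac_r["tac_extract_volume_mL"],
                moisture_fraction=moisture,
            ).tac_mg_per_100g_fw
            assert abs(got_tcc - panel["tcc"]) < 1e-9 * max(1.0, panel["tcc"])
            assert abs(got_tac - panel["tac"]) < 1e-9 * max(1.0, panel["tac"])

    def test_chlorophyll_targets_invertible(self):
        tcc_r, _, flags = invert_pigment_equations(
            {"tcc": 3.0}, moisture_fraction=0.88, chlorophyll_a=2.0, chlorophyll_b=1.0
        )
        assert flags == []
        res = lichtenthaler_tcc(AbsorbanceReadings(**tcc_r))
        assert res.Ca == pytest.approx(2.0) and res.Cb == pytest.approx(1.0)
        assert res.tcc_mg_per_100g_fw == pytest.approx(3.0)

    def test_negative_target_flagged_and_clamped(self):
        tcc_r, _, flags = invert_pigment_equations({"tcc": -0.4}, moisture_fraction=0.88)
        assert "tcc_target_negative_clamped" in flags
        assert lichtenthaler_tcc(AbsorbanceReadings(**tcc_r)).tcc_mg_per_100g_fw == 0.0


def _extract_disk_labs(design, images, calibrate=True):
    """Forward chain: checker calibration -> ROI means -> Lab."""
    out = {}
    for im in images:
        img = im.pixels.astype(float)
        if calibrate:
            model = fit_calibration(measure_chips(img, im.checker_layout, 0.2))
            img = model.transform_image(img)
        for disk_id, poly in im.roi_polygons.items():
            mask = rasterise_polygon(poly, img.shape[:2])
            meas = roi_colour(img, mask)
            out[(im.light_condition, disk_id)] = srgb_to_lab(
                np.clip(meas.mean_rgb, 0, 255), design.illuminant
            )
    return out


class TestRenderingPhysics:
    def test_noiseless_identity_round_trip_recovers_true_lab(self):
        design = StudyDesign(
            seed=5,
            n_replicates=2,
            light_conditions=identity_conditions()[:2],
            colour_noise_sd=0.0,
            pigment_noise_sd={},
            pixel_noise_sd=0.0,
        )
        images, truth, _ = generate_study(design)
        labs = _extract_disk_labs(design, images, calibrate=False)
        for im in images:
            for disk_id, true_lab in im.truth_lab.items():
                got = labs[(im.light_condition, disk_id)]
                assert delta_e_cie76(got, np.asarray(true_lab)) < 0.5

    def test_noiseless_pipeline_recovers_generative_link(self):
        # forward chain through rendered images + calibration; the fitted
        # PLS must recover the generative colour -> pigment coefficients
        design = StudyDesign(
            seed=6,
            n_replicates=3,
            light_conditions=identity_conditions()[:1],
            pigment_noise_sd={},
            pixel_noise_sd=0.5,
        )
        images, truth, _ = generate_study(design)
        labs = _extract_disk_labs(design, images)
        cond = design.light_conditions[0].name
        rows, y = [], []
        sub = truth[truth["light_condition"] == cond]
        for _, r in sub.iterrows():
            L, a, b = labs[(cond, r["disk_id"])]
            rows.append([L, a, b, np.hypot(a, b), np.degrees(np.arctan2(b, a)) % 360])
            y.append(r["tcc"])
        X, y = np.asarray(rows), np.asarray(y)
        model = fit_pls(X, y, n_components=5)
        pred = model.predict(X)
        ss = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss > 0.99
        gen = np.asarray(DEFAULT_PIGMENT_LINKS["tcc"][1])
        cos = model.coef_ @ gen / (np.linalg.norm(model.coef_) * np.linalg.norm(gen))
        assert cos > 0.99

    def test_glare_strictly_raises_mean_lightness(self):
        base = dict(seed=9, n_replicates=2, colour_noise_sd=0.0, pixel_noise_sd=0.0)
        mean_L = []
        for amp in (0.0, 8.0, 16.0, 24.0):
            cond = LightCondition("WF0", "WF", 0, 1 / 50, glare_amplitude=amp)
            design = StudyDesign(light_conditions=[cond], **base)
            images, _, _ = generate_study(design)
            labs = _extract_disk_labs(design, images[:4], calibrate=False)
            mean_L.append(np.mean([v[0] for v in labs.values()]))
        assert all(b > a for a, b in zip(mean_L, mean_L[1:]))

    def test_cross_condition_consistency_after_calibration(self):
        # per-condition calibration brings disk colours of the six distorted
        # conditions into agreement (median over disks < 2 delta-E)
        design = StudyDesign(seed=12, n_replicates=2)
        images, _, _ = generate_study(design)
        labs = _extract_disk_labs(design, images)
        conds = [c.name for c in design.light_conditions]
        deltas = []
        for disk_id in {d for (_c, d) in labs}:
            per_cond = np.array([labs[(c, disk_id)] for c in conds])
            centre = per_cond.mean(axis=0)
            deltas.extend(delta_e_cie76(per_cond, centre))
        assert np.median(deltas) < 2.0
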