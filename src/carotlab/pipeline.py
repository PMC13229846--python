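"""End-to-end orchestration: images -> calibrated colours -> pigments -> models.

Stage order mirrors the study workflow: simulate (or ingest) images, fit a
checker calibration per light condition, extract ROI colours from
calibrated images, convert to CIELab/LCh, compute pigment contents from
the wet-lab table, merge, apply the content filters, fit the model grid,
and emit report tables.  Every stage reads and writes plain CSV/JSON/PNG
so stages are independently runnable and auditable; a manifest records the
seed, per-stage row counts and the per-condition calibration mean Delta-E.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import chemistry, chemometrics, synthetic
from .calibration import CheckerCalibrator, load_checker_reference, measure_chips
from .colours import get_illuminant, lab_to_lch, srgb_to_lab
from .roi import load_rois, rasterise_polygon, roi_colour, save_rois

__all__ = ["PipelineConfig", "run_pipeline", "summarise_contents"]

logger = logging.getLogger(__name__)

DEFAULT_PIGMENTS = ("tcc", "tac")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serialisable)."""

    mode: str = "synthetic"  # synthetic | real
    seed: int = 0
    output_dir: str = "out"
    # real-mode inputs
    images_dir: str | None = None
    rois_path: str | None = None
    checker_layout_path: str | None = None
    wetlab_path: str | None = None
    condition_map_path: str | None = None  # image filename -> condition name
    # analysis parameters
    illuminant: str = "D65_10"
    calibration_method: str = "quadratic_cross_band"
    chip_margin_fraction: float = 0.2
    pigments: tuple = DEFAULT_PIGMENTS
    model_types: tuple = ("pls", "multiple_linear")
    n_components: int = 5
    n_cv_segments: int = 10
    content_threshold: float = chemistry.CONTENT_THRESHOLD
    detection_limit: float = chemistry.DETECTION_LIMIT
    # synthetic design overrides
    n_replicates: int = 6
    colour_noise_sd: float | None = None
    identity_distortion: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be synthetic or real, got {cfg.mode!r}")
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["pigments"] = list(self.pigments)
        d["model_types"] = list(self.model_types)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def build_design(self) -> synthetic.StudyDesign:
        conditions = (
            synthetic.identity_conditions()
            if self.identity_distortion
            else synthetic.default_conditions()
        )
        return synthetic.StudyDesign(
            seed=self.seed,
            n_replicates=self.n_replicates,
            colour_noise_sd=self.colour_noise_sd,
            light_conditions=conditions,
            illuminant=get_illuminant(self.illuminant),
        )


# ----------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    """Generate and persist the synthetic study."""
    design = config.build_design()
    images, truth, wetlab = synthetic.generate_study(design)
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    condition_map = {}
    rois = {}
    layout = None
    for im in images:
        fname = f"{im.light_condition}_{im.cultivar}.png"
        Image.fromarray(im.pixels).save(img_dir / fname)
        condition_map[fname] = im.light_condition
        rois.update({k: v for k, v in im.roi_polygons.items()})
        layout = im.checker_layout
    save_rois(rois, outdir / "rois.json")
    with open(outdir / "checker_layout.json", "w") as fh:
        json.dump(layout, fh)
    with open(outdir / "condition_map.json", "w") as fh:
        json.dump(condition_map, fh, indent=0)
    truth.to_csv(outdir / "truth.csv", index=False)
    wetlab.to_csv(outdir / "wetlab.csv", index=False)
    logger.info("simulated %d images, %d truth rows", len(images), len(truth))
    return {"n_images": len(images), "n_truth_rows": len(truth), "n_wetlab_rows": len(wetlab)}


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Resolve stage-input paths (synthetic outputs or real-mode paths)."""
    if config.mode == "synthetic":
        return {
            "images_dir": outdir / "images",
            "rois": outdir / "rois.json",
            "layout": outdir / "checker_layout.json",
            "wetlab": outdir / "wetlab.csv",
            "condition_map": outdir / "condition_map.json",
        }
    paths = {
        "images_dir": config.images_dir,
        "rois": config.rois_path,
        "layout": config.checker_layout_path,
        "wetlab": config.wetlab_path,
        "condition_map": config.condition_map_path,
    }
    for key, p in paths.items():
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"real mode requires existing {key} path (got {p})")
    return {k: Path(v) for k, v in paths.items()}


def stage_calibrate(config: PipelineConfig, outdir: Path) -> dict:
    """Fit one checker calibration per light condition."""
    inputs = _load_inputs(config, outdir)
    with open(inputs["layout"]) as fh:
        layout = json.load(fh)
    with open(inputs["condition_map"]) as fh:
        condition_map = json.load(fh)
    reference = np.array(
        [c.get("reference_srgb") for c in sorted(layout, key=lambda c: c["chip_id"])],
        dtype=float,
    ) if all("reference_srgb" in c for c in layout) else load_checker_reference()

    by_condition = {}
    for fname, cond in sorted(condition_map.items()):
        img = np.asarray(Image.open(inputs["images_dir"] / fname))
        meas = measure_chips(img, layout, config.chip_margin_fraction, reference=reference)
        by_condition.setdefault(cond, []).append([m.measured_rgb for m in meas])

    cal_dir = outdir / "calibration"
    cal_dir.mkdir(parents=True, exist_ok=True)
    deltas = {}
    for cond, chip_sets in sorted(by_condition.items()):
        measured = np.mean(np.asarray(chip_sets, dtype=float), axis=0)
        model = CheckerCalibrator(
            method=config.calibration_method, illuminant=config.illuminant
        ).fit(measured, reference, light_condition=cond)
        model.save(cal_dir / f"calibration_{cond}.json")
        deltas[cond] = model.mean_delta_
        logger.info("calibration %s: mean delta-E %.3f", cond, model.mean_delta_)
    return {"mean_delta_e": deltas}


def stage_extract(config: PipelineConfig, outdir: Path) -> dict:
    """ROI colour means from calibrated images."""
    inputs = _load_inputs(config, outdir)
    rois = load_rois(inputs["rois"])
    with open(inputs["condition_map"]) as fh:
        condition_map = json.load(fh)
    cal_dir = outdir / "calibration"
    rows = []
    for fname, cond in sorted(condition_map.items()):
        img = np.asarray(Image.open(inputs["images_dir"] / fname), dtype=float)
        model = CheckerCalibrator.load(cal_dir / f"calibration_{cond}.json")
        calibrated = model.transform_image(img, light_condition=cond)
        cultivar = Path(fname).stem.split("_", 1)[1]
        disk_ids = [k for k in rois if k.startswith(cultivar + "-")]
        if not disk_ids:
            raise FileNotFoundError(f"no ROI polygons found for sample {cultivar!r} ({fname})")
        for disk_id in sorted(disk_ids, key=lambda s: int(s.rsplit("-", 1)[1])):
            mask = rasterise_polygon(rois[disk_id], calibrated.shape[:2])
            meas = roi_colour(calibrated, mask)
            rows.append(
                {
                    "disk_id": disk_id,
                    "cultivar": cultivar,
                    "replicate": int(disk_id.rsplit("-", 1)[1]),
                    "light_condition": cond,
                    "mean_R": meas.mean_rgb[0],
                    "mean_G": meas.mean_rgb[1],
                    "mean_B": meas.mean_rgb[2],
                    "sd_R": meas.sd_rgb[0],
                    "sd_G": meas.sd_rgb[1],
                    "sd_B": meas.sd_rgb[2],
                    "n_pixels": meas.n_pixels,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "colours.csv", index=False)
    return {"n_colour_rows": len(df)}


def stage_convert(config: PipelineConfig, outdir: Path) -> dict:
    """Append CIELab and LCh columns to the colour table."""
    df = pd.read_csv(outdir / "colours.csv")
    rgb = df[["mean_R", "mean_G", "mean_B"]].to_numpy(dtype=float)
    lab = srgb_to_lab(np.clip(rgb, 0.0, 255.0), get_illuminant(config.illuminant))
    C, h = lab_to_lch(lab)
    df["L_star"], df["a_star"], df["b_star"] = lab[:, 0], lab[:, 1], lab[:, 2]
    df["C_star"], df["h_deg"] = C, h
    df.to_csv(outdir / "colours.csv", index=False)
    return {"n_colour_rows": len(df)}


def stage_quantify(config: PipelineConfig, outdir: Path) -> dict:
    """Pigment contents (mg/100 g FW) from the wet-lab absorbance table."""
    inputs = _load_inputs(config, outdir)
    wetlab = pd.read_csv(inputs["wetlab"])
    rows = []
    for _, r in wetlab.iterrows():
        readings = chemistry.AbsorbanceReadings(
            A662=r["A662"],
            A645=r["A645"],
            A470=r["A470"],
            path_length_cm=r.get("path_length_cm", 1.0),
            extract_volume_mL=r["extract_volume_mL"],
            sample_mass_g=r["sample_mass_g"],
            moisture_fraction=r["moisture_fraction"],
        )
        res = chemistry.lichtenthaler_tcc(readings)
        row = {
            "disk_id": r["disk_id"],
            "cultivar": r["cultivar"],
            "replicate": r["replicate"],
            "tcc": res.tcc_mg_per_100g_fw,
        }
        if "A520_pH1" in r and pd.notna(r["A520_pH1"]):
            assay = chemistry.AnthocyaninAssay(
                A520_pH1=r["A520_pH1"],
                A700_pH1=r["A700_pH1"],
                A520_pH45=r["A520_pH45"],
                A700_pH45=r["A700_pH45"],
                DF=r["DF"],
                MW=r["MW"],
                EF=r["EF"],
                path_length_cm=r.get("tac_path_length_cm", 1.0),
            )
            row["tac"] = chemistry.ph_differential_tac(
                assay,
                sample_mass_g=r["tac_sample_mass_g"],
                extract_volume_mL=r["tac_extract_volume_mL"],
                moisture_fraction=r["moisture_fraction"],
            ).tac_mg_per_100g_fw
        else:
            row["tac"] = np.nan
        for pig in ("lutein", "lycopene", "alpha_carotene", "beta_carotene"):
            row[pig] = r.get(pig, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "contents.csv", index=False)
    return {"n_content_rows": len(df)}


def stage_model(config: PipelineConfig, outdir: Path) -> dict:
    """Fit the model grid on the merged colour + content table."""
    colours = pd.read_csv(outdir / "colours.csv")
    contents = pd.read_csv(outdir / "contents.csv")
    merged = colours.merge(
        contents.drop(columns=["cultivar", "replicate"]), on="disk_id", how="left"
    )
    merged.to_csv(outdir / "samples.csv", index=False)

    reports = []
    dropped_logs = []
    models_dir = outdir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for pigment in config.pigments:
        for cond, sub in merged.groupby("light_condition", sort=True):
            kept, dropped = chemistry.apply_content_filters(
                sub,
                pigment,
                content_threshold=config.content_threshold,
                detection_limit=config.detection_limit,
            )
            if not dropped.empty:
                log = dropped[["disk_id", "cultivar", "light_condition", "filter_reason"]].copy()
                log["pigment"] = pigment
                dropped_logs.append(log)
            counts[f"{pigment}/{cond}"] = {"in": len(sub), "kept": len(kept)}
            if len(kept) <= config.n_cv_segments or len(kept) <= config.n_components + 1:
                logger.warning("skipping %s under %s: only %d usable rows", pigment, cond, len(kept))
                continue
            X = chemometrics.predictor_matrix(kept)
            y = kept[pigment].to_numpy(dtype=float)
            if "pls" in config.model_types:
                report, model = chemometrics.report_pls(
                    X,
                    y,
                    pigment=pigment,
                    light_condition=cond,
                    n_components=config.n_components,
                    n_segments=config.n_cv_segments,
                    seed=config.seed,
                )
                reports.append(report)
                with open(models_dir / f"pls_{pigment}_{cond}.json", "w") as fh:
                    json.dump(model.to_dict(), fh, indent=1)
            if "multiple_linear" in config.model_types:
                try:
                    reports.append(
                        chemometrics.fit_multiple_linear(
                            X, y, pigment=pigment, light_condition=cond
                        )
                    )
                except np.linalg.LinAlgError as exc:
                    logger.warning("multiple linear %s/%s failed: %s", pigment, cond, exc)
    pd.DataFrame([r.to_dict() for r in reports]).to_csv(outdir / "reports.csv", index=False)
    filtered = (
        pd.concat(dropped_logs, ignore_index=True)
        if dropped_logs
        else pd.DataFrame(columns=["disk_id", "cultivar", "light_condition", "filter_reason", "pigment"])
    )
    filtered.to_csv(outdir / "filtered_samples.csv", index=False)
    with open(outdir / "model_reports.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1)
    return {"n_reports": len(reports), "row_counts": counts, "n_filtered_rows": len(filtered)}


def stage_report(config: PipelineConfig, outdir: Path) -> dict:
    """Emit the report-table grids as CSV and markdown."""
    with open(outdir / "model_reports.json") as fh:
        raw = json.load(fh)
    reports = [chemometrics.ModelReport(**r) for r in raw]
    tables = chemometrics.build_report_tables(reports)
    for name, df in tables.items():
        df.to_csv(outdir / f"table_{name}.csv", index=False)
    (outdir / "report.md").write_text(chemometrics.tables_to_markdown(tables))
    return {"tables": {k: len(v) for k, v in tables.items()}}


_STAGES = {
    "simulate": stage_simulate,
    "calibrate": stage_calibrate,
    "extract": stage_extract,
    "convert": stage_convert,
    "quantify": stage_quantify,
    "model": stage_model,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in order and write a manifest.

    ``stages=None`` runs the full sequence (``simulate`` is skipped in
    real mode).  Returns the manifest dict.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(_STAGES)
        if config.mode == "real":
            stages.remove("simulate")
    manifest = {"seed": config.seed, "mode": config.mode, "stages": {}}
    for name in stages:
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        logger.info("stage %s", name)
        manifest["stages"][name] = _STAGES[name](config, outdir)
    config.to_yaml(outdir / "config_used.yaml")
    manifest["output_checksums"] = _checksums(outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _checksums(outdir: Path) -> dict:
    out = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            out[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return out


def summarise_contents(records: pd.DataFrame, pigments=None) -> pd.DataFrame:
    """Per-cultivar descriptive statistics (mean, sample SD, min, max)."""
    pigments = list(pigments or [p for p in chemistry.PIGMENTS if p in records.columns])
    rows = []
    for cultivar, sub in records.groupby("cultivar", sort=True):
        for pig in pigments:
            vals = sub[pig].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append(
                {
                    "cultivar": cultivar,
                    "pigment": pig,
                    "n": vals.size,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows, columns=["cultivar", "pigment", "n", "mean", "sd", "min", "max"])
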